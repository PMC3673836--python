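"""Per-window heterozygosity density with duplication masking.

The genome is tiled into non-overlapping 1-Mbp windows (the last window
of a chromosome may be short).  Windows overlapping segmental
duplications by more than 40% of their length are discarded, and in the
remaining windows the heterozygous-site count is corrected by the
effective (unmasked) bases: sites inside masked sub-intervals are
excluded from the numerator and masked bases from the denominator, so
the density is het sites per kbp of effective sequence.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .genome import GenomeBuild

logger = logging.getLogger(__name__)

WINDOW_COLUMNS = [
    "chrom", "start", "end", "het_count", "effective_bases",
    "het_per_kbp", "masked_out",
]


def tile_windows(build: GenomeBuild, window_size: int = 1_000_000) -> pd.DataFrame:
    """Tile each chromosome exactly with consecutive windows."""
    if window_size <= 0:
        raise ValueError("window_size must be positive")
    chroms, starts, ends = [], [], []
    for name, length in build.chromosomes:
        edges = np.arange(0, length, window_size, dtype=np.int64)
        chroms.extend([name] * len(edges))
        starts.append(edges)
        ends.append(np.minimum(edges + window_size, length))
    df = pd.DataFrame(
        {
            "chrom": pd.Categorical(chroms, categories=build.names, ordered=True),
            "start": np.concatenate(starts),
            "end": np.concatenate(ends),
        }
    )
    df["het_count"] = 0
    df["effective_bases"] = df["end"] - df["start"]
    df["het_per_kbp"] = np.nan
    df["masked_out"] = False
    return df


def _merge_intervals(starts: np.ndarray, ends: np.ndarray):
    """Sort and merge possibly-overlapping intervals on one chromosome."""
    if len(starts) == 0:
        return starts, ends
    order = np.argsort(starts, kind="stable")
    s, e = starts[order], ends[order]
    out_s, out_e = [s[0]], [e[0]]
    for a, b in zip(s[1:], e[1:]):
        if a <= out_e[-1]:
            out_e[-1] = max(out_e[-1], b)
        else:
            out_s.append(a)
            out_e.append(b)
    return np.asarray(out_s, dtype=np.int64), np.asarray(out_e, dtype=np.int64)


def _overlap_with_mask(qs, qe, ms, me):
    """Total masked bases inside each query interval.

    ``ms``/``me`` are merged, sorted mask intervals; overlap is computed
    from the cumulative mask coverage evaluated at the query bounds.
    """
    if len(ms) == 0:
        return np.zeros(len(qs), dtype=np.int64)
    cum = np.concatenate([[0], np.cumsum(me - ms)])

    def coverage(x):
        # mask bases strictly before position x
        i = np.searchsorted(ms, x, side="right")  # intervals starting before x
        partial = np.clip(x - ms[i - 1], 0, (me - ms)[i - 1]) * (i > 0)
        return cum[np.maximum(i - 1, 0)] + partial

    return (coverage(qe) - coverage(qs)).astype(np.int64)


def mask_windows(
    windows: pd.DataFrame,
    dup_mask: pd.DataFrame,
    max_overlap: float = 0.40,
) -> pd.DataFrame:
    """Flag windows whose duplication overlap exceeds ``max_overlap``.

    The criterion is strict: a window with exactly 40.0% overlap is
    retained.  Surviving windows get ``effective_bases`` = window length
    minus the masked overlap.
    """
    if not 0 <= max_overlap < 1:
        raise ValueError("max_overlap must be in [0, 1)")
    if len(dup_mask) and (dup_mask["end"] <= dup_mask["start"]).any():
        raise ValueError("malformed mask interval: end <= start")
    out = windows.copy()
    out["masked_out"] = False
    out["effective_bases"] = out["end"] - out["start"]
    for chrom, grp in out.groupby("chrom", sort=False, observed=True):
        sub = dup_mask[dup_mask["chrom"] == chrom]
        ms, me = _merge_intervals(
            sub["start"].to_numpy(np.int64), sub["end"].to_numpy(np.int64)
        )
        ov = _overlap_with_mask(
            grp["start"].to_numpy(np.int64), grp["end"].to_numpy(np.int64), ms, me
        )
        wlen = (grp["end"] - grp["start"]).to_numpy(np.int64)
        masked = ov / wlen > max_overlap
        out.loc[grp.index, "masked_out"] = masked
        out.loc[grp.index, "effective_bases"] = np.where(masked, 0, wlen - ov)
    out.loc[out["masked_out"], "het_per_kbp"] = np.nan
    return out


def count_het(
    windows: pd.DataFrame,
    variants: pd.DataFrame,
    dup_mask: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Count heterozygous sites per window and derive the density.

    ``variants`` needs ``chrom``/``pos`` columns (0-based positions) and,
    if present, a ``gt`` column from which only heterozygous records are
    kept.  Sites inside masked sub-intervals of retained windows are
    excluded, consistent with the effective-base correction.  Variants on
    chromosomes absent from the window track are skipped with a warning.
    """
    out = windows.copy()
    out["het_count"] = 0
    if "gt" in variants.columns:
        variants = variants[variants["gt"] == "het"]
    known = set(out["chrom"].astype(str))
    unknown = ~variants["chrom"].astype(str).isin(known)
    if unknown.any():
        logger.warning(
            "skipping %d heterozygous sites on chromosomes absent from the window track",
            int(unknown.sum()),
        )
        variants = variants[~unknown]
    for chrom, grp in out.groupby("chrom", sort=False, observed=True):
        pos = variants.loc[variants["chrom"].astype(str) == str(chrom), "pos"].to_numpy(
            np.int64
        )
        if dup_mask is not None and len(pos):
            sub = dup_mask[dup_mask["chrom"] == chrom]
            ms, me = _merge_intervals(
                sub["start"].to_numpy(np.int64), sub["end"].to_numpy(np.int64)
            )
            if len(ms):
                i = np.searchsorted(ms, pos, side="right") - 1
                in_mask = (i >= 0) & (pos < me[np.maximum(i, 0)])
                pos = pos[~in_mask]
        ws = grp["start"].to_numpy(np.int64)
        we = grp["end"].to_numpy(np.int64)
        idx = np.searchsorted(ws, pos, side="right") - 1
        ok = (idx >= 0) & (pos < we[np.maximum(idx, 0)])
        counts = np.bincount(idx[ok], minlength=len(grp))
        out.loc[grp.index, "het_count"] = counts
    eff = out["effective_bases"].to_numpy(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        dens = 1000.0 * out["het_count"].to_numpy(float) / eff
    dens[eff == 0] = np.nan
    out["het_per_kbp"] = dens
    out.loc[out["masked_out"], "het_per_kbp"] = np.nan
    return out


def write_windows_tsv(windows: pd.DataFrame, path) -> None:
    windows.to_csv(path, sep="\t", index=False, columns=WINDOW_COLUMNS)


def read_windows_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = set(WINDOW_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"windows TSV missing columns: {sorted(missing)}")
    return df
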