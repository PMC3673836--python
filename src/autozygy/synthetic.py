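"""Synthetic inputs for every pipeline stage.

The generator emulates a highly inbred great-ape autosomal genome on
the GRCh37 coordinate frame: heterozygous sites are a homogeneous
Poisson process at a background density outside planted autozygous
tracts and at a strongly reduced density inside them; a segmental
duplication mask covers a configurable fraction of the genome; and an
annotated variant table plants exactly one homozygous non-synonymous
causal variant inside a candidate hypopigmentation gene, private
against a panel of comparison genomes.

Defaults describe the study system this package models: 25 autozygous
tracts totalling 306 Mbp (largest 68 Mbp on chr4; a 40 Mbp tract on
chr5 containing the SLC45A2 candidate region), ~10% of the genome
masked as duplicated, a background density of 1.0 het/kbp and a
residual in-tract density of 0.05 het/kbp.  Planted tracts are aligned
to 1 Mbp window boundaries so that a window-resolution caller can
recover them without partial edge windows.

No linkage structure or sequence-level realism is simulated: downstream
stages consume only marginal site densities and annotations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import GenomeBuild
from .vcfio import VARIANT_COLUMNS

MBP = 1_000_000

#: Candidate oculocutaneous-albinism genes, hg19-like intervals (BED6-style).
DEFAULT_GENES = pd.DataFrame(
    [
        ("chr5", 33_944_623, 33_984_693, "SLC45A2"),
        ("chr9", 12_685_439, 12_710_290, "TYRP1"),
        ("chr11", 88_911_040, 89_028_927, "TYR"),
        ("chr15", 28_000_021, 28_344_461, "OCA2"),
    ],
    columns=["chrom", "start", "end", "name"],
)


@dataclass(frozen=True)
class CausalSpec:
    """The planted recessive causal variant."""

    chrom: str = "chr5"
    pos: int = 33_944_793  # 0-based; VCF position 33,944,794
    ref: str = "C"
    alt: str = "G"
    gene: str = "SLC45A2"


def default_planted_roh() -> list[tuple[str, int, int]]:
    """25 autozygous tracts totalling 306 Mbp, window-aligned."""
    layout = [
        ("chr4", 50, 68), ("chr5", 20, 40),
        ("chr1", 20, 23), ("chr2", 20, 22), ("chr3", 20, 15),
        ("chr6", 20, 14), ("chr7", 20, 12), ("chr8", 20, 11),
        ("chr9", 20, 10), ("chr10", 20, 9), ("chr11", 20, 9),
        ("chr12", 20, 8), ("chr13", 20, 8), ("chr14", 20, 7),
        ("chr15", 20, 7), ("chr16", 20, 6), ("chr17", 20, 6),
        ("chr18", 20, 5), ("chr19", 20, 5), ("chr20", 20, 4),
        ("chr21", 20, 4), ("chr22", 20, 4),
        ("chr1", 120, 3), ("chr2", 120, 3), ("chr3", 120, 3),
    ]
    return [(c, off * MBP, (off + ln) * MBP) for c, off, ln in layout]


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground-truth parameters of one synthetic genome."""

    planted_roh: tuple[tuple[str, int, int], ...] = field(
        default_factory=lambda: tuple(default_planted_roh())
    )
    background_het_rate: float = 1.0  # het sites per kbp outside tracts
    roh_het_rate: float = 0.05  # residual het sites per kbp inside tracts
    dup_fraction: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.roh_het_rate <= self.background_het_rate:
            raise ValueError("need 0 <= roh_het_rate <= background_het_rate")
        if self.background_het_rate > 0 and self.roh_het_rate >= self.background_het_rate:
            raise ValueError("roh_het_rate must be below background_het_rate")
        if not 0 <= self.dup_fraction < 1:
            raise ValueError("dup_fraction must be in [0, 1)")

    def validate_against(self, build: GenomeBuild) -> None:
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, s, e in self.planted_roh:
            if chrom not in build:
                raise ValueError(f"planted tract on unknown chromosome {chrom}")
            if not 0 <= s < e <= build.length_of(chrom):
                raise ValueError(f"planted tract {chrom}:{s}-{e} out of bounds")
            by_chrom.setdefault(chrom, []).append((s, e))
        for chrom, ivs in by_chrom.items():
            ivs.sort()
            for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
                if s2 < e1:
                    raise ValueError(f"planted tracts overlap on {chrom}")

    @property
    def total_planted(self) -> int:
        return sum(e - s for _, s, e in self.planted_roh)


def gen_build(n_chrom: int, total_length: int, seed: int) -> GenomeBuild:
    """A random genome build with lengths summing exactly to ``total_length``.

    Lengths are drawn as a moderately uneven Dirichlet partition and
    rounded so the total is conserved; deterministic for a fixed seed.
    """
    if n_chrom < 1:
        raise ValueError("n_chrom must be >= 1")
    if total_length < n_chrom:
        raise ValueError("total_length must be >= n_chrom")
    rng = np.random.default_rng(seed)
    weights = rng.dirichlet(np.full(n_chrom, 5.0))
    lengths = np.maximum(1, np.floor(weights * total_length).astype(np.int64))
    # distribute the rounding remainder over the largest chromosomes
    deficit = total_length - int(lengths.sum())
    order = np.argsort(-lengths)
    i = 0
    while deficit != 0:
        step = 1 if deficit > 0 else -1
        j = order[i % n_chrom]
        if lengths[j] + step >= 1:
            lengths[j] += step
            deficit -= step
        i += 1
    lengths[::-1].sort()
    return GenomeBuild(tuple((f"chr{i + 1}", int(l)) for i, l in enumerate(lengths)))


def _poisson_positions(rng, start: int, end: int, rate_per_kbp: float) -> np.ndarray:
    """Sorted positions of a homogeneous Poisson process on [start, end)."""
    if rate_per_kbp < 0:
        raise ValueError("rate must be non-negative")
    lam = rate_per_kbp * (end - start) / 1000.0
    n = rng.poisson(lam) if lam > 0 else 0
    if n == 0:
        return np.empty(0, dtype=np.int64)
    pos = start + np.floor(rng.random(n) * (end - start)).astype(np.int64)
    pos.sort()
    return pos


def gen_het_sites(build: GenomeBuild, truth: SyntheticTruth) -> pd.DataFrame:
    """Heterozygous sites as a piecewise-homogeneous Poisson process.

    Density is ``background_het_rate`` outside planted tracts and
    ``roh_het_rate`` inside; output is sorted by (chrom, pos) with
    ``gt == 'het'`` throughout.
    """
    truth.validate_against(build)
    rng = np.random.default_rng(truth.seed)
    tracts: dict[str, list[tuple[int, int]]] = {}
    for chrom, s, e in truth.planted_roh:
        tracts.setdefault(chrom, []).append((s, e))
    chroms: list[str] = []
    positions: list[np.ndarray] = []
    for name, length in build.chromosomes:
        pieces = []
        cursor = 0
        for s, e in sorted(tracts.get(name, [])):
            pieces.append(_poisson_positions(rng, cursor, s, truth.background_het_rate))
            pieces.append(_poisson_positions(rng, s, e, truth.roh_het_rate))
            cursor = e
        pieces.append(_poisson_positions(rng, cursor, length, truth.background_het_rate))
        pos = np.concatenate(pieces)
        positions.append(pos)
        chroms.extend([name] * len(pos))
    pos_all = np.concatenate(positions) if positions else np.empty(0, dtype=np.int64)
    df = pd.DataFrame({"chrom": chroms, "pos": pos_all})
    df["ref"] = "A"
    df["alt"] = "G"
    df["gt"] = "het"
    df["consequence"] = ""
    df["gene"] = ""
    return df[VARIANT_COLUMNS]


def gen_dup_mask(
    build: GenomeBuild,
    dup_fraction: float,
    seed: int,
    mean_interval: int = 50_000,
) -> pd.DataFrame:
    """Non-overlapping duplication intervals covering ~``dup_fraction``.

    Per chromosome, exponential-length intervals are thrown down
    uniformly, merged, and trimmed so the masked total matches the
    target fraction almost exactly.  Intervals never cross chromosome
    boundaries.
    """
    if not 0 <= dup_fraction < 1:
        raise ValueError("dup_fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    rows = []
    if dup_fraction == 0:
        return pd.DataFrame(columns=["chrom", "start", "end"])
    for name, length in build.chromosomes:
        target = int(round(dup_fraction * length))
        if target == 0:
            continue
        covered_s = np.empty(0, dtype=np.int64)
        covered_e = np.empty(0, dtype=np.int64)
        while True:
            n = max(8, int(np.ceil(1.5 * target / mean_interval)))
            lens = np.maximum(
                1000, rng.exponential(mean_interval, size=n)
            ).astype(np.int64)
            lens = np.minimum(lens, max(1000, length // 4))
            lens = np.minimum(lens, length)
            starts = np.floor(rng.random(n) * (length - lens)).astype(np.int64)
            s = np.concatenate([covered_s, starts])
            e = np.concatenate([covered_e, np.minimum(starts + lens, length)])
            order = np.argsort(s, kind="stable")
            s, e = s[order], e[order]
            ms, me = [s[0]], [e[0]]
            for a, b in zip(s[1:], e[1:]):
                if a <= me[-1]:
                    me[-1] = max(me[-1], b)
                else:
                    ms.append(a)
                    me.append(b)
            covered_s = np.asarray(ms, dtype=np.int64)
            covered_e = np.asarray(me, dtype=np.int64)
            if (covered_e - covered_s).sum() >= target:
                break
        # trim to the target coverage
        cum = np.cumsum(covered_e - covered_s)
        k = int(np.searchsorted(cum, target))
        excess = int(cum[k]) - target
        covered_s, covered_e = covered_s[: k + 1].copy(), covered_e[: k + 1].copy()
        covered_e[-1] -= excess
        if covered_e[-1] <= covered_s[-1]:
            covered_s, covered_e = covered_s[:-1], covered_e[:-1]
        for a, b in zip(covered_s, covered_e):
            rows.append((name, int(a), int(b)))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def _positions_outside(rng, build, genes, n: int) -> tuple[list[str], np.ndarray]:
    """n random positions outside all gene intervals (rejection sampling)."""
    lengths = np.array(build.lengths, dtype=float)
    probs = lengths / lengths.sum()
    chroms_out: list[str] = []
    pos_out: list[int] = []
    names = build.names
    gene_iv = {
        c: list(zip(g["start"], g["end"]))
        for c, g in genes.groupby("chrom")
    }
    while len(pos_out) < n:
        ci = rng.choice(len(names), p=probs)
        chrom = names[ci]
        p = int(rng.integers(0, build.length_of(chrom)))
        if any(s <= p < e for s, e in gene_iv.get(chrom, [])):
            continue
        chroms_out.append(chrom)
        pos_out.append(p)
    return chroms_out, np.asarray(pos_out, dtype=np.int64)


def gen_candidate_variants(
    build: GenomeBuild,
    genes: pd.DataFrame = DEFAULT_GENES,
    planted_causal: CausalSpec = CausalSpec(),
    panel_size: int = 2,
    seed: int = 0,
    n_shared_in_gene: int = 19,
    n_het_in_gene: int = 30,
    n_syn_in_gene: int = 30,
    n_background_hom_nonsyn: int = 2000,
    n_background_other: int = 1000,
) -> tuple[pd.DataFrame, list[pd.DataFrame]]:
    """Focal and panel variant tables with one planted private causal.

    Exactly one focal variant — the planted causal — is simultaneously
    homozygous-alt, non-synonymous, inside a candidate gene and absent
    from every panel table.  ``n_shared_in_gene`` additional in-gene
    homozygous non-synonymous variants are present in every panel
    genome, so the full funnel retains 1 + n_shared_in_gene variants
    before the privacy filter and exactly 1 after it.
    """
    rng = np.random.default_rng(seed)
    gene_rows = genes.reset_index(drop=True)
    hit = gene_rows[
        (gene_rows["chrom"] == planted_causal.chrom)
        & (gene_rows["start"] <= planted_causal.pos)
        & (planted_causal.pos < gene_rows["end"])
    ]
    if hit.empty:
        raise ValueError("planted causal variant lies outside all gene intervals")

    rows: list[tuple] = [
        (
            planted_causal.chrom,
            planted_causal.pos,
            planted_causal.ref,
            planted_causal.alt,
            "hom_alt",
            "non_synonymous",
            planted_causal.gene,
        )
    ]
    shared: list[tuple] = []

    def in_gene_positions(n: int) -> list[tuple[str, int, str]]:
        out = []
        for i in range(n):
            g = gene_rows.iloc[int(rng.integers(0, len(gene_rows)))]
            p = int(rng.integers(g["start"], g["end"]))
            out.append((g["chrom"], p, g["name"]))
        return out

    used = {(planted_causal.chrom, planted_causal.pos)}

    def fresh(triples):
        for chrom, p, gname in triples:
            if (chrom, p) in used:
                continue
            used.add((chrom, p))
            yield chrom, p, gname

    for chrom, p, gname in fresh(in_gene_positions(n_shared_in_gene + 5)):
        if len(shared) == n_shared_in_gene:
            break
        shared.append((chrom, p, "C", "T", "hom_alt", "non_synonymous", gname))
    rows += shared
    for chrom, p, gname in fresh(in_gene_positions(n_het_in_gene)):
        rows.append((chrom, p, "G", "A", "het", "non_synonymous", gname))
    for chrom, p, gname in fresh(in_gene_positions(n_syn_in_gene)):
        rows.append((chrom, p, "T", "C", "hom_alt", "synonymous", gname))

    bg_chroms, bg_pos = _positions_outside(
        rng, build, gene_rows, n_background_hom_nonsyn + n_background_other
    )
    background: list[tuple] = []
    for i, (chrom, p) in enumerate(zip(bg_chroms, bg_pos)):
        if (chrom, int(p)) in used:
            continue
        used.add((chrom, int(p)))
        if i < n_background_hom_nonsyn:
            background.append((chrom, int(p), "A", "C", "hom_alt", "non_synonymous", ""))
        else:
            gt = "het" if i % 2 else "hom_alt"
            background.append((chrom, int(p), "A", "C", gt, "synonymous", ""))
    rows += background

    focal = pd.DataFrame(rows, columns=VARIANT_COLUMNS).sort_values(
        ["chrom", "pos"], kind="stable"
    ).reset_index(drop=True)

    panels: list[pd.DataFrame] = []
    for k in range(panel_size):
        prow = list(shared)  # every shared in-gene variant is in every panel
        take = rng.random(len(background)) < 0.5
        for keep, r in zip(take, background):
            if keep:
                prow.append(r)
        pdf = pd.DataFrame(prow, columns=VARIANT_COLUMNS).copy()
        gts = np.where(rng.random(len(pdf)) < 0.5, "het", "hom_alt")
        pdf["gt"] = gts
        panels.append(
            pdf.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
        )
    return focal, panels
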