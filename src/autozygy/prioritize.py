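"""Recessive candidate-variant prioritization.

The filter chain mirrors the classical recessive-disorder funnel:
homozygous non-synonymous variants, restricted to candidate-gene
intervals, kept only when the alternate allele is absent from every
comparison genome (a *private* variant), and finally annotated with
the run of homozygosity containing them — a recessive causal allele is
expected to sit inside an autozygous block.

Each filter is an intersection, so the final set is invariant to the
order in which the filters are applied.  Consequence annotation is
consumed, not computed: the input table must carry a consequence
column (variant effect prediction is upstream of this logic).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .roh import ROHCallset

logger = logging.getLogger(__name__)


def filter_hom_nonsyn(variants: pd.DataFrame) -> pd.DataFrame:
    """Keep homozygous-alt, non-synonymous records.

    Records without a consequence annotation are skipped; their number
    is logged so the funnel stays auditable.
    """
    missing = variants["consequence"].isna() | (variants["consequence"] == "")
    if missing.any():
        logger.warning("skipping %d records without consequence annotation",
                       int(missing.sum()))
    kept = variants[
        ~missing
        & (variants["gt"] == "hom_alt")
        & (variants["consequence"] == "non_synonymous")
    ]
    return kept.reset_index(drop=True)


def restrict_to_genes(variants: pd.DataFrame, genes: pd.DataFrame) -> pd.DataFrame:
    """Keep variants inside any candidate-gene interval (half-open);
    the matched gene name is (re)annotated."""
    if variants.empty:
        return variants.assign(gene=pd.Series(dtype=str))
    out = []
    for _, g in genes.iterrows():
        hit = variants[
            (variants["chrom"] == g["chrom"])
            & (variants["pos"] >= g["start"])
            & (variants["pos"] < g["end"])
        ].copy()
        hit["gene"] = g["name"]
        out.append(hit)
    if not out:
        return variants.iloc[0:0]
    res = pd.concat(out).drop_duplicates(subset=["chrom", "pos", "alt"])
    return res.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)


def private_against_panel(
    variants: pd.DataFrame, panel: list[pd.DataFrame]
) -> pd.DataFrame:
    """Keep variants whose alt allele is carried by no panel individual.

    A site that is absent from a panel table, or present with a
    ``hom_ref``/``missing`` genotype, does not count as carrying the
    allele; sites missing (uncalled) in at least one panel member are
    flagged in a ``panel_missing`` column rather than dropped, because
    "not variant-called" and "confidently reference" differ.
    """
    out = variants.copy()
    out["panel_missing"] = False
    if not panel or out.empty:
        return out
    carrier_keys: set[tuple] = set()
    seen_keys: set[tuple] = set()
    for table in panel:
        for r in table.itertuples(index=False):
            key = (r.chrom, r.pos, r.alt)
            seen_keys.add(key)
            if r.gt in ("het", "hom_alt"):
                carrier_keys.add(key)
    keys = list(zip(out["chrom"], out["pos"], out["alt"]))
    keep = np.array([k not in carrier_keys for k in keys])
    out = out[keep].reset_index(drop=True)
    keys = list(zip(out["chrom"], out["pos"], out["alt"]))
    out["panel_missing"] = [k not in seen_keys for k in keys]
    return out


def annotate_roh_context(
    variants: pd.DataFrame, callset: ROHCallset
) -> pd.DataFrame:
    """Flag each variant with the ROH segment containing it, if any."""
    out = variants.copy()
    out["in_roh"] = False
    out["roh_length"] = pd.array([pd.NA] * len(out), dtype="Int64")
    for seg in callset.segments:
        inside = (
            (out["chrom"] == seg.chrom)
            & (out["pos"] >= seg.start)
            & (out["pos"] < seg.end)
        )
        out.loc[inside, "in_roh"] = True
        out.loc[inside, "roh_length"] = seg.length
    return out


def prioritize(
    variants: pd.DataFrame,
    genes: pd.DataFrame,
    panel: list[pd.DataFrame],
    callset: ROHCallset | None = None,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Full funnel; returns surviving variants and per-stage counts."""
    counts = {"input": len(variants)}
    v = filter_hom_nonsyn(variants)
    counts["hom_nonsyn"] = len(v)
    v = restrict_to_genes(v, genes)
    counts["in_candidate_gene"] = len(v)
    v = private_against_panel(v, panel)
    counts["private"] = len(v)
    if callset is not None:
        v = annotate_roh_context(v, callset)
        counts["in_roh"] = int(v["in_roh"].sum())
    return v, counts
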