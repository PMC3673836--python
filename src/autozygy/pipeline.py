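"""End-to-end orchestration: simulate -> windows -> ROH -> pedigree
simulations -> model ranking -> variant prioritization.

Per-stage record counts are logged so the filtering funnel (all
variants -> homozygous non-synonymous -> in candidate gene -> private)
is auditable, and the single JSON report embeds the config hash and
seed for reproducibility.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np

from . import likelihood, prioritize, roh, synthetic, vcfio, windows
from .config import PipelineConfig
from .genome import GenomeBuild, grch37_autosomes
from .pedigree import MODELS, RecombinationRates, run_model

logger = logging.getLogger(__name__)


def build_from_config(config: PipelineConfig) -> GenomeBuild:
    if config.genome == "grch37":
        return grch37_autosomes()
    if config.genome == "random":
        return synthetic.gen_build(config.n_chrom, config.total_length, config.seed)
    raise ValueError(f"unknown genome spec {config.genome!r}")


def truth_from_config(config: PipelineConfig) -> synthetic.SyntheticTruth:
    planted = (
        tuple(tuple(t) for t in config.planted_roh)
        if config.planted_roh is not None
        else tuple(synthetic.default_planted_roh())
    )
    return synthetic.SyntheticTruth(
        planted_roh=planted,
        background_het_rate=config.background_het_rate,
        roh_het_rate=config.roh_het_rate,
        dup_fraction=config.dup_fraction,
        seed=config.seed,
    )


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Run every stage on synthetic inputs; returns the report dict.

    Any stage failure is re-raised annotated with the stage name.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"config_hash": config.config_hash, "seed": config.seed}
    stage = "setup"
    try:
        stage = "simulate"
        build = build_from_config(config)
        truth = truth_from_config(config)
        het = synthetic.gen_het_sites(build, truth)
        mask = synthetic.gen_dup_mask(build, truth.dup_fraction, config.seed)
        focal, panels = synthetic.gen_candidate_variants(
            build, panel_size=config.panel_size, seed=config.seed
        )
        genes = synthetic.DEFAULT_GENES
        build.to_chrom_sizes(outdir / "genome.sizes.tsv")
        vcfio.write_bed(mask, outdir / "dup_mask.bed")
        vcfio.write_bed(genes, outdir / "candidate_genes.bed")
        logger.info("simulate: %d het sites, %d mask intervals", len(het), len(mask))

        stage = "windows"
        win = windows.tile_windows(build, config.window_size)
        win = windows.mask_windows(win, mask, config.max_dup_overlap)
        win = windows.count_het(win, het, mask)
        windows.write_windows_tsv(win, outdir / "windows.tsv")

        stage = "roh"
        threshold = (
            config.het_threshold
            if config.het_threshold is not None
            else roh.default_het_threshold(win)
        )
        segments = roh.call_roh(win, threshold, config.min_windows)
        segments = roh.postprocess_segments(segments, config.min_length, config.max_gap)
        effective_genome = int(
            win.loc[~win["masked_out"], "effective_bases"].sum()
        )
        callset = roh.compute_f_roh(segments, effective_genome)
        summary = roh.summarize_callset(callset, large_threshold=config.min_length)
        vcfio.segments_to_bed(callset.segments, outdir / "roh.bed")
        report["het_threshold"] = threshold
        report["roh"] = summary

        stage = "pedsim"
        rates = RecombinationRates(config.male_rate, config.female_rate)
        root = np.random.SeedSequence(config.seed)
        streams = root.spawn(len(MODELS))
        runs = {
            model_id: run_model(
                MODELS[model_id], build, rates,
                n_reps=config.n_reps, seed=stream,
                min_length=config.min_length, max_gap=config.max_gap,
            )
            for (model_id, stream) in zip(MODELS, streams)
        }

        stage = "rank"
        binning = likelihood.LengthBinning(
            config.min_length, config.bin_width, config.n_bins
        )
        ranking = likelihood.rank_models(
            list(callset.segments), runs, binning, config.pseudocount
        )
        ranking.to_csv(outdir / "model_ranking.tsv", sep="\t", index=False)
        report["model_ranking"] = ranking.to_dict(orient="records")

        stage = "prioritize"
        hits, funnel = prioritize.prioritize(focal, genes, panels, callset)
        hits.to_csv(outdir / "prioritized_variants.tsv", sep="\t", index=False)
        report["variant_funnel"] = funnel
        report["prioritized_variants"] = hits.to_dict(orient="records")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=_jsonable, sort_keys=True)
    return report


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
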