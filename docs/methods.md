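# Methods

This document describes the statistical models, algorithms, default
parameters and design decisions implemented in `autozygy`. Coordinates
are 0-based half-open throughout the library; VCF files are 1-based at
the file boundary only.

## 1. Genome frame

Analyses run over an autosomal genome described by a `GenomeBuild`
(ordered chromosome names and lengths). The built-in frame
`grch37_autosomes()` uses the 22 GRCh37/hg19 autosome lengths
(2,881,033,286 bp total); gorilla and human autosomes are close enough
in size and count that this is an adequate stand-in for a great-ape
autosomal frame, and it lets gene coordinates use familiar hg19-like
positions. The synthetic generator can also draw a random frame
(Dirichlet partition of a total length into `n_chrom` pieces) for tests.

## 2. Windowed heterozygosity (`autozygy.windows`)

- **Tiling.** Non-overlapping windows of `window_size` = 1 Mbp
  (default). The final window of each chromosome may be shorter.
- **Duplication masking.** Collapsed segmental duplications inflate
  apparent heterozygosity, so windows overlapping a duplication mask by
  strictly more than `max_overlap` = 0.40 of their length are *masked
  out* and excluded from all downstream statistics. For retained
  windows, masked bases are subtracted from the denominator:
  `effective_bases = window_length − masked_overlap`.
- **Counting.** Heterozygous sites falling inside masked subintervals
  are excluded from the numerator. The reported density is
  `het_per_kbp = 1000 · n_het / effective_bases`. Sites on chromosomes
  absent from the build are skipped with a warning rather than an error.
- Interval arithmetic (overlap of each window with a merged mask) is
  done with a cumulative-coverage function and `numpy.searchsorted`
  rather than an interval-tree dependency; for sorted, merged masks this
  is exact and O((n+m) log m).

## 3. ROH calling (`autozygy.roh`)

- **Threshold.** A window is low-heterozygosity when
  `het_per_kbp < t`. By default `t = 0.25 ×` the genome-wide *median*
  het_per_kbp over unmasked windows. The median is robust to the very
  signal being detected (long ROH drag a mean down, much less a
  median), and the 0.25 factor sits far from both the background mode
  and the residual-error mode inside true ROH. `t` can be overridden.
- **Run rule.** A candidate ROH is a run of ≥ `min_windows` = 2
  consecutive low-het windows on one chromosome; the segment spans the
  first to the last window of the run.
- **Masked windows inside runs.** A *single* masked-out window does not
  interrupt a run (it contributes nothing to the window count); two or
  more consecutive masked windows do, because the evidence gap is too
  large to bridge. Trailing windows shorter than 50 % of the nominal
  window size are excluded from calling: their density estimate is too
  noisy to support a call.
- **Post-processing: merge, then filter.** Segments on the same
  chromosome separated by a gap strictly smaller than `max_gap` =
  500 kbp are merged; afterwards segments shorter than `min_length` =
  2 Mbp are dropped. The order matters: merging first lets two
  short fragments of one interrupted ROH survive the length filter as a
  single segment, which is the intended behaviour.
- **F_ROH.** `F_ROH = Σ segment lengths / effective genome`, where the
  effective genome is the sum of `effective_bases` over all *unmasked*
  windows. Overlapping segments in a callset raise an error rather than
  double-count.

## 4. Synthetic data generator (`autozygy.synthetic`)

The generator's defaults **are** the study conditions; they were fixed
a priori from the design of the analysis, not tuned to make tests pass.

- **Planted ROH.** 25 window-aligned tracts totalling exactly 306 Mbp,
  including a 68-Mbp tract (chr4 @ 50 Mbp) and a 40-Mbp tract (chr5 @
  20 Mbp) that contains the planted causal variant. Tract sizes decay
  roughly geometrically across chromosomes, the typical shape of a
  single-generation consanguinity signal.
- **Heterozygous sites.** A piecewise-constant Poisson process:
  `background_het_rate` = 1.0 het/kbp outside planted tracts,
  `roh_het_rate` = 0.05 het/kbp inside (residual genotyping error).
  Invariant: `0 ≤ roh_het_rate < background_het_rate` (equality only in
  the degenerate all-zero case).
- **Duplication mask.** Exponential interval lengths (mean 50 kbp)
  placed uniformly, merged, and trimmed to an exact genome fraction
  `dup_fraction` = 0.10, chosen so that the effective genome after
  window masking is ≈ 2.59 Gbp.
- **Variants.** A focal variant table containing: one causal variant
  (chr5:33,944,793 0-based, C→G, hom-alt, non-synonymous, in SLC45A2),
  19 additional hom-alt non-synonymous variants inside the four
  candidate genes that are *shared* with the panel, plus in-gene
  het/synonymous decoys and genome-wide background variants. Panel
  tables contain every shared variant (het or hom-alt at random) and
  ~50 % of the background. The funnel over this fixture is 20 → 1 by
  construction.
- **Candidate genes.** TYR, OCA2, TYRP1, SLC45A2 at hg19-like
  coordinates — the canonical oculocutaneous-albinism gene set.

## 5. Gene-dropping pedigree simulation (`autozygy.pedigree`)

- **Haplotypes.** A haplotype is a piecewise-constant label map stored
  as two parallel sorted lists (breakpoint starts, founder labels).
  Haplotypes are immutable; a gamete with zero crossovers is a
  *reference* to the parental haplotype, not a copy. This makes one
  full-genome replicate ≈ 1 ms.
- **Founders.** Each founder receives 2 genome-wide labels (one per
  haplotype). Labels are only ever compared within a chromosome, so
  genome-wide labels are sufficient and cheapest.
- **Meiosis.** For each chromosome the number of crossovers is
  Poisson(rate × length) — no crossover interference — with
  sex-specific per-nucleotide rates: male 8.9 × 10⁻⁹, female
  1.4 × 10⁻⁸ (≈ 0.89 and 1.4 expected crossovers per 100 Mbp).
  Crossover positions are uniform; the gamete alternates between the
  two parental haplotypes starting from a fair-coin choice of strand.
- **Models.** Ten pedigrees, all with expected focal inbreeding
  F = 1/8: half siblings (shared father / shared mother), uncle–niece
  and aunt–nephew (the linking siblings are full sibs; paternal /
  maternal transmission variants), and grandparent–grandchild
  (grandfather–granddaughter and grandmother–grandson, each via a son
  or a daughter). Enumerating both sex configurations matters because
  the female:male recombination-rate ratio (≈ 1.6) shifts the
  segment-length spectrum depending on which sexes the IBD path
  traverses.
- **Autozygosity.** The focal individual is autozygous wherever its two
  haplotypes carry the same founder label (two-pointer sweep over the
  breakpoint lists). Segments are then post-processed with exactly the
  same merge/filter rules as called ROH (gap < 500 kbp, length ≥
  2 Mbp), so simulated and observed spectra are comparable.
- **Replication.** `run_model` draws `n_reps` independent replicates
  (default 10,000) with per-replicate RNG streams spawned from a
  `numpy.random.SeedSequence`, making runs reproducible and
  order-independent.

## 6. Multinomial likelihood ranking (`autozygy.likelihood`)

- **Binning.** Segment lengths ≥ 2 Mbp are placed in half-open 5-Mbp
  bins starting at the 2-Mbp cutoff ([2, 7), [7, 12), …), with an
  open-ended top bin; 20 bins by default. Lengths below the cutoff are
  an error — the caller must apply the same filter as the simulator.
- **Model probabilities.** Per-bin probabilities are estimated from the
  *pooled* segments of all replicates of a model, with a pseudocount of
  0.5 per bin (`(c_i + 0.5) / Σ(c_j + 0.5)`) so that an observed
  segment in a bin the simulation never produced yields a finite, very
  negative log-likelihood instead of −∞.
- **Score.** The observed bin counts are scored with
  `scipy.stats.multinomial.logpmf` under each model; models are ranked
  by log-likelihood. This conditions on the *total number* of observed
  segments and uses only the length spectrum — an intentional choice,
  since segment count is also informative but far more sensitive to the
  caller's resolution. Segment count and mean autozygous fraction are
  reported as diagnostics columns instead.
- **Ties.** All models within 1e-9 of the best log-likelihood get
  `is_top = True`. Ties between same-class pedigrees are expected and
  are reported, never silently broken: pedigrees of equal kinship
  produce nearly identical spectra, and the honest output is the set of
  equally supported models.
- An empty observed segment list raises an error with guidance ("no
  inbreeding signal") rather than producing a meaningless uniform
  ranking.

## 7. Variant prioritization (`autozygy.prioritize`)

Filters applied in order, with counts reported at each stage:

1. **hom-alt ∧ non-synonymous.** Records with a missing consequence
   annotation are skipped with a logged warning (they cannot be
   classified, and silently keeping them would inflate the funnel).
2. **Candidate gene overlap** (half-open intervals); the gene name is
   annotated.
3. **Private vs panel.** A variant survives if its alternate allele is
   absent (hom-ref) from every panel genotype at that site. Sites not
   present in a panel at all are kept but flagged `panel_missing = True`
   — absence of evidence is weaker than an observed hom-ref call.
4. **ROH context.** Surviving variants are annotated with `in_roh` and
   the containing segment's length; a long containing ROH is the
   expected signature of an identical-by-descent recessive allele.

## 8. Pipeline, configuration, reproducibility

- `PipelineConfig` (YAML-serializable) carries every parameter with the
  defaults above; unknown keys are rejected. `config_hash` is a
  12-hex-digit SHA-256 prefix of the canonical config for
  run-folder provenance.
- `run_pipeline` chains simulate → windows → ROH → 10 × pedigree
  simulation → ranking → funnel, writes TSV/BED/VCF/JSON artifacts and
  a sorted `report.json`; identical configs give byte-identical
  reports. Stage failures are re-raised naming the stage.
- All randomness flows from one seed through `SeedSequence.spawn`, so
  per-model and per-replicate streams are independent and reproducible.

## 9. Problem sizes and runtime

- Default end-to-end run (GRCh37 frame, 2,897 windows, 10 models ×
  10,000 replicates): ≈ 100 s single-core.
- One gene-dropping replicate at genome scale: ≈ 1 ms.
- `scripts/acceptance.py`: ≈ 2 min; full test suite: ≈ 3 min.

## 10. What the generator emulates — and what it does not

Emulated: the window-scale statistical structure of a highly inbred
genome (ROH length spectrum, residual heterozygosity inside ROH,
duplication-inflated windows, a recessive causal variant private to the
focal individual). Not emulated: sequencing reads, genotype-calling
error models beyond a uniform residual rate, linkage disequilibrium,
mutation, gene conversion, crossover interference, sex chromosomes, and
population structure within the comparison panel. The pedigree
simulator assumes the focal individual's parents are related through
exactly one IBD path and that founders are themselves non-inbred and
unrelated.

## 11. Limitations

- Window-resolution calling means segment boundaries are only accurate
  to ± 1–2 Mbp, and a masked window at a segment edge shifts the called
  boundary inward; F_ROH is much less sensitive to this than individual
  boundaries.
- The likelihood uses pooled-replicate bin probabilities, ignoring
  replicate-to-replicate correlation between bins; this is a standard
  composite-likelihood simplification and only affects absolute, not
  comparative, values in practice.
- Same-class pedigrees (same F, same meiosis count on the IBD path and
  similar sex composition) are often statistically indistinguishable
  from segment lengths alone; the ranking reports such ties explicitly.
- The Poisson crossover model without interference slightly
  overdisperses crossover counts relative to real meiosis; at the
  segment-length scales used here (≥ 2 Mbp, 5-Mbp bins) the effect is
  negligible.
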