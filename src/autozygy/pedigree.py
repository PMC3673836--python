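"""Gene-dropping pedigree simulator with sex-specific recombination.

Founders carry two uniquely labelled haplotypes per chromosome (zero
inbreeding among founders).  Descendants are produced by simulated
meioses: crossover counts are Poisson in physical length at a
sex-specific per-nucleotide rate, crossover positions are uniform (no
interference, no obligate chiasma), and the gamete alternates between
the two parental haplotypes at each crossover, starting from a
fair-coin choice.  Autozygous segments in the focal individual are the
maximal intervals where its two haplotypes carry the same founder
haplotype label (fully penetrant identity by descent, not identity by
state).

Ten inbred mating structures are enumerated in :data:`MODELS`: the five
relationship classes half-siblings, uncle-niece, aunt-nephew,
grandfather-granddaughter and grandmother-grandson, each in its two
sex configurations.  Every model has pedigree inbreeding coefficient
F = 1/8 for the focal offspring, but the mix of male and female meioses
differs, which shifts the length distribution of autozygous segments.

Haplotypes are piecewise-constant maps from position to founder label,
stored as two parallel lists ``(starts, labels)`` with an implicit
terminal breakpoint at the chromosome end.  Lists are treated as
immutable so a crossover-free gamete is a reference, not a copy.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, field

import numpy as np

from .genome import GenomeBuild

__all__ = [
    "RecombinationRates",
    "PedigreeModel",
    "MODELS",
    "make_founder",
    "meiosis",
    "simulate_pedigree",
    "extract_autozygous",
    "run_model",
    "ModelRun",
]

Haplotype = tuple[list[int], list[int]]  # (segment starts, founder labels)
DiploidChrom = tuple[Haplotype, Haplotype]


@dataclass(frozen=True)
class RecombinationRates:
    """Sex-specific crossover rates per nucleotide.

    Defaults are the empirical sex-averaged human map rates used for
    great-ape pedigree simulation: males recombine less than females.
    """

    male_rate: float = 8.9e-9
    female_rate: float = 1.4e-8

    def __post_init__(self) -> None:
        if self.male_rate <= 0 or self.female_rate <= 0:
            raise ValueError("recombination rates must be positive")

    def rate_for(self, sex: str) -> float:
        if sex == "M":
            return self.male_rate
        if sex == "F":
            return self.female_rate
        raise ValueError(f"unknown sex {sex!r}")


@dataclass(frozen=True)
class PedigreeModel:
    """An inbred mating structure with sexes assigned to every member.

    ``parents`` maps each non-founder to ``(father, mother)``; members
    absent from it are founders, assumed mutually unrelated.  ``focal``
    is the offspring of the inbred mating.
    """

    model_id: str
    members: tuple[tuple[str, str], ...]  # (name, sex "M"/"F")
    parents: dict[str, tuple[str, str]]
    focal: str
    inbreeding_coefficient: float = 0.125

    def __post_init__(self) -> None:
        sexes = dict(self.members)
        if len(sexes) != len(self.members):
            raise ValueError("duplicate member names")
        if self.focal not in sexes:
            raise ValueError("focal individual not among members")
        for child, (father, mother) in self.parents.items():
            if sexes.get(father) != "M":
                raise ValueError(f"{child}: father {father!r} is not a male member")
            if sexes.get(mother) != "F":
                raise ValueError(f"{child}: mother {mother!r} is not a female member")
        self.topological_order()  # raises on cycles

    @property
    def founders(self) -> list[tuple[str, str]]:
        return [(n, s) for n, s in self.members if n not in self.parents]

    def sex_of(self, name: str) -> str:
        return dict(self.members)[name]

    def topological_order(self) -> list[str]:
        """Non-founders ordered so parents always precede children."""
        order: list[str] = []
        state: dict[str, int] = {}

        def visit(name: str) -> None:
            if state.get(name) == 2:
                return
            if state.get(name) == 1:
                raise ValueError("cyclic parent map")
            state[name] = 1
            if name in self.parents:
                for p in self.parents[name]:
                    visit(p)
                order.append(name)
            state[name] = 2

        for name, _ in self.members:
            visit(name)
        return order

    def meiosis_schedule(self) -> list[tuple[str, str, str]]:
        """Gametes needed, in simulation order: (child, parent, parent sex)."""
        sched = []
        for child in self.topological_order():
            father, mother = self.parents[child]
            sched.append((child, father, "M"))
            sched.append((child, mother, "F"))
        return sched


def _model(model_id: str, members, parents, focal) -> PedigreeModel:
    return PedigreeModel(model_id, tuple(members), dict(parents), focal)


#: The 10 enumerated pedigree models: 5 relationship classes x 2 sex
#: configurations, all with focal inbreeding coefficient 1/8.
#: Uncles/aunts are FULL siblings of the relevant parent (half-avuncular
#: links would give F = 1/16, inconsistent with the 0.125 class).
MODELS: dict[str, PedigreeModel] = {
    m.model_id: m
    for m in [
        _model(
            "half_sib_shared_father",
            [("F", "M"), ("W1", "F"), ("W2", "F"), ("S", "M"), ("D", "F"), ("X", "F")],
            {"S": ("F", "W1"), "D": ("F", "W2"), "X": ("S", "D")},
            "X",
        ),
        _model(
            "half_sib_shared_mother",
            [("Mo", "F"), ("H1", "M"), ("H2", "M"), ("S", "M"), ("D", "F"), ("X", "F")],
            {"S": ("H1", "Mo"), "D": ("H2", "Mo"), "X": ("S", "D")},
            "X",
        ),
        _model(
            "uncle_niece_paternal",
            [("GF", "M"), ("GM", "F"), ("U", "M"), ("Fa", "M"), ("Mo", "F"),
             ("N", "F"), ("X", "F")],
            {"U": ("GF", "GM"), "Fa": ("GF", "GM"), "N": ("Fa", "Mo"),
             "X": ("U", "N")},
            "X",
        ),
        _model(
            "uncle_niece_maternal",
            [("GF", "M"), ("GM", "F"), ("U", "M"), ("Mo", "F"), ("Fa", "M"),
             ("N", "F"), ("X", "F")],
            {"U": ("GF", "GM"), "Mo": ("GF", "GM"), "N": ("Fa", "Mo"),
             "X": ("U", "N")},
            "X",
        ),
        _model(
            "aunt_nephew_paternal",
            [("GF", "M"), ("GM", "F"), ("A", "F"), ("Fa", "M"), ("Mo", "F"),
             ("Ne", "M"), ("X", "F")],
            {"A": ("GF", "GM"), "Fa": ("GF", "GM"), "Ne": ("Fa", "Mo"),
             "X": ("Ne", "A")},
            "X",
        ),
        _model(
            "aunt_nephew_maternal",
            [("GF", "M"), ("GM", "F"), ("A", "F"), ("Mo", "F"), ("Fa", "M"),
             ("Ne", "M"), ("X", "F")],
            {"A": ("GF", "GM"), "Mo": ("GF", "GM"), "Ne": ("Fa", "Mo"),
             "X": ("Ne", "A")},
            "X",
        ),
        _model(
            "grandfather_granddaughter_via_son",
            [("GF", "M"), ("W1", "F"), ("S", "M"), ("W2", "F"), ("GD", "F"),
             ("X", "F")],
            {"S": ("GF", "W1"), "GD": ("S", "W2"), "X": ("GF", "GD")},
            "X",
        ),
        _model(
            "grandfather_granddaughter_via_daughter",
            [("GF", "M"), ("W1", "F"), ("Da", "F"), ("H2", "M"), ("GD", "F"),
             ("X", "F")],
            {"Da": ("GF", "W1"), "GD": ("H2", "Da"), "X": ("GF", "GD")},
            "X",
        ),
        _model(
            "grandmother_grandson_via_son",
            [("GM", "F"), ("H1", "M"), ("S", "M"), ("W2", "F"), ("GS", "M"),
             ("X", "F")],
            {"S": ("H1", "GM"), "GS": ("S", "W2"), "X": ("GS", "GM")},
            "X",
        ),
        _model(
            "grandmother_grandson_via_daughter",
            [("GM", "F"), ("H1", "M"), ("Da", "F"), ("H2", "M"), ("GS", "M"),
             ("X", "F")],
            {"Da": ("H1", "GM"), "GS": ("H2", "Da"), "X": ("GS", "GM")},
            "X",
        ),
    ]
}


@dataclass
class FounderLabeledGenome:
    """Diploid genome as per-chromosome pairs of labelled haplotypes."""

    build: GenomeBuild
    chroms: list[DiploidChrom]

    def autozygous_fraction(self) -> float:
        total = sum(e - s for _, s, e in self.autozygous_intervals())
        return total / self.build.total_length

    def autozygous_intervals(self) -> list[tuple[str, int, int]]:
        out = []
        for (name, length), (h1, h2) in zip(self.build.chromosomes, self.chroms):
            for s, e in _autozygous_chrom(h1, h2, length):
                out.append((name, s, e))
        return out


def make_founder(build: GenomeBuild, label_source) -> FounderLabeledGenome:
    """A founder: two single-segment haplotypes with globally unique labels."""
    a, b = next(label_source), next(label_source)
    chroms: list[DiploidChrom] = [(([0], [a]), ([0], [b])) for _ in build.chromosomes]
    return FounderLabeledGenome(build, chroms)


def _splice(h0: Haplotype, h1: Haplotype, cuts: list[int], length: int) -> Haplotype:
    """Gamete taking h0 on [0, c1), h1 on [c1, c2), alternating thereafter."""
    haps = (h0, h1)
    starts_out: list[int] = []
    labels_out: list[int] = []
    bounds = [0] + cuts + [length]
    for i in range(len(bounds) - 1):
        a, b = bounds[i], bounds[i + 1]
        if a >= b:
            continue
        starts, labels = haps[i & 1]
        j = bisect_right(starts, a) - 1
        while j < len(starts) and starts[j] < b:
            lab = labels[j]
            if not labels_out or labels_out[-1] != lab:
                starts_out.append(a if starts[j] < a else starts[j])
                labels_out.append(lab)
            j += 1
    return starts_out, labels_out


def meiosis(
    parent: FounderLabeledGenome,
    parent_sex: str,
    rates: RecombinationRates,
    rng: np.random.Generator,
) -> list[Haplotype]:
    """One gamete: per chromosome, Poisson crossovers at the sex's rate.

    Returns one haplotype per chromosome.  With zero crossovers the
    gamete chromosome is an exact copy of one parental haplotype.
    """
    rate = rates.rate_for(parent_sex)
    lengths = parent.build.lengths
    counts = rng.poisson(np.asarray(lengths, dtype=float) * rate)
    firsts = rng.integers(0, 2, size=len(lengths))
    total = int(counts.sum())
    u = rng.random(total) if total else None
    out: list[Haplotype] = []
    ptr = 0
    for c, (hA, hB), length, k, first in zip(
        range(len(lengths)), parent.chroms, lengths, counts, firsts
    ):
        h0, h1 = (hA, hB) if first == 0 else (hB, hA)
        if k == 0:
            out.append(h0)  # lists are never mutated; sharing is safe
            continue
        cuts = sorted(int(x * length) for x in u[ptr : ptr + k])
        ptr += k
        out.append(_splice(h0, h1, cuts, length))
    return out


def simulate_pedigree(
    model: PedigreeModel,
    build: GenomeBuild,
    rates: RecombinationRates,
    rng: np.random.Generator,
) -> FounderLabeledGenome:
    """Drop founder haplotypes through the pedigree; return the focal genome."""
    from itertools import count

    labels = count()
    genomes: dict[str, FounderLabeledGenome] = {
        name: make_founder(build, labels) for name, _ in model.founders
    }
    for child in model.topological_order():
        father, mother = model.parents[child]
        gam_f = meiosis(genomes[father], "M", rates, rng)
        gam_m = meiosis(genomes[mother], "F", rates, rng)
        genomes[child] = FounderLabeledGenome(
            build, [(f, m) for f, m in zip(gam_f, gam_m)]
        )
    return genomes[model.focal]


def _autozygous_chrom(h1: Haplotype, h2: Haplotype, length: int) -> list[tuple[int, int]]:
    """Maximal intervals where both haplotypes carry the same label."""
    s1, l1 = h1
    s2, l2 = h2
    segs: list[tuple[int, int]] = []
    i = j = 0
    pos = 0
    run_start: int | None = None
    while pos < length:
        nxt1 = s1[i + 1] if i + 1 < len(s1) else length
        nxt2 = s2[j + 1] if j + 1 < len(s2) else length
        same = l1[i] == l2[j]
        if same and run_start is None:
            run_start = pos
        elif not same and run_start is not None:
            segs.append((run_start, pos))
            run_start = None
        nxt = nxt1 if nxt1 <= nxt2 else nxt2
        if nxt == nxt1:
            i += 1
        if nxt == nxt2:
            j += 1
        pos = nxt
    if run_start is not None:
        segs.append((run_start, length))
    return segs


def extract_autozygous(focal: FounderLabeledGenome) -> list[tuple[str, int, int]]:
    """Autozygous (IBD) segments of a diploid genome as (chrom, start, end)."""
    return focal.autozygous_intervals()


@dataclass
class ModelRun:
    """Results of simulating one pedigree model many times."""

    model_id: str
    n_reps: int
    per_rep_segments: list[list[tuple[str, int, int]]]  # post-processed
    pre_filter_fractions: np.ndarray  # autozygous genome fraction per rep
    post_filter_fractions: np.ndarray
    genome_length: int = 0

    @property
    def pooled_lengths(self) -> np.ndarray:
        return np.array(
            [e - s for segs in self.per_rep_segments for _, s, e in segs],
            dtype=np.int64,
        )

    @property
    def mean_segment_count(self) -> float:
        return float(np.mean([len(s) for s in self.per_rep_segments]))

    @property
    def mean_autozygous_fraction(self) -> float:
        return float(self.pre_filter_fractions.mean())


def run_model(
    model: PedigreeModel,
    build: GenomeBuild,
    rates: RecombinationRates,
    n_reps: int = 10_000,
    seed: int | np.random.SeedSequence = 0,
    min_length: int = 2_000_000,
    max_gap: int = 500_000,
) -> ModelRun:
    """Simulate ``n_reps`` focal individuals under one pedigree model.

    Autozygous segments of each replicate are post-processed with the
    same rules applied to the observed callset (merge gaps < ``max_gap``,
    then drop segments < ``min_length``) so simulated and observed
    length distributions are comparable.  Each replicate has its own
    deterministic random stream derived from ``seed``.
    """
    from .roh import postprocess_intervals

    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    root = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    streams = root.spawn(n_reps)
    total_len = build.total_length
    per_rep: list[list[tuple[str, int, int]]] = []
    pre = np.empty(n_reps)
    post = np.empty(n_reps)
    for r in range(n_reps):
        rng = np.random.default_rng(streams[r])
        focal = simulate_pedigree(model, build, rates, rng)
        raw = focal.autozygous_intervals()
        pre[r] = sum(e - s for _, s, e in raw) / total_len
        kept = postprocess_intervals(raw, min_length=min_length, max_gap=max_gap)
        post[r] = sum(e - s for _, s, e in kept) / total_len
        per_rep.append(kept)
    return ModelRun(model.model_id, n_reps, per_rep, pre, post, total_len)
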