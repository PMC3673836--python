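"""Gene-dropping simulator: founders, meioses, IBD extraction, models."""

import numpy as np
import pytest

from autozygy.genome import GenomeBuild
from autozygy.pedigree import (
    MODELS,
    FounderLabeledGenome,
    PedigreeModel,
    RecombinationRates,
    extract_autozygous,
    make_founder,
    meiosis,
    run_model,
    simulate_pedigree,
)

MB = 1_000_000

#: rate so small that crossovers essentially never occur (Poisson mean ~1e-13)
NO_RECOMBINATION = RecombinationRates(male_rate=1e-21, female_rate=1e-21)


def label_counter():
    from itertools import count

    return count()


class TestFounders:
    def test_two_distinct_single_segment_haplotypes(self, one_chrom_build):
        f = make_founder(one_chrom_build, label_counter())
        (h1, h2), = f.chroms
        assert h1[0] == [0] and h2[0] == [0]
        assert h1[1][0] != h2[1][0]

    def test_founder_autozygosity_zero(self, tiny_build):
        f = make_founder(tiny_build, label_counter())
        assert f.autozygous_fraction() == 0.0

    def test_two_founders_share_no_labels(self, tiny_build):
        src = label_counter()
        a = make_founder(tiny_build, src)
        b = make_founder(tiny_build, src)
        labels = lambda g: {l for h1, h2 in g.chroms for l in h1[1] + h2[1]}
        assert labels(a) & labels(b) == set()


class TestMeiosis:
    def test_no_recombination_copies_one_haplotype(self, tiny_build):
        f = make_founder(tiny_build, label_counter())
        rng = np.random.default_rng(0)
        picks = set()
        for _ in range(50):
            gam = meiosis(f, "M", NO_RECOMBINATION, rng)
            for (h1, h2), g in zip(f.chroms, gam):
                assert g in (h1, h2)
                picks.add(g[1][0])
        assert len(picks) == 2  # both founder haplotypes get transmitted

    def test_crossover_mean_matches_rate(self):
        """Observable breakpoints per gamete ~ rate x length (100 Mbp)."""
        build = GenomeBuild((("chr1", 100 * MB),))
        f = make_founder(build, label_counter())
        rates = RecombinationRates()
        rng = np.random.default_rng(2024)
        n = 4000
        female = np.empty(n)
        male = np.empty(n)
        for i in range(n):
            female[i] = len(meiosis(f, "F", rates, rng)[0][0]) - 1
            male[i] = len(meiosis(f, "M", rates, rng)[0][0]) - 1
        se_f = np.sqrt(1.4 / n)
        se_m = np.sqrt(0.89 / n)
        assert abs(female.mean() - 1.4) < 4 * se_f
        assert abs(male.mean() - 0.89) < 4 * se_m

    def test_female_to_male_crossover_ratio(self):
        build = GenomeBuild((("chr1", 200 * MB),))
        f = make_founder(build, label_counter())
        rates = RecombinationRates()
        rng = np.random.default_rng(5)
        n = 3000
        fm = np.mean([len(meiosis(f, "F", rates, rng)[0][0]) - 1 for _ in range(n)])
        mm = np.mean([len(meiosis(f, "M", rates, rng)[0][0]) - 1 for _ in range(n)])
        assert fm / mm == pytest.approx(1.4 / 0.89, rel=0.15)

    def test_labels_conserved_from_parent(self, tiny_build):
        src = label_counter()
        f = make_founder(tiny_build, src)
        rng = np.random.default_rng(3)
        rates = RecombinationRates(male_rate=5e-8, female_rate=5e-8)  # many crossovers
        for _ in range(20):
            gam = meiosis(f, "F", rates, rng)
            for (h1, h2), g in zip(f.chroms, gam):
                parent_labels = set(h1[1]) | set(h2[1])
                assert set(g[1]) <= parent_labels
                # full chromosome length covered
                assert g[0][0] == 0
                assert all(a < b for a, b in zip(g[0], g[0][1:]))

    def test_invalid_rates_rejected(self):
        with pytest.raises(ValueError):
            RecombinationRates(male_rate=0.0)
        with pytest.raises(ValueError):
            RecombinationRates().rate_for("X")


class TestModels:
    def test_registry_has_ten_models_in_five_classes(self):
        assert len(MODELS) == 10
        classes = {"half_sib", "uncle_niece", "aunt_nephew",
                   "grandfather_granddaughter", "grandmother_grandson"}
        for cls in classes:
            assert sum(1 for m in MODELS if m.startswith(cls)) == 2
        for m in MODELS.values():
            assert m.inbreeding_coefficient == 0.125

    def test_cyclic_parent_map_rejected(self):
        with pytest.raises(ValueError, match="cyclic"):
            PedigreeModel(
                "bad", (("A", "M"), ("B", "F")),
                {"A": ("A", "B"), "B": ("A", "B")}, "A",
            )

    def test_wrong_parent_sex_rejected(self):
        with pytest.raises(ValueError, match="father"):
            PedigreeModel(
                "bad", (("A", "F"), ("B", "F"), ("C", "F")),
                {"C": ("A", "B")}, "C",
            )


class TestSimulatePedigree:
    def test_unrelated_parents_give_zero_autozygosity(self, tiny_build):
        model = PedigreeModel(
            "outbred", (("F", "M"), ("M", "F"), ("X", "F")),
            {"X": ("F", "M")}, "X", inbreeding_coefficient=0.0,
        )
        rng = np.random.default_rng(11)
        focal = simulate_pedigree(model, tiny_build, RecombinationRates(), rng)
        assert extract_autozygous(focal) == []

    def test_fixed_seed_reproducible(self, tiny_build):
        model = MODELS["uncle_niece_paternal"]
        a = simulate_pedigree(model, tiny_build, RecombinationRates(),
                              np.random.default_rng(99))
        b = simulate_pedigree(model, tiny_build, RecombinationRates(),
                              np.random.default_rng(99))
        assert a.chroms == b.chroms

    def test_mean_autozygosity_near_pedigree_f(self):
        """Genome-wide mean IBD fraction approaches F = 0.125 (small run;
        the 10-model full-scale check lives in the acceptance suite)."""
        build = GenomeBuild((("chr1", 200 * MB), ("chr2", 150 * MB),
                             ("chr3", 100 * MB)))
        run = run_model(MODELS["half_sib_shared_mother"], build,
                        RecombinationRates(), n_reps=600, seed=21)
        se = run.pre_filter_fractions.std() / np.sqrt(run.n_reps)
        assert abs(run.pre_filter_fractions.mean() - 0.125) < 4 * se + 0.005


class TestExtractAutozygous:
    def test_identical_haplotypes_whole_chromosome(self, one_chrom_build):
        hap = ([0], [7])
        g = FounderLabeledGenome(one_chrom_build, [(hap, ([0], [7]))])
        assert extract_autozygous(g) == [("chr1", 0, 10 * MB)]

    def test_disjoint_labels_empty(self, one_chrom_build):
        g = FounderLabeledGenome(one_chrom_build, [(([0], [1]), ([0], [2]))])
        assert extract_autozygous(g) == []

    def test_matches_per_kbp_brute_force(self):
        """Random breakpoint structures vs per-kbp label comparison."""
        rng = np.random.default_rng(31)
        L = 5_000_000
        build = GenomeBuild((("chr1", L),))
        for _ in range(50):
            def random_hap():
                k = int(rng.integers(0, 8))
                starts = [0] + sorted(
                    int(p) * 1000 for p in rng.choice(L // 1000, k, replace=False)
                    if p > 0
                )
                labels = []
                for i in range(len(starts)):
                    choices = [l for l in range(4) if not labels or l != labels[-1]]
                    labels.append(int(rng.choice(choices)))
                return starts, labels

            h1, h2 = random_hap(), random_hap()
            got = extract_autozygous(FounderLabeledGenome(build, [(h1, h2)]))

            def label_at(h, pos):
                s, l = h
                i = np.searchsorted(s, pos, side="right") - 1
                return l[i]

            grid = np.arange(0, L, 1000)
            same = np.array([label_at(h1, p) == label_at(h2, p) for p in grid])
            expected = []
            start = None
            for p, eq in zip(grid, same):
                if eq and start is None:
                    start = p
                elif not eq and start is not None:
                    expected.append(("chr1", int(start), int(p)))
                    start = None
            if start is not None:
                expected.append(("chr1", int(start), L))
            assert got == expected

    def test_segments_never_span_chromosomes(self, tiny_build):
        rng = np.random.default_rng(41)
        model = MODELS["uncle_niece_maternal"]
        rates = RecombinationRates(male_rate=3e-8, female_rate=5e-8)
        for _ in range(10):
            focal = simulate_pedigree(model, tiny_build, rates, rng)
            for chrom, s, e in extract_autozygous(focal):
                assert 0 <= s < e <= tiny_build.length_of(chrom)


class TestRunModel:
    def test_single_replicate_stable(self, tiny_build):
        a = run_model(MODELS["half_sib_shared_father"], tiny_build,
                      RecombinationRates(), n_reps=1, seed=77)
        b = run_model(MODELS["half_sib_shared_father"], tiny_build,
                      RecombinationRates(), n_reps=1, seed=77)
        assert a.per_rep_segments == b.per_rep_segments
        np.testing.assert_array_equal(a.pre_filter_fractions, b.pre_filter_fractions)

    def test_post_filter_fraction_below_pre_filter(self):
        """Dropping short true IBD segments can only lose autozygosity."""
        build = GenomeBuild((("chr1", 150 * MB), ("chr2", 100 * MB)))
        run = run_model(MODELS["half_sib_shared_father"], build,
                        RecombinationRates(), n_reps=400, seed=9)
        # (per replicate, gap-merging may add back a little span, so only
        # the mean is ordered)
        assert run.post_filter_fractions.mean() < run.pre_filter_fractions.mean()

    def test_fewer_meioses_give_fewer_longer_segments(self):
        """A grandparent-grandchild pedigree funnels fewer meioses into the
        focal IBD than a half-sib pedigree: fewer, longer segments."""
        build = GenomeBuild((("chr1", 250 * MB), ("chr2", 200 * MB),
                             ("chr3", 150 * MB)))
        gp = run_model(MODELS["grandfather_granddaughter_via_son"], build,
                       RecombinationRates(), n_reps=500, seed=55)
        hs = run_model(MODELS["half_sib_shared_father"], build,
                       RecombinationRates(), n_reps=500, seed=56)
        assert gp.mean_segment_count < hs.mean_segment_count
        assert gp.pooled_lengths.mean() > hs.pooled_lengths.mean()

    def test_invalid_reps(self, tiny_build):
        with pytest.raises(ValueError):
            run_model(MODELS["half_sib_shared_father"], tiny_build,
                      RecombinationRates(), n_reps=0, seed=1)
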