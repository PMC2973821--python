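import numpy as np
import pandas as pd
import pytest

from divsel import (
    BreedingScheme,
    HaplotypeFreqs,
    Population,
    SelectionParams,
    init_population,
    neutral_fixation_probabilities,
    run_replicates,
    step_generation,
)
from divsel.forward_sim import ParentShortageError


def make_population(n_AA, n_aa, scheme, seed=0):
    """Half-male population of AA and aa homozygotes (B fixed), batched x1."""
    n = n_AA + n_aa
    assert n == scheme.census
    a = np.array([1] * n_AA + [0] * n_aa, dtype=np.int8)[None, :]
    male = np.zeros((1, n), dtype=bool)
    male[0, ::2] = True
    return Population(hapA1=a.copy(), hapB1=np.ones_like(a), hapA2=a.copy(),
                      hapB2=np.ones_like(a), male=male)


class TestInitPopulation:
    def test_degenerate_code_7000_is_fixed(self):
        pop = init_population(HaplotypeFreqs("7000"), BreedingScheme(), seed=0)
        fixed, allele = pop.fixed_at("A")
        assert fixed.all() and (allele == 1).all()
        fixed_b, allele_b = pop.fixed_at("B")
        assert fixed_b.all() and (allele_b == 1).all()

    def test_bad_code_rejected(self):
        with pytest.raises(ValueError, match="sum to 7"):
            HaplotypeFreqs("4004")
        with pytest.raises(ValueError, match="four digits"):
            HaplotypeFreqs("43")

    def test_founder_haplotype_fractions_binomial(self):
        scheme = BreedingScheme()
        pop = init_population(HaplotypeFreqs("4003"), scheme, seed=1, n_reps=50)
        counts = pop.gamete_counts()
        n_hap = 2 * scheme.census * 50
        frac_ab = counts[:, 0].sum() / n_hap
        se = np.sqrt((4 / 7) * (3 / 7) / n_hap)
        assert abs(frac_ab - 4 / 7) < 3 * se
        assert counts[:, 1].sum() == 0 and counts[:, 2].sum() == 0  # only AB/ab drawn

    def test_same_seed_identical(self):
        a = init_population(HaplotypeFreqs("2230"), BreedingScheme(), seed=9)
        b = init_population(HaplotypeFreqs("2230"), BreedingScheme(), seed=9)
        np.testing.assert_array_equal(a.hapA1, b.hapA1)
        np.testing.assert_array_equal(a.hapB2, b.hapB2)
        np.testing.assert_array_equal(a.male, b.male)


class TestStepGeneration:
    def test_census_constant(self):
        scheme = BreedingScheme()
        rng = np.random.default_rng(2)
        pop = init_population(HaplotypeFreqs("4003"), scheme, rng)
        for _ in range(3):
            pop = step_generation(pop, scheme, SelectionParams(0.3, 0.2), 0.1, rng)
            assert pop.size == scheme.census == 288

    def test_neutral_drift_is_martingale(self):
        """s=0, r=0: replicate-averaged allele-A frequency change ~ 0."""
        scheme = BreedingScheme()
        rng = np.random.default_rng(3)
        pop = init_population(HaplotypeFreqs("4003"), scheme, rng, n_reps=500)
        p0 = pop.freq_A().mean()
        for _ in range(5):
            pop = step_generation(pop, scheme, SelectionParams(), 0.0, rng)
        p = pop.freq_A()
        se = p.std(ddof=1) / np.sqrt(p.size)
        assert abs(p.mean() - p0) < 3 * se

    def test_lethal_homozygote_never_breeds(self):
        """s=1: aa parents have fitness 0, so allele a is purged in one step."""
        scheme = BreedingScheme()
        rng = np.random.default_rng(4)
        pop = make_population(200, 88, scheme)
        nxt = step_generation(pop, scheme, SelectionParams(1.0, 1.0, 0.5), 0.0, rng)
        assert (nxt.hapA1 == 1).all() and (nxt.hapA2 == 1).all()

    def test_association_decays_only_with_recombination(self):
        """Founders carry only AB/ab; repulsion gametes appear iff r > 0."""
        scheme = BreedingScheme()
        results = {}
        for r in (0.0, 0.5):
            rng = np.random.default_rng(5)
            pop = init_population(HaplotypeFreqs("4003"), scheme, rng, n_reps=200)
            for _ in range(5):
                pop = step_generation(pop, scheme, SelectionParams(), r, rng)
            counts = pop.gamete_counts().astype(float)
            frac = counts / counts.sum(axis=1, keepdims=True)
            d = frac[:, 0] * frac[:, 3] - frac[:, 1] * frac[:, 2]
            results[r] = (counts[:, 1].sum() + counts[:, 2].sum(), np.abs(d).mean())
        assert results[0.0][0] == 0            # no repulsion gametes without crossover
        assert results[0.5][0] > 0
        assert results[0.5][1] < results[0.0][1]  # association decays toward 0

    def test_shortage_error_names_sex(self):
        scheme = BreedingScheme()
        pop = init_population(HaplotypeFreqs("4003"), scheme, seed=6)
        pop.male[:] = True
        with pytest.raises(ParentShortageError, match="female"):
            step_generation(pop, scheme, SelectionParams(), 0.1, np.random.default_rng(0))


class TestRunReplicates:
    def test_reproducible_and_records_fixation(self):
        args = (HaplotypeFreqs("4003"), BreedingScheme(), SelectionParams(0.31, 0.19), 0.05)
        a = run_replicates(*args, n_reps=40, max_gen=15, seed=7)
        b = run_replicates(*args, n_reps=40, max_gen=15, seed=7)
        pd.testing.assert_frame_equal(a.replicates, b.replicates)
        assert a.prop_fixed_A_by_gen[0] == 0.0
        assert np.all(np.diff(a.prop_fixed_A_by_gen) >= 0)

    def test_strong_selection_fixes_selected_allele(self):
        """With s near 1, every fixed replicate fixes the selected allele."""
        out = run_replicates(
            HaplotypeFreqs("4003"), BreedingScheme(),
            SelectionParams(0.93, 0.56), 0.05, n_reps=60, max_gen=20, seed=8,
        )
        fixed = out.replicates["fix_gen_A"].notna()
        assert fixed.mean() > 0.9
        assert (out.replicates.loc[fixed, "allele_A"] == 1).all()

    def test_fixation_proportion_monotone_in_s(self):
        """Stronger selection fixes more replicates by the same horizon."""
        props = []
        for s in (0.0, 0.15, 0.31, 0.93):
            out = run_replicates(
                HaplotypeFreqs("4003"), BreedingScheme(),
                SelectionParams(s, s * 0.6, 0.5), 0.05,
                n_reps=150, max_gen=25, seed=10,
            )
            props.append(out.prop_fixed_A)
        assert props == sorted(props)

    def test_heterozygosity_decay_rate_matches_effective_size(self):
        """Neutral gene diversity at locus A decays geometrically at a rate
        1 - 1/(2Ne) with Ne inside the scheme's plausible 27-45 band."""
        scheme = BreedingScheme()
        rng = np.random.default_rng(12)
        pop = init_population(HaplotypeFreqs("4003"), scheme, rng, n_reps=300)
        het = []
        for _ in range(15):
            p = pop.freq_A()
            het.append(np.mean(2 * p * (1 - p)))
            pop = step_generation(pop, scheme, SelectionParams(), 0.5, rng)
        rate = np.exp(np.polyfit(np.arange(len(het)), np.log(het), 1)[0])
        ne_fit = 1.0 / (2.0 * (1.0 - rate))
        assert 27 < ne_fit < 45


class TestNeutralFixation:
    def test_already_fixed_start(self):
        probs = neutral_fixation_probabilities(
            HaplotypeFreqs("7000"), BreedingScheme(), n_reps=20, max_gen=5, seed=0
        )
        assert probs["p_fix_A"] == 1.0 and probs["p_fix_a"] == 0.0

    def test_longer_horizon_never_loses_fixations(self):
        short = neutral_fixation_probabilities(
            HaplotypeFreqs("4003"), BreedingScheme(), n_reps=100, max_gen=20, seed=14
        )
        long = neutral_fixation_probabilities(
            HaplotypeFreqs("4003"), BreedingScheme(), n_reps=100, max_gen=40, seed=14
        )
        assert long["p_fix_A"] >= short["p_fix_A"]
        assert long["p_fix_a"] >= short["p_fix_a"]
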