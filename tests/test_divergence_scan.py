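import itertools
from math import comb

import numpy as np
import pytest
from scipy import stats

from divsel import (
    GroupAlleleCounts,
    SweepSpec,
    SynthConfig,
    allelic_chi2,
    block_change_scan,
    compare_heterozygosity_decline,
    fisher_exact,
    generate_dataset,
    heterozygosity_decline,
    max_chi2,
    observed_heterozygosity,
    poisson_window_threshold,
    scan,
    sliding_window_mean,
)
from divsel.genotype_model import GenotypePanel


def fisher_oracle(a, b, c, d):
    """Two-sided Fisher p by full enumeration over tables with fixed margins."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    denom = comb(n, c1)
    p_obs = comb(r1, a) * comb(r2, c) / denom
    p = 0.0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        px = comb(r1, x) * comb(r2, c1 - x) / denom
        if px <= p_obs * (1 + 1e-12):
            p += px
    return p


class TestAllelicChi2:
    @pytest.mark.parametrize(
        "table,expected",
        [
            ((40, 0, 0, 40), 80.0),     # 20 vs 20 birds, alternative fixation
            ((98, 0, 0, 20), 118.0),    # 49 vs 10 birds
            ((10, 10, 10, 10), 0.0),    # identical frequencies
        ],
    )
    def test_fixation_identity(self, table, expected):
        chi2, p = allelic_chi2(GroupAlleleCounts(*table))
        assert chi2 == pytest.approx(expected)
        assert 0 < p <= 1

    def test_equals_total_allele_count_for_any_group_sizes(self):
        for n1, n2 in [(3, 5), (20, 20), (49, 10), (1, 100)]:
            chi2, _ = allelic_chi2(GroupAlleleCounts(2 * n1, 0, 0, 2 * n2))
            assert chi2 == pytest.approx(max_chi2(n1, n2))

    def test_matches_scipy_and_symmetries(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            a, b, c, d = rng.integers(0, 40, size=4)
            if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
                continue
            chi2, p = allelic_chi2(GroupAlleleCounts(a, b, c, d))
            ref = stats.chi2_contingency([[a, b], [c, d]], correction=False)
            assert chi2 == pytest.approx(ref.statistic)
            assert p == pytest.approx(ref.pvalue)
            # invariant to swapping allele labels and swapping groups
            assert allelic_chi2(GroupAlleleCounts(b, a, d, c))[0] == pytest.approx(chi2)
            assert allelic_chi2(GroupAlleleCounts(c, d, a, b))[0] == pytest.approx(chi2)

    def test_monomorphic_is_undefined(self):
        chi2, p = allelic_chi2(GroupAlleleCounts(10, 0, 4, 0))
        assert np.isnan(chi2) and np.isnan(p)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            allelic_chi2(GroupAlleleCounts(0, 0, 5, 5))


class TestFisherExact:
    def test_small_table_enumeration(self):
        assert fisher_exact(GroupAlleleCounts(2, 0, 0, 2)) == pytest.approx(1 / 3)

    def test_identical_columns(self):
        assert fisher_exact(GroupAlleleCounts(5, 5, 5, 5)) == pytest.approx(1.0)

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(30):
            a, b, c, d = rng.integers(0, 8, size=4)
            if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
                continue
            p = fisher_exact(GroupAlleleCounts(a, b, c, d))
            assert p == pytest.approx(fisher_oracle(a, b, c, d), rel=1e-9)


class TestScan:
    def test_planted_sweep_flagged_and_capped(self, sweep_dataset):
        _, ds = sweep_dataset
        panel = ds.panels[40]
        res = scan(panel, ("HIGH", 40), ("LOW", 40))
        core = ds.truth["in_sweep_core"].to_numpy()
        assert res.table.loc[core, "sig_0.001"].all()
        # chi-square at fully fixed SNPs equals the total allele count
        np.testing.assert_allclose(res.table.loc[core, "chi2"], 80.0)
        # Bonferroni monotonicity
        assert (res.table["sig_0.05"] | ~res.table["sig_0.001"]).all()

    def test_identical_groups_flag_nothing(self):
        rng = np.random.default_rng(5)
        geno = rng.choice([0, 1, 2], size=(40, 50)).astype(np.int8)
        panel = GenotypePanel(
            sample_ids=[f"s{i}" for i in range(40)],
            line=np.array(["HIGH"] * 20 + ["LOW"] * 20, dtype=object),
            generation=np.full(40, 40),
            genotypes=np.vstack([geno[:20], geno[:20]]),
            snp_ids=[f"m{j}" for j in range(50)],
        )
        res = scan(panel, ("HIGH", 40), ("LOW", 40))
        assert not res.table["sig_0.05"].any()

    def test_chi2_and_fisher_rank_agree_on_well_filled_tables(self, sweep_dataset):
        _, ds = sweep_dataset
        res = scan(ds.panels[40], ("HIGH", 40), ("LOW", 40), include_fisher=True)
        t = res.table.dropna(subset=["p", "fisher_p"])
        # restrict to tables with all cells >= 5: frequencies away from 0/1
        fh = ds.truth["p_HIGH_40"]
        fl = ds.truth["p_LOW_40"]
        mid = ((fh * 40 >= 5) & ((1 - fh) * 40 >= 5) & (fl * 40 >= 5) & ((1 - fl) * 40 >= 5))
        t = t[mid.to_numpy()[t.index]]
        k = max(1, len(t) // 10)
        top_chi = set(t.nsmallest(k, "p").index)
        top_fis = set(t.nsmallest(k, "fisher_p").index)
        assert len(top_chi & top_fis) / k > 0.8


class TestSlidingWindow:
    def test_constant_series(self):
        vals = np.full(30, 2.5)
        chrom = np.array(["1"] * 30)
        np.testing.assert_allclose(sliding_window_mean(vals, chrom, 20), 2.5)

    def test_single_spike_spreads_mass(self):
        vals = np.zeros(101)
        vals[50] = 1.0
        out = sliding_window_mean(vals, np.array(["1"] * 101), 20)
        assert out[50] == pytest.approx(1 / 20)
        assert out[0] == 0.0

    def test_matches_brute_force(self):
        rng = np.random.default_rng(3)
        vals = rng.random(60)
        chrom = np.array(["1"] * 35 + ["2"] * 25)
        w = 7
        out = sliding_window_mean(vals, chrom, w)
        for j in range(60):
            lo = max(0, j - w // 2)
            same = np.flatnonzero(chrom == chrom[j])
            win = [k for k in range(j - w // 2, j - w // 2 + w) if 0 <= k < 60 and chrom[k] == chrom[j]]
            assert out[j] == pytest.approx(np.mean(vals[win]))

    def test_normalization(self):
        vals = np.full(10, 40.0)
        out = sliding_window_mean(vals, np.array(["1"] * 10), 5, normalize_by=80.0)
        np.testing.assert_allclose(out, 0.5)


class TestBlockChangeScan:
    def test_poisson_threshold(self):
        assert poisson_window_threshold(1e-5, 1.0) == 9
        assert poisson_window_threshold(0.05, 1.0) == 4

    def test_outlier_fraction_bounded(self):
        cfg = SynthConfig(n_snps=2000, seed=21)
        ds = generate_dataset(cfg)
        from divsel.genotype_model import concat_panels

        panel = concat_panels([ds.panels[40], ds.panels[50]])
        bs = block_change_scan(panel, ds.marker_map, "HIGH", 40, 50)
        frac = bs.blocks["outlier"].mean()
        assert frac <= 0.05 + 1e-9  # ties resolved downward

    def test_planted_ongoing_sweep_found(self):
        """A sweep completing between the two timepoints shows up as
        significant 20-block windows overlapping the planted region."""
        cfg = SynthConfig(
            n_snps=4000,
            sweeps=[SweepSpec(chromosome="1", center_bp=10_000_000,
                              half_width_bp=800_000, line_favoured="HIGH",
                              fixation_generation=50)],
            seed=23,
        )
        ds = generate_dataset(cfg)
        from divsel.genotype_model import concat_panels

        panel = concat_panels([ds.panels[40], ds.panels[50]])
        bs = block_change_scan(panel, ds.marker_map, "HIGH", 40, 50)
        sig = bs.windows[bs.windows["significant"]]
        assert len(sig) > 0
        hits = sig[
            (sig["chromosome"] == "1")
            & (sig["start_bp"] <= 10_800_000)
            & (sig["end_bp"] >= 9_200_000)
        ]
        assert len(hits) > 0


class TestHeterozygosity:
    def test_all_het_panel(self):
        panel = GenotypePanel(
            sample_ids=["a", "b"],
            line=np.array(["HIGH", "HIGH"], dtype=object),
            generation=np.array([40, 40]),
            genotypes=np.ones((2, 4), dtype=np.int8),
            snp_ids=list("wxyz"),
        )
        np.testing.assert_allclose(observed_heterozygosity(panel, "HIGH", 40), 1.0)

    def test_identical_generations_give_zero_t(self):
        rng = np.random.default_rng(7)
        geno = rng.choice([0, 1, 2], size=(10, 30)).astype(np.int8)
        panel = GenotypePanel(
            sample_ids=[f"s{i}" for i in range(20)],
            line=np.array(["HIGH"] * 10 + ["LOW"] * 10, dtype=object),
            generation=np.array([40] * 5 + [50] * 5 + [40] * 5 + [50] * 5),
            genotypes=np.vstack([geno[:5], geno[:5], geno[5:10], geno[5:10]]),
            snp_ids=[f"m{j}" for j in range(30)],
        )
        dh = heterozygosity_decline(panel, "HIGH", 40, 50)
        dl = heterozygosity_decline(panel, "LOW", 40, 50)
        assert np.nanmax(np.abs(dh.decrease)) == 0
        t, p = compare_heterozygosity_decline(dh, dl)
        assert t == 0.0 and np.isnan(p)

    def test_drift_decline_matches_decay_oracle(self):
        """Ne=35, 10 generations: mean H_o shrinks by ~(1 - 1/70)^10."""
        cfg = SynthConfig(n_snps=4000, seed=31)
        ds = generate_dataset(cfg)
        from divsel.genotype_model import concat_panels

        panel = concat_panels([ds.panels[40], ds.panels[50]])
        expected = (1 - 1 / 70) ** 10
        for line in ("HIGH", "LOW"):
            h40 = observed_heterozygosity(panel, line, 40)
            h50 = observed_heterozygosity(panel, line, 50)
            blocks = ds.truth["block"].to_numpy()
            import pandas as pd

            bm = pd.DataFrame({"b": blocks, "h40": h40, "h50": h50}).groupby("b").mean()
            ratio = bm["h50"].mean() / bm["h40"].mean()
            n = len(bm)
            se = ratio * np.sqrt(
                bm["h40"].var() / (n * bm["h40"].mean() ** 2)
                + bm["h50"].var() / (n * bm["h50"].mean() ** 2)
            )
            assert abs(ratio - expected) < 3 * se
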