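import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from txnorm import (
    AllUbiquitousScaler,
    CPMScaler,
    DegenerateInputError,
    DomainError,
    GeNormScaler,
    GuideGeneScaler,
    PercentileScaler,
    RandomScaler,
    RandomUbiquitousScaler,
    StabilityScaler,
    TMMScaler,
    TotalCountScaler,
    TotalUbiquitousScaler,
    adjust_factors,
    genorm_select,
    stability_select,
)

positive_factors = st.lists(
    st.floats(min_value=1e-3, max_value=1e3), min_size=2, max_size=8
)


class TestAdjustFactors:
    def test_worked_examples(self):
        np.testing.assert_allclose(adjust_factors(pd.Series([2.0, 0.5])), [2.0, 0.5])
        np.testing.assert_allclose(adjust_factors(pd.Series([4.0, 1.0])), [2.0, 0.5])

    @given(positive_factors)
    def test_product_one_and_ratio_preservation(self, raw):
        f = pd.Series(raw)
        adj = adjust_factors(f)
        assert np.prod(adj) == pytest.approx(1.0, rel=1e-9)
        np.testing.assert_allclose(adj / adj.iloc[0], f / f.iloc[0], rtol=1e-12)

    @given(positive_factors, st.floats(min_value=1e-3, max_value=1e3))
    def test_scale_invariance_and_idempotence(self, raw, c):
        f = pd.Series(raw)
        np.testing.assert_allclose(adjust_factors(c * f), adjust_factors(f), rtol=1e-9)
        np.testing.assert_allclose(adjust_factors(adjust_factors(f)), adjust_factors(f), rtol=1e-9)

    def test_rejects_nonpositive(self):
        with pytest.raises(DomainError):
            adjust_factors(pd.Series([1.0, 0.0]))


class TestTotalsScalers:
    def test_cpm_factors_and_totals(self):
        m = pd.DataFrame({"A": [4.0, 6.0], "B": [8.0, 12.0]}, index=["g1", "g2"])
        scaler = CPMScaler().fit(m)
        np.testing.assert_allclose(scaler.factors_, [1e5, 5e4])
        np.testing.assert_allclose(scaler.transform(m).sum(axis=0), [1e6, 1e6])

    def test_cpm_identity_at_one_million(self):
        m = pd.DataFrame({"A": [4e5, 6e5], "B": [1.0, 2.0]}, index=["g1", "g2"])
        assert CPMScaler().fit(m).factors_["A"] == pytest.approx(1.0)

    def test_cpm_random_matrix_totals(self, random_matrix):
        scaled = CPMScaler().fit_transform(random_matrix)
        np.testing.assert_allclose(scaled.sum(axis=0), 1e6, rtol=1e-9)

    def test_cpm_all_zero_sample(self):
        m = pd.DataFrame({"A": [1.0, 2.0], "B": [0.0, 0.0]}, index=["g1", "g2"])
        with pytest.raises(DegenerateInputError):
            CPMScaler().fit(m)

    def test_total_equalizes_to_average_and_conserves(self):
        m = pd.DataFrame({"A": [4.0, 6.0], "B": [12.0, 18.0]}, index=["g1", "g2"])
        scaler = TotalCountScaler().fit(m)
        np.testing.assert_allclose(scaler.factors_, [2.0, 2 / 3])
        scaled = scaler.transform(m)
        np.testing.assert_allclose(scaled.sum(axis=0), [20.0, 20.0])
        assert scaled.sum().sum() == pytest.approx(m.sum().sum())

    def test_total_identity_for_equal_totals(self, random_matrix):
        m = CPMScaler().fit_transform(random_matrix)
        np.testing.assert_allclose(TotalCountScaler().fit(m).factors_, 1.0, rtol=1e-9)


class TestPercentileScaler:
    def test_worked_example(self):
        # 75th-percentile values (nearest rank: ceil(0.75*4) = 3) are 4 and 8
        # -> factors (1.5, 0.75); after scaling both share the value 6
        m = pd.DataFrame(
            {"A": [1.0, 2.0, 4.0, 9.0], "B": [2.0, 4.0, 8.0, 18.0]}, index=list("wxyz")
        )
        scaler = PercentileScaler(q=0.75).fit(m)
        np.testing.assert_allclose(scaler.factors_, [1.5, 0.75])
        assert scaler.transform(m)["A"].sort_values().iloc[2] == pytest.approx(6.0)
        assert scaler.transform(m)["B"].sort_values().iloc[2] == pytest.approx(6.0)

    def test_identical_samples_give_unit_factors(self, random_matrix):
        m = random_matrix.copy()
        m["S1"] = m["S0"]
        scaler = PercentileScaler(q=0.75).fit(m[["S0", "S1"]])
        np.testing.assert_allclose(scaler.factors_, 1.0)

    def test_upper_decile_differs_from_quartile(self, random_matrix):
        f75 = PercentileScaler(q=0.75).fit(random_matrix).factors_
        f90 = PercentileScaler(q=0.90).fit(random_matrix).factors_
        assert not np.allclose(f75, f90)

    def test_zero_quantile_is_degenerate(self):
        m = pd.DataFrame({"A": [0.0, 0.0, 1.0], "B": [1.0, 2.0, 3.0]}, index=list("xyz"))
        with pytest.raises(DegenerateInputError, match="nonzero_only"):
            PercentileScaler(q=0.5).fit(m)
        # nonzero_only rescues the same input
        PercentileScaler(q=0.5, nonzero_only=True).fit(m)


class TestGuideGeneScaler:
    def test_single_gene_equalization(self):
        m = pd.DataFrame({"A": [10.0, 5.0], "B": [20.0, 7.0]}, index=["hk", "other"])
        scaler = GuideGeneScaler(["hk"]).fit(m)
        np.testing.assert_allclose(scaler.factors_, [np.sqrt(2), 1 / np.sqrt(2)])
        scaled = scaler.transform(m)
        assert scaled.loc["hk", "A"] == pytest.approx(scaled.loc["hk", "B"])

    def test_identical_guides_unit_factors(self):
        m = pd.DataFrame({"A": [3.0, 9.0], "B": [3.0, 1.0]}, index=["hk", "other"])
        np.testing.assert_allclose(GuideGeneScaler(["hk"]).fit(m).factors_, 1.0)

    def test_weight_rescaling_invariance(self, random_matrix):
        genes = list(random_matrix.index[:5])
        w1 = pd.Series([1.0, 2.0, 3.0, 4.0, 5.0], index=genes)
        f1 = GuideGeneScaler(w1).fit(random_matrix).factors_
        f2 = GuideGeneScaler(2 * w1).fit(random_matrix).factors_
        np.testing.assert_allclose(f1, f2, rtol=1e-12)

    def test_zero_guide_error_names_gene(self):
        m = pd.DataFrame({"A": [0.0, 1.0], "B": [2.0, 1.0]}, index=["YWHAZ", "ok"])
        with pytest.raises(DomainError, match="YWHAZ"):
            GuideGeneScaler(["YWHAZ"]).fit(m)

    def test_exact_recovery_of_planted_factors(self, planted):
        # guides exactly proportional -> recovers adjusted truth to 1e-9
        matrix, truth = planted
        noiseless = truth.base_profile.to_frame().to_numpy() * truth.true_factors.to_numpy()[None, :]
        m = pd.DataFrame(noiseless, index=truth.base_profile.index, columns=truth.true_factors.index)
        factors = GuideGeneScaler(list(m.index[:50])).fit(m).factors_
        expected = adjust_factors(1.0 / truth.true_factors)
        np.testing.assert_allclose(factors, expected, rtol=1e-9)

    def test_locality(self, random_matrix):
        genes = list(random_matrix.index[:3])
        f1 = GuideGeneScaler(genes).fit(random_matrix).factors_
        perturbed = random_matrix.copy()
        perturbed.iloc[-1, 0] *= 100
        f2 = GuideGeneScaler(genes).fit(perturbed).factors_
        np.testing.assert_allclose(f1, f2, rtol=1e-12)


class TestGeNorm:
    def _matrix(self):
        rng = np.random.default_rng(21)
        base = rng.lognormal(3, 1, size=6)
        # a, b exactly proportional; c scrambled; d mildly noisy
        a = base
        b = 2 * base
        c = rng.permutation(base) * rng.lognormal(0, 1, size=6)
        d = base * rng.lognormal(0, 0.05, size=6)
        return pd.DataFrame({"a": a, "b": b, "c": c, "d": d}, index=[f"s{i}" for i in range(6)]).T

    def test_scrambled_candidate_removed_first(self):
        selected, ranking = genorm_select(self._matrix(), ["a", "b", "c", "d"], k=3)
        assert ranking.index[0] == "c"
        assert selected == {"a", "b", "d"}

    def test_proportional_pair_zero_contribution(self):
        m = self._matrix()
        _, ranking = genorm_select(m, ["a", "b", "c"], k=3)
        # stdev of log-ratio between proportional a and b is zero, so their
        # M equals the stdev of the ratio against c alone, and matches
        log2 = np.log2(m.loc[["a", "b", "c"]].to_numpy())
        expected_a = np.std(log2[0] - log2[2], ddof=1) / 2 + np.std(log2[0] - log2[1], ddof=1) / 2
        assert ranking.loc["a", "M"] == pytest.approx(expected_a)

    def test_k_equal_to_candidates_is_identity(self):
        selected, ranking = genorm_select(self._matrix(), ["a", "b", "c"], k=3)
        assert selected == {"a", "b", "c"}
        assert len(ranking) == 3

    def test_too_few_candidates(self):
        with pytest.raises(DomainError):
            genorm_select(self._matrix(), ["a", "b"], k=3)

    def test_scaler_uses_selected_guides(self):
        m = self._matrix()
        scaler = GeNormScaler(k=3, candidates=["a", "b", "c", "d"]).fit(m)
        assert scaler.selected_ == {"a", "b", "d"}
        assert np.prod(scaler.factors_) == pytest.approx(1.0)


class TestStabilitySelect:
    def _matrix(self):
        rng = np.random.default_rng(8)
        # stable genes share a tight common profile; noisy genes fluctuate
        # far more across samples
        base = rng.lognormal(3, 0.2, size=10)
        stable = np.outer(rng.lognormal(2, 0.5, size=5), base)
        noisy = rng.lognormal(3, 1.2, size=(50, 10))
        genes = [f"stable{i}" for i in range(5)] + [f"noisy{i:02d}" for i in range(50)]
        return pd.DataFrame(np.vstack([stable, noisy]), index=genes, columns=[f"s{i}" for i in range(10)])

    def test_proportional_genes_selected(self):
        m = self._matrix()
        picked = stability_select(m, set(m.index), n=5, seed=3)
        assert set(picked.index) == {f"stable{i}" for i in range(5)}

    def test_pool_not_larger_than_n_warns_and_returns_pool(self):
        m = self._matrix()
        with pytest.warns(UserWarning, match="whole pool"):
            picked = stability_select(m, set(m.index[:4]), n=10, seed=0)
        assert set(picked.index) == set(m.index[:4])

    def test_seed_determinism(self):
        m = self._matrix()
        a = stability_select(m, set(m.index), n=8, seed=11)
        b = stability_select(m, set(m.index), n=8, seed=11)
        pd.testing.assert_series_equal(a, b)


class TestUbiquitousPoolScalers:
    def test_random_equals_all_when_exhaustive(self, random_matrix):
        pool = set(random_matrix.index[:20])
        f_rand = RandomUbiquitousScaler(n=20, seed=4, pool=pool).fit(random_matrix).factors_
        f_all = AllUbiquitousScaler(pool=pool).fit(random_matrix).factors_
        np.testing.assert_allclose(f_rand, f_all, rtol=1e-12)

    def test_random_seed_reproducible(self, random_matrix):
        pool = set(random_matrix.index[:30])
        f1 = RandomUbiquitousScaler(n=10, seed=9, pool=pool).fit(random_matrix).factors_
        f2 = RandomUbiquitousScaler(n=10, seed=9, pool=pool).fit(random_matrix).factors_
        np.testing.assert_allclose(f1, f2)

    def test_random_n_too_large(self, random_matrix):
        with pytest.raises(DomainError):
            RandomUbiquitousScaler(n=99, pool=set(random_matrix.index[:5])).fit(random_matrix)

    def test_larger_draws_track_truth_more_closely(self, planted):
        """Averaging more randomly drawn ubiquitous guide genes gives factor
        vectors closer to the planted truth (the n=10 draws are much less
        consistent than n=100)."""
        matrix, truth = planted
        target = adjust_factors(1.0 / truth.true_factors)
        pool = set(truth.core_genes)
        err = {n: [] for n in (10, 100)}
        for seed in range(10):
            for n in err:
                f = RandomUbiquitousScaler(n=n, seed=seed, pool=pool).fit(matrix).factors_
                err[n].append(np.abs(np.log2(f / target)).max())
        assert np.mean(err[100]) < np.mean(err[10])

    def test_total_ubiquitous_arithmetic(self):
        m = pd.DataFrame(
            {"A": [4.0, 6.0, 50.0], "B": [12.0, 18.0, 1.0]}, index=["u1", "u2", "x"]
        )
        scaler = TotalUbiquitousScaler(pool={"u1", "u2"}).fit(m)
        np.testing.assert_allclose(scaler.factors_, [2.0, 2 / 3])
        scaled = scaler.transform(m)
        assert scaled.loc[["u1", "u2"]].sum(axis=0).nunique() == 1

    def test_total_ubiquitous_pool_locality(self):
        m = pd.DataFrame(
            {"A": [4.0, 6.0, 50.0], "B": [12.0, 18.0, 1.0]}, index=["u1", "u2", "x"]
        )
        f1 = TotalUbiquitousScaler(pool={"u1", "u2"}).fit(m).factors_
        m2 = m.copy()
        m2.loc["x"] *= 1000
        f2 = TotalUbiquitousScaler(pool={"u1", "u2"}).fit(m2).factors_
        np.testing.assert_allclose(f1, f2)

    def test_empty_pool_raises(self, random_matrix):
        with pytest.raises((DomainError, DegenerateInputError)):
            TotalUbiquitousScaler(pool=set()).fit(random_matrix)


class TestRandomScaler:
    def test_factor_range_and_determinism(self, random_matrix):
        f1 = RandomScaler(seed=2).fit(random_matrix).factors_
        f2 = RandomScaler(seed=2).fit(random_matrix).factors_
        np.testing.assert_allclose(f1, f2)
        assert ((f1 >= 2**-0.5) & (f1 < 2**0.5)).all()

    def test_log_factors_centered(self):
        m = pd.DataFrame(
            np.ones((2, 10_000)), index=["g1", "g2"], columns=[f"s{i}" for i in range(10_000)]
        )
        f = RandomScaler(seed=0).fit(m).factors_
        logf = np.log2(f)
        se = np.std(logf, ddof=1) / np.sqrt(len(logf))
        assert abs(logf.mean()) < 3 * se


class TestTMM:
    def test_identical_samples_unit_factors(self, random_matrix):
        m = random_matrix[["S0", "S1"]].copy()
        m["S1"] = m["S0"]
        scaler = TMMScaler(reference_sample="S0").fit(m)
        np.testing.assert_allclose(scaler.factors_, 1.0, rtol=1e-9)

    def test_pure_depth_difference(self, random_matrix):
        # sample = 2x reference: fractions cancel, depth handled by totals
        m = random_matrix[["S0"]].copy()
        m["S1"] = 2 * m["S0"]
        scaler = TMMScaler(reference_sample="S0").fit(m)
        np.testing.assert_allclose(scaler.tmm_, 1.0, rtol=1e-9)
        scaled = scaler.transform(m)
        np.testing.assert_allclose(scaled["S0"], scaled["S1"], rtol=1e-9)

    def test_composition_bias_trimmed_away(self):
        rng = np.random.default_rng(0)
        base = np.exp2(rng.normal(4, 2, size=500))
        b = base.copy()
        b[rng.choice(500, 50, replace=False)] *= 100  # 10% inflated genes
        m = pd.DataFrame({"A": base, "B": b}, index=[f"g{i:03d}" for i in range(500)])
        scaler = TMMScaler(reference_sample="A").fit(m)
        # after trimming, the unchanged genes dominate: relative factor ~ 1
        assert scaler.factors_["B"] / scaler.factors_["A"] == pytest.approx(1.0, rel=0.05)

    def test_unknown_reference(self, random_matrix):
        with pytest.raises(DomainError):
            TMMScaler(reference_sample="nope").fit(random_matrix)


@pytest.mark.parametrize(
    "scaler",
    [
        CPMScaler(),
        TotalCountScaler(),
        PercentileScaler(q=0.75),
        RandomScaler(seed=1),
        TMMScaler(),
    ],
    ids=lambda s: s.method_name,
)
def test_within_sample_ratios_preserved(random_matrix, scaler):
    """Every factor-based method preserves within-sample gene ratios exactly."""
    scaled = scaler.fit(random_matrix).transform(random_matrix)
    ratio_before = random_matrix.iloc[0] / random_matrix.iloc[1]
    ratio_after = scaled.iloc[0] / scaled.iloc[1]
    np.testing.assert_allclose(ratio_after, ratio_before, rtol=1e-12)


def test_guide_methods_agree_as_noise_vanishes():
    """With vanishing multiplicative noise all guide-based factor vectors
    converge to the same product-1 truth."""
    from txnorm import SynthConfig, generate

    errs = {}
    for sigma in (0.2, 0.02):
        cfg = SynthConfig(
            n_samples=6, n_core_genes=200, n_specific_genes=0, n_noise_genes=0,
            noise_sigma=sigma, seed=13,
        )
        m, truth = generate(cfg)
        target = adjust_factors(1.0 / truth.true_factors)
        pool = set(truth.core_genes)
        for name, est in [
            ("all", AllUbiquitousScaler(pool=pool)),
            ("tu", TotalUbiquitousScaler(pool=pool)),
            ("stab", StabilityScaler(n=50, pool=pool)),
        ]:
            f = est.fit(m).factors_
            errs[(name, sigma)] = np.abs(np.log2(f / target)).max()
    for name in ("all", "tu", "stab"):
        assert errs[(name, 0.02)] < errs[(name, 0.2)]
        assert errs[(name, 0.02)] < 0.05
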