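"""Density estimation, permutation KS test, and the linear effects model."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from adipo3d import (
    estimate_density,
    fit_effects_model,
    ks_statistic,
    permutation_ks_test,
    silverman_bandwidth,
)
from adipo3d.errors import InputError, ModelError, ParameterError
from adipo3d.stats import per_sample_summaries


def brute_force_ks(a, b):
    """Independent oracle: max ECDF gap by direct evaluation at every
    pooled point."""
    points = sorted(set(a) | set(b))
    return max(
        abs(np.mean([x <= p for x in a]) - np.mean([y <= p for y in b]))
        for p in points
    )


class TestSilvermanBandwidth:
    def test_closed_form_on_fixed_sample(self):
        x = np.arange(1.0, 21.0)
        sd = x.std(ddof=1)
        iqr = np.percentile(x, 75) - np.percentile(x, 25)
        expected = 0.9 * min(sd, iqr / 1.34) * 20 ** (-0.2)
        assert silverman_bandwidth(x) == pytest.approx(expected, rel=1e-12)

    def test_falls_back_to_sd_when_iqr_zero(self):
        x = np.array([5.0] * 20 + [0.0, 10.0])
        assert silverman_bandwidth(x) > 0

    def test_rejects_degenerate(self):
        with pytest.raises(InputError):
            silverman_bandwidth([1.0])
        with pytest.raises(InputError):
            silverman_bandwidth([0.0, 0.0, 0.0])


class TestEstimateDensity:
    @pytest.mark.parametrize("seed,dist", [(0, "normal"), (1, "lognormal"),
                                           (2, "bimodal_edges")])
    def test_integrates_to_one(self, seed, dist):
        rng = np.random.default_rng(seed)
        if dist == "normal":
            x = rng.normal(60, 15, 400)
        elif dist == "lognormal":
            x = rng.lognormal(4, 0.3, 400)
        else:  # mass concentrated at both range edges
            x = np.concatenate([rng.normal(0, 0.01, 200), rng.normal(10, 0.01, 200)])
        est = estimate_density(x)
        assert np.trapezoid(est.density, est.grid) == pytest.approx(1.0, abs=1e-3)

    def test_symmetric_input_symmetric_density(self):
        rng = np.random.default_rng(3)
        half = rng.normal(2.0, 0.5, 300)
        x = np.concatenate([half, -half])  # exactly mirror-symmetric around 0
        est = estimate_density(x)
        assert np.allclose(est.density, est.density[::-1], atol=1e-9)

    def test_consistency_against_normal_pdf(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal(100_000)
        est = estimate_density(x)
        truth = sps.norm.pdf(est.grid)
        assert np.abs(est.density - truth).max() < 0.01

    def test_rejects_bad_input(self):
        with pytest.raises(InputError):
            estimate_density([1.0])
        with pytest.raises(InputError):
            estimate_density([2.0, 2.0, 2.0])
        with pytest.raises(ParameterError):
            estimate_density([1.0, 2.0], bandwidth=-1)


class TestKSStatistic:
    def test_identical_samples(self):
        x = [1.0, 2.0, 5.0]
        assert ks_statistic(x, x) == 0.0

    def test_disjoint_supports(self):
        assert ks_statistic([1, 2, 3], [10, 11]) == 1.0

    def test_interleaved_example(self):
        assert ks_statistic([1, 2, 3, 4], [3, 4, 5, 6]) == pytest.approx(0.5)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_oracle_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.integers(0, 8, rng.integers(2, 25)).astype(float)
        b = rng.integers(0, 8, rng.integers(2, 25)).astype(float)
        assert ks_statistic(a, b) == pytest.approx(brute_force_ks(a, b), abs=1e-12)

    def test_matches_scipy(self):
        rng = np.random.default_rng(9)
        a, b = rng.normal(size=40), rng.normal(0.5, 1, 60)
        assert ks_statistic(a, b) == pytest.approx(
            sps.ks_2samp(a, b).statistic, abs=1e-12
        )

    def test_symmetric_in_arguments(self):
        rng = np.random.default_rng(10)
        a, b = rng.normal(size=15), rng.normal(size=25)
        assert ks_statistic(a, b) == ks_statistic(b, a)

    def test_empty_rejected(self):
        with pytest.raises(InputError):
            ks_statistic([], [1.0])


class TestPermutationKS:
    def test_identical_samples_p_one(self):
        x = np.arange(10.0)
        result = permutation_ks_test(x, x, m=200, seed=1)
        assert result.d_observed == 0.0
        assert result.p_value == 1.0

    def test_minimum_p_is_never_zero(self):
        a = np.arange(50.0)
        b = np.arange(100.0, 150.0)  # complete separation
        result = permutation_ks_test(a, b, m=999, seed=2)
        assert result.p_value == pytest.approx(1 / 1000)
        assert result.n_exceed == 0

    def test_p_value_identity_and_bounds(self):
        rng = np.random.default_rng(3)
        result = permutation_ks_test(rng.normal(size=30), rng.normal(size=40),
                                     m=500, seed=4)
        assert result.p_value == (result.n_exceed + 1) / (result.m_permutations + 1)
        assert 1 / 501 <= result.p_value <= 1.0

    def test_deterministic_for_fixed_seed(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(size=25), rng.normal(size=30)
        r1 = permutation_ks_test(a, b, m=300, seed=7)
        r2 = permutation_ks_test(a, b, m=300, seed=7)
        assert r1 == r2

    def test_concatenation_order_invariance(self):
        rng = np.random.default_rng(6)
        a, b = rng.normal(size=20), rng.normal(size=35)
        assert (
            permutation_ks_test(a, b, m=100, seed=1).d_observed
            == permutation_ks_test(b, a, m=100, seed=1).d_observed
        )

    def test_agrees_with_classical_null_distribution(self):
        rng = np.random.default_rng(8)
        a, b = rng.standard_normal(200), rng.standard_normal(200)
        result = permutation_ks_test(a, b, m=3000, seed=9)
        classical = sps.ks_2samp(a, b, method="exact").pvalue
        assert result.p_value == pytest.approx(classical, abs=0.02)

    def test_parameter_errors(self):
        with pytest.raises(ParameterError):
            permutation_ks_test([1.0], [2.0], m=0, seed=1)
        with pytest.raises(InputError):
            permutation_ks_test([], [2.0], m=10, seed=1)


def _cohort_frame(noise_sd, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(24):
        tissue = "VAT" if i < 12 else "SCAT"
        sex = "M" if i % 2 else "F"
        weight = 750.0 if i % 4 < 2 else 1100.0
        response = 10.0 + 17.0 * (tissue == "VAT") + rng.normal(0, noise_sd)
        rows.append(dict(tissue=tissue, sex=sex, body_weight=weight,
                         mean_diameter=response))
    return pd.DataFrame(rows)


class TestEffectsModel:
    def test_recovers_planted_tissue_effect(self):
        result = fit_effects_model(_cohort_frame(noise_sd=0.1), "mean_diameter")
        coef = result.terms["C(tissue)[T.VAT]"]["coefficient"]
        assert coef == pytest.approx(17.0, abs=0.5)
        assert result.terms["C(tissue)[T.VAT]"]["p_value"] < 1e-6

    def test_exact_fit_zero_noise(self):
        result = fit_effects_model(_cohort_frame(noise_sd=0.0), "mean_diameter")
        assert result.r_squared == pytest.approx(1.0, abs=1e-9)
        assert result.terms["C(tissue)[T.VAT]"]["p_value"] < 1e-12

    def test_single_level_factor_named(self):
        frame = _cohort_frame(0.1)
        frame["sex"] = "F"
        with pytest.raises(ModelError, match="sex"):
            fit_effects_model(frame, "mean_diameter")

    def test_missing_column_rejected(self):
        with pytest.raises(InputError):
            fit_effects_model(pd.DataFrame({"tissue": ["VAT"]}), "mean_diameter")


def test_per_sample_summaries_collapses_cells():
    cells = pd.DataFrame(
        {
            "sample_id": ["a"] * 3 + ["b"] * 2,
            "equivalent_diameter": [50.0, 60.0, 70.0, 30.0, 50.0],
            "sphericity": [0.9, 0.8, 0.7, 0.95, 0.85],
            "tissue": ["VAT"] * 3 + ["SCAT"] * 2,
        }
    )
    out = per_sample_summaries(cells).set_index("sample_id")
    assert out.loc["a", "mean_diameter"] == pytest.approx(60.0)
    assert out.loc["b", "n_cells"] == 2
    assert out.loc["b", "tissue"] == "SCAT"
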