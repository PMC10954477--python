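"""Inverse-problem tests: global fits, Monte-Carlo errors, model selection."""


import numpy as np
import pytest

from wclike import (
    RDDataset,
    fit_three_state_triangular,
    fit_two_state,
    model_selection,
    monte_carlo_uncertainty,
)
from wclike.exceptions import ComparisonError, ValidationError
from wclike.rd_fitting import FitResult, RDRecord, assign_anion_state
from wclike.synthetic_data import generate_rd_dataset

from conftest import small_grid_spec


def fast_two_state(data, **kw):
    """Single-start 2-state fit for tests that refit many replicates."""
    kw.setdefault("kex_starts", (5e3,))
    kw.setdefault("dw_scales", (1.0,))
    kw.setdefault("max_nfev", 150)
    return fit_two_state(data, **kw)


@pytest.fixture(scope="module")
def noiseless_small():
    spec = small_grid_spec(noise_frac=0.0, seed=5)
    return generate_rd_dataset(spec)


@pytest.fixture(scope="module")
def noisy_small():
    spec = small_grid_spec(seed=17)
    return generate_rd_dataset(spec)


class TestTwoStateFit:
    def test_noiseless_self_consistency(self, noiseless_small):
        """Noiseless synthetic data refit to ≤ 0.1% relative on every parameter."""
        data, truth = noiseless_small
        fit = fast_two_state(data, max_nfev=400)
        model = truth["model"]
        assert fit.params["p_es"] == pytest.approx(model.population("ES1"), rel=1e-3)
        assert fit.params["k_ex"] == pytest.approx(7200.0, rel=1e-3)
        assert fit.params["dw_ES1_G-N1"] == pytest.approx(34.9, rel=1e-3)
        assert fit.params["dw_ES1_T-N3"] == pytest.approx(25.7, rel=1e-3)
        assert fit.params["r1_G-N1"] == pytest.approx(2.5, rel=1e-3)
        assert fit.params["r2_T-N3"] == pytest.approx(18.0, rel=1e-3)

    def test_record_order_invariance(self, noisy_small):
        data, _ = noisy_small
        shuffled = RDDataset(list(reversed(data.records)), data.metadata)
        f1 = fast_two_state(data)
        f2 = fast_two_state(shuffled)
        assert f1.chi2 == pytest.approx(f2.chi2, rel=1e-6)
        assert f1.params["k_ex"] == pytest.approx(f2.params["k_ex"], rel=1e-4)

    def test_requires_two_powers_per_nucleus(self, noisy_small):
        data, _ = noisy_small
        one_power = RDDataset(
            [r for r in data.records if r.cond.power_hz == 600.0], {})
        with pytest.raises(ValidationError):
            fit_two_state(one_power)

    def test_recovery_coverage_over_replicates(self):
        """Generating parameters fall inside ±2 sd for ≥ 80% of parameters
        over 20 noisy replicates (covariance-based sds)."""
        truth_vals = {"p_es": 0.00083, "k_ex": 7200.0,
                      "dw_ES1_G-N1": 34.9, "dw_ES1_T-N3": 25.7}
        inside = total = 0
        for seed in range(20):
            data, _ = generate_rd_dataset(small_grid_spec(seed=100 + seed))
            fit = fast_two_state(data)
            sds = fit.metadata["covariance_sd"]
            for name, true in truth_vals.items():
                sd = max(sds[name], 1e-12)
                total += 1
                inside += abs(fit.params[name] - true) <= 2 * sd
        assert inside / total >= 0.8


class TestThreeStateFit:
    def test_collapse_to_two_state_when_es2_absent(self, noiseless_small):
        """Generator with p_ES2 = 0: the 3-state fit cannot beat the 2-state
        chi2 by more than optimizer tolerance (nested-model identity)."""
        data, _ = noiseless_small
        f2 = fast_two_state(data)
        f3 = fit_three_state_triangular(
            data, init_from=f2, p2_starts=(1e-4,), kex2_starts=(5e3,),
            dw2_levels=(10.0,), max_nfev=200)
        # noiseless sds are floored at 1e-6 1/s, so a chi2 slack of 5 here
        # means absolute residuals below ~2e-6 1/s — numerically zero
        assert f3.chi2 <= f2.chi2 + 5.0
        # ES1 parameters survive the extension
        assert f3.params["p_es1"] == pytest.approx(f2.params["p_es"], rel=0.3) \
            or f3.params["p_es2"] == pytest.approx(f2.params["p_es"], rel=0.3)

    def test_nested_model_chi2_dominance(self, noisy_small):
        data, _ = noisy_small
        f2 = fast_two_state(data)
        f3 = fit_three_state_triangular(
            data, init_from=f2, p2_starts=(1e-3,), kex2_starts=(5e3,),
            dw2_levels=(10.0,), max_nfev=200)
        assert f3.chi2 <= f2.chi2 + 0.5

    def test_anion_state_assignment_swaps_consistently(self):
        params = {
            "p_es1": 0.001, "p_es2": 0.002,
            "k_ex_gs_es1": 5000.0, "k_ex_gs_es2": 4000.0, "k_ex_es1_es2": 1e4,
            "dw_ES1_G-N1": 1.0, "dw_ES1_U-N3": 58.0,
            "dw_ES2_G-N1": 21.0, "dw_ES2_U-N3": 36.0,
            "r1_G-N1": 2.5, "r2_G-N1": 18.0, "r1_U-N3": 2.5, "r2_U-N3": 18.0,
        }
        fit = FitResult(model_type="3state", nuclei=["G-N1", "U-N3"],
                        params=params, chi2=1.0, n_obs=10, n_params=13,
                        converged=True, n_starts=1)
        out = assign_anion_state(fit)
        assert out.params["dw_ES2_G-N1"] == 1.0
        assert out.params["dw_ES2_U-N3"] == 58.0
        assert out.params["p_es2"] == 0.001
        assert out.params["k_ex_gs_es2"] == 5000.0
        assert out.params["k_ex_es1_es2"] == 1e4
        # idempotent
        assert assign_anion_state(out).params == out.params


@pytest.fixture(scope="module")
def tiny_fit():
    spec = small_grid_spec(seed=23, powers=(600.0, 1800.0), n_offsets=5)
    data, _ = generate_rd_dataset(spec)
    fit = fast_two_state(data, max_nfev=200)
    return data, fit


class TestMonteCarlo:
    def test_near_zero_observation_sds_give_near_zero_parameter_sds(self):
        spec = small_grid_spec(seed=29, noise_frac=0.0, n_offsets=5)
        data, _ = generate_rd_dataset(spec)  # sds floored at 1e-6
        fit = fast_two_state(data, max_nfev=200)
        sds = monte_carlo_uncertainty(data, fit, n_iter=10, seed=0, max_nfev=60)
        # scatter is pure optimizer re-convergence noise at these weights
        assert sds["k_ex"] / fit.params["k_ex"] < 1e-3
        assert sds["p_es"] / fit.params["p_es"] < 1e-2

    def test_single_iteration_degenerate_sd_with_warning(self, tiny_fit):
        data, fit = tiny_fit
        with pytest.warns(UserWarning, match="degenerate"):
            sds = monte_carlo_uncertainty(data, fit, n_iter=1, seed=0, max_nfev=60)
        assert all(v == 0.0 for v in sds.values())

    def test_parameter_sds_scale_linearly_with_observation_sds(self, tiny_fit):
        """Doubling every observed sd roughly doubles the parameter sds."""
        data, fit = tiny_fit
        doubled = RDDataset(
            [RDRecord(r.nucleus, r.cond, r.r1rho, 2 * r.sd) for r in data.records],
            data.metadata)
        sd1 = monte_carlo_uncertainty(data, fit, n_iter=60, seed=3, max_nfev=60)
        sd2 = monte_carlo_uncertainty(doubled, fit, n_iter=60, seed=3, max_nfev=60)
        for name in ("k_ex", "dw_ES1_G-N1"):
            assert sd2[name] / sd1[name] == pytest.approx(2.0, rel=0.3)


class TestModelSelection:
    def make_fit(self, chi2, k, n=100, data_hash="x"):
        return FitResult(model_type="2state", nuclei=["N"], params={},
                         chi2=chi2, n_obs=n, n_params=k, converged=True,
                         n_starts=1, metadata={"data_hash": data_hash})

    def test_identical_models_split_weights_evenly(self):
        fits = model_selection([self.make_fit(50.0, 8), self.make_fit(50.0, 8)])
        assert fits[0].akaike_weight == pytest.approx(0.5)
        assert fits[0].bic_weight == pytest.approx(0.5)

    def test_weights_sum_to_one_and_rank_by_aic(self):
        fits = model_selection(
            [self.make_fit(80.0, 8), self.make_fit(40.0, 13), self.make_fit(60.0, 9)])
        assert sum(f.akaike_weight for f in fits) == pytest.approx(1.0)
        assert fits[0].aic == min(f.aic for f in fits)

    def test_information_criterion_formulas(self):
        f = model_selection([self.make_fit(50.0, 8, n=100)])[0]
        assert f.aic == pytest.approx(100 * np.log(0.5) + 16)
        assert f.bic == pytest.approx(100 * np.log(0.5) + 8 * np.log(100))

    def test_mismatched_datasets_rejected(self):
        with pytest.raises(ComparisonError):
            model_selection([self.make_fit(50.0, 8, data_hash="a"),
                             self.make_fit(40.0, 13, data_hash="b")])

    def test_two_state_data_prefers_two_state_model(self):
        """Across 10 replicates of tautomer-only data, the 2-state model wins
        the Akaike comparison in ≥ 90% of cases."""
        wins = 0
        n_rep = 10
        for seed in range(n_rep):
            data, _ = generate_rd_dataset(small_grid_spec(seed=300 + seed))
            f2 = fast_two_state(data, max_nfev=200)
            f3 = fit_three_state_triangular(
                data, init_from=f2, p2_starts=(1e-3,), kex2_starts=(5e3,),
                dw2_levels=(10.0,), max_nfev=200)
            ranked = model_selection([f2, f3])
            wins += ranked[0].model_type == "2state"
        assert wins / n_rep >= 0.9
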