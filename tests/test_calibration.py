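"""Tests for the multi-stage calibration workflow.

The heavier parameter-recovery checks on full-size designs live in the
acceptance suite; these tests exercise every stage on small designs.
"""

import numpy as np
import pytest
from scipy import stats

from glucodyn import calibrate
from glucodyn.calibrate import (
    IdentifiabilityError,
    bootstrap_intervals,
    fit_dataset_a,
    fit_gin_and_local_kbys,
    fit_gin_constrained,
    fit_kbys_relation,
    kbys_as_function_of_gin,
    linearized_intervals,
    predict,
    refit_relation_accessible,
)
from glucodyn.datasets import Dataset, DesignSpec, TruthParams, NoiseSpec, generate_dataset
from glucodyn.model import BystanderRelation, GlobalParams, InhibitionParams, Well, simulate_forward


@pytest.fixture(scope="module")
def step1(tiny_a):
    """Step-1 fit of the tiny noiseless untreated dataset, shared below."""
    return fit_dataset_a(tiny_a, x0=[0.3, 0.1, 1e-4], compute_ci=True)


@pytest.fixture(scope="module")
def fitted_globals(step1):
    g = step1.globals_
    return GlobalParams(k_p=g["k_p"], k_d=g["k_d"], v=g["v"])


class TestRelationFit:
    def test_exact_data_recovers_exactly(self):
        rel = BystanderRelation(0.1, 0.5, 0.01)
        g0 = np.array([0.0, 0.5, 1.0, 2.0, 5.0, 10.0])
        fit = fit_kbys_relation(g0, rel.rate(g0))
        assert fit.relation.k_bys_0 == pytest.approx(0.1, abs=1e-6)
        assert fit.relation.alpha == pytest.approx(0.5, abs=1e-6)
        assert fit.relation.beta == pytest.approx(0.01, abs=1e-6)

    def test_flat_truth_sum_identifiable(self):
        # alpha = 0 collapses the law to the constant k0 + beta; only the
        # sum is identifiable and the fit must land on that level
        g0 = np.array([0.0, 1.0, 3.0, 7.0, 10.0])
        fit = fit_kbys_relation(g0, np.full(5, 0.07))
        level = fit.relation.k_bys_0 * np.exp(-fit.relation.alpha * g0) + fit.relation.beta
        assert np.allclose(level, 0.07, atol=1e-6)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="distinct glucose"):
            fit_kbys_relation([2.0, 2.0, 2.0, 2.0], [0.1, 0.1, 0.1, 0.1])
        with pytest.raises(ValueError, match="4"):
            fit_kbys_relation([0.0, 1.0, 2.0], [0.3, 0.2, 0.1])

    def test_interval_coverage_for_beta(self):
        # simulation-based check: ~95% of intervals should cover the truth
        rel = BystanderRelation(0.3, 0.5, 0.02)
        rng = np.random.default_rng(7)
        g0 = np.tile(np.array([0.0, 0.3, 0.8, 1.5, 3.0, 6.0, 10.0]), 5)
        covered = 0
        n_rep = 50
        for _ in range(n_rep):
            k = rel.rate(g0) + rng.normal(0, 0.01, g0.size)
            fit = fit_kbys_relation(g0, np.maximum(k, 0.0))
            lo, hi = fit.ci["beta"]
            covered += lo <= 0.02 <= hi
        assert 85 <= 100 * covered / n_rep <= 100


class TestKbysOfGin:
    def test_gin_zero_matches_plain_relation(self, params):
        rel = BystanderRelation(0.8, 0.4, 0.03)
        well = Well("w", 0.5, 5.0, 2.0)
        f = kbys_as_function_of_gin(well, params, rel)
        assert f(0.0) == pytest.approx(rel.rate(5.0), rel=1e-12)

    def test_large_gin_limit_and_monotonicity(self, params):
        rel = BystanderRelation(0.8, 0.4, 0.03)
        well = Well("w", 0.5, 5.0, 10.0)
        f = kbys_as_function_of_gin(well, params, rel)
        assert f(1e3) == pytest.approx(rel.k_bys_0 + rel.beta, rel=1e-6)
        vals = [f(g) for g in np.linspace(0, 1e-2, 30)]
        assert np.all(np.diff(vals) >= -1e-12)


class TestConfidenceIntervals:
    def test_matches_closed_form_on_linear_model(self, rng):
        # straight-line fit: linearized intervals must equal textbook OLS
        x = np.linspace(0, 1, 20)
        y = 1.5 + 2.0 * x + rng.normal(0, 0.1, 20)
        X = np.column_stack([np.ones_like(x), x])
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        resid = y - X @ beta
        ci = linearized_intervals(beta, X, resid)
        s2 = resid @ resid / (20 - 2)
        se = np.sqrt(np.diag(s2 * np.linalg.inv(X.T @ X)))
        tcrit = stats.t.ppf(0.975, 18)
        assert np.allclose(ci[:, 0], beta - tcrit * se, atol=1e-10)
        assert np.allclose(ci[:, 1], beta + tcrit * se, atol=1e-10)

    def test_zero_residuals_zero_width(self):
        jac = np.column_stack([np.ones(10), np.arange(10.0)])
        ci = linearized_intervals(np.array([1.0, 2.0]), jac, np.zeros(10))
        assert np.allclose(ci[:, 0], ci[:, 1])

    def test_bootstrap_refuses_single_unit(self):
        with pytest.raises(ValueError, match="2 resampling units"):
            bootstrap_intervals(lambda units: np.array([0.0]), ["only-well"])

    def test_bootstrap_brackets_mean(self, rng):
        data = {f"w{i}": v for i, v in enumerate(rng.normal(5.0, 1.0, 40))}
        refit = lambda units: np.array([np.mean([data[u] for u in units])])
        ci = bootstrap_intervals(refit, list(data), n_boot=200, seed=1)
        assert ci[0, 0] < 5.0 < ci[0, 1]


class TestStep1:
    def test_noiseless_recovery_within_one_percent(self, step1, truth_noiseless):
        tg = truth_noiseless.globals_
        assert step1.globals_["k_p"] == pytest.approx(tg.k_p, rel=0.01)
        assert step1.globals_["k_d"] == pytest.approx(tg.k_d, rel=0.01)
        assert step1.globals_["v"] == pytest.approx(tg.v, rel=0.01)

    def test_local_rates_recover_generator_truth(self, step1, tiny_a):
        for wid, k in step1.local_kbys.items():
            assert k == pytest.approx(tiny_a.true_kbys[wid], abs=5e-4)

    def test_intervals_contain_estimates(self, step1):
        for name, (lo, hi) in step1.global_ci.items():
            assert lo <= step1.globals_[name] <= hi

    def test_inner_refine_trace_monotone(self, step1):
        trace = step1.diagnostics["initial_cost_trace"]
        assert len(trace) > 1
        assert all(b <= a + 1e-9 for a, b in zip(trace, trace[1:]))

    def test_treated_wells_rejected(self, tiny_b):
        with pytest.raises(ValueError, match="untreated"):
            fit_dataset_a(tiny_b)

    def test_single_well_warns(self, truth_noiseless):
        spec = DesignSpec(dataset_tag="S", seeding_levels={"low": 0.4},
                          glucose_levels=(5.0,), doses=(0.0,), replicates=1)
        ds = generate_dataset(spec, truth_noiseless, seed=2)
        with pytest.warns(UserWarning, match="identifiab"):
            fit_dataset_a(ds, compute_ci=False)


@pytest.fixture(scope="module")
def step4(tiny_b, fitted_globals, truth_noiseless):
    return fit_gin_constrained(tiny_b, fitted_globals, truth_noiseless.relation)


class TestStep4And5:
    def test_gin_recovered_within_five_percent(self, step4, truth_noiseless):
        for dose in (2.0, 10.0):
            truth = truth_noiseless.inhibition.for_dose(dose)
            assert step4[dose].value == pytest.approx(truth, rel=0.05)

    def test_dose_ordering(self, step4):
        assert step4[10.0].value > step4[2.0].value

    def test_intervals_contain_estimates(self, step4):
        for fit in step4.values():
            assert fit.ci[0] <= fit.value <= fit.ci[1]

    def test_step5_point_bounds_pin_gin(self, tiny_b, fitted_globals, step4):
        pinned = {d: (f.value, f.value) for d, f in step4.items()}
        res = fit_gin_and_local_kbys(tiny_b, fitted_globals, pinned, compute_ci=False)
        for d, f in step4.items():
            assert res.diagnostics["gin"][d] == pytest.approx(f.value, rel=1e-12)

    def test_step5_recovery_and_interval_containment(self, tiny_b, fitted_globals, step4,
                                                     truth_noiseless):
        res = fit_gin_and_local_kbys(tiny_b, fitted_globals,
                                     {d: f.ci for d, f in step4.items()}, compute_ci=False)
        # step-4 bounds contain step-5 estimates by construction
        for d, f in step4.items():
            assert f.ci[0] - 1e-15 <= res.diagnostics["gin"][d] <= f.ci[1] + 1e-15
        # free local rates land on the generator truth
        for wid, k in res.local_kbys.items():
            assert k == pytest.approx(tiny_b.true_kbys[wid], abs=2e-2)

    def test_step5_kbys_decays_with_accessible_glucose(self, tiny_b, fitted_globals, step4):
        res = fit_gin_and_local_kbys(tiny_b, fitted_globals,
                                     {d: f.ci for d, f in step4.items()}, compute_ci=False)
        g_acs0 = calibrate.accessible_initial_glucose(tiny_b, fitted_globals,
                                                      res.diagnostics["gin"])
        ids = list(res.local_kbys)
        rho, _ = stats.spearmanr([g_acs0[i] for i in ids],
                                 [res.local_kbys[i] for i in ids])
        assert rho < -0.8

    def test_all_zero_glucose_unidentifiable(self, fitted_globals, truth_noiseless):
        spec = DesignSpec(dataset_tag="Z", seeding_levels={"low": 0.4},
                          glucose_levels=(0.0,), doses=(0.0, 2.0), replicates=2)
        ds = generate_dataset(spec, truth_noiseless, seed=3)
        with pytest.raises(IdentifiabilityError):
            fit_gin_constrained(ds, fitted_globals, truth_noiseless.relation)


class TestStep6:
    def test_accessible_scale_correlates_better(self):
        rel = BystanderRelation(0.8, 0.4, 0.03)
        rng = np.random.default_rng(5)
        g_total = rng.uniform(0.5, 10.0, 40)
        shrink = rng.uniform(0.1, 1.0, 40)  # inhibition factors
        g_acs = g_total * shrink
        k = rel.rate(g_acs)
        ids = [f"w{i}" for i in range(40)]
        out = refit_relation_accessible(dict(zip(ids, k)), dict(zip(ids, g_total)),
                                        dict(zip(ids, g_acs)), rel)
        assert out.pattern_confirmed
        assert abs(out.corr_accessible) > abs(out.corr_total)
        assert out.relation_fit is not None

    def test_untreated_only_identical_correlations(self):
        rel = BystanderRelation(0.8, 0.4, 0.03)
        g = np.array([0.5, 1.0, 2.0, 5.0, 10.0])
        ids = [f"w{i}" for i in range(5)]
        out = refit_relation_accessible(dict(zip(ids, rel.rate(g))), dict(zip(ids, g)),
                                        dict(zip(ids, g)), rel)
        assert out.corr_total == pytest.approx(out.corr_accessible)

    def test_constant_rates_flagged_not_refit(self):
        prior = BystanderRelation(0.5, 1.0, 0.01)
        g = np.array([0.5, 1.0, 2.0, 5.0, 10.0])
        ids = [f"w{i}" for i in range(5)]
        out = refit_relation_accessible(dict(zip(ids, np.full(5, 0.1))), dict(zip(ids, g)),
                                        dict(zip(ids, g)), prior)
        assert not out.pattern_confirmed
        assert out.relation == prior


class TestPredict:
    def test_unknown_dose_raises(self, params):
        rel = BystanderRelation(0.8, 0.4, 0.03)
        well = Well("w", 0.5, 5.0, dose=7.0)
        with pytest.raises(KeyError, match="7"):
            predict(well, params, rel, InhibitionParams.default())

    def test_untreated_prediction_equals_baseline_path(self, params):
        rel = BystanderRelation(0.8, 0.4, 0.03)
        well = Well("w", 0.5, 5.0, dose=0.0, initial_dead_confluence=0.02)
        sim = predict(well, params, rel, InhibitionParams.default())
        base = simulate_forward(well, params, rel.rate(5.0), 0.0)
        assert np.array_equal(sim.course.live, base.course.live)

    def test_heldout_noiseless_wells_near_perfect(self, tiny_b, fitted_globals,
                                                  truth_noiseless, params):
        from glucodyn.metrics import r_squared
        obs, pred = [], []
        for w in tiny_b.wells:
            sim = predict(w, fitted_globals, truth_noiseless.relation,
                          truth_noiseless.inhibition, tiny_b.time_grid)
            tc = tiny_b.courses[w.well_id]
            obs.extend([tc.live, tc.dead])
            pred.extend([sim.course.live, sim.course.dead])
        r2 = r_squared(np.concatenate(pred), np.concatenate(obs))
        assert r2 > 0.99
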