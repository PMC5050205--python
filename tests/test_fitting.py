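import numpy as np
import pytest
from scipy import optimize

from mfa2s.core_network import ValidationError
from mfa2s.fitting import (
    FitOptions,
    FitProblem,
    fit_fluxes,
    ssr,
    ssr_chi2_band,
)
from mfa2s.labeling import FeedLabeling
from mfa2s.measurements import (
    ExchangeMeasurement,
    MDVMeasurement,
    MeasurementSet,
)
from mfa2s.synthetic_data import (
    branch_feed,
    build_branch_fixture,
    build_parallel_routes,
    generate_measurements,
    sample_ground_truth,
)


class TestSsr:
    def test_zero_at_ground_truth_on_noiseless_data(
        self, toy_wry2, ground_truth, noiseless_measurements, noiseless_problem
    ):
        value = ssr(
            toy_wry2,
            ground_truth.v_true,
            noiseless_measurements,
            ground_truth.feed,
            exchange=ground_truth.exchange_true,
            problem=noiseless_problem,
        )
        assert value <= 1e-10

    def test_single_exchange_residual_squares_correctly(self):
        split = build_parallel_routes()
        ms = MeasurementSet(
            exchange_measurements=[ExchangeMeasurement("EX_s", 0.5, 0.25)]
        )
        feed = FeedLabeling("s_e", [("10", 1.0)])
        v = {rid: 0.0 for rid in split.model.reactions}
        v["EX_s"] = 1.0
        assert ssr(split, v, ms, feed) == pytest.approx(4.0)

    def test_matches_hand_recomputation_from_simulated_mdvs(
        self, toy_wry2, ground_truth
    ):
        """SSR equals the direct sum over channels and exchanges."""
        from mfa2s.labeling import simulate_labeling
        from mfa2s.measurements import resolve_fragment

        gt = ground_truth
        ms = generate_measurements(gt, noise_sd=0.01, seed=42)
        # perturbed flux vector: the ground truth is fine
        value = ssr(toy_wry2, gt.v_true, ms, gt.feed,
                    exchange=gt.exchange_true)

        recipes = {m.fragment_id: resolve_fragment(m)
                   for m in ms.mdv_measurements}
        targets = sorted({e for r in recipes.values() for e in r})
        sim = simulate_labeling(toy_wry2, gt.v_true, gt.feed, targets,
                                exchange=gt.exchange_true)
        expected = 0.0
        for m in ms.mdv_measurements:
            val = np.array([1.0])
            for e in recipes[m.fragment_id]:
                val = np.convolve(val, sim[e].fractions)
            expected += float((((val - m.values.fractions) / m.sd) ** 2).sum())
        for em in ms.exchange_measurements:
            expected += ((gt.v_true[em.reaction_id] - em.rate) / em.sd) ** 2
        mu, sd = ms.growth_rate
        expected += ((gt.v_true["BIOMASS"] - mu) / sd) ** 2
        assert value == pytest.approx(expected, rel=1e-6)


class TestFitFluxes:
    def test_noiseless_fit_reaches_zero_ssr(self, noiseless_fit):
        assert noiseless_fit.converged
        assert noiseless_fit.ssr <= 1e-6

    def test_noiseless_fit_recovers_fluxes(self, noiseless_fit, ground_truth):
        for rid, truth in ground_truth.v_true.items():
            if abs(truth) > 1e-2:
                rel = abs(noiseless_fit.v[rid] - truth) / abs(truth)
                assert rel < 1e-3, rid

    def test_solution_satisfies_steady_state_and_bounds(
        self, toy_wry2, noiseless_fit
    ):
        S, mets, rids = toy_wry2.model.stoichiometric_matrix()
        v = np.array([noiseless_fit.v[r] for r in rids])
        assert np.abs(S @ v).max() < 1e-6
        for rid in rids:
            rxn = toy_wry2.model.reactions[rid]
            assert rxn.lower_bound - 1e-9 <= noiseless_fit.v[rid]
            assert noiseless_fit.v[rid] <= rxn.upper_bound + 1e-9

    def test_fixed_seed_reproducible(self, toy_wry2, ground_truth):
        ms = generate_measurements(ground_truth, noise_sd=0.01, seed=5)
        opts = FitOptions(n_starts=2, seed=7)
        sol1 = fit_fluxes(toy_wry2, ms, ground_truth.feed, opts)
        sol2 = fit_fluxes(toy_wry2, ms, ground_truth.feed, opts)
        v1 = np.array(list(sol1.v.values()))
        v2 = np.array(list(sol2.v.values()))
        assert (v1 == v2).all()
        assert sol1.ssr == sol2.ssr

    def test_unidentifiable_parallel_routes_still_fit(self):
        split = build_parallel_routes()
        gt = sample_ground_truth(split, seed=3, fragments=[("x", "x_c", (1, 2))],
                                 measured_exchange_ids=(),
                                 uptake_reaction=None)
        ms = generate_measurements(gt, noise_sd=0.0, seed=0)
        sol = fit_fluxes(split, ms, gt.feed, FitOptions(n_starts=2, seed=0))
        assert sol.converged
        assert sol.ssr <= 1e-8
        # only the total is constrained, the split is free
        assert sol.v["R1"] + sol.v["R2"] == pytest.approx(10.0, abs=1e-6)

    def test_exchange_only_fit_matches_quadratic_programming(self):
        """Without MDVs the fit is a constrained weighted least squares."""
        split = build_branch_fixture(uptake=10.0)
        # loosen the pinned uptake so there is something to fit
        split.model.reactions["EX_s"].lower_bound = -20.0
        split.model.reactions["EX_s"].upper_bound = 0.0
        ms = MeasurementSet(
            exchange_measurements=[
                ExchangeMeasurement("EX_s", -8.0, 0.5),
                ExchangeMeasurement("DP", 7.0, 0.5),
            ]
        )
        feed = branch_feed()
        problem = FitProblem(split, ms, feed)
        sol = fit_fluxes(split, ms, feed, FitOptions(n_starts=4, seed=1),
                         problem=problem)

        # independent QP in alpha-coordinates (linear residuals)
        space = problem.space
        rows, targets, sds = [], [], []
        const = []
        for em in ms.exchange_measurements:
            g = space.net_gradient(em.reaction_id)
            idx = space.column_index()
            b = space.v_p[idx[(em.reaction_id, +1)]]
            rows.append(g / em.sd)
            const.append(b / em.sd)
            targets.append(em.rate / em.sd)
        A = np.vstack(rows)
        b = np.array(targets) - np.array(const)
        # direct quadratic program over the same polytope
        fun = lambda a: float(((A @ a - b) ** 2).sum())
        jac = lambda a: 2 * A.T @ (A @ a - b)
        cons = problem.constraints()
        qp = optimize.minimize(fun, np.zeros(space.dim), jac=jac,
                               method="SLSQP", constraints=cons,
                               options={"ftol": 1e-14, "maxiter": 500})
        assert sol.ssr == pytest.approx(fun(qp.x), abs=1e-6)

    def test_n_starts_must_be_positive(self):
        with pytest.raises(ValidationError):
            FitOptions(n_starts=0)


class TestChi2Band:
    def test_band_brackets_expected_ssr(self):
        lo, hi = ssr_chi2_band(81, 10, level=0.95)
        dof = 71
        assert lo < dof < hi

    def test_band_widens_with_level(self):
        lo95, hi95 = ssr_chi2_band(81, 10, level=0.95)
        lo99, hi99 = ssr_chi2_band(81, 10, level=0.99)
        assert lo99 < lo95 and hi99 > hi95
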