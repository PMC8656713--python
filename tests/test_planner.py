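"""Objective construction, weight optimization, clinical-goal evaluation."""

import dataclasses

import numpy as np
import pytest
from scipy import optimize as sciopt
from scipy import sparse

from daptsim import engine as de
from daptsim import planner as dp
from daptsim.cohort import build_phantom
from daptsim.grid import GridSpec


def toy_phantom_with_masks(dose_map):
    """A 16^3 phantom whose CTV/OAR masks are tiny index sets.

    ``dose_map``: dict structure -> flat voxel indices.
    """
    grid = GridSpec((16, 16, 16), (2.0, 2.0, 2.0))
    ph = build_phantom(GridSpec((40, 40, 30), (4.0, 4.0, 4.0)))  # template for names
    masks = {}
    for name in ph.structures:
        m = np.zeros(grid.shape, bool)
        for idx in dose_map.get(name, []):
            m.ravel()[idx] = True
        masks[name] = m
    masks["external"][:] = True
    masks["ctv_low"] |= masks["ctv_high"]
    rsp = grid.wrap(np.ones(grid.shape))
    return dataclasses.replace(
        ph, rsp=rsp, structures=masks, geometry=None, target_fractions=None
    )


def matrix_from_dense(A, grid):
    nvox, nb = A.shape
    beamlets = [de.Beamlet(0, 100.0, (0.0, 0.0), 5.0) for _ in range(nb)]
    return de.InfluenceMatrix(
        entries=sparse.csc_matrix(A),
        beamlets=beamlets,
        grid_ref=grid,
        row_index=np.arange(int(np.prod(grid.shape)))[:nvox],
    )


class TestObjective:
    def test_zero_at_prescription(self):
        ph = toy_phantom_with_masks({"ctv_high": [0, 1], "ctv_low": [0, 1, 2, 3]})
        pres = dp.Prescription(n_fractions=1)
        obj = dp.build_objective(ph, pres, fraction_scale=1.0, boost_margin_mm=0.0)
        d = np.zeros(len(obj.voxel_indices))
        targets = {0: 70.0, 1: 70.0, 2: 57.0, 3: 57.0}
        for pos, idx in enumerate(obj.voxel_indices):
            d[pos] = targets.get(int(idx), 0.0)
        f, g = obj.value_and_grad(d)
        assert f == pytest.approx(0.0, abs=1e-15)
        assert np.allclose(g, 0.0)

    def test_hand_computed_three_voxel_case(self):
        """CTV-high of 3 voxels at doses (60, 70, 80): value matches the
        documented weighted mean-square formula."""
        ph = toy_phantom_with_masks({"ctv_high": [0, 1, 2], "ctv_low": [0, 1, 2]})
        pres = dp.Prescription(n_fractions=1)
        obj = dp.build_objective(
            ph, pres, fraction_scale=1.0, boost_margin_mm=0.0,
            penalty_weights={"ctv_under": 1000.0, "ctv_over": 100.0},
        )
        d = np.array([60.0, 70.0, 80.0])
        expected = (1000.0 * (10.0 / 70.0) ** 2 + 100.0 * (10.0 / 70.0) ** 2) / 3.0
        assert obj.value(d) == pytest.approx(expected, rel=1e-12)

    def test_oar_mean_term_hand_computed(self):
        ph = toy_phantom_with_masks(
            {"ctv_high": [0], "ctv_low": [0], "larynx": [5, 6]}
        )
        pres = dp.Prescription(n_fractions=1)
        obj = dp.build_objective(ph, pres, fraction_scale=1.0, boost_margin_mm=0.0)
        # CTV exactly at prescription; larynx (limit 40 Gy) at mean 50 Gy
        d = np.zeros(len(obj.voxel_indices))
        values = {0: 70.0, 5: 50.0, 6: 50.0}
        for pos, idx in enumerate(obj.voxel_indices):
            d[pos] = values[int(idx)]
        assert obj.value(d) == pytest.approx((10.0 / 40.0) ** 2, rel=1e-9)

    def test_disabling_goal_removes_term(self):
        spec = {"ctv_high": [0], "ctv_low": [0], "larynx": [5, 6]}
        ph = toy_phantom_with_masks(spec)
        pres = dp.Prescription(n_fractions=1)
        goals = dp.ClinicalGoals().disable("larynx")
        full = dp.build_objective(ph, pres, fraction_scale=1.0)
        reduced = dp.build_objective(ph, pres, goals=goals, fraction_scale=1.0)
        assert {t["structure"] for t in full.terms} - {
            t["structure"] for t in reduced.terms
        } == {"larynx"}


class TestOptimize:
    def test_single_voxel_closed_form(self):
        ph = toy_phantom_with_masks({"ctv_high": [0], "ctv_low": [0]})
        a = 0.37
        im = matrix_from_dense(np.array([[a]]), ph.grid)
        obj = dp.build_objective(
            ph, dp.Prescription(n_fractions=1), fraction_scale=1.0, boost_margin_mm=0.0
        )
        res = dp.optimize(im, obj, ftol=1e-15, gtol=1e-12, maxiter=500)
        assert res.w[0] == pytest.approx(70.0 / a, rel=1e-6)

    def test_fixed_point(self):
        ph = toy_phantom_with_masks({"ctv_high": [0], "ctv_low": [0]})
        a = 0.5
        im = matrix_from_dense(np.array([[a]]), ph.grid)
        obj = dp.build_objective(
            ph, dp.Prescription(n_fractions=1), fraction_scale=1.0, boost_margin_mm=0.0
        )
        w_star = np.array([70.0 / a])
        res = dp.optimize(im, obj, w_init=w_star)
        assert res.w == pytest.approx(w_star, rel=1e-12)
        assert res.n_iter <= 1

    def test_matches_nnls_oracle(self, rng):
        """5-voxel, 3-beamlet pure-target system equals the NNLS solution."""
        idx = [0, 1, 2, 3, 4]
        ph = toy_phantom_with_masks({"ctv_high": idx, "ctv_low": idx})
        A = rng.random((5, 3))
        im = matrix_from_dense(A, ph.grid)
        obj = dp.build_objective(
            ph, dp.Prescription(n_fractions=1), fraction_scale=1.0, boost_margin_mm=0.0,
            penalty_weights={"ctv_under": 100.0, "ctv_over": 100.0},
        )
        res = dp.optimize(im, obj, ftol=1e-16, gtol=1e-12, maxiter=2000)
        w_oracle, _ = sciopt.nnls(A, np.full(5, 70.0))
        assert np.allclose(res.w, w_oracle, atol=1e-5)

    def test_monotone_objective_history(self, tiny_phantom):
        im = de.influence_matrix(
            tiny_phantom,
            [de.Field(180.0, (0.0, 0.0, 0.0))],
            [de.Beamlet(0, E, (u, z), de.sigma_air(E))
             for E in (90.0, 100.0) for u in (-8.0, 0.0, 8.0) for z in (-8.0, 0.0, 8.0)],
        )
        obj = dp.build_objective(tiny_phantom, dp.Prescription(n_fractions=1))
        res = dp.optimize(im, obj, maxiter=50, ftol=1e-12, gtol=1e-12, track_history=True)
        hist = np.asarray(res.history)
        assert len(hist) > 3
        assert np.all(np.diff(hist) <= 1e-12)

    def test_never_worse_than_init(self, tiny_phantom, tiny_plan):
        im = tiny_plan.builder.matrix(
            tiny_plan.builder.wed_rows(tiny_phantom), tiny_plan.beamlets
        )
        obj = dp.build_objective(tiny_phantom, tiny_plan.prescription)
        w0 = tiny_plan.weights.w
        res = dp.optimize(im, obj, w_init=w0, maxiter=5)
        A = im.entries.tocsr()
        pos = np.searchsorted(im.row_index, obj.voxel_indices)
        f0 = obj.value(np.asarray(A[pos] @ w0).ravel())
        assert res.objective_value <= f0 + 1e-12


class TestProximityRule:
    def test_constrictors_disabled_by_default_geometry(self, coarse_phantom):
        disabled = dp.proximity_disabled_structures(coarse_phantom)
        assert "constrictors" in disabled
        assert "larynx" not in disabled
        assert "parotid_l" not in disabled

    def test_threshold_behavior(self, coarse_phantom):
        # with an enormous margin every OAR is near the target
        all_near = dp.proximity_disabled_structures(coarse_phantom, margin_mm=100.0)
        assert set(all_near) == {
            "cord", "parotid_l", "parotid_r", "constrictors", "larynx", "brainstem"
        }
        # constrictors overlap the target, so even a vanishing margin
        # keeps them disabled; everything else re-enables
        assert dp.proximity_disabled_structures(coarse_phantom, margin_mm=0.1) == [
            "constrictors"
        ]


class TestEvaluateGoals:
    def _uniform_dose(self, phantom, structure, value):
        vals = np.zeros(phantom.rsp.shape)
        vals[phantom.structures[structure]] = value
        return phantom.grid.wrap(vals)

    def test_uniform_prescription_passes_d98(self, tiny_phantom):
        dose = self._uniform_dose(tiny_phantom, "ctv_high", 70.0)
        goals = dp.ClinicalGoals()
        reports = dp.evaluate_goals(dose, tiny_phantom, goals, dp.Prescription())
        r = next(x for x in reports if (x.structure, x.metric) == ("ctv_high", "d98"))
        assert r.passed and r.value == pytest.approx(100.0 / 33.0 * 33.0, rel=1e-9)

    def test_overdose_fails_d2(self, tiny_phantom):
        dose = self._uniform_dose(tiny_phantom, "ctv_high", 80.0)
        reports = dp.evaluate_goals(
            dose, tiny_phantom, dp.ClinicalGoals(), dp.Prescription()
        )
        r = next(x for x in reports if (x.structure, x.metric) == ("ctv_high", "d2"))
        assert not r.passed and r.value == pytest.approx(800.0 / 7.0, rel=1e-9)

    def test_cord_just_below_limit_passes(self, tiny_phantom):
        dose = self._uniform_dose(tiny_phantom, "cord", 44.9)
        reports = dp.evaluate_goals(
            dose, tiny_phantom, dp.ClinicalGoals(), dp.Prescription(), scale=1.0
        )
        r = next(x for x in reports if x.structure == "cord")
        assert r.passed and r.value == pytest.approx(44.9)

    def test_disabled_goal_not_applied(self, tiny_phantom):
        goals = dp.ClinicalGoals().disable("parotid_l")
        dose = self._uniform_dose(tiny_phantom, "ctv_high", 70.0)
        reports = dp.evaluate_goals(dose, tiny_phantom, goals, dp.Prescription())
        r = next(x for x in reports if x.structure == "parotid_l")
        assert r.status == "not applied" and r.value is None


def test_warm_start_matches_cold_start_at_adaptation_budget(tiny_cohort, tiny_plan):
    """At the capped online-adaptation budget, warm-starting from the base
    weights reaches an objective equivalent to (never meaningfully worse
    than) a cold start — the property the online workflow relies on."""
    from daptsim.course import _FractionEngine
    from daptsim.cohort import daily_instance

    patient = tiny_cohort[0]
    eng = _FractionEngine(patient, tiny_plan)
    ratios = []
    for j in (2, 5, 9):
        daily = daily_instance(patient, j)
        wed = eng.builder.wed_rows(eng.builder.wed_full(daily.phantom))
        im = eng.builder.matrix(wed, tiny_plan.beamlets, iso_shift=daily.setup_transform)
        obj = dp.build_objective(
            daily.phantom, tiny_plan.prescription, tiny_plan.goals,
            fraction_scale=1.0 / patient.n_fractions,
        )
        warm = dp.optimize(im, obj, w_init=eng.w_base, maxiter=100)
        cold = dp.optimize(im, obj, maxiter=100)
        ratios.append(warm.objective_value / cold.objective_value)
    assert np.median(ratios) <= 1.02
    assert max(ratios) <= 1.05
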