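"""Pencil-beam engine: range model, Bragg curve, WED, spots, influence."""

import dataclasses

import numpy as np
import pytest

from daptsim import engine as de
from daptsim.cohort import build_phantom
from daptsim.grid import GridSpec


MODEL = de.BeamModel()


def water_phantom(shape=(40, 40, 30), spacing=4.0):
    """Uniform water block filling the whole grid (structures nominal)."""
    grid = GridSpec(shape, (spacing,) * 3)
    ph = build_phantom(grid)
    values = np.ones(shape)
    rsp = grid.wrap(values)
    return dataclasses.replace(ph, rsp=rsp)


class TestRangeEnergy:
    def test_power_law_value(self):
        # alpha * E^p with alpha=0.0022, p=1.77 at 150 MeV
        assert de.range_from_energy(150.0) == pytest.approx(15.6, abs=0.1)

    def test_monotonic(self):
        assert de.range_from_energy(100.0) < de.range_from_energy(150.0) < de.range_from_energy(225.0)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            de.range_from_energy(10.0)
        with pytest.raises(ValueError):
            de.range_from_energy(300.0)

    def test_inverse(self):
        for E in (70.0, 120.0, 200.0):
            assert de.energy_from_range(de.range_from_energy(E)) == pytest.approx(E, rel=1e-12)


class TestSigmaAir:
    @pytest.mark.parametrize("E,expected", [(65.0, 6.4), (225.0, 2.5), (145.0, 4.45)])
    def test_linear_interpolation(self, E, expected):
        assert de.sigma_air(E) == pytest.approx(expected, abs=1e-12)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            de.sigma_air(64.0)


class TestDepthDose:
    def test_peak_normalized_at_range(self):
        for E in (80.0, 150.0, 220.0):
            R = de.range_from_energy(E)
            assert de.depth_dose(E, R) == pytest.approx(1.0, abs=0.01)
            wed = np.linspace(0, R * 1.2, 500)
            assert de.depth_dose(E, wed).max() <= 1.0 + 1e-9

    def test_zero_beyond_distal_falloff(self):
        E = 150.0
        R = de.range_from_energy(E)
        sR = de.straggling_sigma(E)
        assert de.depth_dose(E, R + 10 * sR) == 0.0
        assert de.depth_dose(E, R + 4.01 * sR) == 0.0

    def test_entrance_to_peak_ratio(self):
        # regression band for the analytic curve shape at 150 MeV
        ratio = de.depth_dose(150.0, 0.0)
        assert 0.15 < ratio < 0.55

    def test_unimodal(self):
        E = 120.0
        R = de.range_from_energy(E)
        wed = np.linspace(0, R + 1.0, 800)
        d = np.asarray(de.depth_dose(E, wed))
        peak = int(np.argmax(d))
        assert np.all(np.diff(d[:peak]) > -1e-6)

    def test_negative_depth_rejected(self):
        with pytest.raises(ValueError):
            de.depth_dose(150.0, -1.0)


class TestWED:
    def test_uniform_water_closed_form(self):
        ph = water_phantom()
        fld = de.Field(180.0, (0.0, 0.0, 0.0))
        # beam travels +y; point 50 mm past the -y grid edge
        oy = ph.rsp.origin[1]
        point = (0.0, oy + 50.0 - 2.0, 0.0)  # 50 mm from edge of voxel extent
        wed = de.wed_raytrace(ph, fld, [point])[0]
        assert wed == pytest.approx(50.0 + MODEL.range_shifter_wet, abs=2.5)

    def test_entrance_surface_is_shifter_only(self):
        ph = water_phantom()
        fld = de.Field(180.0, (0.0, 0.0, 0.0))
        oy = ph.rsp.origin[1]
        point = (0.0, oy - 1.9, 0.0)  # just outside the voxel extent
        wed = de.wed_raytrace(ph, fld, [point])[0]
        assert wed == pytest.approx(MODEL.range_shifter_wet, abs=0.5)

    def test_linearity_in_rsp(self):
        ph = water_phantom()
        doubled = dataclasses.replace(ph, rsp=ph.rsp.spec.wrap(2.0 * ph.rsp.values))
        fld = de.Field(180.0, (0.0, 0.0, 0.0))
        pts = [(0.0, 10.0, 0.0), (4.0, -14.0, 8.0)]
        w1 = de.wed_raytrace(ph, fld, pts) - MODEL.range_shifter_wet
        w2 = de.wed_raytrace(doubled, fld, pts) - MODEL.range_shifter_wet
        # atol covers the (undoubled) trace through the air padding
        assert np.allclose(w2, 2.0 * w1, rtol=1e-6, atol=0.01)

    @pytest.mark.parametrize("angle", [60.0, 180.0, 300.0])
    def test_grid_matches_raytrace(self, coarse_phantom, angle):
        """Whole-grid WED agrees with the per-point tracer to ~one voxel."""
        ph = coarse_phantom
        fld = de.Field(angle, (0.0, 0.0, 0.0))
        wg = de.wed_grid(ph, fld)
        spec = ph.grid
        rng = np.random.default_rng(0)
        inner = np.argwhere(ph.structures["ctv_low"])
        pick = inner[rng.choice(len(inner), 20, replace=False)]
        pts = [spec.origin + np.asarray(spec.spacing) * idx for idx in pick]
        wr = de.wed_raytrace(ph, fld, pts)
        wg_vals = np.array([wg[tuple(idx)] for idx in pick])
        assert np.abs(wg_vals - wr).max() < 2.0 * min(spec.spacing)


class TestPlaceSpots:
    def test_single_voxel_target(self, tiny_phantom):
        mask = np.zeros(tiny_phantom.rsp.shape, bool)
        ii = np.argwhere(tiny_phantom.structures["ctv_high"])[0]
        mask[tuple(ii)] = True
        fld = de.Field(180.0, (0.0, 0.0, 0.0))
        wed = de.wed_grid(tiny_phantom, fld)
        spots = de.place_spots(tiny_phantom, mask, fld, wed=wed)
        assert len(spots) >= 1
        target_wed = wed[tuple(ii)]
        peaks = np.array([10.0 * de.range_from_energy(b.energy) for b in spots])
        assert np.abs(peaks - target_wed).min() <= 5.0 + 1e-6

    def test_layer_count_for_wed_span(self):
        # 60 mm WED span at 5 mm layer spacing needs >= 13 layers
        ph = water_phantom()
        fld = de.Field(180.0, (0.0, 0.0, 0.0))
        mask = np.zeros(ph.rsp.shape, bool)
        mask[20, 10:26, 15] = True  # 15 voxels * 4 mm = 60 mm deep span
        spots = de.place_spots(ph, mask, fld, spot_spacing=5.0, layer_spacing=5.0)
        energies = sorted({b.energy for b in spots})
        assert len(energies) >= 13

    def test_empty_target_raises(self, tiny_phantom):
        fld = de.Field(180.0, (0.0, 0.0, 0.0))
        with pytest.raises(de.PlanningError):
            de.place_spots(tiny_phantom, np.zeros(tiny_phantom.rsp.shape, bool), fld)

    def test_too_deep_target_raises(self):
        ph = water_phantom(shape=(24, 180, 24), spacing=4.0)
        fld = de.Field(180.0, (0.0, 0.0, 0.0))
        mask = np.zeros(ph.rsp.shape, bool)
        mask[12, -3, 12] = True  # ~700 mm of water: beyond any energy
        with pytest.raises(de.PlanningError):
            de.place_spots(ph, mask, fld)


@pytest.fixture(scope="module")
def water_beam():
    ph = water_phantom()
    fld = de.Field(180.0, (0.0, 0.0, 0.0))
    # energies chosen so every Bragg peak lies inside the water block
    beamlets = [
        de.Beamlet(0, E, (0.0, 0.0), de.sigma_air(E)) for E in (80.0, 95.0, 110.0, 125.0, 140.0)
    ]
    im = de.influence_matrix(ph, [fld], beamlets)
    return ph, fld, beamlets, im


class TestInfluenceMatrix:
    def test_nonnegative_entries(self, water_beam):
        _, _, _, im = water_beam
        assert im.entries.nnz > 0
        assert im.entries.data.min() >= 0

    def test_dose_linearity(self, water_beam, rng):
        _, _, beamlets, im = water_beam
        w1 = rng.random(len(beamlets))
        w2 = rng.random(len(beamlets))
        d1 = de.compute_dose(im, w1).values
        d2 = de.compute_dose(im, w2).values
        d12 = de.compute_dose(im, w1 + w2).values
        assert np.allclose(d12, d1 + d2, rtol=1e-9, atol=1e-12)

    def test_zero_weights_zero_dose(self, water_beam):
        _, _, beamlets, im = water_beam
        assert not np.any(de.compute_dose(im, np.zeros(len(beamlets))).values)

    def test_unit_weight_reproduces_column(self, water_beam):
        _, _, beamlets, im = water_beam
        e2 = np.zeros(len(beamlets))
        e2[2] = 1.0
        dose = de.compute_dose(im, e2)
        col = np.asarray(im.entries[:, 2].todense()).ravel()
        full = np.zeros(dose.values.size)
        full[im.row_index] = col
        assert np.allclose(dose.values.ravel(), full, rtol=1e-6, atol=1e-12)

    def test_bragg_peak_position_in_water(self, water_beam):
        """Peak voxel depth within one voxel of the analytic range minus
        the shifter WET, for five energies."""
        ph, fld, beamlets, im = water_beam
        spec = ph.rsp.spec
        oy = ph.rsp.origin[1]
        h = ph.rsp.spacing[1]
        for k, b in enumerate(beamlets):
            e = np.zeros(len(beamlets))
            e[k] = 1.0
            dose = de.compute_dose(im, e).values
            iy = np.unravel_index(np.argmax(dose), dose.shape)[1]
            depth = (iy + 0.5) * h  # from the -y voxel-extent edge
            expected = 10.0 * de.range_from_energy(b.energy) - MODEL.range_shifter_wet
            assert abs(depth - expected) <= h + 1e-9, b.energy

    def test_entrance_lateral_sigma(self, water_beam):
        """Fitted lateral Gaussian sigma near the entrance within 10% of
        the spot sigma in air."""
        ph, fld, beamlets, im = water_beam
        b = beamlets[-1]  # 200 MeV: deep peak, clean entrance
        e = np.zeros(len(beamlets)); e[-1] = 1.0
        dose = de.compute_dose(im, e).values
        profile = dose[:, 1, dose.shape[2] // 2]
        x = ph.rsp.axes()[0]
        good = profile > profile.max() * 1e-3
        p = np.polyfit(x[good] ** 2, np.log(profile[good]), 1)
        sigma_fit = np.sqrt(-1.0 / (2.0 * p[0]))
        sigma_expected = np.hypot(
            b.sigma_air, de.sigma_medium(MODEL.range_shifter_wet + 1.5 * 4.0)
        )
        assert sigma_fit == pytest.approx(sigma_expected, rel=0.10)

    def test_negative_weights_rejected(self, water_beam):
        _, _, beamlets, im = water_beam
        w = np.zeros(len(beamlets)); w[0] = -1.0
        with pytest.raises(ValueError):
            de.compute_dose(im, w)

    def test_integral_dose_matches_column_sums(self, water_beam, rng):
        _, _, beamlets, im = water_beam
        w = rng.random(len(beamlets))
        dose = de.compute_dose(im, w)
        total = dose.values.sum() * dose.voxel_volume
        expected = float(
            (np.asarray(im.entries.sum(axis=0)).ravel() @ w) * dose.voxel_volume
        )
        assert total == pytest.approx(expected, rel=1e-6)


def test_sparsity_cutoff_negligible_for_plan(tiny_phantom, tiny_plan):
    """Dropping sub-cutoff entries changes CTV voxel doses by < 0.5%."""
    builder_exact = de.InfluenceBuilder(
        tiny_phantom.grid, tiny_plan.fields, row_mask=None, sparsity_cutoff=0.0
    )
    builder_cut = de.InfluenceBuilder(
        tiny_phantom.grid, tiny_plan.fields, row_mask=None, sparsity_cutoff=1e-4
    )
    wed = builder_exact.wed_full(tiny_phantom)
    d_exact = builder_exact.scatter(
        builder_exact.forward(builder_exact.wed_rows(wed), tiny_plan.beamlets, tiny_plan.weights.w)
    ).values
    d_cut = builder_cut.scatter(
        builder_cut.forward(builder_cut.wed_rows(wed), tiny_plan.beamlets, tiny_plan.weights.w)
    ).values
    ctv = tiny_phantom.structures["ctv_low"]
    rel = np.abs(d_cut - d_exact)[ctv] / d_exact[ctv].max()
    assert rel.max() < 0.005
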