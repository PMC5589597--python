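import math

import numpy as np
import pytest

from rtpseudo.io_core import ImageVolume, BinaryMask, PlanningError, SENTINEL
from rtpseudo.dose import (BeamSpec, PlanConfig, hu_to_density, density_from_ct,
                           radiological_path, compute_beam_dose, make_plan,
                           compute_plan_dose, apply_plan_state, dose_at_volume,
                           mask_on_grid)


class TestHuToDensity:
    @pytest.mark.parametrize("hu,red", [
        (-1000.0, 0.0),
        (0.0, 1.0),
        (700.0, 1.0 + 700.0 * 0.85 / 1500.0),
        (1500.0, 1.85),
        (-500.0, 0.5),
    ])
    def test_calibration_anchors_and_interpolation(self, hu, red):
        assert hu_to_density(hu) == pytest.approx(red, abs=1e-9)

    def test_clamped_outside_anchors(self):
        assert hu_to_density(-2000.0) == 0.0
        assert hu_to_density(4000.0) == 1.85

    def test_sentinel_rejected(self):
        with pytest.raises(ValueError):
            hu_to_density(SENTINEL)

    def test_monotone_nondecreasing(self):
        hu = np.linspace(-1500, 3000, 400)
        red = hu_to_density(hu)
        assert np.all(np.diff(red) >= 0)


def _uniform_volume(density=1.0, n=20, spacing=10.0):
    return ImageVolume(np.full((n, n, n), density), (spacing,) * 3,
                       (0.0, 0.0, 0.0), modality="CT")


class TestRadiologicalPath:
    def test_uniform_water_10cm(self):
        vol = _uniform_volume(1.0)
        # ray along x within the voxel-box extent [-5, 195]
        assert radiological_path(vol, (0, 95, 95), (100, 95, 95)) == pytest.approx(10.0)

    def test_vacuum_path_is_zero(self):
        vol = _uniform_volume(0.0)
        assert radiological_path(vol, (0, 95, 95), (100, 95, 95)) == 0.0

    def test_two_layer_closed_form(self):
        # first 50 mm density 1.0, next 50 mm density 0.5 (box edges at
        # -2.5 and 97.5 with 5 mm voxels, so integrate between them)
        data = np.concatenate([np.ones((10, 20, 20)), 0.5 * np.ones((10, 20, 20))])
        vol = ImageVolume(data, (5.0, 10.0, 10.0), (0.0, 0.0, 0.0))
        d = radiological_path(vol, (-2.5, 95, 95), (97.5, 95, 95))
        assert d == pytest.approx(5.0 + 2.5, abs=1e-9)

    def test_zero_length_ray_rejected(self):
        with pytest.raises(Exception):
            radiological_path(_uniform_volume(), (5, 5, 5), (5, 5, 5))

    def test_oblique_ray_against_sampled_integral(self):
        rng = np.random.default_rng(0)
        vol = ImageVolume(rng.uniform(0.0, 2.0, (15, 15, 15)), (4.0, 4.0, 4.0),
                         (0.0, 0.0, 0.0))
        src, dst = np.array([-10.0, 3.0, 7.0]), np.array([60.0, 50.0, 41.0])
        # dense midpoint-sampling oracle
        ts = (np.arange(40000) + 0.5) / 40000
        pts = src + ts[:, None] * (dst - src)
        idx = np.rint(vol.physical_to_index(pts)).astype(int)
        inside = np.all((idx >= 0) & (idx < 15), axis=1)
        dens = np.zeros(len(pts))
        dens[inside] = vol.data[idx[inside, 0], idx[inside, 1], idx[inside, 2]]
        oracle = dens.mean() * np.linalg.norm(dst - src) / 10.0
        assert radiological_path(vol, src, dst) == pytest.approx(oracle, abs=2e-3)


class TestComputeBeamDose:
    def test_isocenter_dose_in_vacuum_equals_weight(self):
        vac = ImageVolume(np.zeros((21, 21, 21)), (10.0,) * 3,
                          (-100.0, -100.0, -100.0))
        beam = BeamSpec(gantry_deg=0.0, isocenter=(0, 0, 0),
                        field_size=100.0, weight=2.0)
        dose = compute_beam_dose(vac, beam)
        assert dose.data[10, 10, 10] == pytest.approx(2.0, rel=1e-6)

    def test_attenuation_closed_form(self):
        # uniform water, isocenter 100 mm deep along the beam; disable
        # inverse-square and penumbra to isolate exp(-mu d)
        water = ImageVolume(np.ones((21, 21, 21)), (10.0,) * 3,
                            (-100.0, -100.0, -100.0))
        beam = BeamSpec(gantry_deg=0.0, isocenter=(0.0, 5.0, 0.0),
                        field_size=150.0, weight=1.0, mu_per_cm=0.05)
        dose = compute_beam_dose(water, beam, inverse_square=False,
                                 penumbra=False)
        # beam from -y: entry at y=-105 (box face), isocenter voxel y=0
        # -> depth 10.5 cm
        got = dose.data[10, 10, 10]
        assert got == pytest.approx(math.exp(-0.05 * 10.5), rel=1e-3)

    def test_bone_slab_reduces_downstream_dose(self, clean_head):
        density = density_from_ct(clean_head.ct)
        water = density.with_data(np.where(density.data > 0, 1.0, 0.0))
        beam = BeamSpec(gantry_deg=0.0, isocenter=(0.0, 0.0, 0.0),
                        field_size=60.0)
        d_true = compute_beam_dose(density, beam)
        d_water = compute_beam_dose(water, beam)
        # behind the skull (beam from -y): bone attenuates more than water
        j = np.argmin(np.abs(density.origin[1] + density.spacing[1]
                             * np.arange(density.shape[1])))
        c = tuple(np.array(density.shape) // 2)
        assert d_true.data[c] < d_water.data[c]

    def test_dose_monotone_with_depth_in_water(self):
        water = ImageVolume(np.ones((21, 21, 41)), (10.0, 10.0, 5.0),
                            (-100.0, -100.0, -100.0))
        beam = BeamSpec(gantry_deg=0.0, isocenter=(0, 0, 0), field_size=150.0)
        dose = compute_beam_dose(water, beam)
        axis_profile = dose.data[10, :, 20]  # along the beam (y axis)
        assert np.all(np.diff(axis_profile) < 0)

    def test_sentinel_volume_rejected(self):
        vol = ImageVolume(np.ones((8, 8, 8)), (10.0,) * 3, (0, 0, 0))
        vol.data[0, 0, 0] = SENTINEL
        with pytest.raises(ValueError):
            compute_beam_dose(vol, BeamSpec(gantry_deg=0.0))


class TestMakePlan:
    def test_five_beams_one_noncoplanar(self, small_head):
        plan = make_plan(small_head.structures["ptv_ord"])
        assert len(plan.beams) == 5
        assert sum(b.couch_deg != 0.0 for b in plan.beams) == 1

    def test_isocenter_at_ptv_centroid(self, small_head):
        ptv = small_head.structures["ptv_ord"]
        plan = make_plan(ptv)
        idx = np.argwhere(ptv.data)
        centroid = ptv.index_to_physical(idx.astype(float)).mean(axis=0)
        assert np.allclose(plan.beams[0].isocenter, centroid, atol=1e-6)

    def test_empty_unscanned_leaves_default_angles(self, small_head):
        cfg = PlanConfig()
        empty = BinaryMask.from_volume(small_head.ct,
                                       np.zeros(small_head.ct.shape, bool))
        plan = make_plan(small_head.structures["ptv_ord"], empty, cfg)
        assert [b.gantry_deg for b in plan.beams[:4]] == list(
            cfg.coplanar_gantry_deg)

    def test_beams_avoid_unscanned_region(self, small_head):
        from rtpseudo.dose import _ray_blocked
        ct = small_head.ct
        # mark an inferior slab as unscanned
        unsc_arr = np.zeros(ct.shape, dtype=bool)
        unsc_arr[:, :, :8] = True
        unsc = BinaryMask.from_volume(ct, unsc_arr)
        # put a couch-rotated beam below so the default entry crosses the slab
        cfg = PlanConfig(noncoplanar_couch_deg=80.0, noncoplanar_gantry_deg=90.0)
        plan = make_plan(small_head.structures["ptv_ord"], unsc, cfg)
        iso = np.asarray(plan.beams[0].isocenter)
        for beam in plan.beams:
            assert not _ray_blocked(unsc, beam.source_position, iso)

    def test_empty_ptv_rejected(self, small_head):
        empty = BinaryMask.from_volume(small_head.ct,
                                       np.zeros(small_head.ct.shape, bool))
        with pytest.raises(PlanningError):
            make_plan(empty)


@pytest.fixture(scope="module")
def plan_dose(small_head):
    ptv = small_head.structures["ptv_ord"]
    plan = make_plan(ptv)
    dose, state = compute_plan_dose(small_head.ct, plan, ptv)
    return small_head, ptv, plan, dose, state


class TestComputePlanDose:
    def test_d95_normalization_exact(self, plan_dose):
        head, ptv, plan, dose, state = plan_dose
        vals = dose.data[mask_on_grid(ptv, dose).data]
        assert dose_at_volume(vals, 95.0) == pytest.approx(100.0, abs=0.01)

    def test_v100_covers_95_percent(self, plan_dose):
        head, ptv, plan, dose, state = plan_dose
        vals = dose.data[mask_on_grid(ptv, dose).data]
        v100 = 100.0 * (vals >= 100.0).mean()
        assert v100 == pytest.approx(95.0, abs=0.1)

    def test_max_ptv_within_110(self, plan_dose):
        head, ptv, plan, dose, state = plan_dose
        vals = dose.data[mask_on_grid(ptv, dose).data]
        assert vals.max() <= 110.0 + 1e-6

    def test_weight_scale_invariance(self, plan_dose):
        head, ptv, plan, dose, state = plan_dose
        doubled = make_plan(ptv)
        for b in doubled.beams:
            b.weight *= 2.0
        dose2, _ = compute_plan_dose(head.ct, doubled, ptv)
        assert np.allclose(dose2.data, dose.data, atol=1e-9)

    def test_deterministic(self, plan_dose):
        head, ptv, plan, dose, state = plan_dose
        dose2, state2 = compute_plan_dose(head.ct, plan, ptv)
        assert np.array_equal(dose.data, dose2.data)
        assert np.array_equal(state.weights, state2.weights)

    def test_dose_nonnegative_finite(self, plan_dose):
        _, _, _, dose, _ = plan_dose
        assert np.all(dose.data >= 0)
        assert np.all(np.isfinite(dose.data))

    def test_frozen_state_reapplies_identically(self, plan_dose):
        head, ptv, plan, dose, state = plan_dose
        again = apply_plan_state(head.ct, plan, state)
        assert np.array_equal(again.data, dose.data)

    def test_frozen_state_exposes_density_change(self, plan_dose):
        # verification contract: a denser CT must yield a lower dose when
        # weights and normalization stay frozen
        head, ptv, plan, dose, state = plan_dose
        denser = head.ct.with_data(head.ct.data + 200.0)
        ver = apply_plan_state(denser, plan, state)
        ptv_grid = mask_on_grid(ptv, dose).data
        assert ver.data[ptv_grid].mean() < dose.data[ptv_grid].mean()


class TestHeterogeneitySensitivity:
    def test_water_override_differs_behind_skull(self, clean_head):
        """Replacing true HU with water changes dose >1% two cm behind bone."""
        density = density_from_ct(clean_head.ct)
        body = clean_head.structures["body"].data
        water = density.with_data(np.where(body, 1.0, 0.0))
        beam = BeamSpec(gantry_deg=0.0, isocenter=(0.0, 0.0, 0.0),
                        field_size=80.0)
        d_true = compute_beam_dose(density, beam)
        d_water = compute_beam_dose(water, beam)
        # beam enters from -y; find the skull exit along y at x=z=center,
        # then look 20 mm downstream
        c = np.array(clean_head.ct.shape) // 2
        ys = clean_head.ct.origin[1] + clean_head.ct.spacing[1] * np.arange(
            clean_head.ct.shape[1])
        skull_rows = np.where(clean_head.structures["skull"].data[c[0], :, c[2]])[0]
        entry_exit = skull_rows[ys[skull_rows] < 0].max()  # inner skull, -y side
        j20 = entry_exit + int(round(20.0 / clean_head.ct.spacing[1]))
        rel = abs(d_true.data[c[0], j20, c[2]] - d_water.data[c[0], j20, c[2]])
        rel /= d_water.data[c[0], j20, c[2]]
        assert rel > 0.01
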