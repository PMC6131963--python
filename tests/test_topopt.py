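"""SIMP compliance minimisation: sensitivities, filtering, OC updates, schedule."""

import numpy as np
import pytest
from scipy import ndimage

import frogpad as fp
from frogpad import fem, topopt
from frogpad.topopt import (
    OptimisationSchedule,
    compliance_and_sensitivity,
    filter_sensitivities,
    update_densities,
)


@pytest.fixture()
def toy_domain(material):
    dom = fp.solid_box(0.3, 0.2, 0.2, (3, 2, 2))
    return dom


@pytest.fixture()
def toy_load():
    return fem.LoadCase(
        fixed_faces={"proximal": (True, True, True)},
        tractions=(fem.FaceTraction("distal", (1e-3, 0, 5e-4)),),
    )


class TestSchedule:
    def test_published_schedule_has_24_stages(self):
        s = OptimisationSchedule()
        assert s.n_stages == 24
        assert np.isclose(s.targets()[-1], 0.40)
        assert np.allclose(np.diff(s.targets()), -0.025)

    @pytest.mark.parametrize(
        "kwargs", [dict(total_reduction=0.6, step=0.07), dict(total_reduction=1.2),
                   dict(step=-0.1)]
    )
    def test_invalid_schedule_raises(self, kwargs):
        with pytest.raises(ValueError):
            OptimisationSchedule(**kwargs)


class TestSensitivity:
    def test_sensitivities_never_positive(self, pad_domain, material, shear_load_case):
        c, sens, _ = compliance_and_sensitivity(pad_domain, material, shear_load_case)
        assert c > 0
        assert np.all(sens <= 0)

    def test_matches_central_finite_difference(self, toy_domain, toy_load, material):
        rng = np.random.default_rng(42)
        toy_domain.density = 0.3 + 0.6 * rng.random(toy_domain.density.shape)
        _, sens, _ = compliance_and_sensitivity(toy_domain, material, toy_load)
        h = 1e-5
        for idx in [(0, 0, 0), (1, 1, 0), (2, 0, 1)]:
            dp, dm = toy_domain.copy(), toy_domain.copy()
            dp.density[idx] += h
            dm.density[idx] -= h
            cp, _, _ = compliance_and_sensitivity(dp, material, toy_load)
            cm, _, _ = compliance_and_sensitivity(dm, material, toy_load)
            fd = (cp - cm) / (2 * h)
            assert abs(fd - sens[idx]) <= 1e-4 * abs(fd)

    def test_compliance_quadratic_in_load(self, toy_domain, material, toy_load):
        c1, _, _ = compliance_and_sensitivity(toy_domain, material, toy_load)
        doubled = fem.LoadCase(
            fixed_faces=toy_load.fixed_faces,
            tractions=(fem.FaceTraction("distal", (2e-3, 0, 1e-3)),),
        )
        c2, _, _ = compliance_and_sensitivity(toy_domain, material, doubled)
        assert np.isclose(c2, 4 * c1, rtol=1e-10)


class TestFilter:
    def test_constant_field_unchanged(self, pad_domain):
        s = np.where(pad_domain.solid_mask, -2.5, 0.0)
        out = filter_sensitivities(s, pad_domain, radius_mm=0.12)
        assert np.allclose(out[pad_domain.solid_mask], -2.5, rtol=1e-12)

    def test_radius_below_voxel_edge_is_identity(self, pad_domain):
        rng = np.random.default_rng(3)
        s = -rng.random(pad_domain.resolution) * pad_domain.solid_mask
        out = filter_sensitivities(s, pad_domain, radius_mm=0.01)
        assert np.array_equal(out, s)

    def test_single_spike_spread_matches_explicit_weights(self):
        dom = fp.solid_box(0.3, 0.3, 0.3, (3, 3, 3))
        s = np.zeros((3, 3, 3))
        s[1, 1, 1] = -1.0
        r = 0.15  # 1.5 voxel edges
        out = filter_sensitivities(s, dom, radius_mm=r)
        # oracle: centre receives w_self/(sum of its weights); neighbour j
        # receives w(d_ij)/(sum of weights around j)
        h = 0.1
        centres = np.stack(np.meshgrid(*[np.arange(3) * h + h / 2] * 3, indexing="ij"), -1)
        pc = centres[1, 1, 1]
        expected = np.zeros((3, 3, 3))
        for i in range(3):
            for j in range(3):
                for k in range(3):
                    p = centres[i, j, k]
                    wsum = 0.0
                    for a in range(3):
                        for b in range(3):
                            for c in range(3):
                                d = np.linalg.norm(centres[a, b, c] - p)
                                if d < r:
                                    wsum += r - d
                    d_c = np.linalg.norm(p - pc)
                    if d_c < r:
                        expected[i, j, k] = -(r - d_c) / wsum
        assert np.allclose(out, expected, atol=1e-12)

    def test_sign_preserved(self, pad_domain):
        rng = np.random.default_rng(5)
        s = -rng.random(pad_domain.resolution) * pad_domain.solid_mask
        out = filter_sensitivities(s, pad_domain, radius_mm=0.12)
        assert np.all(out[pad_domain.solid_mask] <= 0)


class TestUpdateDensities:
    def test_fixed_point_under_uniform_sensitivity(self, pad_domain):
        s = np.where(pad_domain.solid_mask, -1.0, 0.0)
        vf = pad_domain.volume_fraction()
        out = update_densities(pad_domain, s, vf)
        assert np.allclose(out.density, pad_domain.density, atol=1e-5)

    def test_high_sensitivity_region_retains_material(self):
        dom = fp.solid_box(0.4, 0.2, 0.1, (4, 2, 1))
        s = np.zeros(dom.resolution)
        s[:2] = -10.0  # proximal block strongly loaded
        s[2:] = -1e-6
        dom.symmetric = False
        out = update_densities(dom, s, 0.85)
        assert out.density[:2].mean() > out.density[2:].mean()
        assert np.isclose(out.volume_fraction(), 0.85, atol=1e-4)

    def test_mirror_symmetry_exact(self, pad_domain):
        rng = np.random.default_rng(9)
        s = -rng.random(pad_domain.resolution) * pad_domain.solid_mask
        out = update_densities(pad_domain, s, 0.9)
        assert np.array_equal(out.density, out.mirrored(out.density))
        assert np.all(out.density[out.void_mask] == 0)

    def test_volume_target_hit(self, pad_domain):
        rng = np.random.default_rng(10)
        s = -rng.random(pad_domain.resolution) * pad_domain.solid_mask
        out = update_densities(pad_domain, s, 0.95)
        assert abs(out.volume_fraction() - 0.95) < 1e-4

    def test_infeasible_target_raises(self, pad_domain):
        dom = pad_domain.copy()
        dom.freeze_face_layer("ventral")
        frozen_frac = dom.frozen_mask.sum() / dom.solid_mask.sum()
        s = np.where(dom.solid_mask, -1.0, 0.0)
        with pytest.raises(ValueError, match="infeasible"):
            update_densities(dom, s, 0.5 * frozen_frac)


@pytest.fixture(scope="module")
def cantilever_result(material):
    """Planar cantilever (fixed proximal face, tip edge load) reduced by 50%."""
    dom = fp.solid_box(1.2, 0.1, 0.6, (24, 2, 12))
    dom.symmetric = False
    nx, ny, nz = dom.resolution
    iy = np.arange(ny + 1)
    nodes = fem.node_index(dom.resolution, np.full(ny + 1, nx), iy, np.zeros(ny + 1, int))
    lc = fem.LoadCase(
        fixed_faces={"proximal": (True, True, True)},
        line_loads=(fem.LineLoad(tuple(int(n) for n in nodes), (0, 0, -1e-3)),),
    )
    sched = OptimisationSchedule(total_reduction=0.5, step=0.025)
    return fp.optimise(dom, material, lc, sched, freeze_ventral=False,
                       use_symmetry=False, keep_history=False)


class TestOptimise:
    def test_cantilever_keeps_connected_load_path(self, cantilever_result):
        res = cantilever_result
        assert np.isclose(res.final_volume_fraction, 0.5, atol=1e-4)
        solid = res.domain.density > 0.5
        labels, _ = ndimage.label(solid)
        support = set(labels[0][solid[0]].tolist()) - {0}
        loaded = set(labels[-1, :, 0][solid[-1, :, 0]].tolist()) - {0}
        assert support & loaded  # one component joins support and load

    def test_compliance_never_decreases_across_stages(self, cantilever_result):
        res = cantilever_result
        c = np.array(res.compliance_Nmm)
        assert np.all(np.diff(c) >= -1e-6 * c[:-1])
        assert c[0] >= res.initial_compliance_Nmm * (1 - 1e-6)
        assert len(c) == 20

    def test_volume_targets_hit_at_every_stage(self, cantilever_result):
        vf = np.array(cantilever_result.volume_fraction)
        sched = OptimisationSchedule(total_reduction=0.5, step=0.025)
        assert np.allclose(vf, sched.targets(), atol=1e-4)
        assert np.all(np.diff(vf) < 0)

    def test_half_model_matches_full_model(self, pad_domain, material, shear_load_case):
        dom = pad_domain.copy()
        dom.freeze_face_layer("ventral")
        c_full, s_full, _ = compliance_and_sensitivity(dom, material, shear_load_case)
        half = topopt._symmetric_half(dom, shear_load_case)
        assert half is not None
        half_dom, half_lc = half
        c_h, s_h, _ = compliance_and_sensitivity(half_dom, material, half_lc)
        s_mir = np.concatenate([s_h, s_h[:, ::-1, :]], axis=1)
        assert np.isclose(2 * c_h, c_full, rtol=1e-10)
        assert np.allclose(s_mir, s_full, rtol=1e-8, atol=1e-12 * np.abs(s_full).max())
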