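"""Synthetic-data generator: phantoms, measurement noise, cohorts,
scatterer warping."""

import numpy as np
import pytest

from vasoelast.cohort import CohortSpec, GroupSpec, REFERENCE_METRICS, default_cohort_spec, generate_cohort
from vasoelast.geometry import GeometryError
from vasoelast.fem import PressureLoad, solve_forward
from vasoelast.phantom import (
    IntimaSpec,
    PhantomSpec,
    make_phantom,
    scatter_and_warp,
    synth_displacement_measurement,
)
from vasoelast.fem import DisplacementField


class TestPhantom:
    def test_single_region_labelled_wall(self, homog_phantom):
        _, mesh, mat = homog_phantom
        assert set(mesh.region_names()) == {"wall"}
        assert mat.region_moduli == {"wall": 18.0}

    def test_determinism_bytewise(self):
        spec = PhantomSpec(seed=7)
        m1, _ = make_phantom(spec)
        m2, _ = make_phantom(spec)
        assert m1.nodes.tobytes() == m2.nodes.tobytes()
        assert m1.elements.tobytes() == m2.elements.tobytes()

    def test_invalid_specs_rejected(self):
        with pytest.raises(GeometryError):
            PhantomSpec(inner_radius=0.3, outer_radius=0.19)
        with pytest.raises(GeometryError):
            PhantomSpec(intima_spec=IntimaSpec(360, 0.2))  # thicker than wall
        with pytest.raises(ValueError):
            PhantomSpec(region_moduli={"wall": -1.0})
        with pytest.raises(ValueError):
            PhantomSpec(poisson_ratio=0.5)

    def test_eccentric_intima_partial_arc(self):
        spec = PhantomSpec(
            intima_spec=IntimaSpec(angular_extent_deg=120, max_thickness_mm=0.05),
            region_moduli={"intima": 54.0, "media": 18.0},
            mesh_density=0.02,
        )
        mesh, _ = make_phantom(spec)
        assert set(mesh.region_names()) == {"intima", "media"}
        # crescent occupies less than the full ring
        full_ring = np.pi * (0.24**2 - 0.19**2)
        assert 0 < mesh.region_area("intima") < 0.6 * full_ring


class TestSyntheticMeasurement:
    def test_zero_noise_is_exact_forward_solution(self, homog_phantom):
        _, mesh, mat = homog_phantom
        u0 = synth_displacement_measurement(mesh, mat, 131.0, 0.0, seed=1)
        clean = solve_forward(mesh, mat, PressureLoad(131.0))
        np.testing.assert_array_equal(u0.values, clean.values)
        assert u0.provenance == "measured"

    def test_noise_sd_matches_target(self):
        spec = PhantomSpec(region_moduli={"wall": 18.0}, mesh_density=0.012)
        mesh, mat = make_phantom(spec)
        assert mesh.n_nodes >= 1000
        clean = solve_forward(mesh, mat, PressureLoad(131.0))
        noisy = synth_displacement_measurement(mesh, mat, 131.0, 0.01, seed=3)
        resid = (noisy.values - clean.values).ravel()
        target = 0.01 * np.hypot(*clean.values.T).max()
        assert resid.std() == pytest.approx(target, rel=0.10)

    def test_different_seeds_differ(self, homog_phantom):
        _, mesh, mat = homog_phantom
        a = synth_displacement_measurement(mesh, mat, 131.0, 0.01, seed=1)
        b = synth_displacement_measurement(mesh, mat, 131.0, 0.01, seed=2)
        assert not np.array_equal(a.values, b.values)


class TestCohort:
    def test_psv_draws_recover_generating_mean(self):
        spec = default_cohort_spec(seed=11, timepoints=("1wk",))
        data = generate_cohort(spec)
        sham = data.metrics.query("arm == 'sham' and artery == 'LCA'")
        assert len(sham) == 5
        mean, sem = REFERENCE_METRICS[("sham", "1wk", "LCA")]["psv"]
        assert abs(sham["psv"].mean() - mean) < 3 * sem * np.sqrt(5)

    def test_sham_intima_missing_ligated_positive(self):
        data = generate_cohort(default_cohort_spec(seed=5, timepoints=("2wk",)))
        for (animal, artery), areas in data.areas.items():
            intima = areas.areas_um2["intima"]
            if animal.startswith("ligated") and artery == "LCA":
                assert np.all(np.isfinite(intima)) and np.all(intima > 0)
            else:
                assert np.all(np.isnan(intima))

    def test_fold_change_arithmetic_without_jitter(self):
        spec = default_cohort_spec(seed=0, timepoints=("2wk",))
        spec.modulus_cv = 0.0
        data = generate_cohort(spec)
        sham = [p.region_moduli["wall"] for a, p in data.phantoms.items() if a.startswith("sham")]
        lig = [p.region_moduli["wall"] for a, p in data.phantoms.items() if a.startswith("ligated")]
        assert all(e == pytest.approx(18.0) for e in sham)
        assert all(e == pytest.approx(54.0) for e in lig)

    def test_reproducible_and_mean_preserving(self):
        spec = default_cohort_spec(seed=21)
        d1 = generate_cohort(spec)
        d2 = generate_cohort(spec)
        assert d1.metrics.equals(d2.metrics)
        # animal-level modulus jitter is mean-preserving within MC error
        lig = d1.metrics.query("artery=='LCA' and arm=='ligated' and timepoint=='2wk'")
        sham = d1.metrics.query("artery=='LCA' and arm=='sham' and timepoint=='2wk'")
        ratio = lig["wall_modulus_true_kpa"].mean() / sham["wall_modulus_true_kpa"].mean()
        assert ratio == pytest.approx(3.0, rel=0.15)

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            GroupSpec("sham", "1wk", 0, {})
        with pytest.raises(ValueError):
            CohortSpec(groups=[], modulus_fold_change={"1wk": -1.0})


class TestScatterAndWarp:
    def test_zero_field_identity_and_uniform_shift(self, homog_phantom):
        spec, mesh, _ = homog_phantom
        zero = DisplacementField(np.zeros((mesh.n_nodes, 2)))
        pre, post = scatter_and_warp(spec, mesh, zero, density_per_mm2=500, seed=1)
        np.testing.assert_array_equal(pre.positions, post.positions)
        np.testing.assert_array_equal(pre.amplitudes, post.amplitudes)

        shift = DisplacementField(np.tile([5e-3, 0.0], (mesh.n_nodes, 1)))
        pre, post = scatter_and_warp(spec, mesh, shift, density_per_mm2=500, seed=1)
        np.testing.assert_allclose(post.positions - pre.positions,
                                   np.tile([5e-3, 0.0], (len(pre.amplitudes), 1)),
                                   atol=1e-12)

    def test_pressurized_field_expands_radially(self, homog_phantom):
        spec, mesh, mat = homog_phantom
        field = solve_forward(mesh, mat, PressureLoad(10.0))
        pre, post = scatter_and_warp(spec, mesh, field, density_per_mm2=1000, seed=2)
        r_pre = np.hypot(*pre.positions.T)
        r_post = np.hypot(*post.positions.T)
        assert r_post.mean() > r_pre.mean()

    def test_seeded_density(self, homog_phantom):
        spec, mesh, _ = homog_phantom
        zero = DisplacementField(np.zeros((mesh.n_nodes, 2)))
        p1, _ = scatter_and_warp(spec, mesh, zero, density_per_mm2=2000, seed=9)
        p2, _ = scatter_and_warp(spec, mesh, zero, density_per_mm2=2000, seed=9)
        np.testing.assert_array_equal(p1.positions, p2.positions)
        area = np.pi * (spec.outer_radius**2 - spec.inner_radius**2)
        assert len(p1.amplitudes) == pytest.approx(2000 * area, rel=0.25)
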