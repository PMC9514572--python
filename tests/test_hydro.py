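"""Walk-on-spheres estimators against closed-form oracles: capacity of
spheres and sphere pairs, Perrin ellipsoids, gyration tensors, intrinsic
viscosity, and the Monte Carlo scaling/covariance invariants."""

import numpy as np
import pytest

from graftnp import (SphereUnionBody, capacity, distance_to_body, gyration,
                     hydrodynamic_radius, intrinsic_viscosity, rh_rg_ratio)
from graftnp import theory as th
from graftnp.workbench import ellipsoid_tessellation, make_fixture


def _sphere(R=1.0):
    return SphereUnionBody(np.zeros((1, 3)), np.array([R]))


def _dumbbell(R, r):
    return make_fixture("tangent_dumbbell", {"R": R, "r": r}).obj


class TestDistance:
    def test_single_sphere(self):
        assert distance_to_body([2.0, 0, 0], _sphere(1.0)) == pytest.approx(1.0)
        assert distance_to_body([0.0, 0, 0], _sphere(1.0)) == pytest.approx(-1.0)

    def test_tangency_point(self):
        body = _dumbbell(1.0, 0.5)
        assert distance_to_body([0, 0, 1.0], body) == pytest.approx(0.0,
                                                                    abs=1e-12)

    def test_matches_bruteforce(self, rng):
        body = SphereUnionBody(rng.normal(size=(40, 3)),
                               rng.uniform(0.1, 0.5, 40))
        pts = rng.normal(scale=2.0, size=(100, 3))
        brute = np.min(np.linalg.norm(pts[:, None] - body.centers, axis=-1)
                       - body.radii, axis=1)
        assert np.allclose(distance_to_body(pts, body), brute)


class TestCapacity:
    def test_sphere_capacity_equals_radius(self):
        est = capacity(_sphere(1.0), n_walks=100_000, seed=11)
        assert abs(est.value - 1.0) < 3 * est.std_error
        assert est.std_error < 0.002

    def test_two_equal_touching_spheres(self):
        est = capacity(_dumbbell(1.0, 1.0), n_walks=200_000, seed=12)
        assert abs(est.value - 2 * np.log(2)) < 3 * est.std_error

    def test_touching_spheres_R_and_half(self):
        est = capacity(_dumbbell(1.0, 0.5), n_walks=150_000, seed=13)
        assert abs(est.value - np.log(3)) < 3 * est.std_error

    @pytest.mark.parametrize("ratio", [0.1, 0.25, 0.5, 1.0])
    def test_against_russell_closed_form(self, ratio):
        exact = th.capacity_two_touching_spheres(1.0, ratio)
        est = capacity(_dumbbell(1.0, ratio), n_walks=100_000,
                       seed=int(100 * ratio))
        assert abs(est.value - exact) < 3 * est.std_error

    def test_skin_validation(self):
        with pytest.raises(ValueError):
            capacity(_sphere(0.001), n_walks=2_000, skin=0.01)
        with pytest.raises(ValueError):
            capacity(_sphere(1.0), n_walks=10)

    def test_error_scaling_with_walks(self):
        """Reported standard error shrinks as n^{-1/2} (within factor 1.5),
        and the estimate spread across seeds is consistent with it."""
        ses = []
        for n in (1_000, 10_000, 100_000):
            ses.append(capacity(_sphere(1.0), n_walks=n, seed=5,
                                n_batches=10).std_error)
        assert ses[0] / ses[1] == pytest.approx(np.sqrt(10), rel=0.5)
        assert ses[1] / ses[2] == pytest.approx(np.sqrt(10), rel=0.5)
        vals = [capacity(_sphere(1.0), n_walks=4_000, seed=s).value
                for s in range(12)]
        spread = np.std(vals)
        se = capacity(_sphere(1.0), n_walks=4_000, seed=0).std_error
        assert spread / se < 2.5 and spread / se > 0.4

    def test_monotone_under_sphere_addition(self, rng):
        """Capacity never decreases when a sphere is added (checked within
        Monte Carlo error over 50 random increments)."""
        body = SphereUnionBody(rng.normal(size=(2, 3)) * 0.5,
                               rng.uniform(0.3, 0.6, 2))
        prev = capacity(body, n_walks=20_000, seed=0)
        for k in range(50):
            body = body.add_sphere(rng.normal(size=3) * (0.5 + k * 0.02),
                                   rng.uniform(0.05, 0.4))
            cur = capacity(body, n_walks=20_000, seed=k + 1)
            assert cur.value >= prev.value - 4 * (cur.std_error
                                                  + prev.std_error)
            prev = cur


class TestPerrinAgreement:
    @pytest.mark.parametrize("p", [2.0, 3.0])
    def test_tessellated_ellipsoid_capacity(self, p):
        """Capacity analogy vs the exact Perrin translational R_h: within
        1% plus Monte Carlo error."""
        body = ellipsoid_tessellation(p, 1.0, 600)
        est = capacity(body, n_walks=150_000, seed=int(p))
        exact = th.prolate_spheroid_rh(p, 1.0)
        assert abs(est.value - exact) <= 0.01 * exact + 3 * est.std_error


class TestGyration:
    def test_solid_sphere(self):
        g = gyration(_sphere(2.0))
        assert g.R_g == pytest.approx(np.sqrt(3 / 5) * 2.0, rel=1e-12)
        assert np.allclose(g.tensor, g.tensor.T)
        assert g.R_g**2 == pytest.approx(g.eigenvalues.sum())

    def test_equal_touching_spheres(self):
        g = gyration(_dumbbell(1.0, 1.0))
        assert g.R_g == pytest.approx(np.sqrt(8 / 5), rel=1e-12)

    def test_unequal_matches_dumbbell_formula(self):
        g = gyration(_dumbbell(1.0, 0.5))
        assert g.R_g == pytest.approx(th.dumbbell_rg(0.5, 1.0), rel=1e-12)

    def test_contrast_modes_on_grafted_np(self):
        fx = make_fixture("grafted_np", {"R": 3.0, "N_c": 6, "L": 5,
                                         "forcefield": {"r_s_core": 2.675}},
                          seed=3)
        g_core = gyration(fx.obj, "core_only")
        assert g_core.R_g == pytest.approx(np.sqrt(3 / 5) * 3.0)
        g_ch = gyration(fx.obj, "chains_only")
        assert g_ch.R_g > 0
        bare = _sphere(1.0)
        with pytest.raises(ValueError):
            gyration(bare, "chains_only")


class TestRatioAndViscosity:
    def test_solid_sphere_ratio(self):
        est = rh_rg_ratio(_sphere(1.0), n_walks=50_000, seed=21)
        assert est.value == pytest.approx(np.sqrt(5 / 3), abs=0.01)

    def test_dumbbell_ratio(self):
        est = rh_rg_ratio(_dumbbell(1.0, 1.0), n_walks=100_000, seed=22)
        assert est.value == pytest.approx(1.096, abs=0.01)

    def test_dandelion_exceeds_hard_sphere_ratio(self):
        """Dense core with sparse extended rods: R_h/R_g well above the
        hard-sphere value 1.29 (dandelion effect)."""
        body = make_fixture("dandelion_rods",
                            {"R": 3.0, "n_rods": 12, "n_beads": 20,
                             "bead_radius": 0.3}, seed=4).obj
        est = rh_rg_ratio(body, contrast_mode="core_only",
                          n_walks=40_000, seed=23)
        assert est.value > np.sqrt(5 / 3)

    def test_sphere_intrinsic_viscosity(self):
        est = intrinsic_viscosity(_sphere(1.0), n_walks=60_000,
                                  n_volume=400_000, seed=24)
        assert abs(est.value - 2.5) < 3 * est.std_error
        assert est.std_error < 0.02

    def test_viscosity_scale_invariance(self):
        a = intrinsic_viscosity(_sphere(0.37), n_walks=40_000,
                                n_volume=300_000, seed=25)
        assert a.value == pytest.approx(2.5, abs=3 * a.std_error + 1e-3)

    def test_prolate_viscosity_vs_conductor_oracle(self):
        """The polarizability machinery against the exact conducting
        prolate spheroid; and the known few-percent overestimate of the
        Simha viscosity factor for strongly anisotropic bodies."""
        p = 5.0
        body = ellipsoid_tessellation(p, 1.0, 700)
        est = intrinsic_viscosity(body, n_walks=60_000, n_volume=500_000,
                                  seed=26)
        alpha_exact = th.conducting_prolate_polarizability(p, 1.0)
        assert est.extra["alpha"] == pytest.approx(alpha_exact, rel=0.03)
        simha_p5 = 5.806  # tabulated exact viscosity factor, prolate p=5
        assert est.value > 2.5
        assert est.value == pytest.approx(simha_p5, rel=0.08)

    def test_volume_refusal(self):
        with pytest.raises(ValueError, match="volume"):
            intrinsic_viscosity(
                make_fixture("dandelion_rods",
                             {"R": 0.4, "n_rods": 3, "n_beads": 30,
                              "bead_radius": 0.05}, seed=1).obj,
                n_walks=2_000, n_volume=20_000, seed=3)


class TestScaleCovariance:
    def test_lambda_two(self, rng):
        body = SphereUnionBody(rng.normal(size=(6, 3)),
                               rng.uniform(0.3, 0.8, 6))
        big = body.scaled(2.0)
        c1 = capacity(body, n_walks=40_000, seed=31)
        c2 = capacity(big, n_walks=40_000, seed=31)
        assert c2.value == pytest.approx(2 * c1.value,
                                         abs=3 * (2 * c1.std_error
                                                  + c2.std_error))
        assert gyration(big).R_g == pytest.approx(2 * gyration(body).R_g,
                                                  rel=1e-12)
        e1 = intrinsic_viscosity(body, n_walks=30_000, n_volume=300_000,
                                 seed=32)
        e2 = intrinsic_viscosity(big, n_walks=30_000, n_volume=300_000,
                                 seed=32)
        assert e1.value == pytest.approx(
            e2.value, abs=3 * (e1.std_error + e2.std_error))
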