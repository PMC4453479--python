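"""Protocol boundary-value solvers against closed forms, brute-force energy
minimization, and each other."""

import math

import numpy as np
import pytest
from scipy.optimize import minimize_scalar

import afmech as af
from afmech.errors import ConfigurationError, SolverError


def short_grid(n=7, top=1.3):
    return list(np.linspace(1.0, top, n))


class TestProtocolSpec:
    def test_defaults(self):
        spec = af.ProtocolSpec(kind="uniaxial")
        grid = spec.stretch_grid()
        assert len(grid) == 31 and grid[0] == 1.0 and grid[-1] == pytest.approx(1.3)

    @pytest.mark.parametrize("kwargs", [
        {"kind": "uniaxial", "stretches": [1.0, 0.9]},       # not increasing
        {"kind": "uniaxial", "stretches": [-1.0, 1.1]},      # non-positive
        {"kind": "uniaxial", "stretches": [0.9, 1.1]},       # compression
        {"kind": "planar_biaxial", "stretches": [1.0, 1.1],
         "axial_stretches": [1.0]},                          # length mismatch
    ])
    def test_invalid_specs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            af.ProtocolSpec(**kwargs)

    def test_compression_opt_in(self):
        spec = af.ProtocolSpec(kind="uniaxial", stretches=[0.9, 1.0, 1.1],
                               allow_compression=True)
        assert spec.stretch_grid()[0] == 0.9


class TestUniaxial:
    def test_reference_point_is_stress_free(self, fibers, biaxial_set):
        c = af.solve_uniaxial(biaxial_set, fibers,
                              af.ProtocolSpec(kind="uniaxial", stretches=[1.0]))
        assert c.sigma_11[0] == c.p_11[0] == 0.0
        assert c.lambda_2[0] == c.lambda_3[0] == 1.0

    def test_neo_hookean_closed_form_everywhere(self, fibers, neo_hookean):
        c = af.solve_uniaxial(neo_hookean, fibers,
                              af.ProtocolSpec(kind="uniaxial",
                                              stretches=short_grid()))
        lam = c.lambda_1
        np.testing.assert_allclose(c.lambda_2, 1.0 / np.sqrt(lam), atol=1e-10)
        np.testing.assert_allclose(c.lambda_3, 1.0 / np.sqrt(lam), atol=1e-10)
        np.testing.assert_allclose(
            c.sigma_11, 2.0 * neo_hookean.c10 * (lam**2 - 1.0 / lam), atol=1e-10)

    def test_anisotropic_lateral_contraction(self, fibers, biaxial_set):
        c = af.solve_uniaxial(biaxial_set, fibers,
                              af.ProtocolSpec(kind="uniaxial",
                                              stretches=[1.0, 1.05, 1.1]))
        assert abs(c.lambda_2[-1] - c.lambda_3[-1]) > 1e-3

    def test_lateral_solution_minimizes_energy(self, fibers, biaxial_set):
        # brute-force oracle: at fixed lam1 with det F = 1 and zero lateral
        # work, the free stretches minimize total energy
        lam = 1.15
        c = af.solve_uniaxial(biaxial_set, fibers,
                              af.ProtocolSpec(kind="uniaxial",
                                              stretches=short_grid()))
        i = int(np.argmin(np.abs(c.lambda_1 - lam)))

        def energy(l3):
            f = np.diag([lam, 1.0 / (lam * l3), l3])
            return af.strain_energy(af.DeformationState.create(f, fibers, 0.0),
                                    biaxial_set, fibers)

        best = minimize_scalar(energy, bounds=(0.05, 1.2), method="bounded",
                               options={"xatol": 1e-12})
        assert c.lambda_3[i] == pytest.approx(best.x, abs=1e-6)

    def test_solver_consistency_invariants(self, fibers, uniaxial_set):
        c = af.solve_uniaxial(uniaxial_set, fibers, af.ProtocolSpec(kind="uniaxial"))
        np.testing.assert_array_less(np.abs(c.sigma_22), 1e-9)
        np.testing.assert_array_less(np.abs(c.sigma_33), 1e-9)
        np.testing.assert_array_less(
            np.abs(c.lambda_1 * c.lambda_2 * c.lambda_3 - 1.0), 1e-8)

    @pytest.mark.parametrize("which", ["uniaxial", "biaxial"])
    def test_nominal_stress_strictly_increasing(self, which, fibers,
                                                uniaxial_set, biaxial_set):
        params = uniaxial_set if which == "uniaxial" else biaxial_set
        c = af.solve_uniaxial(params, fibers, af.ProtocolSpec(kind="uniaxial"))
        assert np.all(np.diff(c.p_11) > 0.0)

    def test_continuation_continuity(self, fibers, biaxial_set):
        # no branch jumps: successive differences bounded by 10x the local
        # secant slope implied by neighbors
        c = af.solve_uniaxial(biaxial_set, fibers, af.ProtocolSpec(kind="uniaxial"))
        for arr in (c.lambda_2, c.lambda_3, c.p_11):
            d = np.abs(np.diff(arr))
            assert np.all(d[1:] <= 10.0 * d[:-1] + 1e-9)

    def test_radial_axis_is_matrix_only(self, fibers, biaxial_set):
        spec = af.ProtocolSpec(kind="uniaxial", load_axis="radial",
                               stretches=short_grid())
        c = af.solve_uniaxial(biaxial_set, fibers, spec)
        lam = c.lambda_2
        np.testing.assert_allclose(
            c.sigma_22, 2.0 * biaxial_set.c10 * (lam**2 - 1.0 / lam), atol=1e-9)

    def test_wrong_kind_rejected(self, fibers, biaxial_set):
        with pytest.raises(ConfigurationError):
            af.solve_uniaxial(biaxial_set, fibers,
                              af.ProtocolSpec(kind="equibiaxial"))


class TestPlanarBiaxial:
    def test_reference_point_is_stress_free(self, fibers, biaxial_set):
        c = af.solve_planar_biaxial(
            biaxial_set, fibers,
            af.ProtocolSpec(kind="equibiaxial", stretches=[1.0]))
        assert c.sigma_11[0] == c.sigma_33[0] == 0.0

    def test_equibiaxial_family_symmetry(self, fibers, biaxial_set):
        # mirror symmetry of the +/-30 families about x1: both families see
        # the same pseudo-invariant and the in-plane shear vanishes; the
        # two normal stresses differ (fibers lie closer to circumferential)
        f = np.diag([1.1, 1.0 / 1.21, 1.1])
        inv = af.compute_invariants(f, fibers, 0.0)
        assert inv.i4bar[0] == pytest.approx(inv.i4bar[1], rel=1e-14)
        state = af.DeformationState.create(f, fibers, 0.0)
        res = af.cauchy_stress(state, biaxial_set, fibers, pressure=0.0)
        assert abs(res.cauchy[0, 2]) < 1e-12
        assert res.cauchy[0, 0] > res.cauchy[2, 2]  # cos^2(30) > sin^2(30)

    def test_constrained_axis_stress(self, fibers, uniaxial_set):
        spec = af.ProtocolSpec(kind="planar_biaxial", stretches=[1.0, 1.05, 1.1],
                               axial_stretches=1.0)
        c = af.solve_planar_biaxial(uniaxial_set, fibers, spec)
        assert abs(c.sigma_33[-1]) > 1e-3  # constrained axis carries stress
        np.testing.assert_array_less(np.abs(c.sigma_22), 1e-12)

    def test_incompressibility_and_radial_traction(self, fibers, biaxial_set):
        c = af.solve_planar_biaxial(biaxial_set, fibers,
                                    af.ProtocolSpec(kind="equibiaxial"))
        np.testing.assert_allclose(c.lambda_1 * c.lambda_2 * c.lambda_3, 1.0,
                                   atol=1e-12)
        np.testing.assert_array_less(np.abs(c.sigma_22), 1e-12)

    def test_cross_check_against_uniaxial(self, fibers, biaxial_set):
        # imposing the uniaxial solver's solved axial stretch on the biaxial
        # solver must reproduce the uniaxial stress state
        uni = af.solve_uniaxial(biaxial_set, fibers,
                                af.ProtocolSpec(kind="uniaxial",
                                                stretches=short_grid()))
        spec = af.ProtocolSpec(kind="planar_biaxial",
                               stretches=list(uni.lambda_1),
                               axial_stretches=list(uni.lambda_3))
        bi = af.solve_planar_biaxial(biaxial_set, fibers, spec)
        np.testing.assert_allclose(bi.sigma_11, uni.sigma_11, atol=1e-6)
        np.testing.assert_allclose(bi.sigma_33, 0.0, atol=1e-6)


class TestSimpleShear:
    def test_zero_shear_is_stress_free(self, fibers, biaxial_set):
        c = af.solve_simple_shear(biaxial_set, fibers,
                                  af.ProtocolSpec(kind="simple_shear",
                                                  gammas=[0.0]))
        assert c.sigma_13[0] == 0.0

    def test_neo_hookean_shear_closed_form(self, fibers, neo_hookean):
        gammas = [0.0, 0.1, 0.2, 0.3]
        c = af.solve_simple_shear(neo_hookean, fibers,
                                  af.ProtocolSpec(kind="simple_shear",
                                                  gammas=gammas))
        np.testing.assert_allclose(c.sigma_13,
                                   2.0 * neo_hookean.c10 * np.array(gammas),
                                   atol=1e-12)

    def test_normal_stress_asymmetry_under_shear_reversal(self, fibers,
                                                          biaxial_set):
        plus = af.solve_simple_shear(
            biaxial_set, fibers,
            af.ProtocolSpec(kind="simple_shear", gammas=[0.2]))
        minus = af.solve_simple_shear(
            biaxial_set, fibers,
            af.ProtocolSpec(kind="simple_shear", gammas=[-0.2]))
        # shear stress is odd (family mirror swaps), normal pattern persists
        assert plus.sigma_13[0] == pytest.approx(-minus.sigma_13[0], rel=1e-10)
        assert plus.sigma_11[0] == pytest.approx(minus.sigma_11[0], rel=1e-10)


class TestCurveSerialization:
    @pytest.mark.parametrize("kind", ["uniaxial", "equibiaxial", "simple_shear"])
    def test_csv_round_trip_exact(self, kind, tmp_path, fibers, biaxial_set):
        spec = (af.ProtocolSpec(kind=kind, gammas=[0.0, 0.1, 0.2])
                if kind == "simple_shear"
                else af.ProtocolSpec(kind=kind, stretches=short_grid(5, 1.2)))
        curve = af.solve_protocol(biaxial_set, fibers, spec)
        path = tmp_path / "curve.csv"
        curve.to_csv(path)
        back = af.StressStretchCurve.from_csv(path)
        for attr in ("lambda_1", "lambda_2", "lambda_3", "p_11", "p_33",
                     "sigma_11", "sigma_33", "pressure"):
            np.testing.assert_array_equal(getattr(back, attr),
                                          getattr(curve, attr))
        header = path.read_text().splitlines()[0]
        for col in ("protocol", "params_label", "lambda_1", "lambda_2",
                    "lambda_3", "P_11_MPa", "P_33_MPa", "sigma_11_MPa",
                    "sigma_33_MPa"):
            assert col in header.split(",")
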