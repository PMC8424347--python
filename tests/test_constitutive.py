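"""Constitutive model: structure tensors, invariants, energy, stress and
the uniaxial boundary-value solution."""

import numpy as np
import pytest

from artmech import (
    DeformationState,
    DomainError,
    FibreArchitecture,
    MaterialParams,
    NumericRangeError,
    SolverError,
    UndefinedStatisticError,
    cauchy_stress_components,
    generalized_invariant,
    predict_curve,
    r_squared,
    solve_uniaxial,
    strain_energy,
    structure_tensor,
    uniaxial_stresses,
)
from artmech.constitutive import StressStretchCurve


def rand_arch(rng):
    return FibreArchitecture(alpha=rng.uniform(-1.2, 1.2),
                             kappa_ip=rng.uniform(0.0, 0.5),
                             kappa_op=rng.uniform(0.05, 0.5))


def rand_mat(rng):
    return MaterialParams(c=rng.uniform(1, 30), k1=rng.uniform(0, 50),
                          k2=rng.uniform(0, 15))


class TestStructureTensor:
    @pytest.mark.parametrize("kip,kop,expected", [
        (0.5, 1.0 / 3.0, np.eye(3) / 3.0),                      # 3D isotropic
        (0.5, 0.5, np.diag([0.5, 0.5, 0.0])),                   # planar isotropic
    ])
    def test_limit_cases(self, kip, kop, expected):
        arch = FibreArchitecture(0.0, kip, kop)
        np.testing.assert_allclose(structure_tensor(arch, 4), expected,
                                   atol=1e-15)

    def test_perfect_alignment(self):
        arch = FibreArchitecture(0.3, 0.0, 0.5)
        for fam, M in ((4, arch.M4), (6, arch.M6)):
            np.testing.assert_allclose(structure_tensor(arch, fam),
                                       np.outer(M, M), atol=1e-15)

    def test_trace_psd_and_normal_component_over_grid(self):
        for kip in np.linspace(0.0, 0.5, 7):
            for kop in np.linspace(0.05, 0.5, 7):
                arch = FibreArchitecture(0.4, kip, kop)
                H = structure_tensor(arch, 4)
                assert abs(np.trace(H) - 1.0) < 1e-14
                assert np.linalg.eigvalsh(H).min() > -1e-14
                Hnn = arch.Mn @ H @ arch.Mn
                assert abs(Hnn - (1.0 - 2.0 * kop)) < 1e-14

    def test_out_of_range_parameters_rejected(self):
        with pytest.raises(DomainError):
            FibreArchitecture(0.0, 0.6, 0.4)
        with pytest.raises(DomainError):
            FibreArchitecture(0.0, 0.2, 0.0)   # kappa_op must be > 0
        with pytest.raises(DomainError):
            structure_tensor(FibreArchitecture(0.0, 0.2, 0.4), family=5)


class TestGeneralizedInvariant:
    def test_undeformed_gives_unity(self):
        arch = FibreArchitecture(0.5, 0.3, 0.4)
        state = DeformationState(1.0, 1.0, 1.0)
        assert abs(generalized_invariant(state, arch, 4) - 1.0) < 1e-14

    def test_aligned_limit_is_squared_stretch(self):
        arch = FibreArchitecture(0.0, 0.0, 0.5)   # A=0, B=1
        state = DeformationState.incompressible(1.2, 1.0)
        assert abs(generalized_invariant(state, arch, 4) - 1.44) < 1e-12

    def test_matches_dense_trace_product(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            arch = rand_arch(rng)
            state = DeformationState(*rng.uniform(0.7, 1.4, 3))
            for fam in (4, 6):
                oracle = float(np.trace(state.C @ structure_tensor(arch, fam)))
                assert abs(generalized_invariant(state, arch, fam)
                           - oracle) < 1e-12


class TestStrainEnergy:
    def test_undeformed_energy_is_zero(self):
        arch = FibreArchitecture(0.4, 0.2, 0.45)
        mat = MaterialParams(5.0, 20.0, 8.0)
        assert strain_energy(DeformationState(1, 1, 1), arch, mat) == 0.0

    def test_small_k2_matches_quadratic_limit(self):
        arch = FibreArchitecture(0.4, 0.2, 0.45)
        state = DeformationState.incompressible(1.2, 0.95)
        istar = generalized_invariant(state, arch, 4)
        quad = 0.5 * 5.0 * (1.2**2 + 0.95**2 + state.l3**2 - 3.0) \
            + 2.0 * 0.5 * 20.0 * max(istar - 1.0, 0.0) ** 2
        got = strain_energy(state, arch, MaterialParams(5.0, 20.0, 1e-14))
        assert abs(got - quad) / abs(quad) < 1e-8

    def test_matches_high_precision_evaluation(self):
        import mpmath

        mpmath.mp.dps = 50
        rng = np.random.default_rng(3)
        for _ in range(10):
            arch = rand_arch(rng)
            mat = MaterialParams(c=rng.uniform(1, 30), k1=rng.uniform(1, 50),
                                 k2=rng.uniform(0.5, 15))
            l1, l2 = rng.uniform(1.0, 1.3, 2)
            state = DeformationState.incompressible(l1, l2)
            A = mpmath.mpf(2) * mpmath.mpf(arch.kappa_op) * mpmath.mpf(arch.kappa_ip)
            B = mpmath.mpf(2) * mpmath.mpf(arch.kappa_op) * (1 - 2 * mpmath.mpf(arch.kappa_ip))
            L1, L2 = mpmath.mpf(l1), mpmath.mpf(l2)
            L3 = 1 / (L1 * L2)
            I1 = L1**2 + L2**2 + L3**2
            ca, sa = mpmath.cos(mpmath.mpf(arch.alpha)), mpmath.sin(mpmath.mpf(arch.alpha))
            I4 = L1**2 * ca**2 + L2**2 * sa**2
            istar = A * I1 + B * I4 + (1 - 3 * A - B) * L3**2
            e = istar - 1 if istar > 1 else mpmath.mpf(0)
            c, k1, k2 = (mpmath.mpf(x) for x in (mat.c, mat.k1, mat.k2))
            psi = c / 2 * (I1 - 3) + 2 * k1 / (2 * k2) * (mpmath.exp(k2 * e**2) - 1)
            got = strain_energy(state, arch, mat)
            assert abs(got - float(psi)) / abs(float(psi)) < 1e-12

    def test_exponential_overflow_raises(self):
        arch = FibreArchitecture(0.0, 0.0, 0.5)
        mat = MaterialParams(1.0, 1.0, 1000.0)
        with pytest.raises(NumericRangeError):
            strain_energy(DeformationState.incompressible(2.0, 1.0), arch, mat)


class TestCauchyStress:
    def test_reference_state_is_stress_free(self):
        arch = FibreArchitecture(0.4, 0.2, 0.45)
        mat = MaterialParams(c=7.0, k1=20.0, k2=5.0)
        sig = cauchy_stress_components(DeformationState(1, 1, 1), mat.c,
                                       arch, mat)
        np.testing.assert_allclose(sig, 0.0, atol=1e-13)

    def test_neo_hookean_when_fibres_off(self):
        rng = np.random.default_rng(1)
        arch = rand_arch(rng)
        mat = MaterialParams(c=10.0, k1=0.0, k2=3.0)
        state = DeformationState(1.2, 0.9, 1.05)
        p = 4.2
        sig = cauchy_stress_components(state, p, arch, mat)
        expected = [10.0 * l**2 - p for l in (1.2, 0.9, 1.05)]
        np.testing.assert_allclose(sig, expected, rtol=1e-14)

    def test_matches_energy_derivative(self):
        # sigma_ii = 2 lambda_i^2 dPsi/d(lambda_i^2) - p by central
        # differences on the strain energy (fibre switch active branch)
        rng = np.random.default_rng(5)
        for _ in range(20):
            arch = rand_arch(rng)
            mat = MaterialParams(c=rng.uniform(1, 20), k1=rng.uniform(1, 40),
                                 k2=rng.uniform(0.1, 10))
            lams = rng.uniform(1.02, 1.25, 3)
            p = rng.uniform(-5, 5)
            sig = cauchy_stress_components(DeformationState(*lams), p, arch, mat)
            h = 1e-6
            for i in range(3):
                def psi_of(li2):
                    ls = lams.copy()
                    ls[i] = np.sqrt(li2)
                    return strain_energy(DeformationState(*ls), arch, mat)
                li2 = lams[i] ** 2
                dpsi = (psi_of(li2 + h) - psi_of(li2 - h)) / (2 * h)
                assert abs(sig[i] - (2 * li2 * dpsi - p)) < 5e-4 * max(
                    1.0, abs(sig[i]))


class TestUniaxialSolution:
    def test_neo_hookean_closed_form(self):
        arch = FibreArchitecture(0.4, 0.2, 0.45)
        mat = MaterialParams(c=10.0, k1=0.0, k2=0.0)
        sol = solve_uniaxial(1.2, "circ", arch, mat)
        expected = 10.0 * (1.2**2 - 1.0 / 1.2)
        assert abs(sol.sigma_load - expected) / expected < 1e-8
        assert abs(sol.deformation.J - 1.0) < 1e-12

    def test_reference_stretch(self):
        arch = FibreArchitecture(0.4, 0.2, 0.45)
        mat = MaterialParams(c=8.0, k1=15.0, k2=5.0)
        sol = solve_uniaxial(1.0, "axial", arch, mat)
        assert abs(sol.sigma_load) < 1e-9
        assert abs(sol.deformation.l1 - 1.0) < 1e-7
        assert abs(sol.p - mat.c) < 1e-6

    def test_45_degree_symmetry(self):
        arch = FibreArchitecture.from_degrees(45.0, 0.2, 0.45)
        mat = MaterialParams(c=5.0, k1=20.0, k2=8.0)
        sc = solve_uniaxial(1.15, "circ", arch, mat).sigma_load
        sa = solve_uniaxial(1.15, "axial", arch, mat).sigma_load
        assert abs(sc - sa) < 1e-8 * abs(sc)

    def test_swap_symmetry(self):
        # axial loading at angle a == circumferential at pi/2 - a
        mat = MaterialParams(c=5.0, k1=20.0, k2=8.0)
        for deg in (20.0, 35.0, 60.0):
            a1 = FibreArchitecture.from_degrees(deg, 0.25, 0.45)
            a2 = FibreArchitecture.from_degrees(90.0 - deg, 0.25, 0.45)
            s1 = solve_uniaxial(1.15, "axial", a1, mat).sigma_load
            s2 = solve_uniaxial(1.15, "circ", a2, mat).sigma_load
            assert abs(s1 - s2) < 1e-8 * abs(s1)

    def test_dispersion_monotonicity(self):
        mat = MaterialParams(c=5.0, k1=20.0, k2=8.0)
        prev = np.inf
        for kip in np.linspace(0.0, 0.5, 6):
            arch = FibreArchitecture(0.0, kip, 0.45)
            s = solve_uniaxial(1.15, "circ", arch, mat).sigma_load
            assert s <= prev + 1e-9
            prev = s

    def test_k2_zero_continuity(self):
        arch = FibreArchitecture(0.4, 0.2, 0.45)
        grid = np.linspace(1.0, 1.2, 8)
        s0 = uniaxial_stresses(grid, "circ", arch, MaterialParams(5, 20, 0.0))
        s1 = uniaxial_stresses(grid, "circ", arch, MaterialParams(5, 20, 1e-10))
        assert np.abs(s0 - s1).max() < 1e-6

    def test_invalid_inputs(self):
        arch = FibreArchitecture(0.4, 0.2, 0.45)
        mat = MaterialParams(5, 20, 8)
        with pytest.raises(DomainError):
            solve_uniaxial(0.9, "circ", arch, mat)
        with pytest.raises(DomainError):
            solve_uniaxial(1.1, "sideways", arch, mat)


class TestEnergyStressConsistency:
    def test_along_equilibrium_path(self):
        # sigma(lambda) = lambda dW/dlambda with W evaluated at the
        # equilibrium transverse stretches (central differences)
        rng = np.random.default_rng(11)
        checked = 0
        for _ in range(100):
            arch = rand_arch(rng)
            mat = rand_mat(rng)
            lam = rng.uniform(1.05, 1.25)
            direction = "circ" if rng.random() < 0.5 else "axial"
            h = 1e-5

            def w_hat(l):
                sol = solve_uniaxial(l, direction, arch, mat)
                return strain_energy(sol.deformation, arch, mat)

            sigma = solve_uniaxial(lam, direction, arch, mat).sigma_load
            dw = (w_hat(lam + h) - w_hat(lam - h)) / (2 * h)
            if abs(sigma) > 1e-6:
                assert abs(lam * dw - sigma) / abs(sigma) < 1e-4
                checked += 1
        assert checked >= 90


class TestPredictCurve:
    def test_single_point_reference(self):
        arch = FibreArchitecture(0.4, 0.2, 0.45)
        c = predict_curve([1.0], "circ", arch, MaterialParams(5, 20, 8))
        assert abs(c.stress[0]) < 1e-9

    def test_linearity_in_c_for_neo_hookean(self):
        arch = FibreArchitecture(0.4, 0.2, 0.45)
        grid = np.linspace(1.0, 1.3, 7)
        s1 = predict_curve(grid, "axial", arch, MaterialParams(4, 0, 0)).stress
        s2 = predict_curve(grid, "axial", arch, MaterialParams(8, 0, 0)).stress
        np.testing.assert_allclose(s2, 2 * s1, rtol=1e-9, atol=1e-12)

    def test_grid_validation(self):
        arch = FibreArchitecture(0.4, 0.2, 0.45)
        mat = MaterialParams(5, 20, 8)
        with pytest.raises(DomainError):
            predict_curve([0.9, 1.1], "circ", arch, mat)
        with pytest.raises(DomainError):
            predict_curve([1.1, 1.05], "circ", arch, mat)


class TestRSquared:
    def _curve(self, stress):
        return StressStretchCurve("circ", 1.0 + 0.1 * np.arange(len(stress)),
                                  np.asarray(stress, float))

    def test_perfect_and_mean_predictions(self):
        obs = self._curve([1.0, 2.0, 3.0])
        assert r_squared(obs, self._curve([1.0, 2.0, 3.0])).r2 == 1.0
        assert abs(r_squared(obs, self._curve([2.0, 2.0, 2.0])).r2) < 1e-14

    def test_arithmetic_example(self):
        gof = r_squared(self._curve([1.0, 2.0, 3.0]),
                        self._curve([1.0, 2.0, 4.0]))
        assert gof.s_res == 1.0
        assert gof.s_tot == 2.0
        assert abs(gof.r2 - 0.5) < 1e-15

    def test_pooling_across_directions(self):
        a = StressStretchCurve("circ", [1.0, 1.1], [0.0, 2.0])
        b = StressStretchCurve("axial", [1.0, 1.1], [0.0, 6.0])
        ma = StressStretchCurve("circ", [1.0, 1.1], [0.0, 1.0])
        mb = StressStretchCurve("axial", [1.0, 1.1], [0.0, 6.0])
        gof = r_squared([a, b], [ma, mb])
        obs = np.array([0, 2, 0, 6.0])
        s_tot = np.sum((obs - obs.mean()) ** 2)
        assert abs(gof.r2 - (1 - 1.0 / s_tot)) < 1e-14
        assert gof.n_points == 4

    def test_constant_signal_rejected(self):
        obs = self._curve([2.0, 2.0, 2.0])
        with pytest.raises(UndefinedStatisticError):
            r_squared(obs, self._curve([1.0, 2.0, 3.0]))
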