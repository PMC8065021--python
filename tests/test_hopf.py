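"""Hurwitz machinery and Hopf-bifurcation location."""

import math

import numpy as np
import pytest

from oscillab import (
    CoupledIdentical,
    CoupledNonidentical,
    HillRepression,
    SynchronousReduced,
    char_coefficients,
    coupled_identical_hb,
    gamma_peak_gap,
    general_hb_locator,
    hurwitz_determinants,
    identical_alpha_star,
    identical_omega_star,
    single_cell_hb,
    trace_hb_curve,
)
from oscillab.hopf import delta_plus_minus_coeffs, identical_gamma_bound
from oscillab.exceptions import (
    DegenerateCandidateError,
    HopfNotFoundError,
    InfeasibleError,
)


class TestCharPoly:
    def test_single_cell_coefficients(self, ht):
        from oscillab import SingleCell

        m = SingleCell(repression=ht, alpha=0.6)
        eq = m.solve_equilibrium()
        b = char_coefficients(m.jacobian(eq.state)).coeffs
        gamma = ht.gamma(eq.state[2])
        assert b == pytest.approx([3.0, 3.0, 0.6 * gamma + 1.0], rel=1e-12)

    def test_negative_identity(self):
        b = char_coefficients(-np.eye(3)).coeffs
        assert b == pytest.approx([3.0, 3.0, 1.0], abs=1e-13)

    def test_matches_eigenvalue_product_oracle(self, rng):
        for _ in range(20):
            J = rng.normal(size=(8, 8))
            b = char_coefficients(J).coeffs
            oracle = np.poly(np.linalg.eigvals(J))[1:].real
            assert np.allclose(b, oracle, rtol=1e-9, atol=1e-9 * np.abs(oracle).max())


class TestHurwitz:
    def test_cubic_determinant_vanishes_at_hopf(self):
        # (3, 3, b3): D2 = 9 - b3, zero exactly when alpha*gamma = 8
        rep = hurwitz_determinants([3.0, 3.0, 9.0])
        assert rep.determinants[1] == pytest.approx(0.0, abs=1e-12)
        assert rep.classification == "hopf_candidate"

    def test_d2_formula_for_feedback_cubic(self, rng):
        for _ in range(20):
            ag = rng.uniform(0.1, 20.0)
            rep = hurwitz_determinants([3.0, 3.0, ag + 1.0])
            assert rep.determinants[1] == pytest.approx(8.0 - ag, rel=1e-12)

    def test_dm_equals_bm_times_dm_minus_1(self, rng):
        for _ in range(30):
            b = rng.uniform(-2, 4, size=rng.integers(3, 9))
            rep = hurwitz_determinants(b)
            D = rep.determinants
            assert D[-1] == pytest.approx(b[-1] * D[-2], rel=1e-9, abs=1e-9 * (1 + abs(D[-2])))

    def test_classification_against_root_oracle(self, rng):
        # 500 random polynomials of degree 4..8 with known roots
        agree = 0
        for _ in range(500):
            m = int(rng.integers(4, 9))
            n_pairs = int(rng.integers(0, m // 2 + 1))
            roots = []
            for _ in range(n_pairs):
                re = rng.uniform(-2.0, 1.0)
                im = rng.uniform(0.1, 3.0)
                roots += [re + 1j * im, re - 1j * im]
            roots += list(rng.uniform(-3.0, 1.0, size=m - 2 * n_pairs))
            roots = np.array(roots)
            b = np.poly(roots)[1:].real
            rep = hurwitz_determinants(b)
            stable = bool(np.all(roots.real < -1e-9))
            assert (rep.classification == "stable") == stable
            agree += 1
        assert agree == 500


class TestSingleCellHB:
    def test_hill_closed_form(self, ht):
        hp = single_cell_hb(ht)
        assert hp.diagnostics["x_bar"] == pytest.approx(0.148684, abs=1e-5)
        assert hp.diagnostics["gamma"] == pytest.approx(14.674227, abs=1e-5)
        assert hp.parameters["alpha"] == pytest.approx(0.545174, abs=1e-5)
        assert hp.omega_star == pytest.approx(math.sqrt(3), abs=1e-14)
        assert hp.crossing_derivative != 0

    def test_sequestration_closed_form(self, ps):
        hp = single_cell_hb(ps)
        assert hp.diagnostics["x_bar"] == pytest.approx(0.058730, abs=1e-5)
        assert hp.parameters["alpha"] == pytest.approx(0.533809, abs=1e-5)

    def test_low_hill_coefficient_infeasible(self):
        with pytest.raises(InfeasibleError):
            single_cell_hb(HillRepression(n=8, k_H=0.136))

    def test_weak_sequestration_infeasible(self):
        from oscillab import SequestrationRepression

        with pytest.raises(InfeasibleError):
            single_cell_hb(SequestrationRepression(A=1e-3, k_d=1e-5))

    def test_hopf_point_spectrum(self, ht):
        from oscillab import SingleCell

        hp = single_cell_hb(ht)
        m = SingleCell(repression=ht, alpha=hp.parameters["alpha"])
        lam = np.linalg.eigvals(m.jacobian(hp.equilibrium.state))
        near = lam[np.abs(lam.real) <= 1e-7]
        rest = lam[np.abs(lam.real) > 1e-7]
        assert len(near) == 2 and np.all(rest.real < -1e-7)
        assert abs(np.max(near.imag) - hp.omega_star) <= 1e-6


class TestCoupledIdenticalHB:
    def test_hill_example(self, ht):
        hp = coupled_identical_hb(ht, c=0.05, s=20.0)
        assert hp.parameters["alpha"] == pytest.approx(0.4742, abs=1e-4)
        assert hp.omega_star == pytest.approx(1.721229, abs=1e-6)
        assert hp.diagnostics["gamma"] == pytest.approx(15.05911, abs=1e-4)

    def test_sequestration_example(self, ps):
        hp = coupled_identical_hb(ps, c=0.05, s=20.0)
        assert hp.parameters["alpha"] == pytest.approx(0.4766, abs=1e-4)
        assert hp.omega_star == pytest.approx(1.721278, abs=1e-6)

    def test_reduces_to_single_cell_as_coupling_vanishes(self, ht):
        hp0 = single_cell_hb(ht)
        hp = coupled_identical_hb(ht, c=1e-8, s=20.0)
        assert abs(hp.omega_star - math.sqrt(3)) <= 1e-6
        assert abs(hp.parameters["alpha"] - hp0.parameters["alpha"]) <= 1e-6

    def test_timescale_at_most_one_unsupported(self, ht):
        with pytest.raises(InfeasibleError):
            coupled_identical_hb(ht, c=0.05, s=1.0)

    def test_factorization_of_characteristic_polynomial(self, ht, rng):
        # det(lambda I - J) = Delta_plus * Delta_minus for identical cells
        for _ in range(10):
            alpha = float(rng.uniform(0.2, 1.0))
            c = float(rng.uniform(0.01, 0.2))
            s = float(rng.uniform(2.0, 30.0))
            m = CoupledIdentical(repression=ht, alpha=alpha, c=c, s=s)
            eq = m.solve_equilibrium()
            gamma = ht.gamma(eq.state[2])
            full = char_coefficients(m.jacobian(eq.state)).coeffs
            bp, bm = delta_plus_minus_coeffs(alpha, gamma, c, s)
            prod = np.polymul(np.concatenate([[1.0], bp]), np.concatenate([[1.0], bm]))[1:]
            assert np.allclose(full, prod, rtol=1e-9, atol=1e-9 * np.abs(prod).max())

    def test_asynchronous_factor_never_bifurcates_first(self, rng):
        # whenever D3 of Delta_minus vanishes, D3 of Delta_plus is negative
        for _ in range(200):
            gamma = rng.uniform(0.5, 30.0)
            c = rng.uniform(0.005, 0.3)
            s = rng.uniform(1.5, 40.0)
            b1 = s + 3
            b2 = 3 * (s + 1)

            def d3(ag, extra):
                # D3 of a quartic factor: b3 = ag + 3s + 1, b4 = s(ag+1) + extra
                b3 = ag + 3 * s + 1
                b4 = s * (ag + 1) + extra
                return b1 * b2 * b3 - b3**2 - b1**2 * b4

            # alpha*gamma values where D3 of Delta_minus vanishes (quadratic)
            a1 = b1 * b2 - 2 * (3 * s + 1) - b1**2 * s
            a0 = b1 * b2 * (3 * s + 1) - (3 * s + 1) ** 2 - b1**2 * s
            roots = np.roots([-1.0, a1, a0])
            for ag in roots[np.isreal(roots)].real:
                if ag <= 0:
                    continue
                assert d3(ag, c * s * gamma) < 0

    def test_synchronous_reduction_carries_delta_plus(self, ht):
        # the 4-D restricted system's characteristic polynomial is Delta_plus
        m = SynchronousReduced(repression=ht, alpha=0.48, c=0.05, s=20.0)
        eq = m.solve_equilibrium()
        b = char_coefficients(m.jacobian(eq.state)).coeffs
        gamma = ht.gamma(eq.state[2])
        bp, _ = delta_plus_minus_coeffs(0.48, gamma, 0.05, 20.0)
        assert np.allclose(b, bp, rtol=1e-12)

    def test_collective_frequency_decreases_in_gamma_and_coupling(self):
        s = 20.0
        oms = [identical_omega_star(g, 0.05, s) for g in np.linspace(1, 25, 10)]
        assert all(a > b for a, b in zip(oms, oms[1:]))
        oms_c = [identical_omega_star(15.0, c, s) for c in np.linspace(0.005, 0.2, 10)]
        assert all(a > b for a, b in zip(oms_c, oms_c[1:]))

    def test_gamma_bound_required_for_positive_hb_value(self):
        c, s = 0.05, 20.0
        bound = identical_gamma_bound(c, s)
        assert identical_alpha_star(bound * 0.99, c, s) > 0
        assert identical_alpha_star(bound * 1.01, c, s) < 0


class TestGeneralLocator:
    def test_nonidentical_hill_example(self, ht):
        fac = lambda a: CoupledNonidentical(repression=ht, alpha=a, c=0.05, s=20.0, sigma=1.05)
        hp = general_hb_locator(fac, (0.45, 0.58))
        assert hp.parameters["alpha"] == pytest.approx(0.5165, abs=1e-4)
        assert hp.omega_star == pytest.approx(1.801918, abs=1e-6)
        # published spectrum at the HB value
        lam = np.sort(hp.diagnostics["eigenvalues"].real)
        assert lam[0] == pytest.approx(-20.0, abs=1e-4)
        assert lam[1] == pytest.approx(-19.997793, abs=1e-4)

    def test_nonidentical_sequestration_example(self, ps):
        fac = lambda a: CoupledNonidentical(repression=ps, alpha=a, c=0.038, s=20.0, sigma=1.05)
        hp = general_hb_locator(fac, (0.45, 0.58))
        assert hp.parameters["alpha"] == pytest.approx(0.5043, abs=1e-4)
        assert hp.omega_star == pytest.approx(1.806613, abs=1e-6)

    def test_agrees_with_closed_form_at_unit_sigma(self, ht):
        fac = lambda a: CoupledNonidentical(repression=ht, alpha=a, c=0.05, s=20.0, sigma=1.0)
        hp = general_hb_locator(fac, (0.40, 0.55))
        ref = coupled_identical_hb(ht, c=0.05, s=20.0)
        assert abs(hp.parameters["alpha"] - ref.parameters["alpha"]) <= 1e-6
        assert abs(hp.omega_star - ref.omega_star) <= 1e-6

    def test_no_sign_change_reported(self, ht):
        fac = lambda a: CoupledNonidentical(repression=ht, alpha=a, c=0.05, s=20.0, sigma=1.05)
        with pytest.raises(HopfNotFoundError):
            general_hb_locator(fac, (0.63, 0.72), n_scan=10)

    def test_degenerate_candidate_rejected_not_silently_accepted(self, ht):
        # the second zero of D7 (where another pair is already unstable)
        # must be reported, not returned as a Hopf point
        fac = lambda a: CoupledNonidentical(repression=ht, alpha=a, c=0.05, s=20.0, sigma=1.05)
        with pytest.raises(DegenerateCandidateError):
            general_hb_locator(fac, (0.58, 0.62), n_scan=10)

    def test_eigenvalue_certificate_at_every_hopf_point(self, ht, ps):
        points = [
            single_cell_hb(ht),
            single_cell_hb(ps),
            coupled_identical_hb(ht, c=0.05, s=20.0),
            coupled_identical_hb(ps, c=0.05, s=20.0),
        ]
        for hp, rep in zip(points, [ht, ps, ht, ps]):
            eig = hp.diagnostics.get("eigenvalues")
            if eig is None:
                continue
            near = eig[np.abs(eig.real) <= 1e-7]
            rest = eig[np.abs(eig.real) > 1e-7]
            assert len(near) == 2 and np.all(rest.real < -1e-7)


class TestSegmentationClock:
    def test_locator_finds_simple_hopf_in_transcription_rate(self):
        # synthetic parameter set (see conftest): the pair of clock cells
        # loses stability through a simple Hopf as nu1 grows
        from oscillab import SegmentationClockPair
        from tests.conftest import SEGCLOCK_SYNTHETIC

        fac = lambda nu1: SegmentationClockPair(**{**SEGCLOCK_SYNTHETIC, "nu1": nu1})
        hp = general_hb_locator(fac, (0.15, 0.26), n_scan=60, seed_state=np.full(8, 0.3))
        assert 0.15 < hp.parameters["alpha"] < 0.26
        assert hp.omega_star > 0
        assert hp.crossing_derivative != 0
        eig = hp.diagnostics["eigenvalues"]
        near = eig[np.abs(eig.real) <= 1e-7]
        rest = eig[np.abs(eig.real) > 1e-7]
        assert len(near) == 2 and np.all(rest.real < 0)
        assert hp.hurwitz.b_m_positive and hp.hurwitz.inner_determinants_positive


class TestHBCurve:
    def test_identical_curve_properties(self, ht):
        alpha0 = single_cell_hb(ht).parameters["alpha"]
        cs = np.linspace(0.01, 0.1, 10)  # includes c = 0.05
        pts = trace_hb_curve(
            lambda c, a: CoupledIdentical(repression=ht, alpha=a, c=c, s=20.0),
            cs,
            alpha_seed=alpha0,
        )
        assert all(p is not None for p in pts)
        alphas = [p.parameters["alpha"] for p in pts]
        # passes through the published point
        i = int(np.argmin(np.abs(cs - 0.05)))
        assert alphas[i] == pytest.approx(0.4742, abs=5e-4)
        # coupled HB value below the single-cell one; for fast signal
        # kinetics the curve is nearly the straight line alpha + c = alpha0
        for c, a in zip(cs, alphas):
            assert a < alpha0
            assert a + c == pytest.approx(alpha0, rel=0.10)
        # the approximation alpha* + c = alpha0 tightens as c -> 0
        assert alphas[0] + cs[0] == pytest.approx(alpha0, rel=0.01)
        fit = np.polyfit(cs, alphas, 1)
        assert np.max(np.abs(np.polyval(fit, cs) - alphas)) < 1e-3
        assert fit[0] == pytest.approx(-1.0, rel=0.5)

    def test_gamma_peak_gap_values(self, ht):
        x_m, gap = gamma_peak_gap(ht)
        assert x_m == pytest.approx(0.133764, abs=1e-5)
        assert gap > 0  # for n < 17 the HB equilibrium sits right of the peak
        x_m17, gap17 = gamma_peak_gap(HillRepression(n=17, k_H=0.136))
        assert gap17 == pytest.approx(0.0, abs=1e-15)
        with pytest.raises(InfeasibleError):
            gamma_peak_gap(HillRepression(n=8, k_H=0.1))
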