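"""Hurwitz-determinant machinery and Hopf-bifurcation location.

A simple Hopf bifurcation of an m-dimensional system is characterized by a
degenerate Routh–Hurwitz condition on the characteristic polynomial
``lambda^m + b1 lambda^{m-1} + ... + bm``: the equilibrium has exactly one
purely imaginary eigenvalue pair (all other eigenvalues in the open left
half-plane) iff ``bm > 0``, ``D_i > 0`` for ``i = 1..m-2`` and
``D_{m-1} = 0``, where ``D_i`` are the leading Hurwitz determinants. The
bifurcation value is found as a zero of ``D_{m-1}`` along the bifurcation
parameter, with a nonzero crossing derivative.

For the gene-circuit systems closed forms exist: the single cell bifurcates
at ``alpha_0 = 8/gamma`` with frequency ``sqrt(3)``, and the identical-cell
network at an ``alpha*`` solving a quadratic in ``gamma`` with collective
frequency ``omega_c* = sqrt([sqrt((s^2+3)^2 - 4 s c gamma) - (s^2-3)]/2)``.
The general locator needs only a model factory and a bracket.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import optimize

from .exceptions import (
    ConvergenceError,
    DegenerateCandidateError,
    HopfNotFoundError,
    InfeasibleError,
    ValidationError,
)
from .models import (
    CoupledIdentical,
    Equilibrium,
    ModelSystem,
    SingleCell,
)
from .repression import HillRepression, Repression, SequestrationRepression

logger = logging.getLogger(__name__)

__all__ = [
    "CharPoly",
    "HurwitzReport",
    "HopfPoint",
    "char_coefficients",
    "hurwitz_matrix",
    "hurwitz_determinants",
    "single_cell_hb",
    "coupled_identical_hb",
    "identical_alpha_star",
    "identical_omega_star",
    "general_hb_locator",
    "trace_hb_curve",
    "gamma_peak_gap",
]

PS_FEASIBILITY_FACTOR = 127 + 48 * math.sqrt(7)

_EIG_IMAG_TOL = 1e-7


@dataclass(frozen=True)
class CharPoly:
    """Monic characteristic polynomial, coefficients ``b1..bm``."""

    coeffs: np.ndarray

    @property
    def degree(self) -> int:
        return len(self.coeffs)

    def roots(self) -> np.ndarray:
        return np.roots(np.concatenate([[1.0], self.coeffs]))


@dataclass(frozen=True)
class HurwitzReport:
    determinants: np.ndarray  # D_1 .. D_m
    b_m_positive: bool
    inner_determinants_positive: bool  # D_i > 0, i = 1..m-2
    d_m_minus_1_zero: bool
    classification: str  # stable | hopf_candidate | unstable


@dataclass(frozen=True)
class HopfPoint:
    """A located simple Hopf bifurcation."""

    parameters: dict
    equilibrium: Equilibrium
    omega_star: float
    crossing_derivative: float
    hurwitz: HurwitzReport | None = None
    diagnostics: dict = field(default_factory=dict)


def char_coefficients(J: np.ndarray) -> CharPoly:
    """Characteristic coefficients by the Faddeev–LeVerrier recursion.

    Polynomial in the matrix entries (no eigendecomposition), so the Hurwitz
    determinants inherit the smoothness of the Jacobian in the parameters.
    """
    J = np.asarray(J, dtype=float)
    if J.ndim != 2 or J.shape[0] != J.shape[1]:
        raise ValidationError(f"expected a square matrix, got shape {J.shape}")
    m = J.shape[0]
    coeffs = np.empty(m)
    M = np.zeros_like(J)
    ident = np.eye(m)
    c = 1.0
    for k in range(1, m + 1):
        M = J @ M + c * ident
        c = -(J * M.T).sum() / k  # -trace(J M)/k
        coeffs[k - 1] = c
    return CharPoly(coeffs=coeffs)


def hurwitz_matrix(coeffs: Sequence[float], i: int) -> np.ndarray:
    """The i-th Hurwitz matrix H_i; entry (r, k) is b_{2(k+1)-(r+1)} with
    b_0 = 1 and b_j = 0 outside 0..m."""
    b = np.asarray(coeffs, dtype=float)
    m = len(b)
    H = np.zeros((i, i))
    for r in range(i):
        for k in range(i):
            idx = 2 * (k + 1) - (r + 1)
            if idx == 0:
                H[r, k] = 1.0
            elif 1 <= idx <= m:
                H[r, k] = b[idx - 1]
    return H


def hurwitz_determinants(poly: CharPoly | Sequence[float], zero_rtol: float = 1e-9) -> HurwitzReport:
    """All leading Hurwitz determinants plus the degenerate classification."""
    b = poly.coeffs if isinstance(poly, CharPoly) else np.asarray(poly, dtype=float)
    m = len(b)
    if m < 2:
        raise ValidationError("need polynomial degree >= 2")
    D = np.array([np.linalg.det(hurwitz_matrix(b, i)) for i in range(1, m + 1)])
    b_m_pos = b[-1] > 0
    inner_pos = bool(np.all(D[: m - 2] > 0))
    scale = 1.0 + (abs(D[m - 3]) if m >= 3 else 1.0)
    d_prev_zero = abs(D[m - 2]) <= zero_rtol * scale
    if b_m_pos and np.all(D > 0):
        cls = "stable"
    elif b_m_pos and inner_pos and d_prev_zero:
        cls = "hopf_candidate"
    else:
        cls = "unstable"
    return HurwitzReport(
        determinants=D,
        b_m_positive=bool(b_m_pos),
        inner_determinants_positive=inner_pos,
        d_m_minus_1_zero=bool(d_prev_zero),
        classification=cls,
    )


def _imaginary_pair(J: np.ndarray, re_tol: float = _EIG_IMAG_TOL):
    """Return (omega, eigenvalues) if J has exactly one conjugate pair with
    |Re| <= re_tol and every other eigenvalue has Re < -re_tol."""
    eig = np.linalg.eigvals(J)
    near = eig[np.abs(eig.real) <= re_tol]
    rest = eig[np.abs(eig.real) > re_tol]
    if len(near) != 2 or not np.all(rest.real < -re_tol):
        return None, eig
    omega = float(np.max(np.abs(near.imag)))
    if omega <= 0:
        return None, eig
    return omega, eig


# ---------------------------------------------------------------------------
# Single cell
# ---------------------------------------------------------------------------
def single_cell_hb(spec: Repression, sigma: float = 1.0) -> HopfPoint:
    """Closed-form Hopf point of the three-variable single cell.

    Hill repression requires n > 8 (necessary and sufficient); sequestration
    requires A > (127 + 48 sqrt 7) k_d. The HB value is ``alpha_0 = 8/gamma``
    and the frequency is ``sqrt(3)`` (times the rate factor ``sigma``)
    regardless of the repression function.
    """
    if isinstance(spec, HillRepression):
        if spec.n <= 8:
            raise InfeasibleError(
                f"Hill coefficient n={spec.n}: the equilibrium is stable for n <= 8; "
                "a simple Hopf bifurcation requires n > 8"
            )
        xbar = spec.k_H * (8.0 / (spec.n - 8)) ** (1.0 / spec.n)
    elif isinstance(spec, SequestrationRepression):
        A, kd = spec.A, spec.k_d
        if A <= PS_FEASIBILITY_FACTOR * kd:
            raise InfeasibleError(
                f"A={A} too small: need A > (127+48*sqrt(7)) k_d = {PS_FEASIBILITY_FACTOR * kd:.6g}"
            )
        xbar = (64.0 / 63.0) * (A - kd) - (8.0 / 63.0) * math.sqrt(
            (A - kd) ** 2 - 252 * A * kd
        )
    else:
        raise ValidationError(f"unsupported repression spec {type(spec).__name__}")

    gamma = spec.gamma(xbar)
    alpha0 = 8.0 / gamma
    # self-consistency: alpha0 f(xbar) = xbar
    defect = abs(alpha0 * spec.value(xbar) - xbar)
    if defect > 1e-10 * (1 + xbar):
        raise ConvergenceError(
            f"closed-form equilibrium inconsistent: |alpha0 f(x)-x| = {defect:.3e}"
        )

    model = SingleCell(repression=spec, alpha=alpha0, sigma=sigma)
    equilibrium = model.solve_equilibrium()
    poly = char_coefficients(model.jacobian(equilibrium.state))
    report = hurwitz_determinants(poly)
    crossing = _crossing_derivative(
        lambda a: _d_prev_single(spec, a, sigma), alpha0
    )
    return HopfPoint(
        parameters={"alpha": alpha0, "sigma": sigma},
        equilibrium=equilibrium,
        omega_star=math.sqrt(3.0) * sigma,
        crossing_derivative=crossing,
        hurwitz=report,
        diagnostics={"x_bar": xbar, "gamma": gamma},
    )


def _d_prev_single(spec: Repression, alpha: float, sigma: float) -> float:
    model = SingleCell(repression=spec, alpha=alpha, sigma=sigma)
    eq = model.solve_equilibrium()
    b = char_coefficients(model.jacobian(eq.state)).coeffs
    return b[0] * b[1] - b[2]  # D_2 for the cubic


def _crossing_derivative(fn: Callable[[float], float], x0: float) -> float:
    h = 1e-6 * max(1.0, abs(x0))
    d = (fn(x0 + h) - fn(x0 - h)) / (2 * h)
    if d == 0.0:
        raise DegenerateCandidateError("crossing derivative vanishes at the HB value")
    return d


# ---------------------------------------------------------------------------
# Identical cells: closed form
# ---------------------------------------------------------------------------
def identical_alpha_star(gamma: float, c: float, s: float) -> float:
    """HB value of the identical-cell network ('+' branch; requires s > 1)."""
    if s <= 1:
        raise InfeasibleError("only s > 1 is supported (the '+' branch of the HB value)")
    disc = (s * s + 3) ** 2 - 4 * s * c * gamma
    if disc <= 0:
        raise InfeasibleError(
            f"gamma={gamma:.6g} exceeds (s^2+3)^2/(4sc): no real HB value"
        )
    return (-(s - 1) * (s * s + 4 * s + 7) + (s + 3) * math.sqrt(disc)) / (2 * gamma)


def identical_omega_star(gamma: float, c: float, s: float) -> float:
    """Collective frequency at the identical-cell HB value."""
    disc = (s * s + 3) ** 2 - 4 * s * c * gamma
    if disc <= 0:
        raise InfeasibleError("no real collective frequency: discriminant nonpositive")
    val = 0.5 * (math.sqrt(disc) - (s * s - 3))
    if val <= 0:
        raise InfeasibleError("collective frequency formula nonpositive")
    return math.sqrt(val)


def identical_gamma_bound(c: float, s: float) -> float:
    """Positivity bound: the HB value is positive iff gamma is below this."""
    return 8 * (s + 1) ** 3 / (c * s * (s + 3) ** 2)


def delta_plus_minus_coeffs(alpha: float, gamma: float, c: float, s: float):
    """Quartic factors of the identical-cell characteristic polynomial.

    Returns (coeffs of Delta_plus, coeffs of Delta_minus); the synchronous
    factor Delta_plus carries the bifurcation.
    """
    b1 = s + 3.0
    b2 = 3.0 * (s + 1.0)
    b3 = alpha * gamma + 3.0 * s + 1.0
    b4m = s * (alpha * gamma + 1.0)
    b4p = b4m + c * s * gamma
    return np.array([b1, b2, b3, b4p]), np.array([b1, b2, b3, b4m])


def coupled_identical_hb(
    spec: Repression, c: float, s: float, n_cells: int = 2
) -> HopfPoint:
    """Closed-form HB point of the identical-cell network at coupling c.

    Solves the self-consistent pair {alpha* = formula(gamma(x)),
    (alpha* + c) f(x) = x} by bracketed root finding in the equilibrium
    component x. When the sequestration model admits two consistent roots the
    smaller is taken (it gives the smaller HB value).
    """
    if c <= 0:
        raise ValidationError("coupling strength c must be positive")
    if s <= 1:
        raise InfeasibleError("only s > 1 is supported")

    def self_consistency(x: float) -> float:
        return (identical_alpha_star(spec.gamma(x), c, s) + c) * spec.value(x) - x

    # scan for sign changes; the residual is smooth where alpha* is defined
    grid = np.geomspace(1e-8, 10.0, 4000)
    roots: list[float] = []
    prev_x = prev_v = None
    for x in grid:
        try:
            v = self_consistency(x)
        except InfeasibleError:
            prev_x = prev_v = None
            continue
        if prev_v is not None and np.sign(v) != np.sign(prev_v):
            roots.append(optimize.brentq(self_consistency, prev_x, x, xtol=1e-14))
        prev_x, prev_v = x, v
    if not roots:
        raise ConvergenceError("no self-consistent equilibrium for the HB formula")

    candidates = []
    for x in sorted(roots):
        gamma = spec.gamma(x)
        if gamma >= identical_gamma_bound(c, s):
            continue  # HB value would not be positive
        alpha = identical_alpha_star(gamma, c, s)
        if alpha > 0:
            candidates.append((x, gamma, alpha))
    if not candidates:
        raise InfeasibleError(
            "self-consistent roots exist but violate the positivity bound on gamma"
        )
    xbar, gamma, alpha_star = candidates[0]  # smallest x -> smallest alpha*
    omega = identical_omega_star(gamma, c, s)

    model = CoupledIdentical(repression=spec, alpha=alpha_star, c=c, s=s, n_cells=n_cells)
    equilibrium = model.solve_equilibrium()
    J = model.jacobian(equilibrium.state)
    eig = np.linalg.eigvals(J)
    # cross-check the closed-form frequency against the full spectrum; as
    # c -> 0 the asynchronous pair becomes imaginary too (double pair at the
    # decoupled limit), so only the nearest pair is compared
    nearest = eig[np.argmin(np.abs(eig - 1j * omega))]
    if abs(nearest - 1j * omega) > 1e-6 * (1 + omega):
        raise ConvergenceError(
            f"closed-form frequency {omega:.8f} disagrees with spectrum "
            f"{nearest.imag:.8f} (Re {nearest.real:.2e})"
        )
    others = eig[np.abs(eig - 1j * omega) > 1e-6 * (1 + omega)]
    others = others[np.abs(others + 1j * omega) > 1e-6 * (1 + omega)]
    if np.any(others.real > 1e-7):
        raise DegenerateCandidateError(
            "additional eigenvalues in the right half-plane at the HB value"
        )

    crossing = _crossing_derivative(lambda a: _d3_plus(spec, a, c, s), alpha_star)
    report = hurwitz_determinants(
        CharPoly(coeffs=delta_plus_minus_coeffs(alpha_star, gamma, c, s)[0])
    )
    return HopfPoint(
        parameters={"alpha": alpha_star, "c": c, "s": s},
        equilibrium=equilibrium,
        omega_star=omega,
        crossing_derivative=crossing,
        hurwitz=report,
        diagnostics={"x_bar": xbar, "gamma": gamma, "eigenvalues": eig},
    )


def _d3_plus(spec: Repression, alpha: float, c: float, s: float) -> float:
    """D_3 of the synchronous quartic factor, with the equilibrium re-solved."""
    total = alpha + c
    x = optimize.brentq(
        lambda t: total * spec.value(t) - t, 1e-14, total * (1 + 1e-9) + 1e-12, xtol=1e-13
    )
    b, _ = delta_plus_minus_coeffs(alpha, spec.gamma(x), c, s)
    b1, b2, b3, b4 = b
    return b1 * b2 * b3 - b3**2 - b1**2 * b4


# ---------------------------------------------------------------------------
# General numeric locator
# ---------------------------------------------------------------------------
def general_hb_locator(
    model_factory: Callable[[float], ModelSystem],
    bracket: tuple[float, float],
    n_scan: int = 40,
    seed_state: np.ndarray | None = None,
) -> HopfPoint:
    """Locate a simple Hopf bifurcation as a zero of ``D_{m-1}(alpha)``.

    ``model_factory(alpha)`` builds the system at each trial parameter value;
    the equilibrium is re-solved at every evaluation (warm-started along the
    scan). Every sign change of ``D_{m-1}`` in the bracket is refined; a root
    is returned only if the remaining degenerate Routh–Hurwitz conditions
    hold and the spectrum shows exactly one near-imaginary pair, otherwise a
    degenerate-candidate error is raised.
    """
    lo, hi = bracket
    if not lo < hi:
        raise ValidationError("bracket must satisfy lo < hi")

    cache: dict[float, np.ndarray] = {}
    warm = {"state": seed_state}

    def d_prev(alpha: float) -> float:
        model = model_factory(alpha)
        eq = model.solve_equilibrium(seed=warm["state"])
        warm["state"] = eq.state
        cache[alpha] = eq.state
        b = char_coefficients(model.jacobian(eq.state)).coeffs
        m = len(b)
        return float(np.linalg.det(hurwitz_matrix(b, m - 1)))

    grid = np.linspace(lo, hi, n_scan + 1)
    values = [d_prev(a) for a in grid]
    roots = []
    for a0, a1, v0, v1 in zip(grid[:-1], grid[1:], values[:-1], values[1:]):
        if np.sign(v0) != np.sign(v1):
            roots.append(optimize.brentq(d_prev, a0, a1, xtol=1e-12, rtol=8.9e-16))
    if not roots:
        raise HopfNotFoundError(
            f"D_(m-1) has no sign change on [{lo}, {hi}] "
            f"(endpoint values {values[0]:.3e}, {values[-1]:.3e})"
        )

    failures = []
    for alpha_star in roots:
        model = model_factory(alpha_star)
        eq = model.solve_equilibrium(seed=warm["state"])
        J = model.jacobian(eq.state)
        poly = char_coefficients(J)
        report = hurwitz_determinants(poly)
        omega, eig = _imaginary_pair(J)
        # D_{m-1} = 0 is certified by the bracketed root finder; only the
        # side conditions of the degenerate criterion are checked here.
        side_ok = report.b_m_positive and report.inner_determinants_positive
        if omega is None or not side_ok:
            failures.append((alpha_star, report.classification))
            continue
        crossing = _crossing_derivative(d_prev, alpha_star)
        return HopfPoint(
            parameters={"alpha": alpha_star},
            equilibrium=eq,
            omega_star=omega,
            crossing_derivative=crossing,
            hurwitz=report,
            diagnostics={"eigenvalues": eig, "all_roots": roots},
        )
    raise DegenerateCandidateError(
        f"D_(m-1) vanishes at {[f'{a:.6g}' for a, _ in failures]} but the "
        "remaining simple-Hopf conditions fail there"
    )


# ---------------------------------------------------------------------------
# Two-parameter continuation of the HB curve
# ---------------------------------------------------------------------------
def trace_hb_curve(
    family_factory: Callable[[float, float], ModelSystem],
    coupling_grid: Sequence[float],
    alpha_seed: float,
    bracket_halfwidth: float = 0.25,
    n_scan: int = 24,
) -> list[HopfPoint | None]:
    """Natural-parameter continuation of HB values over a coupling grid.

    ``family_factory(c, alpha)`` builds the model; each solved HB value seeds
    the bracket at the next coupling value. On failure the coupling step is
    bisected once before the point is flagged (None in the output).
    """
    points: list[HopfPoint | None] = []
    alpha_prev = alpha_seed
    state_prev = None
    prev_c = None
    for c in coupling_grid:
        def solve_at(cc, seed_alpha, seed_state):
            half = bracket_halfwidth * max(abs(seed_alpha), 0.1)
            hp = general_hb_locator(
                lambda a: family_factory(cc, a),
                (seed_alpha - half, seed_alpha + half),
                n_scan=n_scan,
                seed_state=seed_state,
            )
            hp.parameters["c"] = cc
            return hp

        try:
            hp = solve_at(c, alpha_prev, state_prev)
        except Exception as first_err:  # bisect the coupling step once
            if prev_c is None:
                logger.warning("HB curve: first grid point failed: %s", first_err)
                points.append(None)
                continue
            mid = 0.5 * (prev_c + c)
            try:
                hp_mid = solve_at(mid, alpha_prev, state_prev)
                hp = solve_at(c, hp_mid.parameters["alpha"], hp_mid.equilibrium.state)
            except Exception as second_err:
                logger.warning("HB curve lost the branch at c=%g: %s", c, second_err)
                points.append(None)
                continue
        points.append(hp)
        alpha_prev = hp.parameters["alpha"]
        state_prev = hp.equilibrium.state
        prev_c = c
    return points


# ---------------------------------------------------------------------------
def gamma_peak_gap(spec: HillRepression) -> tuple[float, float]:
    """Peak location x_M of the Hill slope gamma and the signed gap
    ``x_bar^n - x_M^n`` to the single-cell HB equilibrium (zero at n = 17)."""
    if not isinstance(spec, HillRepression):
        raise ValidationError("gamma_peak_gap applies to Hill repression only")
    n, kH = spec.n, spec.k_H
    if n <= 8:
        raise InfeasibleError("n > 8 required for the HB equilibrium to exist")
    x_m = spec.gamma_peak()
    gap = -(kH**n) * n * (n - 17) / ((n - 8) * (n + 1))
    return x_m, gap
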