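"""Hopf normal-form reduction: criticality, cycle stability, period trend.

At a located Hopf point the system is projected onto the center eigenspace
following the classical Hassard–Kazarinoff–Wan reduction. With right/left
eigenvectors ``J q = i w q``, ``p J = i w p`` normalized to ``p q = 1``, the
quadratic and cubic coefficients are

    g20 = p B(q, q),  g11 = p B(q, q_bar),  g02 = p B(q_bar, q_bar),
    g21 = p [ C(q, q, q_bar) + 2 B(q, w11) + B(q_bar, w20) ],

with the center-manifold corrections (critical components projected out)

    w20 = (2 i w I - J)^{-1} [B(q, q) - g20 q - conj(g02) q_bar],
    w11 = -J^{-1} [B(q, q_bar) - g11 q - conj(g11) q_bar].

Then

    C1 = (i / 2w) (g20 g11 - 2 |g11|^2 - |g02|^2 / 3) + g21 / 2,
    p2 = -Re C1 / Re lambda'(a*),   zeta2 = 2 Re C1,
    T2 = -(Im C1 + p2 Im lambda'(a*)) / w.

``p2 > 0`` means the cycle exists past the bifurcation value (supercritical),
``zeta2 < 0`` that it is orbitally stable, and ``T2 > 0`` that the period
grows with the bifurcation parameter; the period expands as
``T = (2 pi / w)(1 + T2 eps^2 + O(eps^4))`` with ``eps^2 = (a - a*) / p2``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import DegenerateCandidateError, ValidationError
from .hopf import HopfPoint
from .models import ModelSystem

__all__ = ["NormalFormResult", "hopf_coefficients"]


@dataclass(frozen=True)
class NormalFormResult:
    g20: complex
    g11: complex
    g02: complex
    g21: complex
    C1: complex
    p2: float
    zeta2: float
    T2: float
    classification: str  # supercritical_stable | subcritical_unstable | degenerate
    lambda_prime: complex = 0j


def _center_pair(J: np.ndarray, re_tol: float = 1e-6):
    """Right and left eigenvectors of the near-imaginary pair, p q = 1."""
    w_all, V = np.linalg.eig(J)
    idx = [i for i, lam in enumerate(w_all) if abs(lam.real) <= re_tol and lam.imag > 0]
    if len(idx) != 1:
        raise DegenerateCandidateError(
            f"expected exactly one eigenvalue near +i omega, found {len(idx)}"
        )
    i0 = idx[0]
    omega = float(w_all[i0].imag)
    q = V[:, i0]
    # fixed scale and phase: largest-magnitude component set to exactly 1
    # (the classical planar normal form z' = (mu+i)z - z|z|^2 then yields
    # C1 = -1); all sign conclusions are invariant under this choice
    k = int(np.argmax(np.abs(q)))
    q = q / q[k]

    wl, U = np.linalg.eig(J.T)
    j0 = int(np.argmin(np.abs(wl - w_all[i0])))
    p = U[:, j0]
    p = p / (p @ q)
    return omega, q, p


def _lambda_prime(model: ModelSystem, hp: HopfPoint, param: str) -> complex:
    """d lambda / d alpha of the crossing branch, by central difference over
    re-solved equilibria."""
    a0 = hp.parameters[param]
    h = 1e-6 * max(1.0, abs(a0))
    vals = []
    for a in (a0 + h, a0 - h):
        m = model.with_params(**{param: a})
        eq = m.solve_equilibrium(seed=hp.equilibrium.state)
        lam = np.linalg.eigvals(m.jacobian(eq.state))
        vals.append(lam[np.argmin(np.abs(lam - 1j * hp.omega_star))])
    return (vals[0] - vals[1]) / (2 * h)


def hopf_coefficients(
    model: ModelSystem,
    hp: HopfPoint,
    param: str = "alpha",
    degenerate_tol: float = 1e-10,
) -> NormalFormResult:
    """Normal-form quantities of ``model`` at the Hopf point ``hp``.

    ``model`` must be built at the bifurcation value; its parameter ``param``
    is perturbed to obtain the eigenvalue crossing speed.
    """
    if abs(model.params().get(param, np.nan) - hp.parameters[param]) > 1e-9 * (
        1 + abs(hp.parameters[param])
    ):
        raise ValidationError("model parameters disagree with the Hopf point")
    x = hp.equilibrium.state
    J = model.jacobian(x)
    omega, q, p = _center_pair(J)

    B = model.bilinear
    C = model.trilinear
    qb = q.conj()
    Bqq = np.asarray(B(x, q, q), dtype=complex)
    Bqqb = np.asarray(B(x, q, qb), dtype=complex)
    Bqbqb = np.asarray(B(x, qb, qb), dtype=complex)

    g20 = p @ Bqq
    g11 = p @ Bqqb
    g02 = p @ Bqbqb

    # center-manifold quadratic corrections: the components along the
    # critical eigenvectors are removed before inverting, so the planar
    # resonant terms enter only through the explicit g20 g11 combination
    w20 = np.linalg.solve(
        2j * omega * np.eye(model.dim) - J,
        Bqq - g20 * q - np.conj(g02) * qb,
    )
    w11 = np.linalg.solve(-J, Bqqb - g11 * q - np.conj(g11) * qb)
    g21 = p @ (
        np.asarray(C(x, q, q, qb), dtype=complex)
        + 2 * np.asarray(B(x, q, w11), dtype=complex)
        + np.asarray(B(x, qb, w20), dtype=complex)
    )

    C1 = (1j / (2 * omega)) * (g20 * g11 - 2 * abs(g11) ** 2 - abs(g02) ** 2 / 3) + g21 / 2

    lam_prime = _lambda_prime(model, hp, param)
    if lam_prime.real == 0:
        raise DegenerateCandidateError("eigenvalue crossing speed vanishes")
    if abs(C1.real) < degenerate_tol:
        return NormalFormResult(
            g20=g20, g11=g11, g02=g02, g21=g21, C1=C1,
            p2=float("nan"), zeta2=2 * C1.real, T2=float("nan"),
            classification="degenerate", lambda_prime=lam_prime,
        )

    p2 = -C1.real / lam_prime.real
    zeta2 = 2 * C1.real
    T2 = -(C1.imag + p2 * lam_prime.imag) / omega
    if p2 > 0 and zeta2 < 0:
        cls = "supercritical_stable"
    elif p2 < 0 and zeta2 > 0:
        cls = "subcritical_unstable"
    else:
        cls = "mixed"
    return NormalFormResult(
        g20=g20, g11=g11, g02=g02, g21=g21, C1=C1,
        p2=p2, zeta2=zeta2, T2=T2, classification=cls, lambda_prime=lam_prime,
    )
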