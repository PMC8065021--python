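"""ODE systems for single-cell and coupled-cell genetic oscillators.

All systems are the nondimensional forms (equal degradation rates, time in
units of the common degradation rate). Each model exposes:

* ``rhs(state)`` — the vector field,
* ``jacobian(state)`` — the analytic Jacobian (hand-coded; a finite-difference
  comparison lives in the test suite, not on the runtime path),
* ``solve_equilibrium()`` — the positive equilibrium,
* ``bilinear`` / ``trilinear`` — second- and third-order directional
  derivatives of ``rhs``, used by the Hopf normal-form reduction.

The gene-circuit models carry their nonlinearity only through the repression
function ``f``, so their derivative tensors are sparse and coded analytically;
the segmentation-clock model falls back on directional finite differences of
its analytic Jacobian.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import optimize

from .exceptions import ConvergenceError, ValidationError
from .repression import Repression, make_repression

__all__ = [
    "Equilibrium",
    "ModelSystem",
    "SingleCell",
    "CoupledIdentical",
    "CoupledNonidentical",
    "SynchronousReduced",
    "SegmentationClockPair",
]

_RESIDUAL_TOL = 1e-10


@dataclass(frozen=True)
class Equilibrium:
    """A positive steady state together with its defect ``max |rhs|``."""

    state: np.ndarray
    residual: float
    params: dict = field(default_factory=dict)


class ModelSystem:
    """Base class: an autonomous ODE system with analytic Jacobian."""

    name: str = "?"
    dim: int = 0

    # -- interface -------------------------------------------------------
    def rhs(self, state: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def jacobian(self, state: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def solve_equilibrium(self, seed: np.ndarray | None = None) -> Equilibrium:
        raise NotImplementedError

    def params(self) -> dict:
        raise NotImplementedError

    def with_params(self, **updates) -> "ModelSystem":
        """Rebuild the model with some scalar parameters replaced."""
        return replace(self, **updates)

    # -- helpers ---------------------------------------------------------
    def _check_state(self, state) -> np.ndarray:
        state = np.asarray(state, dtype=float)
        if state.shape != (self.dim,):
            raise ValidationError(
                f"{self.name} expects a state of dimension {self.dim}, got shape {state.shape}"
            )
        return state

    def _wrap_equilibrium(self, state: np.ndarray) -> Equilibrium:
        state = np.asarray(state, dtype=float)
        res = float(np.max(np.abs(self.rhs(state))))
        scale = 1.0 + float(np.max(np.abs(state)))
        if res > _RESIDUAL_TOL * scale:
            raise ConvergenceError(
                f"{self.name}: equilibrium residual {res:.3e} exceeds tolerance", residual=res
            )
        return Equilibrium(state=state, residual=res, params=self.params())

    # -- derivative tensors (generic finite-difference fallback) ---------
    def bilinear(self, state: np.ndarray, u: np.ndarray, v: np.ndarray) -> np.ndarray:
        """B(u, v): second directional derivative of rhs at ``state``.

        Default: central difference of the analytic Jacobian applied to v.
        Supports complex directions by linearity.
        """
        return _fd_bilinear(self, state, u, v)

    def trilinear(self, state, u, v, w) -> np.ndarray:
        """C(u, v, w): third directional derivative of rhs at ``state``."""
        return _fd_trilinear(self, state, u, v, w)


def _split_complex(vec):
    vec = np.asarray(vec)
    if np.iscomplexobj(vec):
        return [(vec.real, 1.0), (vec.imag, 1j)]
    return [(vec.astype(float), 1.0)]


def _fd_bilinear(model, state, u, v, h=1e-5):
    out = np.zeros(model.dim, dtype=complex)
    scale = h * max(1.0, float(np.max(np.abs(state))))
    for ur, cu in _split_complex(u):
        for vr, cv in _split_complex(v):
            jp = model.jacobian(state + scale * ur)
            jm = model.jacobian(state - scale * ur)
            out += cu * cv * ((jp - jm) @ vr) / (2 * scale)
    return out if np.iscomplexobj(u) or np.iscomplexobj(v) else out.real


def _fd_trilinear(model, state, u, v, w, h=1e-4):
    out = np.zeros(model.dim, dtype=complex)
    scale = h * max(1.0, float(np.max(np.abs(state))))
    for wr, cw in _split_complex(w):
        bp = _fd_bilinear(model, state + scale * wr, u, v)
        bm = _fd_bilinear(model, state - scale * wr, u, v)
        out += cw * (np.asarray(bp, dtype=complex) - bm) / (2 * scale)
    if not any(np.iscomplexobj(np.asarray(a)) for a in (u, v, w)):
        return out.real
    return out


def _bracketed_fixed_point(g, upper: float) -> float:
    """Unique positive root of g on (0, upper], g(0+) > 0 > g(upper)."""
    lo = 1e-14
    hi = upper * (1 + 1e-9) + 1e-12
    if g(lo) < 0 or g(hi) > 0:
        raise ConvergenceError("equilibrium bracket does not enclose a sign change")
    return optimize.brentq(g, lo, hi, xtol=1e-13, rtol=8.9e-16)


# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class SingleCell(ModelSystem):
    """Three-variable negative-feedback loop (mRNA, protein, repressor).

    ``x1' = sigma (alpha f(x3) - x1)``, ``x2' = sigma (x1 - x2)``,
    ``x3' = sigma (x2 - x3)``. The overall rate factor ``sigma`` rescales
    time only (default 1); it is used to build cells with distinct intrinsic
    frequencies.
    """

    repression: Repression
    alpha: float
    sigma: float = 1.0

    name = "single_cell"
    dim = 3

    def __post_init__(self):
        if self.alpha <= 0 or self.sigma <= 0:
            raise ValidationError("alpha and sigma must be positive")

    def params(self) -> dict:
        return {"alpha": self.alpha, "sigma": self.sigma, **self.repression.params()}

    def rhs(self, state):
        x1, x2, x3 = self._check_state(state)
        f = self.repression.value(x3)
        return self.sigma * np.array([self.alpha * f - x1, x1 - x2, x2 - x3])

    def jacobian(self, state):
        _, _, x3 = self._check_state(state)
        g = self.repression.gamma(x3)
        J = np.array(
            [[-1.0, 0.0, -self.alpha * g], [1.0, -1.0, 0.0], [0.0, 1.0, -1.0]]
        )
        return self.sigma * J

    def solve_equilibrium(self, seed=None):
        a = self.alpha
        x = _bracketed_fixed_point(lambda t: a * self.repression.value(t) - t, a)
        return self._wrap_equilibrium(np.array([x, x, x]))

    def bilinear(self, state, u, v):
        x3 = float(np.asarray(state)[2])
        f2 = self.repression.second(x3)
        out = np.zeros(3, dtype=np.result_type(np.asarray(u), np.asarray(v), float))
        out[0] = self.sigma * self.alpha * f2 * u[2] * v[2]
        return out

    def trilinear(self, state, u, v, w):
        x3 = float(np.asarray(state)[2])
        f3 = self.repression.third(x3)
        out = np.zeros(3, dtype=np.result_type(np.asarray(u), np.asarray(v), np.asarray(w), float))
        out[0] = self.sigma * self.alpha * f3 * u[2] * v[2] * w[2]
        return out


# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class CoupledIdentical(ModelSystem):
    """N identical four-variable cells coupled through a released signal.

    Each cell carries (x1, x2, x3, x4) = (mRNA, protein, repressor, signal);
    the signal (e.g. VIP) relaxes toward ``f(x3)`` on the fast timescale ``s``
    and feeds back into every cell's transcription through the population
    mean with strength ``c``.
    """

    repression: Repression
    alpha: float
    c: float
    s: float
    n_cells: int = 2

    name = "coupled_identical"

    def __post_init__(self):
        if self.alpha <= 0 or self.c < 0 or self.s <= 0:
            raise ValidationError("alpha, s must be positive and c nonnegative")
        if self.n_cells < 2:
            raise ValidationError("need at least two cells")
        object.__setattr__(self, "dim", 4 * self.n_cells)

    def params(self) -> dict:
        return {
            "alpha": self.alpha,
            "c": self.c,
            "s": self.s,
            "n_cells": self.n_cells,
            **self.repression.params(),
        }

    def rhs(self, state):
        state = self._check_state(state)
        N = self.n_cells
        cells = state.reshape(N, 4)
        mean_v = cells[:, 3].mean()
        out = np.empty_like(cells)
        for i in range(N):
            x1, x2, x3, _x4 = cells[i]
            f = self.repression.value(x3)
            out[i, 0] = self.alpha * f - x1 + self.c * mean_v
            out[i, 1] = x1 - x2
            out[i, 2] = x2 - x3
            out[i, 3] = self.s * (f - cells[i, 3])
        return out.ravel()

    def jacobian(self, state):
        state = self._check_state(state)
        N = self.n_cells
        cells = state.reshape(N, 4)
        J = np.zeros((4 * N, 4 * N))
        for i in range(N):
            g = self.repression.gamma(cells[i, 2])
            o = 4 * i
            J[o, o] = -1.0
            J[o, o + 2] = -self.alpha * g
            J[o + 1, o] = 1.0
            J[o + 1, o + 1] = -1.0
            J[o + 2, o + 1] = 1.0
            J[o + 2, o + 2] = -1.0
            J[o + 3, o + 2] = -self.s * g
            J[o + 3, o + 3] = -self.s
            for j in range(N):
                J[o, 4 * j + 3] += self.c / N
        return J

    def solve_equilibrium(self, seed=None):
        total = self.alpha + self.c
        x = _bracketed_fixed_point(lambda t: total * self.repression.value(t) - t, total)
        cell = np.array([x, x, x, self.repression.value(x)])
        return self._wrap_equilibrium(np.tile(cell, self.n_cells))

    def bilinear(self, state, u, v):
        state = self._check_state(state)
        u = np.asarray(u)
        v = np.asarray(v)
        out = np.zeros(self.dim, dtype=np.result_type(u, v, float))
        for i in range(self.n_cells):
            o = 4 * i
            f2 = self.repression.second(state[o + 2])
            quad = f2 * u[o + 2] * v[o + 2]
            out[o] = self.alpha * quad
            out[o + 3] = self.s * quad
        return out

    def trilinear(self, state, u, v, w):
        state = self._check_state(state)
        u, v, w = np.asarray(u), np.asarray(v), np.asarray(w)
        out = np.zeros(self.dim, dtype=np.result_type(u, v, w, float))
        for i in range(self.n_cells):
            o = 4 * i
            f3 = self.repression.third(state[o + 2])
            cub = f3 * u[o + 2] * v[o + 2] * w[o + 2]
            out[o] = self.alpha * cub
            out[o + 3] = self.s * cub
        return out


# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class SynchronousReduced(ModelSystem):
    """Four-dimensional restriction of the identical-cell network to its
    synchronous (diagonal) invariant set: one cell sensing its own signal
    with full strength ``c``."""

    repression: Repression
    alpha: float
    c: float
    s: float

    name = "synchronous_reduced"
    dim = 4

    def params(self) -> dict:
        return {"alpha": self.alpha, "c": self.c, "s": self.s, **self.repression.params()}

    def rhs(self, state):
        x1, x2, x3, x4 = self._check_state(state)
        f = self.repression.value(x3)
        return np.array(
            [self.alpha * f - x1 + self.c * x4, x1 - x2, x2 - x3, self.s * (f - x4)]
        )

    def jacobian(self, state):
        _, _, x3, _ = self._check_state(state)
        g = self.repression.gamma(x3)
        return np.array(
            [
                [-1.0, 0.0, -self.alpha * g, self.c],
                [1.0, -1.0, 0.0, 0.0],
                [0.0, 1.0, -1.0, 0.0],
                [0.0, 0.0, -self.s * g, -self.s],
            ]
        )

    def solve_equilibrium(self, seed=None):
        total = self.alpha + self.c
        x = _bracketed_fixed_point(lambda t: total * self.repression.value(t) - t, total)
        return self._wrap_equilibrium(np.array([x, x, x, self.repression.value(x)]))

    def bilinear(self, state, u, v):
        f2 = self.repression.second(float(np.asarray(state)[2]))
        out = np.zeros(4, dtype=np.result_type(np.asarray(u), np.asarray(v), float))
        quad = f2 * u[2] * v[2]
        out[0] = self.alpha * quad
        out[3] = self.s * quad
        return out

    def trilinear(self, state, u, v, w):
        f3 = self.repression.third(float(np.asarray(state)[2]))
        out = np.zeros(
            4, dtype=np.result_type(np.asarray(u), np.asarray(v), np.asarray(w), float)
        )
        cub = f3 * u[2] * v[2] * w[2]
        out[0] = self.alpha * cub
        out[3] = self.s * cub
        return out


# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class CoupledNonidentical(ModelSystem):
    """Two coupled cells with the second cell's internal clock rescaled by
    ``sigma`` (distinct intrinsic frequency); signal kinetics and the mean
    coupling are shared."""

    repression: Repression
    alpha: float
    c: float
    s: float
    sigma: float = 1.05

    name = "coupled_nonidentical"
    dim = 8

    def __post_init__(self):
        if min(self.alpha, self.s, self.sigma) <= 0 or self.c < 0:
            raise ValidationError("alpha, s, sigma must be positive and c nonnegative")

    def params(self) -> dict:
        return {
            "alpha": self.alpha,
            "c": self.c,
            "s": self.s,
            "sigma": self.sigma,
            **self.repression.params(),
        }

    def rhs(self, state):
        x1, x2, x3, x4, y1, y2, y3, y4 = self._check_state(state)
        a, c, s, sg = self.alpha, self.c, self.s, self.sigma
        fx = self.repression.value(x3)
        fy = self.repression.value(y3)
        mean = 0.5 * c * (x4 + y4)
        return np.array(
            [
                a * fx - x1 + mean,
                x1 - x2,
                x2 - x3,
                s * (fx - x4),
                sg * (a * fy - y1) + mean,
                sg * (y1 - y2),
                sg * (y2 - y3),
                s * (fy - y4),
            ]
        )

    def jacobian(self, state):
        st = self._check_state(state)
        a, c, s, sg = self.alpha, self.c, self.s, self.sigma
        g = self.repression.gamma(st[2])
        gt = self.repression.gamma(st[6])
        J = np.zeros((8, 8))
        J[0, 0] = -1.0
        J[0, 2] = -a * g
        J[0, 3] = c / 2
        J[0, 7] = c / 2
        J[1, 0] = 1.0
        J[1, 1] = -1.0
        J[2, 1] = 1.0
        J[2, 2] = -1.0
        J[3, 2] = -s * g
        J[3, 3] = -s
        J[4, 3] = c / 2
        J[4, 4] = -sg
        J[4, 6] = -sg * a * gt
        J[4, 7] = c / 2
        J[5, 4] = sg
        J[5, 5] = -sg
        J[6, 5] = sg
        J[6, 6] = -sg
        J[7, 6] = -s * gt
        J[7, 7] = -s
        return J

    def _decoupled_seed(self) -> float:
        a = self.alpha
        return _bracketed_fixed_point(lambda t: a * self.repression.value(t) - t, a)

    def solve_equilibrium(self, seed=None):
        a, c, sg = self.alpha, self.c, self.sigma
        f = self.repression.value

        def core(v):
            x3, y3 = v
            coup = 0.5 * c * (f(x3) + f(y3))
            return [a * f(x3) - x3 + coup, sg * (a * f(y3) - y3) + coup]

        if seed is not None:
            guess = [float(seed[2]), float(seed[6])]
        else:
            x0 = self._decoupled_seed()
            guess = [x0, x0]
        sol = optimize.root(core, guess, method="hybr")
        x3, y3 = (sol.x if sol.success else guess)
        # damped-Newton polish (the 2-D core is smooth; hybr sometimes stalls
        # near the sharp knee of the sequestration repression)
        df = self.repression.derivative
        for _ in range(60):
            r = np.asarray(core([x3, y3]))
            if np.max(np.abs(r)) < 1e-14 * (1 + abs(x3) + abs(y3)):
                break
            j11 = a * df(x3) - 1 + 0.5 * c * df(x3)
            j12 = 0.5 * c * df(y3)
            j21 = 0.5 * c * df(x3)
            j22 = sg * (a * df(y3) - 1) + 0.5 * c * df(y3)
            step = np.linalg.solve(np.array([[j11, j12], [j21, j22]]), -r)
            lam = 1.0
            while lam > 1e-8 and (x3 + lam * step[0] <= 0 or y3 + lam * step[1] <= 0):
                lam /= 2
            x3, y3 = x3 + lam * step[0], y3 + lam * step[1]
        r = np.asarray(core([x3, y3]))
        if np.max(np.abs(r)) > 1e-11 * (1 + abs(x3) + abs(y3)) or min(x3, y3) <= 0:
            raise ConvergenceError(
                "nonidentical equilibrium solve failed",
                residual=float(np.max(np.abs(r))),
            )
        state = np.array([x3, x3, x3, f(x3), y3, y3, y3, f(y3)])
        return self._wrap_equilibrium(state)

    def bilinear(self, state, u, v):
        st = self._check_state(state)
        u, v = np.asarray(u), np.asarray(v)
        a, c, s, sg = self.alpha, self.c, self.s, self.sigma
        f2x = self.repression.second(st[2])
        f2y = self.repression.second(st[6])
        out = np.zeros(8, dtype=np.result_type(u, v, float))
        qx = f2x * u[2] * v[2]
        qy = f2y * u[6] * v[6]
        out[0] = a * qx
        out[3] = s * qx
        out[4] = sg * a * qy
        out[7] = s * qy
        return out

    def trilinear(self, state, u, v, w):
        st = self._check_state(state)
        u, v, w = np.asarray(u), np.asarray(v), np.asarray(w)
        a, c, s, sg = self.alpha, self.c, self.s, self.sigma
        f3x = self.repression.third(st[2])
        f3y = self.repression.third(st[6])
        out = np.zeros(8, dtype=np.result_type(u, v, w, float))
        cx = f3x * u[2] * v[2] * w[2]
        cy = f3y * u[6] * v[6] * w[6]
        out[0] = a * cx
        out[3] = s * cx
        out[4] = sg * a * cy
        out[7] = s * cy
        return out


# ---------------------------------------------------------------------------
_SEGCLOCK_KEYS = (
    "nu1", "nu2", "nu3", "nu4", "nu5", "nu6", "nu7", "nu8",
    "k1", "k2", "k4", "k6", "k8",  # Michaelis constants and repression threshold
    "k7", "n", "h", "nu_c", "sigma",
)


@dataclass(frozen=True)
class SegmentationClockPair(ModelSystem):
    """Two coupled segmentation-clock cells (zebrafish her-gene circuit).

    Each cell: her mRNA (x1), cytoplasmic Her (x2), nuclear Her (x3) with
    Michaelis–Menten degradations, plus a Delta-like coupling signal (x4)
    produced under Hill repression by nuclear Her and sensed by the partner
    cell with strength ``nu_c``. Cell 2 runs ``sigma`` times faster.
    """

    nu1: float
    nu2: float
    nu3: float
    nu4: float
    nu5: float
    nu6: float
    nu7: float
    nu8: float
    k1: float
    k2: float
    k4: float
    k6: float
    k7: float
    k8: float
    n: int
    h: int
    nu_c: float
    sigma: float = 1.0

    name = "segclock_pair"
    dim = 8

    def __post_init__(self):
        for key in _SEGCLOCK_KEYS:
            if key in ("nu_c",):
                continue
            if getattr(self, key) <= 0:
                raise ValidationError(f"segclock parameter {key} must be positive")
        if self.nu_c < 0:
            raise ValidationError("coupling nu_c must be nonnegative")

    def params(self) -> dict:
        return {k: getattr(self, k) for k in _SEGCLOCK_KEYS}

    def _cell_rhs(self, cell, other_v, drive_scale):
        x1, x2, x3, x4 = cell
        p = self
        hill1 = 1.0 / (1.0 + (x3 / p.k1) ** p.n)
        hill7 = p.nu7 / (1.0 + (x3 / p.k7) ** p.h)
        return np.array(
            [
                hill1 * (p.nu1 + drive_scale * p.nu_c * other_v) - p.nu2 * x1 / (p.k2 + x1),
                p.nu3 * x1 - p.nu4 * x2 / (p.k4 + x2) - p.nu5 * x2,
                p.nu5 * x2 - p.nu6 * x3 / (p.k6 + x3),
                hill7 - p.nu8 * x4 / (p.k8 + x4),
            ]
        )

    def rhs(self, state):
        st = self._check_state(state)
        x, y = st[:4], st[4:]
        fx = self._cell_rhs(x, y[3], 1.0)
        fy = self.sigma * self._cell_rhs(y, x[3], 1.0 / self.sigma)
        return np.concatenate([fx, fy])

    def _cell_jac(self, cell, other_v, drive_scale):
        x1, x2, x3, x4 = cell
        p = self
        J = np.zeros((4, 4))
        rn = (x3 / p.k1) ** p.n
        hn = 1.0 / (1.0 + rn)
        dhn = -(p.n / x3) * rn / (1.0 + rn) ** 2
        rh = (x3 / p.k7) ** p.h
        hh = 1.0 / (1.0 + rh)
        dhh = -(p.h / x3) * rh / (1.0 + rh) ** 2
        drive = p.nu1 + drive_scale * p.nu_c * other_v
        J[0, 0] = -p.nu2 * p.k2 / (p.k2 + x1) ** 2
        J[0, 2] = dhn * drive
        J[1, 0] = p.nu3
        J[1, 1] = -p.nu4 * p.k4 / (p.k4 + x2) ** 2 - p.nu5
        J[2, 1] = p.nu5
        J[2, 2] = -p.nu6 * p.k6 / (p.k6 + x3) ** 2
        J[3, 2] = p.nu7 * dhh
        J[3, 3] = -p.nu8 * p.k8 / (p.k8 + x4) ** 2
        cross = hn * drive_scale * p.nu_c  # d(x1')/d(other_v)
        return J, cross

    def jacobian(self, state):
        st = self._check_state(state)
        x, y = st[:4], st[4:]
        Jx, cross_x = self._cell_jac(x, y[3], 1.0)
        Jy, cross_y = self._cell_jac(y, x[3], 1.0 / self.sigma)
        J = np.zeros((8, 8))
        J[:4, :4] = Jx
        J[0, 7] = cross_x
        J[4:, 4:] = self.sigma * Jy
        J[4, 3] = self.sigma * cross_y
        return J

    def solve_equilibrium(self, seed=None):
        if seed is None:
            raise ValidationError("segclock equilibrium requires a positive seed state")
        seed = self._check_state(seed)

        sol = optimize.root(lambda v: self.rhs(v), seed, method="hybr", tol=1e-13)
        state = sol.x
        if not sol.success or np.any(state <= 0):
            # damped Newton fallback from the same seed
            state = seed.copy()
            for _ in range(200):
                r = self.rhs(state)
                if np.max(np.abs(r)) < 1e-13:
                    break
                step = np.linalg.solve(self.jacobian(state), -r)
                lam = 1.0
                while lam > 1e-6 and np.any(state + lam * step <= 0):
                    lam /= 2
                state = state + lam * step
            else:
                raise ConvergenceError(
                    "segclock equilibrium did not converge",
                    residual=float(np.max(np.abs(self.rhs(state)))),
                )
        return self._wrap_equilibrium(state)
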