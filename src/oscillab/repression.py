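"""Transcription-repression functions for the negative-feedback loop.

Two repression mechanisms are supported, both strictly decreasing with
``f(0) = 1`` and ``f(x) -> 0`` as ``x -> oo``:

* **Hill-type (HT)**: cooperative binding of the repressor to the gene
  promoter, ``f(x) = 1 / (1 + (x/k_H)^n)`` with Hill coefficient ``n`` and
  half-saturation constant ``k_H``.
* **Protein sequestration (PS)**: the repressor binds a free activator (total
  concentration ``A``) into an inactive complex with dissociation constant
  ``k_d``; ``f(x)`` is the unsequestered activator fraction.

The slope magnitude at the equilibrium, ``gamma = -f'(x_bar) > 0``, controls
both the Hopf bifurcation value of the single cell (``alpha_0 = 8/gamma``)
and the collective frequency of coupled cells, so closed-form first, second
and third derivatives are provided for both kinds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .exceptions import ValidationError

__all__ = ["Repression", "HillRepression", "SequestrationRepression", "make_repression"]


@dataclass(frozen=True)
class Repression:
    """Abstract decreasing transcription-rate function."""

    kind = "?"

    def value(self, x: float) -> float:
        raise NotImplementedError

    def derivative(self, x: float) -> float:
        raise NotImplementedError

    def second(self, x: float) -> float:
        raise NotImplementedError

    def third(self, x: float) -> float:
        raise NotImplementedError

    def gamma(self, x: float) -> float:
        """Slope magnitude ``-f'(x)``; positive for all x > 0."""
        if x <= 0:
            raise ValidationError(f"gamma requires x > 0, got {x}")
        return -self.derivative(x)

    def params(self) -> dict[str, float]:
        raise NotImplementedError


@dataclass(frozen=True)
class HillRepression(Repression):
    """Hill-type repression ``f(x) = 1/(1 + (x/k_H)^n)``."""

    n: int
    k_H: float
    kind = "HT"

    def __post_init__(self):
        if self.n < 1 or int(self.n) != self.n:
            raise ValidationError(f"Hill coefficient must be a positive integer, got {self.n}")
        if self.k_H <= 0:
            raise ValidationError(f"half-saturation k_H must be positive, got {self.k_H}")

    def _t(self, x: float) -> float:
        return (x / self.k_H) ** self.n

    def value(self, x: float) -> float:
        if x < 0:
            raise ValidationError(f"repressor concentration must be nonnegative, got {x}")
        return 1.0 / (1.0 + self._t(x))

    def derivative(self, x: float) -> float:
        t = self._t(x)
        return -(self.n / x) * t / (1.0 + t) ** 2

    def second(self, x: float) -> float:
        n, t = self.n, self._t(x)
        tp = n * t / x
        tpp = n * (n - 1) * t / x**2
        return -tpp / (1 + t) ** 2 + 2 * tp**2 / (1 + t) ** 3

    def third(self, x: float) -> float:
        n, t = self.n, self._t(x)
        tp = n * t / x
        tpp = n * (n - 1) * t / x**2
        tppp = n * (n - 1) * (n - 2) * t / x**3
        return -tppp / (1 + t) ** 2 + 6 * tp * tpp / (1 + t) ** 3 - 6 * tp**3 / (1 + t) ** 4

    def gamma_peak(self) -> float:
        """Location ``x_M = k_H ((n-1)/(n+1))^{1/n}`` where gamma attains its maximum."""
        return self.k_H * ((self.n - 1) / (self.n + 1)) ** (1.0 / self.n)

    def params(self) -> dict[str, float]:
        return {"kind": "HT", "n": self.n, "k_H": self.k_H}


@dataclass(frozen=True)
class SequestrationRepression(Repression):
    """Protein-sequestration repression.

    ``f(x) = (w + S) / (2A)`` with ``w = A - x - k_d`` and
    ``S = sqrt(w^2 + 4 A k_d)``: the fraction of activator not bound by the
    repressor when binding is at equilibrium.
    """

    A: float
    k_d: float
    kind = "PS"

    def __post_init__(self):
        if self.A <= 0:
            raise ValidationError(f"activator level A must be positive, got {self.A}")
        if self.k_d <= 0:
            raise ValidationError(f"dissociation constant k_d must be positive, got {self.k_d}")

    def _ws(self, x: float) -> tuple[float, float]:
        w = self.A - x - self.k_d
        return w, math.sqrt(w * w + 4 * self.A * self.k_d)

    def value(self, x: float) -> float:
        if x < 0:
            raise ValidationError(f"repressor concentration must be nonnegative, got {x}")
        w, s = self._ws(x)
        return (w + s) / (2 * self.A)

    def derivative(self, x: float) -> float:
        w, s = self._ws(x)
        return -(w + s) / (2 * self.A * s)

    def second(self, x: float) -> float:
        _, s = self._ws(x)
        return 2 * self.k_d / s**3

    def third(self, x: float) -> float:
        w, s = self._ws(x)
        return 6 * self.k_d * w / s**5

    def params(self) -> dict[str, float]:
        return {"kind": "PS", "A": self.A, "k_d": self.k_d}


def make_repression(kind: str, **kwargs) -> Repression:
    """Build a repression spec from a flat parameter record."""
    kind = kind.upper()
    if kind == "HT":
        return HillRepression(n=int(kwargs["n"]), k_H=float(kwargs["k_H"]))
    if kind == "PS":
        return SequestrationRepression(A=float(kwargs["A"]), k_d=float(kwargs["k_d"]))
    raise ValidationError(f"unknown repression kind {kind!r}; expected 'HT' or 'PS'")
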