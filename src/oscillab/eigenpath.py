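"""Eigenvalue-branch tracing along straight segments in parameter space.

As the parameters move from the decoupled Hopf point ``P0 = (0, alpha_0)``
toward a coupled-cell Hopf value ``P1 = (c*, alpha*)``, the spectrum of the
linearization deforms continuously. Tracking matched branches shows which
conjugate pair reaches the imaginary axis at ``P1`` (the collective
frequency) and how the unstable dimension of the equilibrium changes en
route — the Hill-type and sequestration models differ qualitatively here.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.optimize import linear_sum_assignment

from .exceptions import ValidationError
from .models import ModelSystem

__all__ = ["EigenPath", "trace_segment", "classify_transition"]

_UNSTABLE_TOL = 1e-9


@dataclass(frozen=True)
class EigenPath:
    """Matched eigenvalue trajectories along a parameter segment.

    ``eigenvalues[k, j]`` is branch j at step k; columns are continuous in k.
    """

    start: dict
    end: dict
    parameters: list[dict]
    eigenvalues: np.ndarray          # (steps+1, m) complex, branch-matched
    equilibria: np.ndarray           # (steps+1, m) states
    unstable_dims: np.ndarray        # (steps+1,) ints
    truncated: bool = False


def _match(prev: np.ndarray, new: np.ndarray) -> np.ndarray:
    """Reorder ``new`` to continue the branches of ``prev``.

    Greedy nearest-neighbour, falling back to an optimal (Hungarian)
    assignment whenever the greedy pairing is ambiguous.
    """
    dist = np.abs(prev[:, None] - new[None, :])
    order = np.full(len(new), -1)
    used = set()
    ambiguous = False
    for i in np.argsort(dist.min(axis=1)):
        j = int(np.argmin(dist[i]))
        if j in used:
            ambiguous = True
            break
        order[i] = j
        used.add(j)
    if ambiguous or (order < 0).any():
        _, cols = linear_sum_assignment(dist)
        order = cols
    return new[order]


def trace_segment(
    model_factory: Callable[[dict], ModelSystem],
    P0: dict,
    P1: dict,
    steps: int = 200,
) -> EigenPath:
    """Trace the spectrum along the straight segment from P0 to P1.

    ``model_factory`` maps a parameter record (linear interpolation of P0 and
    P1 entrywise) to a model. Equilibria are warm-started step to step.
    Branch order at the start is by descending imaginary part then real part;
    when the start point carries a degenerate (repeated) pair, the labels
    only become meaningful from the first interior step on.
    """
    if set(P0) != set(P1):
        raise ValidationError("P0 and P1 must share the same parameter names")
    if steps < 1:
        raise ValidationError("need at least one step")

    records = []
    for k in range(steps + 1):
        t = k / steps
        records.append({key: (1 - t) * P0[key] + t * P1[key] for key in P0})

    eigs = []
    states = []
    seed = None
    truncated = False
    for rec in records:
        model = model_factory(rec)
        try:
            eq = model.solve_equilibrium(seed=seed)
        except Exception:
            truncated = True
            break
        seed = eq.state
        lam = np.linalg.eigvals(model.jacobian(eq.state))
        if eigs:
            lam = _match(eigs[-1], lam)
        else:
            lam = lam[np.lexsort((-lam.real, -lam.imag))]
        eigs.append(lam)
        states.append(eq.state)

    eigs_arr = np.array(eigs)
    unstable = (eigs_arr.real > _UNSTABLE_TOL).sum(axis=1)
    return EigenPath(
        start=dict(P0),
        end=dict(P1),
        parameters=records[: len(eigs)],
        eigenvalues=eigs_arr,
        equilibria=np.array(states),
        unstable_dims=unstable,
        truncated=truncated,
    )


def classify_transition(path: EigenPath) -> dict:
    """Summarize stability changes along a traced path.

    Reports, per branch, the maximum real part and whether the branch enters
    the right half-plane, plus the sequence of unstable dimensions. The
    signature ``transient_instability`` (a branch crosses into Re > 0
    mid-segment and returns) distinguishes the Hill-type route to the coupled
    Hopf point from the sequestration route (``stable_interior``), where all
    interior points keep the equilibrium stable.
    """
    eigs = path.eigenvalues
    max_re = eigs.real.max(axis=0)
    crosses = (eigs.real > _UNSTABLE_TOL).any(axis=0)
    interior = path.unstable_dims[1:-1] if len(path.unstable_dims) > 2 else np.array([], int)
    if interior.size and interior.max() > 0:
        signature = "transient_instability"
    else:
        signature = "stable_interior"
    return {
        "branch_max_real": max_re,
        "branch_crosses_axis": crosses,
        "unstable_dims": path.unstable_dims,
        "signature": signature,
        "final_unstable_dim": int(path.unstable_dims[-1]),
    }
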