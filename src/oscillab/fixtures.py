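"""Registry of the worked-example parameter sets.

Every registered record carries the model family, the full parameter values
and, where a specific run is described, the initial condition. These are the
published operating points for the Hill-type (HT, n=11) and protein-
sequestration (PS, A=0.0659, k_d=1e-5) repressions and their coupled-cell
variants (signal timescale s=20, rate mismatch sigma=1.05).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .exceptions import ValidationError
from .models import (
    CoupledIdentical,
    CoupledNonidentical,
    ModelSystem,
    SingleCell,
)
from .repression import make_repression

__all__ = ["Fixture", "FIXTURES", "get_fixture", "build_model", "list_fixtures"]


@dataclass(frozen=True)
class Fixture:
    key: str
    family: str
    params: dict
    note: str
    x0: tuple | None = None


_HT = {"kind": "HT", "n": 11, "k_H": 0.136}
_PS = {"kind": "PS", "A": 0.0659, "k_d": 1e-5}

FIXTURES: dict[str, Fixture] = {
    f.key: f
    for f in [
        Fixture("ex3.1", "single_cell", {**_HT}, "single-cell HT operating point"),
        Fixture("ex3.2", "single_cell", {**_PS}, "single-cell PS operating point"),
        Fixture(
            "ex4.1.1-HT",
            "coupled_identical",
            {**_HT, "s": 20.0, "c": 0.05, "alpha": 0.4742},
            "two identical HT cells at their coupled HB value",
        ),
        Fixture(
            "ex4.1.1-PS",
            "coupled_identical",
            {**_PS, "s": 20.0, "c": 0.05, "alpha": 0.4766},
            "two identical PS cells at their coupled HB value",
        ),
        Fixture(
            "ex4.2-HT",
            "coupled_nonidentical",
            {**_HT, "s": 20.0, "c": 0.05, "sigma": 1.05, "alpha": 0.5165},
            "nonidentical HT pair (sigma=1.05) at its coupled HB value",
        ),
        Fixture(
            "ex4.2-PS",
            "coupled_nonidentical",
            {**_PS, "s": 20.0, "c": 0.038, "sigma": 1.05, "alpha": 0.5043},
            "nonidentical PS pair (sigma=1.05) at its coupled HB value",
        ),
        Fixture(
            "remark2-HT",
            "single_cell",
            {"kind": "HT", "n": 11, "k_H": 0.04, "alpha": 1.0},
            "single-cell HT with the unscaled half-saturation, alpha=1",
            x0=(0.1, 0.1, 0.1),
        ),
        Fixture(
            "remark2-PS",
            "single_cell",
            {**_PS, "alpha": 1.0},
            "single-cell PS at alpha=1 (the unscaled system)",
            x0=(0.1, 0.1, 0.1),
        ),
        Fixture(
            "fig4",
            "single_cell",
            {**_HT, "alpha": 0.60139},
            "single-cell HT run whose waveform matches the PS cell",
            x0=(0.1, 0.1, 0.1),
        ),
        Fixture(
            "fig4-PS",
            "single_cell",
            {**_PS, "alpha": 0.60139},
            "single-cell PS companion run to fig4",
            x0=(0.295, 0.295, 0.295),
        ),
    ]
}


def get_fixture(key: str) -> Fixture:
    try:
        return FIXTURES[key]
    except KeyError:
        raise ValidationError(
            f"unknown fixture {key!r}; available: {', '.join(sorted(FIXTURES))}"
        ) from None


def build_model(key: str, **overrides) -> ModelSystem:
    """Instantiate the fixture's model; scalar parameters may be overridden
    (e.g. ``alpha`` for fixtures that leave the drive free)."""
    fx = get_fixture(key)
    params = {**fx.params, **overrides}
    rep_keys = {"kind", "n", "k_H", "A", "k_d"}
    rep = make_repression(params["kind"], **{k: v for k, v in params.items() if k in rep_keys - {"kind"}})
    rest = {k: v for k, v in params.items() if k not in rep_keys}
    if fx.family == "single_cell":
        return SingleCell(repression=rep, **rest)
    if fx.family == "coupled_identical":
        return CoupledIdentical(repression=rep, **rest)
    if fx.family == "coupled_nonidentical":
        return CoupledNonidentical(repression=rep, **rest)
    raise ValidationError(f"fixture family {fx.family!r} not constructible here")


def list_fixtures() -> list[dict]:
    return [
        {"key": f.key, "family": f.family, "note": f.note, **f.params}
        for f in FIXTURES.values()
    ]
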