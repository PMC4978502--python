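"""Gap cost models.

A gap cost model assigns a signed score contribution to one gap interval of
a (restricted) pairwise alignment, as a function of the interval's length
and terminal status only — never of the partner sequence.  Penalties are
entered as the signed contributions they add to the score, so a penalty is
a negative number; there is no hidden sign flip.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Protocol, runtime_checkable

from .errors import ConfigError
from .gap_intervals import GapInterval


@runtime_checkable
class GapCostModel(Protocol):
    """Contract: O(1) evaluation of one gap interval's score contribution."""

    def evaluate(self, interval: GapInterval) -> float: ...


@dataclass(frozen=True)
class ConstantGapCost:
    """Pure per-column cost: ``length * unit_cost`` (no opening charge)."""

    unit_cost: float

    def evaluate(self, interval: GapInterval) -> float:
        return interval.length * self.unit_cost


@dataclass(frozen=True)
class AffineGapCost:
    """Affine model: ``gap_open + length * gap_extend``.

    Terminal intervals (touching the first or last alignment column) use
    ``gap_open_terminal`` / ``gap_extend_terminal``, which default to the
    internal values.
    """

    gap_open: float
    gap_extend: float
    gap_open_terminal: float | None = None
    gap_extend_terminal: float | None = None

    @property
    def go_term(self) -> float:
        return self.gap_open if self.gap_open_terminal is None else self.gap_open_terminal

    @property
    def ge_term(self) -> float:
        return self.gap_extend if self.gap_extend_terminal is None else self.gap_extend_terminal

    def opening_cost(self, interval: GapInterval) -> float:
        return self.go_term if interval.terminal else self.gap_open

    def extension_cost(self, interval: GapInterval) -> float:
        per_col = self.ge_term if interval.terminal else self.gap_extend
        return interval.length * per_col

    def evaluate(self, interval: GapInterval) -> float:
        return self.opening_cost(interval) + self.extension_cost(interval)


@dataclass(frozen=True)
class LogGapCost:
    """Logarithmic model: ``a + b * ln(length)``."""

    a: float
    b: float

    def evaluate(self, interval: GapInterval) -> float:
        return self.a + self.b * math.log(interval.length)


@dataclass(frozen=True)
class LogAffineGapCost:
    """Log-affine model: ``a + b * length + c * ln(length)``."""

    a: float
    b: float
    c: float

    def evaluate(self, interval: GapInterval) -> float:
        return self.a + self.b * interval.length + self.c * math.log(interval.length)


def gap_cost_from_spec(spec: str) -> GapCostModel:
    """Build a preset model from a ``name:p1,p2,...`` string.

    Presets: ``constant:C``, ``affine:GO,GE[,GOterm,GEterm]``, ``log:A,B``,
    ``logaffine:A,B,C``.
    """
    name, _, params_s = spec.partition(":")
    name = name.lower()
    try:
        params = [float(p) for p in params_s.split(",")] if params_s else []
    except ValueError:
        raise ConfigError(f"cannot parse gap model parameters in {spec!r}")
    if name == "constant" and len(params) == 1:
        return ConstantGapCost(*params)
    if name == "affine" and len(params) in (2, 4):
        return AffineGapCost(*params)
    if name == "log" and len(params) == 2:
        return LogGapCost(*params)
    if name == "logaffine" and len(params) == 3:
        return LogAffineGapCost(*params)
    raise ConfigError(
        f"unknown gap model spec {spec!r}; expected constant:C, affine:GO,GE[,GOt,GEt], "
        f"log:A,B or logaffine:A,B,C"
    )
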