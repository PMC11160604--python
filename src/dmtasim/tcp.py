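"""Target candidate profile (TCP) objectives and the piecewise utility map.

Each objective carries an *acceptable* and an *ideal* interval.  The utility
of an observed value is 1 anywhere inside the ideal interval, interpolates
linearly from 0 to 1 across the band between an acceptable bound and its
same-side ideal bound, and falls off quadratically (unboundedly) outside the
acceptable interval.  The resulting scalar lives in (-inf, 1], is continuous
everywhere, and saturates exactly when all objectives are satisfied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ObjectiveSpec",
    "TCP",
    "objective_utility",
    "composite_utility",
    "tcp_satisfied",
    "default_tcp",
]

NEG_INF = float("-inf")


@dataclass(frozen=True)
class ObjectiveSpec:
    """One TCP objective: units, dynamic range, acceptable and ideal bounds.

    Bounds may be +/-inf on one side (e.g. potency has no upper limit).
    The ideal interval must sit inside the acceptable one, which must sit
    inside the closure of the dynamic range, and at least one acceptable
    bound must be finite.
    """

    name: str
    units: str
    dynamic_range: tuple[float, float]
    acceptable: tuple[float, float]
    ideal: tuple[float, float]

    def __post_init__(self):
        lo, hi = self.dynamic_range
        a_lo, a_hi = self.acceptable
        i_lo, i_hi = self.ideal
        if not (a_lo <= i_lo <= i_hi <= a_hi):
            raise ValueError(f"{self.name}: ideal must lie within acceptable")
        if not (math.isinf(a_lo) or a_lo >= lo) or not (
            math.isinf(a_hi) or a_hi <= hi
        ):
            raise ValueError(
                f"{self.name}: acceptable bounds outside dynamic range"
            )
        if math.isinf(a_lo) and math.isinf(a_hi):
            raise ValueError(f"{self.name}: at least one acceptable bound finite")

    def _ramp_width(self, side: str) -> float:
        """Width of the linear band on one side; falls back to 10% of the
        dynamic range when ideal and acceptable bounds coincide."""
        if side == "lo":
            w = self.ideal[0] - self.acceptable[0]
        else:
            w = self.acceptable[1] - self.ideal[1]
        if not math.isfinite(w) or w <= 0:
            span = self.dynamic_range[1] - self.dynamic_range[0]
            w = 0.1 * span
        return w

    def to_dict(self) -> dict:
        def enc(x):
            return x if math.isfinite(x) else ("inf" if x > 0 else "-inf")

        return {
            "name": self.name,
            "units": self.units,
            "dynamic_range": [enc(v) for v in self.dynamic_range],
            "acceptable": [enc(v) for v in self.acceptable],
            "ideal": [enc(v) for v in self.ideal],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ObjectiveSpec":
        def dec(x):
            return float(x)

        return cls(
            name=d["name"],
            units=d.get("units", ""),
            dynamic_range=tuple(dec(v) for v in d["dynamic_range"]),
            acceptable=tuple(dec(v) for v in d["acceptable"]),
            ideal=tuple(dec(v) for v in d["ideal"]),
        )


@dataclass(frozen=True)
class TCP:
    """A target candidate profile: objectives, scalarization weights, and the
    interval (acceptable or ideal) that defines program success."""

    objectives: tuple[ObjectiveSpec, ...]
    weights: tuple[float, ...] = ()
    success_criterion: str = "acceptable"

    def __post_init__(self):
        if self.success_criterion not in ("acceptable", "ideal"):
            raise ValueError("success_criterion must be 'acceptable' or 'ideal'")
        w = self.weights
        if not w:
            w = tuple(1.0 for _ in self.objectives)
        if len(w) != len(self.objectives):
            raise ValueError("one weight per objective required")
        if any(x < 0 for x in w):
            raise ValueError("weights must be non-negative")
        total = sum(w)
        if total <= 0:
            raise ValueError("weights must not all be zero")
        object.__setattr__(self, "weights", tuple(x / total for x in w))

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(o.name for o in self.objectives)

    def spec(self, name: str) -> ObjectiveSpec:
        for o in self.objectives:
            if o.name == name:
                return o
        raise KeyError(name)

    def to_dict(self) -> dict:
        return {
            "objectives": [o.to_dict() for o in self.objectives],
            "weights": list(self.weights),
            "success_criterion": self.success_criterion,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TCP":
        return cls(
            objectives=tuple(ObjectiveSpec.from_dict(o) for o in d["objectives"]),
            weights=tuple(d.get("weights", ())),
            success_criterion=d.get("success_criterion", "acceptable"),
        )


def objective_utility(value: float, spec: ObjectiveSpec) -> float:
    """Map one objective value into (-inf, 1].

    1 inside the ideal interval; linear 0->1 across each acceptable-to-ideal
    band; beyond an acceptable bound, a quadratic descent
    ``u_boundary - (excess / ramp_width)**2`` where ``u_boundary`` is the
    utility at that bound -- 0 at the foot of a linear band, 1 when the ideal
    and acceptable bounds coincide (no band exists), keeping the function
    continuous everywhere.  A side whose acceptable bound is infinite never
    penalizes.  Non-finite values (missing measurements) map to -inf so they
    can never win a selection.
    """
    if not math.isfinite(value):
        return NEG_INF
    a_lo, a_hi = spec.acceptable
    i_lo, i_hi = spec.ideal
    if i_lo <= value <= i_hi:
        return 1.0
    if value < i_lo:
        if value >= a_lo:
            return (value - a_lo) / (i_lo - a_lo)
        u_boundary = 1.0 if i_lo == a_lo else 0.0
        return u_boundary - ((a_lo - value) / spec._ramp_width("lo")) ** 2
    # value > i_hi
    if value <= a_hi:
        return (a_hi - value) / (a_hi - i_hi)
    u_boundary = 1.0 if i_hi == a_hi else 0.0
    return u_boundary - ((value - a_hi) / spec._ramp_width("hi")) ** 2


def composite_utility(values: dict[str, float], tcp: TCP) -> float:
    """Weighted arithmetic mean of per-objective utilities.

    Equals 1 iff every objective is inside its ideal interval; any missing
    objective dominates the mean with -inf.
    """
    total = 0.0
    for spec, w in zip(tcp.objectives, tcp.weights):
        v = values.get(spec.name)
        u = objective_utility(v, spec) if v is not None else NEG_INF
        if u == NEG_INF:
            return NEG_INF
        total += w * u
    return total


def utilities_vector(values: dict[str, float], tcp: TCP) -> np.ndarray:
    """Per-objective utilities in TCP order (missing -> -inf)."""
    out = np.empty(len(tcp.objectives))
    for j, spec in enumerate(tcp.objectives):
        v = values.get(spec.name)
        out[j] = objective_utility(v, spec) if v is not None else NEG_INF
    return out


def tcp_satisfied(measured: dict[str, float], tcp: TCP) -> bool:
    """True iff every objective's *measured* value lies in the success interval.

    Only ground-truth measurements count here, never predictions; any
    unmeasured objective fails.
    """
    for spec in tcp.objectives:
        v = measured.get(spec.name)
        if v is None or not math.isfinite(v):
            return False
        lo, hi = spec.acceptable if tcp.success_criterion == "acceptable" else spec.ideal
        if not (lo <= v <= hi):
            return False
    return True


def default_tcp(success_criterion: str = "acceptable") -> TCP:
    """The hit-to-lead profile used throughout: potency (pIC50), lipophilicity
    (Log P) and aqueous solubility (Log S) with bounds typical of approved
    oral drugs."""
    inf = float("inf")
    return TCP(
        objectives=(
            ObjectiveSpec(
                "affinity", "pIC50", (3.0, 11.0), (8.0, inf), (9.0, inf)
            ),
            ObjectiveSpec(
                "lipophilicity", "Log P", (-1.0, 8.0), (0.0, 4.0), (0.0, 3.0)
            ),
            ObjectiveSpec(
                "solubility", "Log S", (-8.0, 1.0), (-4.0, 0.0), (-3.0, 0.0)
            ),
        ),
        success_criterion=success_criterion,
    )
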