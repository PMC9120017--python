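"""Declarative kinetic schemes and their evaluation into rate matrices.

A channel gating mechanism is a continuous-time Markov chain whose
generator (Q matrix) depends on membrane voltage and on the ligand
concentrations that multiply binding steps.  The chain is declared as a
:class:`MechanismSpec` — a list of directed transitions, each carrying a
named rate constant, an optional ligand dependence (the rate is
multiplied by the molar Ca2+ or blocker concentration), and an optional
voltage partitioning.  A voltage-dependent rate is multiplied by
``v**(delta/2)`` where ``v = exp(-+ z*V*F/(R*T))`` (minus for the
forward direction, plus for the backward one), ``z`` is the valence of
the moving particle and ``delta`` the fraction of the membrane field it
traverses; the product ``delta*z`` is the apparent valence of the step.

Two mechanisms ship with the package:

``open_block``
    An 8-state Ca2+-gating scheme for a calcium-activated chloride
    channel with a dead-end blocked state (state 7) appended to the
    single open state (state 0).  The blocker on-rate carries the
    blocker concentration and half the voltage factor; the off-rate
    carries the reciprocal half factor.

``closed_antagonism``
    A 10-state alternative in which the blocker binds three closed
    states (3, 5, 6 -> dead-end states 7, 8, 9) and never the open
    state.  It predicts the opposite Ca2+ dependence of inhibition and
    serves as the contrast model.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping

import numpy as np

from .constants import DEFAULT_TEMPERATURE, FARADAY, GAS_CONSTANT
from .errors import ConfigurationError, InvalidArgumentError

__all__ = [
    "TransitionSpec",
    "VoltageDependence",
    "MechanismSpec",
    "ParameterSet",
    "Conditions",
    "RateMatrix",
    "voltage_factor",
    "build_rate_matrix",
    "packaged_mechanism",
]

Direction = Literal["forward", "backward"]


def voltage_factor(
    valence: float,
    voltage: float,
    temperature: float = DEFAULT_TEMPERATURE,
    direction: Direction = "forward",
) -> float:
    """Exponential voltage factor ``exp(-+ z*V*F/(R*T))`` of a rate.

    Parameters
    ----------
    valence
        Signed charge ``z`` of the particle moving through the field.
    voltage
        Membrane voltage in volts.
    temperature
        Absolute temperature in kelvin.
    direction
        ``"forward"`` uses the minus sign in the exponent,
        ``"backward"`` the plus sign, so that the product of the two
        factors is exactly 1.
    """
    if not (math.isfinite(valence) and math.isfinite(voltage)):
        raise InvalidArgumentError("valence and voltage must be finite")
    if not (math.isfinite(temperature) and temperature > 0):
        raise InvalidArgumentError("temperature must be finite and > 0")
    if direction not in ("forward", "backward"):
        raise InvalidArgumentError(f"unknown direction {direction!r}")
    sign = -1.0 if direction == "forward" else 1.0
    return math.exp(sign * valence * voltage * FARADAY / (GAS_CONSTANT * temperature))


@dataclass(frozen=True)
class VoltageDependence:
    """Voltage partitioning of a transition.

    ``delta_name`` selects which fractional electrical distance of the
    parameter set applies (``delta_b`` for the blocker, ``delta_ca`` for
    Ca2+), ``valence_name`` the matching charge (``z_b`` / ``z_ca``).
    """

    delta_name: Literal["delta_b", "delta_ca"]
    valence_name: Literal["z_b", "z_ca"]
    direction: Direction

    def __post_init__(self) -> None:
        if self.delta_name not in ("delta_b", "delta_ca"):
            raise InvalidArgumentError(f"unknown delta {self.delta_name!r}")
        if self.valence_name not in ("z_b", "z_ca"):
            raise InvalidArgumentError(f"unknown valence {self.valence_name!r}")
        if self.direction not in ("forward", "backward"):
            raise InvalidArgumentError(f"unknown direction {self.direction!r}")


@dataclass(frozen=True)
class TransitionSpec:
    """One directed transition of a kinetic scheme.

    ``ligand`` states whether the rate constant is multiplied by the
    molar Ca2+ concentration (``"calcium"``), the molar blocker
    concentration (``"blocker"``), or neither (``"none"``).
    """

    from_state: int
    to_state: int
    rate_name: str
    ligand: Literal["none", "calcium", "blocker"] = "none"
    voltage: VoltageDependence | None = None

    def __post_init__(self) -> None:
        if self.from_state == self.to_state:
            raise InvalidArgumentError("self-transitions are not allowed")
        if self.from_state < 0 or self.to_state < 0:
            raise InvalidArgumentError("state indices must be non-negative")
        if self.ligand not in ("none", "calcium", "blocker"):
            raise InvalidArgumentError(f"unknown ligand {self.ligand!r}")


@dataclass(frozen=True)
class MechanismSpec:
    """A kinetic scheme: states, transitions, and which states conduct.

    The transition graph must form a single connected component so that
    a unique stationary distribution exists at generic conditions, and
    the conducting and blocked state sets must be disjoint.
    """

    name: str
    n_states: int
    transitions: tuple[TransitionSpec, ...]
    conducting_states: frozenset[int]
    blocked_states: frozenset[int] = frozenset()

    def __init__(
        self,
        name: str,
        n_states: int,
        transitions: Iterable[TransitionSpec],
        conducting_states: Iterable[int],
        blocked_states: Iterable[int] = (),
    ) -> None:
        object.__setattr__(self, "name", name)
        object.__setattr__(self, "n_states", int(n_states))
        object.__setattr__(self, "transitions", tuple(transitions))
        object.__setattr__(self, "conducting_states", frozenset(conducting_states))
        object.__setattr__(self, "blocked_states", frozenset(blocked_states))
        self._validate()

    def _validate(self) -> None:
        if self.n_states < 2:
            raise InvalidArgumentError("a mechanism needs at least two states")
        for t in self.transitions:
            if t.from_state >= self.n_states or t.to_state >= self.n_states:
                raise InvalidArgumentError(
                    f"transition {t.rate_name} references a state >= n_states"
                )
        for s in self.conducting_states | self.blocked_states:
            if not 0 <= s < self.n_states:
                raise InvalidArgumentError("conducting/blocked state out of range")
        if self.conducting_states & self.blocked_states:
            raise InvalidArgumentError("conducting and blocked states overlap")
        # undirected connectivity: every state reachable in the transition graph
        adj: list[set[int]] = [set() for _ in range(self.n_states)]
        for t in self.transitions:
            adj[t.from_state].add(t.to_state)
            adj[t.to_state].add(t.from_state)
        seen = {0}
        stack = [0]
        while stack:
            for nb in adj[stack.pop()]:
                if nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        if len(seen) != self.n_states:
            raise InvalidArgumentError(
                f"mechanism {self.name!r}: transition graph is not connected"
            )

    @property
    def rate_names(self) -> set[str]:
        return {t.rate_name for t in self.transitions}

    def to_json(self) -> str:
        """Serialise the scheme to the package's JSON config layout."""
        doc = {
            "name": self.name,
            "n_states": self.n_states,
            "transitions": [
                {
                    "from": t.from_state,
                    "to": t.to_state,
                    "rate": t.rate_name,
                    "ligand": t.ligand,
                    **(
                        {
                            "voltage": {
                                "delta": t.voltage.delta_name,
                                "valence": t.voltage.valence_name,
                                "direction": t.voltage.direction,
                            }
                        }
                        if t.voltage is not None
                        else {}
                    ),
                }
                for t in self.transitions
            ],
            "conducting": sorted(self.conducting_states),
            "blocked": sorted(self.blocked_states),
        }
        return json.dumps(doc, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "MechanismSpec":
        doc = json.loads(text)
        transitions = []
        for t in doc["transitions"]:
            volt = None
            if "voltage" in t and t["voltage"] is not None:
                v = t["voltage"]
                volt = VoltageDependence(v["delta"], v["valence"], v["direction"])
            transitions.append(
                TransitionSpec(t["from"], t["to"], t["rate"], t.get("ligand", "none"), volt)
            )
        return cls(
            name=doc["name"],
            n_states=doc["n_states"],
            transitions=transitions,
            conducting_states=doc["conducting"],
            blocked_states=doc.get("blocked", ()),
        )


@dataclass
class ParameterSet:
    """Numeric values for a mechanism: rate constants plus the voltage
    partitioning parameters.

    Rates are s^-1 for unimolecular transitions and M^-1 s^-1 for
    ligand-multiplied ones.  ``delta_b`` and ``delta_ca`` are fractions
    of the membrane field in [0, 1]; ``z_b`` and ``z_ca`` the signed
    valences of blocker and Ca2+.
    """

    rates: dict[str, float]
    delta_b: float = 0.0
    delta_ca: float = 0.0
    z_b: float = -1.0
    z_ca: float = 2.0

    def __post_init__(self) -> None:
        for name, value in self.rates.items():
            if not (math.isfinite(value) and value > 0):
                raise InvalidArgumentError(f"rate {name!r} must be finite and > 0")
        for dname in ("delta_b", "delta_ca"):
            d = getattr(self, dname)
            if not 0.0 <= d <= 1.0:
                raise InvalidArgumentError(f"{dname} must lie in [0, 1]")

    def delta(self, name: str) -> float:
        return getattr(self, name)

    def valence(self, name: str) -> float:
        return getattr(self, name)

    def replace(self, **changes) -> "ParameterSet":
        """A copy with rates and/or scalar fields replaced."""
        rates = dict(self.rates)
        rates.update(changes.pop("rates", {}))
        fields = {
            "delta_b": self.delta_b,
            "delta_ca": self.delta_ca,
            "z_b": self.z_b,
            "z_ca": self.z_ca,
        }
        fields.update(changes)
        return ParameterSet(rates=rates, **fields)

    def to_json(self) -> str:
        doc = {
            "rates": self.rates,
            "delta_b": self.delta_b,
            "delta_ca": self.delta_ca,
            "z_b": self.z_b,
            "z_ca": self.z_ca,
            "units": {
                "rates": "s^-1 (unimolecular) or M^-1 s^-1 (ligand-multiplied)",
                "delta_b": "fraction of membrane field, dimensionless",
                "delta_ca": "fraction of membrane field, dimensionless",
                "z_b": "elementary charges",
                "z_ca": "elementary charges",
            },
        }
        return json.dumps(doc, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "ParameterSet":
        doc = json.loads(text)
        return cls(
            rates={k: float(v) for k, v in doc["rates"].items()},
            delta_b=float(doc.get("delta_b", 0.0)),
            delta_ca=float(doc.get("delta_ca", 0.0)),
            z_b=float(doc.get("z_b", -1.0)),
            z_ca=float(doc.get("z_ca", 2.0)),
        )


@dataclass(frozen=True)
class Conditions:
    """Experimental conditions at which a rate matrix is evaluated.

    Voltage in volts, ligand concentrations in molar, temperature in
    kelvin.  The human-facing interfaces speak mV and uM; conversion
    happens at that boundary only.
    """

    voltage: float = 0.0
    calcium: float = 0.0
    blocker: float = 0.0
    temperature: float = DEFAULT_TEMPERATURE

    def __post_init__(self) -> None:
        if self.calcium < 0:
            raise InvalidArgumentError("calcium concentration must be >= 0")
        if self.blocker < 0:
            raise InvalidArgumentError("blocker concentration must be >= 0")
        if not self.temperature > 0:
            raise InvalidArgumentError("temperature must be > 0")


@dataclass(frozen=True)
class RateMatrix:
    """Evaluated generator of the chain: off-diagonal entry (i, j) is
    the i -> j transition rate, diagonals close each row to zero."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        q = np.asarray(self.matrix, dtype=float)
        if q.ndim != 2 or q.shape[0] != q.shape[1]:
            raise InvalidArgumentError("rate matrix must be square")
        off = q - np.diag(np.diag(q))
        if np.any(off < 0):
            raise InvalidArgumentError("off-diagonal rates must be >= 0")
        scale = max(1.0, float(np.abs(q).max()))
        if np.any(np.abs(q.sum(axis=1)) > 1e-12 * scale):
            raise InvalidArgumentError("rate-matrix rows must sum to zero")
        object.__setattr__(self, "matrix", q)

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    def __array__(self, dtype=None, copy=None):
        return np.asarray(self.matrix, dtype=dtype)


def build_rate_matrix(
    spec: MechanismSpec, params: ParameterSet, cond: Conditions
) -> RateMatrix:
    """Evaluate a mechanism into a numeric generator at given conditions.

    Each transition contributes ``k * [ligand concentration] *
    v**(delta/2)`` to its off-diagonal entry; the diagonal is the
    negative row sum, so every row of the result sums to zero.
    """
    missing = spec.rate_names - set(params.rates)
    if missing:
        raise ConfigurationError(
            f"mechanism {spec.name!r} needs values for rates: {sorted(missing)}"
        )
    q = np.zeros((spec.n_states, spec.n_states))
    for t in spec.transitions:
        rate = params.rates[t.rate_name]
        if t.ligand == "calcium":
            rate *= cond.calcium
        elif t.ligand == "blocker":
            rate *= cond.blocker
        if t.voltage is not None:
            v = voltage_factor(
                params.valence(t.voltage.valence_name),
                cond.voltage,
                cond.temperature,
                t.voltage.direction,
            )
            rate *= v ** (params.delta(t.voltage.delta_name) / 2.0)
        q[t.from_state, t.to_state] += rate
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    return RateMatrix(q)


def _gating_core(k24_voltage: bool) -> list[TransitionSpec]:
    """The shared 7-state Ca2+ gating core (states 0..6; 0 is open).

    Ca2+ binding accelerates the 4->2, 5->3 and 6->5 steps; their
    reverses and the 3->5, 5->6 steps carry the Ca2+ voltage factor.
    The printed scheme leaves the 2->4 step without a voltage factor
    even though its reverse carries one; ``k24_voltage=True`` attaches
    the symmetric forward factor for users who prefer the balanced form.
    """
    fwd_ca = VoltageDependence("delta_ca", "z_ca", "forward")
    bwd_ca = VoltageDependence("delta_ca", "z_ca", "backward")
    return [
        TransitionSpec(0, 1, "k01"),
        TransitionSpec(1, 0, "k10"),
        TransitionSpec(1, 2, "k12"),
        TransitionSpec(2, 1, "k21"),
        TransitionSpec(2, 3, "k23"),
        TransitionSpec(3, 2, "k32"),
        TransitionSpec(2, 4, "k24", voltage=fwd_ca if k24_voltage else None),
        TransitionSpec(4, 2, "k42", ligand="calcium", voltage=bwd_ca),
        TransitionSpec(3, 5, "k35", voltage=fwd_ca),
        TransitionSpec(5, 3, "k53", ligand="calcium", voltage=bwd_ca),
        TransitionSpec(4, 5, "k45"),
        TransitionSpec(5, 4, "k54"),
        TransitionSpec(5, 6, "k56", voltage=fwd_ca),
        TransitionSpec(6, 5, "k65", ligand="calcium", voltage=bwd_ca),
    ]


def packaged_mechanism(which: str, k24_voltage: bool = False) -> MechanismSpec:
    """Return one of the two packaged blocker mechanisms.

    ``"open_block"``: 8 states, blocker binds the open state 0 (dead-end
    state 7).  ``"closed_antagonism"``: 10 states, blocker binds closed
    states 3, 5, 6 (dead-end states 7, 8, 9).  ``k24_voltage`` attaches
    the otherwise-absent forward Ca2+ voltage factor to the 2->4 step.
    """
    fwd_b = VoltageDependence("delta_b", "z_b", "forward")
    bwd_b = VoltageDependence("delta_b", "z_b", "backward")
    core = _gating_core(k24_voltage)
    if which == "open_block":
        transitions = core + [
            TransitionSpec(0, 7, "k07", ligand="blocker", voltage=fwd_b),
            TransitionSpec(7, 0, "k70", voltage=bwd_b),
        ]
        return MechanismSpec(
            name="open_block",
            n_states=8,
            transitions=transitions,
            conducting_states={0},
            blocked_states={7},
        )
    if which == "closed_antagonism":
        transitions = core + [
            TransitionSpec(3, 7, "k37", ligand="blocker", voltage=fwd_b),
            TransitionSpec(7, 3, "k73", voltage=bwd_b),
            TransitionSpec(5, 8, "k58", ligand="blocker", voltage=fwd_b),
            TransitionSpec(8, 5, "k85", voltage=bwd_b),
            TransitionSpec(6, 9, "k69", ligand="blocker", voltage=fwd_b),
            TransitionSpec(9, 6, "k96", voltage=bwd_b),
        ]
        return MechanismSpec(
            name="closed_antagonism",
            n_states=10,
            transitions=transitions,
            conducting_states={0},
            blocked_states={7, 8, 9},
        )
    raise InvalidArgumentError(f"unknown mechanism {which!r}")
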