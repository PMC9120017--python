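"""Dose-response analysis: mechanism-derived concentration-response
curves, Hill fits, IC50-voltage profiles, and the voltage dependence of
the blocker dissociation constant.

For an open-channel blocker appended as a dead-end state to the open
state, the steady-state normalized current is exactly

    I / I0 = 1 / (1 + b * P_open / K_d(V)),

so the half-inhibition concentration is IC50 = K_d(V) / P_open(V, x)
with Hill coefficient 1: the apparent potency rises with the open
probability set by Ca2+ and voltage, while K_d itself only carries the
exp(delta_b * z_b * V F / RT) field dependence of the binding step.
The functions below nonetheless compute every curve from equilibrium
occupancies of the full mechanism, so they remain valid for arbitrary
schemes (e.g. closed-state antagonism) where no such closed form holds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .constants import DEFAULT_TEMPERATURE, FARADAY, GAS_CONSTANT
from .errors import InvalidArgumentError
from .fitting import FitResult, fit, _activation_model, _inhibition_model
from .mechanism import Conditions, MechanismSpec, ParameterSet

__all__ = [
    "HillFit",
    "DoseResponseCurve",
    "block_response",
    "ca_activation",
    "hill_fit",
    "hill_curve",
    "ic50_voltage_profile",
    "kd_at_voltage",
    "default_blocker_grid",
]


def default_blocker_grid(n: int = 12, lo: float = 1e-7, hi: float = 1e-4) -> np.ndarray:
    """Log-spaced blocker concentrations, default 0.1-100 uM."""
    return np.logspace(math.log10(lo), math.log10(hi), n)


@dataclass(frozen=True)
class DoseResponseCurve:
    """Normalized response vs ligand concentration at fixed voltage/Ca2+."""

    concentrations: np.ndarray
    response: np.ndarray
    voltage: float
    calcium: float

    def __post_init__(self) -> None:
        c = np.asarray(self.concentrations, dtype=float)
        r = np.asarray(self.response, dtype=float)
        if c.shape != r.shape or c.ndim != 1:
            raise InvalidArgumentError("concentration and response shapes differ")
        if np.any(np.diff(c) <= 0):
            raise InvalidArgumentError("concentrations must be strictly increasing")
        object.__setattr__(self, "concentrations", c)
        object.__setattr__(self, "response", r)


@dataclass
class HillFit:
    """Hill-equation fit: half-maximal concentration and steepness."""

    ic50: float
    hill_h: float
    residual_ssq: float
    ci95_ic50: tuple[float, float]
    ci95_h: tuple[float, float]
    direction: str = "inhibition"
    flags: list[str] = field(default_factory=list)


def hill_curve(
    conc: np.ndarray, ic50: float, h: float, direction: str = "inhibition"
) -> np.ndarray:
    """Hill equation response; ``"activation"`` rises to 1 with
    concentration, ``"inhibition"`` is its mirror falling from 1."""
    conc = np.asarray(conc, dtype=float)
    with np.errstate(divide="ignore"):
        act = 1.0 / (1.0 + (ic50 / np.where(conc > 0, conc, np.nan)) ** h)
    act = np.where(conc > 0, act, 0.0)
    return 1.0 - act if direction == "inhibition" else act


def block_response(
    spec: MechanismSpec,
    params: ParameterSet,
    cond_base: Conditions,
    blocker_grid: np.ndarray | None = None,
) -> DoseResponseCurve:
    """Steady-state block concentration-response from equilibrium
    occupancies, normalized to the blocker-free open probability."""
    grid = default_blocker_grid() if blocker_grid is None else np.asarray(
        blocker_grid, dtype=float
    )
    if np.any(grid < 0):
        raise InvalidArgumentError("blocker concentrations must be >= 0")
    resp = _inhibition_model(spec, params, cond_base, grid)
    return DoseResponseCurve(
        concentrations=grid,
        response=resp,
        voltage=cond_base.voltage,
        calcium=cond_base.calcium,
    )


def ca_activation(
    spec: MechanismSpec,
    params: ParameterSet,
    voltage: float,
    ca_grid: np.ndarray,
    temperature: float = DEFAULT_TEMPERATURE,
) -> DoseResponseCurve:
    """Absolute equilibrium open probability vs Ca2+ (blocker-free)."""
    grid = np.asarray(ca_grid, dtype=float)
    cond = Conditions(voltage=voltage, calcium=0.0, blocker=0.0, temperature=temperature)
    resp = _activation_model(spec, params, cond, grid)
    return DoseResponseCurve(
        concentrations=grid, response=resp, voltage=voltage, calcium=np.nan
    )


def _initial_ic50(conc: np.ndarray, resp: np.ndarray, direction: str) -> float:
    """Log-linear interpolation of the half-response crossing."""
    half = 0.5 * (resp.max() + resp.min())
    r = resp if direction == "activation" else -resp
    target = half if direction == "activation" else -half
    for i in range(len(conc) - 1):
        lo, hi = r[i], r[i + 1]
        if (lo - target) * (hi - target) <= 0 and hi != lo:
            f = (target - lo) / (hi - lo)
            return float(
                10 ** (np.log10(conc[i]) + f * (np.log10(conc[i + 1]) - np.log10(conc[i])))
            )
    return float(np.sqrt(conc[0] * conc[-1]))


def hill_fit(curve: DoseResponseCurve, direction: str = "inhibition") -> HillFit:
    """Least-squares Hill fit of a dose-response curve.

    Initialisation takes IC50 from the log-interpolated half-response
    crossing and h = 1; IC50 is bounded two decades beyond the sampled
    grid and h within (0, 10].  Curves whose response spans less than
    0.2 are fitted anyway but flagged as poorly determined.
    """
    if direction not in ("inhibition", "activation"):
        raise InvalidArgumentError(f"unknown direction {direction!r}")
    conc = curve.concentrations
    resp = curve.response
    mask = conc > 0
    if mask.sum() < 4:
        raise InvalidArgumentError("need at least 4 positive concentrations")
    conc, resp = conc[mask], resp[mask]

    flags = []
    if resp.max() - resp.min() < 0.2:
        flags.append("poorly-determined: response spans < 0.2 over the grid")

    def residual(p):
        return hill_curve(conc, p["ic50"], p["h"], direction) - resp

    result: FitResult = fit(
        residual,
        init={"ic50": _initial_ic50(conc, resp, direction), "h": 1.0},
        bounds={"ic50": (conc.min() / 100, conc.max() * 100), "h": (1e-6, 10.0)},
        transforms={"ic50": "log", "h": "linear"},
    )
    return HillFit(
        ic50=result.estimates["ic50"],
        hill_h=result.estimates["h"],
        residual_ssq=result.ssq,
        ci95_ic50=result.ci95["ic50"],
        ci95_h=result.ci95["h"],
        direction=direction,
        flags=flags + result.flags,
    )


def ic50_voltage_profile(
    spec: MechanismSpec,
    params: ParameterSet,
    calcium: float,
    voltages: np.ndarray,
    blocker_grid: np.ndarray | None = None,
    temperature: float = DEFAULT_TEMPERATURE,
) -> list[tuple[float, HillFit | None]]:
    """Hill-fitted IC50 at each voltage; per-voltage failures are
    reported as ``None`` and the profile continues."""
    out: list[tuple[float, HillFit | None]] = []
    for v in np.asarray(voltages, dtype=float):
        cond = Conditions(
            voltage=float(v), calcium=calcium, blocker=0.0, temperature=temperature
        )
        try:
            curve = block_response(spec, params, cond, blocker_grid)
            out.append((float(v), hill_fit(curve, "inhibition")))
        except Exception:  # noqa: BLE001 - profile robustness
            out.append((float(v), None))
    return out


def kd_at_voltage(
    kd0: float,
    delta_b: float,
    z_b: float,
    voltage: float,
    temperature: float = DEFAULT_TEMPERATURE,
) -> float:
    """Blocker dissociation constant at a given voltage.

    The binding step senses the fraction ``delta_b`` of the field, so
    K_d(V) = K_d(0) * exp(delta_b * z_b * V F / (R T)).
    """
    if kd0 <= 0:
        raise InvalidArgumentError("kd0 must be > 0")
    return kd0 * math.exp(
        delta_b * z_b * voltage * FARADAY / (GAS_CONSTANT * temperature)
    )
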