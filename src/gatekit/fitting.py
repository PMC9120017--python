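"""Shared least-squares machinery: composite objectives, bound-constrained
fits, Jacobian-based 95% confidence intervals, and error propagation.

All model fits in the package funnel through :func:`fit`, a thin wrapper
around ``scipy.optimize.least_squares`` that adds per-parameter bounds
and transforms (rate constants are optimised on a log scale so they stay
positive; electrical-distance fractions on a linear [0, 1] scale) and
linearised confidence intervals: with J the Jacobian at the optimum,
s^2 = ssq / (n_obs - n_free) and Cov = s^2 (J^T J)^-1, the 95% interval
of each parameter is estimate +- t_{0.975, dof} * stderr.  Intervals of
log-transformed parameters are formed on the log scale and mapped back,
which keeps them positive and containing the estimate.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from typing import Callable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import DegenerateConditionError, FitFailureError, InvalidArgumentError
from .mechanism import Conditions, MechanismSpec, ParameterSet, build_rate_matrix
from .solver import equilibrium, open_probability

__all__ = [
    "FitResult",
    "DataBlock",
    "CompositeDataset",
    "composite_ssq",
    "composite_residuals",
    "fit",
    "fit_block_mechanism",
    "propagate_error",
    "apply_block_params",
]

_PENALTY_RESIDUAL = 1e3  # per-observation residual when the solver fails


@dataclass
class FitResult:
    """Point estimates with linearised 95% confidence intervals."""

    estimates: dict[str, float]
    ci95: dict[str, tuple[float, float]]
    stderr: dict[str, float]
    ssq: float
    n_obs: int
    n_free: int
    converged: bool
    flags: list[str] = field(default_factory=list)
    seed_metadata: dict = field(default_factory=dict)

    def to_json(self) -> str:
        doc = {
            "estimates": self.estimates,
            "ci95": {k: list(v) for k, v in self.ci95.items()},
            "stderr": self.stderr,
            "ssq": self.ssq,
            "n_obs": self.n_obs,
            "n_free": self.n_free,
            "converged": self.converged,
            "flags": self.flags,
            "seed_metadata": self.seed_metadata,
        }
        doc["config_hash"] = hashlib.sha256(
            json.dumps(doc, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]
        return json.dumps(doc, indent=1, default=str)


@dataclass
class DataBlock:
    """One homogeneous slice of a composite dataset.

    ``kind`` is ``"inhibition"`` (normalized current vs blocker),
    ``"ca_activation"`` (absolute open probability vs Ca2+), or ``"iv"``
    (current vs voltage).  ``table`` holds one row per observation in
    the CSV dialect of the producing module; ``conditions`` tags the
    block with the held-fixed voltage / Ca2+.
    """

    kind: Literal["inhibition", "ca_activation", "iv"]
    conditions: Conditions
    table: pd.DataFrame

    def __post_init__(self) -> None:
        if self.kind not in ("inhibition", "ca_activation", "iv"):
            raise InvalidArgumentError(f"unknown block kind {self.kind!r}")
        if len(self.table) == 0:
            raise InvalidArgumentError("data block is empty")


@dataclass
class CompositeDataset:
    blocks: list[DataBlock]

    @property
    def n_obs(self) -> int:
        return sum(len(b.table) for b in self.blocks)


def _inhibition_model(
    spec: MechanismSpec, params: ParameterSet, cond: Conditions, concs: np.ndarray
) -> np.ndarray:
    """Equilibrium open probability at each blocker concentration,
    normalised by the blocker-free value."""
    ref = open_probability(
        equilibrium(build_rate_matrix(spec, params, _with(cond, blocker=0.0))), spec
    )
    if ref <= 1e-12:
        raise DegenerateConditionError("open probability is zero without blocker")
    out = np.empty(len(concs))
    for i, b in enumerate(concs):
        p = equilibrium(build_rate_matrix(spec, params, _with(cond, blocker=float(b))))
        out[i] = open_probability(p, spec) / ref
    return out


def _activation_model(
    spec: MechanismSpec, params: ParameterSet, cond: Conditions, concs: np.ndarray
) -> np.ndarray:
    out = np.empty(len(concs))
    for i, x in enumerate(concs):
        p = equilibrium(build_rate_matrix(spec, params, _with(cond, calcium=float(x))))
        out[i] = open_probability(p, spec)
    return out


def _with(cond: Conditions, **changes) -> Conditions:
    base = {
        "voltage": cond.voltage,
        "calcium": cond.calcium,
        "blocker": cond.blocker,
        "temperature": cond.temperature,
    }
    base.update(changes)
    return Conditions(**base)


def composite_residuals(
    params: ParameterSet,
    data: CompositeDataset,
    spec: MechanismSpec,
    flags: list[str] | None = None,
) -> np.ndarray:
    """(model - observation) over every observation of every block.

    A solver failure in any block does not abort the evaluation: the
    affected observations contribute a large constant residual and a
    flag is recorded, which keeps optimisers alive near bad corners of
    parameter space.
    """
    from .permeation import iv_current  # local import avoids a cycle

    residuals: list[np.ndarray] = []
    for block in data.blocks:
        try:
            if block.kind == "inhibition":
                concs = block.table["conc_molar"].to_numpy()
                uniq, inv = np.unique(concs, return_inverse=True)
                model = _inhibition_model(spec, params, block.conditions, uniq)[inv]
                obs = block.table["response"].to_numpy()
            elif block.kind == "ca_activation":
                concs = block.table["conc_molar"].to_numpy()
                uniq, inv = np.unique(concs, return_inverse=True)
                model = _activation_model(spec, params, block.conditions, uniq)[inv]
                obs = block.table["response"].to_numpy()
            else:  # iv
                volts = block.table["voltage_v"].to_numpy()
                pp = block.table.attrs["permeation_params"]
                model = np.array([iv_current(pp, v) for v in volts])
                obs = block.table["current"].to_numpy()
            residuals.append(model - obs)
        except Exception as exc:  # noqa: BLE001 - penalty path must be broad
            if flags is not None:
                flags.append(f"{block.kind} block failed: {exc}")
            residuals.append(np.full(len(block.table), _PENALTY_RESIDUAL))
    return np.concatenate(residuals)


def composite_ssq(
    params: ParameterSet,
    data: CompositeDataset,
    spec: MechanismSpec,
    flags: list[str] | None = None,
) -> float:
    """Unweighted total sum of squared deviations over all blocks."""
    r = composite_residuals(params, data, spec, flags)
    return float(np.dot(r, r))


def fit(
    residual_fn: Callable[[Mapping[str, float]], np.ndarray],
    init: Mapping[str, float],
    bounds: Mapping[str, tuple[float, float]] | None = None,
    transforms: Mapping[str, Literal["linear", "log"]] | None = None,
    restarts: int = 0,
    restart_seed: int = 0,
    seed_metadata: Mapping | None = None,
) -> FitResult:
    """Bound-constrained least squares with Jacobian 95% CIs.

    ``residual_fn`` maps a name -> value dict to a residual vector.
    ``transforms`` selects the internal scale per parameter (``"log"``
    for positive quantities).  ``restarts > 0`` re-runs the optimiser
    from seeded, jittered initial points and keeps the best optimum.
    The whole procedure is deterministic for identical inputs.
    """
    names = list(init)
    bounds = dict(bounds or {})
    transforms = dict(transforms or {})

    def to_internal(name: str, value: float) -> float:
        if transforms.get(name) == "log":
            if value <= 0:
                raise InvalidArgumentError(f"{name} must be > 0 for log transform")
            return math.log(value)
        return value

    def to_natural(name: str, value: float) -> float:
        return math.exp(value) if transforms.get(name) == "log" else value

    x0 = np.array([to_internal(n, init[n]) for n in names])
    lo = np.array(
        [to_internal(n, bounds[n][0]) if n in bounds else -np.inf for n in names]
    )
    hi = np.array(
        [to_internal(n, bounds[n][1]) if n in bounds else np.inf for n in names]
    )
    if np.any(x0 < lo) or np.any(x0 > hi):
        raise InvalidArgumentError("initial values must lie within bounds")

    def wrapped(x: np.ndarray) -> np.ndarray:
        params = {n: to_natural(n, xi) for n, xi in zip(names, x)}
        return np.asarray(residual_fn(params), dtype=float)

    starts = [x0]
    if restarts > 0:
        rng = np.random.default_rng(restart_seed)
        span = np.where(np.isfinite(hi - lo), hi - lo, 2.0)
        for _ in range(restarts):
            jitter = rng.uniform(-0.1, 0.1, size=len(names)) * span
            starts.append(np.clip(x0 + jitter, lo, hi))

    best = None
    for start in starts:
        try:
            res = optimize.least_squares(wrapped, start, bounds=(lo, hi))
        except Exception:  # a single bad start must not kill the fit
            continue
        if res.success and (best is None or res.cost < best.cost):
            best = res
    if best is None:
        raise FitFailureError("least-squares optimisation did not converge")

    n_obs = len(best.fun)
    n_free = len(names)
    ssq = float(np.dot(best.fun, best.fun))
    flags: list[str] = []
    dof = n_obs - n_free
    internal_se = np.full(n_free, np.nan)
    if dof <= 0:
        flags.append("no residual degrees of freedom; CIs unavailable")
    else:
        jtj = best.jac.T @ best.jac
        s2 = ssq / dof
        try:
            cond_num = np.linalg.cond(jtj)
            if not np.isfinite(cond_num) or cond_num > 1e12:
                raise np.linalg.LinAlgError("ill-conditioned J^T J")
            cov = s2 * np.linalg.inv(jtj)
            internal_se = np.sqrt(np.maximum(np.diag(cov), 0.0))
        except np.linalg.LinAlgError:
            flags.append("singular J^T J: parameter(s) unidentifiable, CI unbounded")
            internal_se = np.full(n_free, np.inf)

    tq = stats.t.ppf(0.975, dof) if dof > 0 else np.inf
    estimates, ci95, stderr = {}, {}, {}
    for i, n in enumerate(names):
        est_internal = best.x[i]
        est = to_natural(n, est_internal)
        estimates[n] = est
        se_i = internal_se[i]
        if not np.isfinite(se_i):
            ci95[n] = (-np.inf, np.inf) if transforms.get(n) != "log" else (0.0, np.inf)
            stderr[n] = np.inf
            continue
        lo_i, hi_i = est_internal - tq * se_i, est_internal + tq * se_i
        ci95[n] = (to_natural(n, lo_i), to_natural(n, hi_i))
        # report stderr on the natural scale (delta method for log params)
        stderr[n] = se_i * (est if transforms.get(n) == "log" else 1.0)

    return FitResult(
        estimates=estimates,
        ci95=ci95,
        stderr=stderr,
        ssq=ssq,
        n_obs=n_obs,
        n_free=n_free,
        converged=True,
        flags=flags,
        seed_metadata=dict(seed_metadata or {}),
    )


def apply_block_params(
    base: ParameterSet, values: Mapping[str, float]
) -> ParameterSet:
    """Map high-level blocker parameters onto a mechanism parameter set.

    ``kd_1pbc`` (molar, at 0 mV) sets the blocker off-rate through
    k70 = Kd * k07 with the on-rate k07 held fixed; ``delta_b`` /
    ``delta_ca`` set the electrical distances; any other name is taken
    as a rate constant.
    """
    rates: dict[str, float] = {}
    fields: dict[str, float] = {}
    for name, value in values.items():
        if name == "kd_1pbc":
            rates["k70"] = value * base.rates["k07"]
        elif name in ("delta_b", "delta_ca", "z_b", "z_ca"):
            fields[name] = value
        else:
            rates[name] = value
    return base.replace(rates=rates, **fields)


def fit_block_mechanism(
    data: CompositeDataset,
    spec: MechanismSpec,
    base_params: ParameterSet,
    free: Sequence[str] = ("kd_1pbc", "delta_b"),
    init: Mapping[str, float] | None = None,
    restarts: int = 0,
    restart_seed: int = 0,
    seed_metadata: Mapping | None = None,
) -> FitResult:
    """Global fit of a blocker mechanism to a composite dataset.

    By default only the blocker dissociation constant at 0 mV and its
    apparent electrical distance are free while the gating rates stay at
    their calibrated values (two-stage logic: gating characterised
    separately, block parameters estimated here).  Passing rate names in
    ``free`` unlocks joint fitting of gating constants.
    """
    defaults = {
        "kd_1pbc": base_params.rates["k70"] / base_params.rates["k07"],
        "delta_b": base_params.delta_b,
        "delta_ca": base_params.delta_ca,
    }
    init = dict(init or {})
    start, bounds, transforms = {}, {}, {}
    for name in free:
        if name in ("delta_b", "delta_ca"):
            start[name] = init.get(name, defaults[name])
            bounds[name] = (0.0, 1.0)
            transforms[name] = "linear"
        elif name == "kd_1pbc":
            start[name] = init.get(name, defaults["kd_1pbc"])
            bounds[name] = (1e-12, 1.0)
            transforms[name] = "log"
        else:
            start[name] = init.get(name, base_params.rates[name])
            bounds[name] = (start[name] * 1e-6, start[name] * 1e6)
            transforms[name] = "log"

    flags: list[str] = []

    def residual_fn(values: Mapping[str, float]) -> np.ndarray:
        params = apply_block_params(base_params, values)
        return composite_residuals(params, data, spec, flags)

    result = fit(
        residual_fn,
        init=start,
        bounds=bounds,
        transforms=transforms,
        restarts=restarts,
        restart_seed=restart_seed,
        seed_metadata=seed_metadata,
    )
    result.flags.extend(sorted(set(flags)))
    return result


def propagate_error(
    op: Literal["sum", "difference", "product", "quotient"],
    a: float,
    sa: float,
    b: float,
    sb: float,
) -> float:
    """First-order propagation of standard errors through +, -, *, /.

    Sums and differences combine in quadrature; products and quotients
    combine the relative errors in quadrature and scale by |f(a, b)|.
    """
    if sa < 0 or sb < 0:
        raise InvalidArgumentError("standard errors must be >= 0")
    if op in ("sum", "difference"):
        return math.hypot(sa, sb)
    if op in ("product", "quotient"):
        if a == 0 or b == 0:
            raise InvalidArgumentError(
                "relative-error propagation is undefined at a = 0 or b = 0"
            )
        f = a * b if op == "product" else a / b
        return abs(f) * math.hypot(sa / abs(a), sb / abs(b))
    raise InvalidArgumentError(f"unknown operation {op!r}")
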