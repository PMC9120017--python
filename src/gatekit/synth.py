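"""Seeded generators of synthetic patch-clamp datasets.

Raw inside-out patch recordings behind the published dose-response and
I-V figures are not available as numeric tables, so every analysis stage
here is exercised on synthetic stand-ins: mechanism-derived mean curves
with additive Gaussian replicate noise on the normalized response and,
optionally, a multiplicative per-sweep rundown drift.  Every generator
is a pure function of its inputs and a seed.

The packaged gating calibration plays the role of the separately
characterised activation mechanism whose rate constants are held fixed
while blocker parameters are estimated.  Its defining property, checked
at build time, is an open probability of 0.90 at 2 uM Ca2+ and 0 mV
(the value forced by consistency of a 3.6 uM dissociation constant with
a ~4 uM half-inhibition concentration through IC50 = K_d / P_open),
with P_open increasing in Ca2+ across the 0.1-15 uM range.  The planted
blocker truth used by recovery benchmarks is K_d(0 mV) = 3.6 uM with
apparent electrical distance 0.27 for a single negative charge.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd

from .block import default_blocker_grid
from .errors import ConfigurationError, InvalidArgumentError, RundownCorrectionError
from .fitting import CompositeDataset, DataBlock, _activation_model, _inhibition_model
from .mechanism import (
    Conditions,
    MechanismSpec,
    ParameterSet,
    build_rate_matrix,
    packaged_mechanism,
)
from .permeation import IVDataset, PermeationParams, iv_current
from .solver import equilibrium, occupancy_timecourse, open_probability

__all__ = [
    "NoiseModel",
    "BlockDesign",
    "default_calibration",
    "default_truth",
    "generate_block_dataset",
    "generate_iv_dataset",
    "generate_jump_trace",
    "correct_rundown",
    "KD0_TRUTH",
    "DELTA_B_TRUTH",
]

KD0_TRUTH = 3.6e-6
"""Planted blocker dissociation constant at 0 mV, molar."""

DELTA_B_TRUTH = 0.27
"""Planted fraction of the membrane field sensed by blocker binding."""

_CALIBRATION_POPEN = 0.90
_CALIBRATION_CA = 2e-6
_K07 = 1e8  # blocker on-rate, M^-1 s^-1 (diffusion-limited scale)

# Ca2+-gating rate constants (s^-1, or M^-1 s^-1 for Ca2+-multiplied
# steps).  Chosen to place the Ca2+ activation midpoint near 0.3 uM at
# 0 mV with pronounced voltage dependence, emulating a calcium-activated
# chloride channel; k10 is solved at build time (see default_calibration).
_GATING_RATES = {
    "k01": 150.0,
    "k12": 300.0,
    "k21": 600.0,
    "k23": 500.0,
    "k32": 2000.0,
    "k24": 120.0,
    "k42": 4e7,
    "k35": 60.0,
    "k53": 3e7,
    "k45": 100.0,
    "k54": 60.0,
    "k56": 50.0,
    "k65": 4e7,
}
_DELTA_CA = 0.30


@dataclass(frozen=True)
class NoiseModel:
    """Replicate noise structure of a synthetic experiment.

    ``sigma`` is the additive Gaussian SD on the normalized response
    (0.03 with 6 replicates yields an SEM near 0.012, comparable to
    published error bars); ``rundown_rate`` is the per-sweep fractional
    amplitude loss (0 disables rundown).
    """

    sigma: float = 0.03
    n_replicates: int = 6
    rundown_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise InvalidArgumentError("sigma must be >= 0")
        if self.n_replicates < 1:
            raise InvalidArgumentError("need at least one replicate")
        if not 0.0 <= self.rundown_rate < 1.0:
            raise InvalidArgumentError("rundown_rate must lie in [0, 1)")


@dataclass(frozen=True)
class BlockDesign:
    """Experimental design of a block concentration-response study.

    Defaults mirror the published design: Ca2+ at 400 nM, 800 nM and
    2 uM, voltages -80 and +80 mV, 12 log-spaced blocker concentrations
    from 0.1 to 100 uM.  ``ref_interval`` interleaves a blocker-free
    reference sweep every so many test sweeps (used by rundown
    correction); 0 disables references.
    """

    ca_levels: tuple[float, ...] = (400e-9, 800e-9, 2e-6)
    voltages: tuple[float, ...] = (-0.080, 0.080)
    blocker_grid: tuple[float, ...] = tuple(default_blocker_grid())
    temperature: float = 293.15
    ref_interval: int = 0


@lru_cache(maxsize=8)
def default_calibration(delta_ca: float = _DELTA_CA) -> ParameterSet:
    """The packaged gating + blocker parameter set.

    The closed->open rate k10 is solved exactly from the stationary
    weights of the closed sub-chain so that P_open(2 uM Ca2+, 0 mV) =
    0.90: with the open state connected to the rest through a single
    edge, stationary flux balance gives p0/p1 = k10/k01 while the
    relative weights among the closed states are independent of k10.
    """
    spec = packaged_mechanism("open_block")
    rates = dict(_GATING_RATES)
    rates["k10"] = 1000.0  # provisional; replaced by the solve below
    rates["k07"] = _K07
    rates["k70"] = KD0_TRUTH * _K07
    provisional = ParameterSet(
        rates=rates, delta_b=DELTA_B_TRUTH, delta_ca=delta_ca, z_b=-1.0, z_ca=2.0
    )
    cond = Conditions(voltage=0.0, calcium=_CALIBRATION_CA, blocker=0.0)
    p = np.asarray(equilibrium(build_rate_matrix(spec, provisional, cond)))
    w1 = p[1] / (1.0 - p[0])  # weight of state 1 within the closed sub-chain
    target = _CALIBRATION_POPEN
    k10 = target / (1.0 - target) * rates["k01"] / w1
    params = provisional.replace(rates={"k10": k10})
    check = open_probability(
        equilibrium(build_rate_matrix(spec, params, cond)),
        spec,
    )
    if abs(check - target) > 1e-3:
        raise ConfigurationError(
            f"calibration failed: P_open = {check:.6f}, expected {target}"
        )
    return params


def default_truth() -> dict[str, float]:
    """Planted ground-truth blocker parameters for recovery benchmarks."""
    return {"kd_1pbc": KD0_TRUTH, "delta_b": DELTA_B_TRUTH}


def generate_block_dataset(
    spec: MechanismSpec | None = None,
    params: ParameterSet | None = None,
    design: BlockDesign | None = None,
    noise: NoiseModel | None = None,
) -> CompositeDataset:
    """Synthetic block concentration-response study.

    One inhibition block per (Ca2+, voltage) condition.  Per replicate,
    each response is the equilibrium model mean, times the cumulative
    rundown factor ``(1 - rundown_rate)**sweep``, plus Gaussian noise.
    Tables carry columns conc_molar, response, replicate, sweep,
    is_reference; dataset-level provenance (seed, truth, design, noise)
    is stored in each table's ``attrs``.
    """
    spec = spec or packaged_mechanism("open_block")
    params = params or default_calibration()
    design = design or BlockDesign()
    noise = noise or NoiseModel()
    rng = np.random.default_rng(noise.seed)
    grid = np.asarray(design.blocker_grid, dtype=float)

    provenance = {
        "seed": noise.seed,
        "truth": {
            "kd_1pbc": params.rates.get("k70", np.nan)
            / params.rates.get("k07", np.nan),
            "delta_b": params.delta_b,
            "delta_ca": params.delta_ca,
        },
        "design": {
            "ca_levels": list(design.ca_levels),
            "voltages": list(design.voltages),
            "blocker_grid": list(grid),
        },
        "noise": {
            "sigma": noise.sigma,
            "n_replicates": noise.n_replicates,
            "rundown_rate": noise.rundown_rate,
        },
    }

    blocks = []
    for ca in design.ca_levels:
        for v in design.voltages:
            cond = Conditions(
                voltage=v, calcium=ca, blocker=0.0, temperature=design.temperature
            )
            mean = _inhibition_model(spec, params, cond, grid)
            rows = []
            for rep in range(noise.n_replicates):
                sweep = 0
                for i, b in enumerate(grid):
                    if design.ref_interval and i % design.ref_interval == 0:
                        ref = 1.0 * (1.0 - noise.rundown_rate) ** sweep
                        rows.append(
                            (0.0, ref + rng.normal(0.0, noise.sigma), rep, sweep, True)
                        )
                        sweep += 1
                    value = mean[i] * (1.0 - noise.rundown_rate) ** sweep
                    rows.append(
                        (b, value + rng.normal(0.0, noise.sigma), rep, sweep, False)
                    )
                    sweep += 1
            table = pd.DataFrame(
                rows,
                columns=["conc_molar", "response", "replicate", "sweep", "is_reference"],
            )
            table.attrs["provenance"] = provenance
            blocks.append(DataBlock(kind="inhibition", conditions=cond, table=table))
    return CompositeDataset(blocks=blocks)


def generate_ca_activation_blocks(
    spec: MechanismSpec | None = None,
    params: ParameterSet | None = None,
    ca_grid: np.ndarray | None = None,
    voltages: tuple[float, ...] = (-0.080, 0.080),
    noise: NoiseModel | None = None,
) -> CompositeDataset:
    """Synthetic Ca2+ activation study: absolute open probability vs
    Ca2+ at the given voltages, replicate noise as in the block study."""
    spec = spec or packaged_mechanism("open_block")
    params = params or default_calibration()
    noise = noise or NoiseModel()
    if ca_grid is None:
        ca_grid = np.logspace(-7.3, -4.8, 10)
    rng = np.random.default_rng(noise.seed)
    blocks = []
    for v in voltages:
        cond = Conditions(voltage=v, calcium=0.0, blocker=0.0)
        mean = _activation_model(spec, params, cond, ca_grid)
        rows = []
        for rep in range(noise.n_replicates):
            for x, m in zip(ca_grid, mean):
                rows.append((x, m + rng.normal(0.0, noise.sigma), rep))
        table = pd.DataFrame(rows, columns=["conc_molar", "response", "replicate"])
        blocks.append(DataBlock(kind="ca_activation", conditions=cond, table=table))
    return CompositeDataset(blocks=blocks)


def generate_iv_dataset(
    p: PermeationParams,
    voltages: np.ndarray | None = None,
    noise: NoiseModel | None = None,
) -> IVDataset:
    """Synthetic instantaneous I-V sweeps; the Gaussian noise SD is
    ``sigma`` times the largest model current magnitude."""
    noise = noise or NoiseModel()
    if voltages is None:
        voltages = np.arange(-0.100, 0.101, 0.020)
    voltages = np.asarray(voltages, dtype=float)
    rng = np.random.default_rng(noise.seed)
    mean = np.array([iv_current(p, v) for v in voltages])
    scale = np.abs(mean).max()
    rows = []
    for rep in range(noise.n_replicates):
        eps = rng.normal(0.0, noise.sigma * scale, size=len(voltages))
        for v, m, e in zip(voltages, mean, eps):
            rows.append((v, m + e, rep, np.nan))
    table = pd.DataFrame(rows, columns=["voltage_v", "current", "replicate", "ca_molar"])
    table.attrs["provenance"] = {
        "seed": noise.seed,
        "truth": {
            "sigma_h": p.sigma_h,
            "sigma_beta": p.sigma_beta,
            "amplitude": p.amplitude,
        },
        "noise": {"sigma": noise.sigma, "n_replicates": noise.n_replicates},
    }
    return IVDataset(table=table)


def generate_jump_trace(
    spec: MechanismSpec,
    params: ParameterSet,
    protocol: list[tuple[Conditions, float]],
    sample_dt: float,
    noise: NoiseModel | None = None,
) -> pd.DataFrame:
    """Simulated concentration-jump experiment.

    The occupancy starts at the equilibrium of the first segment's
    conditions; each subsequent segment relaxes spectrally under the
    rate matrix built at its own conditions from the occupancy reached
    at the end of the previous one.  Columns: time_s, state_0 ...
    state_{n-1}, p_open; Gaussian noise (if any) is added to the
    observable p_open only.
    """
    if not protocol:
        raise InvalidArgumentError("protocol must contain at least one segment")
    if sample_dt <= 0:
        raise InvalidArgumentError("sample_dt must be > 0")
    for _, duration in protocol:
        if duration <= 0:
            raise InvalidArgumentError("segment durations must be > 0")
    noise = noise or NoiseModel(sigma=0.0)
    rng = np.random.default_rng(noise.seed)

    p = np.asarray(equilibrium(build_rate_matrix(spec, params, protocol[0][0])))
    t_offset = 0.0
    records = []
    for cond, duration in protocol:
        q = build_rate_matrix(spec, params, cond)
        local_times = np.arange(0.0, duration, sample_dt)
        traj = occupancy_timecourse(q, p, np.append(local_times, duration))
        for t, occ in zip(local_times, traj[:-1]):
            records.append((t_offset + t, np.asarray(occ)))
        p = np.asarray(traj[-1].values)
        t_offset += duration
    records.append((t_offset, p))

    n = spec.n_states
    data = {
        "time_s": [t for t, _ in records],
        **{f"state_{i}": [occ[i] for _, occ in records] for i in range(n)},
    }
    frame = pd.DataFrame(data)
    p_open = frame[[f"state_{i}" for i in sorted(spec.conducting_states)]].sum(axis=1)
    if noise.sigma > 0:
        p_open = p_open + rng.normal(0.0, noise.sigma, size=len(p_open))
    frame["p_open"] = p_open
    return frame


def correct_rundown(table: pd.DataFrame) -> pd.DataFrame:
    """Remove exponential rundown drift using interleaved reference sweeps.

    A geometric decay ``(1 - r)**sweep`` is fitted per replicate to the
    log responses of the blocker-free reference sweeps; all responses of
    that replicate are divided by the fitted drift.  Requires at least
    two reference sweeps per replicate.
    """
    if "is_reference" not in table.columns or "sweep" not in table.columns:
        raise RundownCorrectionError("dataset carries no reference-sweep annotation")
    out = table.copy()
    for rep, group in table.groupby("replicate"):
        refs = group[group["is_reference"]]
        if len(refs) < 2:
            raise RundownCorrectionError(
                f"replicate {rep}: need >= 2 reference sweeps, found {len(refs)}"
            )
        s = refs["sweep"].to_numpy(dtype=float)
        y = refs["response"].to_numpy(dtype=float)
        if np.any(y <= 0):
            raise RundownCorrectionError(
                f"replicate {rep}: non-positive reference amplitude"
            )
        slope, intercept = np.polyfit(s, np.log(y), 1)
        idx = group.index
        drift = np.exp(intercept + slope * group["sweep"].to_numpy(dtype=float))
        out.loc[idx, "response"] = group["response"].to_numpy() / drift
    return out
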