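import numpy as np
import pytest

from gatekit.mechanism import (
    Conditions,
    ParameterSet,
    build_rate_matrix,
    packaged_mechanism,
)
from gatekit.synth import default_calibration


@pytest.fixture(scope="session")
def open_block_spec():
    return packaged_mechanism("open_block")


@pytest.fixture(scope="session")
def closed_antagonism_spec():
    return packaged_mechanism("closed_antagonism")


@pytest.fixture(scope="session")
def calibrated_params():
    return default_calibration()


@pytest.fixture(scope="session")
def closed_antagonism_params(calibrated_params):
    """Calibrated gating core plus blocker binding on closed states 3/5/6
    with the same planted affinity and valence as the open-block truth."""
    rates = {
        k: v for k, v in calibrated_params.rates.items() if k not in ("k07", "k70")
    }
    rates.update(k37=1e8, k73=360.0, k58=1e8, k85=360.0, k69=1e8, k96=360.0)
    return ParameterSet(
        rates=rates,
        delta_b=calibrated_params.delta_b,
        delta_ca=calibrated_params.delta_ca,
        z_b=calibrated_params.z_b,
        z_ca=calibrated_params.z_ca,
    )


def two_state_q(k01: float, k10: float) -> np.ndarray:
    return np.array([[-k01, k01], [k10, -k10]])


def random_generator_matrix(rng: np.random.Generator, n: int) -> np.ndarray:
    """Random irreducible generator: all off-diagonal rates positive,
    log-uniform over four decades."""
    q = 10 ** rng.uniform(-1.0, 3.0, size=(n, n))
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    return q


def random_open_block_params(rng: np.random.Generator) -> ParameterSet:
    """Random positive parameter draw for the 8-state open-block scheme."""
    uni = {
        name: 10 ** rng.uniform(1.0, 3.0)
        for name in (
            "k01", "k10", "k12", "k21", "k23", "k32", "k24",
            "k35", "k45", "k54", "k56", "k70",
        )
    }
    lig = {name: 10 ** rng.uniform(6.5, 8.5) for name in ("k42", "k53", "k65", "k07")}
    return ParameterSet(
        rates={**uni, **lig},
        delta_b=rng.uniform(0.0, 0.6),
        delta_ca=rng.uniform(0.0, 0.6),
        z_b=-1.0,
        z_ca=2.0,
    )


def draw_measurable_open_block(rng: np.random.Generator, spec):
    """Random (params, conditions, popen0) with a measurable blocker-free
    open probability and a spectrally well-separated generator over the
    whole concentration-response range.

    Draws where block would be unmeasurable (open probability below 2%)
    or where the stationary mode is not numerically separable from the
    slowest relaxation (spectral spread beyond 1e7 at the top of the
    blocker grid) are redrawn; they fall outside the operating domain of
    an equilibrium dose-response experiment.
    """
    from gatekit.block import kd_at_voltage
    from gatekit.solver import equilibrium, open_probability

    while True:
        params = random_open_block_params(rng)
        cond = random_conditions(rng)
        q0 = build_rate_matrix(spec, params, cond)
        popen0 = open_probability(equilibrium(q0), spec)
        if popen0 < 0.02:
            continue
        kd_v = kd_at_voltage(
            params.rates["k70"] / params.rates["k07"],
            params.delta_b, params.z_b, cond.voltage, cond.temperature,
        )
        b_max = 100.0 * kd_v / popen0
        q_top = np.asarray(
            build_rate_matrix(
                spec, params,
                Conditions(
                    voltage=cond.voltage, calcium=cond.calcium, blocker=b_max
                ),
            )
        )
        lam = np.linalg.eigvals(q_top)
        nonzero = np.abs(lam.real)[np.abs(lam) > 1e-9 * max(1.0, np.abs(lam).max())]
        if len(nonzero) < q_top.shape[0] - 1:
            continue
        if np.abs(lam).max() / nonzero.min() > 1e7:
            continue
        return params, cond, popen0


def random_conditions(rng: np.random.Generator) -> Conditions:
    return Conditions(
        voltage=rng.uniform(-0.08, 0.08),
        calcium=10 ** rng.uniform(-6.5, -5.0),
        blocker=0.0,
        temperature=293.15,
    )
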