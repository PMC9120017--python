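"""Kinetic-scheme declaration and rate-matrix evaluation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gatekit.constants import FARADAY, GAS_CONSTANT
from gatekit.errors import ConfigurationError, InvalidArgumentError
from gatekit.mechanism import (
    Conditions,
    MechanismSpec,
    ParameterSet,
    RateMatrix,
    TransitionSpec,
    VoltageDependence,
    build_rate_matrix,
    packaged_mechanism,
    voltage_factor,
)

from conftest import random_conditions, random_open_block_params


class TestVoltageFactor:
    @pytest.mark.parametrize(
        "z, v, direction, expected",
        [
            (-1, 0.0, "forward", 1.0),
            (-1, 0.080, "forward", math.exp(0.080 * FARADAY / (GAS_CONSTANT * 293.15))),
            (2, 0.080, "forward", math.exp(-2 * 0.080 * FARADAY / (GAS_CONSTANT * 293.15))),
        ],
    )
    def test_scalar_values(self, z, v, direction, expected):
        assert voltage_factor(z, v, 293.15, direction) == pytest.approx(expected, rel=1e-12)

    def test_printed_magnitudes(self):
        # independently evaluated scalars: e^(0.080 F/RT) and e^(-0.160 F/RT)
        assert voltage_factor(-1, 0.080, 293.15, "forward") == pytest.approx(23.74, rel=1e-3)
        assert voltage_factor(2, 0.080, 293.15, "forward") == pytest.approx(1.78e-3, rel=1e-2)

    @settings(max_examples=100, derandomize=True)
    @given(
        z=st.floats(-3, 3),
        v=st.floats(-0.2, 0.2),
        t=st.floats(250.0, 330.0),
    )
    def test_forward_backward_product_is_one(self, z, v, t):
        fwd = voltage_factor(z, v, t, "forward")
        bwd = voltage_factor(z, v, t, "backward")
        assert fwd * bwd == pytest.approx(1.0, rel=1e-12)

    def test_rejects_nonfinite_and_bad_temperature(self):
        with pytest.raises(InvalidArgumentError):
            voltage_factor(float("nan"), 0.0)
        with pytest.raises(InvalidArgumentError):
            voltage_factor(-1, float("inf"))
        with pytest.raises(InvalidArgumentError):
            voltage_factor(-1, 0.0, temperature=0.0)


class TestBuildRateMatrix:
    def test_blocker_free_leaves_blocked_state_unreachable(
        self, open_block_spec, calibrated_params
    ):
        q = build_rate_matrix(
            open_block_spec, calibrated_params, Conditions(voltage=0.0, calcium=2e-6)
        ).matrix
        assert q[0, 7] == 0.0
        assert q[0, 0] == pytest.approx(-calibrated_params.rates["k01"])
        assert np.all(q[:, 7] == 0.0) or q[7, 0] > 0  # nothing enters state 7

    def test_blocker_entry_is_concentration_times_rate(self, open_block_spec):
        params = random_open_block_params(np.random.default_rng(0)).replace(
            rates={"k07": 1e6}
        )
        q = build_rate_matrix(
            open_block_spec, params, Conditions(voltage=0.0, calcium=1e-6, blocker=1e-5)
        ).matrix
        assert q[0, 7] == pytest.approx(10.0, rel=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_row_sums_vanish(self, open_block_spec, seed):
        rng = np.random.default_rng(seed)
        params = random_open_block_params(rng)
        cond = random_conditions(rng)
        q = build_rate_matrix(open_block_spec, params, cond).matrix
        scale = np.abs(q).max()
        assert np.abs(q.sum(axis=1)).max() <= 1e-12 * scale

    def test_matches_hand_transcribed_matrix(self, open_block_spec):
        """Entry-by-entry oracle: the printed 8-state matrix written out
        explicitly from the rate formulas, on a random parameter draw."""
        rng = np.random.default_rng(42)
        p = random_open_block_params(rng)
        V, x, b, T = 0.043, 1.3e-6, 5e-6, 296.0
        k = p.rates
        vb = math.exp(-p.z_b * V * FARADAY / (GAS_CONSTANT * T))
        vca = math.exp(-p.z_ca * V * FARADAY / (GAS_CONSTANT * T))
        db2, dca2 = p.delta_b / 2, p.delta_ca / 2
        e = np.zeros((8, 8))
        e[0, 1] = k["k01"]
        e[0, 7] = b * k["k07"] * vb**db2
        e[1, 0] = k["k10"]
        e[1, 2] = k["k12"]
        e[2, 1] = k["k21"]
        e[2, 3] = k["k23"]
        e[2, 4] = k["k24"]  # printed without a voltage factor
        e[3, 2] = k["k32"]
        e[3, 5] = k["k35"] * vca**dca2
        e[4, 2] = x * k["k42"] * (1 / vca) ** dca2
        e[4, 5] = k["k45"]
        e[5, 3] = x * k["k53"] * (1 / vca) ** dca2
        e[5, 4] = k["k54"]
        e[5, 6] = k["k56"] * vca**dca2
        e[6, 5] = x * k["k65"] * (1 / vca) ** dca2
        e[7, 0] = k["k70"] * (1 / vb) ** db2
        np.fill_diagonal(e, -e.sum(axis=1))
        q = build_rate_matrix(
            open_block_spec, p, Conditions(voltage=V, calcium=x, blocker=b, temperature=T)
        ).matrix
        np.testing.assert_allclose(q, e, rtol=1e-12, atol=0)

    def test_zero_deltas_make_matrix_voltage_independent(self, open_block_spec):
        params = random_open_block_params(np.random.default_rng(3)).replace(
            delta_b=0.0, delta_ca=0.0
        )
        cond = dict(calcium=1e-6, blocker=2e-6)
        q1 = build_rate_matrix(open_block_spec, params, Conditions(voltage=-0.08, **cond))
        q2 = build_rate_matrix(open_block_spec, params, Conditions(voltage=0.12, **cond))
        np.testing.assert_array_equal(q1.matrix, q2.matrix)

    def test_k24_voltage_flag_attaches_forward_factor(self):
        spec = packaged_mechanism("open_block", k24_voltage=True)
        params = random_open_block_params(np.random.default_rng(7))
        cond = Conditions(voltage=0.05, calcium=1e-6)
        q = build_rate_matrix(spec, params, cond).matrix
        expected = params.rates["k24"] * voltage_factor(
            params.z_ca, 0.05, 293.15, "forward"
        ) ** (params.delta_ca / 2)
        assert q[2, 4] == pytest.approx(expected, rel=1e-12)

    def test_missing_rate_raises_configuration_error(self, open_block_spec):
        params = ParameterSet(rates={"k01": 1.0})
        with pytest.raises(ConfigurationError, match="k"):
            build_rate_matrix(open_block_spec, params, Conditions())

    def test_negative_concentration_rejected(self):
        with pytest.raises(InvalidArgumentError):
            Conditions(calcium=-1e-6)
        with pytest.raises(InvalidArgumentError):
            Conditions(blocker=-1e-6)


class TestPackagedMechanisms:
    def test_open_block_topology(self, open_block_spec):
        assert open_block_spec.n_states == 8
        assert len(open_block_spec.transitions) == 16
        blocker_steps = {
            (t.from_state, t.to_state)
            for t in open_block_spec.transitions
            if t.ligand == "blocker"
        }
        assert blocker_steps == {(0, 7)}
        assert open_block_spec.conducting_states == {0}

    def test_closed_antagonism_topology(self, closed_antagonism_spec):
        assert closed_antagonism_spec.n_states == 10
        blocker_steps = {
            (t.from_state, t.to_state)
            for t in closed_antagonism_spec.transitions
            if t.ligand == "blocker"
        }
        assert blocker_steps == {(3, 7), (5, 8), (6, 9)}
        assert closed_antagonism_spec.conducting_states == {0}

    @pytest.mark.parametrize("which", ["open_block", "closed_antagonism"])
    def test_conducting_and_blocked_disjoint(self, which):
        spec = packaged_mechanism(which)
        assert not (spec.conducting_states & spec.blocked_states)

    def test_unknown_name_rejected(self):
        with pytest.raises(InvalidArgumentError):
            packaged_mechanism("no_such_scheme")

    def test_json_round_trip(self, open_block_spec):
        restored = MechanismSpec.from_json(open_block_spec.to_json())
        assert restored == open_block_spec

    def test_parameter_set_json_round_trip(self, calibrated_params):
        restored = ParameterSet.from_json(calibrated_params.to_json())
        assert restored.rates == calibrated_params.rates
        assert restored.delta_b == calibrated_params.delta_b
        assert restored.z_ca == calibrated_params.z_ca


class TestValidation:
    def test_self_transition_rejected(self):
        with pytest.raises(InvalidArgumentError):
            TransitionSpec(1, 1, "k11")

    def test_disconnected_graph_rejected(self):
        with pytest.raises(InvalidArgumentError, match="connected"):
            MechanismSpec(
                name="broken",
                n_states=4,
                transitions=[
                    TransitionSpec(0, 1, "a"),
                    TransitionSpec(2, 3, "b"),
                ],
                conducting_states={0},
            )

    def test_rate_matrix_rejects_negative_off_diagonal(self):
        with pytest.raises(InvalidArgumentError):
            RateMatrix(np.array([[-1.0, 1.0], [-2.0, 2.0]]))

    def test_parameter_set_rejects_nonpositive_rate_and_bad_delta(self):
        with pytest.raises(InvalidArgumentError):
            ParameterSet(rates={"k01": 0.0})
        with pytest.raises(InvalidArgumentError):
            ParameterSet(rates={"k01": 1.0}, delta_b=1.5)
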