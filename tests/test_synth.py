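"""Synthetic-data generators: determinism, calibration, noise
structure, rundown correction, and concentration-jump traces."""

import numpy as np
import pandas as pd
import pytest

from gatekit.errors import InvalidArgumentError, RundownCorrectionError
from gatekit.mechanism import Conditions, build_rate_matrix
from gatekit.permeation import PermeationParams, iv_current
from gatekit.solver import equilibrium, open_probability
from gatekit.synth import (
    BlockDesign,
    NoiseModel,
    correct_rundown,
    default_calibration,
    default_truth,
    generate_block_dataset,
    generate_iv_dataset,
    generate_jump_trace,
)


class TestDefaultCalibration:
    def test_open_probability_at_reference_condition(self, open_block_spec):
        params = default_calibration()
        q = build_rate_matrix(
            open_block_spec, params, Conditions(voltage=0.0, calcium=2e-6)
        )
        po = open_probability(equilibrium(q), open_block_spec)
        assert po == pytest.approx(0.90, abs=1e-3)

    def test_open_probability_monotone_over_physiological_range(self, open_block_spec):
        params = default_calibration()
        pos = []
        for ca in np.logspace(-7, np.log10(15e-6), 10):
            q = build_rate_matrix(
                open_block_spec, params, Conditions(voltage=0.0, calcium=ca)
            )
            pos.append(open_probability(equilibrium(q), open_block_spec))
        assert np.all(np.diff(pos) > 0)

    def test_planted_truth_matches_blocker_rates(self):
        params = default_calibration()
        truth = default_truth()
        assert params.rates["k70"] / params.rates["k07"] == pytest.approx(
            truth["kd_1pbc"]
        )
        assert params.delta_b == truth["delta_b"]


class TestBlockDatasetGenerator:
    def test_same_seed_reproduces_identical_dataset(self, open_block_spec):
        params = default_calibration()
        kwargs = dict(design=BlockDesign(), noise=NoiseModel(seed=11))
        a = generate_block_dataset(open_block_spec, params, **kwargs)
        b = generate_block_dataset(open_block_spec, params, **kwargs)
        for x, y in zip(a.blocks, b.blocks):
            pd.testing.assert_frame_equal(x.table, y.table)

    def test_zero_noise_returns_model_means(self, open_block_spec, calibrated_params):
        data = generate_block_dataset(
            open_block_spec, calibrated_params, BlockDesign(),
            NoiseModel(sigma=0.0, n_replicates=3, seed=0),
        )
        for block in data.blocks:
            per_conc = block.table.groupby("conc_molar")["response"].nunique()
            assert (per_conc == 1).all()  # replicates identical without noise

    def test_replicate_mean_approaches_model_mean(self, open_block_spec, calibrated_params):
        """Law of large numbers at one condition: the mean of 10^4
        replicates sits within 3 sigma/100 of the model value."""
        design = BlockDesign(ca_levels=(2e-6,), voltages=(0.08,),
                            blocker_grid=(4e-6,))
        noisy = generate_block_dataset(
            open_block_spec, calibrated_params, design,
            NoiseModel(sigma=0.03, n_replicates=10_000, seed=0),
        )
        clean = generate_block_dataset(
            open_block_spec, calibrated_params, design,
            NoiseModel(sigma=0.0, n_replicates=1, seed=0),
        )
        mean = noisy.blocks[0].table["response"].mean()
        truth = clean.blocks[0].table["response"].iloc[0]
        assert abs(mean - truth) < 3 * 0.03 / 100

    def test_provenance_records_truth_and_seed(self, open_block_spec, calibrated_params):
        data = generate_block_dataset(
            open_block_spec, calibrated_params, noise=NoiseModel(seed=42)
        )
        prov = data.blocks[0].table.attrs["provenance"]
        assert prov["seed"] == 42
        assert prov["truth"]["kd_1pbc"] == pytest.approx(3.6e-6)


class TestIvGenerator:
    def test_seed_reproducibility(self):
        p = PermeationParams(sigma_h=0.3, sigma_beta=0.5, amplitude=1e-4)
        a = generate_iv_dataset(p, noise=NoiseModel(seed=3))
        b = generate_iv_dataset(p, noise=NoiseModel(seed=3))
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_zero_noise_matches_model_exactly(self):
        p = PermeationParams(sigma_h=0.3, sigma_beta=0.5, amplitude=1e-4)
        data = generate_iv_dataset(
            p, noise=NoiseModel(sigma=0.0, n_replicates=1, seed=0)
        )
        for _, row in data.table.iterrows():
            assert row["current"] == pytest.approx(
                iv_current(p, row["voltage_v"]), rel=1e-12
            )


class TestJumpTraces:
    def test_single_segment_ends_at_equilibrium(self, open_block_spec, calibrated_params):
        cond = Conditions(voltage=0.08, calcium=2e-6, blocker=5e-6)
        trace = generate_jump_trace(
            open_block_spec, calibrated_params, [(cond, 2.0)], 1e-2
        )
        q = build_rate_matrix(open_block_spec, calibrated_params, cond)
        po_eq = open_probability(equilibrium(q), open_block_spec)
        assert trace["p_open"].iloc[-1] == pytest.approx(po_eq, abs=1e-6)

    def test_washout_returns_to_initial_open_probability(
        self, open_block_spec, calibrated_params
    ):
        base = dict(voltage=0.08, calcium=2e-6)
        protocol = [
            (Conditions(blocker=0.0, **base), 0.05),
            (Conditions(blocker=1e-5, **base), 0.5),
            (Conditions(blocker=0.0, **base), 5.0),
        ]
        trace = generate_jump_trace(
            open_block_spec, calibrated_params, protocol, 1e-3
        )
        assert trace["p_open"].iloc[-1] == pytest.approx(
            trace["p_open"].iloc[0], abs=1e-3
        )
        assert trace["p_open"].min() < 0.2  # deep block during application

    def test_higher_calcium_slows_unblock_recovery(
        self, open_block_spec, calibrated_params
    ):
        """The observable relaxation of p_open during washout is slower
        at saturating Ca2+: the recovery time to 90% of the gap grows."""
        t90 = {}
        for ca in (400e-9, 2e-6):
            base = dict(voltage=0.08, calcium=ca)
            protocol = [
                (Conditions(blocker=1e-5, **base), 1.0),
                (Conditions(blocker=0.0, **base), 0.3),
            ]
            trace = generate_jump_trace(
                open_block_spec, calibrated_params, protocol, 1e-4
            )
            wash = trace[trace["time_s"] >= 1.0].reset_index(drop=True)
            po = wash["p_open"].to_numpy()
            frac = (po - po[0]) / (po[-1] - po[0])
            t90[ca] = wash["time_s"][int(np.argmax(frac >= 0.9))] - 1.0
        assert t90[2e-6] > t90[400e-9]

    def test_probability_columns_sum_to_one(self, open_block_spec, calibrated_params):
        cond = Conditions(voltage=0.0, calcium=2e-6, blocker=1e-6)
        trace = generate_jump_trace(
            open_block_spec, calibrated_params, [(cond, 0.1)], 1e-2
        )
        states = trace[[f"state_{i}" for i in range(8)]].to_numpy()
        np.testing.assert_allclose(states.sum(axis=1), 1.0, atol=1e-9)

    def test_invalid_protocol_rejected(self, open_block_spec, calibrated_params):
        with pytest.raises(InvalidArgumentError):
            generate_jump_trace(open_block_spec, calibrated_params, [], 1e-3)
        with pytest.raises(InvalidArgumentError):
            generate_jump_trace(
                open_block_spec, calibrated_params,
                [(Conditions(calcium=2e-6), -1.0)], 1e-3,
            )


class TestRundownCorrection:
    def _dataset(self, spec, params, rundown, sigma, seed=0):
        return generate_block_dataset(
            spec, params, BlockDesign(ref_interval=4),
            NoiseModel(sigma=sigma, rundown_rate=rundown, seed=seed),
        )

    def test_no_rundown_leaves_responses_unchanged(self, open_block_spec, calibrated_params):
        data = self._dataset(open_block_spec, calibrated_params, 0.0, 0.0)
        table = data.blocks[0].table
        corrected = correct_rundown(table)
        np.testing.assert_allclose(
            corrected["response"].to_numpy(), table["response"].to_numpy(), atol=1e-12
        )

    def test_exact_recovery_without_noise(self, open_block_spec, calibrated_params):
        drifted = self._dataset(open_block_spec, calibrated_params, 0.02, 0.0)
        clean = self._dataset(open_block_spec, calibrated_params, 0.0, 0.0)
        corrected = correct_rundown(drifted.blocks[0].table)
        np.testing.assert_allclose(
            corrected["response"].to_numpy(),
            clean.blocks[0].table["response"].to_numpy(),
            atol=1e-9,
        )

    def test_noisy_correction_is_unbiased_within_sem(self, open_block_spec, calibrated_params):
        sigma, n_rep = 0.03, 24
        drifted = generate_block_dataset(
            open_block_spec, calibrated_params, BlockDesign(ref_interval=4),
            NoiseModel(sigma=sigma, n_replicates=n_rep, rundown_rate=0.02, seed=5),
        )
        clean = generate_block_dataset(
            open_block_spec, calibrated_params, BlockDesign(ref_interval=4),
            NoiseModel(sigma=0.0, n_replicates=1, seed=5),
        )
        corrected = correct_rundown(drifted.blocks[0].table)
        test_rows = corrected[~corrected["is_reference"]]
        means = test_rows.groupby("conc_molar")["response"].mean()
        truth = clean.blocks[0].table
        truth = truth[~truth["is_reference"]].set_index("conc_molar")["response"]
        bias = np.abs(means - truth).mean()
        assert bias < 2 * sigma / np.sqrt(n_rep)

    def test_too_few_references_rejected(self, open_block_spec, calibrated_params):
        data = generate_block_dataset(
            open_block_spec, calibrated_params, BlockDesign(ref_interval=0),
            NoiseModel(sigma=0.0, seed=0),
        )
        with pytest.raises(RundownCorrectionError):
            correct_rundown(data.blocks[0].table)
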