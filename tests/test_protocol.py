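"""Protocol engine: sessions, drugs, seeding and replication."""

import numpy as np
import pandas as pd
import pytest

from decondnet import (
    REACTIVATION_PARAMS,
    DynamicsParams,
    ExperimentSpec,
    PlasticityParams,
    SessionSpec,
    apply_drug,
    reexposure_pattern,
    retrieval_cue,
    run_experiment,
    run_session,
)
from decondnet.io import write_result
from decondnet.patterns import initial_weight_noise


@pytest.fixture()
def trained_weights(layout):
    return initial_weight_noise(layout.n, 5)


def small_spec(**kw):
    defaults = dict(n_simulations=2, n_retrieval_trials=10, master_seed=42)
    defaults.update(kw)
    return ExperimentSpec(**defaults)


class TestApplyDrug:
    def test_nimodipine_knocks_out_degradation(self):
        out = apply_drug(PlasticityParams(S=0.25, D=0.95), "nimodipine")
        assert (out.S, out.D) == (0.25, 0.0)

    def test_hebbian_block_knocks_out_learning(self):
        out = apply_drug(PlasticityParams(S=0.25, D=0.95), "hebbian_block")
        assert (out.S, out.D) == (0.0, 0.95)

    def test_vehicle_is_identity(self):
        params = PlasticityParams(S=0.25, D=0.95)
        assert apply_drug(params, "vehicle") == params

    def test_unknown_drug_rejected(self):
        with pytest.raises(ValueError, match="unknown drug"):
            apply_drug(PlasticityParams(S=0.25, D=0.95), "propranolol")


class TestSessionSpec:
    def test_learning_sessions_require_cue_and_params(self, layout):
        with pytest.raises(ValueError, match="learning cue"):
            SessionSpec(kind="reactivation", label="r1",
                        retrieval_cue=retrieval_cue(layout, "B"))

    def test_readout_sessions_reject_learning_cue(self, layout):
        with pytest.raises(ValueError, match="pure readout"):
            SessionSpec(kind="test", label="test",
                        retrieval_cue=retrieval_cue(layout, "B"),
                        learning_cue=reexposure_pattern(layout, "footshock"),
                        plasticity=REACTIVATION_PARAMS)


class TestRunSession:
    def test_retrieval_battery_leaves_weights_untouched(self, layout, trained_weights):
        spec = SessionSpec(kind="test", label="test",
                           retrieval_cue=retrieval_cue(layout, "B"),
                           n_retrieval_trials=5)
        W, record = run_session(trained_weights, spec, layout,
                                np.random.default_rng(0))
        assert W is trained_weights
        assert record["session_end_freezing"] is None
        assert 0 <= record["tone_freezing"] <= 100

    def test_null_plasticity_reactivation_preserves_weights(self, layout, trained_weights):
        spec = SessionSpec(kind="reactivation", label="r1",
                           retrieval_cue=retrieval_cue(layout, "B"),
                           learning_cue=reexposure_pattern(layout, "footshock"),
                           plasticity=PlasticityParams(S=0.0, D=0.0, gamma=0.0),
                           n_retrieval_trials=5)
        W, _ = run_session(trained_weights, spec, layout, np.random.default_rng(0))
        np.testing.assert_array_equal(W, trained_weights)

    def test_vehicle_reactivation_changes_weights(self, layout, trained_weights):
        spec = SessionSpec(kind="reactivation", label="r1",
                           retrieval_cue=retrieval_cue(layout, "B"),
                           learning_cue=reexposure_pattern(layout, "footshock"),
                           plasticity=REACTIVATION_PARAMS,
                           n_retrieval_trials=5)
        W, record = run_session(trained_weights, spec, layout, np.random.default_rng(0))
        assert np.linalg.norm(W - trained_weights) > 0
        assert record["session_end_freezing"] is not None


class TestRunExperiment:
    def test_session_sequence_and_record_shape(self):
        res = run_experiment(small_spec(group="footshock"))
        sessions = list(res.freezing["session"].unique())
        assert sessions == ["background", "training", "reactivation_1",
                            "reactivation_2", "reactivation_3", "reactivation_4",
                            "test", "renewal"]
        probes = res.freezing.groupby("session")["probe"].nunique()
        assert probes["test"] == 1 and probes["reactivation_1"] == 2
        assert res.freezing["freezing_pct"].between(0, 100).all()
        # 5x5 cluster summary per simulation and session
        counts = res.cluster_weights.groupby(["simulation", "session"]).size()
        assert (counts == 25).all()

    def test_same_master_seed_reproduces_bit_for_bit(self):
        a = run_experiment(small_spec())
        b = run_experiment(small_spec())
        pd.testing.assert_frame_equal(a.freezing, b.freezing)
        pd.testing.assert_frame_equal(a.cluster_weights, b.cluster_weights)

    def test_different_seeds_differ(self):
        a = run_experiment(small_spec(master_seed=1))
        b = run_experiment(small_spec(master_seed=2))
        assert not a.freezing["freezing_pct"].equals(b.freezing["freezing_pct"])

    def test_simulations_are_independent_of_replication_count(self):
        # the first replicate's records do not depend on how many others run
        lone = run_experiment(small_spec(n_simulations=1))
        batch = run_experiment(small_spec(n_simulations=3))
        first = batch.freezing[batch.freezing["simulation"] == 0].reset_index(drop=True)
        pd.testing.assert_frame_equal(lone.freezing, first)

    def test_non_settling_simulations_are_flagged_not_fatal(self):
        spec = small_spec(dynamics=DynamicsParams(max_steps=3))
        res = run_experiment(spec)
        assert len(res.failures) == spec.n_simulations
        assert res.freezing.empty

    def test_invalid_group_and_drug_rejected(self):
        with pytest.raises(ValueError):
            ExperimentSpec(group="massed")
        with pytest.raises(ValueError):
            ExperimentSpec(drug="propranolol")


class TestExport:
    def test_written_tables_round_trip(self, tmp_path):
        res = run_experiment(small_spec())
        paths = write_result(res, tmp_path)
        freeze = pd.read_csv(paths["freezing"])
        pd.testing.assert_frame_equal(freeze, res.freezing, check_dtype=False)
        assert paths["meta"].exists()
        weights = pd.read_csv(paths["weights"])
        assert set(weights.columns) == {"group", "drug", "simulation", "session",
                                        "pre_cluster", "post_cluster", "mean_weight"}
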