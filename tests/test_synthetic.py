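"""Ground-truth generator: construction guarantees and recovery metrics."""

import numpy as np
import pandas as pd
import pytest

from oxbscall import (
    CallConfig,
    GroupDesign,
    GroupProfile,
    OxbsValidationError,
    SimulationConfig,
    call_hmc,
    compute_delta_beta,
    simulate_dataset,
    truth_evaluation,
)
from oxbscall.model import CALL_HMC, CALL_NOT_CALLED, CallSummary, HmcCallTable
from oxbscall.synthetic import read_truth, write_truth


def _delta(sim, group="brain1"):
    design = GroupDesign.from_sheet(sim.sheet, group)
    return compute_delta_beta(sim.matrix, design)


class TestSimulateDataset:
    def test_fixed_seed_is_reproducible(self):
        cfg = SimulationConfig(n_probes=500, seed=123)
        a = simulate_dataset(cfg)
        b = simulate_dataset(cfg)
        pd.testing.assert_frame_equal(a.matrix.values, b.matrix.values)
        pd.testing.assert_frame_equal(a.matrix.detection_p, b.matrix.detection_p)
        pd.testing.assert_frame_equal(a.truth, b.truth)

    def test_truth_respects_unit_interval_budget(self, brain_sim):
        total = brain_sim.truth["true_mc"] + brain_sim.truth["true_hmc"]
        assert (total <= 1.0 + 1e-12).all()

    def test_null_config_centres_delta_on_zero(self):
        cfg = SimulationConfig(
            n_probes=4000,
            groups=(GroupProfile("null", hmc_fraction=0.0),),
            noise_sd=0.03,
            seed=5,
        )
        sim = simulate_dataset(cfg)
        delta = _delta(sim, "null")["delta_beta"]
        se = delta.std() / np.sqrt(len(delta))
        assert abs(delta.mean()) < 4 * se + 1e-3

    def test_noiseless_limit_recovers_truth_exactly(self):
        cfg = SimulationConfig(n_probes=300, noise_sd=0.0, seed=9)
        sim = simulate_dataset(cfg)
        delta = _delta(sim)
        truth = sim.truth.set_index("probe_id").loc[delta.index, "true_hmc"]
        np.testing.assert_allclose(delta["delta_beta"], truth, atol=1e-12)

    def test_mean_recovered_delta_matches_configured_level(self):
        # 10% of probes at level 0.4 exactly; Monte-Carlo mean within 3 SE
        cfg = SimulationConfig(
            n_probes=10000,
            groups=(
                GroupProfile(
                    "g", hmc_fraction=0.10, hmc_level_low=0.4, hmc_level_high=0.4
                ),
            ),
            noise_sd=0.03,
            seed=77,
        )
        sim = simulate_dataset(cfg)
        delta = _delta(sim, "g")
        truth = sim.truth.set_index("probe_id")
        hm = truth.index[truth["true_hmc"] > 0].intersection(delta.index)
        est = delta.loc[hm, "delta_beta"]
        se = est.std() / np.sqrt(len(est))
        assert est.mean() == pytest.approx(0.4, abs=3 * se)

    def test_detection_failures_occur_at_configured_rate(self):
        cfg = SimulationConfig(n_probes=20000, detection_failure_rate=0.01, seed=3)
        sim = simulate_dataset(cfg)
        rate = (sim.matrix.detection_p.to_numpy() > 0.01).mean()
        assert rate == pytest.approx(0.01, rel=0.25)

    def test_sex_probes_present_at_configured_fraction(self, brain_sim):
        frac = len(brain_sim.annotation.sex_probes()) / len(brain_sim.annotation.probe_ids)
        assert frac == pytest.approx(0.024, abs=0.01)

    def test_incomplete_oxidation_leaves_residual_oxbs_signal(self):
        base = dict(n_probes=2000, noise_sd=0.0, seed=21)
        full = simulate_dataset(SimulationConfig(oxidation_efficiency=1.0, **base))
        partial = simulate_dataset(SimulationConfig(oxidation_efficiency=0.8, **base))
        d_full = _delta(full)["delta_beta"]
        d_partial = _delta(partial)["delta_beta"]
        hm = full.truth.set_index("probe_id")["true_hmc"]
        hm = hm[hm > 0].index
        assert (d_partial.loc[hm] < d_full.loc[hm]).all()

    def test_feature_weights_bias_hmc_placement_preserving_rate(self):
        from oxbscall.synthetic import BRAIN_CGI_WEIGHTS, BRAIN_FEATURE_WEIGHTS

        cfg = SimulationConfig(
            n_probes=30000,
            groups=(
                GroupProfile(
                    "brain1",
                    hmc_fraction=0.15,
                    feature_weights=BRAIN_FEATURE_WEIGHTS,
                    cgi_weights=BRAIN_CGI_WEIGHTS,
                ),
            ),
            seed=31,
        )
        sim = simulate_dataset(cfg)
        truth = sim.truth.set_index("probe_id")
        hm = truth["true_hmc"] > 0
        assert hm.mean() == pytest.approx(0.15, rel=0.1)
        feat = sim.annotation.data["feature"]
        body_in_hm = (feat[hm.index[hm]] == "BODY").mean()
        body_overall = (feat == "BODY").mean()
        assert body_in_hm > body_overall
        cgi = sim.annotation.data["cgi_relation"]
        island_in_hm = (cgi[hm.index[hm]] == "ISLAND").mean()
        assert island_in_hm < (cgi == "ISLAND").mean()

    def test_invalid_config_rejected(self):
        with pytest.raises(OxbsValidationError):
            SimulationConfig(replicates=1)
        with pytest.raises(OxbsValidationError):
            GroupProfile("g", hmc_fraction=1.5)


class TestSensitivityMonotonicity:
    def _sensitivity(self, noise_sd, replicates, seeds=range(3)):
        vals = []
        for seed in seeds:
            cfg = SimulationConfig(
                n_probes=4000,
                groups=(
                    GroupProfile(
                        "g",
                        hmc_fraction=0.10,
                        hmc_level_low=0.30,
                        hmc_level_high=0.59,
                        hmc_level_shape=None,
                    ),
                ),
                replicates=replicates,
                noise_sd=noise_sd,
                seed=1000 + seed,
            )
            sim = simulate_dataset(cfg)
            table = call_hmc(_delta(sim, "g"), CallConfig(mode="threshold"), group="g")
            vals.append(truth_evaluation(table, sim.truth, level_floor=0.35).sensitivity)
        return float(np.mean(vals))

    def test_sensitivity_decreases_with_noise(self):
        assert self._sensitivity(0.02, 2) >= self._sensitivity(0.08, 2)

    def test_sensitivity_increases_with_replicates(self):
        assert self._sensitivity(0.05, 4) >= self._sensitivity(0.05, 2)


class TestTruthEvaluation:
    def _calls_table(self, truth, called_ids, group="brain1"):
        t = truth[truth["group"] == group].set_index("probe_id")
        data = pd.DataFrame(
            {
                "delta_beta": t["true_hmc"],
                "stat": 0.0,
                "p_value": 1.0,
                "q_value": 1.0,
                "call": np.where(t.index.isin(called_ids), CALL_HMC, CALL_NOT_CALLED),
            },
            index=t.index,
        )
        summary = CallSummary(len(t), len(called_ids), 0, np.nan, np.nan, np.nan, np.nan)
        return HmcCallTable(data=data, summary=summary, group=group)

    def test_perfect_calls_score_perfectly(self, brain_sim):
        truth = brain_sim.truth
        hm = truth.loc[truth["true_hmc"] > 0, "probe_id"]
        table = self._calls_table(truth, set(hm))
        m = truth_evaluation(table, truth)
        assert m.sensitivity == 1.0
        assert m.false_call_rate == 0.0
        assert m.delta_mae == pytest.approx(0.0, abs=1e-12)

    def test_empty_call_set_scores_zero_sensitivity(self, brain_sim):
        table = self._calls_table(brain_sim.truth, set())
        m = truth_evaluation(table, brain_sim.truth)
        assert m.sensitivity == 0.0
        assert np.isnan(m.false_call_rate)

    def test_agrees_with_independent_set_arithmetic(self, brain_sim):
        # independent oracle: plain set operations on probe ids
        rng = np.random.default_rng(8)
        truth = brain_sim.truth
        called = set(rng.choice(truth["probe_id"], size=700, replace=False))
        table = self._calls_table(truth, called)
        m = truth_evaluation(table, truth, level_floor=0.1)
        hm = set(truth.loc[(truth["true_hmc"] >= 0.1) & (truth["true_hmc"] > 0), "probe_id"])
        nulls = set(truth.loc[truth["true_hmc"] == 0, "probe_id"])
        assert m.sensitivity == pytest.approx(len(hm & called) / len(hm))
        assert m.false_call_rate == pytest.approx(len(nulls & called) / len(called))

    def test_disjoint_probe_sets_rejected(self, brain_sim):
        foreign = brain_sim.truth.copy()
        foreign["probe_id"] = "zz" + foreign["probe_id"]
        table = self._calls_table(brain_sim.truth, set())
        with pytest.raises(OxbsValidationError, match="share no probes"):
            truth_evaluation(table, foreign)


def test_truth_round_trip(tmp_path, brain_sim):
    path = tmp_path / "truth.tsv"
    write_truth(brain_sim.truth, path)
    back = read_truth(path)
    assert list(back.columns) == list(brain_sim.truth.columns)
    np.testing.assert_allclose(back["true_hmc"], brain_sim.truth["true_hmc"], atol=1e-6)
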