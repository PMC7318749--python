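"""Platform simulator: accrual, routing, interims, confirmatory stage."""

import numpy as np
import pandas as pd
import pytest

import probio_sim as ps
from probio_sim.trial_engine import (
    OBSERVATIONAL,
    PlatformState,
    ScenarioConfig,
    ScenarioError,
    _one_sided_logrank,
    accrue,
    assign_true_pfs,
    run_trial,
)


class TestScenarioConfig:
    def test_defaults_are_valid(self):
        sc = ScenarioConfig()
        assert sc.accrual_rate == 7.0
        assert sc.p_nonevaluable == 0.1
        assert sc.thresholds.graduation_prob == 0.85

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"treatments": ()},
            {"treatments": ("A", "A")},
            {"treatments": ("control",)},
            {"baseline_mean_pfs": -1},
            {"accrual_rate": 0},
            {"p_nonevaluable": 1.5},
            {"effects": {("Z", "All"): 5.0}},
            {"effects": {("A", "nope"): 5.0}},
            {"effects": {("A", "All"): -5.0}},
            {"control_mix": {"A": 0.7}},
        ],
    )
    def test_invalid_scenarios_rejected(self, kwargs):
        with pytest.raises(ScenarioError):
            ScenarioConfig(**kwargs)

    def test_dict_roundtrip_preserves_hash(self):
        sc = ps.single_effect_scenario(10.0)
        again = ScenarioConfig.from_dict(sc.to_dict())
        assert again.config_hash() == sc.config_hash()

    def test_yaml_roundtrip(self, tmp_path):
        sc = ps.single_effect_scenario(5.0, horizon_months=12)
        path = tmp_path / "scenario.yaml"
        sc.to_yaml(path)
        assert ScenarioConfig.from_yaml(path).config_hash() == sc.config_hash()

    def test_effect_matrix_uses_max_over_signatures(self):
        sc = ScenarioConfig(
            treatments=("A",),
            effects={("A", "TP53+"): 5.0, ("A", "DRD+"): 10.0},
        )
        mat = sc.effect_matrix()
        # subgroup 6 = drd+tp53 mutated: in both signatures -> max applies
        assert mat[0, 6] == 10.0
        # subgroup 2 = tp53 only
        assert mat[0, 2] == 5.0
        # subgroup 0 = all wild-type
        assert mat[0, 0] == 0.0


class TestAssignTruePfs:
    def test_null_scenario_same_distribution_everywhere(self):
        sc = ps.null_scenario()
        assert not sc.effect_matrix().any()

    def test_effect_shifts_the_mean(self):
        sc = ScenarioConfig(treatments=("A",), effects={("A", "TP53+"): 10.0})
        rng = np.random.default_rng(0)
        draws = [
            assign_true_pfs(2, 0, sc, sc.effect_matrix(), rng)
            for _ in range(4000)
        ]
        assert np.mean(draws) == pytest.approx(18.0, rel=0.1)

    def test_unknown_drug_rejected(self):
        sc = ps.null_scenario()
        with pytest.raises(ValueError):
            assign_true_pfs(0, 9, sc, sc.effect_matrix(), np.random.default_rng(0))


class TestAccrual:
    def test_tiny_rate_accrues_nobody(self):
        sc = ps.null_scenario(accrual_rate=1e-4)
        state = PlatformState(scenario=sc)
        assert accrue(state, sc, np.random.default_rng(0)) == []

    def test_poisson_mean(self):
        sc = ps.null_scenario()
        rng = np.random.default_rng(1)
        counts = []
        for _ in range(300):
            state = PlatformState(scenario=sc)
            counts.append(len(accrue(state, sc, rng)))
        assert np.mean(counts) == pytest.approx(7.0, abs=3 * np.sqrt(7 / 300))

    def test_nonevaluable_patients_are_observational(self):
        sc = ps.null_scenario(p_nonevaluable=1.0, horizon_months=3)
        res = run_trial(sc, seed=2)
        frame = res.patients_frame()
        assert (frame["arm"] == "observational").all()


class TestRunTrial:
    def test_zero_horizon_is_empty(self):
        res = run_trial(ps.null_scenario(horizon_months=0), seed=1)
        assert len(res.state.ledger) == 0
        assert res.decision_history == []

    def test_seed_required(self):
        with pytest.raises(ScenarioError):
            run_trial(ps.null_scenario())

    def test_replay_is_bit_identical(self, short_null_scenario):
        a = run_trial(short_null_scenario, seed=11)
        b = run_trial(short_null_scenario, seed=11)
        pd.testing.assert_frame_equal(a.patients_frame(), b.patients_frame())
        pd.testing.assert_frame_equal(a.decisions_frame(), b.decisions_frame())
        pd.testing.assert_frame_equal(a.allocations_frame(), b.allocations_frame())
        assert a.manifest() == b.manifest()

    def test_censoring_sanity(self, short_null_scenario):
        res = run_trial(short_null_scenario, seed=3)
        frame = res.patients_frame()
        months_since_entry = res.state.month - frame["entry_month"]
        assert (frame["observed_time"] <= months_since_entry + 1e-9).all()
        assert (frame["observed_time"] >= 0).all()
        assert (
            (frame["event"] == 1)
            == (frame["observed_time"] == frame["true_pfs"])
        ).all()

    def test_ledger_conservation(self, short_null_scenario):
        """Every accrued patient-line is in exactly one arm category and
        subgroup counts sum to total accrual."""
        res = run_trial(short_null_scenario, seed=4)
        frame = res.patients_frame()
        arms = set(frame["arm"])
        assert arms <= {"observational", "control", "A", "B"}
        assert frame["subgroup_index"].between(0, 15).all()
        assert frame.groupby("subgroup_index").size().sum() == len(frame)
        # patient ids unique per line
        assert frame.groupby(["patient_id", "line"]).size().max() == 1

    def test_decision_records_replay_consistent(self, short_null_scenario):
        from probio_sim.decision_rules import evaluate

        res = run_trial(short_null_scenario, seed=5)
        for rec in res.decision_history:
            assert (
                evaluate(
                    rec.superiority,
                    rec.n_treated,
                    rec.n_signature,
                    rec.consistency,
                    short_null_scenario.thresholds,
                )
                is rec.decision
            )

    def test_allocation_rows_sum_to_one_every_interim(self, short_null_scenario):
        res = run_trial(short_null_scenario, seed=6)
        alloc = res.allocations_frame()
        sums = alloc.groupby(["month", "subgroup_index"])["probability"].sum()
        assert np.allclose(sums, 1.0)


class TestGraduationFlow:
    def test_graduation_opens_confirmatory_and_reroutes(
        self, quick_graduation_scenario
    ):
        res = run_trial(quick_graduation_scenario, seed=8)
        conf = res.confirmatory
        assert conf, "expected a graduation under relaxed thresholds"
        trial = conf[0]
        assert trial.signature == "All"
        assert abs(trial.n_treat - trial.n_ctrl) <= 1
        # while the confirmatory is open, evaluable entrants in the
        # graduated signature bypass platform randomization entirely
        members = quick_graduation_scenario.catalog.get(trial.signature).members
        grad_month = next(
            r.month
            for r in res.decision_history
            if r.decision.value == "graduate"
        )
        frame = res.patients_frame()
        closed = trial.closed_month if trial.closed_month is not None else res.state.month
        while_open = frame[
            (frame["entry_month"] >= grad_month + 1)
            & (frame["entry_month"] < closed + 1)
            & frame["subgroup_index"].isin(members)
            & (frame["arm"] != "observational")
        ]
        assert (while_open["confirmatory_id"] == trial.trial_id).all()
        # confirmatory patients exist and are platform-excluded
        conf_patients = frame[frame["confirmatory_id"] == trial.trial_id]
        assert len(conf_patients) == trial.n_treat + trial.n_ctrl
        assert conf_patients["subgroup_index"].isin(members).all()

    def test_trial_stops_early_when_everything_resolves(
        self, quick_graduation_scenario
    ):
        res = run_trial(quick_graduation_scenario, seed=8)
        if all(t.outcome != "pending" for t in res.confirmatory):
            assert res.state.month <= quick_graduation_scenario.horizon_months


class TestRerandomization:
    def _scenario(self):
        return ps.null_scenario(
            n_drugs=2, horizon_months=24, rerandomize=True, dropout_prob=0.0
        )

    def test_second_line_records_trace_back_to_active_arms(self):
        res = run_trial(self._scenario(), seed=9)
        frame = res.patients_frame()
        line2 = frame[frame["line"] == 2]
        assert len(line2) > 0
        assert frame["line"].max() <= 2  # never a third randomization
        line1 = frame[frame["line"] == 1].set_index("patient_id")
        for pid in line2["patient_id"]:
            assert line1.loc[pid, "arm"] in {"A", "B"}

    def test_control_and_observational_stay_put(self):
        res = run_trial(self._scenario(), seed=10)
        frame = res.patients_frame()
        stayers = frame[
            (frame["line"] == 1) & frame["arm"].isin(["control", "observational"])
        ]
        line2_ids = set(frame.loc[frame["line"] == 2, "patient_id"])
        assert not (set(stayers["patient_id"]) & line2_ids)

    def test_disabled_rerandomization_has_single_lines(self, short_null_scenario):
        res = run_trial(short_null_scenario, seed=12)
        assert (res.patients_frame()["line"] == 1).all()


class TestConfirmatoryAnalysis:
    def test_one_sided_logrank_calibrated_under_the_null(self):
        """With identical survival in both halves the rejection rate over
        replicates approximates the one-sided alpha."""
        rng = np.random.default_rng(13)
        alpha, reps, n = 0.15, 400, 60
        rejections = 0
        for _ in range(reps):
            t_a = rng.exponential(8, n)
            t_b = rng.exponential(8, n)
            e = np.ones(n, dtype=bool)
            if _one_sided_logrank(t_a, e, t_b, e) < alpha:
                rejections += 1
        rate = rejections / reps
        assert abs(rate - alpha) < 3 * np.sqrt(alpha * (1 - alpha) / reps)

    def test_rejects_with_a_real_effect(self):
        rng = np.random.default_rng(14)
        n = 200
        t_a = rng.exponential(18, n)
        t_b = rng.exponential(8, n)
        e = np.ones(n, dtype=bool)
        assert _one_sided_logrank(t_a, e, t_b, e) < 0.01
        # and the reversed direction is nowhere near rejection
        assert _one_sided_logrank(t_b, e, t_a, e) > 0.5

    def test_result_save_roundtrip(self, tmp_path, short_null_scenario):
        res = run_trial(short_null_scenario, seed=15)
        res.save(tmp_path)
        for name in (
            "patients.csv",
            "decisions.csv",
            "allocations.csv",
            "confirmatory.csv",
            "manifest.json",
        ):
            assert (tmp_path / name).exists()
        reloaded = pd.read_csv(tmp_path / "patients.csv")
        assert len(reloaded) == len(res.patients_frame())
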