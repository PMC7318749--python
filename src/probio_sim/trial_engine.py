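"""Discrete-time simulator of the adaptive platform trial.

The simulator advances in calendar months, the cadence at which outcome data
and randomization probabilities are updated.  Each month it:

1. accrues a Poisson number of new mCRPC patients, draws their biomarker
   profiles from the calibrated joint prevalence, and routes the
   non-evaluable fraction (undetectable ctDNA, technical failure,
   MSI/hypermutation) to an observational standard-of-care arm;
2. randomizes evaluable patients within their biomarker subgroup
   combination — into an open nested confirmatory trial when their subgroup
   belongs to a graduated signature, otherwise by the current platform
   allocation table;
3. optionally re-randomizes first-line progressors on active arms (maximum
   of two randomizations; control and observational patients remain in
   their arm upon progression);
4. runs the monthly interim: conjugate posteriors per (arm, signature)
   stratum with censoring at the current date, probabilities of superiority
   against the pooled control, graduation/futility/cap decisions with the
   subgroup-consistency guard, confirmatory-trial analyses, and the
   allocation-table update with control protection.

Progression-free survival is Weibull with fixed shape; each scenario states
a baseline mean PFS and additive mean-PFS effects per (treatment,
signature).  A patient on a drug receives the largest effect among the
signatures containing their subgroup; control and observational patients
receive the effect of the standard-of-care drug actually chosen for them
(sampled from a configurable physician's-choice mix, blind to biomarkers).

Everything is reproducible from (scenario, seed).
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import special, stats

from . import allocation as alloc
from .allocation import ArmState, ArmStatus, CONTROL
from .biomarker_model import (
    JointPrevalence,
    SignatureCatalog,
    calibrate_joint_prevalence,
    default_catalog,
    sample_subgroup_indices,
    N_SUBGROUPS,
)
from .decision_rules import (
    Decision,
    DecisionRecord,
    DecisionThresholds,
    apply_decisions,
    evaluate,
    subgroup_consistency,
)
from .weibull_bayes import PriorSpec, rate_for_mean, prob_superiority_arrays

__all__ = [
    "ScenarioConfig",
    "ScenarioError",
    "PlatformState",
    "ConfirmatoryTrial",
    "TrialResult",
    "accrue",
    "assign_true_pfs",
    "run_interim",
    "progress_and_rerandomize",
    "confirmatory_step",
    "run_trial",
]

OBSERVATIONAL = -1  # arm code for the observational SOC arm
CONTROL_CODE = 0  # arm code for the randomized control


class ScenarioError(ValueError):
    """Invalid simulation scenario."""


@dataclass(frozen=True)
class ScenarioConfig:
    """Complete specification of one simulated trial configuration.

    effects maps (treatment, signature) to the added mean PFS in months that
    the treatment confers on patients of that signature; absent pairs confer
    nothing.  control_mix gives the probability that the treating physician
    chooses each drug as standard of care (uniform over the treatments by
    default), so the control arm inherits the same signature effects as the
    corresponding active drugs.
    """

    treatments: tuple[str, ...] = ("A", "B", "C", "D")
    baseline_mean_pfs: float = 8.0
    shape_k: float = 1.0
    effects: Mapping[tuple[str, str], float] = field(default_factory=dict)
    control_mix: Mapping[str, float] | None = None
    accrual_rate: float = 7.0
    p_nonevaluable: float = 0.1
    horizon_months: int = 60
    burn_in_n: int = 50
    thresholds: DecisionThresholds = field(default_factory=DecisionThresholds)
    prior: PriorSpec = field(default_factory=PriorSpec)
    catalog: SignatureCatalog = field(default_factory=default_catalog)
    rerandomize: bool = False
    dropout_prob: float = 0.1
    confirmatory_alpha: float = 0.15
    confirmatory_target_events: int | None = None
    confirmatory_design_effect: float = 5.0
    confirmatory_power: float = 0.8
    seed: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "treatments", tuple(self.treatments))
        object.__setattr__(
            self,
            "effects",
            {(str(t), str(s)): float(m) for (t, s), m in dict(self.effects).items()},
        )
        self.validate()

    def validate(self) -> None:
        if not self.treatments:
            raise ScenarioError("at least one treatment is required")
        if len(set(self.treatments)) != len(self.treatments):
            raise ScenarioError("treatment names must be unique")
        if CONTROL in self.treatments:
            raise ScenarioError(f"{CONTROL!r} is reserved for the control arm")
        if self.baseline_mean_pfs <= 0:
            raise ScenarioError("baseline_mean_pfs must be positive")
        if self.shape_k <= 0:
            raise ScenarioError("shape_k must be positive")
        if self.accrual_rate <= 0:
            raise ScenarioError("accrual_rate must be positive")
        if not 0.0 <= self.p_nonevaluable <= 1.0:
            raise ScenarioError("p_nonevaluable must be a probability")
        if not 0.0 <= self.dropout_prob <= 1.0:
            raise ScenarioError("dropout_prob must be a probability")
        if self.horizon_months < 0:
            raise ScenarioError("horizon_months must be nonnegative")
        if self.burn_in_n < 0:
            raise ScenarioError("burn_in_n must be nonnegative")
        if not 0.0 < self.confirmatory_alpha < 1.0:
            raise ScenarioError("confirmatory_alpha must be in (0, 1)")
        names = set(self.catalog.names)
        for (t, s), months in self.effects.items():
            if t not in self.treatments:
                raise ScenarioError(f"effect refers to unknown treatment {t!r}")
            if s not in names:
                raise ScenarioError(f"effect refers to unknown signature {s!r}")
            if months < 0:
                raise ScenarioError("effects must be nonnegative months")
        if self.control_mix is not None:
            mix = dict(self.control_mix)
            if any(d not in self.treatments for d in mix):
                raise ScenarioError("control_mix refers to unknown treatments")
            if any(p < 0 for p in mix.values()):
                raise ScenarioError("control_mix probabilities must be >= 0")
            if abs(sum(mix.values()) - 1.0) > 1e-9:
                raise ScenarioError("control_mix must sum to 1")

    # -- serialization ----------------------------------------------------

    def resolved_control_mix(self) -> dict[str, float]:
        if self.control_mix is None:
            p = 1.0 / len(self.treatments)
            return {t: p for t in self.treatments}
        return dict(self.control_mix)

    def to_dict(self) -> dict:
        return {
            "treatments": list(self.treatments),
            "baseline_mean_pfs": self.baseline_mean_pfs,
            "shape_k": self.shape_k,
            "effects": [
                {"treatment": t, "signature": s, "months": m}
                for (t, s), m in sorted(self.effects.items())
            ],
            "control_mix": (
                None if self.control_mix is None else dict(self.control_mix)
            ),
            "accrual_rate": self.accrual_rate,
            "p_nonevaluable": self.p_nonevaluable,
            "horizon_months": self.horizon_months,
            "burn_in_n": self.burn_in_n,
            "thresholds": asdict(self.thresholds),
            "prior": asdict(self.prior),
            "signatures": [
                {
                    "name": s.name,
                    "members": sorted(s.members),
                    "prevalence": s.target_prevalence,
                }
                for s in self.catalog
            ],
            "rerandomize": self.rerandomize,
            "dropout_prob": self.dropout_prob,
            "confirmatory_alpha": self.confirmatory_alpha,
            "confirmatory_target_events": self.confirmatory_target_events,
            "confirmatory_design_effect": self.confirmatory_design_effect,
            "confirmatory_power": self.confirmatory_power,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, spec: Mapping) -> "ScenarioConfig":
        spec = dict(spec)
        kwargs: dict = {}
        for key in (
            "treatments",
            "baseline_mean_pfs",
            "shape_k",
            "control_mix",
            "accrual_rate",
            "p_nonevaluable",
            "horizon_months",
            "burn_in_n",
            "rerandomize",
            "dropout_prob",
            "confirmatory_alpha",
            "confirmatory_target_events",
            "confirmatory_design_effect",
            "confirmatory_power",
            "seed",
        ):
            if key in spec and spec[key] is not None:
                kwargs[key] = spec[key]
            elif key in spec and key == "control_mix":
                kwargs[key] = None
        if "effects" in spec:
            effects = spec["effects"]
            if isinstance(effects, Mapping):
                kwargs["effects"] = {
                    tuple(k.split("|", 1)) if isinstance(k, str) else tuple(k): v
                    for k, v in effects.items()
                }
            else:
                kwargs["effects"] = {
                    (e["treatment"], e["signature"]): e["months"] for e in effects
                }
        if "thresholds" in spec and spec["thresholds"] is not None:
            kwargs["thresholds"] = DecisionThresholds(**spec["thresholds"])
        if "prior" in spec and spec["prior"] is not None:
            kwargs["prior"] = PriorSpec(**spec["prior"])
        if "signatures" in spec and spec["signatures"] is not None:
            kwargs["catalog"] = SignatureCatalog.from_dict(
                {"signatures": spec["signatures"]}
            )
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScenarioConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def effect_matrix(self) -> np.ndarray:
        """(n_treatments, 16) array of the mean-PFS effect each drug confers
        on each subgroup: the max over containing signatures with a stated
        effect."""
        mat = np.zeros((len(self.treatments), N_SUBGROUPS))
        for (t, s), months in self.effects.items():
            d = self.treatments.index(t)
            for g in self.catalog.get(s).members:
                mat[d, g] = max(mat[d, g], months)
        return mat


@dataclass
class ConfirmatoryTrial:
    """Nested confirmatory stage for one graduated (treatment, signature).

    New platform entrants whose subgroup belongs to the graduated signature
    are split 1:1 by strict alternation between the graduated treatment and
    standard of care, so the arm counts never differ by more than one.  Once the target number of progression
    events is observed, a one-sided log-rank test at ``alpha`` decides
    reject (treatment confirmed) or fail.  The SOC half also continues to
    act as a comparator for the platform's remaining active arms.
    """

    trial_id: int
    treatment: str
    signature: str
    alpha: float = 0.15
    target_events: int = 50
    opened_month: int = 0
    outcome: str = "pending"  # pending | reject | fail
    closed_month: int | None = None
    p_value: float | None = None
    n_treat: int = 0
    n_ctrl: int = 0
    _next_treat: bool = True  # alternation pointer

    def assign(self) -> int:
        """Next 1:1 assignment: 1 = graduated treatment, 0 = SOC."""
        arm = 1 if self._next_treat else 0
        self._next_treat = not self._next_treat
        if arm == 1:
            self.n_treat += 1
        else:
            self.n_ctrl += 1
        return arm


class _Ledger:
    """Column-oriented patient ledger (one row per patient-line)."""

    COLUMNS = (
        "patient_id",
        "entry",
        "subgroup",
        "arm_code",
        "line",
        "true_pfs",
        "drug_code",
        "conf_id",
        "conf_arm",
    )

    def __init__(self) -> None:
        self.patient_id: list[int] = []
        self.entry: list[float] = []
        self.subgroup: list[int] = []
        self.arm_code: list[int] = []
        self.line: list[int] = []
        self.true_pfs: list[float] = []
        self.drug_code: list[int] = []
        self.conf_id: list[int] = []
        self.conf_arm: list[int] = []
        self.rerandomized: list[bool] = []

    def __len__(self) -> int:
        return len(self.entry)

    def append(
        self,
        patient_id: int,
        entry: float,
        subgroup: int,
        arm_code: int,
        line: int,
        true_pfs: float,
        drug_code: int,
        conf_id: int = -1,
        conf_arm: int = -1,
    ) -> None:
        self.patient_id.append(patient_id)
        self.entry.append(entry)
        self.subgroup.append(subgroup)
        self.arm_code.append(arm_code)
        self.line.append(line)
        self.true_pfs.append(true_pfs)
        self.drug_code.append(drug_code)
        self.conf_id.append(conf_id)
        self.conf_arm.append(conf_arm)
        self.rerandomized.append(False)

    def arrays(self) -> dict[str, np.ndarray]:
        return {
            "patient_id": np.asarray(self.patient_id, dtype=np.int64),
            "entry": np.asarray(self.entry, dtype=float),
            "subgroup": np.asarray(self.subgroup, dtype=np.int64),
            "arm_code": np.asarray(self.arm_code, dtype=np.int64),
            "line": np.asarray(self.line, dtype=np.int64),
            "true_pfs": np.asarray(self.true_pfs, dtype=float),
            "drug_code": np.asarray(self.drug_code, dtype=np.int64),
            "conf_id": np.asarray(self.conf_id, dtype=np.int64),
            "conf_arm": np.asarray(self.conf_arm, dtype=np.int64),
        }


@dataclass
class PlatformState:
    """Mutable state of one simulated platform trial."""

    scenario: ScenarioConfig
    month: int = 0
    ledger: _Ledger = field(default_factory=_Ledger)
    arm_status: ArmStatus = None  # type: ignore[assignment]
    allocation_table: alloc.AllocationTable = field(default_factory=dict)
    confirmatory: list[ConfirmatoryTrial] = field(default_factory=list)
    decision_history: list[DecisionRecord] = field(default_factory=list)
    allocation_history: list[tuple[int, int, str, float]] = field(
        default_factory=list
    )
    superiority: dict[tuple[str, str], float] = field(default_factory=dict)
    _next_patient_id: int = 0
    _joint: JointPrevalence = None  # type: ignore[assignment]
    _effect_matrix: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        sc = self.scenario
        if self.arm_status is None:
            self.arm_status = ArmStatus.all_active(sc.treatments, sc.catalog.names)
        if self._joint is None:
            self._joint = calibrate_joint_prevalence(sc.catalog)
        if self._effect_matrix is None:
            self._effect_matrix = sc.effect_matrix()
        if not self.allocation_table:
            self.allocation_table = alloc.build_allocation_table(
                sc.catalog, self.arm_status, None, burn_in=True
            )

    # -- counters ---------------------------------------------------------

    def total_active_n(self) -> int:
        """Platform patients randomized to active (non-control) arms, the
        burn-in counter."""
        return sum(
            1
            for arm, conf in zip(self.ledger.arm_code, self.ledger.conf_id)
            if arm >= 1 and conf < 0
        )

    def open_confirmatory(self, treatment: str, signature: str) -> ConfirmatoryTrial:
        trial = ConfirmatoryTrial(
            trial_id=len(self.confirmatory),
            treatment=treatment,
            signature=signature,
            alpha=self.scenario.confirmatory_alpha,
            target_events=_confirmatory_target(self.scenario, treatment, signature),
            opened_month=self.month,
        )
        self.confirmatory.append(trial)
        return trial

    def open_confirmatory_for(self, subgroup: int) -> ConfirmatoryTrial | None:
        for trial in self.confirmatory:
            if trial.outcome == "pending" and subgroup in self.scenario.catalog.get(
                trial.signature
            ).members:
                return trial
        return None


def _confirmatory_target(
    scenario: ScenarioConfig, treatment: str, signature: str
) -> int:
    """Number of progression events for the nested confirmatory test.

    Uses the Schoenfeld event count for a one-sided log-rank test at the
    confirmatory alpha with the configured power, against the scenario's own
    effect for the pair (falling back to the design effect when the pair is
    truly null, so a target always exists).
    """
    if scenario.confirmatory_target_events is not None:
        return int(scenario.confirmatory_target_events)
    effect = scenario.effects.get((treatment, signature), 0.0)
    if effect <= 0:
        effect = scenario.confirmatory_design_effect
    base = scenario.baseline_mean_pfs
    k = scenario.shape_k
    hr = rate_for_mean(base + effect, k) / rate_for_mean(base, k)
    z_a = stats.norm.ppf(1.0 - scenario.confirmatory_alpha)
    z_b = stats.norm.ppf(scenario.confirmatory_power)
    return max(10, math.ceil(4.0 * (z_a + z_b) ** 2 / math.log(hr) ** 2))


# -- monthly operations ---------------------------------------------------


def assign_true_pfs(
    subgroup: int,
    drug_index: int,
    scenario: ScenarioConfig,
    effect_matrix: np.ndarray,
    rng: np.random.Generator,
) -> float:
    """Draw a Weibull PFS time for a patient receiving the indexed drug.

    The mean is the baseline plus the drug's largest applicable signature
    effect for the patient's subgroup (zero when the drug is inert there).
    """
    if not 0 <= drug_index < len(scenario.treatments):
        raise ValueError(f"unknown drug index {drug_index}")
    mean = scenario.baseline_mean_pfs + effect_matrix[drug_index, subgroup]
    lam = rate_for_mean(mean, scenario.shape_k)
    return float(
        rng.weibull(scenario.shape_k) * lam ** (-1.0 / scenario.shape_k)
    )


def _draw_soc_drug(scenario: ScenarioConfig, rng: np.random.Generator) -> int:
    mix = scenario.resolved_control_mix()
    probs = np.array([mix[t] for t in scenario.treatments])
    return int(rng.choice(len(scenario.treatments), p=probs))


def accrue(
    state: PlatformState, scenario: ScenarioConfig, rng: np.random.Generator
) -> list[int]:
    """Accrue one month of patients and randomize them.

    Returns the ledger row indices of the new records.  Entry times are
    uniform within the month.  Non-evaluable patients go to the
    observational arm; patients in a graduated signature enter its open
    confirmatory trial; patients with no eligible arms anywhere (all pairs
    resolved for their subgroup) are observed on SOC.
    """
    n_new = int(rng.poisson(scenario.accrual_rate))
    if n_new == 0:
        return []
    entries = np.sort(state.month + rng.uniform(0.0, 1.0, size=n_new))
    subgroups = sample_subgroup_indices(state._joint, n_new, rng)
    nonevaluable = rng.uniform(size=n_new) < scenario.p_nonevaluable
    new_rows: list[int] = []
    for entry, subgroup, noneval in zip(entries, subgroups, nonevaluable):
        subgroup = int(subgroup)
        pid = state._next_patient_id
        state._next_patient_id += 1
        conf_id, conf_arm = -1, -1
        if noneval:
            arm_code = OBSERVATIONAL
            drug = _draw_soc_drug(scenario, rng)
        else:
            trial = state.open_confirmatory_for(subgroup)
            if trial is not None:
                conf_id = trial.trial_id
                conf_arm = trial.assign()
                if conf_arm == 1:
                    drug = scenario.treatments.index(trial.treatment)
                    arm_code = drug + 1
                else:
                    drug = _draw_soc_drug(scenario, rng)
                    arm_code = CONTROL_CODE
            else:
                row = state.allocation_table.get(subgroup)
                if row is None:
                    arm_code = OBSERVATIONAL
                    drug = _draw_soc_drug(scenario, rng)
                else:
                    arm_id = alloc.randomize_patient(row, rng)
                    if arm_id == CONTROL:
                        arm_code = CONTROL_CODE
                        drug = _draw_soc_drug(scenario, rng)
                    else:
                        drug = scenario.treatments.index(arm_id)
                        arm_code = drug + 1
        pfs = assign_true_pfs(subgroup, drug, scenario, state._effect_matrix, rng)
        state.ledger.append(
            pid, float(entry), subgroup, arm_code, 1, pfs, drug, conf_id, conf_arm
        )
        new_rows.append(len(state.ledger) - 1)
    return new_rows


def progress_and_rerandomize(
    state: PlatformState, scenario: ScenarioConfig, rng: np.random.Generator
) -> int:
    """Re-enter first-line progressors on active arms at line 2.

    Only runs when the scenario enables re-randomization.  Progressions in
    the current month are detected; each progressor either discontinues
    (with the configured dropout probability) or is re-randomized by the
    current allocation table with an unchanged biomarker profile.  Control
    and observational patients remain in their arm; second-line progressors
    exit the trial.  Returns the number of re-randomized patients.
    """
    if not scenario.rerandomize:
        return 0
    now = state.month + 1.0
    ledger = state.ledger
    n_rerand = 0
    for i in range(len(ledger)):
        if (
            ledger.line[i] != 1
            or ledger.arm_code[i] < 1
            or ledger.conf_id[i] >= 0
            or ledger.rerandomized[i]
        ):
            continue
        t_prog = ledger.entry[i] + ledger.true_pfs[i]
        if t_prog > now:
            continue
        ledger.rerandomized[i] = True
        if rng.uniform() < scenario.dropout_prob:
            continue
        subgroup = ledger.subgroup[i]
        row = state.allocation_table.get(subgroup)
        if row is None:
            continue
        arm_id = alloc.randomize_patient(row, rng)
        if arm_id == CONTROL:
            arm_code = CONTROL_CODE
            drug = _draw_soc_drug(scenario, rng)
        else:
            drug = scenario.treatments.index(arm_id)
            arm_code = drug + 1
        pfs = assign_true_pfs(subgroup, drug, scenario, state._effect_matrix, rng)
        ledger.append(
            ledger.patient_id[i], t_prog, subgroup, arm_code, 2, pfs, drug
        )
        n_rerand += 1
    return n_rerand


def _interim_statistics(state: PlatformState, now: float) -> dict:
    """Event/exposure/count aggregates at calendar time ``now``.

    Returns per-(subgroup, arm-slot) arrays for the analysis pool (platform
    line-1 patients; confirmatory SOC patients are pooled into the control
    slot as comparators) and platform-only counts for the accrual metrics.
    Arm slot 0 is the control, slots 1..K the treatments.
    """
    sc = state.scenario
    k = sc.shape_k
    n_slots = len(sc.treatments) + 1
    a = state.ledger.arrays()
    entered = a["entry"] < now
    followup = np.maximum(now - a["entry"], 0.0)
    observed = np.minimum(a["true_pfs"], followup)
    event = (a["true_pfs"] <= followup) & entered
    exposure = np.where(entered, observed**k, 0.0)

    platform = (a["conf_id"] < 0) & (a["arm_code"] >= 0) & entered
    line1 = a["line"] == 1
    conf_ctrl = (a["conf_id"] >= 0) & (a["conf_arm"] == 0) & entered
    analysis = ((platform | conf_ctrl)) & line1

    counts = np.zeros((N_SUBGROUPS, n_slots))
    events = np.zeros((N_SUBGROUPS, n_slots))
    expos = np.zeros((N_SUBGROUPS, n_slots))
    idx = np.flatnonzero(analysis)
    np.add.at(counts, (a["subgroup"][idx], a["arm_code"][idx]), 1.0)
    np.add.at(events, (a["subgroup"][idx], a["arm_code"][idx]), event[idx])
    np.add.at(expos, (a["subgroup"][idx], a["arm_code"][idx]), exposure[idx])

    counts_platform = np.zeros((N_SUBGROUPS, n_slots))
    pidx = np.flatnonzero(platform)
    np.add.at(counts_platform, (a["subgroup"][pidx], a["arm_code"][pidx]), 1.0)

    return {
        "counts": counts,
        "events": events,
        "exposure": expos,
        "counts_platform": counts_platform,
        "arrays": a,
        "event": event,
        "observed": observed,
        "entered": entered,
    }


def run_interim(
    state: PlatformState, scenario: ScenarioConfig
) -> list[DecisionRecord]:
    """Monthly interim: posteriors, superiority, decisions, allocation.

    Censors every subject at the current calendar date, computes conjugate
    posteriors per (arm, signature) against the pooled control of the same
    stratum, evaluates graduation/futility/cap for every active pair with
    the subgroup-consistency guard, applies the decisions (spawning nested
    confirmatory trials on graduation), and recomputes the allocation table
    — burn-in equal split until 50 patients sit on active arms, control-
    protected adaptive proportions afterwards.
    """
    sc = scenario
    now = state.month + 1.0
    stats_ = _interim_statistics(state, now)
    counts, events, expos = stats_["counts"], stats_["events"], stats_["exposure"]
    counts_platform = stats_["counts_platform"]
    prior = sc.prior
    member = sc.catalog.member_matrix()  # (S, 16)

    # posterior parameters per (signature, arm slot)
    ev_sig = member.astype(float) @ events
    ex_sig = member.astype(float) @ expos
    n_sig_platform = member.astype(float) @ counts_platform
    alpha_sig = prior.alpha + ev_sig
    beta_sig = prior.beta + ex_sig

    sig_index = {name: i for i, name in enumerate(sc.catalog.names)}
    superiority: dict[tuple[str, str], float] = {}
    records: list[DecisionRecord] = []
    for (treatment, sig_name) in state.arm_status.active_pairs():
        d = sc.treatments.index(treatment) + 1
        s = sig_index[sig_name]
        p_sup = float(
            prob_superiority_arrays(
                alpha_sig[s, d], beta_sig[s, d], alpha_sig[s, 0], beta_sig[s, 0]
            )
        )
        superiority[(treatment, sig_name)] = p_sup
        members = sorted(sc.catalog.get(sig_name).members)
        per_subgroup = {}
        for g in members:
            n_g = int(counts_platform[g, d])
            if n_g >= sc.thresholds.consistency_min_n:
                p_g = float(
                    special.betainc(
                        prior.alpha + events[g, d],
                        prior.alpha + events[g, 0],
                        (prior.beta + expos[g, d])
                        / (2 * prior.beta + expos[g, d] + expos[g, 0]),
                    )
                )
                per_subgroup[g] = (n_g, p_g)
        consistent = subgroup_consistency(per_subgroup, sc.thresholds)
        n_treated = int(counts_platform[member[s], d].sum())
        n_total = int(n_sig_platform[s].sum())
        n_control = int(counts_platform[member[s], 0].sum())
        decision = evaluate(
            p_sup, n_treated, n_total, consistent, sc.thresholds
        )
        records.append(
            DecisionRecord(
                month=state.month,
                treatment=treatment,
                signature=sig_name,
                decision=decision,
                superiority=p_sup,
                n_treated=n_treated,
                n_signature=n_total,
                n_control=n_control,
                consistency=consistent,
            )
        )

    apply_decisions(state, records)
    state.decision_history.extend(records)
    state.superiority = superiority

    confirmatory_step(state, scenario)

    burn_in = alloc.in_burn_in(state.total_active_n(), sc.burn_in_n)
    state.allocation_table = alloc.build_allocation_table(
        sc.catalog, state.arm_status, superiority, burn_in=burn_in
    )
    for subgroup, row in state.allocation_table.items():
        for arm_id, p in row.items():
            state.allocation_history.append((state.month, subgroup, arm_id, p))
    return records


def confirmatory_step(
    state: PlatformState, scenario: ScenarioConfig
) -> None:
    """Analyze any open confirmatory trial that has reached its event target.

    The comparison uses only the nested trial's own patients (never the
    platform controls): a log-rank test, made one-sided at the confirmatory
    alpha with the direction taken from the arms' event/exposure rate
    estimates.
    """
    now = state.month + 1.0
    open_trials = [t for t in state.confirmatory if t.outcome == "pending"]
    if not open_trials:
        return
    a = state.ledger.arrays()
    followup = np.maximum(now - a["entry"], 0.0)
    observed = np.minimum(a["true_pfs"], followup)
    event = a["true_pfs"] <= followup
    for trial in open_trials:
        mask = a["conf_id"] == trial.trial_id
        if int(event[mask].sum()) < trial.target_events:
            continue
        treat = mask & (a["conf_arm"] == 1)
        ctrl = mask & (a["conf_arm"] == 0)
        p_one = _one_sided_logrank(
            observed[treat], event[treat], observed[ctrl], event[ctrl]
        )
        trial.p_value = p_one
        trial.outcome = "reject" if p_one < trial.alpha else "fail"
        trial.closed_month = state.month


def _one_sided_logrank(
    t_treat: np.ndarray,
    e_treat: np.ndarray,
    t_ctrl: np.ndarray,
    e_ctrl: np.ndarray,
) -> float:
    """One-sided log-rank p-value for treatment superiority (longer PFS)."""
    from lifelines.statistics import logrank_test

    if len(t_treat) == 0 or len(t_ctrl) == 0:
        return 1.0
    res = logrank_test(t_treat, t_ctrl, e_treat, e_ctrl)
    # direction from the exponential rate estimates (events per exposure)
    rate_t = e_treat.sum() / max(t_treat.sum(), 1e-12)
    rate_c = e_ctrl.sum() / max(t_ctrl.sum(), 1e-12)
    p_two = float(res.p_value)
    return p_two / 2.0 if rate_t < rate_c else 1.0 - p_two / 2.0


# -- whole-trial driver ---------------------------------------------------


@dataclass
class TrialResult:
    """Complete, replayable outcome of one simulated trial."""

    scenario: ScenarioConfig
    seed: int
    state: PlatformState

    @property
    def decision_history(self) -> list[DecisionRecord]:
        return self.state.decision_history

    @property
    def confirmatory(self) -> list[ConfirmatoryTrial]:
        return self.state.confirmatory

    def final_states(self) -> dict[tuple[str, str], ArmState]:
        return dict(self.state.arm_status.states)

    def patients_frame(self) -> pd.DataFrame:
        a = self.state.ledger.arrays()
        horizon = float(self.state.month)
        followup = np.maximum(horizon - a["entry"], 0.0)
        observed = np.minimum(a["true_pfs"], followup)
        event = a["true_pfs"] <= followup
        arm_names = np.array(
            ["observational", CONTROL, *self.scenario.treatments], dtype=object
        )
        frame = pd.DataFrame(
            {
                "patient_id": a["patient_id"],
                "entry_month": a["entry"],
                "line": a["line"],
                "subgroup_index": a["subgroup"],
                "arm": arm_names[a["arm_code"] + 1],
                "received_drug": [
                    self.scenario.treatments[d] for d in a["drug_code"]
                ],
                "true_pfs": a["true_pfs"],
                "observed_time": observed,
                "event": event.astype(int),
                "confirmatory_id": a["conf_id"],
            }
        )
        return frame

    def decisions_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "month": r.month,
                    "treatment": r.treatment,
                    "signature": r.signature,
                    "decision": r.decision.value,
                    "superiority": r.superiority,
                    "n_treated": r.n_treated,
                    "n_signature": r.n_signature,
                    "n_control": r.n_control,
                    "consistency": r.consistency,
                }
                for r in self.decision_history
            ]
        )

    def allocations_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.state.allocation_history,
            columns=["month", "subgroup_index", "arm", "probability"],
        )

    def confirmatory_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "trial_id": t.trial_id,
                    "treatment": t.treatment,
                    "signature": t.signature,
                    "alpha": t.alpha,
                    "target_events": t.target_events,
                    "opened_month": t.opened_month,
                    "closed_month": t.closed_month,
                    "outcome": t.outcome,
                    "p_value": t.p_value,
                    "n_treat": t.n_treat,
                    "n_ctrl": t.n_ctrl,
                }
                for t in self.confirmatory
            ]
        )

    def manifest(self) -> dict:
        return {
            "config_hash": self.scenario.config_hash(),
            "seed": self.seed,
            "months_run": self.state.month,
            "n_patient_lines": len(self.state.ledger),
        }

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.patients_frame().to_csv(out / "patients.csv", index=False)
        self.decisions_frame().to_csv(out / "decisions.csv", index=False)
        self.allocations_frame().to_csv(out / "allocations.csv", index=False)
        self.confirmatory_frame().to_csv(out / "confirmatory.csv", index=False)
        with open(out / "manifest.json", "w") as fh:
            json.dump(self.manifest(), fh, indent=2)


def run_trial(scenario: ScenarioConfig, seed: int | None = None) -> TrialResult:
    """Simulate one complete platform trial.

    Monthly loop of accrual, randomization, optional re-randomization,
    interim analysis, and confirmatory updates, until the horizon is reached
    or every treatment-signature pair is resolved and every confirmatory
    trial has reported.  Bit-for-bit reproducible from (scenario, seed).
    """
    if seed is None:
        seed = scenario.seed
    if seed is None:
        raise ScenarioError("a seed is required for a reproducible run")
    scenario.validate()
    rng = np.random.default_rng(seed)
    state = PlatformState(scenario=scenario)
    for month in range(scenario.horizon_months):
        state.month = month
        accrue(state, scenario, rng)
        progress_and_rerandomize(state, scenario, rng)
        run_interim(state, scenario)
        state.month = month + 1
        if not state.arm_status.active_pairs() and all(
            t.outcome != "pending" for t in state.confirmatory
        ):
            break
    return TrialResult(scenario=scenario, seed=seed, state=state)
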