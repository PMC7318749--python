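"""Replicated simulation and operating-characteristics estimation.

Operating characteristics of a platform design — type-I error, power,
expected sample size and duration — cannot be derived in closed form, so
they are estimated by Monte Carlo: many independent trial replicates under a
fixed scenario, with decisions scored against the scenario's truth table
(which treatment-signature pairs are truly effective).

Error-rate conventions:

* the *per-drug* type-I error is the probability that a truly ineffective
  drug graduates in at least one signature within a replicate;
* the *familywise* (overall) type-I error is the probability that at least
  one truly-null treatment-signature pair graduates anywhere in a replicate;
* the two-stage error of graduate-then-confirm is the product of the
  screening familywise bound and the confirmatory alpha (independent
  stages), e.g. 30% x 15% = 4.5%.

All estimates carry Monte-Carlo standard errors and record the replicate
count and base seed, so bound checks are explicit and runs are replayable.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .allocation import ArmState
from .decision_rules import Decision
from .trial_engine import ScenarioConfig, TrialResult, run_trial

__all__ = [
    "TruthTable",
    "OCReport",
    "run_replicates",
    "type_one_error",
    "power_and_sample_size",
    "two_stage_type_one",
    "export_report",
    "load_report",
    "merge_reports",
]

#: Accrual bases available for the "participants per pair" summaries.
N_BASES = ("n_signature", "n_treated", "n_comparison")

#: Default basis: all randomized patients (control + active arms) in the
#: signature — the same accrual basis as the signature cap of 150.
DEFAULT_N_BASIS = "n_signature"


@dataclass(frozen=True)
class TruthTable:
    """Which (treatment, signature) pairs are truly effective in a scenario."""

    effective: frozenset[tuple[str, str]]
    treatments: tuple[str, ...]
    signatures: tuple[str, ...]

    @classmethod
    def from_scenario(cls, scenario: ScenarioConfig) -> "TruthTable":
        return cls(
            effective=frozenset(
                pair for pair, months in scenario.effects.items() if months > 0
            ),
            treatments=scenario.treatments,
            signatures=scenario.catalog.names,
        )

    def is_effective(self, treatment: str, signature: str) -> bool:
        return (treatment, signature) in self.effective

    def null_drugs(self) -> tuple[str, ...]:
        """Drugs with no effective signature anywhere."""
        effective_drugs = {t for t, _ in self.effective}
        return tuple(t for t in self.treatments if t not in effective_drugs)

    def null_pairs(self) -> tuple[tuple[str, str], ...]:
        return tuple(
            (t, s)
            for t in self.treatments
            for s in self.signatures
            if (t, s) not in self.effective
        )


def _extract_outcomes(result: TrialResult, rep: int) -> list[dict]:
    """One row per (treatment, signature) pair for a finished replicate."""
    final = result.final_states()
    resolution: dict[tuple[str, str], dict] = {}
    for rec in result.decision_history:
        if rec.decision is not Decision.CONTINUE:
            resolution[(rec.treatment, rec.signature)] = {
                "month": rec.month,
                "superiority": rec.superiority,
                "n_treated": rec.n_treated,
                "n_signature": rec.n_signature,
                "n_comparison": rec.n_treated + rec.n_control,
            }
    rows = []
    for (treatment, signature), state in final.items():
        res = resolution.get((treatment, signature))
        rows.append(
            {
                "rep": rep,
                "treatment": treatment,
                "signature": signature,
                "outcome": state.value,
                "resolution_month": None if res is None else res["month"],
                "months_in_platform": (
                    result.state.month if res is None else res["month"] + 1
                ),
                "superiority": None if res is None else res["superiority"],
                "n_treated": None if res is None else res["n_treated"],
                "n_signature": None if res is None else res["n_signature"],
                "n_comparison": None if res is None else res["n_comparison"],
            }
        )
    return rows


@dataclass
class OCReport:
    """Aggregated decision outcomes over a batch of trial replicates.

    ``pair_outcomes`` holds one row per (replicate, treatment, signature)
    with the pair's terminal state and its accrual figures at resolution;
    every summary below is recomputed from this table, so archived CSVs
    reproduce the live numbers exactly.
    """

    scenario: ScenarioConfig
    n_reps: int
    base_seed: int
    pair_outcomes: pd.DataFrame
    truth: TruthTable = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.truth is None:
            self.truth = TruthTable.from_scenario(self.scenario)

    # -- per-pair summaries ----------------------------------------------

    def graduation_rate(self, treatment: str, signature: str) -> float:
        df = self.pair_outcomes
        mask = (df["treatment"] == treatment) & (df["signature"] == signature)
        return float((df.loc[mask, "outcome"] == "graduated").mean())

    def pair_summary(self, n_basis: str = DEFAULT_N_BASIS) -> pd.DataFrame:
        """Graduation/drop/cap probabilities with Monte-Carlo standard
        errors, plus mean accrual and duration among graduating replicates,
        per (treatment, signature)."""
        if n_basis not in N_BASES:
            raise ValueError(f"n_basis must be one of {N_BASES}")
        rows = []
        df = self.pair_outcomes
        for (treatment, signature), grp in df.groupby(
            ["treatment", "signature"], sort=False
        ):
            n = len(grp)
            grad = grp["outcome"] == "graduated"
            p_grad = float(grad.mean())
            p_drop = float((grp["outcome"] == "dropped").mean())
            p_cap = float((grp["outcome"] == "capped").mean())
            grads = grp.loc[grad]
            rows.append(
                {
                    "treatment": treatment,
                    "signature": signature,
                    "truly_effective": self.truth.is_effective(
                        treatment, signature
                    ),
                    "n_reps": n,
                    "graduation_prob": p_grad,
                    "graduation_se": math.sqrt(p_grad * (1 - p_grad) / n),
                    "drop_prob": p_drop,
                    "cap_prob": p_cap,
                    "mean_n_at_graduation": (
                        float(grads[n_basis].mean()) if len(grads) else None
                    ),
                    "se_n_at_graduation": (
                        float(grads[n_basis].std(ddof=1) / math.sqrt(len(grads)))
                        if len(grads) > 1
                        else None
                    ),
                    "mean_months_at_graduation": (
                        float(grads["months_in_platform"].mean())
                        if len(grads)
                        else None
                    ),
                }
            )
        return pd.DataFrame(rows)

    # -- replicate-level indicator helpers --------------------------------

    def _reps_with_false_graduation(self) -> pd.Series:
        df = self.pair_outcomes
        null_pairs = set(self.truth.null_pairs())
        is_null = [
            (t, s) in null_pairs
            for t, s in zip(df["treatment"], df["signature"])
        ]
        false_grad = (df["outcome"] == "graduated") & pd.Series(
            is_null, index=df.index
        )
        return false_grad.groupby(df["rep"]).any()

    def familywise_error(self) -> tuple[float, float]:
        """(rate, Monte-Carlo SE) of >= 1 truly-null pair graduating."""
        per_rep = self._reps_with_false_graduation()
        rate = float(per_rep.mean())
        return rate, math.sqrt(rate * (1 - rate) / len(per_rep))

    def per_drug_error(self) -> dict[str, tuple[float, float]]:
        """Per truly-null drug: (rate, SE) of graduating in any signature."""
        df = self.pair_outcomes
        out: dict[str, tuple[float, float]] = {}
        for drug in self.truth.null_drugs():
            sub = df[df["treatment"] == drug]
            per_rep = (sub["outcome"] == "graduated").groupby(sub["rep"]).any()
            rate = float(per_rep.mean())
            out[drug] = (rate, math.sqrt(rate * (1 - rate) / len(per_rep)))
        return out


def run_replicates(
    scenario: ScenarioConfig,
    n_reps: int,
    base_seed: int,
    progress: bool = False,
) -> OCReport:
    """Run ``n_reps`` independent trial replicates and aggregate outcomes.

    Replicate ``i`` uses seed ``base_seed + i``, so disjoint seed batches
    are independent and pooling two batches equals one larger batch
    (results do not depend on execution order).
    """
    if n_reps < 1:
        raise ValueError("n_reps must be at least 1")
    rows: list[dict] = []
    for i in range(n_reps):
        result = run_trial(scenario, seed=base_seed + i)
        rows.extend(_extract_outcomes(result, rep=i))
        if progress and (i + 1) % 25 == 0:
            print(f"  replicate {i + 1}/{n_reps}")
    return OCReport(
        scenario=scenario,
        n_reps=n_reps,
        base_seed=base_seed,
        pair_outcomes=pd.DataFrame(rows),
    )


def merge_reports(first: OCReport, second: OCReport) -> OCReport:
    """Pool two replicate batches of the same scenario.

    Replicate indices of the second batch are offset, so pooled rates equal
    the replicate-weighted mean of the batch rates.
    """
    if first.scenario.config_hash() != second.scenario.config_hash():
        raise ValueError("cannot merge reports from different scenarios")
    shifted = second.pair_outcomes.copy()
    shifted["rep"] = shifted["rep"] + first.n_reps
    return OCReport(
        scenario=first.scenario,
        n_reps=first.n_reps + second.n_reps,
        base_seed=first.base_seed,
        pair_outcomes=pd.concat(
            [first.pair_outcomes, shifted], ignore_index=True
        ),
    )


def type_one_error(
    report: OCReport, truth: TruthTable | None = None
) -> dict:
    """Per-drug and familywise false-graduation rates.

    ``truth`` defaults to the report's own scenario truth table; passing a
    truth table with effective pairs marked for a scoring request that
    claims to be null raises, because the rates would not be type-I errors.
    """
    truth = truth or report.truth
    if truth.effective and truth != report.truth:
        raise ValueError(
            "a null scoring request must not contain effective pairs"
        )
    familywise, fw_se = report.familywise_error()
    per_drug = report.per_drug_error()
    return {
        "familywise": familywise,
        "familywise_se": fw_se,
        "per_drug": {d: rate for d, (rate, _) in per_drug.items()},
        "per_drug_se": {d: se for d, (_, se) in per_drug.items()},
        "max_per_drug": max(
            (rate for rate, _ in per_drug.values()), default=0.0
        ),
    }


def power_and_sample_size(
    report: OCReport,
    truth: TruthTable | None = None,
    n_basis: str = DEFAULT_N_BASIS,
) -> pd.DataFrame:
    """Power, accrual and duration for each truly effective pair.

    Power is the fraction of replicates in which the pair graduates; mean
    participants and months are averaged over graduating replicates only,
    and reported as missing (not zero) when no replicate graduates.
    """
    truth = truth or report.truth
    if not truth.effective:
        raise ValueError("scenario has no truly effective pair")
    summary = report.pair_summary(n_basis=n_basis)
    eff = summary[summary["truly_effective"]].copy()
    eff = eff.rename(columns={"graduation_prob": "power"})
    return eff[
        [
            "treatment",
            "signature",
            "n_reps",
            "power",
            "graduation_se",
            "mean_n_at_graduation",
            "se_n_at_graduation",
            "mean_months_at_graduation",
        ]
    ].reset_index(drop=True)


def two_stage_type_one(
    screening_bound: float, confirmatory_alpha: float
) -> float:
    """Overall type-I error of graduate-then-confirm under independence:
    the product of the screening familywise bound and the confirmatory
    alpha (e.g., 0.30 x 0.15 = 0.045)."""
    for p in (screening_bound, confirmatory_alpha):
        if not 0.0 <= p <= 1.0:
            raise ValueError("both arguments must be probabilities")
    return screening_bound * confirmatory_alpha


def export_report(
    report: OCReport,
    path: str | Path,
    n_basis: str = DEFAULT_N_BASIS,
    plots: bool = False,
) -> None:
    """Write an OCReport to a directory: pair outcomes and summary CSVs, a
    JSON manifest with the headline rates, and (optionally) a graduation
    probability bar chart."""
    out = Path(path)
    out.mkdir(parents=True, exist_ok=True)
    report.pair_outcomes.to_csv(out / "pair_outcomes.csv", index=False)
    report.pair_summary(n_basis=n_basis).to_csv(
        out / "pair_summary.csv", index=False
    )
    familywise, fw_se = report.familywise_error()
    manifest = {
        "n_reps": report.n_reps,
        "base_seed": report.base_seed,
        "config_hash": report.scenario.config_hash(),
        "scenario": report.scenario.to_dict(),
        "n_basis": n_basis,
        "familywise_error": familywise,
        "familywise_error_se": fw_se,
        "per_drug_error": {
            d: rate for d, (rate, _) in report.per_drug_error().items()
        },
    }
    with open(out / "report.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    if plots:
        _plot_graduation(report, out / "graduation_probabilities.png")


def _plot_graduation(report: OCReport, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    summary = report.pair_summary()
    labels = summary["treatment"] + " / " + summary["signature"]
    fig, ax = plt.subplots(figsize=(8, 0.35 * len(summary) + 1.5))
    ax.barh(labels, summary["graduation_prob"], xerr=summary["graduation_se"])
    ax.set_xlabel("graduation probability")
    ax.set_xlim(0, 1)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def load_report(path: str | Path) -> OCReport:
    """Re-load an exported report; summaries recompute from the archived
    outcome table and match the original exactly."""
    out = Path(path)
    with open(out / "report.json") as fh:
        manifest = json.load(fh)
    scenario = ScenarioConfig.from_dict(manifest["scenario"])
    outcomes = pd.read_csv(out / "pair_outcomes.csv")
    return OCReport(
        scenario=scenario,
        n_reps=int(manifest["n_reps"]),
        base_seed=int(manifest["base_seed"]),
        pair_outcomes=outcomes,
    )
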