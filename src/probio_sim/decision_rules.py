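"""Graduation, futility and cap decisions per (treatment, signature).

At every monthly interim each active treatment-signature pair is scored by
its probability of superiority over the pooled control within the signature.
The pair *graduates* to the nested confirmatory stage when at least 20
patients have been treated in the signature, the superiority probability
reaches 85%, and the treatment also performs well in every member subgroup
with enough treated patients (the subgroup-consistency guard against
graduating on high-prevalence signatures alone).  It is *dropped* for
futility when the superiority probability falls to 15% or below — with no
minimum sample size, so clearly ineffective arms can exit early.  When the
signature's accrual reaches its cap (150 randomized patients) without either
decision, evaluation stops and the pair is frozen as inconclusive.

The engine emits recommendations; in the live trial the data and safety
monitoring board retains discretion.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import TYPE_CHECKING, Iterable, Mapping, Sequence

from .allocation import ArmState, ArmStatus

if TYPE_CHECKING:  # pragma: no cover - typing only
    from .trial_engine import PlatformState

__all__ = [
    "Decision",
    "DecisionThresholds",
    "DecisionRecord",
    "subgroup_consistency",
    "evaluate",
    "apply_decisions",
]


class Decision(str, enum.Enum):
    GRADUATE = "graduate"
    DROP = "drop"
    CONTINUE = "continue"
    CAP_REACHED = "cap_reached"


@dataclass(frozen=True)
class DecisionThresholds:
    """Design thresholds of the screening stage.

    graduation_prob: superiority probability required to graduate (0.85).
    futility_prob: superiority probability at or below which a pair drops
        (0.15).
    min_n_signature: treated patients in the signature required before
        graduation (20).
    max_n_signature: cap on randomized patients in a signature (150).
    consistency_prob: subgroup-level superiority each sufficiently-populated
        member subgroup must exceed for graduation (0.5).
    consistency_min_n: treated patients a member subgroup needs before the
        consistency check binds (1: every member subgroup with any treated
        patients must individually beat the control, the literal reading of
        the all-subgroups requirement; 0 would demand positive evidence in
        empty subgroups and block graduation outright, while larger values
        let high-prevalence signatures graduate on a handful of populated
        subgroups and inflate the false-graduation rate far beyond the
        design's calibrated type-I error).
    """

    graduation_prob: float = 0.85
    futility_prob: float = 0.15
    min_n_signature: int = 20
    max_n_signature: int = 150
    consistency_prob: float = 0.5
    consistency_min_n: int = 1

    def __post_init__(self) -> None:
        if not 0.0 <= self.futility_prob < self.graduation_prob <= 1.0:
            raise ValueError(
                "need 0 <= futility_prob < graduation_prob <= 1"
            )
        if not 0 < self.min_n_signature <= self.max_n_signature:
            raise ValueError("need 0 < min_n_signature <= max_n_signature")
        if not 0.0 <= self.consistency_prob <= 1.0:
            raise ValueError("consistency_prob must be a probability")


@dataclass(frozen=True)
class DecisionRecord:
    """One interim recommendation for a treatment-signature pair.

    ``n_treated`` counts patients on the treatment within the signature;
    ``n_signature`` counts all randomized patients (control + active arms)
    in the signature — the accrual basis of the cap; ``n_control`` counts
    the signature's control patients.
    """

    month: int
    treatment: str
    signature: str
    decision: Decision
    superiority: float
    n_treated: int
    n_signature: int
    n_control: int = 0
    consistency: bool = True


def subgroup_consistency(
    per_subgroup: Mapping[int, tuple[int, float]] | Iterable[tuple[int, float]],
    thresholds: DecisionThresholds = DecisionThresholds(),
) -> bool:
    """Is the treatment performing well in every populated member subgroup?

    ``per_subgroup`` gives, for each member subgroup of the signature, the
    number of treated patients and the superiority probability computed from
    that subgroup's data alone.  The check passes when every subgroup with at
    least ``consistency_min_n`` treated patients exceeds
    ``consistency_prob``; it passes vacuously when no subgroup reaches the
    minimum count.
    """
    pairs = (
        per_subgroup.values()
        if isinstance(per_subgroup, Mapping)
        else per_subgroup
    )
    return all(
        p > thresholds.consistency_prob
        for n, p in pairs
        if n >= thresholds.consistency_min_n
    )


def evaluate(
    superiority: float,
    n_treated: int,
    n_signature_total: int,
    consistency: bool,
    thresholds: DecisionThresholds = DecisionThresholds(),
) -> Decision:
    """Single-pass decision for one active pair at one interim.

    Graduation requires the minimum treated count, the superiority threshold
    and subgroup consistency; futility has no minimum count by default and
    is checked next; then the accrual cap; otherwise continue.
    """
    if not 0.0 <= superiority <= 1.0:
        raise ValueError("superiority must be a probability")
    if n_treated < 0 or n_signature_total < 0:
        raise ValueError("counts must be nonnegative")
    if (
        n_treated >= thresholds.min_n_signature
        and superiority >= thresholds.graduation_prob
        and consistency
    ):
        return Decision.GRADUATE
    if superiority <= thresholds.futility_prob:
        return Decision.DROP
    if n_signature_total >= thresholds.max_n_signature:
        return Decision.CAP_REACHED
    return Decision.CONTINUE


_DECISION_TO_STATE = {
    Decision.GRADUATE: ArmState.GRADUATED,
    Decision.DROP: ArmState.DROPPED,
    Decision.CAP_REACHED: ArmState.CAPPED,
}


def apply_decisions(
    state: "PlatformState | ArmStatus",
    records: Sequence[DecisionRecord],
) -> list[DecisionRecord]:
    """Apply one interim's recommendations to the platform state.

    Graduated pairs leave the platform's active arms for their signature and
    spawn a nested confirmatory trial; dropped pairs are removed; capped
    pairs freeze as inconclusive.  A treatment with no remaining active
    signature has exited the platform entirely (this falls out of the status
    ledger — allocation simply finds it eligible nowhere).

    ``state`` may be a full :class:`~probio_sim.trial_engine.PlatformState`
    (confirmatory trials are then spawned on it) or a bare
    :class:`~probio_sim.allocation.ArmStatus`.  Returns the graduation
    records, in order.  Raises on conflicting records for one pair: decision
    evaluation must be single-pass.
    """
    seen: set[tuple[str, str]] = set()
    for rec in records:
        key = (rec.treatment, rec.signature)
        if key in seen:
            raise ValueError(
                f"conflicting decision records for pair {key} in one interim"
            )
        seen.add(key)

    status = state if isinstance(state, ArmStatus) else state.arm_status
    graduated: list[DecisionRecord] = []
    for rec in records:
        if rec.decision is Decision.CONTINUE:
            continue
        status.set_state(
            rec.treatment, rec.signature, _DECISION_TO_STATE[rec.decision]
        )
        if rec.decision is Decision.GRADUATE:
            graduated.append(rec)
            if not isinstance(state, ArmStatus):
                state.open_confirmatory(rec.treatment, rec.signature)
    return graduated
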