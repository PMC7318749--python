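"""Outcome-adaptive randomization with control protection.

Randomization happens within biomarker subgroup combinations.  Before the
platform has accrued a minimum number of patients on active arms (burn-in,
default 50), every subgroup row randomizes equally between the control and
each eligible treatment.  Thereafter each treatment's allocation is
proportional to its Bayesian probability of superiority over the control,
aggregated across the signatures containing the subgroup, while the control
receives a pseudo-weight equal to the best single-arm weight so that its
allocation probability never falls below any single treatment's — mimicking
1:1 randomization against the most promising arm.

Allocation tables are recomputed at monthly interims as a pure function of
the posterior superiority map and the arm status ledger.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .biomarker_model import SignatureCatalog, SubgroupCombination, N_SUBGROUPS

__all__ = [
    "CONTROL",
    "ArmState",
    "ArmStatus",
    "AllocationTable",
    "in_burn_in",
    "burn_in_row",
    "arm_weight",
    "adaptive_row",
    "randomize_patient",
    "build_allocation_table",
]

#: Reserved arm identifier for the standard-of-care control.
CONTROL = "control"


class ArmState(str, enum.Enum):
    ACTIVE = "active"
    GRADUATED = "graduated"
    DROPPED = "dropped"
    CAPPED = "capped"


#: States a (treatment, signature) pair can never leave.
ABSORBING_STATES = frozenset(
    {ArmState.GRADUATED, ArmState.DROPPED, ArmState.CAPPED}
)


@dataclass
class ArmStatus:
    """Per-(treatment, signature) life-cycle ledger.

    Graduated, dropped and capped are absorbing: attempting to move a pair
    out of them raises.
    """

    states: dict[tuple[str, str], ArmState] = field(default_factory=dict)

    @classmethod
    def all_active(
        cls, treatments: Iterable[str], signature_names: Iterable[str]
    ) -> "ArmStatus":
        sig_names = tuple(signature_names)
        return cls(
            {
                (t, s): ArmState.ACTIVE
                for t in treatments
                for s in sig_names
            }
        )

    @property
    def treatments(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for t, _ in self.states:
            seen.setdefault(t)
        return tuple(seen)

    def state(self, treatment: str, signature: str) -> ArmState:
        return self.states[(treatment, signature)]

    def set_state(self, treatment: str, signature: str, new: ArmState) -> None:
        current = self.states[(treatment, signature)]
        if current in ABSORBING_STATES and new != current:
            raise ValueError(
                f"({treatment}, {signature}) is {current.value}, an absorbing "
                f"state; cannot move to {new.value}"
            )
        self.states[(treatment, signature)] = new

    def active_pairs(self) -> list[tuple[str, str]]:
        return [k for k, v in self.states.items() if v is ArmState.ACTIVE]

    def active_signatures(self, treatment: str) -> set[str]:
        return {
            s
            for (t, s), v in self.states.items()
            if t == treatment and v is ArmState.ACTIVE
        }

    def treatment_in_platform(self, treatment: str) -> bool:
        """A treatment remains in the platform while active in >= 1 signature."""
        return bool(self.active_signatures(treatment))

    def copy(self) -> "ArmStatus":
        return ArmStatus(dict(self.states))


#: A full allocation table: subgroup index -> {arm_id: probability}.  A
#: subgroup absent from the table has no eligible arms; such patients route
#: to the observational arm upstream.
AllocationTable = dict[int, dict[str, float]]


def in_burn_in(total_active_n: int, burn_in_n: int = 50) -> bool:
    """True while fewer than ``burn_in_n`` patients sit on active arms
    platform-wide; fixed equal randomization applies."""
    if total_active_n < 0 or burn_in_n < 0:
        raise ValueError("counts must be nonnegative")
    return total_active_n < burn_in_n


def burn_in_row(eligible_arms: Sequence[str]) -> dict[str, float]:
    """Equal split of probability among the control and each eligible arm."""
    arms = list(eligible_arms)
    if not arms:
        raise ValueError(
            "no eligible arms; the patient should route to the "
            "observational arm upstream"
        )
    if CONTROL in arms:
        raise ValueError("the control is implicit, not an eligible arm")
    p = 1.0 / (len(arms) + 1)
    row = {arm: p for arm in arms}
    row[CONTROL] = p
    return row


def arm_weight(
    treatment: str,
    subgroup: SubgroupCombination | int,
    superiority: Mapping[tuple[str, str], float],
    catalog: SignatureCatalog,
    status: ArmStatus,
) -> float:
    """Subgroup-level allocation weight for one treatment.

    The weight is the unweighted mean of the treatment's superiority
    probabilities over the signatures that (a) contain the subgroup and
    (b) still have the treatment active.  Raises if the treatment is active
    in none of the containing signatures (the arm is then simply excluded
    from the allocation row).
    """
    index = subgroup if isinstance(subgroup, int) else subgroup.index
    probs = [
        superiority[(treatment, sig.name)]
        for sig in catalog
        if index in sig.members
        and status.state(treatment, sig.name) is ArmState.ACTIVE
    ]
    if not probs:
        raise ValueError(
            f"{treatment!r} is not active in any signature containing "
            f"subgroup {index}"
        )
    return float(np.mean(probs))


def adaptive_row(weights: Mapping[str, float]) -> dict[str, float]:
    """Allocation probabilities proportional to arm weights, with the
    control given a pseudo-weight equal to the largest arm weight.

    The control's probability therefore equals the maximum single-arm
    probability in the row.  If every weight is zero (no information can
    rank the arms) the row falls back to the equal burn-in split.
    """
    if not weights:
        raise ValueError("need at least one weighted arm")
    if any(w < 0 for w in weights.values()):
        raise ValueError("weights must be nonnegative")
    best = max(weights.values())
    if best == 0.0:
        return burn_in_row(list(weights))
    total = sum(weights.values()) + best
    row = {arm: w / total for arm, w in weights.items()}
    row[CONTROL] = best / total
    return row


def randomize_patient(
    row: Mapping[str, float], rng: np.random.Generator
) -> str:
    """One categorical draw from an allocation row."""
    arms = list(row)
    probs = np.fromiter((row[a] for a in arms), dtype=float, count=len(arms))
    if np.any(probs < 0) or abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError("allocation row must be a probability distribution")
    probs = probs / probs.sum()
    return arms[int(rng.choice(len(arms), p=probs))]


def build_allocation_table(
    catalog: SignatureCatalog,
    status: ArmStatus,
    superiority: Mapping[tuple[str, str], float] | None,
    burn_in: bool,
) -> AllocationTable:
    """Allocation rows for all 16 subgroups from the current platform state.

    During burn-in (or when ``superiority`` is None) rows are equal splits.
    Subgroups where no treatment is eligible are omitted from the table.
    """
    table: AllocationTable = {}
    for index in range(N_SUBGROUPS):
        eligible = [
            t
            for t in status.treatments
            if any(
                index in catalog.get(s).members
                for s in status.active_signatures(t)
            )
        ]
        if not eligible:
            continue
        if burn_in or superiority is None:
            table[index] = burn_in_row(eligible)
        else:
            weights = {
                t: arm_weight(t, index, superiority, catalog, status)
                for t in eligible
            }
            table[index] = adaptive_row(weights)
    return table
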