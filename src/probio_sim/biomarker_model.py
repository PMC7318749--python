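"""Biomarker combinatorics and synthetic patient profiles.

The trial stratifies metastatic castration-resistant prostate cancer (mCRPC)
patients on four binary tumor biomarkers: AR (mutations and structural
rearrangements of the androgen receptor), DRD (DNA-repair deficiency gene
alterations), TP53, and TEfus (TMPRSS2-ERG fusions).  The joint status of the
four markers defines 2**4 = 16 mutually exclusive *subgroup combinations*,
which are the randomization strata.  Treatments are evaluated at the coarser
level of *biomarker signatures* — overlapping unions of subgroup combinations
(e.g., all TP53-mutated patients).  A patient belongs to exactly one subgroup
combination but possibly to several signatures.

This module enumerates the subgroup combinations, defines the default
five-signature catalog with its estimated population prevalences, calibrates a
joint distribution over the 16 subgroups that reproduces those prevalences,
and draws reproducible synthetic patient profiles from it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MARKERS",
    "N_SUBGROUPS",
    "BiomarkerProfile",
    "SubgroupCombination",
    "Signature",
    "SignatureCatalog",
    "JointPrevalence",
    "CalibrationError",
    "enumerate_subgroups",
    "default_catalog",
    "signature_membership",
    "calibrate_joint_prevalence",
    "joint_from_marginals",
    "sample_profiles",
    "sample_subgroup_indices",
    "profiles_to_frame",
]

#: Marker names in index-bit order, most significant first.
MARKERS: tuple[str, ...] = ("ar", "drd", "tp53", "tefus")

N_SUBGROUPS = 16


@dataclass(frozen=True)
class BiomarkerProfile:
    """Mutation status of the four markers; True means mutated."""

    ar: bool
    drd: bool
    tp53: bool
    tefus: bool

    @property
    def index(self) -> int:
        """Subgroup index under the (AR, DRD, TP53, TEfus) bit convention,
        AR most significant."""
        return (
            (int(self.ar) << 3)
            | (int(self.drd) << 2)
            | (int(self.tp53) << 1)
            | int(self.tefus)
        )

    @classmethod
    def from_index(cls, index: int) -> "BiomarkerProfile":
        if not 0 <= index < N_SUBGROUPS:
            raise ValueError(f"subgroup index must be in [0, 16), got {index}")
        return cls(
            ar=bool(index >> 3 & 1),
            drd=bool(index >> 2 & 1),
            tp53=bool(index >> 1 & 1),
            tefus=bool(index & 1),
        )

    def status(self, marker: str) -> bool:
        if marker not in MARKERS:
            raise ValueError(f"unknown marker {marker!r}")
        return bool(getattr(self, marker))


@dataclass(frozen=True)
class SubgroupCombination:
    """One of the 16 mutually exclusive joint marker states."""

    index: int
    profile: BiomarkerProfile

    def __post_init__(self) -> None:
        if self.profile.index != self.index:
            raise ValueError(
                f"index {self.index} does not match profile bits "
                f"{self.profile.index}"
            )


def enumerate_subgroups() -> list[SubgroupCombination]:
    """All 16 subgroup combinations, ordered by index (0 = all wild-type)."""
    return [
        SubgroupCombination(i, BiomarkerProfile.from_index(i))
        for i in range(N_SUBGROUPS)
    ]


@dataclass(frozen=True)
class Signature:
    """A named union of subgroup combinations with a target prevalence.

    Signatures may overlap: a TP53-mutated, DRD-mutated patient is a member
    of both the TP53+ and the DRD+ signatures.
    """

    name: str
    members: frozenset[int]
    target_prevalence: float

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"signature {self.name!r} has no members")
        if not all(0 <= m < N_SUBGROUPS for m in self.members):
            raise ValueError(
                f"signature {self.name!r} has member indices outside [0, 16)"
            )
        if not 0.0 <= self.target_prevalence <= 1.0:
            raise ValueError(
                f"signature {self.name!r} target prevalence must be in [0, 1]"
            )

    @classmethod
    def from_constraints(
        cls,
        name: str,
        constraints: Mapping[str, bool],
        target_prevalence: float,
    ) -> "Signature":
        """Build a signature from marker-status constraints.

        ``constraints`` maps marker name to required status (True = mutated);
        unconstrained markers may take either value.
        """
        for marker in constraints:
            if marker not in MARKERS:
                raise ValueError(f"unknown marker {marker!r}")
        members = frozenset(
            sub.index
            for sub in enumerate_subgroups()
            if all(
                sub.profile.status(m) == want for m, want in constraints.items()
            )
        )
        return cls(name=name, members=members, target_prevalence=target_prevalence)

    def contains(self, subgroup_index: int) -> bool:
        return subgroup_index in self.members


@dataclass(frozen=True)
class SignatureCatalog:
    """Ordered collection of candidate signatures."""

    signatures: tuple[Signature, ...]

    def __post_init__(self) -> None:
        names = [s.name for s in self.signatures]
        if len(set(names)) != len(names):
            raise ValueError("duplicate signature names in catalog")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.signatures)

    def __iter__(self):
        return iter(self.signatures)

    def __len__(self) -> int:
        return len(self.signatures)

    def get(self, name: str) -> Signature:
        for s in self.signatures:
            if s.name == name:
                return s
        raise KeyError(f"no signature named {name!r}")

    def member_matrix(self) -> np.ndarray:
        """Boolean matrix (n_signatures, 16): entry [s, g] is membership of
        subgroup g in signature s."""
        mat = np.zeros((len(self.signatures), N_SUBGROUPS), dtype=bool)
        for i, sig in enumerate(self.signatures):
            mat[i, sorted(sig.members)] = True
        return mat

    @classmethod
    def from_dict(cls, spec: Mapping) -> "SignatureCatalog":
        """Build a catalog from a plain mapping (e.g., parsed YAML/JSON).

        Each entry of ``spec["signatures"]`` needs a ``name``, a
        ``prevalence``, and either explicit ``members`` (list of subgroup
        indices) or ``constraints`` (marker -> "mutated"/"wild-type").
        """
        sigs = []
        for entry in spec["signatures"]:
            name = entry["name"]
            prev = float(entry["prevalence"])
            if "members" in entry:
                sigs.append(
                    Signature(name, frozenset(int(m) for m in entry["members"]), prev)
                )
            else:
                constraints = {
                    marker: _parse_status(status)
                    for marker, status in entry["constraints"].items()
                }
                sigs.append(Signature.from_constraints(name, constraints, prev))
        return cls(tuple(sigs))


def _parse_status(status) -> bool:
    if isinstance(status, bool):
        return status
    text = str(status).strip().lower()
    if text in {"mutated", "mut", "+", "true", "1"}:
        return True
    if text in {"wild-type", "wildtype", "wt", "-", "false", "0"}:
        return False
    raise ValueError(f"cannot parse marker status {status!r}")


# Default signature names used throughout.
SIG_ALL = "All"
SIG_TP53NEG_ARNEG = "TP53- and AR-"
SIG_TP53 = "TP53+"
SIG_DRD = "DRD+"
SIG_TEFUS = "TEfus+"


def default_catalog() -> SignatureCatalog:
    """The five candidate signatures with their estimated prevalences.

    All patients (1.0); TP53 and AR double wild-type (0.5); TP53 mutated
    (0.37); DRD mutated (0.19); TMPRSS2-ERG fusion (0.32).  Membership is
    defined logically from marker status, so the three single-marker
    signatures each have 8 member subgroups and the double-negative has 4.
    """
    return SignatureCatalog(
        (
            Signature.from_constraints(SIG_ALL, {}, 1.0),
            Signature.from_constraints(
                SIG_TP53NEG_ARNEG, {"tp53": False, "ar": False}, 0.5
            ),
            Signature.from_constraints(SIG_TP53, {"tp53": True}, 0.37),
            Signature.from_constraints(SIG_DRD, {"drd": True}, 0.19),
            Signature.from_constraints(SIG_TEFUS, {"tefus": True}, 0.32),
        )
    )


def signature_membership(
    catalog: SignatureCatalog, subgroup: SubgroupCombination | int
) -> set[str]:
    """Names of every catalog signature containing the subgroup.

    Under the default catalog the result is never empty, because the "All"
    signature contains every subgroup.
    """
    index = subgroup if isinstance(subgroup, int) else subgroup.index
    if not 0 <= index < N_SUBGROUPS:
        raise ValueError(f"subgroup index must be in [0, 16), got {index}")
    return {s.name for s in catalog if index in s.members}


@dataclass(frozen=True)
class JointPrevalence:
    """Probability vector over the 16 subgroup combinations."""

    probs: np.ndarray = field()

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        object.__setattr__(self, "probs", probs)
        if probs.shape != (N_SUBGROUPS,):
            raise ValueError(f"probs must have shape (16,), got {probs.shape}")
        if np.any(probs < 0):
            raise ValueError("probabilities must be nonnegative")
        if abs(probs.sum() - 1.0) > 1e-12:
            raise ValueError("probabilities must sum to 1 within 1e-12")

    def signature_prevalence(self, signature: Signature) -> float:
        return float(self.probs[sorted(signature.members)].sum())

    def marker_marginal(self, marker: str) -> float:
        return float(
            sum(
                p
                for i, p in enumerate(self.probs)
                if BiomarkerProfile.from_index(i).status(marker)
            )
        )


class CalibrationError(ValueError):
    """Raised when signature prevalences admit no valid joint distribution."""


def joint_from_marginals(
    p_ar: float, p_drd: float, p_tp53: float, p_tefus: float
) -> JointPrevalence:
    """Product joint over the 16 subgroups from independent marker marginals."""
    for name, p in zip(MARKERS, (p_ar, p_drd, p_tp53, p_tefus)):
        if not 0.0 <= p <= 1.0:
            raise CalibrationError(f"marginal P({name}+) = {p:.4f} outside [0, 1]")
    marginals = dict(ar=p_ar, drd=p_drd, tp53=p_tp53, tefus=p_tefus)
    probs = np.empty(N_SUBGROUPS)
    for sub in enumerate_subgroups():
        p = 1.0
        for marker in MARKERS:
            m = marginals[marker]
            p *= m if sub.profile.status(marker) else 1.0 - m
        probs[sub.index] = p
    probs /= probs.sum()  # guard rounding; product already sums to 1
    return JointPrevalence(probs)


def calibrate_joint_prevalence(catalog: SignatureCatalog) -> JointPrevalence:
    """Joint subgroup distribution reproducing the catalog prevalences.

    The catalog prints only signature-level marginals, so the joint is built
    as a minimal-assumption product model: DRD, TP53 and TEfus marginals are
    read off their single-marker signatures, and the AR marginal is solved
    from the double wild-type constraint P(AR- & TP53-) = p under
    independence of AR and TP53, i.e. P(AR+) = 1 - p / (1 - P(TP53+)).

    Raises :class:`CalibrationError` if the constraints are infeasible (an
    implied marginal outside [0, 1]) or if some signature's prevalence cannot
    be reproduced by any product joint (e.g., a non-product membership set
    with an inconsistent target).
    """
    single: dict[str, float] = {}
    double_neg: tuple[float, frozenset[str]] | None = None
    for sig in catalog:
        constraints = _infer_constraints(sig)
        if constraints is None:
            continue
        if len(constraints) == 1:
            (marker, status), = constraints.items()
            if status:
                single[marker] = sig.target_prevalence
        elif len(constraints) == 2 and not any(constraints.values()):
            double_neg = (sig.target_prevalence, frozenset(constraints))

    missing = [m for m in ("drd", "tp53", "tefus") if m not in single]
    if missing:
        raise CalibrationError(
            f"catalog lacks single-marker signatures for {missing}; cannot "
            "identify their marginals"
        )
    p_tp53 = single["tp53"]
    if "ar" in single:
        p_ar = single["ar"]
    else:
        if double_neg is None or double_neg[1] != frozenset({"ar", "tp53"}):
            raise CalibrationError(
                "catalog pins P(AR+) neither directly nor via an "
                "AR-/TP53- double wild-type signature"
            )
        p_both_neg = double_neg[0]
        if p_tp53 >= 1.0:
            raise CalibrationError("P(TP53+) = 1 leaves P(AR+) unidentified")
        if p_both_neg > 1.0 - p_tp53 + 1e-12:
            raise CalibrationError(
                f"P(AR- & TP53-) = {p_both_neg} exceeds P(TP53-) = {1 - p_tp53}"
            )
        p_ar = 1.0 - p_both_neg / (1.0 - p_tp53)
    joint = joint_from_marginals(p_ar, single["drd"], p_tp53, single["tefus"])
    for sig in catalog:
        got = joint.signature_prevalence(sig)
        if abs(got - sig.target_prevalence) > 1e-9:
            raise CalibrationError(
                f"product joint gives prevalence {got:.6f} for signature "
                f"{sig.name!r}, target {sig.target_prevalence}"
            )
    return joint


def _infer_constraints(sig: Signature) -> dict[str, bool] | None:
    """Recover marker constraints if the member set is exactly a marker
    cylinder (all subgroups with some markers fixed); None otherwise."""
    for n_fixed in range(len(MARKERS) + 1):
        if len(sig.members) != N_SUBGROUPS >> n_fixed:
            continue
        from itertools import combinations, product

        for markers in combinations(MARKERS, n_fixed):
            for statuses in product((False, True), repeat=n_fixed):
                constraints = dict(zip(markers, statuses))
                members = frozenset(
                    sub.index
                    for sub in enumerate_subgroups()
                    if all(
                        sub.profile.status(m) == want
                        for m, want in constraints.items()
                    )
                )
                if members == sig.members:
                    return constraints
    return None


def sample_subgroup_indices(
    joint: JointPrevalence, n: int, rng: np.random.Generator | int
) -> np.ndarray:
    """``n`` i.i.d. subgroup indices from the joint; reproducible given seed."""
    if n < 0:
        raise ValueError("n must be nonnegative")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    return rng.choice(N_SUBGROUPS, size=n, p=joint.probs)


def sample_profiles(
    joint: JointPrevalence, n: int, seed: np.random.Generator | int
) -> list[BiomarkerProfile]:
    """``n`` i.i.d. synthetic patient profiles from the joint."""
    indices = sample_subgroup_indices(joint, n, seed)
    return [BiomarkerProfile.from_index(int(i)) for i in indices]


def profiles_to_frame(
    profiles: Sequence[BiomarkerProfile],
    catalog: SignatureCatalog | None = None,
) -> pd.DataFrame:
    """Tabulate profiles, one row per patient, for CSV export.

    Columns: patient_id, the four marker statuses (0/1), subgroup_index, and
    — when a catalog is given — a semicolon-joined list of signature
    memberships.
    """
    rows = {
        "patient_id": np.arange(len(profiles)),
        **{
            marker: [int(p.status(marker)) for p in profiles]
            for marker in MARKERS
        },
        "subgroup_index": [p.index for p in profiles],
    }
    frame = pd.DataFrame(rows)
    if catalog is not None:
        frame["signatures"] = [
            ";".join(
                s.name for s in catalog if p.index in s.members
            )
            for p in profiles
        ]
    return frame
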