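"""Reference simulation scenarios.

These builders encode the study conditions used for calibrating the design's
operating characteristics: four active drugs against physician's-choice
standard of care, the default five-signature catalog, accrual of about seven
evaluable-or-not patients per month, a 10% non-evaluable fraction, a baseline
mean PFS of 8 months (matching the prior mean of the Gamma(10, 80)
specification at shape 1), and a five-year horizon.
"""

from __future__ import annotations

from .biomarker_model import SIG_TP53
from .trial_engine import ScenarioConfig

__all__ = ["null_scenario", "single_effect_scenario"]


def null_scenario(
    n_drugs: int = 4,
    horizon_months: int = 60,
    **overrides,
) -> ScenarioConfig:
    """Global null: every drug shares the control's PFS distribution.

    Used to estimate the screening stage's type-I error — the probability
    that a truly ineffective drug graduates anywhere.
    """
    treatments = tuple(chr(ord("A") + i) for i in range(n_drugs))
    return ScenarioConfig(
        treatments=treatments,
        effects={},
        horizon_months=horizon_months,
        **overrides,
    )


def single_effect_scenario(
    effect_months: float,
    signature: str = SIG_TP53,
    n_drugs: int = 4,
    horizon_months: int = 60,
    **overrides,
) -> ScenarioConfig:
    """One effective drug in one signature; the other drugs are inert.

    Drug "A" prolongs mean PFS by ``effect_months`` for patients in the
    given signature (default TP53+, the kind of biomarker-restricted effect
    the platform is designed to detect).  The physician's-choice control mix
    is uniform over all drugs, so the control arm is partially diluted by
    the effective drug, as it would be in practice.
    """
    treatments = tuple(chr(ord("A") + i) for i in range(n_drugs))
    return ScenarioConfig(
        treatments=treatments,
        effects={("A", signature): float(effect_months)},
        horizon_months=horizon_months,
        **overrides,
    )
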