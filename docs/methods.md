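# Methods

This note documents the statistical model behind `probio_sim`, the design
choices made where the trial protocol leaves the machinery open, what the
synthetic-data generator does and does not emulate, and the numerical
conventions of the simulator.

## Survival model and inference

PFS times are Weibull with rate λ and fixed shape *k*, parameterized as
S(t) = exp(−λtᵏ). Conjugacy of the Gamma prior on λ holds only when *k* is
known, and the trial's stated ability to compute posteriors "without MCMC"
is only possible under that reading; the package therefore fixes *k* per
analysis (default 1, i.e., exponential PFS) and exposes it as
configuration. With the default Gamma(10, 80) prior and *k* = 1, the prior
mean PFS is β/α = 8 months — clinically plausible for all-comer mCRPC —
and the prior carries the weight of ten pseudo-patients (α_post − d = 10
always).

The update is `Gamma(α + d, β + Σ tᵢᵏ)` with every subject contributing
transformed exposure, progressed or censored. Interim censoring time is the
current calendar date minus entry date. Superiority is defined on the rate
(equivalently, on mean or median PFS — the orderings coincide at common
fixed shape) and computed exactly as a regularized incomplete beta
function; Monte-Carlo and quadrature equivalents exist only as test
oracles.

## Biomarker population

The trial publishes signature-level prevalences only. The generator builds
a joint distribution over the 16 subgroup combinations as a minimal
product model: P(TP53⁺) = 0.37, P(DRD⁺) = 0.19, P(TEfus⁺) = 0.32 read off
the single-marker signatures, and P(AR⁺) = 1 − 0.5/0.63 ≈ 0.206 solved
from the double wild-type constraint under AR ⫫ TP53. This reproduces all
five published prevalences exactly and is the least-assumption completion;
correlated joints can be supplied explicitly. Signature membership is
defined logically from marker status (each single-marker signature has 8
member subgroups, the double-negative 4), not parsed from any tabulated
marks. The catalog is data-driven, so new markers or signatures can be
introduced without code changes.

What the generator does **not** emulate: marker–marker correlation (beyond
the AR–TP53 constraint), clonal evolution of profiles between
randomizations (profiles are held fixed at re-randomization), calendar
drift in prevalence, and site effects. Passing tests therefore demonstrate
correctness of the design machinery under an idealized stationary
population, not performance on any real cohort.

## Randomization

Fixed equal randomization (control and each eligible arm) applies until 50
patients have been allocated to active arms platform-wide; adaptation then
starts. A treatment's subgroup-level weight is the unweighted mean of its
superiority probabilities over the signatures that contain the subgroup
and still have the treatment active (the protocol does not define this
aggregation; the mean is order-independent and reduces exactly to the
single-signature case). Control protection is implemented on
probabilities: the control receives a pseudo-weight equal to the largest
arm weight, so its allocation probability equals the maximum single-arm
probability in every row. Allocation is recomputed at monthly interims,
not per patient. With no outcome information anywhere, all superiority
probabilities are 0.5 and the adaptive row coincides with the burn-in
split — a consistent limit.

## Decision rules

Per (treatment, signature) at each monthly interim, in order: graduate if
≥ 20 treated patients in the signature, superiority ≥ 85%, and the
subgroup-consistency check passes; else drop if superiority ≤ 15% (no
minimum sample size — clearly ineffective arms may exit early); else
freeze as inconclusive if the signature has reached 150 randomized
patients; else continue. Graduated, dropped and capped are absorbing. The
cap counts all randomized patients (control + active) whose subgroup
belongs to the signature; a capped signature stops evaluation while its
patients continue to be randomized for other signatures.

The consistency requirement — the graduating treatment must perform well
in *all* member subgroup combinations — is quantified as subgroup-level
superiority strictly above 0.5, computed from each subgroup's data alone,
for every member subgroup with at least one treated patient
(`consistency_min_n = 1`). This is the literal reading restricted to
subgroups where the check is evaluable. The two neighboring readings fail
on the design's own published properties: requiring evidence in *empty*
subgroups blocks graduation outright (power ≈ 0 even for a 10-month
effect), while requiring three or more treated patients before the check
binds lets high-prevalence signatures graduate on a handful of populated
subgroups and roughly doubles the false-graduation rate. Both the minimum
count and the 0.5 threshold remain configuration.

## Simulator

Time advances in calendar months (the interim cadence). Accrual is Poisson
(default 7 patients/month, the trial's reported rate) with entry times
uniform within the month; 10% of patients are non-evaluable (undetectable
ctDNA, technical failure, MSI/hypermutation folded into one probability)
and enter an observational SOC arm. Control and observational patients
receive a standard-of-care drug sampled from a configurable
physician's-choice mix — uniform over the active drugs by default, and the
mix inherits the same signature effects as the corresponding active drugs,
since physicians choose without biomarker knowledge. A patient on a drug
receives the largest applicable signature effect (the protocol never
defines composition for overlapping effective signatures; max is the
conservative single-effect reading).

Re-randomization (off by default, since operating characteristics concern
screening-stage graduation) re-enters first-line progressors on active
arms at line 2 with profile unchanged, subject to a configurable dropout
probability (default 0.1); control and observational patients remain in
their arm; a second progression exits the trial. Analyses are stratified
by line, and decisions are driven by the first-line stratum.

The nested confirmatory trial assigns new patients of the graduated
signature 1:1 by strict alternation (counts never differ by more than
one); its SOC half also serves as a comparator for the platform's
remaining arms, while the confirmatory comparison itself uses only the
nested trial's own patients. The event target defaults to the Schoenfeld
count for a one-sided log-rank test at α = 0.15 with 80% power against the
scenario's own effect (falling back to a 5-month design effect for truly
null graduates). One-sidedness takes its direction from the arms'
event/exposure rate estimates.

Everything is reproducible from (scenario, seed): one `numpy` Generator
drives a replicate, replicate *i* of a batch uses `base_seed + i`, and run
manifests record the scenario hash and seed for bit-exact replay.

## Operating characteristics and problem sizes

Type-I error conventions: per-drug error is the probability that a
truly-null drug graduates in ≥ 1 signature in a replicate; familywise
error is the probability that ≥ 1 truly-null pair graduates anywhere. The
two-stage overall error is the product of the screening familywise bound
and the confirmatory alpha (0.30 × 0.15 = 0.045). All rates carry binomial
Monte-Carlo standard errors.

The packaged reproduction runs at desk scale: 200 replicates per scenario
(standard errors ≈ 3.5 percentage points on a 50% rate), 100,000 profile
draws for prevalence checks, 60-month horizon, accrual 7/month. The
acceptance script completes in a few minutes on one CPU at these sizes.

## Known limitations

* The original design calibration used an unpublished scenario grid with
  unknown accrual, horizon and replicate count; reproduction of its
  printed operating characteristics is approximate by construction. In
  particular, the number of monthly interim looks a pair experiences
  before its cap scales inversely with accrual, and the false-graduation
  rate of a repeatedly-tested posterior threshold grows with the number of
  looks. At 7 patients/month over 60 months this implementation measures a
  familywise false-graduation rate of roughly 45% and a worst per-drug
  rate of roughly 18–20%, above the design's published 30%/10% bounds;
  both are reported as measured rather than forced to the bounds. The
  published expected-duration band (21–30 months to graduation) likewise
  depends on the original accrual assumption and is treated as a
  diagnostic, not a target.
* Outcome-adaptive randomization is simulated without calendar-time drift;
  the known critique of adaptive designs under drift is out of scope.
* Safety/toxicity stopping, overall survival and other secondary
  endpoints, DSMB discretion, and mid-trial entry of new treatments are
  not modeled (the status ledger supports new arms structurally, but no
  entry-scheduling policy is implemented).
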