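# Methods

## Triage model

Each daily check-in scores eleven symptoms on a 0–3 ordinal scale. A triage
policy maps every (symptom, score) pair to a tier, green < amber < red; the
map must be total and non-decreasing in score for every symptom. The
published description of the deployed platform calls its thresholds
"UKONS-informed" without printing them, so the concrete table is treated as
service configuration. The package default — 0,1 → green, 2 → amber,
3 → red for all symptoms — is the simplest table consistent with a
green-dominant alert distribution (~75% green); a 1 → amber table could not
plausibly produce one. The multi-amber upgrade (two or more individually
amber symptoms ⇒ red) is on by default with threshold 2, following the
UKONS triage-toolkit convention; both the table and the upgrade are
overridable from YAML/JSON.

The check-in tier is the maximum per-symptom tier plus the upgrade; this
makes the tier monotone in every score, a property the suite tests. Exactly
one alert is emitted per check-in; per-symptom escalations are recorded
only as the alert's contributing symptoms and their domains. Temperature is
scored on the same ordinal scale by default; optional numeric cutpoints
(°C thresholds for scores 1–3) can derive the score from a measured value.

In-hours status is judged by converting the submission time to the
service's IANA timezone (default Europe/London) and testing membership in
the staffed window, Monday–Friday [09:00, 17:00). The window is half-open
so that a 17:00:00 submission is out-of-hours: a deterministic boundary in
place of an unstated one.

## Episode grouping

Amber/red alerts are consolidated per patient. An alert joins an open
episode when (a) it arrives no more than `episode_window_hours` (default
48, inclusive) after that episode's most recent alert, and (b) its domain
set intersects the episode's cumulative domain set (union over members).
Otherwise it opens a new episode, so one patient may carry several
concurrent episodes with distinct symptom patterns.

Two points were genuinely open in the source description and are resolved
here as package design choices:

* continuity is evaluated against the episode's *cumulative* domain set,
  not only the latest alert's domains — an episode models one evolving but
  connected clinical problem, and a GI → GI+pain → pain sequence should not
  fragment;
* when an alert is eligible for more than one open episode it joins the
  one with the most recent last alert, ties broken by larger domain
  intersection, then earlier episode start. Episodes are never merged.
  This makes the partition deterministic and auditable; shuffling the
  input record order never changes it (tested). Equal timestamps within a
  patient are ordered by check-in id.

On single-domain streams the rule reduces to classic 48-hour-gap chain
clustering, which the tests exploit as a brute-force oracle.

## Service analytics

All analyses are descriptive — counts, proportions, medians, ranges —
mirroring quality-improvement practice; no inferential statistics are
computed. Conventions:

* engagement = distinct check-in patient-days ÷ expected patient-days,
  where a patient's expected days run from enrollment to study end,
  inclusive of both endpoints; repeat same-day submissions count once in
  the numerator (each is still triaged);
* percentages are emitted with their numerator and denominator and
  rendered half-up to one decimal place (exact rational arithmetic via
  `decimal`, so 34.375% renders 34.4);
* timeliness covers in-hours red alerts only, using the first response per
  alert; unresponded alerts are reported separately, never folded into the
  delay distribution; "same day" compares service-local calendar dates,
  never UTC. Out-of-hours reds are reported as a count and share of all
  reds;
* run charts zero-fill every calendar day in the observed span and carry
  the median of the daily counts, the standard QI annotation.

## Safety case-finding

Every acute-care encounter (OHAU, ED, admission) is audited against the
preceding 48 hours (inclusive at −48 h, matching the episode-window
convention). Four candidate rules operationalize the predefined signal
categories: missed deterioration (green-only lookback with a same-day green
check-in before presentation), delayed escalation (in-hours red whose first
response exceeded a threshold, default 2 hours, chosen from the service's
own reporting of reviews that exceeded 2 hours; an unresponded red counts
as exceeded), inappropriate reassurance (a production-green check-in that a
reference audit policy would tier amber or worse — a constructed proxy that
only fires when the production policy is more lenient than the audit
policy), and technical failure (a check-in with no alert record). Output is
one audit per encounter, flagged or not, with the full lookback evidence
embedded; adjudication is explicitly a human step, and the tool never
asserts harm or attribution.

## Synthetic cohort generator

The generator emulates the statistical structure of the evaluated
deployment; it is a test harness calibrated to aggregate service
proportions, not a pharmacotoxicity model.

Latent structure per patient-day-symptom:

    z = α(symptom) + f(patient) + g(patient, symptom) + s(patient, day)
        + b(day-in-cycle) + ε,     ε ~ N(0, 1)

thresholded at shared cutpoints c1 < c2 < c3 into scores 0–3.
Components, with defaults and rationale:

| component | default | role |
|---|---|---|
| α, per-symptom baseline | fatigue 0.5 … bleeding −0.9 | relative symptom frequency; level absorbed by cutpoints |
| f, log of patient frailty multiplier | N(0, 0.6) | right-skewed per-patient burden (some patients never red, a few ≥10 reds) |
| g, patient×symptom susceptibility | N(0, 1.8) | a patient's alerts recur in their own symptoms, giving the domain continuity episodes need |
| s, AR(1) toxic-spell state | SD 1.2, autocorr 0.92 | multi-day bad spells, so alerts chain into multi-alert episodes |
| b, cycle bump | height 1.2, Gaussian around day 8 of 21, width 4 d | mid-cycle toxicity peaks |

The cutpoints are **not** free parameters. At run time they are solved
(2-D root find) so that the marginal green/amber/red probabilities of a
check-in equal the configured targets (default 0.749/0.158/0.093) under the
default triage policy, integrating over the day-level Gaussian effects
(Gauss–Hermite, 40 nodes; f and s marginalize jointly, g inflates the
per-symptom noise variance without breaking conditional independence
across symptoms) and the exact day-in-cycle occupancy implied by the
enrollment stagger. Parameter-recovery tests therefore compare simulated
frequencies against configured values, with nothing fitted after the fact.
When the targets are unreachable — strong day-level correlation puts a
floor under the red share, because double-amber days are upgraded to red —
calibration fails loudly rather than approximating.

Other generator components: enrollment staggered uniformly over the first
42 days (so expected patient-days ≈ 1580 for 32 patients over 70 days,
matching the reported 1574-day denominator and 12–70 per-patient check-in
range); daily adherence Bernoulli(0.917); submission times N(12:00, 3.5 h)
clipped to 06:00–22:00, which yields roughly half of red alerts in staffed
hours; first-response delays for in-hours reds drawn by inverse-CDF from a
log-normal (σ = 0.8) truncated to the observed 12–360 minute range, with
the log-location solved so the truncated median is exactly 47 minutes; an
episode review log with actionability probability 0.25/0.50 for
amber/red-max episodes and action mix 50/37.5/8.3/4.2% (telephone/OHAU/ED/
admission), escalating actions generating acute encounters; and rare
intraday deteriorations after a green check-in (rate 0.0015 per green
check-in, ≈2 per cohort) that produce encounters with no preceding alert,
exercising safety case-finding. All timestamps are timezone-aware; a given
config and seed reproduces every output file byte-for-byte.

What the generator does **not** reproduce: the deployed service reported a
5.8-fold alert-to-episode consolidation (mean 5.8 alerts per episode),
implying that nearly all of a patient's ~11 amber/red alerts fell into one
or two long episodes. Under this latent model the achievable consolidation
at the published tier mix is ≈2.5–3×: pushing day-to-day correlation high
enough for 5.8 lifts the multi-amber red floor above the published 9.3%
red share, so both cannot hold at once in this family. The defaults
prioritize the tier mix and keep consolidation qualitatively right
(multi-alert chains up to ~20 alerts, episodes per patient ≈ 2–7). Passing
pipeline tests on synthetic data therefore demonstrate rule correctness
and calibration of the targeted aggregates, not that real clinical episode
structure is reproduced. Tier-mix recovery tests use cluster-robust
standard errors (patients are the clusters) because frailty and spells
correlate a patient's check-ins; adherence is independent per patient-day
and uses plain binomial errors.

## Numerical and degenerate-input choices

* Tier-mix calibration: `scipy.optimize.root` (hybr) on (c2, log gap),
  residual tolerance 1e-8; c1 is pinned 1 latent unit below c2 (it only
  shapes the harmless 0-vs-1 split inside green).
* Truncated-lognormal location: Brent root find on the truncated median,
  with adaptive bracketing and clipped tail probabilities.
* Episode statistics on zero episodes raise `EmptyInput` (means are
  undefined; no NaN propagation). Engagement with zero expected days
  raises `ZeroExpectedDays`; burden with an empty roster raises
  `EmptyRoster`.
* Validation never imputes: a missing symptom, out-of-range score, or
  offset-less timestamp is a named, row-addressed error.

## Problem sizes

The default cohort is the deployment-scale 32 × 70 configuration (~1.5 s
end-to-end including triage, episodes, report, and safety pass).
Calibration-recovery checks use 500 × 70 (~35k patient-days, a few
seconds), chosen so that three standard errors of the recovered quantities
are small relative to their targets while the suite stays fast.

## Known limitations

* The score→tier table is a declared default, not the deployed service's
  (unpublished) table; results depending on the table should be read as
  properties of the configured policy.
* Episode continuity via the cumulative domain set is one defensible
  reading of "symptom-domain continuity"; the deployed service also used
  periodic human adjudication the package does not model.
* The inappropriate-reassurance rule is a constructed audit proxy; with
  identical production and audit policies it can never fire.
* Engagement makes no carve-outs for inpatient days or device downtime.
* The generator's consolidation-factor gap described above.
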