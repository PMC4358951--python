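# Methods

This note documents the model behind `rhdcea`: its structure and
assumptions, the parameters that matter and where their defaults come
from, the choices made where the published description of this class of
evaluation leaves the design open, and what the synthetic-data machinery
does and does not demonstrate.

## Model structure

The unit of analysis is a closed cohort (default 273,933 persons aged
5–24 at the 1986 index year) observed over a 10-year program window with
a lifetime horizon for consequences. Disease enters through first ARF
episodes: expected episodes in program year *t* equal the arm's incidence
(per 100,000 person-years) times the cohort size. The do-nothing arm
holds the 1986 incidence (12.2/100,000) constant; the program arm follows
the observed declining series (12.2 → 2.0/100,000).

Each episode cohort then traverses a fixed decision tree:

1. **First episode.** Death with the ARF case fatality (0.014 both arms);
   survivors develop RHD at first presentation with probability
   `rhd_given_first_arf`, split mild-moderate vs. severe carditis
   (`severe_given_first_rhd`). Severe carditis carries the arm's
   presentation case fatality (0.357 control / 0 intervention); surviving
   RHD cases undergo valve surgery with probability 0.071 (control).
2. **Recurrence.** Survivors face one-shot lifetime probabilities of at
   least one recurrence, by history (ARF-only 0.567/0.176, RHD
   0.778/0.250). A recurrence in an ARF-only patient may produce new RHD
   (`rhd_given_recurrence`, again split by severity, with the recurrent
   severe-carditis case fatality 0.444/0); a recurrence in an RHD patient
   may involve severe carditis with the same fatality.
3. **Progression.** Established mild-moderate disease progresses with
   probability `progression_given_mild`; progression carries its own case
   fatality (0.385/0) and surgery probability (0.154/0); non-operated
   progressed disease is treated as end-stage chronic RHD and is fatal
   after `chronic_rhd_duration` years (default 5).

Interpretive decisions, all configurable:

* **Recurrence/progression probabilities are lifetime (one-shot), not
  annual hazards.** The source tables state no time structure; applying
  them once per person at risk reproduces their definition as "probability
  of ≥1 recurrence".
* **Event timing.** Recurrences and first-presentation surgery occur one
  `event_lag` year (default 1) after onset, progression two, chronic death
  `2·lag + duration` years after onset. Attained ages at death drive YLL.
* **The "five years of chronic RHD followed by death" convention is
  applied to end-stage (progressed, non-operated) disease.** Compensated
  severe disease at presentation accrues disability and cost but not
  certain death; making every severe case fatal would push deaths — and
  averted YLL — far above anything consistent with the published DALY
  total.
* **Background mortality is ignored** (closed cohort, disease-attributable
  events only) and the susceptible pool is not depleted: with incidence
  ≤ 12.2 × 10⁻⁵/yr the depletion correction is below 10⁻³ relative.
* **Onset ages** follow a configurable distribution over the cohort age
  range, uniform by default; ages at downstream events are onset age plus
  the lags above.

A seeded microsimulation samples individuals through the identical
topology (same branch conditioning, integer counts) and is used only to
validate the expectation engine: every event total at n = 200,000 must
fall within four binomial standard errors of the scaled expectation.

## Reconstructed transition probabilities

The published main tables provide the incidence series, case-fatality,
recurrence and surgery rows. The remaining edges — probability of RHD
after a first or recurrent episode, the severity split, and the
progression probability — appeared only in unavailable supplementary
material. They are reconstructed as follows, and marked `[calibrated]` in
the defaults:

* Candidate values on a coarse grid (multiples of 0.05) were screened
  once against the published base-case aggregates (≈ $7.85 M direct
  medical savings, ≈ 5051 DALYs averted) and frozen:
  `rhd_given_first_arf` 0.60 / 0.05 (control / program),
  `rhd_given_recurrence` 0.80 / 0.05, severity split 0.10 / 0.05,
  `progression_given_mild` 0.25 / 0.05. The control values sit at the
  high end of the clinical literature on carditis after untreated ARF;
  the large arm contrast encodes the source's report that disease
  severity, not just incidence, collapsed under the program.
* `n_source` denominators — which set the width of every binomial bound
  and hence the spread of the probabilistic sensitivity analysis — are
  the model's own implied at-risk counts, rounded (e.g. 330 first-episode
  survivors in the control arm), floored at 5 where a program-arm stratum
  is nearly empty so bounds stay meaningful.

Limits of the reconstruction: with these edges the model reproduces the
published savings and DALY totals to within roughly 10%, but **not** the
published counts of averted ARF (231) and RHD (117) cases — the model
generates more, smaller-consequence cases. Those counts cannot be
reconciled with the printed incidence table under any reading (averted
first episodes computable from the table alone are ≈ 219, already short
of 231 before recurrences enter), so the calibration prioritises the
economic and burden totals that drive every downstream result. The event
ledger reports first episodes and recurrences separately so users can
apply their own definitions.

## DALYs

* **YLL** uses the classic GBD closed form with `C = 0.1658`, `β = 0.04`,
  age-weighting modulation `K = 1` and discount rate `r = 0`; setting
  `K = 0` reproduces unweighted (GBD-2010-style) DALYs, and `r > 0`
  switches to the full discounted expression (the r = 0 branch is the
  analytic limit, not a numerical approximation; the suite checks the
  closed form against quadrature to 10⁻⁸ across ages 0–80).
* **Residual life expectancy** comes from a packaged synthetic standard
  table consistent in level and shape with GBD-era reference life tables
  (82.5 years at birth, strictly decreasing, linearly interpolated,
  overridable in config).
* **YLD** is disability weight × duration without age weighting. Weights
  default to documented placeholders taken from the GBD-2010 families
  (acute severe infectious episode 0.21 for an ARF attack lasting 0.25
  years; heart-failure weights 0.07 / 0.186 for mild-moderate / severe
  RHD over the chronic duration). They are non-authoritative; YLD
  contributes only a few percent of DALYs here, so no headline quantity
  depends on them.

## Costs

All values are 2010 USD as published; no currency conversion or inflation
is performed.

* **Hospitalizations** are billed per episode: uncomplicated ARF episodes
  at $1490, new mild-moderate RHD at $2139, new severe RHD and
  progression events at $6343. A recurrent episode in an established RHD
  patient is billed under the patient's RHD category, not the
  uncomplicated-ARF tariff.
* **Lifetime follow-up costs** attach once per incident case according to
  its resolved state (ARF-only $15,515–18,699; mild-moderate RHD
  $21,359–25,259; severe RHD $40,714–49,298; operated $56,285–62,532).
  The larger endpoint maps to the youngest diagnosis age (longer
  remaining follow-up), linear in age between the cohort age limits.
  Acute deaths carry no lifetime stream; end-stage chronic deaths carry
  the severe stream, progression deaths the mild stream they lived in.
* **Secondary prophylaxis** is a separable component of each lifetime
  range ($3205–6222 ARF-only, $7262–11,161 with RHD, interpreted as
  full-adherence costs) and is scaled by the arm's adherence (0.683
  control, 0.969 intervention).
* **Program costs** (six components, totalling $202,890 over ten years)
  accrue to the intervention arm only. The printed components sum to
  $202,889 — one dollar short of the printed total, a rounding artefact
  in the source table — so the defaults carry the components rescaled by
  202,890/202,889 (sub-cent changes) to restore exact additivity.

## Probabilistic sensitivity analysis

Each of the (default 1000) draws samples every tree edge, both arms, from
a beta distribution fitted by the method of moments to its 95% bounds:
mean = bound midpoint, standard deviation = (high − low)/3.92. When the
point estimate is not the midpoint (bounds clipped at 0 or 1), the fit is
recentred on the point with the same spread; point estimates exactly at 0
or 1 fall back to the midpoint of the rule-of-three interval, which the
bound construction keeps strictly inside (0, 1), so no edge ever
degenerates. Zero-width bounds are treated as point masses. Medical and
program cost multipliers are drawn independently from Uniform(0.5, 2.0);
the medical multiplier applies jointly to both arms.

One seeded generator drives everything, with a documented draw order —
edges in sorted (edge, arm) order, then the medical, then the program
multiplier — so identical seeds give byte-identical per-draw tables. All
parameters are drawn independently (no correlation structure is
published). Summaries report both the mean of per-draw ICERs (the
headline) and the ratio of means; draws with non-positive DALYs averted
are excluded from the ICER mean with a logged count (none occur under the
defaults). The 95% interval is percentile-based (2.5th/97.5th).

## Scenarios

* *Lower program effectiveness*: the counterfactual declines linearly by
  2.5% of the base rate per year, `rate_t = 12.2 × (1 − 0.025 t)`
  (t = 0…9); a geometric variant (× 0.975ᵗ) is available behind a flag.
* *Longer RHD duration*: chronic duration 20 years instead of 5 (defers
  chronic deaths, extends disabled person-time).
* *Higher program cost*: every program component × 20. The source is
  internally inconsistent here (its table labels the scenario ten-fold
  while its text and abstract say 20-fold); the battery defaults to
  20-fold and exposes a ten-fold variant rather than reconciling.
* *Worst case*: all three simultaneously. Scenario application is pure
  (never mutates its input), idempotent for the base case, and commutes.

## Synthetic registries

`generate_registry` samples patient-level ARF case histories (onset year
∝ incidence, onset age from the onset distribution, downstream path from
the same sampler as the microsimulation) and serialises them as an event
line list; `estimate_probabilities` recovers every edge as events/at-risk
with binomial bounds, exactly as the original evaluation estimated its
inputs from aggregated registry reports. The registries emulate the
statistical structure the model assumes — and nothing more: no
under-ascertainment, reporting delay, migration, or model
mis-specification. Passing the round trip (generate → estimate → re-run
reproduces averted DALYs within 5% at 200,000 patients/arm) therefore
demonstrates internal consistency of the estimation machinery, not
robustness to real-world registry imperfections.

## Numerical and testing choices

* Expected counts are never rounded; currency is rounded only in
  human-readable summaries. Conservation (inflow = deaths + terminal
  classes per cell) holds to 10⁻⁹ relative and is asserted.
* Degenerate inputs: empty registries raise estimation errors; edges with
  zero at-risk count are reported absent, not zero; zero DALYs averted
  yields an "undefined" ICER flag rather than a division error; health
  loss with extra cost is flagged dominated.
* Problem sizes in the test suite — 200,000-individual microsimulation,
  100,000–200,000-patient registries, 1000-draw uncertainty analyses —
  were chosen so Monte Carlo error sits well inside each assertion's
  tolerance while the whole suite runs in well under a minute on one
  core.
* Seeded stochastic assertions use 4-standard-error windows where many
  checks run simultaneously, so nominal-coverage noise cannot trip a
  fixed-seed test.

## Known limitations

* The reconstructed edges are calibrated, not observed; conclusions that
  depend on their exact values (notably the worst-case cost-saving
  probability) carry reconstruction uncertainty of several percentage
  points beyond the Monte Carlo error.
* Averted ARF/RHD case counts are not comparable to the published counts
  (see above).
* The life table and disability weights are documented stand-ins, not the
  (uncited) originals.
* No transmission dynamics: the synergy between primary and secondary
  prevention enters only through the observed incidence series.
* Healthcare-system perspective only; no household or productivity costs.
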