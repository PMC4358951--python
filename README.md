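# rhdcea — cost-effectiveness of comprehensive ARF/RHD control

`rhdcea` is a decision-analytic cohort model for evaluating comprehensive
acute rheumatic fever (ARF) / rheumatic heart disease (RHD) control
programs — combined primary prevention (treating streptococcal
pharyngitis) and secondary prevention (registers plus penicillin
prophylaxis) — against a do-nothing counterfactual. It re-implements, as a
tested and configurable package, the economic evaluation of the 10-year
Pinar del Rio (Cuba, 1986–1996) program: a closed cohort of 273,933
children and young adults aged 5–24 is pushed through a decision tree of
ARF/RHD natural history, and the two arms are compared on
disability-adjusted life years (DALYs) averted and 2010-USD costs over a
lifetime horizon, without discounting, from the healthcare-system
perspective.

It is written for health economists and epidemiologists who want a
reproducible, fully parameterised version of this class of analysis:
every input (incidence series, transition probabilities with binomial
uncertainty bounds, cost schedules, DALY constants, acceptability
thresholds) is a documented, overridable configuration value.

## The model

**Cohort engine.** Expected first ARF episodes in program year *t* are
`incidence(arm, t) × N`. Each episode cohort is pushed along the tree:
death during the episode (case-fatality 0.014); RHD at first presentation,
split mild-moderate vs. severe carditis (severe cases face the arm's
case-fatality, e.g. 0.357 in the counterfactual); valve surgery; one-shot
lifetime recurrence probabilities by history (0.567 / 0.778 control,
0.176 / 0.250 intervention); progression of established mild-moderate
disease; and end-stage chronic RHD, fatal after a fixed duration (5 years
by default). All counts are expectations, exactly linear in cohort size; a
seeded individual-level microsimulation of the same topology serves as an
independent validation oracle.

**Health outcomes.** Years of life lost use the Global Burden of Disease
closed form with age weighting `C x e^{-βx}` (C = 0.1658, β = 0.04,
K = 1, discount rate r = 0):

    YLL(a, L) = K·C/β² · [e^{-βa}(βa+1) − e^{-β(a+L)}(β(a+L)+1)] + (1−K)·L

with `L` the residual life expectancy at the age of death. Years lived
with disability are disability weight × duration. DALYs averted =
control − intervention.

**Economics.** Medical costs combine per-episode hospitalization tariffs
with lifetime follow-up costs per incident case, interpolated in age at
diagnosis (the younger the diagnosis, the longer and costlier the
follow-up) and with the secondary-prophylaxis component scaled by each
arm's adherence (68.3% vs. 96.9%). Program costs (total US$ 202,890 over
ten years) accrue to the intervention arm only. ICERs use the
(intervention − control) cost over (control − intervention) DALY
convention, with WHO-style thresholds: cost saving, "best buy"
(< $100/DALY), very cost-effective (< $5702, 1× GDP per capita) and
cost-effective (< $17,106, 3× GDP).

**Uncertainty.** The probabilistic sensitivity analysis draws every
transition probability from a beta distribution parameterised by its 95%
binomial bounds (method of moments, recentred on the point estimate) and
independent medical / program cost multipliers from Uniform(0.5, 2.0),
re-running the whole pipeline per draw. Scenario analyses cover a 2.5%/yr
declining counterfactual, a 20-year chronic-RHD duration, 20-fold program
costs, and their combination ("worst case").

The transition probabilities that the source evaluation published only in
supplementary material are reconstructed values, calibrated once against
the published base-case aggregates and clearly marked in the defaults; see
`docs/methods.md` for the calibration and its limits.

## Worked example

```sh
rhdcea basecase --out out/
```

prints the deterministic base case (and writes ledgers, DALY, cost and
parameter CSVs plus a JSON run manifest to `out/`):

```
              quantity           value
         dalys_averted     4813.234843
dalys_averted_per_100k     1757.084704
   medical_savings_usd  7391261.489126
      program_cost_usd        202890.0
  incremental_cost_usd -7188371.489126
     icer_usd_per_daly    -1493.459539
           cost_saving            True
```

Read: compared with doing nothing, the program averts ≈ 4813 DALYs
(≈ 1757 per 100,000 children) and saves ≈ $7.39 million in direct medical
care — roughly 36 times its $202,890 cost — so the incremental cost is
negative and the program dominates (the negative ICER is reported for
reference). The same pipeline is available from Python:

```python
import rhdcea

params = rhdcea.load_parameters()          # defaults, or a JSON overlay
control = rhdcea.run_cohort(params, "control")
program = rhdcea.run_cohort(params, "intervention")
dalys = rhdcea.compute_dalys(control, program, params.daly, params.cohort)
summary, draws = rhdcea.run_psa(params, n_draws=1000, seed=1)
```

Other commands: `rhdcea psa` (per-draw table + summary), `rhdcea
scenarios` (the five-scenario battery), `rhdcea synth` (synthetic patient
registry line lists), `rhdcea validate` (configuration checking).

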