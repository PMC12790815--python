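# Methods

## Causal knowledge graph model

The graph couples four relation types over disease (ICD-10) and drug
(RxNorm) nodes. Only two carry a causal reading: disease progression
(disease → disease) and the *inverse* of indication (a diagnosis leads to a
prescription, so the causal subgraph contains one disease → drug edge per
indication edge). Side-effect and `is_a` edges stay out of the causal
subgraph but drive the contradiction filters and the subsumption
constraint. Both the causal subgraph and the `is_a` hierarchy must be
acyclic; violations are structural errors that name one offending cycle.

ICD-10 codes are normalised internally by stripping dots and uppercasing
(`E11.9` → `E119`), since cohort dialects differ in punctuation. The
population map assigns to a disease node everyone ever diagnosed with the
code **or any `is_a`-descendant** (full transitive closure — the
specification of `f` at interior hierarchy levels is genuinely open; we
chose closure over direct children because it is the unique choice that
makes the subsumption constraint `f(u) ⊆ f(v)` hold at every level by
construction), and to a drug node everyone ever prescribed it. `P` is the
relative frequency on the cohort, so binary "ever" encodings of treatment,
mediator and outcome are exactly node probabilities under `P`.

## Temporal validity

A person enters a hypothesis's analysis table only if they have follow-up
data and their record respects the order indication → drug → outcome:
persons whose outcome's first diagnosis precedes the indication's first
diagnosis or the first prescription, or whose prescriptions all predate
the indication, are excluded. Same-day events count as validly ordered
(same-visit prescribing is common). Persons with the drug but without the
indication are retained — the mediator model needs variation in M given
T=0. Severity proxies (distinct 3-character diagnosis categories; distinct
drugs prescribed) are computed over the whole record; restricting them to
pre-treatment records is a known open choice.

## Hypothesis generation and filtering

Comorbidity candidate pairs use the relative risk
RR = (n_both · n_total)/(n_a · n_b) with a one-sided Fisher exact test of
enrichment on the person-level 2×2 table (the exact test is robust for the
sparse pairs this screen produces), BH correction once over all tested
pairs, and orientation by first-diagnosis dates with a strict-majority
rule — exact ties drop the pair rather than guess a direction. Filtering
removes triples the graph already explains: the drug indicated for both
diseases (treatment overlap), or any single drug listing both diseases as
side effects (common downstream effect); the same predicate can be run as
a SPARQL ASK query over the sorted N-Triples export and is tested to agree
with the native implementation. The support filter then requires at least
one person with T = M = Y = 1 after temporal encoding. The two filters
commute.

## Adjustment-set identification

For each hypothesis the candidate edge drug → outcome is first added to
the causal subgraph (if it would create a cycle the hypothesis is
untestable). The backdoor search targets the (indication, outcome) pair —
sequential ignorability wants pre-treatment covariates, and the mediator
drug is never admitted to a set because it is the exposure under test.
Candidate sets are enumerated by increasing cardinality then
lexicographically; with that order the first valid set *is* the
minimum-cardinality, first-encountered-on-ties choice, and the 1000-set
cap only matters as an enumeration budget. d-separation itself is
delegated to networkx; the test suite checks it exhaustively against a
path-enumeration oracle. The disjunctive-cause criterion takes the graph
parents of treatment and outcome. Finally, when a set contains a disease
and one of its `is_a`-ancestors the descendant is pruned (the rule reaches
a fixpoint and is idempotent). Demographic covariates (sex, age, BMI,
dummy-coded ethnicity) and the two severity proxies are always appended to
the graph-derived set before modelling.

## LASSO covariate selection

Two L1-penalised logistic models — one predicting the indication, one the
outcome — are fit over the graph-derived covariates; the adjustment set
used downstream is the union of covariates with non-zero coefficients in
either model. Targets here are binary, so logistic loss replaces the
squared-error form of the generic objective. λ is chosen to minimise
10-fold cross-validated binomial deviance on a 20-point log grid
(10⁻⁴…1 per-observation scale); fold assignment is fully determined by the
seed, and the liblinear solver is seeded so the output is bit-stable.
Demographics are exempt from selection: they enter the penalised design
(selection of graph covariates is conditional on them) but are kept
regardless of shrinkage. Note that CV-minimum LASSO deliberately
over-selects — it is tuned for prediction, not support recovery — so noise
covariates appear in selections at a non-trivial rate; the tests assert
the defensible properties (true signal always kept, selection strictly
smaller than the candidate pool) rather than exact support recovery.

## Mediation estimation

Mediator model M ~ T + X and outcome model Y ~ T + M (+ T×M) + X, logistic
links for binary variables and identity links for continuous ones, both
with HC3 heteroskedasticity-consistent covariances (the "robust" flavour
chosen here; HC3 is the conservative small-sample default). The T×M
interaction is kept only when its robust p-value is below 0.05 in a
pre-screen fit. Quasi-Bayesian inference draws 1000 coefficient vectors
per model from N(β̂, Σ̂_HC3); per draw and per person the potential-outcome
expectations E[Y(t, M(t′))] are computed by **exact summation over the
binary mediator** (for a continuous mediator, by plugging its mean into
the linear outcome model), so the coefficient draw is the only stochastic
element — this removes the mediator-sampling Monte-Carlo noise that a
simulation over M would add. ACME is reported at t = 0 (the natural
indirect effect), the average direct effect at t = 1, and the total effect
is their exact per-draw sum. The CI is the 2.5/97.5 draw percentile
interval; p = 2·min(Pr(draw ≤ 0), Pr(draw ≥ 0)) floored at 1/sims; the
mediated proportion is the draw-median of ACME/total (robust near a zero
total effect; it is negative under suppression, i.e. opposing direct and
indirect paths). Degenerate tables (constant T/M/Y) and quasi-separated
fits (logistic coefficients beyond ±30 or non-finite covariances) mark
the hypothesis untestable rather than raising. BH runs once over all
`ok` results in a run.

## Synthetic cohorts

Each planted triple is an independent block of logistic structural
equations per person: T ~ Bern(σ(α_T + γ_T·C)),
M ~ Bern(σ(α_M + a·T + γ_M·C + s_M·S)),
Y ~ Bern(σ(α_Y + b·M + c·T + γ_Y·C + s_Y·S)), where C is a standardised
confounder score built from the demographic covariates (so demographics
genuinely confound) and S is a latent severity. Defaults (α_T = −0.8,
α_M = −1.5, α_Y = −2.2, a = 1.5, c = 0.5, γ = 0.4, b = 1.2 for planted
effects) give indication prevalence ≈ 0.31, drug uptake ≈ 0.5 given the
indication, and outcome prevalence of a few percent — a regime where a
mediated absolute risk increase of ≈ 4–6 percentage points is a realistic
adverse-effect signal at cohort sizes of 10⁴. Dates are drawn uniformly in
windows respecting indication → drug → outcome; 2% of records are
deliberately disordered and 2% of persons lack follow-up so the exclusion
rules always have work to do; 20% of diagnoses are recorded at a child
ICD code so the subsumption closure is exercised end to end. Decoys are
generated one per filter rule (double indication, shared side-effect
listing, never-prescribed drug). The severity mechanism drives both drug
use and outcome and also inflates the background comorbidity/prescription
Poisson rates, so the observable proxies genuinely proxy S — adjusting for
them demonstrably shrinks the severity-induced bias.

The oracle `true_nie` simulates the potential mediators M(0), M(1) and
potential outcomes Y(0, M(1)), Y(0, M(0)) directly from the structural
equations (shared outcome noise isolates the mediator contrast) —
a code path independent of the estimator.

What the generator does **not** emulate: realistic ICD-10 epidemiology,
correlated disease blocks, time-varying confounding, episode-level
prescription patterns, coding errors or missing-data mechanisms beyond
absent follow-up. Passing tests therefore show estimator and pipeline
correctness under the stated structural assumptions, not robustness to
real-data violations of them.

## Problem sizes and numerical choices

Calibration studies run 200 replicates at n = 5000 with 1000 coefficient
draws; the end-to-end planted-truth run uses 10 000 persons, 5 planted
effects and 20 nulls; graphical-criterion audits use 200 random DAGs of
4–8 nodes checked exhaustively — sizes chosen so the whole battery
completes in minutes while keeping the binomial standard errors of the
measured rates (≈1.5 percentage points) well inside the asserted bands.
HC3 covariances are symmetrised and given a 10⁻¹² trace-scaled jitter
before Cholesky sampling. All randomness flows from one top-level seed via
a deterministic per-hypothesis seed map, so reruns are byte-identical.

### Interval calibration

The percentile CI inherits two sources of anti-conservatism. First, the
T×M pre-screen is a pretest estimator: in the ~5% of datasets where a
spurious interaction is kept, the refitted model's extra variability is
not reflected in the coefficient draws, so the selection step costs about
one percentage point of coverage. Second, percentile intervals carry
higher-order error at moderate n. Diagnostic decompositions (per-model
robust SEs against empirical coefficient SDs; delta-method variance with
full versus block-diagonal cross-model covariance) show the coefficient
covariances themselves are well calibrated and that drawing the two
models' coefficients independently is, if anything, slightly conservative.
The net effect is empirical 95% CI coverage in the low-to-mid 90s rather
than exactly 95 — measured, not assumed, by the calibration study in
`scripts/acceptance.py`.

## Known limitations

- Sequential ignorability is assumed, not tested; no sensitivity analysis
  for unmeasured confounding of the mediator–outcome path.
- Backdoor enumeration is exponential in the eligible node count; a subset
  budget turns pathological cases into untestable flags.
- The continuous-mediator path plugs the mediator mean into the outcome
  model, which is exact only for identity links.
- Binary lifetime ("ever") encodings discard dose, duration and recurrence
  information.
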