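# Methods

## Clinical derivation layer

All derivations operate on fasting labs and follow Korean guideline
definitions, with every band's lower bound inclusive of its named
threshold.

Indices: `HOMA-IR = insulin·FBG/405` (unitless; missing insulin yields a
missing HOMA-IR, never zero), `TyG = ln(TG·FBG/2)` (natural-log units),
`TG/HDL = TG/HDL` (unitless).  FBG, TG and HDL must be strictly positive;
violations raise a domain error naming the offending field.

Categorical bands (mg/dL, mmHg, %): SBP <120 / 120–139 / ≥140;
DBP <80 / 80–89 / ≥90; FBG <100 / 100–125 / ≥126; HbA1c <5.7 / 5.7–6.3 /
≥6.4; TG <150 / 150–199 / ≥200; TCHOL <200 / 200–239 / ≥240; LDL <130 /
130–189 / ≥190; HDL <40 = Danger.  The guideline LDL bands leave a
129/130 gap; we use <130 as the Normal bound, consistent with the
inclusive-threshold convention (similarly HbA1c values in [6.3, 6.4) are
Caution).  Behaviour recodes: sleep <6 h, drinking <1 occasion/month,
smoking = ever ≥5 packs or current smoker.  A configurable guard range
(default `[0, 10× top threshold]`) rejects physiologically impossible
inputs, listing the offending record ids.

Composite outcomes are the logical OR of their criteria (diagnosis or
medication flags; FBG ≥126 or HbA1c ≥6.5 for diabetes; TCHOL ≥240,
LDL ≥160, HDL ≤40, or TG ≥200 for dyslipidemia; SBP ≥140 or DBP ≥90 for
hypertension; BMI ≥25, sex-specific WC ≥90/85 cm, WHtR ≥0.5 for the three
obesity indicators).  A record is "yes" as soon as one criterion is met,
even with other components missing; it is missing only when every
component is missing (counted in the log).  Unmeasured LDL is filled by
the Friedewald estimate `TCHOL − HDL − TG/5`; negative estimates are
retained with a warning flag rather than rejected, since the category
assignment is still well defined.

The exclusion cascade runs completeness → age window → disease history
(CVD, cancer, kidney), attributing doubly excluded records to the first
matching criterion.  The guideline phrasing of the age window ("40–70
years") conflicts with age strata that end at 60–69; we include
`40 ≤ age ≤ 69` and expose the upper bound in configuration.

Quartile groups use **unweighted** empirical quartiles with
linear-interpolation between closest ranks (survey weights deliberately
ignored for binning, so cut points are fixed, citable numbers), and boundary values
fall into the lower group: Q1 iff `x ≤ q1`, Q2 iff `q1 < x ≤ q2`, etc.
Fewer than four distinct values is a degenerate-quartile error.

## Survey-weighted estimators

Weighted proportions are ratio estimators `Σ w·1{cell} / Σ w·1{margin}`.
The test of independence is the Pearson chi-square computed on weighted
proportions with the **second-order Rao-Scott correction**: the
generalized design-effect matrix `Δ = (H V₀ Hᵀ)⁻¹ (H V̂ Hᵀ)` compares the
stratified between-PSU linearization covariance `V̂` of the independence
residuals with their multinomial covariance `V₀`; the statistic
`F = X² / tr(Δ)` is referred to an F distribution with Satterthwaite
numerator df `tr(Δ)²/tr(Δ²)` and denominator df scaled by the design
degrees of freedom (PSUs − strata).  The result records the first- and
second-order eigenvalue summaries (mean design effect, eigenvalue CV²).
Strata with a single PSU raise an error by default; a logged
centered-at-stratum-mean fallback (zero contribution) is available.
Under a trivial design (equal weights, one stratum, one record per PSU)
the weighted X² equals the classical Pearson statistic exactly.  A
2,000-replicate null simulation with clustered predictors and informative
weights gives a rejection rate of ~0.04–0.06 at α = 0.05.

Weighted mutual information is the plug-in estimate over the weighted
joint (nats, `0·ln 0 = 0`).  The percentage normalization is the
**uncertainty coefficient** `100·MI/H(outcome)`: analyses in this field
report MI in percent without always defining the normalizer, and an
outcome-referenced, [0, 100]-bounded coefficient matches that usage; raw
nats are always reported alongside.  Natural log throughout.

The weighted AUC is the weighted Mann-Whitney statistic with ties counted
½, computed on the *continuous* index values (not quartile labels); the
ROC curve enumerates weighted (FPR, TPR) at every distinct threshold.
All four estimators are invariant to global weight rescaling and collapse
to their unweighted counterparts under equal weights.

## Bayesian-network stack

Scores are decomposable and maximized.  The multinomial log-likelihood of
node `i` with parent set π is `Σⱼₖ Nⱼₖ ln(Nⱼₖ/Nⱼ)`; the AIC score
subtracts the free-parameter count `(r−1)·q` (r node levels, q parent
configurations) with penalty coefficient 1, the convention of standard BN
toolkits (the classical `−2(logL − k)` scaling selects identical graphs).
Declared level counts, not observed ones, determine `r`, so collapsed
columns keep their nominal dimension.

Hill-climbing starts from the empty graph (plus any whitelist), scans
add → delete → reverse moves in lexicographic arc order, and accepts the
best strictly improving legal move each iteration; ties go to the first
move in scan order, making runs bit-reproducible.  The search stops at a
verified single-move local optimum (or returns a non-convergence flag
when `max_iter` is reached).  No random restarts by default.  An
exhaustive enumeration oracle (≤5 nodes; 3/25/543/29,281 labelled DAGs
for 2–5 nodes) provides the global optimum for testing; ties break to the
lexicographically smallest arc set.

Bootstrap arc strengths use nonparametric row resampling at full n,
unweighted (survey weights enter the descriptive estimators; structure
learning follows the common unweighted-resampling convention, with a
weighted-resampling switch for sensitivity analysis).  Degenerate
resamples (a variable collapsing to one observed level) are redrawn and
logged.  Model averaging keeps unordered pairs with adjacency frequency
≥ threshold (default 0.75), orients each by majority direction
(exact ties → lexicographic orientation, logged), and repairs any
resulting cycle by repeatedly dropping the weakest kept arc (logged).
The 75 % rule operates on *adjacency* (either direction) because a
bootstrap arc frequency does not distinguish orientation within an
equivalence class.

CPT fitting is maximum likelihood with optional Laplace smoothing
`(Nⱼₖ+α)/(Nⱼ+αr)`; with α = 0 an unseen parent configuration yields a
flagged uniform row so queries never silently divide by zero.
d-separation is decided by Bayes-ball reachability; Markov blankets are
parents ∪ children ∪ co-parents, which the test battery verifies to be
the unique minimum-cardinality d-separating set by brute force.

Queries run against the model-averaged, refitted network (average → fit →
query).  The default estimator is likelihood weighting with 10⁵ samples
(evidence clamped, weights multiplied by evidence CPT entries; ratio-
estimator delta-method SE; effective sample size `(Σw)²/Σw²`); rejection
sampling is available for parity with logic-sampling defaults.  An exact
enumeration oracle is guarded to ≤ 2²⁰ joint states.

## Synthetic cohort generator

The generator defines the study conditions for every downstream test: a
20-variable ground-truth network over demographics (sex, age group,
education), behaviours (smoking, drinking, muscle activity), clinical
categories (FBG, TG, HDL, TCHOL, LDL bands), outcomes (diabetes,
dyslipidemia, hypertension, three obesity indicators) and the three index
quartile variables.  Required structure: the chain TG/HDL → TyG → HOMA-IR;
FBG parent of all three indices and child of diabetes; TG, HDL, TCHOL,
LDL and age parents of dyslipidemia; obesity indicators children of
HOMA-IR (hence inside its Markov blanket).  Default demographic/behaviour
arcs are sex → smoking, sex → drinking, age → education; an optional
switch (`behavior_index_arcs=True`) couples behaviours directly into the
indices.  That denser variant yields richer blanket membership
lists but destabilizes greedy orientation (shielded
colliders), so the default keeps the sparser graph for which skeleton
recovery at n = 20,000 is reliable — median skeleton SHD 1 over five
replicate cohorts at B = 200, every true arc at adjacency ≥ 0.95.

Ordinal dependence uses a softmax CPT family
`pₖ ∝ exp(sₖ · Σ βₚ uₚ)` with child-level scores `sₖ` on [−1.5, 1.5] and
parent-level scores `uₚ` on [−1, 1]; couplings (β between 1.0 and 1.6)
are chosen so that every arc shifts the child conditional by ≥ 0.25 total
variation between adjacent parent levels for at least one configuration
of the other parents (the package exposes `arc_shift_strength` to audit
this).  CPT rows that would contradict an outcome definition carry zero
mass (FBG cannot be in the Danger band without diabetes; a Danger-band
lipid forces dyslipidemia) — mirroring the structural zeros such data
shows in descriptive tables.  A consequence of favouring strong,
recoverable dependencies is that outcome prevalences are higher than in
the population the generator imitates (diabetes ≈ 25 % weighted rather
than ≈ 15 %); the generator models statistical *structure*, not incidence.

Sampling is vectorized ancestral sampling in topological order from a
single seeded stream; identical `(spec, n, seed)` gives bit-identical
tables.  Survey design: 17 strata × 20 PSUs (counts arbitrary and
configurable; the imitated survey's design parameters are not public),
log-normal mean-1 weights drawn independently of all variables, so
weighted and unweighted analyses agree asymptotically; an informative-
weights switch ties weights to age/sex to verify that weighted estimators
respond.

Continuous emission adds raw labs inside the band of each sampled
categorical state (truncated log-normal per band), so re-categorizing
reproduces the sampled state exactly, and re-deriving the composite
outcomes reproduces the outcome nodes exactly (diagnosis flags are set
whenever an outcome is "yes" without a lab criterion; LDL for
non-dyslipidemic records in the Caution band is capped below the 160
mg/dL outcome threshold).  Insulin is back-solved from the sampled
HOMA-IR band (`insulin = 405·HOMA/FBG`), so the HOMA-IR formula
round-trips bit-exactly.  **Known limitation:** the emitted TyG and
TG/HDL columns are drawn from their own quartile bands and are not
constrained to equal `ln(TG·FBG/2)` or `TG/HDL` recomputed from the
separately emitted labs — enforcing all deterministic identities jointly
with the categorical ground truth is infeasible.  On synthetic cohorts
the sampled quartile variables are therefore the analysis variables
(derivation keeps existing columns); on user data the pipeline derives
indices and quartiles from the labs.  Passing tests consequently show
correctness of the estimators and the learnability of the designed
structure; they do not certify behaviour under real-data features the
generator omits (measurement error correlated across labs, missingness,
informative cluster sampling).

## Pipeline, determinism, and problem sizes

The pipeline runs simulate/load → exclusions → derivation → weighted
descriptives with Rao-Scott p-values → marker MI/AUC → bootstrap
structure learning → model averaging → CPT fit → Markov blankets →
scenario grids, and writes one JSON report plus delimited tables and a
DOT graph.  No timestamps; every stochastic stage's seed is derived from
the configured master seed and echoed in the report, so a configuration
reproduces its report byte-for-byte.

Production defaults are cohort 8,195, B = 1,000 bootstrap networks,
threshold 0.75, and 10⁵ query samples.  The test suite and the acceptance
script use desk-scale sizes chosen for stable statistics at interactive
cost — identical estimators, reduced Monte-Carlo precision: structure
recovery at n = 20,000, B = 200 over five seeds; oracle-equivalence
batteries of 100 datasets/queries; 2,000-replicate null calibration;
byte-identity runs at n ≈ 1,000, B ≈ 10.

Numerical conventions: natural logarithms everywhere; `0·ln 0 = 0`;
strict-improvement epsilon 10⁻⁹ in the greedy search; CPT rows validated
to sum to 1 within 10⁻¹² (10⁻⁹ after serialization round-trips);
quartile and band boundaries resolved by the inclusive rules above.

## Known limitations

- The hill-climbing + AIC combination adds a spurious arc between truly
  independent variables whenever the sample chi-square exceeds twice the
  parameter penalty (probability ≈ 0.16 per binary pair, independent of
  n).  This is a property of AIC model selection, not a defect of the
  search; bootstrap model averaging at 0.75 removes such arcs in ≈ 90 %
  of datasets and is the supported way to read the learned structure.
- In the recovery experiment the consensus typically contains one extra
  skeleton edge between TG and HDL bands: both are parents of
  dyslipidemia, whose deterministic OR rows make them strongly dependent
  within the moralized neighbourhood; orientation noise then promotes the
  moral edge into the consensus.  Pairs outside the true moral graph stay
  below the 0.75 threshold in the median across replicate seeds, though a
  single seed can transiently inflate one such pair.
- Inference uses enumeration/likelihood weighting, adequate at desk
  scale; no junction-tree engine, and no continuous or
  conditional-Gaussian networks.  Constraint-based and hybrid structure
  learners are out of scope.
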