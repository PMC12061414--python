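# irnet

Comparison of three insulin-resistance (IR) surrogate markers — **HOMA-IR**,
the **TyG index** and the **TG/HDL ratio** — against diabetes and
dyslipidemia in a complex-survey cohort, using survey-weighted statistics
and a discrete Bayesian-network analysis.

Measuring IR directly (the euglycemic clamp) is impractical in routine
care, so clinicians rely on surrogate indices computed from fasting labs:

```
HOMA-IR   = insulin [µIU/mL] × FBG [mg/dL] / 405
TyG index = ln( TG [mg/dL] × FBG [mg/dL] / 2 )
TG/HDL    = TG [mg/dL] / HDL [mg/dL]
```

The package asks how these three markers relate to each other and to
metabolic disease, not just how well each one discriminates.  Beyond
per-marker weighted mutual information and ROC/AUC, it learns a Bayesian
network `B = (G, P)` over all categorical analysis variables, where the
DAG `G` factorizes the joint as `P(V) = ∏ᵢ P(Vᵢ | π(Vᵢ))`.  Structure is
learned by score-based hill-climbing with the AIC score
(`AIC = log L − k`, maximized), stabilized by nonparametric bootstrap model
averaging: arcs kept only if they appear in ≥ 75 % of the bootstrap
networks.  Each marker's **Markov blanket** (parents ∪ children ∪
co-parents) then identifies the minimal variable set that screens it from
the rest of the network, and conditional-probability queries
(likelihood weighting, with an exact-enumeration oracle) produce scenario
grids such as `P(diabetes = yes | TyG ∈ Q4, obese)`.

Because population survey microdata are access-restricted, the package
ships a first-class synthetic cohort generator: a fully specified
ground-truth network over the analysis variables (index quartile chain
TG/HDL → TyG → HOMA-IR, fasting glucose as parent of all three indices and
child of diabetes, lipid panel and age as parents of dyslipidemia, obesity
indicators adjacent to HOMA-IR) that samples KNHANES-like records with
survey weights, strata and PSUs, and emits raw labs that re-derive to
exactly the sampled categorical states.  Every downstream stage is
validated against this known ground truth.

## Who this is for

Biostatisticians and epidemiologists who want a tested, reproducible
pipeline for surrogate-marker comparison on complex-survey data — or any
of its parts: the survey estimators (Rao-Scott corrected chi-square,
weighted MI, weighted AUC), the from-scratch discrete Bayesian-network
stack, or the clinical derivation rules (guideline cut-offs, Friedewald
LDL, composite outcomes, exclusion cascade).

## Worked example

```bash
irnet all --seed 7 --n 2000 --bootstrap 25 --out results/demo
```

simulates a 2,000-record cohort from the ground truth, derives the
clinical variables, and runs the full analysis.  It prints:

```
 marker      outcome  mi_nats    mi_pct      auc  auc_rank  mi_rank
homa_ir     diabetes 0.114981 19.564542 0.762754         1        1
    tyg     diabetes 0.083639 14.231609 0.721138         2        2
 tg_hdl     diabetes 0.026212  4.460147 0.631922         3        3
homa_ir dyslipidemia 0.019791  3.603755 0.607488         2        3
    tyg dyslipidemia 0.029344  5.343245 0.593357         3        2
 tg_hdl dyslipidemia 0.055320 10.073164 0.661220         1        1
```

Read this as: HOMA-IR is the best single discriminator of diabetes
(AUC 0.76, uncertainty-coefficient MI 19.6 % of the outcome entropy),
the TG/HDL ratio is best for dyslipidemia (AUC 0.66, MI 10.1 %), and the
TyG index ranks second for both — the "bridging" behaviour the network
analysis explains structurally.  The report (`results/demo/report.json`)
also contains the consensus DAG and the Markov blankets of the three
markers:

```json
"homa_ir_q": ["fbg_cat", "obesity_bmi", "obesity_wc", "obesity_whtr", "tyg_q"],
"tyg_q":     ["fbg_cat", "homa_ir_q", "tg_hdl_q"],
"tg_hdl_q":  ["fbg_cat", "hdl_cat", "tg_cat", "tyg_q"]
```

TyG appears in the blankets of both other markers while HOMA-IR and
TG/HDL never appear in each other's — given TyG (and FBG), the two
extreme markers are conditionally independent.  The scenario grid in the
same report shows risk rising monotonically across TyG quartiles,
e.g. `P(diabetes | TyG ∈ Q1) = 0.145` up to `P(diabetes | TyG ∈ Q4) = 0.639`
(each estimate with its Monte-Carlo SE and seed).

Individual stages are available as subcommands (`simulate`, `derive`,
`describe`, `compare`, `learn`, `average`, `query`, `report`); the library
API mirrors them (`irnet.pipeline.run_pipeline`, `irnet.bn_structure`,
`irnet.bn_inference`, `irnet.survey_stats`, `irnet.cohort_model`,
`irnet.synthetic_cohort`).

To analyze your own cohort instead of a synthetic one, pass a delimited
cohort file plus a YAML codebook via `RunConfig(cohort_path=...,
codebook_path=...)`; continuous labs are derived into categories,
outcomes and quartiles automatically.

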