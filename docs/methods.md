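# Methods

## Statistical model and procedure

### Differential expression

Each signature gene is compared between two sample classes (tumor vs
normal, or control vs perturbed) with a two-sided Wilcoxon rank-sum test
on log2 expression. The test is exact — full enumeration of the rank-sum
permutation distribution with midrank scores, two-sided p =
2·min(P(W ≤ w), P(W ≥ w)) capped at 1 — whenever the pooled sample size is
at most 20, and otherwise uses the normal approximation with the standard
tie correction (no continuity correction). A rank-based test was chosen
because public tumor expression matrices arrive in unknown units
(FPKM/TPM/log-counts) and ranks are invariant to any monotone rescaling;
Welch's t-test is available behind a switch. The effect size is
log2FC = mean(class2) − mean(class1), with class2 always the
tumor/perturbed arm.

A gene is called up/down when p < alpha (default 0.05) **and**
|log2FC| ≥ fc_min (default 1). The gate uses the raw p by default, since
per-gene volcano criteria are the screening dialect this pipeline
implements; Benjamini–Hochberg q-values are always computed (via
statsmodels) and a strict-FDR mode gates on q instead. Signature genes
absent from the matrix are reported separately as "unmeasured" rather
than silently dropped.

### Survival risk model

Cox proportional-hazards fits use lifelines with the Efron approximation
for tied event times. The forest stage fits one single-covariate model
per gene; HR = e^β per log2-expression unit with Wald 95% CIs, and a gene
is "significant" when the CI excludes 1. Genes whose fit fails to
converge yield a flagged row rather than aborting the batch.

Model selection is greedy bidirectional stepwise search minimizing
AIC = 2k − 2·log partial likelihood, starting from the null model. The
null model's Efron partial log-likelihood is computed in closed form
(at a death time with d tied deaths and n at risk it contributes
−Σ_{j<d} log(n − j)). Determinism is guaranteed by scanning candidates
in input order, requiring a strict improvement (ΔAIC < −1e−6), and
taking the single best move per iteration with ties going to the earlier
candidate. Additions stop when events per covariate would fall below 5.
Steps that fail to converge (e.g. a duplicated covariate making the
design singular) are skipped with a warning, which also implements the
"exactly one of two duplicate covariates" contract.

Risk scores are the centered linear predictor of the selected model.
Stratification splits at the median score with ties assigned to the
low-risk group; Kaplan–Meier curves and the two-group log-rank test come
from lifelines. Harrell's C is implemented directly with the pair rule
stated in its contract: a pair is usable when censoring determines its
ordering (the strictly earlier time carries an event); score ties count
0.5; tied event times are indeterminate and excluded. The in-sample C is
reported, matching what a single printed model-level concordance implies;
there is no cross-validation machinery.

### Drug screen

The funnel first keeps drugs whose catalog entry links them to at least
one panel-measurable regulator, then tests exactly the (drug, regulator)
pairs present in the catalog — the catalog defines which hypotheses
exist, mirroring how curated chemical–gene databases are used. Each pair
is tested by Pearson correlation over pairwise-complete cell lines, with
a two-sided t-distribution p on n − 2 df; pairs with fewer than
`min_lines` (default 10) complete observations, or zero variance in
either vector, are rejected outright because Pearson p is unstable there.
Per-pair raw p < alpha (default 0.05) defines a significant edge,
matching the per-pair-starred convention of activity–expression screens;
a BH mode across all tested edges is available. All reporting uses
r_ic50 = −r (activity z-scores rise with sensitivity), so "negative"
uniformly means sensitizing.

### Synergy sign rule and network

For each significant edge whose gene has a non-ns perturbation direction:
concordant ⇔ (r_ic50 < 0 ∧ up) ∨ (r_ic50 > 0 ∧ down). The second clause
is the mirror image of the stated synergy case and is included by
symmetry under the default rule; `rule="paper_literal"` restricts to the
first clause only. Genes with ns direction never contribute. A drug's
synergy score sums |r_ic50|·|log2FC| over its concordant edges (count
mode uses weight 1); the score definition is this package's own ranking
device — any monotone aggregation of concordant evidence would order
strong single-gene sensitizers first, and the weighted sum also rewards
multi-gene support. Ties break lexicographically by drug id so output is
reproducible. The exported network is tripartite
(perturbation → genes → drugs) with signs from the direction and from
sign(r_ic50), written as SIF plus node/edge attribute TSVs in
byte-stable order.

### Dose–response

Viability curves follow the four-parameter logistic
r(d) = bottom + (top − bottom)/(1 + (d/ic50)^hill) with top > bottom and
hill > 0. Fitting is Levenberg–Marquardt least squares over
(top, bottom, log ic50, log hill) — the log parametrizations enforce
positivity and make the fit equivariant under dose-unit changes — with
quartile-based initialization and 5 deterministic starts varying the
IC50 guess across the dose range and the Hill guess over {0.5, 1, 2}.
An IC50 landing outside the tested range is reported as a censored bound
("> max dose" / "< min dose"), never as a point estimate; exactly flat
response data (amplitude unidentifiable) is reported as above-range
directly. Fold change is ic50_alone / ic50_combo; an above-range alone
arm yields a lower bound, an above-range combination leaves the fold
change undefined.

## Synthetic data: what it emulates, and what it does not

The generators reproduce the *statistical structure* of the funnel's
inputs, with defaults fixed at the motivating study's shape:

- **Cohort** (`gen_cohort`): 238 genes × (169 tumor + 36 normal);
  per-gene log2 expression ~ Normal(baseline, 0.5) with baselines
  ~ Normal(8, 1); 28 planted DE genes shifted ±2 log2 units in tumors.
  Survival is exponential proportional hazards on the centered expression
  of 5 risk genes drawn from the DE set (default |β| = 0.7 alternating
  sign, baseline hazard 0.01 events/month). Censoring is independent
  exponential with its rate solved by root-finding so the expected
  censored fraction equals `censor_rate` (default 0.2), keeping the PH
  assumption intact.
- **Panel** (`gen_panel`): 60 cell lines, 2,000 drugs, 94 planted
  sensitizers. A planted drug's activity is ρ·z(expression of its target
  gene) + √(1−ρ²)·noise with ρ = 0.9, so the population Pearson
  correlation equals ρ exactly. Each drug links to each signature gene in
  the catalog independently with probability 0.05, and every planted pair
  is forced into the catalog. A configurable withheld-gene list (default
  8 in the demo) removes rows from the panel expression matrix to emulate
  signature genes the reference panel never measured.
- **Perturbation** (`gen_perturbation`): two arms × 5 replicates,
  planted genes shifted ±2 log2 units.
- **Dose–response** (`gen_dose_response`): exact 4PL mean plus Gaussian
  noise in % viability.

Deliberate simplifications: log2-normal noise rather than count-level
negative binomial (the pipeline consumes processed matrices, not reads);
genes are independent (no co-expression blocks, so the DE false-positive
behavior is the idealized i.i.d. case); one activity vector per drug with
a single planted target gene; exponential rather than Weibull baseline
hazard; no batch effects or missingness patterns beyond explicit NA
support. Passing recovery tests therefore demonstrates the machinery is
correct and calibrated under its stated model — not that the thresholds
would achieve the same operating characteristics on real cohort data,
where correlation structure inflates effective false-positive rates.

Determinism: every generator takes one integer seed into
`numpy.random.default_rng`; sub-generators (panel, perturbation) use
fixed +1/+2 offsets so partial regeneration is stable. Identical config
⇒ bit-identical outputs and, through the pipeline, a byte-identical
manifest.

## Numerical choices and edge cases

- Exact rank-sum enumeration switches to the normal approximation above a
  pooled n of 20 (C(20,10) = 184,756 assignments is the practical exact
  ceiling per gene). All-tied input returns p = 1.
- Stepwise move tolerance 1e−6 on ΔAIC; Cox convergence failures skip the
  move rather than aborting the search.
- Median split assigns score ties to the low-risk group; all-identical
  scores raise a "degenerate stratification" error.
- Missing values: "NA" and empty string parse as missing; any other
  non-numeric cell raises with (gene, sample) coordinates. Duplicate gene
  rows collapse by mean with a logged warning; duplicate sample columns
  are an error.
- Gene symbols uppercase; an optional alias TSV (chains resolved at load)
  maps cross-species orthologs such as Ctsl → CTSV.
- Network export orders nodes lexicographically and edges by
  (source, type, target) so re-export is byte-identical.

## Problem sizes used in tests and the acceptance script

The bundled demo and the acceptance script run the funnel at the study's
published shape (238 genes, 169/36 cohort, 60 cell lines, 2,000 drugs,
94 planted sensitizers, 20 planted synergists) — the drug axis is the
study's catalog scale reduced ~12×, which preserves every rate the tests
measure while keeping a full run under half a minute. Survival
simulations use n = 400–500 tumors; CI-coverage checks use 200
replicates at n = 100; dose–response recovery uses 9–12 doses spanning
2–4 decades with 100 noise seeds.

## Known limitations

- Stepwise selection by AIC keeps any covariate whose likelihood-ratio
  statistic exceeds 2, so with many null candidates the selected set
  carries a predictable complement of spurious genes (≈ 0.16 per null
  candidate). This is inherent to AIC stepwise selection, not a defect of
  the search; users wanting sparser models should pre-filter candidates
  (e.g. to forest-significant genes) or use the forward-only mode with a
  smaller candidate list.
- The screen's per-pair alpha with no multiplicity correction matches the
  screening convention it implements but will nominate ~alpha × (tested
  pairs) chance candidates; the BH mode is provided for stricter use.
- In-sample C-index is optimistic relative to external validation.
- The synergy score ranks hypotheses; it has no calibrated scale across
  datasets.
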