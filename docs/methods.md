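# Methods

This note documents the statistical machinery implemented in `gradedcat`,
the defaults it runs with, and the choices made where more than one sound
design existed.

## The graded response model and its metric

Responses are ordered categories 0..K−1. The GRM puts logistic cumulative
curves P*(X ≥ k | θ) = expit(a(θ − b_k)) through K−1 ordered thresholds;
category probabilities are differences of adjacent curves. Slopes are on
the plain logistic metric — no 1.702 scaling constant — matching the
magnitude of published PROMIS parameter tables; the bundled 46-item
upper-extremity bank (slopes 1.7–3.6, thresholds −2.7 to 1.5) is stored in
this metric, and bank files record the reporting metric (T = 50 + 10·θ by
default) so a bank is self-describing.

Scoring is expected a posteriori (EAP) under a standard-normal prior on a
fixed quadrature grid — by default 61 equally spaced nodes on [−4, 4] with
renormalised normal-density weights, a grid matching common IRT software
defaults. A 10,001-point trapezoid-grid oracle in the test-suite bounds the
quadrature error at 1e−4 on toy patterns. With zero answered items the
prior mean 0 and prior SD 1 are returned, flagged by `n_items_used = 0`.
Reliability is reported as r = 1 − (SE_T/10)², clamped at 0; a
zero-information item set yields an infinite SE flag rather than an
exception so cohort summaries can proceed.

## Calibration

`fit_grm` is Bock–Aitkin EM with the same fixed grid and prior (the prior
identifies the latent metric: calibrations are always on the sample
metric). The M-step updates all items simultaneously by Fisher scoring
(expected-information Newton steps) with per-item step-halving on the
expected complete-data log-likelihood; thresholds are parameterised as
(b1, log-gaps), so ordering can never break, and slopes are clipped to
[0.05, 10] to stop divergence on degenerate items. Convergence is declared
when no natural-scale parameter moves more than 1e−4 between cycles (cap
500 cycles; non-convergence returns the best iterate with a warning). The
EM log-likelihood is recorded every cycle and asserted non-decreasing in
the tests. Items with an empty response category cannot be calibrated and
raise with an instruction to merge categories first;
`suggest_collapse_plan` derives an order-preserving merge plan from the
observed counts, and `collapse_categories` applies user-supplied plans
(adjacent, order-preserving merges only).

Missing responses are handled with full information in the E-step (each
person contributes their answered items); persons with no answers are
dropped with a warning.

## Item fit: polytomous S-X²

For each item, persons are grouped by their rest score (summed score over
the other items). Expected category frequencies per rest-score group come
from the Lord–Wingersky recursion for summed-score likelihoods, integrated
against the prior; the recursion's output is checked to sum to one over
scores at every node (1e−10). Adjacent rest-score groups are pooled until
every expected cell reaches 1.0 (the Orlando–Thissen convention), then
adjacent category cells within a pooled row are merged under the same rule.
Degrees of freedom are Σ_rows (cells − 1) minus the item's parameter count;
row totals are fixed by the observed counts, so the row constraint is
subtracted — simulation from the fitted model reproduces the nominal
p ≤ 0.001 rate at the study's sample size (n = 521, 50 replicates in the
acceptance suite). Items with fewer than two usable score groups, or
non-positive degrees of freedom, are skipped with a warning. Misfit is
flagged at p ≤ 0.001.

## Assumption screening

*Polychorics.* Two-step estimator: thresholds from the univariate margins
by inverse-normal transform, then each pairwise correlation by maximising
the bivariate-normal likelihood of the contingency table (bounded scalar
search on [−0.999, 0.999]). The bivariate normal CDF is evaluated through
Owen's T function, which keeps the 1035 pairwise optimisations of a
46-item bank under two seconds; it is unit-tested against scipy's
multivariate-normal CDF at 1e−10. A non-PSD matrix (possible with pairwise
estimation) is repaired by eigenvalue clipping and re-scaling, with a
warning.

*Eigenvalue rules.* First-factor share ≥ 20 % and first/second eigenvalue
ratio > 4, evaluated on the polychoric matrix.

*Forced two-factor EFA.* Principal-axis extraction with iterated
communalities (initialised at squared multiple correlations, Heywood
communalities clipped at 0.999) followed by varimax. Varimax is run from
several deterministic starts because the unrotated solution is a saddle of
the criterion whenever the first factor is near-uniform; the best
criterion value wins. Variance shares quoted for the "small second factor"
property use the extraction (unrotated) sums of squares, the conventional
way forced-EFA variance is reported — rotation itself redistributes
variance between columns even for unidimensional data.

*Bifactor indices.* Oblique quartimin (oblimin, γ = 0) rotation by
gradient projection, started from the varimax solution, then a
Schmid–Leiman transform: second-order loadings from the factor
correlations (for two group factors the just-identified convention
γ1 = γ2 = √φ12; for three or more, a one-factor ULS fit of Φ). ECV is the
general factor's share of common variance; ω-H uses the column sums of the
Schmid–Leiman pattern. Hierarchical solutions are only identified when
every first-order factor is defined by salient content, so group factors
with fewer than two loadings ≥ 0.30 are dropped; if a single factor
remains the data are effectively unidimensional and the report is ECV = 1,
ω-H = ω-total. Under the generator's minor-factor construction
(θ* = √(1−s)·θ + √s·η on a designated item subset) the implied
between-block factor correlation is √(1−s), and the estimated ECV tracks
it closely — loading shares around 0.7 are needed before ECV drops below
the 0.60 criterion.

*Local dependence.* One-factor loadings are an unweighted least-squares
fit of the off-diagonal polychorics; residuals r_ij − λ_iλ_j are averaged
over the unique pairs, pairs more than 0.20 above that mean are flagged,
and SRMR is the root mean squared residual. The 0.20 offset is exact by
construction (`critical − mean == 0.20`).

*Monotonicity.* Mokken scalability: H_ij is the observed covariance over
its maximum given the margins, the maximum attained by the comonotone
coupling (northwest-corner allocation on cumulative counts); H_i and H
aggregate numerators and denominators. Pairwise-complete observations are
used; constant items are excluded with a warning. Pass rules: items ≥
0.30, scale ≥ 0.50.

## DIF

Per item, three nested proportional-odds models (statsmodels
`OrderedModel`, logit link): response ~ θ̂; + group; + θ̂×group, with
McFadden R² computed against the closed-form intercept-only multinomial
log-likelihood. An item is flagged when R²(M3) − R²(M1) ≥ 0.02, classified
uniform when the main-effect change is at least the interaction change,
non-uniform otherwise — a disambiguation of the usual binary labels.
The matching variable θ̂ is the pooled-bank EAP in a single pass; an
optional purification flag rescores once without the flagged items.
Failed or inconsistent fits are reported as `unstable`, never silently
dropped. Continuous covariates are median-split; single-level covariates
are skipped with a warning. Ordinal-regression DIF has limited power
against pure slope changes: a slope halving on one item is near the
detection edge at n = 2000, while threshold shifts of 0.5 on a
high-slope item are detected with power above 0.8 at 1000 per group
(simulated in the acceptance suite).

Score impact: flagged items are re-estimated per group with all unflagged
items fixed at their pooled parameters (anchored EM), every person is
rescored with their group's bank, and the initial-minus-corrected
differences are summarised by quartiles. Flagging every item leaves no
anchors and raises.

## CAT simulation

Post-hoc design: each simulee's full recorded response vector is replayed.
The first item maximises information at the starting trait (default θ = 0;
ties go to bank order; an explicit override is accepted since production
CATs sometimes fix a different starting item). After every response the
posterior is updated and the next item maximises information at the
interim EAP. Standard rules stop at SE_T ≤ 3.0 — inclusive comparison,
configurable — or 12 items; a fixed-length mode administers exactly L
items; `min_items` defaults to 0. Stop reasons are recorded
(`se_reached`, `max_items`, `fixed_length`, `items_exhausted`), the
administered set never repeats an item, and an exhaustive CAT reproduces
the full-bank EAP exactly (same likelihood). No exposure control or
content balancing is implemented.

## Precision and relative efficiency

SE-versus-T curves are computed analytically for fixed item sets and as
binned medians (2 T-point bins) of per-person final (T, SE) pairs for
CATs. Percent-reliable uses the strict inequality r > 0.90. Relative
efficiency per person is (1/SE_θ)² divided by the number of items
administered; instruments are compared as the ratio of cohort means (not
the mean of ratios), so RE(a,b)·RE(b,a) need not be 1. Legacy-style
instruments are each calibrated on their own sample and placed on their
own T metric; no cross-instrument linking is attempted, matching how
comparative SE overlays are usually drawn.

## The synthetic cohort

The generator draws θ per group from normals (defaults: one group,
N(0, 1), n = 521 — the validation study's size on its own calibration
metric), produces graded responses from the bank's category curves,
and can inject uniform DIF (threshold shift), non-uniform DIF
(multiplicative slope change), a minor second factor via the convex
loading split above, and MCAR missingness. All randomness comes from one
integer-seeded PCG64 generator; identical seeds reproduce output arrays
bit for bit. What the generator does *not* emulate: real response styles,
non-MCAR nonresponse, the marginal score distributions of any clinical
sample, or multi-instrument correlated error structures — so green
simulation suites certify the estimators against their own model family,
not against clinical data.

## Problem sizes used in the test-suite

Parameter recovery runs 20 replicate calibrations of a 10-item bank at
n = 1000; the S-X² null runs 50 fit-then-test replicates at n = 521; DIF
null and power run 20 replicates at 500 and 1000 per group. These sizes
give Monte-Carlo error comfortably inside the asserted bounds while
keeping a full run of the suite in the minutes range on a single core.

## Known limitations

- No WLSMV confirmatory factor analysis or scaled fit indices; the
  unidimensionality evidence comes from the EFA, bifactor, residual and
  SRMR routes.
- Item-parameter standard errors are not computed.
- EAP is the only scoring rule (no ML/MAP/WLE).
- Two-level DIF contrasts only; no IRT-based DIF statistics.
- The S-X² degrees of freedom assume the item parameters were estimated
  from the data being tested; testing externally fixed parameters makes
  the statistic mildly anti-conservative.
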