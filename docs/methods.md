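# Methods

## The model

`seqreg` estimates a *regression graph* by sequences of regressions.
Variables are declared a priori in ordered boxes: box 0 holds the ultimate
responses (pQCT bone phenotype: distal and diaphyseal total cross-sectional
area, total/cortical volumetric BMD, cortical area), box 1 the intermediate
responses (body habitus: lean mass, fat-mass percentage, height), box 2 the
circulating markers of osteoblast and adipocyte function (leptin,
adiponectin, osteocalcin, undercarboxylated osteocalcin (UCOC),
phylloquinone), and the last, context box holds age.  Each response is
regressed by ordinary least squares on the variables in strictly later
boxes, after transforming every variable to natural logarithms, so a
partial regression coefficient β reads as an elasticity: a 1% difference in
the explanatory variable goes with a β% difference in the response,
holding the remaining regressors fixed.  Arrows in the graph are the
retained terms; dashed lines join two same-box responses whose residual
association survives controlling for the union of their selected
regressors; full lines join context variables.

Separation statements are read off the fitted graph with m-separation: a
node on a path is a collider when both incident path edges carry an
edge-mark at it (arrowheads mark their head; dashed edges mark both ends;
full lines mark neither), and a path connects x and y given C when every
non-collider avoids C and every collider lies in the anterior set of C.
The production implementation is a walk-based reachability search over
half-edge states (complete because an m-connecting path exists iff an
m-connecting walk does); a naive path-enumeration oracle exists only in the
test suite.  Correctness is anchored to the linear-Gaussian oracle: on
randomized block-ordered structures with generic weights, m-separation must
coincide with a vanishing partial correlation in the implied covariance
(I − B)⁻¹ Ω (I − B)⁻ᵀ, where response-box error covariances carry the
dashed pattern and context-box error *precisions* carry the full-line
pattern (the concentration-graph reading of context boxes).

## Model selection

The selection procedure is backward elimination from the full candidate
set at α = 0.05 (drop the largest-p term until all retained p < α),
followed by greedy screening of two-way products and squares of
mean-centred log variables: the smallest-p significant augmentation is
added, the model re-pruned, and the loop repeats until nothing enters.
Selection is hierarchical — a retained product or square locks its main
effects into the model.  Exact p-value ties break by candidate order (box
order, then declaration order).  Two open choices deserve note:

* **Screening scope.** By default products/squares are screened over *all*
  candidate variables, not only currently retained mains.  In the centred
  parameterization the main effects of interaction partners equal the local
  slopes at the cohort mean, which for this system are small (|β| ≈ 0.04 –
  0.10), so retained-only screening would find the published interaction
  terms in only 2–12% of study-sized replicates, at odds with their
  detection in a single n = 70 dataset.  All-candidate screening retains
  them in 50–64% of replicates, at the cost of roughly two spurious small
  terms per model per replicate (reported by `recovery_experiment` as
  `mean_spurious_terms`).  The policy is configurable
  (`FitConfig.interaction_scope`).
* **Centring.** Products and squares are built from mean-centred logs,
  which leaves the product coefficient itself invariant and turns
  lower-order coefficients into slopes at the sample mean, reducing
  collinearity between a product and its mains.

No multiple-testing adjustment is applied: each test addresses a distinct,
individually interpretable association, and this choice is recorded in the
output metadata.  Inference uses the residual t distribution with
n − k − 1 degrees of freedom; within-box tests use the t transform of the
residual partial correlation with n − |conditioning set| − 2 degrees of
freedom.  Missing data are handled by complete-case analysis per fitted
model, not listwise over the whole table.

## The synthetic cohort generator

The study's raw data are not public, so the generator is the test bed.  It
reproduces the analysis-level joint distribution, not the measurement
process (no pQCT precision structure, assay CVs, or body-composition
equations):

* **Exogenous marginals** (age and the five biomarkers) are truncated
  normals on the log scale whose post-truncation mean and SD are solved
  numerically to match the published descriptive table, truncated at the
  published ranges.  Within-box dependence uses a Gaussian copula, so the
  marginals stay exactly truncated-normal.
* **Structural equations** carry the published coefficient set, including
  the adiponectin×UCOC (−0.10), adiponectin×age (−1.2) and
  phylloquinone×age (0.64) products and the osteocalcin (0.2) and
  phylloquinone (0.03) squares.  Unreported dependencies default to zero,
  with three exceptions: leptin→FM% (0.32) and osteocalcin→lean mass
  (−0.07) from the reported habitus models, and within-box error
  correlations — distal CSA ~ total vBMD 0.5, diaphyseal CSA ~ cortical
  area 0.4, diaphyseal CSA ~ cortical vBMD 0.4 (the reported dashed
  edges), leptin ~ adiponectin −0.3 (magnitude conventional, sign chosen
  negative on physiological grounds), osteocalcin ~ UCOC 0.6 (UCOC is a
  sub-fraction of total osteocalcin; this dependence is what lets
  osteocalcin explain the lean-mass–UCOC association).  True values for
  all of these are unknown; they are free parameters of the spec.
* **Coefficient scale.** The published interaction models are internally
  consistent only if log-adiponectin sits near 9.1 — an ng/L-type analysis
  scale (the source tables themselves disagree between µg/L and mg/L).  On
  the µg/L scale the raw mains (adiponectin 4.9, age 11 in the diaphyseal
  CSA model) would imply structural SDs an order of magnitude above the
  observed marginal SDs.  The generator therefore stores variables in the
  descriptive table's units and converts raw mains of interaction and
  quadratic partners into centred mains (local slopes at the cohort mean)
  using that analysis scale; product/square coefficients pass through
  verbatim.  This reconstruction is the package's own reading and is the
  single most consequential interpretation in the generator.
* **Noise calibration.** Residual SDs are set by bisection so each
  response's population R² (structural variance over total) matches the
  published value — FM% 0.71, distal CSA 0.45, diaphyseal CSA 0.49,
  cortical area 0.27, total vBMD 0.15, cortical vBMD 0.18, lean mass 0.09 —
  to within 0.001 on an 80 000-row calibration cohort; intercepts are then
  anchored so log-scale means match the descriptive table.  Height, which
  has no fitted model, is calibrated to its marginal SD instead.
* **Missingness.** Missing-completely-at-random holes at 1.4% per measured
  variable, chosen so complete-case n per bone model at n = 70 is ≈ 60–62,
  matching the per-model sample sizes of the published tables.

What passing tests show, and what they do not: the generator reproduces
marginal means, biomarker SDs, the published coefficients and R², and the
conditional-independence structure, so recovery results speak to the
estimator's behaviour under the published model.  They do not certify
behaviour under features the generator omits — non-lognormal biomarker
shapes, informative missingness, measurement error, or real lean–height
dependence (set to zero here because the published R² and marginal
variances leave no budget for it alongside the printed coefficients; the
derived bone-response marginal SDs are consequently mildly inflated
relative to the descriptive table, e.g. distal CSA ≈ 150 vs 121 mm²).

## Recovery experiments and their reading

`recovery_experiment` repeats simulate→fit at a chosen n, recording, per
structural term, the retention rate, the mean/SD of estimates conditional
on retention, bias, and CI coverage.  Conditioning on retention biases
borderline terms (|t| ≈ 2 at n = 70) upward in magnitude by ~0.01–0.03; the
`mode="fixed"` variant fits the generative term set with no selection, the
regime in which 95% CIs cover at their nominal rate.  Problem sizes used
by the shipped checks: 500 replicates at n = 70 for coefficient recovery,
n = 100 000 single cohorts for R² verification, n = 5000 for marginal
fidelity, 200 random ≤ 7-node graphs at conditioning sizes ≤ 3 for the
separation/oracle equivalence.

## Numerical conventions and edge cases

* OLS via QR with a rank check on |diag(R)|; rank deficiency raises a
  collinearity error naming the dependent columns.
* Tertiles at linearly interpolated empirical 1/3 and 2/3 quantiles; ties
  to the lower group; an all-ties vector degenerates to a single group
  with a warning.  The convention is stamped into output metadata.
* Geometric means require strictly positive values (guaranteed post
  log-transform); empty cells in tertile grids are flagged, never
  interpolated.
* "Zero" partial correlation in oracle checks means |r| < 1e-10; the
  faithfulness converse (non-separated ⇒ |r| > 1e-8) is logged rather than
  asserted, since measure-zero cancellations are possible in principle.
* The Gaussian oracle is defined only for the interaction-free
  linearization (`SyntheticSpec.linearized()`, which also lifts marginal
  truncation so the system is exactly Gaussian); m-separation is a linear
  notion and no graphical claims are made about the interaction terms.
* Seeds: all randomness flows through `numpy.random.default_rng`; identical
  spec and seed give bit-identical cohorts.

## Known limitations

Cross-sectional associations only — the block ordering is declared, not
learned, and nothing here supports causal claims.  The generator's
distributional choices (log-truncated-normal, Gaussian copula) are
conventions; published point estimates are treated as exact truths even
though their CIs are wide.  Post-selection inference is reported but not
corrected.  Radius-site replication is supported structurally (same
pipeline, different columns) but has no calibrated generator of its own.
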