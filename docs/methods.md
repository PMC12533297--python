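# Methods

This note documents the models, conventions and design choices behind
`lnmts`, and what the synthetic validation does and does not show.

## Imaging features

Input is a per-patient 3D instance-label array with axis 0 the slice
(through-plane) direction and axes 1–2 in-plane; label 0 is background,
1 the primary tumor, and every label ≥ 2 one lymph node. Geometry is
always in millimetres: in-plane pixel spacings, section thickness `T` and
inter-section gap `G`. The through-plane voxel pitch (center-to-center
distance of adjacent slices) is `T + G`. Voxel indices are 0-based and a
voxel's physical coordinate is `index × spacing` at the voxel center;
because all distances are coordinate *differences*, the origin choice is
immaterial.

**Node volume.** The formulation this package implements approximates a
node's volume from its segmentation pixel count, `V = N × p`, where `p`
is the in-plane pixel area. The narrative behind that formula is
internally ambiguous about whether `N` counts the maximum single-slice
cross-section or the accumulated count over all slices; both readings are
shipped as modes and neither is asserted as the authors' intent:

| mode | N | V |
|---|---|---|
| `accumulated` (default) | all labeled voxels of the node | `N × p` |
| `max_cross_section` | largest single-slice count | `N × p` |
| `voxel_volume` | all labeled voxels | `N × p × (T + G)` |

`accumulated` is the default because the formula text accumulates counts
over slices. Note `N × p` is dimensionally an area (mm²) although the
quantity is conventionally labeled mm³; `voxel_volume` is the
dimensionally consistent alternative. Every output carries the mode used
so numbers remain interpretable.

**Drainage distance.** Each structure's reference point is the arithmetic
mean of its voxel-center coordinates (the 3D centroid of the whole mask;
the tumor "center" is not defined more precisely in the source
formulation, and a per-slice alternative is deliberately not offered).
In-plane offsets are centroid differences in mm. The through-plane term
uses the slice-index difference ΔS = |round(s_node) − round(s_tumor)|
(nearest integer, ties away from zero — ΔS is integral by construction,
"a difference of ΔS sections") and equals

    ΔS·G + (ΔS−1)·T        for ΔS ≥ 1,
    0                      for ΔS = 0.

The ΔS = 0 rule is a deliberate deviation from the literal printed form,
which would yield (−T)² = T² for two structures on the *same* slice and
thereby contradict the plain 3D Euclidean definition it specializes; the
same-slice case is treated as the degenerate in-plane case. Note the
ΔS ≥ 1 term also differs from the conventional center-to-center distance
ΔS·(T+G); it is implemented as formulated, not "corrected", and the
pipeline log records the rule in force. Per-patient totals are plain
sums: `tLNV = Σ V_i`, `tLND = Σ D_i`, with a zero-node patient yielding
(0, 0) and an explicit flag rather than an error.

**Per-node annotation.** Individual nodes are labeled S-LN/L-LN at a
0.5 cm diameter threshold and N-LN/D-LN at a 5 cm tumor-distance
threshold (both configurable, both inclusive on the large/distant side).
Since a radiologic short-axis measurement is not recoverable from pixel
counts, "diameter" is operationalized as the diameter of the circle with
the same area as the node's maximal cross-section.

## Cutoff search

The prognostic dichotomization threshold for each feature is the
maximally selected log-rank cutpoint: the two-group statistic of the
split `feature ≥ c` vs `< c` is evaluated at every distinct observed
value `c` whose split keeps at least `min_group_frac` (default 10%) of
patients on each side, and the maximizing value is returned, ties broken
toward the smaller cutoff. Searching over observed values (rather than
midpoints) makes the procedure exactly equivariant under strictly
increasing transformations of the feature. The full candidate grid
(value, statistic, group sizes) is retained for audit. The default
endpoint is overall survival.

Because the maximum is selected over many correlated tests, its nominal
chi-square p-value is optimistic; `permutation_pvalue` re-runs the entire
search on feature-permuted data and reports
`p = (1 + #{perm ≥ obs}) / (n_perm + 1)`, which is bounded below by
`1/(n_perm+1)` by construction and approximately uniform under the null.

The grid evaluation is vectorized: with `R` the event-time × subject
at-risk indicator, `E` the event indicator and `F` the subject ×
candidate "at or above" indicator, the upper-group risk-set and event
counts for *all* candidates are the matrix products `R·F` and `E·F`,
making the permutation test cheap.

## Risk subtypes

`L-tLNV` ⇔ tLNV ≥ cutoff_V and `D-tLND` ⇔ tLND ≥ cutoff_D (favorable
side inclusive — the source does not state the boundary side, so it is
fixed once and printed in every report header). The mapping
(L,D)→LRS, (L,N)→MRS, (S,D)→MRS, (S,N)→HRS is total and deterministic;
missing features raise rather than impute. The published cutoff pair
(71.5 mm³, 140.5 mm) is available as the named configuration
`paper-2025`, clearly a transferred constant rather than something this
package re-derives.

The stratified report gives per-subtype Kaplan–Meier curves, 5-year
rates (KM estimate at 1826 days; a group whose follow-up ends earlier is
reported as "not reached" (NaN), never extrapolated), global and pairwise
log-rank tests over the subtypes present, and Cox hazard ratios for MRS
vs LRS and HRS vs LRS, optionally adjusted for user-supplied covariates.
Absent subtypes are reported as absent and their contrasts skipped.

## Survival statistics

Implemented directly (numpy) with explicit conventions:

* **Kaplan–Meier** — product-limit estimator; subjects censored exactly at
  an event time remain in the risk set at that time.
* **Log-rank** — k-group observed-minus-expected over pooled event times,
  hypergeometric variance with the `(n−d)/(n−1)` tie correction,
  chi-square with k−1 degrees of freedom.
* **Cox PH** — Newton–Raphson maximization of the partial likelihood;
  Breslow ties by default (the source does not state its ties method),
  Efron as an option; covariates are mean-centered and the linear
  predictor max-shifted for numerical stability; convergence at relative
  partial-log-likelihood change < 1e−9 or 100 iterations with
  step-halving on overshoot; Wald 95% CIs `exp(β ± 1.96·SE)`.
  Non-convergence is reported on the fit object; |β| > 15 flags suspected
  monotone likelihood (separation); a singular information matrix raises.

Tests cross-check these against independent implementations —
Kaplan–Meier and log-rank against lifelines, Cox against scikit-survival
(which agrees to machine precision; lifelines' damped final Newton step
leaves its estimates ~1e−6 from the optimum, which is why it is not used
for the tight Cox comparison).

## Synthetic data

**Phantoms** emulate instance masks only: axis-aligned ellipsoidal tumor
and nodes rasterized by voxel-center membership (no partial volumes),
which makes the ground truth exact and recountable. The ground-truth
routine (counts, centroids, distances) is written as deliberately naive
loops sharing no geometry code with the feature extractor, so agreement
between the two is a meaningful dual-route check. Random phantoms draw
clinically plausible MRI geometry (in-plane spacing 0.4–1.0 mm, T 3–5 mm,
G 0–1.5 mm, up to 6 nodes) with node centers snapped to voxel centers and
rejection-sampled non-overlap. Phantoms contain no image intensities,
no segmentation noise and no irregular node shapes — passing the
geometry oracle shows the arithmetic is right, not that segmentation
would be.

**Cohorts** plant effects two ways: by subtype membership (hazard
multipliers HR_MRS, HR_HRS vs LRS) or by feature cutpoints (a subject's
hazard is multiplied by HR_f when feature f lies at or above its planted
cutpoint — the same inclusive side the classifier uses). Baseline event
times are exponential with median ≈ 5 years (1826 days), matching the
5-year endpoint scale without claiming any cohort's actual rates; a
Weibull baseline is available. Censoring is administrative at the 10-year
horizon plus an optional independent exponential early-censoring process
whose rate `λ_c = λ_e·r/(1−r)` targets a marginal censoring fraction `r`
(r = 1 degenerates to immediate censoring); independence from the event
process is preserved by construction. Feature values are drawn
Uniform(0, 2×cutpoint) so the planted threshold sits mid-range with ample
data on both sides. No covariate correlation structure beyond the planted
effect is simulated, so the cutoff-recovery results speak to the
procedure, not to confounded real cohorts.

All generators take explicit integer seeds and are bit-reproducible;
there is no global random state.

## Validation problem sizes

The shipped tests and the acceptance script use: 20–50 random phantoms
for the geometry oracle; n = 600 over 20 seeds for cutpoint recovery
(planted cutpoint 100, HR 0.3, recovery band [90, 110]); exhaustive
brute-force equivalence on fixtures of n ≤ 50; 1000 replicates of n = 100
for log-rank null calibration; n = 1000 for Cox recovery of HR = 2 and a
50-row fixture for reference agreement; n = 900 for the end-to-end
subtype ordering; and a 40-patient pipeline run for byte-stability.
These sizes give stable Monte-Carlo behavior at interactive runtimes.

## Known limitations

* The two non-default volume modes inherit the formulation's unit
  ambiguity; cross-cohort comparability requires fixing one mode.
* The through-plane distance term is the printed one, not the
  center-to-center convention; distances are therefore not strictly
  isotropic Euclidean: the printed term is exactly one thickness `T`
  shorter than the conventional center-to-center offset `ΔS·(T+G)`.
  Results depend on the convention and the run log records it.
* Proportional hazards is assumed, not diagnosed; no time-varying
  covariates, competing risks or frailty.
* The cutoff search returns a single threshold per feature; multi-way
  splits and cross-validated cutpoint selection are out of scope.
* Which endpoint (OS, DFS or both) drove the original threshold choice is
  unknowable from the source; the default here is OS and configurable.
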