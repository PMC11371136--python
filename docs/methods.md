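# Methods

## Coordinate and angle conventions

All geometry lives in image coordinates: `x` rightward, `y` downward,
so the gravity vector is `(0, +1)`. A signed angle is computed as the
two-argument arctangent `atan2(Δx, Δy)` of a direction vector and
reported in degrees in `(−180, 180]`: 0° is a root segment growing
straight down, +90° points right, −90° left. This matches the pixel
space of scanner/time-lapse images, in which control roots sit between
0° and −90°/+0° and salt-deflected roots between 0° and +90° (the sign
of the salt deflection is a simulator parameter, not an assumption —
tilt protocols in the literature are reported both clockwise and
anticlockwise, so we expose the sign rather than guess).

**RTD** is the angle of the chord spanning the last `tip_fraction`
(default 0.10) of the root's *arc length*, with the chord start
linearly interpolated to the exact 90% arc position — not the last 10%
of traced points, which would depend on node density. **RVA** uses the
first point of the *first* frame as the base (the root position at
transfer) and the current tip. A zero-length chord is returned as an
explicit `undefined` flag with a reason code, never silently as 0°.
Frame lookup at a requested time accepts the nearest frame within half
the frame interval (±10 min at the default 20-min cadence) and raises
otherwise; there is no extrapolation. Duplicate consecutive points are
dropped with a warning; traces that shrink between frames beyond a
small tolerance are rejected as tracing errors.

The halotropism (salt-avoidance) readout is implemented as the
*change* in tip direction between two times, `RTD(t) − RTD(t0)`, i.e.
re-orientation since gradient application. An absolute-angle reading
would differ by a constant; the change-since-treatment reading is the
one we adopt and flag.

## Root simulator

The synthetic root is a first-order relaxation of the tip heading θ
(degrees from gravity) toward a treatment setpoint:

    θ ← θ + g·dt·(θ_set − θ) + ε,   ε ~ N(0, σ_θ²·dt)

with the tip advancing `v·dt` cm along the heading each frame. Noise
is added to the heading (not the position) and scaled by √dt so
trajectories are consistent across step sizes. This is the simplest
stochastic process whose RTD trajectory follows the exponential-decay
kinetics the fitting stage assumes — a stand-in for real roots, not a
biological model. Noiseless, the heading follows the geometric decay
`θ_set + (θ0 − θ_set)(1 − g·dt)^(t/dt)`, which tends to
`exp(−g·t)` as dt → 0; at the default dt = 1/3 h the discretization
bias in a fitted `k` is ≈ g·dt/2 ≈ 5%, which is why the round-trip
check uses a 15% band.

Defaults emulate the assay's study conditions: 20-min imaging over
24 h (73 frames), initial heading 90° (the tilt), control setpoint 0°,
salt setpoint +45°, heading noise 3°/√h, growth speed
0.035 ± 0.005 cm/h (a typical seedling primary-root extension rate).
What the simulator does **not** emulate: root waving/circumnutation,
growth-rate inhibition by the treatment, tracing jitter correlated
along the root, lateral roots, or plate-edge effects. Passing tests
therefore demonstrate correctness of the *analysis chain*, not realism
of any particular biology.

## Genotype/phenotype simulator

Subpopulation allele frequencies follow the Balding–Nichols
construction: an ancestral frequency drawn uniformly from `maf_range`
and per-subpopulation frequencies from
`Beta(p(1−F)/F, (1−p)(1−F)/F)` with differentiation `F = fst`
(default 0.1, two subpopulations). Dosages are `Binomial(2, p)`.
The phenotype is `β·x_causal + u + e` with `u ~ N(0, σ_g²·K)` drawn
through the Cholesky factor of the realized VanRaden kinship (rescaled
to its nominal variance) and `β` set so the causal SNP explains
`h2_snp` of the unit total variance. The truth record (causal index,
β, variance components, subpopulation labels) makes every downstream
stage testable against ground truth.

## Decay model

Default variant EXP: `y = y0 + L·e^(−kt)` — value `y0 + L` at t = 0,
asymptote `y0`. A logistic variant `y0 + L/(1 + e^(k(t−t0)))` is
retained for trajectories with a lag phase. Fitting is bounded
nonlinear least squares (trust-region reflective) with initialization
`y0 ← min(y)`, `L ← y(0) − y0`, `k` from the slope of
`log(max(y − y0, 0.5°))` vs t; bounds `k ∈ [0, 50 h⁻¹]`, parameter
tolerance 1e-12, ≤ 500·p function evaluations. A constant series is
flagged non-identifiable (`L = 0, k = 0`) rather than fitted, and a
fit that does worse than the flat model `y = mean(y)` is rejected with
a reason code — the residual sum of squares therefore never exceeds
the flat model's. The standard error of `k` comes from the Jacobian at
the optimum (`σ²(JᵀJ)⁻¹`).

`K^N/C` is the ratio `k_salt / k_ctrl` (flagged undefined when the
control rate is below 1e-6 h⁻¹); the difference `k_salt − k_ctrl` is
also emitted as a robust companion. `RTD^N−C` and `RVA^N−C` are taken
from the raw frames nearest 5 h and 23 h respectively (not from fitted
values), within the ±10 min lookup tolerance. Response phases are
closed intervals `[0, 10]`, `[10, 20]`, `[20, ∞)` h (boundary frames
count in both adjacent phases), matching per-phase means on a uniform
grid.

Broad-sense heritability uses the one-way ANOVA estimator:
`σ̂_g² = max(0, (MS_g − MS_e)/r̄)` with `r̄` the harmonic-mean
replicate count (robust to unbalanced designs), `σ̂_e² = MS_e`, and
`H² = σ̂_g²/(σ̂_g² + σ̂_e²)` clipped to [0, 1].

## Mixed-model scan

Kinship defaults to the VanRaden centered cross-product
(`Z Zᵀ/m` with `Z` the per-SNP standardized dosages), which is PSD by
construction; allele-sharing IBS is exposed as an option since
published EMMAX pipelines differ on this point. Missing dosages are
mean-imputed per SNP before kinship and scan. The MAF filter is a
*strict* inequality (`maf > threshold`, default 0.05).

The null model is fitted by REML through the spectral decomposition of
K: with `K = U Λ Uᵀ`, the rotated residuals are independent with
variances ∝ `λ_i + δ`, `δ = σ_e²/σ_g²`, so the restricted likelihood
is a 1-D function of δ, profiled on a 41-point grid over
`log10 δ ∈ [−5, 5]` and refined by bounded Brent search — fully
deterministic. The scan then follows the EMMAX approximation: variance
components fixed from the null fit, each marker tested by generalized
least squares in the rotated (whitened) basis, with a two-sided t test
on `n − q − 1` degrees of freedom (q = fixed covariates including the
intercept; the t reference is conservative at small n relative to a
normal). Optional population-structure covariates are the top
eigenvector scores of K (unit norm, sign fixed by the
largest-magnitude loading).

The significance threshold is `T = −log10(α/m)` with `m` the
*post-filter* SNP count and α = 0.05 by default (0.1 is a setting used
by some web GWAS tools and is configurable). Hits are ordered by p,
ties broken by genomic coordinates.

Note on identifiability: with n ≲ 300 accessions and a kinship built
from a few thousand SNPs, the REML heritability has large sampling
variance (individual estimates can hit the 0 or 1 boundary even when
the truth is 0.5); recovery tests therefore assert on the median over
replicates. The EMMAX test itself is much less sensitive to this
noise, which the calibration results confirm.

## Haplotype follow-up

Accessions are grouped by their exact allele combination across the
selected (significant) SNPs; any accession with a missing call at
those SNPs is excluded; groups smaller than `min_size` (default 10)
are reported but labeled minor and excluded from testing. Two retained
groups are compared with Welch's unequal-variance t test; more than
two with the Kruskal–Wallis rank test.

## Problem sizes and tolerances in the shipped checks

The test suite and `scripts/acceptance.py` use desk-scale problem
sizes chosen to make each property measurable with comfortable
Monte-Carlo margins: decay recovery at 73 frames × 100 noise
replicates; the ordinary-regression equivalence at n = 100, m = 200
(tolerance 1e-8 — both paths are closed-form); type-I calibration
averaged over 10 structured null panels of n = 200, m = 2000; power as
the top-hit rate over 50 replicates at n = 300, m = 5000,
h²_snp = 0.15; haplotype recovery on 120 accessions with a 3-SNP block
in perfect linkage. Geometric identities hold to 1e-9 (the 45° elbow
case to 1e-3, limited only by the 4-decimal fixture coordinates).

## Known limitations

- No exact per-SNP REML, multi-locus models, LD clumping, or
  genomic-control diagnostics beyond the calibration tests.
- The RSML writer/reader covers the polyline-geometry subset of
  RSML 1.0 (one scene per time point); annotations, functions and
  multi-root plants are out of scope.
- The VCF dialect is intentionally minimal (biallelic, GT-only);
  multi-allelic records are skipped, not decomposed.
- `trait_timeseries` assumes incremental tracing (frames extend
  earlier frames); retraced-from-scratch series with shrinking length
  are rejected rather than reconciled.
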