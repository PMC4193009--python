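# Methods

This note documents the models, numerical choices and synthetic study
conditions behind `dynconn`, and what the passing tests do and do not
establish about real data.

## The analysis model

The pipeline treats region-level BOLD as a multivariate Gaussian whose
covariance switches with the state of the epileptic network around each
interictal discharge.  Four event-locked windows (before, during, after,
baseline — offsets −L, 0, +2L and +4L window lengths from the onset)
sample that state; the tapered, weighted covariance of each window is
regularized by the graphical lasso; Fisher-z condition means summarize
each subject; and three graph measures (integration, node strength,
weighted clustering) carry the group comparison.

### Window geometry and validity

The window length L defaults to 8 TRs (16 s at TR 2.0 s; 18 s at 2.25 s)
and is analyzed at L ∈ {6, 8, 10} by the sensitivity wrapper.  Taper
weights are the L central samples of rectangle(L) ∗ Gaussian(σ = 2 TRs),
kernel truncated at ±4σ (truncation error < 1e−4 of mass), normalized to
unit sum so windowed covariances share scale across L.  The weighted
covariance uses weighted means and no small-sample correction: with a
uniform taper it equals the population-normalized sample covariance of
the window (its expectation is (1 − Σwᵢ²)Σ; the shrink factor is common
to all windows and conditions and cancels from every contrast).

Validity: all four windows must lie inside one run, and no other event
may fall in the exclusion zone [t − L, t + 7L) — the union of the four
windows plus the 2L guard after baseline.  The zone is applied
symmetrically (events closer than 7L TRs invalidate each other), which
also forbids a "before" window overlapping a predecessor's baseline.
The source material states three mutually inconsistent spacing rules
(80 s eligibility; the window-definition guard; "at least 4L"); the
window-definition guard is the one enforced, and the eligibility check
(≥ 10 events, ≥ 80 s spacing) is reported separately — for L ≥ 6 at TR
2 s, 80 s spacing (40 TRs) does **not** guarantee window validity
(7L = 42–70 TRs); the validity flags are authoritative.

### Sparse precision estimation

Each window covariance (rank ≤ L ≪ N = 14) enters the penalized
likelihood  log det Ω − tr(SΩ) − λ‖Ω‖₁  with the penalty over **all**
entries, exactly as the objective is printed in the source (so the
fitted covariance has W₍ᵢᵢ₎ = Sᵢᵢ + λ; an off-diagonal-only switch is
provided, off by default — note that modern scikit-learn's
`graphical_lasso` implements the off-diagonal convention, which the test
suite exploits as an independent cross-check).  The solver is a monotone
FISTA/proximal-gradient scheme: gradient step on S − Ω⁻¹, elementwise
soft-threshold, backtracking that enforces positive definiteness
(Cholesky) and the majorization bound, momentum restart on objective
increase, stopping on the duality-gap surrogate
|tr(SΩ) + λ·pen(Ω) − N| < tol (default 1e−5, max 500 iterations at the
function level; the pipeline allows 2000 and warm-starts every window
fit from the fit of the subject-mean covariance at the selected λ).
Coordinate-descent solvers were found numerically fragile on these
rank-deficient tapered covariances; the proximal scheme is exact for the
printed objective and fast after JIT compilation.  Singular S receives a
1e−8 diagonal jitter; λ = 0 is the plain inverse.  Non-convergence is
flagged on the fit object, never raised.

λ is selected per subject by leave-one-window-out cross-validation over
all valid windows pooled across conditions: fit on the mean of the
remaining windows' covariances, score the held-out window by
log det Ω − tr(S_ho Ω), pick the λ (20 log-spaced values in
[10⁻³, 1] × max|offdiag(S̄)|) with the best mean score, ties to the
smaller λ.  λ values with any non-converged fold are dropped with a
warning.

### Fisher transform and condition means

The regularized covariance is normalized to correlations before atanh
(atanh of raw covariances is undefined above 1); entries are clipped to
±(1 − 1e−7) and the diagonal set to 0.  Condition means come from an OLS
GLM with one indicator per condition, which equals the per-condition
arithmetic mean — asserted at run time as a cross-check.  A zero-variance
region would propagate as a zero correlation row (N stays 14).

### Graph measures

* **Integration** defaults to Marrelec's −½ log det R (R on the
  correlation scale; ≥ 0, nats).  The source's printed formula has the
  opposite sign (+½ log det M), which is negative for any
  correlation-like M and inconsistent with the positive values its own
  tables report; the printed form is retained as `mode="literal"`.
  Matrices are floored at eigenvalue 1e−8 (logged) before the log-det.
* **Strength** is the signed row sum of tanh(z) edge weights.
* **Clustering** uses |tanh(z)| weights scaled by the maximum weight,
  cube-root triangle intensity, and the binary-degree denominator (the
  toolbox convention the source cites); the literal strength-based
  denominator is available (`degree_kind="strength"`).  Nodes with
  binary degree < 2, or a non-positive denominator, get 0.  Negative
  weights are zeroed with a log message.
* **Density** is significant edges over N(N−1)/2.

### Group inference

Six subjects per cohort make asymptotics invalid, so the Wilcoxon
signed-rank test enumerates the full sign-assignment distribution
(dynamic program over doubled midranks, exact for n ≤ 20; the minimal
two-sided p at n = 6 is 0.03125).  Zero differences are dropped; all-zero
gives p = 1 with a warning.  FDR families follow the per-panel logic: the
six network-level pair tests form one family; each (measure ×
condition-pair) forms a 14-node family; masks at q and at 0.1 are both
reported.

NBS: per-edge paired t on Fisher-z differences (zero-variance edges
excluded, logged), two-sided primary threshold at p = 0.05 with
df = S − 1, connected components by extent, null = within-subject sign
flips (full 2^S enumeration when 2^S ≤ n_perm — deterministic and
seed-independent — else random draws), corrected
p = (1 + #{null ≥ obs}) / (1 + #draws) with the identity always counted.
Under a two-sided threshold the global sign flip reproduces |t| exactly,
so the smallest attainable corrected p at S = 6 is 2/64 = 0.03125.

The Bayesian group-integration sampler draws each subject's covariance
from the inverse-Wishart posterior IW(n, n·Ŝ) under a Jeffreys prior
(the source only names the sampling scheme; this prior is a documented
stand-in), computes Marrelec integration per draw, and averages across
subjects (default 1000 draws; n must exceed N + 1).

## The synthetic study conditions

The generator emulates the study geometry: TR 2.0 s, six 300-volume
runs, 18 discharges per subject (the recordings span 10–22), minimum
spacing 72 TRs = 144 s (satisfying both the 80-s eligibility rule and
the 7L window guard up to L = 10), 14 regions, six subjects per cohort.
Noise is a variance-preserving AR(1) filter (coefficient 0.3, restarted
at run boundaries) plus sinusoidal scanner drift (amplitude 0.5 signal
units, period 128 s, random phase per region); both default on,
switchable to 0 for exact-distribution tests.  All randomness flows from
one integer seed through per-purpose child seeds.  A synthetic series
can also be rendered as a 4-D NIfTI plus region mask
(`roi_series_to_nifti`): each region's course fills the 30 grid voxels
nearest its peak within the peak's Voronoi cell (regions stay disjoint,
as real cluster masks are), which makes nearest-voxel extraction an
exact round trip and exercises the voxel path end to end.

Planted structure: equicorrelated covariances with baseline r = 0.22
(integration 0.94 nats for N = 14, the scale the study reports at
baseline) and a decaying elevation around each event — r = 0.40 (2.41
nats) on [t−10, t), r = 0.34 (1.86) on [t, t+10), r = 0.30 (1.52) on
[t+10, t+26), baseline elsewhere.  Two deliberate choices:

* **Spans, not per-window planting.**  Analysis windows at different L
  sample different offsets; the after-windows for L = 6/8/10 lie in
  [t+12, t+30), and the stretch [t+24, t+30) is simultaneously the L = 6
  *baseline* window — no single planting can make every window pure at
  every L.  The spans above cover the union of window positions where
  that is unambiguous and split the conflicted stretch: after-windows
  are fully elevated at L = 6/8 and 60 % elevated at L = 10, while the
  L = 6 baseline window carries 2 of 6 elevated volumes (L = 8/10
  baseline windows are pure).  This residual is inherent to the window
  scheme, not to the generator.
* **Contrast sizes.**  With six subjects, a two-sided Wilcoxon can only
  reach p ≤ 0.05 when all six subjects agree in sign, so reliable
  recovery requires per-subject detection probability ≳ 0.96.  The
  pre-event contrast (1.47 nats over baseline) is sized so the
  8-sample-window estimation chain achieves that; the four levels are
  planted distinct with within-L margins ≈ 0.35 nats so the
  condition *ordering* of mean integration is well defined and stable
  across L (a planted tie would make the ordering a coin flip).

What the generator does **not** emulate: hemodynamic-response
convolution of the events (the event-related BOLD analysis is out of
scope), spatially structured physiological noise, motion artifacts,
inter-subject covariance heterogeneity, or EEG waveforms.  Passing
recovery tests therefore show that the estimation chain is correct and
adequately powered under Gaussian switching-covariance dynamics — not
that real discharges produce such contrasts.

Estimated integration levels sit above the planted population values:
log-det integration from 8-sample windows is upward-biased (estimated
correlation matrices are noisier, hence smaller determinants).  The bias
is common to all conditions at fixed L, so paired contrasts and
orderings are preserved — which is why all tests compare conditions, not
absolute levels, against the planted truth.

## Problem sizes in tests and the acceptance script

Recovery uses 50 replicate six-subject cohorts at the study conditions;
family-wise error control uses 500 null cohorts with full 64-flip
enumeration; the solver oracles use p ∈ {2, 3, 14} against closed forms,
an independent ADMM solver, a fixed-step projected-gradient reference
and scikit-learn's off-diagonal variant; Wilcoxon is checked against
literal 2ⁿ enumeration for n ≤ 10.  These sizes keep a full run of the
suite plus the acceptance script under about twenty minutes on one CPU
while leaving the binomial error of the rate estimates small relative to
the margins being asserted.

## Known limitations

* The cross-validation score is computed on fits to *averaged* training
  covariances (full rank), while final fits are per-window (rank ≤ L);
  the selected λ is therefore slightly smaller than a per-window
  criterion would choose, and a few per-window fits can hit the
  iteration cap at that λ (flagged, logged, and rare after
  warm-starting).
* The during/after windows inherit some elevation from neighbouring
  planted spans through the AR(1) filter (≈ +0.1 nats at ρ = 0.3); this
  spillover is part of the simulated physiology, not of the estimator.
* Window-validity and eligibility rules are enforced as stated, but the
  80-s eligibility rule alone does not guarantee analyzable events for
  L ≥ 6 (see above); cohort builders should use spacing ≥ 7L TRs.
* `extract_roi_series` assumes the BOLD and mask grids are already in
  MNI space and share an affine; no registration is performed.
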