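# Methods

This note records the models, conventions, and numerical choices behind
`alpsnet`, in the order the pipeline runs. Units: diffusivities are
µm²/ms (= 10⁻³ mm²/s) throughout; b-values are s/mm²; streamline geometry
is in mm; voxel indices are 0-based.

## Diffusion phantom (`synthcohort.generate_dwi_phantom`)

**Forward model.** Each voxel holds a symmetric tensor `D`; the signal for
gradient direction `g` and b-value `b` is the Stejskal–Tanner monoexponential
`S = S0·exp(−b·gᵀDg)`. Rician noise (the magnitude-MRI convention) is
applied as `|S + n₁ + i·n₂|` with `n₁, n₂ ~ N(0, σ)` and `σ = S0/snr`;
`snr = ∞` skips the noise path entirely, so the noiseless signal is
bit-for-bit reproducible.

**Geometry.** The phantom is built directly in atlas-aligned axes
(x = right–left, y = anterior–posterior, z = inferior–superior), which
removes the registration step a patient pipeline needs: the ALPS arithmetic
only requires axis-aligned diffusivities. A 40×40×20 grid of 2 mm voxels
(the common clinical DTI resolution) contains a CSF ventricle proxy
(isotropic 3.0 µm²/ms), projection-fiber bundles (principal axis z) beside
it, association-fiber bundles (axis y) lateral to those, and isotropic
background (0.8 µm²/ms). Bundle tensors are axially symmetric with
λ∥ = 1.2, λ⊥ = 0.3 µm²/ms — representative deep-white-matter values. The
perivascular component is an additive x-axis diffusivity Δ inside the
bundles (scalar or per-hemisphere), giving the closed-form index

    ALPS = (λ⊥ + Δ) / λ⊥.

The defaults Δ = 0.24 and the alternative 0.285 on λ⊥ = 0.3 give ALPS
exactly 1.8 and 1.95 — the reported impaired/normal group means — which
keeps the oracle values legible. λ∥ = λ⊥ is allowed as the degenerate
isotropic phantom whose index is exactly 1.

**Gradient scheme.** 64 unit directions (plus one b = 0 volume) spread by
Coulomb repulsion of antipodally symmetrized points from a seeded start, so
the scheme is deterministic and well-conditioned; the count matches a
standard 64-direction, b = 0/1000 protocol.

**What the phantom does *not* emulate:** susceptibility/eddy distortion,
motion, partial volume at bundle edges, crossing fibers, multi-shell
acquisitions, and lesions (no quantitative lesion model for how
stroke/white-matter damage alters local diffusivity exists to copy; only
the perivascular Δ effect is modeled). Passing tests therefore validate the
estimators' numerics and conventions, not robustness to real-world
artifacts.

## Tensor fitting (`dti.fit_tensor`)

Plain ordinary least squares on the log-signal: per voxel,
`ln(S_i/S0) = −b_i·gᵢᵀDgᵢ` is solved for the six unique tensor elements,
with `S0` the mean of the b = 0 volumes. OLS (not weighted LS, not robust
variants) is the baseline behaviour of the common FSL fit and is exactly
invertible on noiseless phantoms — fit residuals and tensor recovery error
are ≤ 1e−8 there, which the tests assert.

Numerical choices:

- Signals are floored at `1e−6·S0` before the log so noise cannot produce
  −∞; voxels with fewer than 6 strictly positive diffusion-weighted
  measurements (or non-positive S0) are excluded from the mask and counted
  in a QC report.
- Negative eigenvalues (possible under noise) are clamped to zero and the
  tensor is **rebuilt from the clamped eigensystem**. This keeps FA ∈ [0, 1]
  and preserves the trace identity `Dxx + Dyy + Dzz = λ₁ + λ₂ + λ₃` exactly
  on every fitted voxel; noiseless fits are unaffected.
- The principal eigenvector is sign-normalized to non-negative z (then y,
  then x) — the tensor model is antipodal, and a fixed hemisphere makes
  outputs reproducible.
- Axis diffusivities Dxx/Dyy/Dzz are the tensor **diagonal in image axes**
  (the FSL tensor-component convention), not eigenvalue projections; that is
  what "diffusivity along the x-axis" denotes in the ALPS literature.

## ALPS index (`alps`)

ROIs are spheres of 5 mm diameter rasterized by the voxel-center-in-sphere
rule (no partial-volume weighting): with 2 mm isotropic voxels and an
on-center placement this is the center plus its six face neighbours
(face distance 2 ≤ 2.5 < √8). ROI diffusivities are averaged **first** and
the ratio applied to the ROI means, matching the index's ROI-mean
definition; per-voxel ratios are never averaged. The subject index is the
exact mean of left and right.

Placement: phantom mode passes through the ground-truth bundle centers;
real-data mode takes four user-supplied centers. Manual avoidance of
ischemic lesions cannot be automated faithfully, so the proxy is a QC flag
when an ROI's mean FA falls below 0.15 (or when the sphere is clipped at
the grid edge); flagged subjects are reported, not excluded. Under SNR 30
Rician noise the mean index over 50 realizations stays within 2% of the
noiseless value (tested).

## Tractography (`tract`)

FACT ("fiber assignment by continuous tracking") with nearest-neighbour
eigenvector lookup — the defining property of the named algorithm, and
exactly reproducible, unlike interpolated variants. Conventions the
literature leaves open are fixed as:

- step 1.0 mm (half the smallest voxel dimension); the turning-angle check
  (default 45°) compares successive step directions;
- bidirectional tracking from every seed voxel with FA ≥ 0.2, seeded at
  voxel centers with no jitter (additional seeds per voxel are uniformly
  jittered from a seeded RNG);
- streamlines kept when 10 mm ≤ length ≤ 300 mm (the floor suppresses
  single-voxel artifacts);
- a streamline joins region pair (A, B) when its two endpoint voxels carry
  labels A ≠ B; unlabeled endpoints discard the streamline (no dilation).

Connectome edges accumulate streamline count, mean of per-streamline mean
FA, and mean length; all three matrices are symmetric with zero diagonal.

## Graph metrics (`graphmetrics`)

Weights convert to distances by reciprocal (`d = 1/w`, ∞ for absent edges);
shortest paths by Dijkstra. Eg is the mean of `1/d` over ordered pairs with
`1/∞ = 0`; Lp averages over connected pairs only, with the excluded-pair
count reported (both conventions circulate; one is fixed and logged). Eloc
is the mean over nodes of the global efficiency of each node's
neighbour-induced subgraph; Cp is Onnela geometric-mean weighted clustering
(triangle density per node on binary graphs). The default analysis weight
is the streamline count, the most common choice for deterministic
connectomes; mean-FA and binary weights are selectable. No sparsity-
threshold sweep is applied — metrics are computed on the raw weighted
network, matching single-value-per-subject reporting.

Small-worldness: `sigma = (Cp/⟨Cp_null⟩)/(Lp/⟨Lp_null⟩)` over 100 (default)
Maslov–Sneppen degree-preserving nulls, 10·|E| attempted double-edge swaps
each, weights carried with the rewired edges; null seeds are spawned from
one seed, so sigma is bit-for-bit reproducible. Graphs admitting no legal
swap (complete graphs) return identical copies, making sigma exactly 1
there. Disconnected inputs are reduced to the largest component with a
warning.

## Statistics (`stats`)

The two-group conventions are locked by verification against published
summary tables: the pooled-variance Student t (17.42, −5.90, −1.47 from the
printed means/SDs/ns) and the uncorrected Pearson chi-square (13.64, 11.46,
5.77, 4.16, 0.97 from the printed counts) — Welch or Yates-corrected forms
do not reproduce those values. Mann–Whitney uses midranks and the
tie-corrected normal Z for the first-listed sample, which equals the exact
permutation moment computation (the test oracle enumerates all group
assignments). Logistic CIs are Wald-type; the `percent` option rescales a
designated predictor by 100 so odds ratios read per percentage point.
Standardized-regression VIFs are `1/(1−R²_j)`; perfect collinearity raises
an error carrying the (infinite) VIF table.

**Mediation.** OLS paths with covariate adjustment (defaults: age, sex,
education): `a` from M ~ X, `b` and `c′` from Y ~ X + M, `c` from Y ~ X;
indirect = a·b, and `c = c′ + a·b` holds to machine precision by OLS
algebra. The CI is the percentile bootstrap (5,000 case resamples by
default, seeded) — the default of the macro this mirrors; significance is
"CI excludes 0". Paths use plain least squares rather than a full
regression framework because the bootstrap needs ~10⁵–10⁶ tiny fits;
a statsmodels OLS cross-check is in the tests. The mediation ratio defaults
to indirect/total; indirect/(|direct| + |indirect|) is provided because the
reported "33% mediated" is ambiguous between the two. With exactly zero
mediator residual the outcome design is rank-deficient (M is an affine
function of X) and path b is unidentified; `mediate` warns in that case.

## Cohort simulator and what the recovery tests mean

`simulate_cohort` draws ALPS ~ N(group mean, group SD) with defaults
1.95/0.11 (NC) and 1.80/0.16 (VCI), then
`Eg = α + a·ALPS + ε₁` and
`MoCA = μ + c′·ALPS + b·Eg + covariate terms + ε₂`, clipped to [0, 30].
Covariate distributions (age, sex, education, vascular risk factors, FSRP,
lacunes, WMH, perivascular-space scores) follow the published two-group
demographics. Default structural coefficients a = 0.05, b = 150, c′ = 15
put the indirect effect at 7.5 and the mediated fraction at 1/3 on Eg and
MoCA scales matching the reported group values (Eg ≈ 0.20, NC MoCA ≈ 26.4).
Intercepts are auto-calibrated so the NC-group means hit their targets for
*any* coefficient choice.

Two deliberate consequences:

- At the default targets the MoCA ceiling (30) truncates the upper tail,
  mimicking the real ceiling effect of the instrument — and biasing naive
  effect estimates, as it would in practice. Parameter-recovery and
  coverage simulations therefore place the MoCA mean mid-scale
  (`moca_target_nc = 20`), where clipping is negligible, so they measure
  estimator behaviour rather than instrument truncation.
- The simulator draws both groups from their own ALPS distributions but has
  no diagnosis-by-MoCA selection, so simulated VCI MoCA means are milder
  than clinically selected cohorts; group-difference tests remain valid.

## Problem sizes and calibration designs

- Acceptance-style checks run on: the 40×40×20 phantom (~32k voxels, 65
  volumes); bundle phantoms of ~200–300 streamlines; 50 random 30-node
  graphs for the all-pairs oracle; 100 nulls for sigma; 200 simulated
  cohorts of n = 300 (point recovery, a·b = 3.0) and 200 of n = 150 with
  1,000 bootstrap draws each (null coverage); 2,000 null draws for type-I
  calibration.
- The type-I simulation draws 2×2 tables with group size 80 so expected
  cell counts are 20: the uncorrected chi-square is asymptotic, and at
  small counts its true size (~5.9% at 40/40) reflects discreteness of the
  counts, not an implementation property.

## Known limitations

- Single-tensor model only; no crossing-fiber, kurtosis, or multi-shell
  support, and no brain-extraction — the mask is an input.
- No atlas registration: phantom ROIs come from ground truth; real scans
  need user-supplied ROI coordinates in image space.
- Deterministic tractography undercounts through noisy or curving regions;
  no probabilistic variant is provided.
- Patient-level published estimates (cohort odds ratios, the indirect
  effect 7.46) depend on unreleased raw data; the statistics are validated
  by parameter recovery, oracles, and calibration instead.
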