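# Methods

## Signal model

A voxel is treated as a collection of sub-voxel environments, each with
Gaussian diffusion. Under a diffusion-encoding b-tensor **B** the voxel
signal is the weighted mixture

S(**B**) = S₀ · Σᵢ fᵢ · exp(−**B** : **D**ᵢ),

where **D**ᵢ is the apparent diffusion tensor of environment *i* and
fᵢ ≥ 0, Σ fᵢ = 1. The b-tensor is parameterized axisymmetrically by its
trace b (ms/μm²), shape b_Δ ∈ [−0.5, 1] and symmetry axis **n**:

**B** = b · [ (1 − b_Δ)/3 · **I** + b_Δ · **n n**ᵀ ],

so b_Δ = 1 is linear encoding (LTE, rank 1), b_Δ = 0 spherical encoding
(STE, isotropic). Gradient-waveform design is out of scope: a waveform is
abstracted to its (b, b_Δ, **n**).

After powder averaging — the arithmetic mean of the signal over the
encoding directions of each (b, b_Δ) shell — the direction-averaged signal
depends only on the distribution of apparent diffusivities along the
encoding. Its mean is MD and its variance is

V(b_Δ) = V_iso + b_Δ² · V_aniso,
V_iso = Var_f(D_iso),  V_aniso = (4/45) · Σᵢ fᵢ (λ∥,ᵢ − λ⊥,ᵢ)²,

for axisymmetric components with axial/radial diffusivities λ∥, λ⊥ and
D_iso = (λ∥ + 2λ⊥)/3. The 4/45 coefficient is the variance of cos²θ on the
sphere; both coefficients are verified in the test suite against an
independent numeric oracle (a degree-6 polynomial fit of ln S on a fine
b ∈ [0, 0.1] grid of exactly orientation-averaged signals, agreeing to
better than 1e−6 relative).

Modelling the diffusivity distribution per shape as a gamma distribution
gives the fitted form

S(b, b_Δ)/S₀ = (1 + (1/3) b·MD·MK)^(−3/MK),  MK = MK_I + b_Δ²·MK_A,

with MK_I = 3 V_iso/MD² (isotropic kurtosis, tissue heterogeneity) and
MK_A = 3 V_aniso/MD² (anisotropic kurtosis, microscopic anisotropy
surviving full orientation dispersion). STE data (b_Δ = 0) are blind to
MK_A, so the joint LTE+STE fit separates the two terms; with a single shape
MK_A is structurally non-identifiable and the fit proceeds with MK_A fixed
at 0, flagged in the result.

## Fitting

- **Solver**: bounded trust-region least squares (scipy `least_squares`,
  TRF), residuals on linear-scale signals with uniform shell weights
  (log-domain residuals available via `FitConfig(loss_domain="log")`).
  Linear loss is the common default for magnitude MR data; the choice
  matters little at the SNR regimes tested.
- **Bounds**: MD ∈ [0, 4] μm²/ms, MK_I, MK_A ∈ [0, 10], S₀ > 0. Both
  kurtosis terms are variances up to scale and therefore constrained
  non-negative.
- **Initialization**: deterministic closed-form cumulant start — a
  log-quadratic fit per b-tensor shape gives MD (slope) and a variance per
  shape (curvature); MK_I comes from the most spherical shape, MK_A from
  the curvature difference to the most anisotropic shape, clipped into
  bounds. No random restarts: fits and maps are bit-reproducible.
- **MK → 0 singularity**: the power form (1 + x)^(−3/MK) is unstable for
  small MK; below `mk_threshold` (default 1e−4) the log-signal is evaluated
  by its series −b·MD + (b·MD)²·MK/6 − (b·MD)³·MK²/27 (truncation error
  O(MK³), agreement with the exact form at the switch better than 1e−10).
- **Convergence tolerances**: xtol = ftol = gtol = 1e−14, enough for the
  1e−6-relative round-trip recovery verified in the tests.
- **Monoexponential ADC**: least-squares slope of ln(mean signal) vs b over
  shells with b ≤ b_max. The default b_max = 0.8 ms/μm² takes the lower
  half of the default protocol; it is configurable because "low b" is a
  convention, not a sharp definition. At finite b the ADC sits below MD by
  approximately V·mean(b) — on heterogeneous voxels the gamma MD therefore
  always exceeds the low-b ADC, and tests assert the inequality rather than
  a cohort-specific percentage.

## Acquisition protocol

The default scheme is 5 b-values (0.2, 0.5, 0.8, 1.2, 1.5 ms/μm²) × two
shapes (LTE, STE) × 8 directions = 80 volumes in 10 shells. No b = 0 volume
is required; S₀ is a fitted parameter. The 8-direction table is a frozen
antipodal electrostatic-repulsion optimum (all restarts of the optimization
reach the same energy; minimum pairwise angle 44.8°), with a spherical
Fibonacci fallback for other direction counts and a hook for user-supplied
tables. Units are fixed to b in ms/μm² and diffusivity in μm²/ms; scheme
files declaring `b_units=s/mm2` are converted (×10⁻³) on read.

## Synthetic data and phantom

The generator emulates a prostate-like study: voxels are finite
multi-Gaussian mixtures, acquired with the default protocol and corrupted
with Rician noise (default SNR 30 at b = 0, i.e. σ = S₀/30).

- "Randomly ordered" anisotropic environments are realized by component
  expansion: one axisymmetric tensor replicated over a quasi-uniform
  spherical Fibonacci lattice (default 256 copies; a convergence test
  checks the discrete moments against the analytic single-tensor values),
  optionally seed-jittered. This keeps the forward model strictly
  multi-Gaussian.
- `TensorDistribution.from_moment_targets(md, mk_i, mk_a)` builds a voxel
  with prescribed moments: half the weight is an isotropic sub-population
  whose diffusivities follow a *discretized gamma* distribution (a smooth,
  unimodal spread — two-point splits are legal but are the worst case for
  the gamma fit and not tissue-like), half is the oriented anisotropic
  tensor. Ground truth stored with the phantom is always the exact moment
  of the realized mixture, not the requested target.
- The default phantom is a 16 × 16 × 4 grid in four y-slabs (background,
  tumor-like, PZ-like, TZ-like; 256 voxels each) with per-voxel parameters
  drawn uniformly from class ranges: tumor MD 0.8–1.0 μm²/ms, MK_I 1.0–1.4,
  MK_A 0.2–0.4; PZ MD 1.1–1.3, MK_I 0.5–0.8, MK_A 0.7–0.9; TZ MD 1.4–1.6,
  MK_I 0.2–0.4, MK_A 0.3–0.5. The ranges encode only the qualitative
  orderings the method is meant to detect (tumor: low MD, high MK_I;
  PZ: lower MD and higher MK_A than TZ) with clear separation, while
  keeping all micro-tensor eigenvalues non-negative; the absolute values
  are configuration, not claims about tissue. Background voxels carry only
  the Rician noise floor.

What the phantom does **not** emulate: T2/TE compartment weighting and
relaxation-diffusion correlations, time-dependent (non-Gaussian within
compartment) diffusion, exchange, motion/eddy-current artifacts, partial
volume at class boundaries, and scanner b-value jitter. Passing the
end-to-end tests therefore demonstrates correctness of the estimator on
data satisfying the multi-Gaussian model with ideal shells — not robustness
to those confounds on scanner data.

## Model-approximation bias and documented tolerances

The gamma model is an approximation: the true powder-averaged signal of a
finite mixture is not exactly gamma-distributed in diffusivity. A
noise-free study over the phantom's class ranges (20 random voxels per
class, default protocol, b_max = 1.5 ms/μm²) measured:

- MD: within ~2% (slight overestimation, worst +1.6%);
- MK_I: within ~9% relative;
- MK_A: systematic overestimation up to ~+0.2 absolute at MK_A 0.8–0.9
  (the third cumulant of the orientation-averaged anisotropic signal is
  absorbed into MK_A at high b).

On the noisy phantom (SNR 30, medians over 256 voxels per class) the
additional noise bias raises low-kurtosis medians slightly (Rician floor
plus noise-driven curvature). The end-to-end tests therefore assert class
medians to MD within 5% relative, MK_I within 0.15 absolute and MK_A within
0.25 absolute, and — more importantly — that all generating class orderings
survive estimation and that the pooled cancers-vs-normal MK_I comparison is
detected at the 0.05 level. These tolerances document measured model bias;
they are not estimator noise.

## Voxelwise mapping and ROIs

Volumes are 4D NIfTI with the acquisition scheme aligned to the 4th axis.
Each masked voxel is powder-averaged and fitted independently (voxel
independence and bit-reproducibility are tested). The default mask keeps
voxels whose mean lowest-b-shell signal exceeds 2% of the volume maximum —
a guard against fitting noise-floor voxels, which produce spuriously high
kurtosis; note that at SNR 30 the Rician floor of truly empty voxels
(~4% of tissue signal) exceeds this default, so explicit masks are
preferable when background matters. Maps are written one NIfTI per
parameter with a shared sidecar JSON (units, config hash, version); missing
voxels are NaN. ROI values are the median over fitted voxels (mean via
config); empty ROIs are reported with n = 0 rather than dropped. ROIs must
be supplied on the map grid — registration/resampling is out of scope.

## Group statistics

Per parameter (MD, MK_I, MK_A): all pairwise comparisons between cancer
grades (G3+3, G3+4, G4+3), pooled cancers vs pooled normal (PZ + TZ), and
PZ vs TZ — five tests per parameter. Tests are two-sided
Wilcoxon–Mann–Whitney: exact when n_a + n_b ≤ 12 with no ties (verified
against a full-enumeration oracle), otherwise normal approximation with
mid-ranks, tie-corrected variance and continuity correction (relative error
vs exact < 5% at moderate n). Significance is judged on the raw p at 0.05
with no multiplicity correction — matching the study design this mirrors —
but a Holm-adjusted column is emitted alongside for transparency. Each
result reports the signed difference of medians; no directional hypothesis
is imposed. Degenerate data (all values identical) yield p = 1 with a flag.
Type-I error at the 0.05 threshold is verified to be within binomial error
over 2000 null simulations.

When several ROIs come from one subject they enter the comparison
independently (per-ROI pooling); per-patient aggregation can be performed
upstream on the ROI table before calling `run_comparisons`.

## Problem sizes used in the shipped checks

Round-trip recovery uses 50 random parameter draws; the moment oracle 20
random mixtures; the bias inequality 20 mixtures; the phantom 16 × 16 × 4
voxels (768 fitted); the null calibration 2000 repeats at n = 12 + 12.
These sizes give stable medians and tight Monte-Carlo error while keeping
the full suite fast on a single CPU.

## Known limitations

- The gamma model's MK_A overestimation grows with b·MD·MK; at protocols
  with higher maximal b the documented tolerances would need re-measuring.
- Powder averaging uses the arithmetic mean without Rician noise-floor
  correction; at SNR well below ~20 the floor biases high-b shells upward
  and inflates kurtosis.
- The exact-p path refuses ties (falls back to the approximation), so
  heavily quantized data never use the enumeration path.
- No μFA or full covariance-tensor (QTI) estimation; b_Δ values other than
  0 and 1 are simulated and fitted but untested against an external
  reference.
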