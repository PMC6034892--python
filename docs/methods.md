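# Methods

`attnflow` implements the computational chain used to ask where a
spatially global, feature-based attention effect originates in a
cortical network: block-amplitude statistics on region-of-interest BOLD
signals, a parcel-level GLM, bilinear dynamic causal modelling (DCM)
with random-effects Bayesian model selection (BMS), and multivariate
Granger causality — all exercised on synthetic data whose ground truth
is known. This note documents the models, the numerical choices, and
what the synthetic experiments do and do not establish.

## Experimental skeleton

The simulated acquisition is a blocked design: eight 16-s stimulus
blocks interleaved with eight 12-s blanks (224 s per run, 112 volumes
at TR = 2 s). Stimulus blocks alternate between a "Same" condition
(the ignored stimulus shares the attended feature) and a "Different"
condition. Two input functions are derived from the design: the Same
boxcar (the modulatory input of the connectivity models) and the union
of all stimulus boxcars (the "all visual" driving input). Inputs are
represented on a microtime grid of `tr / microtime_bins`; 16 bins per
TR is the conventional resolution, and the integrator below is accurate
enough that 4–8 bins are used in the large simulation studies.

## Block amplitudes and the attention index

For each stimulus block, the response amplitude is the mean signal in
the closed window [5, 16] s after block onset minus the mean of the
baseline window, expressed in percent of the baseline level. The
baseline is the 2 s preceding the onset; with start-of-TR sampling that
is the single sample at −2 s, and the response window holds the six
samples at 6–16 s. Edge inclusion is a convention we fix (closed
response interval, half-open baseline `[onset − 2, onset)`); a block
whose windows do not fit inside the run — notably a block starting at
t = 0 — is skipped with a warning. The attentional modulation index is

    I_A = (A_Same − A_Different) / (A_Same + A_Different) × 100%,

tested against zero with a one-sample t across subjects. Time-series
conditioning operators are provided as in standard fMRI practice:
per-region linear-trend removal, high-pass filtering at 0.015 Hz
(realized as projection on a discrete cosine basis, which removes DC
exactly; a zero-phase Butterworth filter is available), and grand-mean
scaling of each session to 100.

## GLM

The subject-level model is ordinary least squares on a design of
HRF-convolved condition boxcars (canonical two-gamma HRF: response
peak 6 s, undershoot peak 16 s, unit dispersions, undershoot ratio 1/6,
32-s kernel, unit sum), optional nuisance regressors (e.g. six motion
parameters), and an intercept — nine columns for the standard
two-condition design. Convolution is done at microtime resolution and
downsampled to the TR grid. Group inference on a contrast is a
random-effects one-sample t across subjects per region, thresholded
with Benjamini–Hochberg FDR. The whole-brain search of a voxel-wise
analysis is emulated at parcel scale: regions stand in for voxels.

## DCM

Neural dynamics follow the bilinear state equation
`dz/dt = (A + Σ_j u_j B_j) z + C u` with intrinsic coupling A (Hz),
modulatory matrices B_j, and driving weights C. Each region's activity
drives a balloon–Windkessel cascade (signal decay κ = 0.64/s,
autoregulation γ = 0.32/s, transit time τ = 2 s, stiffness α = 0.32,
resting extraction E₀ = 0.4, venous volume V₀ = 0.04) observed through
the classical nonlinear BOLD equation, in percent signal about zero.
Flow, volume, and dHb are integrated in log space to preserve
positivity; the integrator is Heun's method (second order) on the
microtime grid, which keeps the step-refinement error of the sampled
BOLD near 0.3% RMS at 8 bins per TR. States are clipped at generous
saturation bounds; a trajectory that reaches them is reported as
diverged rather than returning infinities.

Inversion is variational Laplace under a fixed-form Gaussian
posterior: Gauss–Newton/Fisher-scoring updates of the posterior mode
using a finite-difference Jacobian of the forward model (computed for
all parameters in one batched integration), step halving whenever a
candidate step lowers the free energy, and an outer loop re-estimating
per-region observation variance. The free energy
F = accuracy − complexity (Gaussian log-likelihood, prior penalty, and
log-determinant Occam terms) is the per-subject model evidence passed
to BMS. Convergence is declared when ΔF < 0.01 nats (default; 128
iteration cap), non-convergence is flagged on the returned fit, and an
ill-conditioned posterior Hessian is ridge-repaired with a warning.

Priors: off-diagonal A entries N(0, 1/64); B and C entries N(0, 1);
self-connections are parameterized as −0.5·exp(θ) with θ ~ N(0, 1/4).
The self-decay prior deserves a comment: a near-delta prior on θ pins
every region's time constant at 2 s, which makes networks whose regions
differ in intrinsic dynamics unrepresentable — and representing that
heterogeneity is precisely what lets model comparison attribute a
modulated connection to one source (see below). The N(0, 1/4) width
allows time constants of roughly 0.7–5.5 s at two prior standard
deviations. Hemodynamic parameters are fixed at the defaults above.

Model spaces are generated programmatically: the 15-model space puts
the Same-condition modulation on feedback from every nonempty subset of
{IPS, FEF, IFJ, mFG} to the ignored-side visual node, ordered
singletons → pairs → triples → full set (lexicographic within size, so
Model 3 is the IFJ-only model); three 7-model families test the
direction of modulation between IFJ and the other frontoparietal areas
(IFJ→others, others→IFJ, and their pairwise unions); a 3-model space
tests feedback to V1 (from IFJ, from the extrastriate visual area, or
both); and any space can be duplicated into contralateral/ipsilateral
tagged families.

## Random-effects BMS

Model frequencies across subjects carry a Dirichlet posterior estimated
with the standard variational scheme (subject responsibilities
`u_nk ∝ exp(logev_nk + ψ(α_k) − ψ(Σα))`, concentrations
`α = α₀ + Σ_n u_nk`, iterated to Δα < 1e−6). Exceedance probabilities —
the probability that a model is the most frequent in the population —
are computed by seeded Monte Carlo over the Dirichlet posterior (10⁶
draws by default); for two models the exact Beta-CDF expression is used
and cross-validates the sampling path. Family inference rescales the
prior concentrations to give each family equal prior mass
(α₀ = K_total / (F·K_family) per model) and measures the probability
that a family's summed frequency is maximal; with singleton families
this reduces exactly to model-level inference. Note that with unequal
family sizes and completely flat evidence the variational approximation
does not return exactly uniform family exceedances — a property of the
scheme, not a bug. Bayesian model averaging draws a model per subject
from its posterior model probabilities and parameters from that model's
Gaussian posterior, with absent parameters contributing zero.

## Granger causality

The data-driven stage fits a multivariate autoregressive model by least
squares (order selected by BIC over a common sample, default cap 5) and
measures conditional pairwise causality
`gc(i→j) = ln(var_reduced(j) / var_full(j))`, where the reduced model
omits node i's lags from node j's equation while conditioning on all
other nodes. Significance comes from bootstrap surrogates generated
under the reduced model: residual rows are resampled jointly over time
(preserving contemporaneous covariance and the null autocorrelation),
the system is re-run forward, and the causality is recomputed on each
surrogate; `p = (1 + #{surrogate ≥ observed}) / (1 + n_boot)` with
10,000 surrogates by default. Edge-wise BH-FDR at p < 0.05 across all
n(n−1) directed pairs yields the significance mask. Degrees are
weighted sums of significant causality values (a binary-count variant
is available): outflow, inflow, and netflow = outflow − inflow, which
sums to zero by construction. The node maximizing both outflow and
netflow is labelled the network source (if the two argmaxes disagree,
both are reported and no source is claimed); the highest-inflow node is
the sink. Nuisance confounds, when supplied, are regressed out before
fitting.

## The synthetic ground truth, and why it looks the way it does

The generator emulates a five-node network — four frontoparietal areas
(IPS, FEF, IFJ, mFG) and an ignored-side visual node — with the visual
node receiving the driving input (weight 0.3 Hz) and the Same condition
modulating the IFJ→visual feedback with 0.5 Hz in the generating model.
The frontoparietal nodes have deliberately heterogeneous time
constants: self-decays −0.9, −0.45, −0.2, and −0.65 Hz, with direct
visual drives (0.45, 0.22, 0.05, 0.3 Hz) scaled so steady-state
activities are comparable, plus a weak serial chain (0.1 Hz) and weak
feedback onto the visual node (0.03 Hz). This heterogeneity is load
bearing. In a homogeneous network every non-visual node's time course
is near-proportional to the others (we measured candidate-source effect
regressors correlated at r ≈ 0.999), so all single-source models
predict essentially the same data and selection is decided by Occam
terms — systematically favouring whichever source happens to have the
weakest activity. With distinct time constants a fast region plateaus
within ~2 s of block onset while the slow integrator (the IFJ analogue,
τ = 5 s) ramps across the whole block, the candidate effects decorrelate,
and the data can genuinely attribute the modulation. All effective
coupling matrices (A, and A + B during modulated blocks) have
eigenvalues strictly in the left half plane.

Between-subject variability adds independent Gaussian perturbations to
every free entry (defaults: sd 0.05 Hz on A, 0.2 Hz on B, 0.05 Hz on C,
0.05 on self-decays); draws are rejected and redrawn until the
subject's effective coupling matrices are stable, which is the only way
a truncation rule actually guarantees stability once off-diagonal
entries are perturbed. Observation noise is additive Gaussian
(optionally AR(1), coefficient 0.3) with the marginal sd set from a
target SNR, defined as mean per-region signal sd over noise sd; SNR 1
is the default study condition, and the noise level is deliberately a
free parameter rather than a claimed property of any particular
dataset. Simulated BOLD is expressed as percent signal about a
baseline of 100, matching the grand-mean-scaling convention.

What the synthetic data do **not** emulate: voxel-level structure and
spatial smoothing, motion and physiological (cardiac/respiratory)
artifacts, scanner drift beyond what the conditioning operators are
tested on, hemodynamic variability across regions or subjects, and any
mismatch between the generative model class and the fitted one. Passing
recovery studies therefore demonstrates the correctness and calibration
of the estimators under their own assumptions — not that real
recordings satisfy those assumptions.

## Problem sizes in the shipped studies

The recovery studies are run at sizes chosen to keep a full check
affordable on a single CPU: parameter recovery uses 12 subjects at 8
microtime bins; model-selection recovery uses 10 replicate groups of 8
subjects fitting Models 1–4 at 4 microtime bins; family inference uses
one group of 6 subjects fitting all 21 direction-family models;
Granger source recovery uses 10 replicates of a 5-node VAR (T = 400,
1,000 surrogates); calibration uses 20,000 paired-t null replicates and
500 bootstrap null datasets of length 200 with 500 surrogates. At
these sizes the expected outcomes (weight error ≪ 0.25 Hz, ≥ 8/10
correct selections, ≥ 9/10 source recoveries, type-I rates in
[0.03, 0.07]) reproduce comfortably; larger sizes sharpen, but do not
change, the conclusions.

## Known limitations

- The inversion fixes hemodynamics at literature values; when real data
  violate that, bias flows into A and B estimates.
- Euler/Heun integration and the finite-difference Jacobian trade some
  precision for speed; the free energy is a Laplace approximation, so
  small evidence differences (≲ 0.5 nats per subject) should not be
  over-interpreted.
- Granger causality on hemodynamically smoothed, TR-sampled signals is
  fragile; the source-recovery guarantees here are established on VAR
  ground truth, not on forward-model BOLD, and the full-pipeline
  Granger stage on DCM-generated data will typically identify the
  driven visual node as the flow source (which is the correct answer
  for those dynamics).
- Protected exceedance probabilities, fixed-effects model comparison,
  stochastic/two-state DCM, and spectral Granger measures are out of
  scope.
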