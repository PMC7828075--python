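# Methods

`salience-dcm` implements, end to end, the inferential chain of a two-group
(first-episode schizophrenia vs healthy control) resting-state fMRI + 7T MRS
study of the salience network: a hierarchical Bayesian comparison of dACC
metabolite levels (glutamate, glutathione), spectral dynamic causal modeling
of a two-region excitatory/inhibitory circuit (dACC, anterior insula), and a
parametric-empirical-Bayes (PEB) group model that regresses each subject's
connectivity parameters on group membership and centred metabolite levels.
Because the clinical data are not publicly deposited, the package ships a
synthetic study generator that emulates the design, and the analyses are
validated as parameter-recovery experiments on that generator.

## Hierarchical metabolite model

For one metabolite, `Metabolite_i = beta0 + beta_{group(i)} + e_i`, with
`e_i ~ N(0, sigma_i^2)` shared across groups.  Priors are data-scaled:
`beta0 ~ N(mean_data, (5 SD_data)^2)`; deflections `beta_g ~ N(0,
sigma_beta^2)`; `sigma_beta` has a gamma prior specified by mode
`SD_data / 2` and SD `2 SD_data` (the convention of the hierarchical
Bayesian estimation literature; a literal gamma *shape* below one would put
unbounded density at zero and shrink the group difference against the
evidence); `sigma_i` is uniform on `(SD_data/1000, 1000 SD_data)`.

Sampling is Metropolis-within-Gibbs: conjugate Gaussian updates for `beta0`
and the deflections, log-space random-walk Metropolis for the two scales
with step sizes adapted toward ~44% acceptance during a 1,000-iteration
burn-in, then 110,000 draws thinned by 10 to the 11,000 retained draws
reported.  After sampling, the deflections are recentred to sum to zero
(their common mean moves into `beta0`), which yields the exact
`beta_FES = -beta_HC` symmetry of the reported tables.  The between-group
difference is `beta_FES - beta_HC` and the effect size is that difference
divided by `sigma_i`, draw by draw.  Summaries are mean, median, KDE mode
(Gaussian kernel, Silverman bandwidth, 512-point grid) and the 95% highest
density interval by shortest-interval scan.  A batch-mean Geweke z-score is
provided as a convergence check.  With the scales clamped, the sampler is an
exact conjugate Gibbs sampler and is tested against the closed-form Gaussian
posterior (Kolmogorov–Smirnov D < 0.02 at 11,000 draws).

## Generative circuit model

Each region has one excitatory (E) and one inhibitory (I) population.  In
state order [dACC_E, dACC_I, AI_E, AI_I], the neural Jacobian has:

- extrinsic E→E coupling `+0.125 · exp(theta_ee)` Hz (free, one per
  direction); at zero log-scaling this is the +1/8 Hz default;
- intrinsic I→E coupling `−0.125 · exp(theta_ie)` Hz (free, one per
  region); −1/8 Hz at zero;
- a fixed E→I drive of +3.0 1/s and fixed self-inhibition −0.25 1/s on
  every population.

The log-scaling parameterization keeps excitatory connections positive and
inhibitory ones negative for any finite parameter.  The fixed constants set
the operating point of the E/I loop and were chosen for identifiability:
they place the loop's resonance (`sqrt(0.125 · EI_drive · exp(theta_ie))`
rad/s) inside the 0.0078–0.1 Hz analysis band, so scaling the inhibitory
return path visibly moves spectral shape.  An overdamped alternative
(self-inhibition −0.5 with a 0.125 E→I drive) leaves the symmetrised
spectral divergence between clearly different inhibition levels below one
nat over a six-minute record — no estimator can recover inhibition there,
which would defeat the purpose of the model.

Neural activity drives a balloon model per region (vasodilatory signal s,
inflow f, volume v, deoxyhemoglobin q) with canonical constants
κ = 0.64 s⁻¹, γ = 0.32 s⁻¹, τ = 2 s, α = 0.32, E0 = 0.4, ε = 1; only the E
population drives the vasodilatory signal.  BOLD is the standard
three-term observation equation with k1 = 4.3·ϑ0·E0·TE, k2 = ε·r0·E0·TE,
k3 = 1−ε (ϑ0 = 40.3 s⁻¹, r0 = 25 s⁻¹, TE = 20 ms, V0 = 0.04).

Endogenous fluctuations enter every neural state with two-sided power-law
PSD `a_v f^(−b_v)` and channel noise adds `a_e f^(−b_e)` per ROI.  Because
the neural dynamics are linear and the hemodynamics are linearized at rest,
the model's cross-spectral density is available in closed form,

    G_y(f) = L (2πif·I − J)⁻¹ B G_v(f) Bᵀ (2πif·I − J)⁻ᴴ Lᴴ + G_e(f)·I ,

with J the full 12×12 Jacobian, L the BOLD gradient (nonzero only in the
v, q columns) and B the injection into the neural states.  All spectra in
the package are two-sided PSDs: a white series of variance σ² at sampling
interval tr is flat at σ²·tr.

## Synthetic study generator

Metabolites are group-shifted Gaussians whose defaults reproduce the
emulated study's posterior baselines (GLU 6.44/6.84 mM, SD 1.374; GSH
1.49/1.72 mM, SD 0.374 for HC/FES).  Each subject's four connectivity
log-scalings are `(design row)·B_true` plus `N(0, 0.1)` between-subject
deviations, where the design row comes from the same builder the group
analysis uses (one shared coding convention).  The default `B_true` places
patient-specific couplings on inhibition — GLU slope −0.4/mM on dACC
inhibition and GSH slope +1.2/mM on both regions' inhibition in the FES
group, zero in controls, split evenly between main effects and group
interactions — and a cohort baseline of −0.5 on both inhibitory
log-scalings (constant row), which centres the circuit in the estimator's
linear range.  Couplings were sized by a design-stage power rule (implied
second-level z ≈ 3 at n = 39): the recovery experiment asks whether the
machinery finds effects the design can in principle detect, mirroring a
study that reported detected effects.

BOLD is generated by Euler–Maruyama integration at dt = 0.05 s (20 steps
per TR), with spectrally synthesised power-law noise; below the analysis
band the noise PSD saturates at its 0.0078 Hz value (the exponent is only
identified in band, and an unbounded 1/f tail eventually drives the
nonlinear balloon model out of its stable domain on long simulations).
Inflow, volume and deoxyhemoglobin are floored at 0.01 as a guard — they
are physically positive.  Observation noise is a single power-law process
(white noise is its b_e → 0 limit), exactly matching the generative model
the inversion assumes.  Default amplitudes: a_v = 1e-4 keeps neural
excursions small relative to the balloon model's stable range; a_e = 1.35e-7
gives a band-averaged spectral signal-to-noise ratio of ≈ 4.

What the generator does *not* emulate: spatial structure (no voxels, no
realignment/normalization), physiological confounds with structure
(cardiac/respiratory peaks), non-Gaussian metabolite distributions, scanner
drifts beyond the sub-band cosines, and any coupling between metabolites
and hemodynamics.  Passing recovery tests therefore demonstrates that the
estimation chain is correct and calibrated under its own assumptions, not
that those assumptions hold in clinical data.

## Preparation and spectral estimation

ROI pairs are residualized against a constant, discrete cosine regressors
below 0.0078 Hz (slow drifts) and any supplied confound columns; in-band
cosines are orthogonal to these, so band content is preserved and the
operation is an idempotent projection.  The cross-spectral density is a
Welch estimate (Hann window, 128-sample segments, 50% overlap) interpolated
onto 32 log-spaced frequencies in 0.0078–0.1 Hz; the cross term is
conjugated to match the model's `E[X conj(Y)]` convention.

## Subject-level inversion

The feature vector stacks Re S11, Re S22, Re S12, Im S12 over the grid.
Each frequency's entries are divided by the observed mean autospectrum at
that frequency (variance stabilization — Welch sampling SD is proportional
to the spectral level; without this the likelihood fits only the lowest
bins).  The likelihood is Gaussian with one log-precision, updated in
closed form; priors are N(0, 1/16) on the four log-scalings, N(0, 1/4) on
the log amplitude *scaling factors* of the noise (relative to the module
defaults, the same convention the connections use) and a scaled-logistic
parameterization keeping the spectral exponents in (0, 3) with prior mode 1
and delta-method SD 0.5.  Optimization is damped Gauss–Newton with
central-difference Jacobians (step 1e-3), initialized at the prior mean,
accepting only free-energy increases; it stops when ΔF < 1e-4 nats or at
64 iterations.  The whole pipeline is deterministic.

Identifiability under study conditions (360 volumes) is asymmetric: the
inhibitory scalings are well recovered over roughly θ ∈ (−1.2, +0.4) around
zero (hence the generator baseline of −0.5), while the extrinsic E→E
scalings are bounded by the realization noise of the endogenous
fluctuations themselves (an ideal observer distinguishes ±0.4 only ~75% of
the time, independent of channel noise).  Posterior SDs are approximately
calibrated but modestly overconfident at the study length because
neighbouring features share Welch segments; the low-noise, longer-record
self-inversion checks confirm 3-SD calibration in the asymptotic regime.

## Group level: PEB, BMR, model comparison

The design matrix has columns (group ±1, centred GLU, GLU×group, centred
GSH, GSH×group, constant), metabolites centred across the pooled sample.
The hierarchical model replaces each subject's shrinkage prior over the
four connectivity parameters with the empirical prior
`N(Bᵀx_i, exp(−γ)·I)` via the Gaussian model-reduction identity; this
de-attenuates first-level shrinkage.  The resulting objective is quadratic in
vec(B), so B is integrated out in closed form; the scalar between-subject
log-precision γ (prior N(ln 16, 1)) is optimized by bounded Brent search
with a Laplace correction from its numerical curvature.  The prior on each
second-level effect is N(0, 1/16) *per covariate SD* (scale-invariant: an
effect prior in raw per-mM units would penalize covariates by their units).

Reduced models are scored analytically: shrinking the pruned covariates'
prior variance to ~0 and applying the Gaussian reduction identity to the
full posterior — no refit.  The two-model comparison (full "two-metabolite"
vs "only-group", which keeps the group and constant columns) uses fixed-
effects posterior probabilities `softmax(F)`, with a winner declared only
above PP 0.95 (a Bayes factor of 20 corresponds to PP 20/21 ≈ 0.952).
Per-effect posterior probabilities are Gaussian tail masses on the
estimated side of zero; the Bayesian-model-averaging alternative reading is
not implemented.

## Measured operating characteristics

Under the frozen default conditions (n = 20/19, 360 volumes, TR 1 s,
master seed 1, 20 replicates): the reported effect-sign pattern (GLU →
dACC inhibition negative; GSH → both inhibitions positive) is recovered in
20/20 replicates; null cohorts select the group-only model in 19/20; the
two-metabolite model wins outright (PP > 0.95) in 15/20.  The last rate is
limited by the information a 4-segment Welch estimate carries about
inhibition under the feature-Gaussian likelihood (realized second-level
z ≈ 2.2 where the design targeted 3); it is reported, not asserted, and is
recomputed by `scripts/acceptance.py`.

## Numerical choices and degenerate inputs

- Frequencies are strictly positive (power-law PSDs diverge at 0); the DC
  component of synthesised noise is zero.
- `estimate_csd` refuses records shorter than one Welch segment and bands
  outside the resolvable range; `cosine_basis` refuses empty bands.
- Zero-variance metabolite data and non-positive prior variances raise.
- Unstable neural Jacobians raise a stability error naming the offending
  eigenvalue, both in simulation and (silently, as a rejected step) inside
  the optimizer's search.
- Constant MCMC chains summarize to themselves with zero-width HDIs.
- Model comparison is computed with a stabilized softmax and is invariant
  to adding a constant to all free energies.

## Known limitations

- Exact numerical equivalence with SPM's spectral DCM is not a goal: the
  CSD estimator (Welch vs MAR), the noise feature scheme and the priors
  differ.
- Extrinsic (E→E) effects are close to unidentifiable at study length;
  claims about them should rest on longer recordings.
- One MCMC chain per fit; between-chain diagnostics are not implemented.
- The PEB variant is the summary-statistic/empirical-prior formulation; it
  omits the constant first-level free-energy terms, which cancel in every
  comparison the package makes but would matter for comparing different
  first-level feature sets.
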