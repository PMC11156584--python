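# Methods

This note documents the models implemented in `glymphkit`, their
assumptions, the parameters that matter, and the numerical and design
choices made where alternatives existed.

## Units

All lengths are micrometres, times seconds, diffusion coefficients
μm²·s⁻¹, temperatures °C. Concentrations and fluorescence intensities are
arbitrary units throughout: every fitted transport quantity (D, τ, peak
time) is scale-free in the amplitude, and an explicit linear calibration
(`IntensityCalibration`) converts intensities to concentration units when
absolute values are needed.

## Gaussian volume-source diffusion

The core assumption is that the bleached (or injected) dye starts as a
hemispherical Gaussian of width σ and thereafter moves by isotropic
Fickian diffusion with a single effective coefficient D:

    C(r,t) = C(0,0) [1 + 2Dt/σ²]^(-3/2) exp(−r²/(4Dt + 2σ²)).

The spreading width at time t is √(σ² + 2Dt); total moles are conserved
(verified in the tests by adaptive quadrature to 1e−6 relative). Hindered
extracellular diffusion is summarized by the tortuosity λ = √(D_aq/D);
no anisotropy, no multi-compartment (ventricular/CSF) transport, and no
local paired flows are modelled.

The moles of bleached dye inside the detection hemisphere of radius R are
the shell integral of C, which has an erf-based closed form. The recorded
fluorescence recovery is I(t) = I∞ − (I∞ − I0)·M(t)/M(0): linear mapping
between moles of bleached dye and lost fluorescence.

**Detection radius.** R defaults to σ (light penetration for bleaching
and recording assumed comparable). M(t) is insensitive to R, so this
assumption has little effect on fitted D; R remains an explicit parameter.

**Finite bleach duration.** The source keeps spreading during the 30-s
bleach. `bleach_spread_sigma` time-averages the concentration profile over
the bleach window (Simpson rule over 61 time slices) and refits a
hemispherical Gaussian; the inflation is bounded above by the
end-of-bleach width √(σ² + 2D·t_bleach) and stays below 8 % for typical
tissue parameters (D ≈ 32 μm²/s, σ ≈ 300 μm, 30 s).

**Bulk flow.** With flow speed v the hemisphere integral acquires the
advected term exp(−(r² + 2rvt)/(4Dt + 2σ²)) with prefactor
exp(−v²t²/(4Dt + 2σ²)); it has no closed form and is evaluated by
adaptive quadrature (relative tolerance 1e−9, absolute 1e−12) with a
10⁴-point Simpson fallback and an explicit `QuadratureError` if both fail.
M is non-increasing in v; at the default recovery geometry a 0.5 μm/s
flow separates the recovery curve from the no-flow curve by several times
a 1 %-CV noise envelope, which is what makes flows above ~0.5 μm/s
detectable in principle.

## Slab efflux (direct gel diffusimetry)

Dye draining from a slab of thickness L with an impermeable face at x = 0
follows the cosine series

    C(x,t) = (4C₀/π) Σ (−1)ⁿ/(2n+1) exp(−D(2n+1)²π²t/4L²) cos((2n+1)πx/2L).

Truncation: next-term magnitude < 1e−12·C₀ or 200 terms, whichever comes
first. At t = 0 the alternating series converges only like 1/n, so the
exact initial condition is returned directly. Because of the cosine
factor the read-out is insensitive to the measurement depth: at x = 0.1 L
the curve differs from the barrier value by at most ~0.9 % of C₀
(late-time relative offset 1 − cos(π·0.05) ≈ 1.2 %). The series is
validated against a Crank–Nicolson finite-difference solution (reflecting
boundary at x = 0, absorbing at x = L, Rannacher start-up smoothing of
the initial boundary discontinuity) to ≤ 1e−4 relative over
Dt/L² ∈ [0.01, 2].

## Clearance kinetics

Clearance multiplies the diffusive solution by the surviving fraction
1 − t/(t+τ), i.e. clearance(%) = 100·t/(t+τ), with half-time τ. τ = ∞
encodes the no-clearance (gel) limit. The cleared curve peaks earlier
than the pure-diffusion curve, whose peak time has the closed form
t_peak = (r²/3 − σ²)/(2D) (zero in the monotone-decay regime r² ≤ 3σ²,
which is physically meaningful rather than an error). The cleared curve's
peak has no closed form and is located by grid search plus bounded 1-D
refinement.

## Estimators

All curve fits are bounded trust-region least squares
(`scipy.optimize.least_squares`) in log₁₀ of the positive rate parameters,
multi-started (5 log-spaced D starts; 3 τ starts spanning 10³–10⁵ s) with
the lowest residual sum of squares kept. 95 % intervals come from the
linearized covariance at the optimum (delta method back to the linear
scale); a bootstrap alternative is available through `glymphkit.stats`.
A fit with D pinned at its bounds is reported `converged=False`; a τ whose
95 % interval spans more than three decades is flagged
`tau_unidentifiable` rather than silently returned.

**FRAP fits** (`FrapEstimator`): σ (and R) are required inputs — they are
not jointly identifiable with D from a single recovery curve, and the in
vivo bleach width must be measured independently. I0/I∞ are free
parameters by default (initialized from the first sample and the late
plateau), which makes the D estimate exactly invariant to affine
transforms of the intensity scale; they can be fixed instead.

**Clearance fits** (`ClearanceEstimator`): parameters are amplitude, D
and τ, with r (source–detector distance) and σ fixed. Both the
coordinate-derived default separation (3335 μm) and a measured postmortem
distance are supported — the geometric distance between the implant
coordinates is ≈ 3353 μm, slightly different from the calculated 3335 μm;
the package takes 3335 μm as its default and lets the user override.
The first 20 min are masked by default: the model describes parenchymal
spread only, and the earliest arrival can be contaminated by ventricular
transit. Clearance-at-peak is evaluated at the fitted model's peak, not
the noisy data's argmax, for robustness.

**Baseline correction** (`BaselineCorrector`): the photometry baseline
declines slowly (~6 %/h); a least-squares cubic spline is fitted to data
outside every bleach/recovery window (plus a 15-min post-window guard),
with interior knots every 60 min (knots that would leave fewer than four
points per interval are dropped; under 30 min of total baseline is an
error). Correction is ratiometric by default (division suits a
multiplicative sensitivity drift; subtraction is available) and rescaled
to the mean baseline level so that a drift-free trace passes through
unchanged and intensity units are preserved.

**Histology profiles** (`GaussianProfileModel`): Gaussian plus constant
baseline, four free parameters, width reported as a standard deviation.
Under the transport model a profile taken at kill time t should have
SD = √(σ² + 2Dt), which is what the synthetic generator plants and the
round-trip tests check.

**Calibration** (`IntensityCalibration`): ordinary least squares line,
slope must be positive; inversion maps intensity to concentration.

## Synthetic data

Every generator is the exact forward model of its fitter — the noiseless
mean is produced by the same code path the estimator fits — so round-trip
recovery is a genuine identifiability check rather than a tautology.
Defaults encode the recording design the models target: 150-μm bleach
width with matched detection radius, 30-s bleach pulses at 1 Hz over a
2-h window with 1 % CV noise; 250-μm injected bolus observed at 3335 μm
at 0.2 Hz over 8 h with 2 % CV noise and τ = 1800 s, which places the
clearance-at-peak near 75 %, the regime of interest for saline controls
(D defaults: 136 μm²/s for gel-like recovery, 230.7 μm²/s for the free
dye in vivo). Noise is multiplicative Gaussian (lock-in photometry noise
scales with signal); the published recordings' true noise level is not
public, so these CVs are package conventions. Baseline drift is exactly
(1 − rate)^(t/1 h). All randomness flows from one explicit seed per
scenario.

What the generators deliberately do not emulate: ventricular transit at
early times, slice-to-slice histology variability beyond multiplicative
noise, raw EEG/EMG physiology (the feature-level generator draws
per-state multivariate normals; the optional toy waveform mode exists
only to exercise the filter/band-power path). Passing round-trip tests
therefore demonstrates correctness of the estimation machinery under the
stated model, not robustness to every artifact of real recordings.

## Sleep scoring

EEG is high-pass filtered at 0.5 Hz and EMG band-pass filtered 1–50 Hz
(2nd-order Butterworth, zero-phase, so the −3 dB points of the squared
response sit at the design frequencies). Per 5-s bin: delta (1–4 Hz) and
theta (5–10 Hz) band powers from a Welch periodogram (2-s Hann windows,
50 % overlap — an unspecified-but-standard trade-off), their ratio, and
the EMG RMS. A 0.5–4 Hz delta variant is available as an override for
depth-of-sleep analyses. Scoring fits a 3-component full-covariance
Gaussian mixture to z-scored log-features (band powers are right-skewed);
singular components trigger a refit with 100× covariance regularization.
Components map to states deterministically: highest EMG RMS → wake; of
the rest, higher theta/delta → REM; remainder → NREM. Bins are scored
independently — no transition constraints (manual confirmation replaced
them in the original workflow and is out of scope here).

## Estimation statistics

`bca_ci` implements the bias-corrected and accelerated bootstrap: z₀ from
the position of the point estimate in the bootstrap distribution (ties
counted half), acceleration from jackknife skewness, adjusted percentiles
of the resampled distribution (5000 resamples by convention). Degenerate
(all-equal) bootstrap distributions return a flagged zero-width interval.
Seeded runs are bit-reproducible. The implementation is cross-checked in
the tests against `scipy.stats.bootstrap(method="BCa")` and reduces to
the percentile interval when bias and acceleration vanish. Holm's
step-down adjustment is implemented directly and cross-checked against
statsmodels. ANOVA and t-tests are deliberately not re-implemented;
`scipy.stats` serves for those.

## Problem sizes used in validation

The validation suite and acceptance script run at desk scale: 1-h
recovery traces at 1 Hz (3601 points), 6–8-h arrival curves at 0.2 Hz
(~4300–5800 points), 20-seed noise studies, 10⁷-sample Monte-Carlo checks
of the flow integral, a 401-node/20 000-step Crank–Nicolson reference,
1000 Monte-Carlo replicates × 1000 bootstrap resamples for coverage, and
10-seed sleep-scorer runs of 720 bins. These sizes were chosen so each
check resolves its stated tolerance with margin.

## Known limitations

- σ of the in vivo bleached volume is a required input; it cannot be
  inferred from a recovery curve alone.
- The clearance model is a single well-mixed loss term; spatially varying
  clearance and large-molecule behaviour are outside its scope.
- The flow model assumes a single uniform advection direction away from
  the source; opposed paired local flows would cancel in M(t).
- The GMM scorer has no temporal smoothing, so isolated mislabelled bins
  are expected at cluster boundaries.
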