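# Methods

## Signal model and generator

The generator emulates a three-group (experimental n=22, active control
n=23, passive control n=21), three-phase (T0/T1/T2) neonatal fNIRS design.
Each subject × phase recording is a 3-min resting window followed by a test
session of 12 forward + 12 backward 6-s trials with inter-trial intervals
drawn uniformly from 12–16 s (plus a 2-s lead-in so the first epoch's
baseline exists; whether a final ITI follows the last trial is a
convention — the generator appends the post-trial tail it needs for the
last epoch). Sampling is 10 Hz, two wavelengths (760, 850 nm), 52 channels
at 2.3 cm source–detector separation by default.

**Evoked response.** The analysis itself is deliberately HRF-free (infant
haemodynamics are too variable for a fixed-kernel GLM), but a generator
needs *some* kernel. We use a gamma density parameterised by peak time
(default 8 s) and dispersion (gamma s.d., default 3 s), normalised to unit
peak: with these defaults the response concentrates its energy in the
6–16 s window used for the amplitude feature and decays below 1% of peak by
20 s, so epochs are effectively self-contained. Group × phase × stimulus
cells of the ground truth set each channel's peak amplitude (µmol/l) and
peak time (s); the default effect structure plants (i) a
forward-minus-backward amplitude difference of 0.8 µmol/l for the
experimental group at T2 on the ST/SM/IP-labelled channels, (ii) a −2.5 s
forward peak shift for the experimental group at T1 and T2 on IF-labelled
channels, and (iii) a +0.5 Fisher-z resting-coupling increment among the
labelled network channels for both trained groups at T2, on a base
coupling of z ≈ 0.17 with global phase offsets (0, +0.05, +0.2). Δ[Hb] is
−0.3 × Δ[HbO] delayed 1 s — a qualitative mirror-trace model; nothing
downstream depends on its magnitude.

**Noise.** Concentration-domain: slow drift (0.5 µmol/l at ~0.004 Hz plus
a small linear slope), Mayer (0.1 Hz, 0.25 µmol/l), respiratory (0.7 Hz,
0.15), cardiac (2.5 Hz, 0.2) oscillators with phase jitter and 2%
frequency scatter per channel, and white noise (s.d. 0.15 µmol/l).
Intensity-domain (after the forward MBLL projection): detector noise
(s.d. 0.002), spike jumps (1/min/channel, 2–4 samples, 0.08–0.18 device
units) and motion artifacts — zero-mean Gaussian-windowed wiggles
(~2 s) with peak-to-peak 0.25–0.6 × the dynamic-range width at
0.5/min/channel. The artifact rate was set so that the 20%-of-range
rejection rule removes on the order of 15–20% of trial × channel cells,
the removal rate the preprocessing is meant to operate at; the zero-mean
shape keeps intensities inside the device range, so the saturation screen
fires on no channel (its positive behaviour is tested with synthetic
clipping instead).

**Resting activity.** Independent white series per channel are band-passed
to 0.01–0.2 Hz, standardised, and mixed by the Cholesky factor of the
target correlation matrix (eigenvalue-clipped to the PSD cone and
re-normalised if needed); identical per-channel filtering makes the
population correlation of the mixture exactly the target. Because the
band-limited samples are strongly autocorrelated, the effective sample
size of a 1,800-sample window is roughly 2 × bandwidth × duration ≈ 70,
and single-window sample correlations scatter accordingly; tests therefore
check means over seeds against Fisher-interval widths rather than single
draws.

**Device constants.** The MBLL uses extinction coefficients
ε(760) = (1.4866, 3.8437), ε(850) = (2.5264, 1.7986) (mM·cm)⁻¹ for
(HbO, Hb), DPF 5.0 at both wavelengths, log base 10, I₀ = 1, dynamic range
(0, 2) — conventional continuous-wave values, all configurable; only
forward/inverse consistency is ever asserted about them.

**Determinism.** All randomness derives from one master seed through
`numpy` `SeedSequence` spawn keys indexed by (subject, phase), so
subsetting subjects never shifts other subjects' data, and identical
(config, seed) reproduce byte-identical datasets.

## Preprocessing

Stages run in a fixed order: saturation screen → artifact-epoch rejection →
spike correction → optical density → band-pass → MBLL inversion, each
logged with parameters in the provenance record.

* *Saturation*: a channel is excluded when either wavelength sits at the
  dynamic-range maximum for ≥ 10 consecutive samples (an automated
  stand-in for a manual screen).
* *Artifact rejection* operates on the trial epoch grid (−2..20 s per
  event), on raw intensity ("dynamic range of the device input"): a
  trial × channel cell is removed when peak-to-peak exceeds 20% of the
  range width. Validity is carried per cell rather than rasterised into
  the sample mask because adjacent epoch windows overlap in time
  (22-s windows vs ≈ 20-s spacing); a sample-level mask would let one
  artifact spuriously invalidate its neighbours. Lowering the threshold
  never unmasks a cell.
* *Spike correction*: sliding 1-s-window peak-to-peak compared against
  6 × the channel's robust s.d. (1.4826 × MAD over the recording, robust
  precisely so the spikes being detected do not inflate the scale);
  flagged spans are linearly interpolated from the neighbouring clean
  samples (held at the boundary), leaving all other samples untouched and
  acting as the identity on clean data.
* *Optical density*: ΔOD = −log₁₀(I/Ī) with Ī the per-channel,
  per-wavelength mean. The mean reference leaves an arbitrary per-channel
  constant (relative measures have no absolute zero); the 0.01-Hz
  high-pass removes it, and an explicit-I₀ reference is available for
  exact simulation round trips. Non-positive samples are masked and
  replaced by the reference.
* *Band-pass*: 3rd-order Butterworth, forward–backward (`sosfiltfilt`,
  zero phase). Because two passes square the magnitude response, the
  design corners are widened by (√2−1)^(−1/6) ≈ 1.158 so the overall
  response is −3 dB at the nominal 0.01/0.2 Hz edges; the realised filter
  has < 0.5 dB ripple over 0.02–0.15 Hz and ≈ 80 dB attenuation at 1 Hz.
* *MBLL inversion*: per-sample 2 × 2 solve, output in µmol/l; the exact
  linear inverse of the generator's forward projection (round trip
  ~1e−15 µmol/l).

## Features

Epochs span −2..+20 s (221 samples at 10 Hz, endpoints inclusive) and are
baseline-corrected to the mean over [−2, 0) s (idempotent). Mean amplitude
averages Δ[HbO] over 6 ≤ t ≤ 16 s, both endpoints included for
bit-reproducibility. Peak latency is the time of the epoch maximum at
one-sample resolution with ties broken to the earliest sample; the search
window defaults to [0, 20] s — a pre-stimulus maximum has no haemodynamic
meaning — but can be widened to the full epoch. Partially masked epochs are
dropped per channel (all-or-none); the feature table keeps one row per
retained trial × channel in deterministic order.

## Mixed-effects inference

The models have crossed random factors — participant and channel (or
channel pair) — each contributing several *uncorrelated* random slopes:
V = σ²(I + Σₖ λₖ ZₖZₖᵀ) with one variance ratio per random term.
By-participant structures include only within-subject terms (stimulus,
phase contrasts and their products: 6 terms); by-channel structures include
all 18 fixed terms; per-channel refits keep participant terms only.

No installed Python package fits crossed variance-component models of this
size efficiently, so the package carries its own REML engine: fixed
effects and σ² are profiled out via the Henderson normal equations, and
each evaluation of the criterion and its analytic gradient costs O(q³) in
the number of random-effect levels (q ≈ 300 at validation scale),
independent of the number of rows — the data enter only through the
cross-product matrices computed once per model. Optimisation is bounded
L-BFGS-B on the variance ratios; ratios pinned at zero are reported as
singular fits (the fit is still returned), and convergence is accepted
when the projected gradient vanishes. The engine reproduces
lme4/lmerTest estimates, standard errors, variance components,
Satterthwaite df and p-values to ≈ 5 decimals on crossed test problems
(asserted in the suite via Rscript).

*Satterthwaite df* follow the classical recipe df = 2f²/Var(f) with
f = cᵀCov(β̂)c: the gradient of f in the variance parameters is analytic,
and Var comes from the delta method with the observed information of the
REML criterion (central differences of the analytic gradient). Parameters
estimated on the zero boundary are excluded from the information;
degenerate information falls back to the normal approximation (df = ∞)
with a warning. Limits behave correctly: zero variance ratios give the
residual df, and a balanced two-group random-intercept design gives the
classical 2g−2. p-values are two-tailed throughout.

*Contrast scale.* Helmert coding fixes only the comparisons, not the
scale; the exact numeric codes above are part of the package contract, and
β magnitudes are interpretable only on that scale.

*BLUPs.* Per-channel effect maps are fixed β + the channel's conditional
mode (λₖ × ZₖᵀV₀⁻¹(y−Xβ̂)); zero slope variance collapses all channels
onto the fixed estimate. Channel significance tables come from per-channel
refits (participant random effects only) — the conditional-mode route is
also available — and the 52 per-analysis p-values of the named three-way
term enter Benjamini–Hochberg selection at q* = 0.15 (via
`statsmodels.multipletests`), with the amplitude and latency seed sets
unioned for connectivity. The q* sensitivity sweep is a config option.

## Connectivity

Per subject × phase, the 180-s window ending at the test onset yields a
Pearson correlation matrix (pairwise-complete over masked samples;
constant channels excluded with a logged count) and z = artanh(r).
Analysis uses Δ[HbO] only. Pairs touching at least one seed channel are
enumerated once each (s(n−1) − s(s−1)/2). The reduced model drops the
stimulus factor (no stimuli at rest): intercept + 4 contrasts + 4
group × phase products, random by participant (intercept + phase) and by
pair (all terms). Per-pair refits report the group₁ × phase₂ interaction
at uncorrected α = 0.05 with a sign split. The display threshold is the
absolute value of the most negative mean z in the experimental group at
rest — implemented as T0 by default ("at rest" could also mean all resting
windows; both rules are provided).

## Validation scale and what it shows

The validation batteries run at a reduced scale — 8 subjects/group, 8
channels, 12 trials/condition, subject/channel random s.d. 0.1–0.3 around
unit residual s.d. — chosen as the smallest design that still exercises
every variance component. At that scale, 100 planted-effect replicates
recover the three-way amplitude effect with ≈ 1% mean relative error and
95% CI coverage, 200 null replicates reject at ≈ 4.5% (nominal 5%), and
the connectivity model recovers a planted z-increment with < 10% bias.
Because the generator writes the effect structure directly into the
model's own data-generating process (for these batteries) or into kernel
amplitudes/times (for the end-to-end path), passing them shows the
*estimator and pipeline* are correct and calibrated — not that real
neonatal recordings satisfy the model's assumptions (normality,
uncorrelated random effects, stationary noise, montage-wide common HRF
family). Real-data idiosyncrasies the generator does not emulate include
serial correlation of trial features beyond the planted structure,
heteroscedastic movement epochs, optode-coupling drift, and anatomical
variation in channel placement.

## Known limitations

* Random-effect correlations are omitted by design (as in the analysis the
  package reimplements); genuinely correlated slopes would be absorbed
  into variances.
* The Satterthwaite information matrix is numerically differentiated;
  extremely flat likelihoods near multiple boundaries can force the
  normal-approximation fallback.
* The full 66-subject, 52-channel maximal model is fittable but slow
  (q ≈ 1,300; minutes per fit); the defaults in examples and validation
  use reduced designs.
* SNIRF/HDF5 import is not provided; the TSV+JSON layout is the native
  interchange format.
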