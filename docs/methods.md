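# Methods

## Forward spectral model

A chip is a set of four configured optical modes on a 500–800 nm band
(0.5 nm grid, spectrometer-like): two gold–water surface plasmons
(P1 at 580 nm, P4 at 728 nm), the first-order Wood–Rayleigh anomaly
(P2 at 665 nm) and a gold–silicon interface plasmon (P3 at 680 nm). P3 is a
*configured* mode: the closed-form grating condition with a plausible silicon
permittivity does not reproduce 680 nm, so its position is taken as an
empirical input rather than derived. Likewise the gold-permittivity table
behind the 580/728 nm assignments is not uniquely determined; the resonance
functions accept either a constant ε_Au per mode or a tabulated/dispersive
model solved by damped fixed-point iteration (tolerance 1e-6 nm, at most 100
iterations, damping 0.5, started from the same-order anomaly wavelength).

Spectra are a flat baseline (default reflectance 0.95) minus one inverted
Lorentzian per mode (center, FWHM, dip depth), clipped to [0, 1] with clipping
events logged. Fano asymmetry is deliberately omitted: symmetric lineshapes
make trough positions well defined, which keeps every downstream readout
testable against closed forms.

### Binding response

Binding at concentration *x* (Langmuir constant *K*, default 1 in reciprocal
concentration units, so concentrations are expressed in units of 1/K):

* monolayer coverage θ = Kx/(1+Kx) sets the effective surface index
  n = θ·1.60 + (1−θ)·1.33 and shifts each gold–water plasmon by S·(n−1.33);
  bulk sensitivities default to S(P1) = 24 and S(P4) = 40 nm/RIU, so the P4
  saturation shift (10.8 nm) stays inside its readout window;
* the absorbing load uses a second, lower-affinity coverage channel
  θ_abs = K_abs·x/(1+K_abs·x) with K_abs = 0.05·K, giving absorbance
  A = ε·(c_max·θ_abs)·l (defaults ε = 1, l = 1, c_max = 2.5) and a dip-contrast
  factor 10^−A. A single-channel model (c ∝ θ) cannot reproduce the observed
  regime change — if both channels saturate together, the normalized intensity
  response is concave in the normalized shift response and never overtakes
  it — whereas a slower-saturating absorbing load reproduces it exactly:
  the shift readout leads at low concentration, the intensity readout keeps
  growing after the monolayer fills, and their normalized responses cross
  once (at x* ≈ 25/K with the defaults). Physically this is cumulative
  particle accumulation continuing past the high-affinity monolayer.
  A corollary used deliberately in the study design: at high loading the
  attenuated dip becomes shallow and the *wavelength* readout degrades exactly
  where the intensity readout is strongest — the two channels are
  complementary, not redundant;
* resonance loading broadens the linewidth: FWHM′ = FWHM·(1 + β·θ), β = 0.2.

The Wood anomaly and the substrate-interface plasmon have no field overlap
with the bound layer and are returned unchanged by binding.

Measurement noise is additive Gaussian (default σ = 0.015 reflectance units)
plus a random linear baseline tilt (default amplitude 0.0375 over the band),
fully seeded; identical seeds give identical realizations.

## Synthetic cohort

The generator emulates the study structure: 600 PDAC and 1200 control
subjects (900 healthy, 100 pancreatitis, 100 cholangiocarcinoma, 100
hepatocellular carcinoma), two markers per subject (GPC1, EphA2), five
replicate pre/post spectrum pairs per marker — 18,000 spectra at full scale —
split 60/20/20 into train/test/external partitions at the *subject* level
(per-class stratified, globally exact to one subject) so replicates never leak
across partitions. Optional EphA2-positive other-cancer classes (breast,
colorectal) are available but off by default.

Per-class marker concentrations are log-normal (log-s.d. 0.7): GPC1 medians
0.7 (PDAC) vs 0.05–0.07 (all controls) — the specificity anchor; EphA2 0.6
(PDAC), 0.06–0.10 (healthy/pancreatitis), 0.25 (other cancers) — the
sensitivity amplifier. Replicates add log-normal concentration jitter
(log-s.d. 0.05, assay repeatability) and independent spectral noise on both
spectra of a pair. An `effect_scale` dial shrinks every class's log-median
toward the healthy baseline; 0 produces a null cohort with identical
concentration distributions in every class.

The medians, sensitivities and noise level were calibrated jointly, once, to
place the default conditions in the study's qualitative regime — conventional
readouts in the mid-0.9s with NLE ≥ max(RE, SE), and the full-spectrum
classifier around 0.99 subject-level AUC — and then frozen. What passing
tests show about real data is correspondingly limited: the generator has a
single latent severity variable per subject and marker, no serum-matrix
interference, no antibody-affinity chemistry, no instrument drift beyond a
linear tilt, and class-conditional distributions that are exactly log-normal.
Results quantify what the pipeline extracts from this idealization, not
clinical performance.

## Readouts

Troughs are located per configured window (defaults [560,610), [650,672),
[672,700), [700,760) nm) as the within-window minimum refined by three-point
parabolic interpolation (ties toward the lower wavelength); a window whose
minimum sits on its edge is flagged rather than fatal, and dataset-level
extraction skips such records with a logged warning (a quality-control step;
below 0.1% of records at default noise). RE is the per-mode shift of the
refined trough wavelength, SE the per-mode change of the refined minimum
reflectance, NLE their concatenation; single-mode subsets and four-mode
fusion use the same code path. Because P2 and P3 are closer than three
linewidths, each biases the other's apparent minimum by under 1 nm; the bias
is static and cancels in pre−post differences.

The full-spectrum pathway normalizes the pre and post channels by scalar
per-channel training-set mean/s.d. — scalar, not per-wavelength, so the
informative variation stays at the resonances instead of being equalized into
featureless baseline regions — then tiles them into contiguous 16-sample
patches (last patch edge-replicated), 38 patches for the 601-point grid.

## Classifier

KAN layers: each edge carries a cubic B-spline (grid of 5 points on [−3, 3],
extended uniform knots, 7 basis functions, inputs clamped to the range) plus a
SiLU base activation; node outputs sum incoming edges. Spline coefficients
initialize as N(0, 0.1); base weights as N(0, 1/√fan-in) — a zero-mean,
fan-in-scaled init, because constant base weights at width 64 accumulate a
SiLU DC offset large enough to saturate the output sigmoid and stall training.
Feature inputs are z-scored by training-set statistics so they sit inside the
spline range.

The full-spectrum model is: linear patch embedding to d_model = 64, additive
sinusoidal positional encoding (angle rate pos/10000^(2i/d_model), evaluated
directly so position 0 is defined; standard sine/cosine interleaving), two
pre-norm residual self-attention blocks with 4 heads each (per-head weight
matrices exposed for interpretability), a closing LayerNorm, mean pooling
over patches, and a KAN head [64, 16, 1]. KAN layers appear only in the head,
not inside the attention blocks. The feature-pathway model is a KAN stack
[K, 16, 8, 1]; the reference architecture is a ReLU MLP [K, 64, 32, 1], which
needs more parameters than the default KAN at comparable capacity.

Training minimizes clipped binary cross-entropy (clip 1e-7; gradient taken
analytically through the sigmoid) with Adam (lr 1e-3, batch 64), early
stopping on validation BCE, best-validation checkpointing, and single-threaded
numpy throughout, so fixed seeds give bit-identical learning curves. All
backward passes are hand-derived and pinned by finite-difference gradient
checks in the test suite. Subject-level scores are the mean probability over
a subject's replicate records.

## Evaluation

ROC/AUC uses the midrank tie convention (equal to the pairwise-comparison
probability with ties counted one half; verified against a brute-force oracle),
PR-AUC uses step-wise interpolation (average precision), and operating points
come from Youden's J on a designated validation set or a fixed threshold.
Dual-marker fusion trains a small KAN head [2, 4, 1] on the validation
partition's paired subject scores (mean fusion as the non-trainable fallback);
marker importance is the permutation-induced AUC drop, averaged over seeded
permutations, clipped at zero and normalized to sum to 1 (an even split is
reported if neither permutation hurts). Attention heatmaps export every
(layer, head) weight matrix averaged over records, with patch axes annotated
by wavelength range.

## Protocols fixed by the package

* **Study-scale comparison** (test suite): a 600-subject proportionally scaled
  cohort, GPC1 records, feature models trained 150 epochs (patience 20) and
  the full-spectrum model 30 epochs (batch 128, patience 8), all evaluated as
  subject-level AUC on the external partition. Scaled size and epoch budgets
  are the package's desk-scale choice; ordering margins were verified across
  several generator seeds before freezing.
* **Null calibration**: a single null-cohort AUC at this scale has s.d.
  ≈ 0.05, so chance level is asserted on the *mean* external AUC of three
  independent zero-effect cohorts (fast NLE pathway), band 0.5 ± 0.05.
* **Binding-constant recovery**: twelve concentrations log-spaced over the
  sensor's dynamic range (0.03–5 in units of 1/K — above that the absorbing
  load flattens the P4 dip and trough readout fails by design), spectra at
  σ = 0.002, P4 trough shifts, nonlinear least squares for (K, Δλ_max);
  median relative error over 20 seeded replicates is below 10%.

## Known limitations

* The lineshape model is phenomenological; no field distributions, Fano
  asymmetry, or angular dispersion.
* The cohort has one latent severity variable per marker; real serum adds
  interferents and covariate structure the classifier never sees here.
* Attention-map "importance" is descriptive, not causal; it is validated only
  as localization on noiseless synthetic data.
* The MLP is the only reference architecture; no CNN/Transformer comparison.
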