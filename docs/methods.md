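# Methods

`mmcyto` analyses a microfluidic experiment in which each particle transit
is observed twice: a high-speed monochrome camera images the particle
between the electrodes, and a multi-frequency lock-in amplifier records
the impedance perturbation. The package implements the full analysis —
optical sizing, electrical peak extraction, time-based fusion, regression
validation, and fine-tree classification — together with a synthetic
acquisition generator that provides co-registered data with ground truth.

## Optical sizing

For each frame, the blank channel is estimated as the mean of the 50
preceding frames (any history of at least 10 frames is accepted; `strict`
mode demands the full window). The absolute difference between the frame
and this background isolates the transiting particle as a bright ring.
Pixels above an intensity threshold are grouped into 8-connected
components (minimum area 4 px); the particle centre is the unweighted mean
of component pixel coordinates, and the radial intensity profile is the
mean difference intensity per 1-px distance bin from that sub-pixel
centre.

The diameter read-off is the *outer half-maximum crossing* of the radial
profile: the first radius beyond the profile peak at which the intensity
falls below half the peak, linearly interpolated between bins, doubled and
scaled by the pixel size (0.2 µm/px). This rule is robust for both
ring-like (defocused bead) and disk-like profiles and reduces to the true
edge for an ideal step profile. A profile whose peak does not reach 3x its
median is treated as containing no particle. The sphere volume is
V = (π/6)·d³; for aggregates, one diameter per resolved component is taken
from the event's best frame and the volumes are summed. Velocity is the
mean frame-to-frame centroid displacement scaled by pixel size and frame
rate; single-frame events carry a NaN velocity and a quality flag.

Two thresholding details matter in practice. The detection threshold
defaults to the difference-image median plus 5 robust sigmas
(1.4826 × MAD), pooled over a spread of sampled frames; MAD is scaled to
be a consistent sigma estimate because the raw MAD of folded-normal noise
sits near 0.4σ and would flood the frame with noise components. Second,
the rolling background remembers a departed particle for one window
length, and the *absolute* difference renders that memory as a faint
ghost with amplitude roughly (visible frames)/(window) of the true ring;
a component is therefore only accepted when its peak intensity reaches 3x
the threshold, which ghosts at the configured transit rate cannot.

## Electrical extraction

Each amplitude channel is normalized to ΔZ/Z₀ against a rolling-median
baseline (1 s window, evaluated on a strided grid and interpolated — the
baseline varies on much longer scales than the window). An
already-normalized trace is returned unchanged, making normalization
idempotent. Peak intensity is reported as normalized ΔZ/Z₀ throughout.

Transits are detected on a reference channel (the lowest carrier by
default) matched-filter style: the channel is smoothed with a Gaussian of
half the expected pulse scale (default pulse FWHM 20 ms), and local maxima
are kept when their prominence reaches `prominence_k` (default 5) times
the robust noise scale σ̂ — the MAD of the raw channel's first differences
— and their half-prominence width is at least 0.6x the expected pulse
width. Applying the k·σ̂ bar to the smoothed signal is what gives the
detector its margin: smoothing suppresses white noise about threefold
while a pulse keeps ~94 % of its height, so 5σ̂ excursions of pure noise
are vanishingly rare (no false positives in 2×10⁶ noise-only samples)
while pulses of 8σ̂ and above are detected essentially always. Candidates
closer than 60 ms are merged (flagged `merged`), as are over-wide peaks
(width > 1.5x the pulse scale), which indicate unresolved double transits.
The peak intensity at each carrier is the un-smoothed channel maximum
within the measured width of the reference peak time.

## Fusion, regression and classification

Optical and electrical events are paired greedily nearest-in-time within
a 50 ms tolerance (≈6 frame intervals at 125 fps); unmatched events on
either side are reported, never dropped silently. Feature tables carry
the peak intensity at one carrier (500 kHz by default) or at all eight,
the optical volume, and optionally the velocity; events missing a
required feature are excluded (complete-case), since the fused classifier
needs both modalities.

The validation regression is ordinary least squares of log₁₀(PI) on
log₁₀(VOL) per carrier, with the standard R². The velocity check fits the
same regression with and without velocity as a second predictor and
reports both R² values explicitly.

The classifier is a single CART tree with Gini impurity, at most 100
internal splits, and a minimum parent size of 20 — the "fine tree"
preset; the parent floor is scaled to the few-hundred-event tables used
here, where near-single-sample leaves fit device-specific noise and do
not survive a device change. Training uses stratified 5-fold
cross-validation (stratification protects the smaller classes and is
disclosed here); the reported model is refit on the full table. Ties in
leaf class frequencies resolve toward the lower class id. Evaluation
builds the confusion matrix by counting and derives per-class one-vs-rest
metrics: ACC = (TP+TN)/(TN+TP+FN+FP), TPR = TP/(TP+FN), TNR = TN/(TN+FP),
FPR = FP/(TN+FP), FNR = FN/(TP+FN); TPR+FNR = 1 and TNR+FPR = 1 hold
exactly whenever defined, and overall multiclass accuracy (trace/total)
is reported alongside.

The comparison experiment trains on events pooled from three training
runs — separate simulated devices, each with its own gain — and evaluates
on one independent test run of about one third the pooled training size,
for each mode (electrical, optical, multimodal) at the representative
single carrier and with all eight. Headline per-modality test accuracies
are the averages over the two frequency configurations. Everything
derives from one seed, so a manifest reproduces the experiment
bit-identically.

## The synthetic acquisition

The generator emulates the study conditions: four particle classes
(beads of 2.0–2.9, 4.0–4.5 and 5.0–5.9 µm, and 15.0–17.0 µm carcinoma
cells), a 125 fps camera at 0.2 µm/px with 8-bit-like grayscale, and
eight amplitude channels (100 kHz–1.75 MHz) at 899 S/s. Transits are
scheduled every 0.45 s (±50 ms jitter) so the 50-frame background window
rarely overlaps a neighbouring transit; velocity is uniform in
150–350 µm/s, independent of class, because flow in the channel does not
sort by size. Ten percent of transits are aggregates of 2–3 particles,
rendered as a vertical chain of resolvable rings and summed into a single
impedance peak; a chain that cannot fit the region of interest falls back
to fewer particles, so cell-sized aggregates are effectively absent.

**Optics.** A particle is rendered as a radial-Gaussian annulus placed so
that, after the Gaussian point-spread blur (σ = 1 px), the outer
half-maximum of its radial profile sits at the nominal radius — the ring
a defocused bead leaves in a difference image. The *apparent* diameter is
the true diameter plus a defocus/illumination jitter (σ = 0.35 µm) and a
product-specific halo bias, then snapped to the camera pixel grid; this
quantization is why recovered diameters cluster on a ≈0.2 µm lattice.
The 4.0–4.5 µm product carries a +0.5 µm halo bias: its apparent size
leaks one-sidedly into the next class, which is the optical failure mode
the fused classifier repairs (the impedance still follows the true
volume). Frames are background (level 30, gentle gradient, fixed-pattern
noise) plus rendered rings plus Gaussian read noise (σ = 2 grey levels),
rounded and clipped to [0, 255].

**Electronics.** Each channel is Z₀ · (1 + drift + Σ amp·kernel) + noise
with a unipolar Gaussian pulse kernel (FWHM 20 ms; a bipolar dialect is
available but off by default), a slow sinusoidal baseline drift
(amplitude 10⁻³ relative, ~8 s period) and additive noise of 2×10⁻⁵
relative to baseline. The pulse amplitude follows PI = g·G·ΣVᵢᵇ with
b = 1 and g = 2×10⁻⁴ per µm³, where G is a run-level log-normal gain
(σ = 0.12) sampled once per run — the device-to-device variation that
makes absolute PI thresholds learned on one device misfire on another.
Per event, the amplitude carries multiplicative log-normal scatter that
is mostly *shared across channels* (σ = 0.48 log₁₀ at the 8 µm³ reference
volume) with a small independent per-channel part (σ = 0.12 log₁₀), both
scaled by (V_ref/V)^0.3 (capped at 1.7x) — a noise floor that makes small
pulses relatively noisier. The scatter is event-level by design: scatter
that averaged away over eight channels would make the electrical-only
classifier far stronger than the electrical measurements it emulates.
Each class additionally tilts the response linearly across the carrier
set (±0.15; cells −0.22), a minimal model of material-dependent
dispersion — beads and cells do not perturb the impedance identically at
every frequency — and the reason the eight-carrier feature set carries
information beyond size.

This calibration has measurable consequences the test suite checks: at
n≈400 the per-frequency log-log R² of volume against peak intensity falls
at 0.86–0.88 (the shared scatter is sized for this; measured VOL adds
x-axis noise that keeps it at the lower half of the band), the fitted
exponent recovers b = 1 within ±0.05 on the across-frequency mean (the
per-carrier slopes at the extreme carriers are tilted ±0.03 by the
dispersion model), adding velocity changes R² by far less than 0.01, and
the end-to-end experiment reproduces the qualitative modality ordering:
electrical ≈ 0.69–0.75, optical ≈ 0.81–0.88, multimodal at or above
optical with a ≥10-point margin over electrical, and the all-8-frequency
electrical classifier beating the single-frequency one.

## What the generator does not emulate

Pixel intensities are an idealized ring model — no diffraction rings,
motion blur (the 63.75 µs exposure is metadata only), illumination
flicker, or debris; particles appear only when fully inside the frame, so
there are no partial entry/exit frames; trajectories are straight and
horizontal with constant speed; the impedance kernel is a fixed-width
Gaussian rather than a geometry-dependent electrode response, and no
equivalent-circuit physics is modelled. Passing tests therefore show that
the *analysis* is correct and well-calibrated under the stated
statistical structure, not that the generator reproduces any particular
instrument; on real recordings the thresholds (intensity threshold,
prominence, matching tolerance) are the knobs expected to need
site-specific adjustment.

## Numerical and degenerate-input choices

Coordinates are row/col, 0-based, pixel centres at integers; radial
distances are measured from sub-pixel centroids; empty radial bins hold
NaN and are skipped. Backgrounds with fewer than 10 prior frames raise;
between 10 and 50, the available history is averaged (lenient default).
Noise-free traces fall back to a signal-relative epsilon for the
prominence bar so that every resolvable pulse is kept. Events failing
diameter estimation keep a `no_clean_frame` flag and are excluded from
feature tables. The problem sizes used by the test suite and the
acceptance script — 100 rendered beads, 200 injected pulses, a 400-event
regression run, and five replicate experiments of three 140-event
training runs plus one 140-event test run — are the package's desk-scale
reproduction of the study design.
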