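# Methods

This note documents the models behind each analysis stage, the defaults
and why they were chosen, what the synthetic-data generators do and do not
emulate, and the package's numerical conventions and known limitations.

## Action potentials

**Segmentation.** Beats are cut at take-offs. With stimulus annotations,
the take-off is the dV/dt maximum within 10 ms of each annotation;
without, upward crossings of a dV/dt threshold (default 20 V/s) separated
by a refractory period (default 100 ms). Each segment keeps a 60 ms
lead-in so a pre-stimulus diastolic window exists.

**Take-off refinement.** APD is measured from the take-off. On a linear
upstroke the "time of dV/dt max" is ambiguous at the sample level, so the
take-off is refined by extrapolating the maximal-slope tangent back to
E_diast (the phase-0 "foot"). This is exact for linear upstrokes and makes
APD estimates on noiseless synthetic trains agree with closed-form ground
truth to ~1e-10 ms rather than 1–2 samples.

**Features.** E_diast is the mean over a 50 ms window ending 5 ms before
take-off (configurable; the segment tail is used as a fallback for a beat
with no lead-in). The repolarization reference span is peak − E_diast.
APD_x is the time from take-off to the first crossing of
peak − x·(peak − E_diast) after the peak, linearly interpolated between
samples. An AP that never reaches a level inside its segment gets NaN for
that APD — no extrapolation. dV/dt uses central finite differences with
optional Savitzky–Golay smoothing (off by default; the derivative of
noiseless templates needs none).

**STV.** STV = Σ|APDₙ₊₁ − APDₙ| / (n_beats·√2), the mean orthogonal
deviation of consecutive-APD (Poincaré) pairs from the identity line.
Some definitions divide by n_beats·2 instead; `denominator="two"` selects
that variant. STV is translation-invariant and scales linearly with the
APD sequence, both asserted as property tests. The conventional window is
30 consecutive steady-state beats; any length ≥ 2 is accepted.

**DADs.** A DAD is a depolarizing deflection inside diastole (after APD₉₀
completion + 20 ms, before the next take-off − 20 ms) whose amplitude —
peak minus the median of the surrounding diastole — is ≥ 1 mV
(inclusive). Peak picking runs on a 2 ms boxcar-smoothed copy; an absolute
slack of 1e-3 mV at the threshold absorbs the sub-sample attenuation of
sampling plus smoothing so the inclusive 1.0 mV boundary behaves as
written for humps of physiological width (σ ≳ 10 ms). On generator output
the detector achieves recall = precision = 1 for 1.5 mV events at 0.2 mV
noise.

**EADs.** Flagged where repolarization (between the AP peak and the APD₉₀
crossing) reverses into a secondary depolarization with prominence above a
configurable minimum deflection (default 1 mV). No amplitude rule is
asserted beyond the configurable setting. Note that a deflection can only
form an EAD where its maximal slope exceeds the local repolarization
rate — on the steep linear template this requires either a large
deflection or a plateau phase (see Generators).

## Ca²⁺ transients

**Normalization.** F/F₀ = (F − background)/(F₀ − background). F₀ is the
diastolic fluorescence: the median over the last 20 % of each
inter-stimulus cycle (plus the pre-stimulation baseline), or, for resting
traces, the median after two rounds of excluding samples > 3 robust SD
above it. Background at or above the diastolic level is a hard error.
Normalization is invariant to affine rescaling of the raw signal given a
consistently measured background.

**Evoked transients.** Amplitude = peak − pre-stimulus diastolic mean
(50 ms window). T₀.₅ = interpolated time from the peak to 50 % decay; it
is left missing when the signal does not fall below 50 % before the next
stimulus. For a mono-exponential decay T₀.₅ = τ·ln 2 exactly; the
pipeline reproduces this within one sample interval when transients are
well separated. At high pacing rates the residual of the preceding
transient superposes on the next one; with τ = 200 ms this biases T₀.₅ by
~1 % at 1 Hz — an artifact of superposition, not of the estimator.
Steady-state summaries average the last 5 transients.

**Caffeine.** CaSR is the caffeine-transient amplitude (raw peak minus
the pre-pulse diastolic level). Note the raw peak carries the usual
max-of-noise upward bias (~2.5·noise SD over a 1.5 s search window); on
noiseless data CaSR is exact to < 1 %. The decay from the peak over 95 %
of the remaining record is fitted with A·exp(−t/τ) + C
(scipy least squares, A ≥ 0, τ > 0); τ estimates NCX-dominated extrusion.
A segment that does not decay (tail mean ≥ head mean) raises an error —
there is no silent fallback. Noiseless recovery is exact across
τ = 100–2000 ms; at 5 % noise τ is recovered within 5 %.

**Resting events.** The resting level and SD come from the raw samples
with two rounds of 3 SD exclusion (events inflate a naive SD). Candidates
are runs of ≥ 3 samples above F_rest + 1.5 SD on a 50 ms boxcar-smoothed
copy; a candidate is an event when its smoothed peak amplitude strictly
exceeds the cutoff (default 3) × SD. The two-stage design exists because
the 3 SD rule is expressed in units of the noise itself: a per-sample
threshold cannot separate a 2.9 SD from a 3.5 SD excursion, while the
smoothed-peak amplitude can (the 50 ms boxcar passes slow waves nearly
unattenuated and cuts white noise ~10×). Detection is empirically stable
for cutoffs 3–5 on 6 SD events and produces zero false positives on 100
seeded noise-only traces. Events whose ΔF/F₀ amplitude reaches 50 % of
the cell's paced transient amplitude (or 0.5 ΔF/F₀ when no paced record
exists) are labelled resting transients; smaller ones are waves. That
boundary is a labelled assumption — the wave/resting-transient
distinction has no standard quantitative criterion.

**Control normalization.** Per cycle length: treated mean / control mean,
with SE propagated as ratio·√((SE_t/m_t)² + (SE_c/m_c)²). Missing control
cycle lengths are an error listing the mismatch.

## Ca²⁺ sparks

**Detection** (criterion cri = 3.8, deterministic): per spatial pixel,
baseline mean and SD of the temporal signal are estimated with iterative
exclusion of samples above mean + cri·SD (≤ 6 rounds). The image is
normalized to ΔF/F₀ per column, smoothed with a 3×3 boxcar, and core
pixels above cri × the raw per-column noise SD are grown to the connected
region above (cri − 1)·SD; regions smaller than 4 pixels are dropped.
Because the criterion is referenced to the raw SD while the thresholded
image is smoothed (white noise reduced ~3×), cri = 3.8 corresponds to
~11 smoothed-noise SDs under the null: measured false positives are 0
over 100 noise-only 512×512 scans, while sparks of amplitude ≥ 0.5 ΔF/F₀
at 0.1·F₀ noise stay well above threshold (recall ≥ 0.95 on seeded
populations). Raising cri can only remove detections (asserted as a
property test). A zero-variance image yields no detections with a
warning.

**Parameterization** follows the conventional two-profile construction.
A narrow 3-column temporal profile locates the peak; the spatial profile
is the temporal average over the event's half-maximal duration, FWHM is
measured on it by interpolated half-maximum crossings; the temporal
profile is then recomputed as the spatial average over the half-maximal
width, giving FDHM, FD (crossings at baseline + 2 profile-noise SD), TtP
(onset = last crossing of baseline + 2 SD before the peak) and τ (mono-
exponential fit from the peak to the 10 % level). FW is measured at
baseline + 2 SD on the spatial profile — a true zero-crossing is
undefined in noise. Events whose half-max crossings leave the image, or
whose region touches an edge, are flagged partial and excluded from
summaries.

**Amplitude.** The narrow profile is median-3 filtered in time; for a
near-exponential decay the median replaces the peak with its decay-side
neighbour (factor e^(−Δt/τ)) and the 3-column mean scales a spatial
Gaussian by (1 + 2e^(−px²/2σ²))/3. Both attenuations are computed from
the spark's own fitted τ and measured FWHM and divided out (capped at
1.3×). On seeded populations (amplitude 0.5–1.0 ΔF/F₀, noise 0.1·F₀) the
median relative errors are ≈ −3 % (amplitude), ≈ −1 % (FWHM) and ≈ +4 %
(FDHM); recovery accuracy is an aggregate (median) statement — per-event
noise at amplitude 0.5 is irreducibly ~6–12 %.

**Derived indices.** Spark mass = amplitude·1.206·FWHM³ (a spherical-
volume index); SR leak = mean in-focus spark mass × spark frequency;
frequency = in-focus event count / scan duration / (line length/100 μm),
with multi-frame acquisitions (e.g. ten 512-line frames at 2 ms/line =
10.24 s) concatenated along time. Only in-focus events (amplitude
strictly > 0.3) enter summaries; embers are sparks with FDHM strictly
> 20 ms. All three rules and both identities are enforced exactly and
covered by boundary tests.

## T-tubule index

The image (or ROI) is averaged across the transverse direction into a 1-D
longitudinal profile; the mean is removed, a Hann taper applied, and the
1-D power spectrum computed. The index is the trapezoidal spectral area
inside the band (default 0.3–0.7 μm⁻¹, bracketing the 0.5 μm⁻¹ sarcomeric
harmonic at 2.0 μm spacing) divided by the total spectral area from the
first non-DC bin to Nyquist. DC is excluded because it encodes brightness,
not structure; together with the ratio form this makes the index invariant
to affine intensity changes and bounded in [0, 1]. The returned spectrum
is additionally divided by its lowest non-DC bin ("central peak"
normalization, display only — the index does not depend on it). 1-D
profiling was chosen over a 2-D radial average because the band is defined
on a scalar spatial frequency along the cell axis. The absolute index is
implementation-scaled: only within-pipeline comparisons (ordered vs
disarrayed, group contrasts) are meaningful. On synthetic images the index
falls monotonically in the mean as z-line jitter rises 0 → 1 μm
(≈ 0.86 → 0.51 over 20 seeds per level) and as striation dropout rises,
reaching ≈ 0.04 at full dropout — the computational analog of
treatment-induced T-tubule disarray.

`orient_roi` rotates a cell so its long axis is horizontal before
profiling, using the principal axis of the second-order moments of the
Otsu-thresholded mask (recovered within 2° on synthetic rotated cells);
near-isotropic images warn and default to 0°.

## Group statistics

Mean ± SE per group; unpaired t-test for two groups; one-way ANOVA with
pairwise t-tests and Bonferroni adjustment p_adj = min(1, m·p) for more;
two-way fixed-effects ANOVA (statsmodels OLS) on balanced designs —
repeated-measures/mixed structures are out of scope. Chi-square on the
flag × group contingency table without Yates continuity correction by
default (flag available), so the 2×2 table [[9,1],[1,9]] gives the
classical χ² = 12.8. Simulated operating characteristics (1000 runs):
family-wise error ≤ 0.05 under the three-group null, power ≥ 0.95 for a
2 SD shift at n = 20/group. Significance is flagged at p < 0.05; flags
never alter results.

## Synthetic data generators

All generators draw from a single seeded `numpy` Generator per call, are
bit-reproducible, and return ground truth sufficient to score every
estimator.

- **AP trains** use a piecewise-analytic template: linear upstroke at
  dV/dt_max (default 150 V/s, −80 → +40 mV), optionally a 5 ms phase-1
  notch to a plateau (default off; plateau sits notch_drop = 15 mV below
  the peak), then linear repolarization to E_diast. APD₉₀ per beat is
  drawn Normal(mean, sd) and the decline duration solved in closed form,
  so true APD₅₀/APD₉₀ are exact. DADs are Gaussian humps (σ ≤ 25 ms)
  centred in the diastole with a per-diastole Bernoulli probability.
  Defaults emulate 1 Hz pacing, 250 ms APD₉₀, 10 kHz sampling.
- **Fluorescence traces**: events are linear-rise/exponential-decay
  kernels on a baseline f₀ (default 1000 counts) plus background (50);
  evoked transients (10 ms rise), caffeine responses (50 ms rise, default
  amplitude 0.8 ΔF/F₀, τ 800 ms) and slow resting waves (200 ms rise,
  500 ms decay — narrower kernels would be attenuated by the detector's
  smoothing and make the SD-ratio rules untestable). Sampling 2 kHz.
- **Line-scans**: 512×512 at 2 ms/line and 0.2 μm/pixel; sparks are
  separable Gaussian(space, σ 0.7–1.2 μm) × linear-rise(8–14 ms)/
  exp-decay(25–45 ms) kernels, so FWHM = 2σ√(2 ln 2) and
  FDHM = rise/2 + τ·ln 2 in closed form. Gaussian noise, then quantized
  to integer counts (16-bit) so written TIFFs round-trip exactly.
  `random_spark_population` rejection-samples well-separated events for
  unambiguous matching.
- **Striation images**: 1024×1024 at 78/1024 μm/pixel; vertical Gaussian
  bands (σ 0.25 μm) at the sarcomere spacing (default 2.0 μm →
  fundamental 0.5 μm⁻¹), per-band positional jitter, per-segment dropout
  (64-pixel granularity), optional elliptical cell silhouette and
  rotation, 8-bit output.

What the generators do **not** emulate: ionic-current dynamics (no
Hodgkin–Huxley model, no drug action), motion artifacts, photobleaching,
dye saturation and buffering, spatially varying baselines, out-of-focus
spark truncation in 2-D, and wave propagation (waves are temporally, not
spatially, resolved). Passing tests therefore demonstrate correctness of
the estimators under their stated models and noise, not robustness to
every confound of real recordings.

## Numerical conventions and problem sizes

Level crossings are always linearly interpolated; ties in argmax resolve
to the earliest index; all detectors are deterministic given the input.
Exponential fits use `scipy.optimize.curve_fit` with positivity bounds
and explicit failure (no silent fallback). Times are ms, lengths μm;
voltage sampling rates are kHz, fluorescence rates Hz (file headers carry
units and are normalized on read).

Test-suite and acceptance problem sizes were chosen for single-core
desk-scale runs: 60 sparks across six 512×512 scans plus 100 null scans
for the false-positive rate; 20 seeds per jitter level for the T-tubule
sweep; 1000 simulations for each statistical operating characteristic;
1000 random sequences for the STV oracle. The full suite runs in ~15 s.

## Known limitations

- Spark parameters assume temporally well-separated events; overlapping
  events merge into one region (the dominant one is parameterized).
- The caffeine CaSR peak is a raw maximum and carries max-of-noise bias;
  τ, the fitted quantity, does not.
- EAD detection reports threshold crossings only; no EAD amplitude rule
  is asserted because none is standard.
- The wave vs resting-transient boundary is configurable, not canonical.
- The T-tubule index is comparable only within a fixed configuration
  (band, window, profiling direction).
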