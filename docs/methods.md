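# Methods

## Problem and model

`paatlas` estimates the local volume fraction of an exogenous contrast agent
(methylene blue, MB) mixed with an endogenous chromophore (hemoglobin, Hb)
from photoacoustic channel data acquired at two laser wavelengths, 710 and
870 nm.  The estimator does not rely on the optical amplitude alone: with
fiber-tip illumination the fluence decays radially, so differently absorbing
mixtures excite differently sized volumes and emit acoustic pulses with
different *frequency content*.  The method therefore works in the acoustic
spectral domain:

1. **Beamforming.**  Receive-only delay-and-sum (DAS) with one-way delays
   forms an RF image per frame; M-weighted short-lag spatial coherence
   (SLSC) with cumulative lag M = 20 forms a coherence image.  SLSC sums the
   normalized cross-correlation c&#770;(m) of delayed channel pairs over lags
   m = 1..M; the M-weighted variant uses triangular weights
   w_m = M − m + 1 (normalized), so low lags dominate and the resulting
   masks are less disjointed.  Lag weights are configurable; uniform weights
   reduce exactly to normalized SLSC.
2. **Segmentation.**  Coherence images are thresholded (absolute threshold
   0.7 by default, −3 dB relative mode also provided) and the per-frame
   masks of all frames and both wavelengths are OR-merged into one mask per
   trial.  Masks are compared with the Dice coefficient; `select_M` picks
   the cumulative lag whose masks agree best (highest mean Dice, then
   smallest SD, then smallest M) with plain-SLSC (M = 5) reference masks.
3. **Features.**  The beamformed RF image is IQ-demodulated (2.75 MHz
   modulation, 85% fractional bandwidth — the band that actually contains
   the photoacoustic content, well below the 5.5-MHz transducer center
   frequency).  For each masked pixel a Hann-windowed axial kernel
   (1.8 mm default) yields a power spectrum, zero-padded to 128 bins.  The
   710- and 870-nm spectra of the same pixel are concatenated, normalized to
   the row maximum, log-compressed (10 log10) and floored at the dynamic
   range (60 dB default).  Normalizing the *concatenated* row preserves the
   relative 710-vs-870 amplitude that carries the optical-absorption
   contrast.
4. **Atlas.**  PCA (mean-centered, deterministic sign convention) is fitted
   once on the pooled rows of one pure-MB and one pure-Hb training trial;
   p = 1 component by default.  The projected pure-class rows form the
   atlas.
5. **Mixture estimation.**  For each masked pixel and frame, N atlas pairs
   (MB_i, Hb_i) are drawn uniformly with replacement and

       C'_i = 1/2 + (‖x − Hb_i‖₁ − ‖x − MB_i‖₁) / (2 ‖Hb_i − MB_i‖₁),

   clamped to [0, 1].  If the feature x is an exact linear blend of point
   atlases, C' equals the blend fraction for every draw (the closure the
   acceptance suite checks on a 101-point grid).  A histogram filter keeps
   the most populated of 10 equal-width bins on [0, 1] (ties toward the
   lowest bin) and averages it; the per-frame scalars form a tensor that a
   median filter (0.64 mm × 0.70 mm × 30 frames, shrinking windows at
   borders) reduces to the final 2-D concentration map.  With 20 frames per
   trial the 30-frame kernel always spans the whole frame axis.

Evaluation uses the coefficient of determination about the 1:1 line
(R² = 1 − Σ(C_ki − k)² / Σ(C_ki − C̄)²), Spearman's ρ of the per-label mean
estimates (|ρ| ≥ 0.8 is treated as a strong monotonic trend) and the mean
absolute error in % concentration (overall MAE = equal-weight mean of the
per-label MAEs).

## Synthetic phantom

The simulator emulates the experiment the estimator targets: a 15-mm
circular chamber centered 20 mm from a 128-element, 0.3-mm-pitch linear
array, with the optical fiber tip at the chamber center.  Per shot pair,
`n_sources` point absorbers (160 by default, dense enough to mimic a liquid
absorber) are placed uniformly in the chamber disk; the same positions are
used for the 710- and 870-nm frames of the pair because the laser alternates
wavelengths between consecutive shots of the same medium, and positions are
redrawn between pairs (the stirred mixture decorrelates over time).

Each absorber receives fluence E·exp(−μ_eff r)/max(r, r₀)² from the fiber
tip with μ_eff(c, λ) = c·μ_MB(λ) + (1 − c)·μ_Hb(λ), and emits a
Gaussian-envelope pulse whose center frequency interpolates between the
class pulse models with weight c and scales as (μ_eff/μ̄)^0.2 — a stylized
version of the fluence-driven mechanism (stronger absorption excites a
smaller volume, hence a shorter, higher-frequency pulse).  Channel signals
sum the absorber pulses at exact one-way arrival times; per-shot laser
energy is Normal(3.13, 0.4) mJ truncated positive, and white noise is added
at 5% of the frame's peak amplitude.

The chromophore templates are synthetic, stylized values (not literature
absorption spectra): MB {710: 0.15, 870: 0.04} mm⁻¹ with pulse centers
{2.6, 2.1} MHz, Hb {710: 0.06, 870: 0.135} mm⁻¹ with {1.7, 2.4} MHz, both
with 0.6 fractional bandwidth.  They encode the qualitative physics — MB
dominates the 710-nm response, Hb the 870-nm response, pulse content in the
1–4 MHz band — that makes the atlas non-degenerate.

What the simulator does *not* model: acoustic attenuation and dispersion,
chamber-wall reverberation, MB staining of the chamber walls, oxygenation
variability of Hb, element directivity, and sub-aperture (64-channel)
acquisition stitching.  Passing tests therefore demonstrate the estimator's
correctness under its stated assumptions (linear mixing of class spectra,
coherent signal confined to the chamber), not its accuracy on tissue.

One consequence of the single-interpolated-pulse model: at intermediate c
the mean mixture spectrum is *not* bin-wise between the pure-class spectra
(its peak sits between the class peaks), so monotone recovery is carried by
the dual-wavelength amplitude ratio and the spectral shift jointly; the test
suite checks the monotone 710/870 energy ratio rather than bin-wise
betweenness.

## Problem sizes and numerical choices

* Default study: 11 fractions (0–100% MB in 10% steps) × 5 trials ×
  10 frames per wavelength at 40 MHz sampling.  The *scaled* study used by
  the acceptance checks (`scaled_study_config`) keeps the study design but
  runs 2 trials × 5 frames per wavelength at 12 MHz sampling, truncates the
  image grid just below the chamber (484 rows), strides feature extraction
  by 2 pixels and uses N = 300 atlas draws; a full pass takes a few minutes
  on one CPU.
* Image grid: axial rows at the RF-derived spacing c/(2 fs), lateral
  columns at the element pitch; nearest-sample one-way delays; index 0 at
  the transducer face.
* SLSC correlation kernel: one acoustic wavelength at the transducer center
  frequency (in image rows, minimum 4); negative correlations are kept in
  the lag sum; border windows shrink (zero contribution outside the image).
  A numba-compiled kernel computes the lag images; a pure-numpy reference
  implementation is kept and cross-checked in the tests.
* IQ low-pass: zero-phase FIR (firwin + filtfilt), ≤ 101 taps, cutoff
  0.85 × 2.75/2 MHz; no decimation.
* Histogram bins span [0, 1] fixed (C' is already clamped), making the
  lowest-bin tie-break reproducible; clamping precedes the histogram
  filter.  Degenerate atlas pairs are redrawn up to 100 times, then error.
* Median filter mm→pixels: nearest odd count, minimum 1.
* Randomness: a single master seed; per-trial and per-map generators are
  spawned via `numpy.random.SeedSequence`, so every artifact is bit-exactly
  reproducible from the manifest.

## Known limitations

* Sub-aperture acquisition, vendor file formats and GPU execution are out
  of scope; the container format is the package's own HDF5 layout.
* The estimator assumes both wavelengths are present in every trial and
  that frame k of one wavelength pairs with frame k of the other.
* With very high coherence thresholds masks can be empty; sweeps record
  such settings as absent rather than failing.
* Real MB/Hb molar absorption values are deliberately not claimed; users
  applying the pipeline to measured data supply their own acquisition and
  only the estimator configuration matters.
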