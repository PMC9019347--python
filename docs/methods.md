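# Methods

## Scope and model

`boomloc` studies azimuthal localization of extremely low-frequency bird
calls (Eurasian-bittern booming, ~100–150 Hz) with small circular
microphone arrays, entirely in simulation.  The model chain is

1. **Source synthesis** (`call_synth`): a booming phrase of enveloped
   low-frequency syllables in a 10-s clip.
2. **Free-field propagation** (`array_scene`): exact fractional delays
   and spherical spreading onto a planar 8-microphone array; diffuse
   ambient noise at a target SNR.
3. **Band-limited MUSIC** (`music_core`): STFT, per-bin time-averaged
   spatial covariance, eigendecomposition, noise-subspace spatial
   spectrum over an azimuth grid.
4. **Event tracking and scoring** (`tracking`): peaks → source events;
   duration-ratio accuracy, circular DOA histograms, temporal
   distributions.
5. **Experiment suite** (`experiments`): the radius × SNR × band grid,
   hybrid-array runs, window-span analysis, and the detectability
   metrics.

Everything is planar (azimuth only), anechoic and free-field: no
reverberation, ground/water reflection, or atmospheric absorption.
Those effects dominate real wetland recordings; this package isolates
the geometry/bandwidth question that can be answered at a desk.

## Synthetic booming source

Each syllable is a carrier at fundamental `f0` (default 125 Hz) whose
instantaneous frequency **glides downward** across the phrase band
(default excursion 30 Hz) with a slow noise-like wobble (std 12 Hz,
~10 Hz variation rate), plus a phase-locked 2nd harmonic at −12 dB and
an optional pink-noise "prelude" at −20 dB during the attack.  The
envelope has a 30 ms attack and 120 ms exponential decay.  A phrase is
6 syllables of 0.4 s separated by 1.0 s (all configurable); clips are
peak-normalized to 0.25 so the conventional +12 dB level boost applied
to quiet field sources stays within full scale.

The glide-plus-wobble structure matters and is the package's own
modeling choice: booming energy *fills* a band a few tens of Hz wide
rather than sitting on a spectral line.  A pure stationary tone keeps
perfect cross-microphone phase coherence at any aperture, which would
make arbitrarily large arrays look ideal; a source whose frequency
moves makes microphones separated by large propagation delays sample
visibly different instantaneous frequencies within one analysis window,
which is precisely the aperture-versus-window-span effect the study
exists to exhibit.  With the defaults, the instantaneous frequency
stays inside ~100–150 Hz and ≥90 % of clip energy lies below 300 Hz.

What the generator does **not** emulate: individually distinctive boom
structure, amplitude variation between syllables, "bad poor booms",
wind/vegetation noise with temporal structure, other singing species,
and echoes.  Passing tests therefore show that the *processing chain*
behaves as expected under controlled conditions, not that field
recordings of comparable SNR would score the same.

## Scene simulation

* Speed of sound is a configuration key (default 340 m/s), never
  hard-coded: published distance equivalences for the same setup imply
  values between ≈312 and ≈338 m/s, so `window_span_analysis` takes `c`
  explicitly.
* Fractional delays are applied as frequency-domain phase shifts on
  zero-padded blocks — exact to machine precision, no interpolation
  kernel to choose.
* "Diffuse" noise is spatially **independent** white Gaussian noise per
  channel, scaled so clip-averaged signal power over clip-averaged
  noise power hits the target SNR.  A truly isotropic field is coherent
  across a subwavelength array; independence is the neutral choice when
  no coherence model is stated, and it was verified to change the
  qualitative spatial findings little (the 180° spurious peak arises
  from array symmetry, not the noise model).
* The 16-bit/16 kHz rendering convention is honored by the WAV writer
  (16-bit PCM out; 16/24/32-bit PCM read).

## MUSIC implementation choices

* STFT: Hann window, 512 samples, 160-sample hop, frames taken without
  padding (`floor((N−512)/160)+1` frames; 997 for 10 s).  Bins are
  31.25 Hz wide; in 1-based labeling from the 0 Hz bin, the 50–250 Hz
  band is the 3rd–9th bin (62.5–250 Hz, seven bins).
* Covariance: mean of W = 50 consecutive outer products (500 ms),
  evaluated every PERIOD = 16 frames and held between evaluations.
* The spatial-spectrum denominator sums **magnitudes** of the
  noise-subspace projections (the formulation this pipeline
  reproduces); `squared=True` selects the textbook squared-magnitude
  form.  The magnitude form is basis-dependent when noise eigenvalues
  are nearly degenerate, which adds visible ripple — one reason spatial
  metrics smooth before peak detection (below).  A floor of 1e−12 on
  the denominator keeps P finite at perfect steering matches.
* Band aggregation is the arithmetic mean of per-bin P (`sum` and
  geometric mean available); the azimuth grid defaults to 5°
  (configurable to 1°), consistent with the 10° same-source gate.
* Steering vectors come in spherical (1/d amplitude, exact distances at
  the scene's source range) and planar far-field variants; spherical is
  the default throughout.

## Detectability metrics

* **Temporal detectability** is the ROC area of P(θ_true, f) against
  the syllable-activity indicator (frame center inside a syllable
  interval): 1.0 = peaks perfectly co-timed with calls, 0.5 =
  uninformative.  Syllable-level truth is used because inter-syllable
  gaps are genuinely silent.  The published analysis reports this only
  qualitatively; ROC area is this package's quantification and is
  swappable.
* **Spatial metrics** are computed at the "best" evaluation frame (the
  one maximizing band-aggregated P at the true azimuth; clip-specific
  frame indices are meaningless for synthetic clips).  Main-lobe width
  is the contiguous circular span above half the peak's prominence
  measured **on the decibel scale** — P spans orders of magnitude, and
  linear half-prominence resolves only the tip of the matched-steering
  cusp rather than the lobe a practitioner sees on a log axis.  The
  ghost is the largest local maximum outside ±30° of the main peak
  (ratio 0 if none); ±30° is wider than any observed low-frequency
  main-lobe half-width at r ≥ 10 cm.  Detection runs on a 3-point
  circular moving average because the genuine spurious structure is
  tens of degrees wide while estimation ripple is grid-scale.
* Stochastic conditions default to 10 replicate seeds; trend statements
  use medians.

## Findings the simulation does and does not reproduce

Reproduced under the default conditions (20 dB SNR, LF band):

* global MUSIC maximum at the true azimuth for all radii (and exact
  agreement with an independent delay-and-sum beamformer when
  noiseless);
* the spurious peak at 180° on the 10 cm array — the steering vector
  opposite the source is the antipodal *permutation* of the true one,
  and permutation barely changes a near-constant-phase vector, so small
  arrays cannot tell front from back;
* strictly narrowing main lobes with growing radius (23° → 15° → 10° →
  3° medians on a 1° grid);
* temporal detectability highest on the 10 cm array and lower on the
  10 m array, whose 20 m aperture (~941 samples of inter-microphone
  delay at 16 kHz) exceeds the 512-sample analysis window;
* narrowed-band (LF) temporal detectability above wideband on the
  10 cm array;
* DOA error at 0 dB SNR within one grid step of 20 dB for r ≥ 0.5 m.

Not reproduced: the monotone decrease of the *ghost-to-main-peak ratio*
across all four radii.  The 180° peak does shrink in absolute terms as
the array grows, but on large apertures the gliding source decoheres
and the main peak collapses faster, so the ratio rises at 10 m.  The
corresponding acceptance test is left failing rather than weakened; the
absolute ghost behavior and every other trend hold.  Field-scale results
(call counts, nightly activity distributions, 250 m detection range)
require the original recordings and are out of scope.

## Tracking conventions

* An event closes PAUSE_LENGTH after its **last** accepted peak (the
  published parameter description is ambiguous about the reference
  point).
* With NUM_SOURCE = 1, when two above-threshold peaks persist the
  stronger wins per frame; newcomers beyond the angular gate are
  dropped while a source is open.
* Circular means use the vector-sum definition; events enter temporal
  histograms by onset time.
* The duration-ratio accuracy is reported unclamped (values above 100 %
  indicate under-coverage); it is a coverage ratio, not a precision
  measure.

## Problem sizes

Default clips are 10 s, 8 channels, 16 kHz.  One LF condition runs in
~0.2 s and one WB condition in ~0.7 s on a single CPU; the full default
grid (4 radii × 3 SNRs × 2 bands × 10 replicates) completes in about
two minutes, and the acceptance script (two targets × 10 replicates) in
a few seconds.
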