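# boomloc

Localizing extremely low-frequency bird calls with small microphone
arrays.

The Eurasian bittern (*Botaurus stellaris*) is a secretive wetland bird
whose males advertise with "booming" — loud, monotonous phrases of a few
short syllables with nearly all their energy between roughly 100 and
150 Hz.  Because the boom's wavelength (~2.5 m) dwarfs any portable
microphone array, it is unclear how well standard subspace
direction-of-arrival (DOA) methods can localize it.  `boomloc` is a
desk-scale simulation laboratory for that question, aimed at
bioacousticians planning passive monitoring of low-frequency callers: it
synthesizes booming clips, renders them onto circular (or hybrid)
8-channel arrays in a free acoustic field, estimates DOA with a
band-limited MUSIC pipeline, tracks source events, and runs the array
radius × SNR × frequency-band detectability study.

## Method

For an M-microphone array with steering (transfer-function) vectors
H(θ, ω) and short-time spectra X(ω, f) (512-sample window, 160-sample
hop at 16 kHz → 257 bins of 31.25 Hz), the per-bin spatial covariance is
time-averaged over W = 50 frames (500 ms),

    R(ω, f) = (1/W) Σᵢ X(ω, f+i) X*(ω, f+i),

eigendecomposed as R = E Λ E⁻¹ with eigenvalues descending, and the
MUSIC spatial spectrum over an azimuth grid is

    P(θ, ω, f) = H*(θ,ω) H(θ,ω) / Σ_{i=Ns+1..M} |H*(θ,ω) eᵢ(ω,f)|,

with Ns = 1 assumed source and the denominator summing *magnitudes* of
the noise-subspace projections (a squared-magnitude toggle gives the
textbook form).  Localization restricts the bins to 50–250 Hz (LF, seven
bins from 62.5 to 250 Hz) or 50–2800 Hz (WB), aggregates P across bins,
finds per-frame peaks above a threshold, and strings peaks into source
events using an angular gate (MIN_SRC_INTERVAL = 10°) and a silence
timeout (PAUSE_LENGTH = 500 ms).  Localization accuracy follows the
field convention: annotated call duration divided by localized event
duration, as a percentage.

## Worked example

```python
import numpy as np
from boomloc import BoomSpec, SceneConfig, make_circular_array, run_condition

boom = BoomSpec()                       # 6 syllables, f0 = 125 Hz
scene = SceneConfig()                   # source at 0 deg, 30 m
for radius in (0.1, 1.0):
    geom = make_circular_array(radius, 8)
    m = run_condition(geom, snr_db=20.0, band="LF", boom=boom, scene=scene, seed=1)
    print(f"r = {radius:4.1f} m | DOA error {m['doa_error_deg']:4.1f} deg | "
          f"main lobe {m['main_lobe_width_deg']:5.1f} deg | "
          f"ghost at {m['ghost_azimuth_deg']:5.1f} deg (ratio {m['ghost_ratio']:.3f}) | "
          f"temporal AUC {m['temporal_auc']:.3f}")
```

prints

```
r =  0.1 m | DOA error  0.0 deg | main lobe  35.0 deg | ghost at 180.0 deg (ratio 0.057) | temporal AUC 0.964
r =  1.0 m | DOA error  0.0 deg | main lobe  15.0 deg | ghost at 180.0 deg (ratio 0.098) | temporal AUC 0.924
```

Both arrays put the global MUSIC maximum exactly at the true azimuth.
The 10 cm array shows the characteristic spurious peak diametrically
opposite the source at 180° — its steering vector there is the antipodal
permutation of the true one, which barely changes a vector whose
inter-microphone phases are tiny — and a wide main lobe; the 1 m array
resolves a narrower lobe.  The temporal AUC measures how well the
spectrum's power at the true azimuth tracks syllable timing (1.0 =
perfect co-timing); it is highest on the smallest array.

A command-line front end wraps the same library:

```
boomloc synth --out boom.wav --truth truth.csv
boomloc simulate --source boom.wav --radius 0.1 --azimuth 45 --snr-db 20 \
        --out scene.wav --config scene.yaml
boomloc localize --recording scene.wav --config scene.yaml --thresh 1 --out events.csv
boomloc grid --seed 0 --replicates 10 --out grid.csv
boomloc report --grid-csv grid.csv --plot trends.png
```

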