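# radarhrv

Non-contact heart-rate-variability (HRV) estimation from FMCW
millimeter-wave radar, end to end and fully simulatable: synthetic
chest-wall motion and raw radar cubes, 3D target localization, phase
demodulation, separation of the faint heartbeat from the much larger
respiratory motion, and time-domain HRV metrics.

## The problem

A 60 GHz FMCW radar pointed at a seated person sees the thoracic wall
vibrate with respiration (0.1–0.5 Hz, ~1–12 mm) and the heartbeat
(0.8–2.0 Hz, ~0.01–0.2 mm). Both displacements modulate the two-way
carrier phase of the de-chirped echo by 4πd/λc, so sub-millimetre motion
is visible in the phase of the range bin containing the subject. The
hard part is recovering beat-to-beat timing: the respiratory signal is
not sinusoidal, and its harmonics fall inside the heart band at
amplitudes comparable to the heartbeat itself, which is why a plain
band-pass filter fails.

## The method

1. **Localization** — moving-target-indication (MTI) differencing along
   slow time cancels static clutter; windowed range/Doppler FFTs and
   delay-and-sum beamforming on the horizontal and vertical subarrays
   give two range–angle energy maps, fused into a 3D volume
   `E3D[i,j,k] = Ehor[k,i]·Ever[k,j]`, thresholded at η·max and
   clustered with DBSCAN. Beam/range indices convert to Cartesian
   coordinates.
2. **Phase extraction** — per frame, the range FFT is beamformed toward
   the target cell, the complex sample's four-quadrant arctangent is
   unwrapped and mean-removed, giving y(t) = xb(t) + xh(t) + e(t).
3. **Separation** — a second-order spectral sparse separation algorithm
   with Lagrangian multipliers. Both components are quasi-periodic and
   hence low-rank in the eigenstructure of their Hankel (trajectory)
   covariances R = (1/K)·H(x)Hᵀ(x). The objective

   J = αb·Σ_{i>n} λb,i² + αh·Σ_{j>n} λh,j² + β‖d²y/dt² − xh‖² + γ‖y − xb − xh‖²

   is minimized under the constraints λi = (1/K)‖Hᵀ(x)ui‖², enforced by
   multipliers updated by gradient ascent; each iteration performs a
   closed-form eigenvalue update, a fresh eigendecomposition, a rank-n
   reconstruction by diagonal averaging, stationarity updates of both
   signals, and a multiplier step. The respiratory component is
   initialized by a harmonic-series fit at the estimated respiratory
   fundamental so that its in-band harmonics start (and stay) on the
   respiratory side.
4. **HRV** — beats are prominent peaks of the recovered cardiac signal
   (refined to sub-sample precision via the analytic-signal phase); the
   inter-beat-interval (IBI) series gives Mean IBI, RMSSD, SDRR and
   pNN50.

## Worked example

```python
import numpy as np
from radarhrv import (VitalSignParams, NoiseConfig, compose_displacement,
                      generate_ibi_sequence, separate, detect_beats,
                      ibi_series, hrv_report)

fs = 20.0                              # radar frame rate (Hz)
t = np.arange(int(60 * fs)) / fs       # 60 s of slow time
params = VitalSignParams()             # 4 mm respiration, 0.12 mm heartbeat, mean IBI 0.85 s
rng = np.random.default_rng(5)
ibis = generate_ibi_sequence(params.mean_ibi_s, 0.03, 75, rng)
trace = compose_displacement(params, ibis, NoiseConfig(snr_db=10.0), t, rng)

result = separate(trace.y, fs)         # respiration + heartbeat components
report = hrv_report(ibi_series(detect_beats(result.xh, fs)))
print(report.as_dict())
```

With the ground truth retained by the generator this prints (truth in
parentheses):

```
heartbeat correlation: 0.954
estimated mean IBI: 845.7 ms   (truth 845.6 ms)
estimated RMSSD:    26.7 ms   (truth 21.4 ms)
estimated SDRR:     19.6 ms   (truth 20.6 ms)
estimated pNN50:    2.9 %    (truth 0.0 %)
```

The mean IBI is recovered to a fraction of a millisecond even though the
heartbeat displacement is ~30× smaller than respiration and the
micro-motion noise is only 10 dB below the heartbeat.

The same chain runs from raw radar cubes via the CLI:

```bash
radarhrv run --config scenario.yaml --out out/          # full pipeline
radarhrv localize --cube out/cube.h5 --out targets.json
radarhrv extract --cube out/cube.h5 --targets targets.json --out phase.csv
radarhrv separate --phase phase.csv --out components.csv
radarhrv hrv --components components.csv --out hrv.json
```

`scenario.yaml` holds the physiological, radar, scene and algorithm
parameters (see `PipelineConfig.from_yaml`); every artifact embeds the
seed and a config hash, and runs are bit-reproducible per seed.

## Data layout

Radar cubes are HDF5 files: `/cube` (complex64, `[frame, chirp, rx,
sample]`), `/config` (radar attributes plus `rx_positions`), `/truth`
(`t, xb, xh, e, y, beat_times` when synthesized). Displacement traces
and phase/component series are plain CSV.

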