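# mfudsa

Multifrequency ultrafast Doppler spectral analysis for wall shear stress
quantification — a Python toolkit for researchers developing quantitative
Doppler ultrasound methods.

Cardiovascular disease announces itself mechanically before it does
anatomically: wall shear stress (WSS), the viscous drag of blood on the
endothelium, drops in vessels at risk of atherosclerosis long before a
stenosis forms. Measuring WSS with Doppler ultrasound demands better
velocity resolution and spectral SNR than conventional pulsed-wave (PW)
processing delivers. This package implements a two-dimensional
*multifrequency* spectral estimator that recovers both.

A transmitted burst of centre frequency `f_c` and bandwidth `BW` carries a
band of RF frequencies, each with its own Doppler shift
`f_d(f_RF) = (2 v cosθ / c)·f_RF`. Conventional 1-D processing superposes
these shifts unresolved; the 2-D estimator resolves the IQ data over
(RF frequency × Doppler frequency), rescales each RF column's Doppler axis
by `f_RF/f_c` so the ridge aligns across the band, and averages:

    P_MF(f_d) = ∫ P(f_RF, f_d·f_RF/f_c) df_RF / ∫ |U(f_RF − f_c)|² df_RF ,

integrated over `[f_c − BW/2, f_c + BW/2]`, with `|U|²` the pulse envelope
power spectrum and `Q = (f_c/BW)·ln 2` the narrowbandness index of each
pulse setting. The package provides:

* `synthio` — a seeded synthetic IQ simulator (speckle sliding through the
  range gate, exact Doppler ridge law, calibrated noise) with constant,
  linear-ramp, cosine and pulsatile ground-truth waveforms, plus vessel
  cross-sections with parabolic or plug profiles;
* `spectral` — the 2-D estimator, the matched 1-D Fourier baseline, and
  time–velocity sonograms with ridge extraction;
* `metrics` — spectral SNR, velocity-resolution FWHM, the 2-D/1-D ratio
  sweep over pulse lengths, and the Q factor;
* `wss` — gradient and parabolic (Poiseuille) wall-shear-stress estimators
  and paired comparisons between conditions;
* `io` / CLI — an open IQ container (`.iqz` + JSON sidecar), CSV reports,
  and a `mfudsa` command with `simulate / analyze / metrics / wss / run`
  subcommands driven by a single JSON config.

## Worked example

Simulate a 0.2 m/s flow (5 MHz, 4 half cycles, PRF 4 kHz, 20 dB SNR) and
compare the two estimators:

```python
from mfudsa import (AcquisitionSpec, PulseSpec, baseline_1d_spectrum,
                    constant_waveform, mfudsa_spectrum, q_factor,
                    simulate_gate)
from mfudsa.metrics import spectrum_quality

pulse = PulseSpec(fc=5e6, half_cycles=4)
acq = AcquisitionSpec(prf=4000.0, n_slow=2048, snr_db=20.0, seed=1)
iq = simulate_gate(constant_waveform(0.20), pulse, acq)

q2 = spectrum_quality(mfudsa_spectrum(iq))
q1 = spectrum_quality(baseline_1d_spectrum(iq))
print(f"2-D peak {q2.peak_v*100:5.2f} cm/s  FWHM {q2.fwhm_v*100:.2f} cm/s  SNR {q2.snr_linear:8.1f}")
print(f"1-D peak {q1.peak_v*100:5.2f} cm/s  FWHM {q1.fwhm_v*100:.2f} cm/s  SNR {q1.snr_linear:8.1f}")
print(f"R_SNR  = {q2.snr_linear/q1.snr_linear:.2f}")
print(f"R_FWHM = {q1.fwhm_v/q2.fwhm_v:.2f}")
```

prints

```
2-D peak 19.73 cm/s  FWHM 1.73 cm/s  SNR  10627.5
1-D peak 21.18 cm/s  FWHM 5.63 cm/s  SNR   1344.0
R_SNR  = 7.91
R_FWHM = 3.25
```

Both estimators locate the 20 cm/s target, but the multifrequency
realignment concentrates the energy that transit-time broadening smears in
the 1-D spectrum: here an ~8× SNR gain and a velocity peak three times
narrower. Downstream, per-gate peak velocities feed the WSS estimators:

```python
from mfudsa import VelocityProfile, wss_gradient, wss_parabolic
import numpy as np

R = 3e-3                          # vessel radius, m
r = np.array([0.7, 0.8, 0.9, 0.95]) * R
v = 0.5 * (1 - (r / R) ** 2)      # parabolic profile, V_max = 0.5 m/s
prof = VelocityProfile(r=r, v=v, R=R, mu=4e-3)
print(wss_gradient(prof, n_fit=3).wss)   # 1.162 Pa (secant fit at the wall)
print(wss_parabolic(0.5, 4e-3, R).wss)   # 1.333 Pa (Poiseuille)
```

From the shell, the same pipeline runs as

```sh
mfudsa simulate --waveform cosine --prf 7000 --n-slow 21000 --seed 1 --out cos.iqz
mfudsa analyze --in cos.iqz --out sonogram.csv
mfudsa metrics --grid 2,4,6,8 --n-seeds 45 --out report.csv
```

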