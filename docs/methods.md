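# Methods

## Problem setting

Pulsed-wave Doppler ultrasound estimates blood velocity from the slow-time
phase progression of complex baseband (IQ) echoes. A transmitted tone burst
of centre frequency `f_c` and bandwidth `BW` contains a whole band of RF
frequencies, and each one carries its own Doppler shift

    f_d(f_RF) = (2 v cosθ / c) · f_RF .

Conventional 1-D processing collapses the fast-time (depth) axis before the
Fourier analysis, so these shifts superpose unresolved and the velocity
spectrum is broadened in proportion to `BW`. The multifrequency 2-D
estimator implemented here keeps the fast-time axis, resolves the echo over
(RF frequency × Doppler frequency), rescales each RF column's Doppler axis
by `f_RF / f_c` so the ridge lines up across the band, and averages:

    P_MF(f_d) =  ∫ P(f_RF, f_d·f_RF/f_c) df_RF  /  ∫ |U(f_RF − f_c)|² df_RF ,

with both integrals over `[f_c − BW/2, f_c + BW/2]` and `|U|²` the power
spectrum of the pulse's complex envelope. The realignment concentrates the
signal that 1-D processing smears, raising the spectral SNR and narrowing
the velocity peak. A narrowbandness index `Q = (f_c / BW)·ln 2`
summarises each pulse setting; broader bands (low `Q`, short pulses) supply
more frequencies to average.

Wall shear stress (WSS) then follows from the radial velocity profile
`V(r)` measured gate by gate across a vessel: `WSS = −μ·dV/dr` at the wall
`r = R` (gradient method), or `WSS = 2 μ V_max / R` under the Poiseuille
assumption (parabolic method).

## Synthetic IQ model

`simulate_gate` synthesises one range gate (`n_fast` samples at `fs_fast`)
over `n_slow` pulse lines. The echo delay integrates the ground-truth
waveform line by line,

    τ(n) = τ0 − (2 cosθ / c) Σ_{m<n} v(m)/PRF ,

and is applied as an exact fractional delay together with the carrier phase
`exp(−i 2π f_c τ(n))`, so every RF component obeys the ridge law above by
construction. Two scatterer models share this kernel:

* **`speckle`** (default): a frozen, fully developed complex white
  reflectivity, convolved once with the pulse envelope, slides through the
  recorded gate as the flow displaces it. Scatterers genuinely enter and
  leave the gate; this transit is what broadens conventional 1-D Doppler,
  and it also means successive Welch segments see fresh speckle, so segment
  averaging smooths the fading raggedness exactly as in a real acquisition.
  The integer part of the displacement is applied by indexing and the
  fractional part by an FFT phase ramp on a padded window, so the delay is
  exact to machine precision.
* **`single`**: a lone reflector treated circularly in the gate (a delay is
  a pure phase ramp in the gate's DFT domain). Every RF column is then an
  exact Doppler tone — convenient wherever tests want bit-exact ridges
  (ridge-slope fits, the narrowband limit).

Complex circular Gaussian noise is added after synthesis to a prescribed
`snr_db` relative to the mean signal power over the gate (`None` disables
noise); a realised-SNR check holds to within 1 dB for records of a thousand
lines or more. Everything is driven by one `numpy` generator seeded from
the acquisition spec, so identical specs give bit-identical data.

The pulse is sampled on mid-bin instants so a rectangular burst of duration
`T = half_cycles/(2 f_c)` occupies exactly `round(T·fs_fast)` samples; its
discrete spectrum then has its first null at `1/T` and the measured FWHM
bandwidth halves when the pulse length doubles, matching the closed-form
Fourier pairs used as test oracles.

## Processing chain and numerical choices

`mfudsa_spectrum` runs: Welch segmentation (Bartlett window, default
`win_slow = 128` lines, 75 % overlap) → Bartlett windowing of **both** gate
axes (both DFT axes suffer truncation sidelobes; the slow-only variant is a
flag) → 2-D DFT onto physical axes (Parseval is preserved exactly) → a
Doppler-axis low-pass that removes content near the PRF edge
(`cutoff_frac = 0.9` of Nyquist, raised-cosine taper over the top 10 % of
the passband, interior untouched; applied before scaling, matching the
stage order of the processing diagram) → spectral scaling and averaging.

The scaling step evaluates each RF column at `f_d·f_RF/f_c` by linear
interpolation (zero outside support) and integrates over the measured FWHM
bandwidth of the pulse with the trapezoidal rule, normalised by the
trapezoidal integral of `|U|²`. Linear interpolation plus trapezoids is
the simplest scheme whose error vanishes under grid refinement; it is
validated by the collapse property (the realigned spectrum is never wider
than the unscaled RF marginal, and strictly narrower for `BW/f_c > 0.2`).
If the band is narrower than one RF bin the column nearest `f_c` is used
directly, which makes the 2-D estimator degenerate smoothly into the 1-D
one (they agree to within 5 % in that limit).

The **1-D baseline** is the equivalent architecture without the fast-time
dimension: coherent summation over a range gate, Bartlett windowing of the
resulting slow-time series, Welch-averaged periodograms. The gate defaults
to **one transmitted pulse length, centred in the ROI** — the textbook PW
Doppler sample volume. This choice matters: integrating the whole recorded
line would average away the transit-time fluctuation and produce an
unrealistically clean 1-D spectrum, making the comparison meaningless. A
`gate_len` override exists for algebraic checks.

Sonograms tile the record with the same sliding windows and place one
velocity spectrum per segment at the segment's centre time; the ridge is
the per-frame argmax velocity. Velocities map through
`v = c·f_d/(2 f_c cosθ)` with positive velocity toward the transducer;
aliased content wraps into `(−v_nyq, +v_nyq]` and is never unwrapped.

Metric definitions (the source material uses both quantities without
defining them):

* **SNR**: peak power divided by the mean power over all bins farther than
  three signal half-widths from the peak, the half-width defaulting to half
  the measured FWHM. Robust, estimator-agnostic and monotone in true SNR.
* **FWHM**: width at half of (peak − floor) with sub-bin linear
  interpolation on both flanks; the floor is the median power so a raised
  noise floor does not inflate the width. Flat spectra and peaks whose
  half level is never crossed raise `NoPeakError`; the ratio sweep drops
  and counts such replicates and aborts beyond 50 % failures.

## Default parameters

| parameter | default | units | rationale |
|---|---|---|---|
| `fc` | 5e6 | Hz | transmit frequency of the reference acquisitions |
| `half_cycles` | 4 | — | the selected optimum pulse length |
| `fs_fast` | 20e6 | Hz | 4·fc, the minimum that resolves the pulse band |
| `n_fast` | 64 | samples | 3.2 µs gate ≈ 2.5 mm, a small-vessel lumen |
| `prf` | 4000 | Hz | string-phantom acquisition rate |
| `snr_db` | 20 | dB | typical research-mode IQ quality; config-exposed |
| `win_slow` / overlap | 128 / 0.75 | lines / — | ~30 ms frames, standard spectral-Doppler Welch settings |
| `cutoff_frac` | 0.9 | — | PRF-edge suppression with minimal passband loss |
| `mu` | 4.0e-3 | Pa·s | blood / blood-mimicking-fluid viscosity |
| `n_fit` | 3 | gates | nearest-wall secant fit; no no-slip point imposed |
| pulsatile peak / period | 0.45 / 0.5 | m/s / s | umbilical-like waveform, fetal heart-rate range |

The ratio sweep uses 45 replicate seeds per setting and a constant
0.2 m/s target — the centre of the ±20 cm/s ramp range — at beam angle 0.

## What the simulator does and does not emulate

It reproduces: the multifrequency ridge across the transmitted band,
transit-time (bandwidth) broadening of 1-D processing, fully developed
speckle with Rayleigh fading refreshed by flow, slow-time aliasing at the
PRF, additive receiver noise, and radially sampled vessel profiles.

It omits: beamforming and diffraction, depth attenuation, wall clutter and
clutter filtering, transducer element response, non-axial motion and
spectral broadening from beam geometry. Consequences worth knowing:

* The 2-D/1-D SNR gain at short pulse lengths is larger here than on a
  physical scanner (tens rather than ~8), because nothing limits the
  usable bandwidth at 2 half cycles — a real transducer's finite response
  and the hydrophone-measured bandwidth do. At the 4-half-cycle operating
  point the simulated gain (~7–8×) sits inside the physically observed
  range.
* The resolution ratio R_FWHM decreases monotonically with pulse length in
  this model (broadening scales with bandwidth), so the interior optimum
  at 4 half cycles seen on hardware — where long pulses also degrade the
  2-D path — does not occur. Passing tests therefore show the realignment
  mechanism works, not that the hardware optimum is reproduced.
* WSS magnitudes depend on the chosen vessel/flow parameters, not on
  recovered phantom physics; only the estimator identities (gradient vs
  parabolic agreement, blunting monotonicity, linearity) are meaningful.

## Other design decisions

* Ties between equal spectral maxima break toward the lower frequency;
  the FWHM span is the widest contiguous half-power region of the global
  peak.
* The Doppler axis convention is `(−prf/2, +prf/2]` (the even-length DFT's
  −Nyquist bin is reported at +Nyquist).
* The IQ container is deliberately minimal: raw little-endian complex
  matrix + JSON sidecar with a format version, so scanner exports can be
  converted with a few lines of any language. Proprietary formats are out
  of scope.
* Pipeline outputs contain no timestamps; a run is a pure function of
  (config, seed), and the provenance record stores the config hash.
* The paired t-test uses `scipy.stats.ttest_rel`; all-zero differences
  return `t = 0, p = 1`, constant nonzero differences are rejected as
  degenerate rather than reported as infinite.

## Problem sizes

The bundled experiments are sized for a single CPU: the 45-seed × 4-setting
sweep uses 2048-line records (≈10 s), the ramp and cosine recoveries use
the full 15,000- and 21,000-line records (≈2 s each), and the whole test
suite runs in well under a minute.
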