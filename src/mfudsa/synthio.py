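"""Synthetic pulsed-Doppler IQ data generation.

This module produces complex baseband (IQ) datasets with known ground-truth
velocity waveforms, for exercising and benchmarking the multifrequency 2-D
spectral estimator and the conventional 1-D baseline.

Signal model
------------
A single transmitted tone burst of centre frequency ``fc`` and duration
``half_cycles / (2 fc)`` is scattered by targets moving along the beam at
velocity ``v(t)``.  After demodulation at ``fc`` the echo recorded in one
range gate (``n_fast`` samples at ``fs_fast``) on slow-time line ``n`` is

    s(t_f, n) = a(t_f - tau(n)) * exp(-i 2 pi fc tau(n)) + noise,

with round-trip delay ``tau(n) = tau0 - (2 cos(theta) / c) * sum_{m<n} v(m)/prf``.
The delay is applied exactly (integer part by indexing, fractional part by
an FFT phase ramp), so every fast-frequency column of the 2-D spectrum
carries a Doppler ridge at exactly

    f_d(f_RF) = (2 v cos(theta) / c) * f_RF,

the multifrequency law the 2-D estimator exploits.

Two scatterer models are available: ``"speckle"`` (default) convolves the
envelope with a long frozen random reflectivity that the flow slides
through the recorded gate, emulating blood-mimicking fluid with targets
entering and leaving the sample volume; ``"single"`` is a lone reflector
treated circularly in the gate, useful when bit-exact ridges are wanted in
tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

__all__ = [
    "PulseSpec",
    "AcquisitionSpec",
    "VelocityWaveform",
    "IQDataset",
    "VesselSpec",
    "constant_waveform",
    "linear_waveform",
    "cosine_waveform",
    "pulsatile_waveform",
    "make_pulse",
    "envelope_function",
    "pulse_power_spectrum",
    "measure_fwhm_bandwidth",
    "simulate_gate",
    "simulate_vessel",
]

SPEED_OF_SOUND = 1540.0  # m/s, soft-tissue convention

_ENVELOPES = ("rectangular", "bartlett", "gaussian")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PulseSpec:
    """Transmitted tone-burst description.

    Parameters
    ----------
    fc : float
        Centre transmit frequency in Hz.
    half_cycles : int
        Pulse length in transducer half cycles; duration is
        ``half_cycles / (2 fc)``.
    envelope : {"rectangular", "bartlett", "gaussian"}
        Envelope shape of the burst.
    fs_fast : float
        Fast-time sampling rate in Hz; must be at least ``4 fc`` so the
        pulse spectrum is resolvable in the gate.
    """

    fc: float
    half_cycles: int = 4
    envelope: str = "rectangular"
    fs_fast: float = 20e6

    def __post_init__(self) -> None:
        if self.fc <= 0:
            raise ValueError("fc must be positive")
        if int(self.half_cycles) != self.half_cycles or self.half_cycles < 1:
            raise ValueError("half_cycles must be an integer >= 1")
        if self.envelope not in _ENVELOPES:
            raise ValueError(f"envelope must be one of {_ENVELOPES}")
        if self.fs_fast < 4 * self.fc:
            raise ValueError("fs_fast must be >= 4*fc")

    @property
    def duration(self) -> float:
        """Pulse duration in seconds: half_cycles / (2 fc)."""
        return self.half_cycles / (2.0 * self.fc)


@dataclass(frozen=True)
class AcquisitionSpec:
    """Slow-time acquisition parameters.

    ``snr_db`` is the additive complex-white-Gaussian noise level relative
    to the mean signal power over the gate; ``None`` disables noise.
    """

    prf: float
    n_slow: int
    n_fast: int = 64
    theta: float = 0.0
    c: float = SPEED_OF_SOUND
    snr_db: float | None = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.prf <= 0:
            raise ValueError("prf must be positive")
        if self.n_slow < 2:
            raise ValueError("n_slow must be >= 2")
        if self.n_fast < 2:
            raise ValueError("n_fast must be >= 2")
        if not (0 <= self.theta < math.pi / 2):
            raise ValueError("theta must lie in [0, pi/2)")
        if self.c <= 0:
            raise ValueError("c must be positive")


@dataclass(frozen=True)
class VelocityWaveform:
    """Ground-truth axial velocity as a function of slow time.

    ``kind`` selects the parametric family; use the factory helpers
    (:func:`constant_waveform` etc.) rather than building params by hand.
    """

    kind: Literal["constant", "linear", "cosine", "pulsatile"]
    params: dict = field(default_factory=dict)

    def sample(self, n_slow: int, prf: float) -> np.ndarray:
        """Velocities (m/s) at the ``n_slow`` pulse-line times ``n / prf``."""
        n = np.arange(n_slow, dtype=float)
        t = n / prf
        p = self.params
        if self.kind == "constant":
            v = np.full(n_slow, float(p["v_const"]))
        elif self.kind == "linear":
            frac = n / max(n_slow - 1, 1)
            v = p["v_start"] + (p["v_end"] - p["v_start"]) * frac
        elif self.kind == "cosine":
            v = p["v_peak"] * np.cos(2 * np.pi * t / p["period"])
        elif self.kind == "pulsatile":
            v = p["v_peak"] * _umbilical_template(t / p["period"])
        else:  # pragma: no cover - guarded by dataclass literal
            raise ValueError(f"unknown waveform kind {self.kind!r}")
        if not np.all(np.isfinite(v)):
            raise ValueError("waveform produced non-finite velocities")
        return v

    def peak_velocity(self) -> float:
        p = self.params
        return {
            "constant": lambda: abs(p["v_const"]),
            "linear": lambda: max(abs(p["v_start"]), abs(p["v_end"])),
            "cosine": lambda: abs(p["v_peak"]),
            "pulsatile": lambda: abs(p["v_peak"]),
        }[self.kind]()


def constant_waveform(v: float) -> VelocityWaveform:
    return VelocityWaveform("constant", {"v_const": float(v)})


def linear_waveform(v_start: float, v_end: float) -> VelocityWaveform:
    """Velocity ramping affinely from ``v_start`` (first line) to ``v_end`` (last)."""
    return VelocityWaveform("linear", {"v_start": float(v_start), "v_end": float(v_end)})


def cosine_waveform(v_peak: float, period: float = 1.0) -> VelocityWaveform:
    """Zero-mean cosine of amplitude ``v_peak`` (m/s) and ``period`` (s)."""
    if period <= 0:
        raise ValueError("period must be positive")
    return VelocityWaveform("cosine", {"v_peak": float(v_peak), "period": float(period)})


def pulsatile_waveform(v_peak: float = 0.45, period: float = 0.5) -> VelocityWaveform:
    """Paediatric-umbilical-like pulsatile waveform, peak ``v_peak`` m/s.

    A three-harmonic template (systolic spike with forward diastolic flow),
    rescaled so its maximum equals ``v_peak``.  Default peak 0.45 m/s,
    period 0.5 s (~120 bpm, fetal range).
    """
    if period <= 0:
        raise ValueError("period must be positive")
    return VelocityWaveform("pulsatile", {"v_peak": float(v_peak), "period": float(period)})


_TEMPLATE_NORM: float | None = None


def _umbilical_template(phase: np.ndarray) -> np.ndarray:
    """Unit-peak 3-harmonic pulsatile template evaluated at cycle ``phase``."""
    global _TEMPLATE_NORM
    x = 2 * np.pi * np.asarray(phase, dtype=float)

    def raw(xx: np.ndarray) -> np.ndarray:
        return (0.55
                + 0.35 * np.cos(xx - 0.6)
                + 0.16 * np.cos(2 * xx - 1.7)
                + 0.06 * np.cos(3 * xx - 2.9))

    if _TEMPLATE_NORM is None:
        grid = 2 * np.pi * np.linspace(0.0, 1.0, 4096, endpoint=False)
        _TEMPLATE_NORM = float(np.max(raw(grid)))
    return raw(x) / _TEMPLATE_NORM


@dataclass(frozen=True)
class IQDataset:
    """Complex baseband data matrix ``[fast-time sample, slow-time pulse]``."""

    data: np.ndarray
    pulse: PulseSpec
    acq: AcquisitionSpec
    truth: VelocityWaveform | None = None

    def __post_init__(self) -> None:
        d = np.asarray(self.data)
        if d.shape != (self.acq.n_fast, self.acq.n_slow):
            raise ValueError(
                f"data shape {d.shape} != (n_fast, n_slow) = "
                f"({self.acq.n_fast}, {self.acq.n_slow})")
        if not np.all(np.isfinite(d)):
            raise ValueError("data contains non-finite entries")

    @property
    def n_fast(self) -> int:
        return self.acq.n_fast

    @property
    def n_slow(self) -> int:
        return self.acq.n_slow


@dataclass(frozen=True)
class VesselSpec:
    """Radially sampled vessel with a known cross-sectional velocity profile."""

    R: float
    gate_radii: tuple
    profile: Literal["parabolic", "plug"] = "parabolic"
    v_max: float = 0.5

    def __post_init__(self) -> None:
        if self.R <= 0:
            raise ValueError("R must be positive")
        r = np.asarray(self.gate_radii, dtype=float)
        if r.ndim != 1 or len(r) < 1:
            raise ValueError("gate_radii must be a non-empty 1-D sequence")
        if np.any(r < 0) or np.any(r >= self.R):
            raise ValueError("gate radii must satisfy 0 <= r < R")
        if np.any(np.diff(r) <= 0):
            raise ValueError("gate radii must be strictly increasing")
        if self.profile not in ("parabolic", "plug"):
            raise ValueError("profile must be 'parabolic' or 'plug'")

    @property
    def n_gates(self) -> int:
        return len(self.gate_radii)

    def velocity_at(self, r: float) -> float:
        """Profile velocity at radius ``r``: Poiseuille or plug flow."""
        if self.profile == "parabolic":
            return self.v_max * (1.0 - (r / self.R) ** 2)
        return self.v_max


# ---------------------------------------------------------------------------
# pulse synthesis and bandwidth measurement
# ---------------------------------------------------------------------------

def envelope_function(pulse: PulseSpec):
    """Return the continuous unit-peak complex envelope ``a(t)`` on [0, T]."""
    T = pulse.duration

    def a(t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        inside = (t >= 0) & (t <= T)
        if pulse.envelope == "rectangular":
            env = inside.astype(float)
        elif pulse.envelope == "bartlett":
            env = np.where(inside, 1.0 - np.abs(2.0 * t / T - 1.0), 0.0)
        else:  # gaussian, truncated at +-3 sigma
            sigma = T / 6.0
            env = np.where(inside, np.exp(-0.5 * ((t - T / 2) / sigma) ** 2), 0.0)
        return env.astype(complex)

    return a


def make_pulse(pulse: PulseSpec) -> np.ndarray:
    """Sampled complex baseband envelope of the tone burst, unit peak magnitude.

    The burst spans ``[0, T]`` with ``T = half_cycles / (2 fc)``; it is
    sampled at ``fs_fast`` on the ``round(T * fs_fast)`` mid-bin instants
    ``(k + 1/2) / fs_fast`` so the sampled support is exactly ``T`` (one
    sample period per sample) and the discrete spectrum of a rectangular
    burst has its first null at ``1/T``.
    """
    T = pulse.duration
    n = int(round(T * pulse.fs_fast))
    if n < 2:
        raise ValueError("pulse too short for fs_fast")
    t = (np.arange(n) + 0.5) / pulse.fs_fast
    env = envelope_function(pulse)(t)
    peak = np.max(np.abs(env))
    if peak == 0:
        raise ValueError("degenerate envelope")
    return env / peak


def pulse_power_spectrum(
    envelope: np.ndarray, fs_fast: float, df_max: float = 10e3
) -> tuple[np.ndarray, np.ndarray]:
    """Power spectral density ``|U(f - fc)|^2`` of the complex envelope.

    Zero-pads so the bin spacing is at most ``df_max`` (default 10 kHz).
    Returns ``(freq_offsets, power)`` with frequencies centred on 0 (i.e.
    offsets from the carrier) and strictly increasing.
    """
    env = np.asarray(envelope, dtype=complex)
    if env.size == 0:
        raise ValueError("empty envelope")
    nfft = max(len(env), int(math.ceil(fs_fast / df_max)))
    spec = np.fft.fftshift(np.fft.fft(env, n=nfft))
    freqs = np.fft.fftshift(np.fft.fftfreq(nfft, d=1.0 / fs_fast))
    return freqs, np.abs(spec) ** 2


def measure_fwhm_bandwidth(freqs: np.ndarray, power: np.ndarray) -> float:
    """Full width at half maximum of a single-peaked power spectrum, in Hz.

    The half-power crossings are located with sub-bin linear interpolation
    around the widest contiguous half-power span containing the global peak;
    ties between equal maxima break toward the lower frequency.
    """
    freqs = np.asarray(freqs, dtype=float)
    power = np.asarray(power, dtype=float)
    if freqs.shape != power.shape or freqs.ndim != 1:
        raise ValueError("freqs and power must be matching 1-D arrays")
    peak = float(np.max(power))
    if peak <= 0 or np.min(power) == peak:
        raise ValueError("no spectral peak (flat or all-zero spectrum)")
    ipk = int(np.argmax(power))  # argmax returns the first (lowest-f) maximum
    half = peak / 2.0

    left = _cross_below(freqs, power, ipk, half, step=-1)
    right = _cross_below(freqs, power, ipk, half, step=+1)
    return right - left


def _cross_below(freqs, power, ipk, level, step):
    """Interpolated frequency where power first drops below ``level``."""
    i = ipk
    while 0 <= i + step < len(power) and power[i + step] >= level:
        i += step
    j = i + step
    if j < 0 or j >= len(power):
        raise ValueError("half-power level never crossed inside the spectrum")
    # linear interpolation between samples i (>= level) and j (< level)
    f = freqs[i] + (freqs[j] - freqs[i]) * (power[i] - level) / (power[i] - power[j])
    return float(f)


# ---------------------------------------------------------------------------
# IQ simulation
# ---------------------------------------------------------------------------

def simulate_gate(
    waveform: VelocityWaveform,
    pulse: PulseSpec,
    acq: AcquisitionSpec,
    scatterers: Literal["speckle", "single"] = "speckle",
) -> IQDataset:
    """Simulate the IQ record of one range gate insonated by a tone burst.

    The echo delay integrates the waveform velocity line by line,
    ``tau(n) = tau0 - (2 cos(theta)/c) * sum_{m<n} v(m)/prf``, and is applied
    as an exact circular fractional delay in the gate's fast-time DFT domain
    together with the carrier phase ``exp(-i 2 pi fc tau)``.  With
    ``scatterers="speckle"`` the envelope excites a frozen unit-variance
    complex white reflectivity filling the gate; with ``"single"`` it is a
    lone reflector initially centred in the gate.

    Complex circular Gaussian noise is added to achieve ``acq.snr_db``
    relative to the mean signal power over the gate; the generator is fully
    determined by ``acq.seed``.
    """
    fs, fc, c = pulse.fs_fast, pulse.fc, acq.c
    n_fast, n_slow = acq.n_fast, acq.n_slow
    v = waveform.sample(n_slow, acq.prf)

    v_alias = fs * c / (4.0 * fc)
    if np.max(np.abs(v)) * 2 * fc / c >= fs / 2:
        raise ValueError(
            f"fast-time aliasing: |v| must stay below {v_alias:.3f} m/s "
            f"for fs_fast = {fs:g}")

    env = make_pulse(pulse)
    if len(env) > n_fast:
        raise ValueError("pulse longer than the fast-time gate (increase n_fast)")

    rng = np.random.default_rng(acq.seed)

    # accumulated axial displacement (m) before each line; delta(0) = 0
    disp = np.concatenate(([0.0], np.cumsum(v[:-1]))) / acq.prf
    dtau = (2.0 * math.cos(acq.theta) / c) * disp  # tau0 - tau(n)

    if scatterers == "single":
        data = _synth_single(env, dtau, n_fast, n_slow, fs, fc)
    elif scatterers == "speckle":
        data = _synth_speckle(env, dtau, n_fast, n_slow, fs, fc, rng)
    else:
        raise ValueError("scatterers must be 'speckle' or 'single'")

    if acq.snr_db is not None:
        p_sig = float(np.mean(np.abs(data) ** 2))
        sigma = math.sqrt(p_sig * 10.0 ** (-acq.snr_db / 10.0) / 2.0)
        noise = sigma * (rng.standard_normal(data.shape)
                         + 1j * rng.standard_normal(data.shape))
        data = data + noise

    return IQDataset(data=data, pulse=pulse, acq=acq, truth=waveform)


def _synth_single(env, dtau, n_fast, n_slow, fs, fc):
    """Lone reflector, circular in the gate: exact closed-form synthesis.

    A delay is an exact phase ramp in the gate's DFT domain, so every RF
    column of the 2-D spectrum is a pure Doppler tone on the multifrequency
    ridge - useful where bit-exact ridges are wanted.
    """
    buf = np.zeros(n_fast, dtype=complex)
    start = (n_fast - len(env)) // 2  # echo centred in the gate at n = 0
    buf[start:start + len(env)] = env
    A = np.fft.fft(buf)
    f = np.fft.fftfreq(n_fast, d=1.0 / fs)
    data = np.empty((n_fast, n_slow), dtype=complex)
    chunk = max(1, int(2e6 / n_fast))
    for s in range(0, n_slow, chunk):
        ramp = np.exp(2j * np.pi * np.outer(f + fc, dtau[s:s + chunk]))
        data[:, s:s + chunk] = np.fft.ifft(A[:, None] * ramp, axis=0)
    return data


_FRAC_MARGIN = 32  # gate offset inside the fractional-delay window


def _synth_speckle(env, dtau, n_fast, n_slow, fs, fc, rng):
    """Frozen scatterer field sliding through the gate.

    A long white complex reflectivity is convolved once with the pulse
    envelope; each slow-time line reads the gate-sized window of the field
    displaced by the accumulated delay (integer part by indexing, fractional
    part by an exact FFT phase ramp) and carries the carrier phase
    ``exp(2 pi i fc dtau)``.  Scatterers thus genuinely enter and leave the
    gate - the transit effect that broadens conventional 1-D Doppler - and
    each Welch segment sees fresh speckle once the flow has displaced the
    field by a gate length.
    """
    shift = dtau * fs  # field displacement in fast-time samples, signed
    k = np.floor(shift).astype(int)
    frac = shift - k
    kmin, kmax = int(k.min()), int(k.max())

    W = 1 << max(7, (n_fast + 2 * _FRAC_MARGIN - 1).bit_length())
    L = (kmax - kmin) + W + len(env)
    refl = (rng.standard_normal(L) + 1j * rng.standard_normal(L)) / math.sqrt(2.0)
    nfft = 1 << int(np.ceil(np.log2(L + len(env))))
    field = np.fft.ifft(np.fft.fft(refl, nfft) * np.fft.fft(env, nfft))[:L]

    base = k - kmin
    idx = base[None, :] + np.arange(W)[:, None]
    chunks = np.fft.fft(field[idx], axis=0)
    nu = np.fft.fftfreq(W)
    chunks *= np.exp(2j * np.pi * nu[:, None] * frac[None, :])
    lines = np.fft.ifft(chunks, axis=0)[_FRAC_MARGIN:_FRAC_MARGIN + n_fast, :]
    return lines * np.exp(2j * np.pi * fc * dtau)[None, :]


def simulate_vessel(
    vessel: VesselSpec,
    pulse: PulseSpec,
    acq: AcquisitionSpec,
    waveform: VelocityWaveform | None = None,
    scatterers: Literal["speckle", "single"] = "speckle",
) -> list[IQDataset]:
    """One IQ dataset per radial range gate of a vessel cross-section.

    Gate ``j`` at radius ``r_j`` carries the profile velocity
    ``v_j = profile(r_j)`` - constant by default, or ``waveform`` rescaled so
    its peak equals ``v_j``.  Gate seeds are offset from ``acq.seed`` so the
    gates are statistically independent.
    """
    datasets = []
    for j, r in enumerate(vessel.gate_radii):
        v_j = vessel.velocity_at(float(r))
        if waveform is None:
            wf = constant_waveform(v_j)
        else:
            pk = waveform.peak_velocity()
            if pk == 0:
                raise ValueError("waveform peak velocity is zero; cannot rescale")
            wf = _rescale_waveform(waveform, v_j / pk)
        acq_j = replace(acq, seed=acq.seed + j)
        datasets.append(simulate_gate(wf, pulse, acq_j, scatterers=scatterers))
    return datasets


def _rescale_waveform(wf: VelocityWaveform, factor: float) -> VelocityWaveform:
    p = dict(wf.params)
    for key in ("v_const", "v_start", "v_end", "v_peak"):
        if key in p:
            p[key] = p[key] * factor
    return VelocityWaveform(wf.kind, p)
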