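"""The multifrequency 2-D Doppler spectral estimator and the 1-D baseline.

Processing chain (2-D path): the IQ record is cut into overlapping slow-time
segments, Bartlett-windowed along both gate axes, transformed with a 2-D DFT
into (RF frequency, Doppler frequency) space, low-pass masked near the PRF
edge, then *spectrally scaled and averaged*: each RF column's Doppler axis is
rescaled by ``f_RF / f_c`` so the Doppler ridge, which obeys
``f_d = (2 v cos(theta) / c) f_RF``, lines up across the transmitted band,
and the columns are integrated over ``[fc - BW/2, fc + BW/2]`` with the
pulse's own power spectrum as normaliser:

    P_MF(f_d) = int P(f_RF, f_d f_RF / fc) df_RF / int |U(f_RF - fc)|^2 df_RF

The 1-D baseline applies the equivalent architecture without the fast-time
dimension: coherent summation over a conventional pulse-length range gate,
Bartlett windowing of the resulting slow-time series, and Welch-averaged
periodograms.  Both estimators share the velocity mapping
``v = c f_d / (2 fc cos(theta))``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator, Literal

import numpy as np

from .synthio import (
    IQDataset,
    make_pulse,
    measure_fwhm_bandwidth,
    pulse_power_spectrum,
)

__all__ = [
    "WindowSpec",
    "Spectrum2D",
    "VelocitySpectrum",
    "Sonogram",
    "segment_pulse_lines",
    "apply_bartlett",
    "fft2d",
    "lowpass_prf",
    "spectral_scale_average",
    "doppler_to_velocity",
    "velocity_to_doppler",
    "nyquist_velocity",
    "mfudsa_spectrum",
    "baseline_1d_spectrum",
    "build_sonogram",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WindowSpec:
    """Slow-time segmentation: window length, fractional overlap, Bartlett family."""

    win_slow: int = 128
    overlap_frac: float = 0.75

    def __post_init__(self) -> None:
        if self.win_slow < 2:
            raise ValueError("win_slow must be >= 2")
        if not (0 <= self.overlap_frac < 1):
            raise ValueError("overlap_frac must lie in [0, 1)")

    @property
    def hop(self) -> int:
        return max(1, int(round(self.win_slow * (1.0 - self.overlap_frac))))

    def n_segments(self, n_slow: int) -> int:
        if self.win_slow > n_slow:
            raise ValueError("win_slow exceeds the number of slow-time lines")
        return (n_slow - self.win_slow) // self.hop + 1


@dataclass(frozen=True)
class Spectrum2D:
    """Power over (RF frequency, Doppler frequency); the object Eq.-style
    spectral averaging consumes."""

    power: np.ndarray  # [rf bin, doppler bin], >= 0
    f_rf_axis: np.ndarray  # absolute RF frequencies, Hz
    f_d_axis: np.ndarray  # Doppler frequencies in (-prf/2, +prf/2], Hz
    fc: float
    prf: float

    def __post_init__(self) -> None:
        p = np.asarray(self.power)
        if p.shape != (len(self.f_rf_axis), len(self.f_d_axis)):
            raise ValueError("power shape does not match axes")
        if np.any(np.diff(self.f_rf_axis) <= 0) or np.any(np.diff(self.f_d_axis) <= 0):
            raise ValueError("axes must be strictly increasing")
        if not np.all(np.isfinite(p)) or np.any(p < 0):
            raise ValueError("power must be finite and non-negative")


@dataclass(frozen=True)
class VelocitySpectrum:
    """1-D power versus velocity; output of both estimators."""

    power: np.ndarray
    f_d_axis: np.ndarray  # Doppler frequency referenced to fc, Hz
    v_axis: np.ndarray  # m/s
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (len(self.power) == len(self.f_d_axis) == len(self.v_axis)):
            raise ValueError("power and axes must have equal length")
        dv = np.diff(self.v_axis)
        if not (np.all(dv > 0) or np.all(dv < 0)):
            raise ValueError("v_axis must be monotone")

    @property
    def dv(self) -> float:
        """Velocity bin width (m/s)."""
        return float(abs(self.v_axis[1] - self.v_axis[0]))

    def peak_velocity(self) -> float:
        return float(self.v_axis[int(np.argmax(self.power))])


@dataclass(frozen=True)
class Sonogram:
    """Time-velocity power map assembled from sliding-window spectra."""

    power: np.ndarray  # [velocity bin, time frame]
    t_axis: np.ndarray  # frame centre times, s
    v_axis: np.ndarray  # m/s
    window: WindowSpec
    method: str = "mfudsa"

    def __post_init__(self) -> None:
        if self.power.shape != (len(self.v_axis), len(self.t_axis)):
            raise ValueError("power shape does not match axes")
        if np.any(self.power < 0):
            raise ValueError("power must be non-negative")

    def ridge(self) -> np.ndarray:
        """Per-frame argmax velocity trace (m/s)."""
        return self.v_axis[np.argmax(self.power, axis=0)]


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _resolve_roi(iq_or_nfast, roi) -> tuple[int, int]:
    n_fast = iq_or_nfast if isinstance(iq_or_nfast, int) else iq_or_nfast.n_fast
    if roi is None:
        return 0, n_fast
    a, b = int(roi[0]), int(roi[1])
    if not (0 <= a < b <= n_fast):
        raise ValueError(f"roi {roi} outside fast-time range [0, {n_fast})")
    return a, b


def segment_pulse_lines(
    iq: IQDataset, roi: tuple[int, int] | None, win: WindowSpec
) -> Iterator[np.ndarray]:
    """Yield the roi rows of consecutive ``win_slow``-line windows.

    Hop is ``win_slow * (1 - overlap_frac)`` rounded (minimum 1); the number
    of segments is ``floor((n_slow - win_slow) / hop) + 1``.
    """
    a, b = _resolve_roi(iq, roi)
    n_seg = win.n_segments(iq.n_slow)
    for k in range(n_seg):
        s = k * win.hop
        yield iq.data[a:b, s:s + win.win_slow]


def apply_bartlett(segment: np.ndarray, axes: tuple[int, ...] = (0, 1)) -> np.ndarray:
    """Multiply a segment by triangular (Bartlett) windows along ``axes``.

    Default windows both the fast-time and slow-time axes, suppressing
    truncation sidelobes on both DFT axes.
    """
    seg = np.asarray(segment)
    if seg.size == 0:
        raise ValueError("empty segment")
    out = seg.astype(complex, copy=True)
    for ax in axes:
        w = np.bartlett(seg.shape[ax])
        shape = [1] * seg.ndim
        shape[ax] = seg.shape[ax]
        out = out * w.reshape(shape)
    return out


def fft2d(segment: np.ndarray, fs_fast: float, prf: float, fc: float) -> Spectrum2D:
    """2-D DFT power of a windowed segment on physical frequency axes.

    Fast-time bins are mapped to absolute RF frequencies about ``fc``;
    slow-time bins to Doppler frequencies in ``(-prf/2, +prf/2]``.  Total
    power satisfies Parseval: ``sum(power) / (n_rf n_d) == sum |segment|^2``.
    """
    seg = np.asarray(segment, dtype=complex)
    if seg.ndim != 2 or seg.shape[0] < 2 or seg.shape[1] < 2:
        raise ValueError("segment must have at least 2 rows and 2 columns")
    nf, ns = seg.shape
    power = np.abs(np.fft.fft2(seg)) ** 2
    power = np.fft.fftshift(power, axes=(0, 1))
    f_rf = fc + np.fft.fftshift(np.fft.fftfreq(nf, d=1.0 / fs_fast))
    f_d = np.fft.fftshift(np.fft.fftfreq(ns, d=1.0 / prf))
    if ns % 2 == 0:  # move the -Nyquist bin to +prf/2 so f_d in (-prf/2, prf/2]
        power = np.roll(power, -1, axis=1)
        f_d = np.append(f_d[1:], prf / 2.0)
    return Spectrum2D(power=power, f_rf_axis=f_rf, f_d_axis=f_d, fc=fc, prf=prf)


def lowpass_prf(spec: Spectrum2D, cutoff_frac: float = 0.9) -> Spectrum2D:
    """Suppress Doppler content near the pulse-repetition-frequency edge.

    Components with ``|f_d| > cutoff_frac * prf/2`` are zeroed; a raised
    cosine tapers the top 10% of the passband; the passband interior is
    untouched.
    """
    if not (0 < cutoff_frac <= 1):
        raise ValueError("cutoff_frac must lie in (0, 1]")
    edge = cutoff_frac * spec.prf / 2.0
    knee = 0.9 * edge
    fd = np.abs(spec.f_d_axis)
    mask = np.ones_like(fd)
    taper = (fd > knee) & (fd <= edge)
    mask[taper] = 0.5 * (1 + np.cos(np.pi * (fd[taper] - knee) / (edge - knee)))
    mask[fd > edge] = 0.0
    return Spectrum2D(power=spec.power * mask[None, :], f_rf_axis=spec.f_rf_axis,
                      f_d_axis=spec.f_d_axis, fc=spec.fc, prf=spec.prf)


def spectral_scale_average(
    spec: Spectrum2D,
    fc: float,
    bw: float,
    u_power: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Multifrequency spectral scaling and averaging over the pulse band.

    For each output Doppler frequency ``f_d`` (referenced to ``fc``) the RF
    column at ``f_RF`` is sampled at ``f_d * f_RF / fc`` by linear
    interpolation (zero outside support), integrated over
    ``f_RF in [fc - bw/2, fc + bw/2]`` with the trapezoidal rule, and
    normalised by the trapezoidal integral of ``u_power`` (the pulse power
    spectrum ``|U(f_RF - fc)|^2``; uniform if omitted) over the same limits.

    Returns ``(f_d_axis, power)`` on the input Doppler bin grid.
    """
    if bw <= 0:
        raise ValueError("bw must be positive")
    lo, hi = fc - bw / 2.0, fc + bw / 2.0
    f_rf = spec.f_rf_axis
    if lo < f_rf[0] or hi > f_rf[-1]:
        raise ValueError("bandwidth limits exceed the RF axis span")
    band = (f_rf >= lo) & (f_rf <= hi)
    if np.count_nonzero(band) == 0:  # narrower than one RF bin: nearest column
        band = np.zeros(len(f_rf), dtype=bool)
        band[int(np.argmin(np.abs(f_rf - fc)))] = True
    F = f_rf[band]
    cols = spec.power[band, :]
    if u_power is None:
        u_band = np.ones(len(F))
    else:
        u_power = np.asarray(u_power, dtype=float)
        if u_power.shape != f_rf.shape:
            raise ValueError("u_power must be aligned with f_rf_axis")
        u_band = u_power[band]

    fd_out = spec.f_d_axis
    sampled = np.empty((len(F), len(fd_out)))
    for i, (Fi, col) in enumerate(zip(F, cols)):
        sampled[i] = np.interp(fd_out * (Fi / fc), spec.f_d_axis, col,
                               left=0.0, right=0.0)
    if len(F) == 1:  # degenerate band: plain ratio instead of trapezoids
        num = sampled[0]
        den = float(u_band[0])
    else:
        num = np.trapezoid(sampled, x=F, axis=0)
        den = float(np.trapezoid(u_band, x=F))
    if den <= 0:
        raise ValueError("non-positive spectral normaliser")
    return fd_out, num / den


def doppler_to_velocity(f_d, fc: float, c: float, theta: float = 0.0):
    """Axial velocity from Doppler shift: ``v = c f_d / (2 fc cos(theta))``."""
    cos = math.cos(theta)
    if cos <= 1e-12:  # theta at (or numerically at) a right angle
        raise ValueError("beam angle must satisfy cos(theta) > 0")
    return c * np.asarray(f_d, dtype=float) / (2.0 * fc * cos)


def velocity_to_doppler(v, fc: float, c: float, theta: float = 0.0):
    """Doppler shift of velocity ``v`` at RF ``fc``: ``f_d = 2 v fc cos(theta)/c``."""
    return 2.0 * np.asarray(v, dtype=float) * fc * math.cos(theta) / c


def nyquist_velocity(prf: float, fc: float, c: float, theta: float = 0.0) -> float:
    """Largest unaliased velocity magnitude: ``c prf / (4 fc cos(theta))``."""
    return float(doppler_to_velocity(prf / 2.0, fc, c, theta))


# ---------------------------------------------------------------------------
# estimator pipelines
# ---------------------------------------------------------------------------

def _pulse_band(iq: IQDataset) -> tuple[float, np.ndarray, np.ndarray]:
    """Measured FWHM bandwidth and power spectrum of the dataset's pulse."""
    env = make_pulse(iq.pulse)
    f_off, psd = pulse_power_spectrum(env, iq.pulse.fs_fast)
    bw = measure_fwhm_bandwidth(f_off, psd)
    return bw, f_off, psd


def _mfudsa_segment(seg, iq, bw, u_interp, cutoff_frac, window_axes):
    seg = apply_bartlett(seg, axes=window_axes)
    spec = fft2d(seg, iq.pulse.fs_fast, iq.acq.prf, iq.pulse.fc)
    spec = lowpass_prf(spec, cutoff_frac)
    u_power = u_interp(spec.f_rf_axis - iq.pulse.fc)
    fd, p = spectral_scale_average(spec, iq.pulse.fc, bw, u_power)
    return fd, p


def mfudsa_spectrum(
    iq: IQDataset,
    roi: tuple[int, int] | None = None,
    win: WindowSpec | None = None,
    cutoff_frac: float = 0.9,
    window_axes: tuple[int, ...] = (0, 1),
) -> VelocitySpectrum:
    """Velocity spectrum by the 2-D multifrequency estimator.

    Composition: segmentation -> Bartlett (both axes) -> 2-D DFT -> PRF
    low-pass -> spectral scaling/averaging over the measured pulse FWHM
    bandwidth, Welch-averaged over segments.
    """
    win = _default_win(iq, win)
    bw, f_off, psd = _pulse_band(iq)
    u_interp = lambda f: np.interp(f, f_off, psd, left=0.0, right=0.0)

    acc = None
    fd = None
    for seg in segment_pulse_lines(iq, roi, win):
        fd, p = _mfudsa_segment(seg, iq, bw, u_interp, cutoff_frac, window_axes)
        acc = p if acc is None else acc + p
    n_seg = win.n_segments(iq.n_slow)
    power = acc / n_seg
    v = doppler_to_velocity(fd, iq.pulse.fc, iq.acq.c, iq.acq.theta)
    meta = {"method": "mfudsa", "fc": iq.pulse.fc, "bw": bw, "prf": iq.acq.prf,
            "win_slow": win.win_slow, "n_segments": n_seg,
            "c": iq.acq.c, "theta": iq.acq.theta}
    return VelocitySpectrum(power=power, f_d_axis=fd, v_axis=v, meta=meta)


def _default_win(iq: IQDataset, win: WindowSpec | None) -> WindowSpec:
    if win is not None:
        return win
    return WindowSpec(win_slow=min(128, iq.n_slow), overlap_frac=0.75)


def _default_gate(iq: IQDataset, roi: tuple[int, int] | None,
                  gate_len: int | None) -> tuple[int, int]:
    """Conventional PW Doppler sample volume: one pulse length, centred in the roi."""
    a, b = _resolve_roi(iq, roi)
    if gate_len is None:
        gate_len = int(round(iq.pulse.duration * iq.pulse.fs_fast))
    gate_len = max(1, min(gate_len, b - a))
    mid = (a + b) // 2
    g0 = max(a, mid - gate_len // 2)
    return g0, min(b, g0 + gate_len)


def baseline_1d_spectrum(
    iq: IQDataset,
    roi: tuple[int, int] | None = None,
    win: WindowSpec | None = None,
    gate_len: int | None = None,
) -> VelocitySpectrum:
    """Conventional 1-D spectral Doppler with the equivalent architecture.

    Fast-time samples of a range gate inside the roi are summed coherently
    (range-gate integration; the gate defaults to one transmitted pulse
    length - the standard PW Doppler sample volume), the slow-time series is
    Bartlett-windowed per segment, and periodograms are Welch-averaged.  The
    velocity axis is referenced to the carrier ``fc``.
    """
    win = _default_win(iq, win)
    g0, g1 = _default_gate(iq, roi, gate_len)
    y = iq.data[g0:g1, :].sum(axis=0)

    n_seg = win.n_segments(iq.n_slow)
    w = np.bartlett(win.win_slow)
    acc = np.zeros(win.win_slow)
    for k in range(n_seg):
        s = k * win.hop
        acc += np.abs(np.fft.fft(w * y[s:s + win.win_slow])) ** 2
    power = np.fft.fftshift(acc / n_seg)
    fd = np.fft.fftshift(np.fft.fftfreq(win.win_slow, d=1.0 / iq.acq.prf))
    if win.win_slow % 2 == 0:
        power = np.roll(power, -1)
        fd = np.append(fd[1:], iq.acq.prf / 2.0)
    v = doppler_to_velocity(fd, iq.pulse.fc, iq.acq.c, iq.acq.theta)
    meta = {"method": "baseline_1d", "fc": iq.pulse.fc, "prf": iq.acq.prf,
            "win_slow": win.win_slow, "n_segments": n_seg,
            "gate": (g0, g1), "c": iq.acq.c, "theta": iq.acq.theta}
    return VelocitySpectrum(power=power, f_d_axis=fd, v_axis=v, meta=meta)


def build_sonogram(
    iq: IQDataset,
    win: WindowSpec | None = None,
    method: Literal["mfudsa", "baseline"] = "mfudsa",
    roi: tuple[int, int] | None = None,
    cutoff_frac: float = 0.9,
) -> Sonogram:
    """Time-velocity sonogram: one velocity spectrum per sliding window.

    Each segment's spectrum is placed at the segment's centre time; the
    ridge trace is available as per-frame argmax velocity
    (:meth:`Sonogram.ridge`).
    """
    win = _default_win(iq, win)
    n_seg = win.n_segments(iq.n_slow)

    if method == "mfudsa":
        bw, f_off, psd = _pulse_band(iq)
        u_interp = lambda f: np.interp(f, f_off, psd, left=0.0, right=0.0)
        frames = []
        fd = None  # axis identical for every frame
        for seg in segment_pulse_lines(iq, roi, win):
            fd, p = _mfudsa_segment(seg, iq, bw, u_interp, cutoff_frac, (0, 1))
            frames.append(p)
    elif method == "baseline":
        g0, g1 = _default_gate(iq, roi, None)
        y = iq.data[g0:g1, :].sum(axis=0)
        w = np.bartlett(win.win_slow)
        frames = []
        for k in range(n_seg):
            s = k * win.hop
            frames.append(np.fft.fftshift(
                np.abs(np.fft.fft(w * y[s:s + win.win_slow])) ** 2))
        fd = np.fft.fftshift(np.fft.fftfreq(win.win_slow, d=1.0 / iq.acq.prf))
        if win.win_slow % 2 == 0:
            frames = [np.roll(f, -1) for f in frames]
            fd = np.append(fd[1:], iq.acq.prf / 2.0)
    else:
        raise ValueError("method must be 'mfudsa' or 'baseline'")

    power = np.stack(frames, axis=1)
    centres = (np.arange(n_seg) * win.hop + (win.win_slow - 1) / 2.0) / iq.acq.prf
    v = doppler_to_velocity(fd, iq.pulse.fc, iq.acq.c, iq.acq.theta)
    return Sonogram(power=power, t_axis=centres, v_axis=np.asarray(v),
                    window=win, method=method)
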