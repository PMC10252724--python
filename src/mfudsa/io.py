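"""Container I/O, run configuration and the end-to-end pipeline.

The open IQ container is a raw little-endian complex matrix (``.iqz``,
row-major, fast-time x slow-time) with a JSON metadata sidecar carrying the
pulse/acquisition parameters, the ground-truth waveform and a format-version
string.  Reports are RFC-4180 CSV with a mandatory header row.  A pipeline
run is fully determined by its :class:`RunConfig` plus seed; identical
configs produce byte-identical outputs (timestamps appear only in logging).
"""

from __future__ import annotations

import csv
import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .metrics import ratio_experiment
from .spectral import Sonogram, VelocitySpectrum, WindowSpec, build_sonogram, \
    mfudsa_spectrum
from .synthio import (
    AcquisitionSpec,
    IQDataset,
    PulseSpec,
    VelocityWaveform,
    VesselSpec,
    simulate_gate,
    simulate_vessel,
)
from .wss import DEFAULT_VISCOSITY, profile_from_gates, wss_gradient, wss_parabolic

__all__ = [
    "FORMAT_VERSION",
    "IQContainerError",
    "MetadataError",
    "ShapeMismatchError",
    "FormatVersionError",
    "write_iq_container",
    "read_iq_container",
    "write_velocity_spectrum_csv",
    "write_sonogram_csv",
    "save_sonogram_png",
    "RunConfig",
    "run_pipeline",
]

log = logging.getLogger("mfudsa")

FORMAT_VERSION = "1.0"
_DTYPES = {"complex64": "<c8", "complex128": "<c16"}


class IQContainerError(ValueError):
    """Base error for the IQ container format."""


class MetadataError(IQContainerError):
    """Sidecar is missing or malformed."""


class ShapeMismatchError(IQContainerError):
    """Matrix size disagrees with the declared shape/dtype."""


class FormatVersionError(IQContainerError):
    """Unsupported container format version."""


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_iq_container(ds: IQDataset, path, dtype: str = "complex128") -> Path:
    """Write ``<path>.iqz`` (raw little-endian matrix) plus ``<path>.json``."""
    if dtype not in _DTYPES:
        raise IQContainerError(f"dtype must be one of {sorted(_DTYPES)}")
    path = Path(path).with_suffix(".iqz")
    np.ascontiguousarray(ds.data).astype(_DTYPES[dtype]).tofile(path)
    meta = {
        "format_version": FORMAT_VERSION,
        "dtype": dtype,
        "n_fast": ds.acq.n_fast,
        "n_slow": ds.acq.n_slow,
        "fc_hz": ds.pulse.fc,
        "fs_fast_hz": ds.pulse.fs_fast,
        "prf_hz": ds.acq.prf,
        "theta_rad": ds.acq.theta,
        "c_ms": ds.acq.c,
        "half_cycles": ds.pulse.half_cycles,
        "envelope": ds.pulse.envelope,
        "snr_db": ds.acq.snr_db,
        "seed": ds.acq.seed,
        "truth_waveform": (
            {"kind": ds.truth.kind, "params": ds.truth.params}
            if ds.truth is not None else None),
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1, sort_keys=True))
    return path


_REQUIRED_KEYS = ("format_version", "dtype", "n_fast", "n_slow", "fc_hz",
                  "fs_fast_hz", "prf_hz", "theta_rad", "c_ms", "half_cycles",
                  "envelope")


def read_iq_container(path) -> IQDataset:
    """Read and validate an ``.iqz`` + JSON sidecar pair."""
    path = Path(path).with_suffix(".iqz")
    side = _sidecar_path(path)
    if not path.exists() or not side.exists():
        raise MetadataError(f"container requires both {path.name} and {side.name}")
    try:
        meta = json.loads(side.read_text())
    except json.JSONDecodeError as e:
        raise MetadataError(f"sidecar is not valid JSON: {e}") from e
    for key in _REQUIRED_KEYS:
        if key not in meta:
            raise MetadataError(f"sidecar missing required key {key!r}")
    if meta["format_version"] != FORMAT_VERSION:
        raise FormatVersionError(
            f"unsupported format version {meta['format_version']!r} "
            f"(expected {FORMAT_VERSION!r})")
    if meta["dtype"] not in _DTYPES:
        raise MetadataError(f"unsupported dtype {meta['dtype']!r}")
    raw = np.fromfile(path, dtype=_DTYPES[meta["dtype"]])
    n_fast, n_slow = int(meta["n_fast"]), int(meta["n_slow"])
    if raw.size != n_fast * n_slow:
        raise ShapeMismatchError(
            f"matrix holds {raw.size} samples, sidecar declares "
            f"{n_fast} x {n_slow} = {n_fast * n_slow}")
    data = raw.reshape(n_fast, n_slow).astype(complex)
    pulse = PulseSpec(fc=meta["fc_hz"], half_cycles=int(meta["half_cycles"]),
                      envelope=meta["envelope"], fs_fast=meta["fs_fast_hz"])
    acq = AcquisitionSpec(prf=meta["prf_hz"], n_slow=n_slow, n_fast=n_fast,
                          theta=meta["theta_rad"], c=meta["c_ms"],
                          snr_db=meta.get("snr_db"), seed=int(meta.get("seed", 0)))
    truth = None
    tw = meta.get("truth_waveform")
    if tw is not None:
        truth = VelocityWaveform(tw["kind"], dict(tw["params"]))
    return IQDataset(data=data, pulse=pulse, acq=acq, truth=truth)


# ---------------------------------------------------------------------------
# CSV / image export
# ---------------------------------------------------------------------------

def write_velocity_spectrum_csv(vs: VelocitySpectrum, path) -> Path:
    path = Path(path)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["v_ms", "f_d_hz", "power"])
        for v, f, p in zip(vs.v_axis, vs.f_d_axis, vs.power):
            w.writerow([repr(float(v)), repr(float(f)), repr(float(p))])
    meta_path = path.with_suffix(".meta.json")
    meta_path.write_text(json.dumps(vs.meta, indent=1, sort_keys=True, default=str))
    return path


def write_sonogram_csv(sono: Sonogram, path) -> Path:
    """Velocity bins as rows, frames as columns headed by their centre times."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["v_ms"] + [repr(float(t)) for t in sono.t_axis])
        for i, v in enumerate(sono.v_axis):
            w.writerow([repr(float(v))] + [repr(float(p)) for p in sono.power[i]])
    return path


def save_sonogram_png(sono: Sonogram, path, db_range: float = 40.0) -> Path:
    """Optional image export (requires matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    p = sono.power / max(sono.power.max(), 1e-300)
    img = 10 * np.log10(np.maximum(p, 10 ** (-db_range / 10)))
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.imshow(img, aspect="auto", origin="lower", cmap="gray",
              extent=[sono.t_axis[0], sono.t_axis[-1],
                      sono.v_axis[0] * 100, sono.v_axis[-1] * 100])
    ax.set_xlabel("time (s)")
    ax.set_ylabel("velocity (cm/s)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

def _from_dict(cls, d: dict):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(d) - names
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    return cls(**d)


@dataclass(frozen=True)
class SimulateConfig:
    waveform: str = "constant"
    waveform_params: dict = field(default_factory=lambda: {"v_const": 0.2})
    fc_hz: float = 5e6
    half_cycles: int = 4
    envelope: str = "rectangular"
    fs_fast_hz: float = 20e6
    prf_hz: float = 4000.0
    n_slow: int = 2000
    n_fast: int = 64
    theta_rad: float = 0.0
    c_ms: float = 1540.0
    snr_db: float | None = 20.0
    scatterers: str = "speckle"


@dataclass(frozen=True)
class AnalyzeConfig:
    method: str = "mfudsa"
    win_slow: int = 128
    overlap_frac: float = 0.75
    cutoff_frac: float = 0.9
    roi: tuple | None = None


@dataclass(frozen=True)
class MetricsConfig:
    grid: tuple = (2, 4, 6, 8)
    n_seeds: int = 45
    v_const: float = 0.2


@dataclass(frozen=True)
class WSSConfig:
    R_m: float = 3e-3
    mu_pas: float = DEFAULT_VISCOSITY
    gate_radii_frac: tuple = (0.0, 0.2, 0.4, 0.6, 0.8, 0.85, 0.9, 0.95)
    v_max_ms: float = 0.5
    profile: str = "parabolic"
    n_fit: int = 3
    position: str = "10 mm distal to the vessel curvature"


@dataclass(frozen=True)
class RunConfig:
    """Everything a reproducible run needs, serialisable as one JSON document."""

    seed: int = 0
    outdir: str = "mfudsa_run"
    simulate: SimulateConfig | None = field(default_factory=SimulateConfig)
    analyze: AnalyzeConfig | None = field(default_factory=AnalyzeConfig)
    metrics: MetricsConfig | None = None
    wss: WSSConfig | None = None

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - names
        if unknown:
            raise ValueError(f"unknown RunConfig keys: {sorted(unknown)}")
        sub = {"simulate": SimulateConfig, "analyze": AnalyzeConfig,
               "metrics": MetricsConfig, "wss": WSSConfig}
        kw = {}
        for k, v in d.items():
            if k in sub and v is not None:
                kw[k] = _from_dict(sub[k], dict(v))
            else:
                kw[k] = v
        return cls(**kw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k in ("simulate", "analyze", "metrics", "wss"):
            if d[k] is not None:
                for kk, vv in list(d[k].items()):
                    if isinstance(vv, tuple):
                        d[k][kk] = list(vv)
        return d

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        return cls.from_dict(json.loads(text))

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=1, sort_keys=True)


def _build_waveform(sim: SimulateConfig) -> VelocityWaveform:
    return VelocityWaveform(sim.waveform, dict(sim.waveform_params))


def _build_specs(sim: SimulateConfig, seed: int):
    pulse = PulseSpec(fc=sim.fc_hz, half_cycles=sim.half_cycles,
                      envelope=sim.envelope, fs_fast=sim.fs_fast_hz)
    acq = AcquisitionSpec(prf=sim.prf_hz, n_slow=sim.n_slow, n_fast=sim.n_fast,
                          theta=sim.theta_rad, c=sim.c_ms, snr_db=sim.snr_db,
                          seed=seed)
    return pulse, acq


def run_pipeline(config: RunConfig, outdir=None) -> dict:
    """Execute the configured stages in order; returns paths of the outputs.

    Stage order: simulate -> analyze -> metrics -> wss.  Each stage logs its
    parameters; failures abort with a stage-named diagnostic.  A provenance
    record (config hash, seed, versions) is always written.
    """
    out = Path(outdir if outdir is not None else config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    produced: dict = {}

    iq = None
    if config.simulate is not None:
        sim = config.simulate
        log.info("simulate: %s", sim)
        try:
            pulse, acq = _build_specs(sim, config.seed)
            iq = simulate_gate(_build_waveform(sim), pulse, acq,
                               scatterers=sim.scatterers)
            produced["container"] = str(write_iq_container(iq, out / "simulated.iqz"))
        except Exception as e:
            raise RuntimeError(f"simulate stage failed: {e}") from e

    if config.analyze is not None:
        an = config.analyze
        log.info("analyze: %s", an)
        try:
            if iq is None:
                iq = read_iq_container(out / "simulated.iqz")
            win = WindowSpec(min(an.win_slow, iq.n_slow), an.overlap_frac)
            roi = tuple(an.roi) if an.roi is not None else None
            sono = build_sonogram(iq, win=win, method=an.method, roi=roi,
                                  cutoff_frac=an.cutoff_frac)
            produced["sonogram"] = str(write_sonogram_csv(sono, out / "sonogram.csv"))
        except Exception as e:
            raise RuntimeError(f"analyze stage failed: {e}") from e

    if config.metrics is not None:
        me = config.metrics
        log.info("metrics: %s", me)
        try:
            sim = config.simulate or SimulateConfig()
            pulse, acq = _build_specs(sim, config.seed)
            from .synthio import constant_waveform
            rows = ratio_experiment(constant_waveform(me.v_const), me.grid,
                                    pulse, acq, n_seeds=me.n_seeds)
            path = out / "metrics.csv"
            with path.open("w", newline="") as fh:
                w = csv.writer(fh)
                w.writerow(["half_cycles", "Q", "R_SNR_mean", "R_SNR_sd",
                            "R_FWHM_mean", "R_FWHM_sd", "n_seeds", "n_failed"])
                for r in rows:
                    w.writerow([r.half_cycles, repr(r.q), repr(r.r_snr),
                                repr(r.r_snr_sd), repr(r.r_fwhm),
                                repr(r.r_fwhm_sd), r.n_seeds, r.n_failed])
            produced["metrics"] = str(path)
        except Exception as e:
            raise RuntimeError(f"metrics stage failed: {e}") from e

    if config.wss is not None:
        ws = config.wss
        log.info("wss: %s", ws)
        try:
            sim = config.simulate or SimulateConfig()
            pulse, acq = _build_specs(sim, config.seed)
            radii = tuple(f * ws.R_m for f in ws.gate_radii_frac)
            vessel = VesselSpec(R=ws.R_m, gate_radii=radii,
                                profile=ws.profile, v_max=ws.v_max_ms)
            gates = simulate_vessel(vessel, pulse, acq)
            spectra = [mfudsa_spectrum(g) for g in gates]
            prof = profile_from_gates(spectra, radii, ws.R_m, ws.mu_pas)
            grad = wss_gradient(prof, n_fit=ws.n_fit, position=ws.position)
            para = wss_parabolic(max(prof.v), ws.mu_pas, ws.R_m,
                                 position=ws.position)
            path = out / "wss.csv"
            with path.open("w", newline="") as fh:
                w = csv.writer(fh)
                w.writerow(["station", "method", "wss_pa", "shear_rate_inv_s"])
                for res in (grad, para):
                    w.writerow([res.position, res.method, repr(res.wss),
                                repr(res.shear_rate)])
            produced["wss"] = str(path)
        except Exception as e:
            raise RuntimeError(f"wss stage failed: {e}") from e

    cfg_json = config.to_json()
    provenance = {
        "config": config.to_dict(),
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "seed": config.seed,
        "mfudsa_version": __version__,
        "numpy_version": np.__version__,
    }
    (out / "provenance.json").write_text(
        json.dumps(provenance, indent=1, sort_keys=True))
    produced["provenance"] = str(out / "provenance.json")
    return produced
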