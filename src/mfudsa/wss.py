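"""Wall shear stress estimation from radial velocity profiles.

Wall shear stress (WSS) is the viscous drag per unit area exerted by flowing
blood on the vessel wall,

    WSS = -mu * dV/dr |_{r = R},

with ``mu`` the dynamic viscosity, ``V(r)`` the axial velocity profile and
``R`` the lumen radius.  Two estimators are provided:

* the *gradient* method - a least-squares line through the outermost range
  gates, extrapolated to the wall (no zero-velocity wall point is imposed,
  since measurements exist only inside the lumen); and
* the *parabolic* method - Poiseuille's law with an assumed parabolic
  profile, ``WSS = 2 mu V_max / R``, needing only the centreline velocity.

Paired comparisons between acquisition conditions use a two-sided paired
t-test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .metrics import NoPeakError, fwhm_of_spectrum
from .spectral import VelocitySpectrum

__all__ = [
    "VelocityProfile",
    "WSSResult",
    "PairedTestResult",
    "DEFAULT_VISCOSITY",
    "profile_from_gates",
    "wall_shear_rate",
    "wss_gradient",
    "wss_parabolic",
    "compare_conditions",
]

#: Dynamic viscosity default, Pa s - typical for blood / blood-mimicking fluid.
DEFAULT_VISCOSITY = 4.0e-3


@dataclass(frozen=True)
class VelocityProfile:
    """Radial velocity samples across a vessel lumen."""

    r: np.ndarray  # gate radii, m, strictly increasing in [0, R)
    v: np.ndarray  # velocity per gate, m/s
    R: float  # vessel radius, m
    mu: float = DEFAULT_VISCOSITY

    def __post_init__(self) -> None:
        r = np.asarray(self.r, dtype=float)
        v = np.asarray(self.v, dtype=float)
        if len(r) != len(v) or len(r) < 3:
            raise ValueError("need at least 3 gates with matching radii/velocities")
        if np.any(r < 0) or np.any(r >= self.R):
            raise ValueError("radii must satisfy 0 <= r < R")
        if np.any(np.diff(r) <= 0):
            raise ValueError("radii must be strictly increasing")
        if self.mu <= 0:
            raise ValueError("viscosity must be positive")


@dataclass(frozen=True)
class WSSResult:
    """Wall shear stress estimate (Pa) with its provenance."""

    wss: float
    method: str  # "gradient" or "parabolic"
    shear_rate: float  # wall shear rate, 1/s
    position: str = ""  # longitudinal station label


@dataclass(frozen=True)
class PairedTestResult:
    t: float
    dof: int
    p: float
    mean_difference: float


def profile_from_gates(
    gate_spectra: Sequence[VelocitySpectrum],
    radii,
    R: float,
    mu: float = DEFAULT_VISCOSITY,
) -> VelocityProfile:
    """Velocity profile from per-gate spectra: ``v_j`` = spectral-peak mode.

    Every gate must show a detectable peak (verified through the FWHM
    measurement); gates and radii are paired positionally.
    """
    radii = np.asarray(radii, dtype=float)
    if len(gate_spectra) != len(radii):
        raise ValueError("one spectrum per radius required")
    v = []
    for j, vs in enumerate(gate_spectra):
        try:
            fwhm_of_spectrum(vs)  # peak-detectability check
        except NoPeakError as e:
            raise NoPeakError(f"gate {j} (r = {radii[j]:.4g} m): {e}") from e
        v.append(vs.peak_velocity())
    return VelocityProfile(r=radii, v=np.asarray(v), R=R, mu=mu)


def wall_shear_rate(profile: VelocityProfile, n_fit: int = 3) -> float:
    """Wall shear rate (1/s) from a straight-line fit near the wall.

    A least-squares line is fitted to the ``n_fit`` gates with the largest
    radii; the shear rate is minus the fitted slope (constant along the
    line, hence its value at ``r = R``).
    """
    if n_fit < 2:
        raise ValueError("n_fit must be >= 2")
    r = np.asarray(profile.r, dtype=float)[-n_fit:]
    v = np.asarray(profile.v, dtype=float)[-n_fit:]
    if len(r) < 2 or np.ptp(r) == 0:
        raise ValueError("degenerate fit: need >= 2 distinct radii near the wall")
    slope, _ = np.polyfit(r, v, 1)
    return float(-slope)


def wss_gradient(
    profile: VelocityProfile, n_fit: int = 3, position: str = ""
) -> WSSResult:
    """Gradient-method WSS: ``mu`` times the wall shear rate.

    The sign convention makes forward flow (velocity decreasing toward the
    wall) yield positive WSS.
    """
    rate = wall_shear_rate(profile, n_fit)
    return WSSResult(wss=profile.mu * rate, method="gradient",
                     shear_rate=rate, position=position)


def wss_parabolic(
    v_max: float, mu: float = DEFAULT_VISCOSITY, R: float = 3e-3,
    position: str = "",
) -> WSSResult:
    """Parabolic (Poiseuille) WSS: ``2 mu v_max / R``."""
    if R <= 0:
        raise ValueError("R must be positive")
    rate = 2.0 * v_max / R
    return WSSResult(wss=mu * rate, method="parabolic",
                     shear_rate=rate, position=position)


def compare_conditions(wss_a, wss_b) -> PairedTestResult:
    """Two-sided paired t-test between matched WSS sample sequences.

    Samples are paired by longitudinal position.  Identical sequences give
    ``t = 0, p = 1``; a nonzero constant difference has zero variance and is
    rejected as degenerate.
    """
    a = np.asarray(wss_a, dtype=float)
    b = np.asarray(wss_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 3:
        raise ValueError("need equal-length paired sequences of length >= 3")
    d = a - b
    if np.all(d == d[0]):
        if d[0] == 0:
            return PairedTestResult(t=0.0, dof=len(a) - 1, p=1.0,
                                    mean_difference=0.0)
        raise ValueError("constant nonzero paired difference: zero variance")
    res = stats.ttest_rel(a, b)
    return PairedTestResult(t=float(res.statistic), dof=len(a) - 1,
                            p=float(res.pvalue), mean_difference=float(d.mean()))
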