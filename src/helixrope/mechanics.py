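"""Mechanical-curve analysis: tensile stress–strain metrics and
Hertz-model AFM nanoindentation fits.

Units are SI throughout this module (Pa, N, m); curve files may carry
other units and are converted by the readers' column scale factors.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "TensileCurve", "TensileMetrics", "ForceCurve", "HertzFit",
    "tensile_metrics", "hertz_force", "hertz_fit", "point_stiffness",
    "read_tensile_csv", "read_force_csv",
]


@dataclass
class TensileCurve:
    strain: np.ndarray              # dimensionless
    stress: np.ndarray              # Pa
    gauge_length: float | None = None   # m
    diameter: float | None = None       # m

    def __post_init__(self) -> None:
        self.strain = np.asarray(self.strain, float)
        self.stress = np.asarray(self.stress, float)
        if self.strain.shape != self.stress.shape:
            raise ValueError("strain and stress series must have equal length")
        if np.any(np.diff(self.strain) < 0):
            raise ValueError("strain series must be non-decreasing")

    @classmethod
    def from_force_displacement(cls, displacement, force, gauge_length, diameter):
        """Engineering stress/strain from raw force–displacement."""
        area = np.pi * (diameter / 2.0) ** 2
        return cls(np.asarray(displacement, float) / gauge_length,
                   np.asarray(force, float) / area, gauge_length, diameter)


@dataclass
class TensileMetrics:
    modulus: float                  # Pa
    fracture_stress: float          # Pa
    fracture_strain: float
    work_of_rupture: float          # J m^-3
    fit_window: tuple[float, float]


@dataclass
class ForceCurve:
    z: np.ndarray                   # piezo displacement, m
    force: np.ndarray               # N
    tip_radius: float               # m
    poisson: float = 0.3
    spring_constant: float | None = None    # cantilever k_c, N/m

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, float)
        self.force = np.asarray(self.force, float)
        if self.z.shape != self.force.shape:
            raise ValueError("z and force series must have equal length")
        if self.tip_radius <= 0:
            raise ValueError("tip radius must be positive")
        if not 0.0 <= self.poisson < 0.5:
            raise ValueError("Poisson ratio must lie in [0, 0.5)")


@dataclass
class HertzFit:
    modulus: float                  # Pa
    contact_point: float            # m
    rms_residual: float             # N
    indentation_range: tuple[float, float]  # m


def tensile_metrics(curve: TensileCurve,
                    modulus_window: tuple[float, float] = (0.0, 0.002),
                    min_points: int = 5) -> TensileMetrics:
    """Elastic modulus, fracture point and work of rupture.

    The modulus is the least-squares slope of stress against strain over
    the initial linear window (default 0–0.2 % strain); fracture is the
    maximum-stress point; work of rupture is the trapezoidal integral of
    stress over strain up to fracture.
    """
    eps, sig = curve.strain, curve.stress
    lo, hi = modulus_window
    mask = (eps >= lo) & (eps <= hi)
    if mask.sum() < min_points:
        raise ValueError(
            f"only {int(mask.sum())} points inside the modulus window "
            f"[{lo}, {hi}]; need {min_points}")
    A = np.vstack([eps[mask], np.ones(mask.sum())]).T
    slope, _ = np.linalg.lstsq(A, sig[mask], rcond=None)[0]
    i_frac = int(np.argmax(sig))
    work = float(np.trapezoid(sig[: i_frac + 1], eps[: i_frac + 1]))
    return TensileMetrics(float(slope), float(sig[i_frac]), float(eps[i_frac]),
                          work, modulus_window)


def hertz_force(E: float, nu: float, tip_radius: float, delta) -> np.ndarray:
    """Hertzian sphere-on-flat contact force F = 4/3·E/(1−ν²)·√R·δ^{3/2}."""
    delta = np.asarray(delta, float)
    if np.any(delta < 0):
        raise ValueError("indentation depth must be non-negative")
    return (4.0 / 3.0) * E / (1.0 - nu**2) * np.sqrt(tip_radius) * delta**1.5


def _indentation(curve: ForceCurve, z0: float) -> np.ndarray:
    """Deflection-corrected sample indentation δ = (z − z0) − F/k_c."""
    delta = curve.z - z0
    if curve.spring_constant:
        delta = delta - curve.force / curve.spring_constant
    return delta


def hertz_fit(curve: ForceCurve, loss: str = "soft_l1",
              noise_mult: float = 3.0) -> HertzFit:
    """Fit sample modulus E and contact point z₀ to an approach curve.

    The contact point is a free parameter, initialised at the first
    point where the force exceeds ``noise_mult`` × the pre-contact noise
    SD; E and z₀ are then refined jointly by robust least squares
    (soft-L1 by default) on the post-contact region.  Residuals are
    weighted relative to the model force (with a small floor), which
    matches the multiplicative character of AFM force noise and keeps
    the near-contact region — where z₀ is determined — from being
    swamped by the high-force tail.
    """
    z, F = curve.z, curve.force
    if len(z) < 5:
        raise ValueError("force curve too short to fit")
    if np.all(F == 0):
        raise ValueError("force curve is identically zero; no contact found")
    # pre-contact noise from the first 20 % of the curve
    k = max(3, len(F) // 5)
    noise = float(np.std(F[:k]))
    thresh = noise_mult * noise if noise > 0 else 0.0
    above = np.where(F > thresh)[0]
    if len(above) == 0 or above[0] >= len(z) - 3:
        raise ValueError("no post-contact data above the noise threshold")
    z0_init = float(z[above[0]])
    f_floor = 0.02 * float(np.max(np.abs(F)))
    prefac = (4.0 / 3.0) / (1.0 - curve.poisson**2) * np.sqrt(curve.tip_radius)

    def model(params):
        logE, z0 = params
        delta = np.clip(_indentation(curve, z0), 0.0, None)
        return np.exp(logE) * prefac * delta**1.5

    dmax = float(np.max(_indentation(curve, z0_init)))
    if dmax <= 0:
        raise ValueError("no positive indentation beyond the contact point")
    E_init = float(np.max(F) / (prefac * dmax**1.5))

    def residuals(params):
        m = model(params)
        return (m - F) / (m + f_floor)

    fit = least_squares(residuals, [np.log(E_init), z0_init], loss=loss,
                        xtol=1e-14, ftol=1e-14, gtol=1e-14)
    E = float(np.exp(fit.x[0]))
    z0 = float(fit.x[1])
    if not np.isfinite(E) or E <= 0:
        raise ValueError("fit produced a non-positive modulus; bad contact point")
    resid = model(fit.x) - F
    delta = _indentation(curve, z0)
    return HertzFit(E, z0, float(np.sqrt(np.mean(resid**2))),
                    (float(max(delta.min(), 0.0)), float(delta.max())))


def point_stiffness(curve: ForceCurve, contact_point: float | None = None,
                    mode: str = "ratio") -> float:
    """Point stiffness (N/m) at maximum load.

    ``ratio`` mode (the definition used here): maximum normal force
    divided by the cantilever-deflection-corrected sample deformation at
    that point.  ``slope`` mode: local dF/dδ_s near maximum load.
    """
    if curve.spring_constant is None:
        raise ValueError("point stiffness requires the cantilever spring constant")
    if contact_point is None:
        contact_point = hertz_fit(curve).contact_point
    delta = _indentation(curve, contact_point)
    i_max = int(np.argmax(curve.force))
    ds = float(delta[i_max])
    if ds <= 0:
        raise ValueError("sample deformation at maximum load is non-positive")
    if mode == "ratio":
        return float(curve.force[i_max] / ds)
    if mode == "slope":
        sel = delta >= 0.8 * ds
        if sel.sum() < 2:
            raise ValueError("too few points near maximum load for a slope")
        A = np.vstack([delta[sel], np.ones(sel.sum())]).T
        slope, _ = np.linalg.lstsq(A, curve.force[sel], rcond=None)[0]
        return float(slope)
    raise ValueError(f"unknown mode {mode!r}")


# ------------------------------------------------------------- readers

def read_tensile_csv(path, strain_col: str = "strain", stress_col: str = "stress",
                     stress_scale: float = 1.0, sep=None) -> TensileCurve:
    df = pd.read_csv(Path(path), sep=sep, engine="python")
    return TensileCurve(df[strain_col].to_numpy(),
                        df[stress_col].to_numpy() * stress_scale)


def read_force_csv(path, z_col: str = "z", force_col: str = "force",
                   tip_radius: float = 10e-9, poisson: float = 0.3,
                   spring_constant: float | None = None,
                   z_scale: float = 1.0, force_scale: float = 1.0,
                   sep=None) -> ForceCurve:
    df = pd.read_csv(Path(path), sep=sep, engine="python")
    return ForceCurve(df[z_col].to_numpy() * z_scale,
                      df[force_col].to_numpy() * force_scale,
                      tip_radius, poisson, spring_constant)
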