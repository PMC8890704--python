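"""Stiles-Crawford-like directionality of light delivery to the OSR.

A cone tilted away from the direction of incident light still focuses along
the light's axis (the optical axis), so the light available to its own — now
tilted — outer segment falls off with tilt angle.  The classical
Stiles-Crawford parameterization describes this falloff as

    eta(d) = 10^(-rho d^2),

with d the pupil displacement in mm (angle of incidence / 2.5 deg per mm for
a ~25-mm eye) and rho the directionality parameter in mm^-2 (human values
~0.05-0.09).  Here the relative intensity at each tilt is the OSR
concentration along the cone's anatomical axis divided by that along the
optical axis (the light a perfectly aligned cone would receive), and rho
comes from a least-squares fit of log10(relative intensity) against -d^2 with
the intercept fixed at 1.  Tilt angles are measured from the simulated data
(anatomical vs optical axis in 3D), not assumed from the model rotation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .focusing_metrics import AxisAnnotation, osr_concentration

__all__ = [
    "DEG_PER_MM",
    "DirectionalityCurve",
    "measure_tilt",
    "relative_osr",
    "fit_rho",
    "tilt_series",
]

DEG_PER_MM = 2.5  # pupil displacement-to-incident-angle conversion


@dataclass
class DirectionalityCurve:
    """Relative OSR intensity vs incidence angle with its rho fit."""

    angles_deg: np.ndarray
    relative_intensity: np.ndarray
    rho: float = np.nan            # mm^-2
    fit_r2: float = np.nan
    conversion_deg_per_mm: float = DEG_PER_MM
    negative_rho: bool = False     # fit came out negative (flagged, sign kept)

    def __post_init__(self) -> None:
        self.angles_deg = np.asarray(self.angles_deg, float)
        self.relative_intensity = np.asarray(self.relative_intensity, float)


def measure_tilt(annotation: AxisAnnotation) -> float:
    """3D angle (degrees, in [0, 90]) between anatomical and optical axes."""
    a = annotation.anatomical_axis
    o = annotation.optical_axis
    c = abs(float(a @ o)) / (np.linalg.norm(a) * np.linalg.norm(o))
    return float(np.degrees(np.arccos(np.clip(c, 0.0, 1.0))))


def relative_osr(intensity, background, annotation: AxisAnnotation,
                 resolution: float | None = None) -> float:
    """OSR concentration along the anatomical axis relative to the optical axis.

    The optical-axis OSR is anchored where the optical axis crosses the distal
    tip's z plane, approximating the OS position of a perfectly aligned cone.
    """
    res = annotation.resolution if resolution is None else resolution
    tip = annotation.distal_tip
    anat = osr_concentration(intensity, background, tip,
                             annotation.anatomical_axis, res)
    o = annotation.optical_axis
    t = (tip[2] - annotation.halo_center[2]) / o[2]
    tip_opt = annotation.halo_center + t * o
    opt = osr_concentration(intensity, background, tip_opt, o, res)
    if opt <= 0:
        raise ValueError("optical-axis OSR concentration is zero")
    return anat / opt


def fit_rho(angles_deg, relative_intensity,
            conversion: float = DEG_PER_MM) -> tuple[float, float]:
    """Fit log10(relative intensity) = -rho d^2 (d = angle / conversion, mm).

    Zero-angle points pin the intercept at 1 by construction and drop out of
    the least squares.  Returns (rho in mm^-2, R^2 of the fit in log space).
    """
    ang = np.asarray(angles_deg, float)
    y = np.asarray(relative_intensity, float)
    if len(ang) < 2 or not np.any(np.isclose(ang, 0.0, atol=1e-9)) and len(ang) < 2:
        raise ValueError("need at least 2 angles")
    if np.any(y <= 0):
        raise ValueError("relative intensities must be positive to fit rho")
    d2 = (ang / conversion) ** 2
    ly = np.log10(y)
    sel = d2 > 0
    if not sel.any():
        return 0.0, 1.0
    rho = -float(d2[sel] @ ly[sel]) / float(d2[sel] @ d2[sel])
    resid = ly[sel] + rho * d2[sel]
    ss_tot = float(((ly[sel] - ly[sel].mean()) ** 2).sum())
    ss_res = float((resid ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res < 1e-20 else 0.0)
    return rho, r2


def tilt_series(run_one, angles_deg=(0.0, 5.0, 10.0),
                conversion: float = DEG_PER_MM) -> DirectionalityCurve:
    """Assemble a directionality curve from a tilt series.

    ``run_one(angle_deg)`` must run one condition and return
    ``(intensity, background, annotation)``; this function measures the tilt
    from the data, computes relative OSR intensities, and fits rho.  The fit
    pools all angles of the series.
    """
    meas_angles, rel = [], []
    for ang in angles_deg:
        intensity, background, annotation = run_one(ang)
        measured = measure_tilt(annotation)
        if abs(ang) < 1e-9:
            # aligned reference: anatomical == optical by construction
            meas_angles.append(0.0)
            rel.append(1.0)
        else:
            meas_angles.append(measured)
            rel.append(relative_osr(intensity, background, annotation))
    rho, r2 = fit_rho(meas_angles, rel, conversion)
    return DirectionalityCurve(
        angles_deg=np.array(meas_angles), relative_intensity=np.array(rel),
        rho=rho, fit_r2=r2, conversion_deg_per_mm=conversion,
        negative_rho=rho < 0)
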