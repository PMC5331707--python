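"""Rotation, twist, and torsion from reconstructed displacement trajectories.

Torsion is the difference in rotation between an apical and a basal slice
divided by the inter-slice distance taken from the plane-position metadata.
Rotation angles are counter-clockwise-positive as viewed from foot to head.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .phantom import SliceAcquisition
from .recon import DisplacementTrajectories, build_trajectories

__all__ = [
    "TwistCurve",
    "TorsionMeasurement",
    "endocardial_centroid",
    "rotation_curve",
    "slice_distance",
    "torsion_curve",
    "twist_from_acquisition",
]


@dataclass
class TwistCurve:
    """Per-frame rotation angle of one slice, degrees, zero at frame 0."""

    angles_deg: np.ndarray
    slice_label: str = ""
    plane_position: float | None = None
    subject_id: str = ""
    acquisition_index: int = -1
    window_label: str = ""
    protocol: str = ""

    def __post_init__(self) -> None:
        self.angles_deg = np.asarray(self.angles_deg, dtype=float)
        if not np.all(np.isfinite(self.angles_deg)):
            raise ValueError("twist angles must be finite")

    @property
    def n_frames(self) -> int:
        return self.angles_deg.size


@dataclass
class TorsionMeasurement:
    """Torsion over the cycle for one basal/apical pair, deg/cm."""

    tau: np.ndarray
    d_cm: float
    basal_ref: int = -1
    apical_ref: int = -1
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.tau = np.asarray(self.tau, dtype=float)
        if self.d_cm <= 0:
            raise ValueError("inter-slice distance must be > 0")

    @property
    def peak_torsion(self) -> float:
        return float(np.max(self.tau))


def endocardial_centroid(mask: np.ndarray, pixel_spacing: float):
    """Centroid (x, y) in mm of the end-diastolic endocardial boundary.

    The boundary is taken as mask pixels adjacent to the enclosed cavity; if
    the mask has no cavity (solid region) the centroid of all masked pixels is
    used.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    cavity = ndimage.binary_fill_holes(mask) & ~mask
    if cavity.any():
        boundary = mask & ndimage.binary_dilation(cavity)
    else:
        boundary = mask
    rr, cc = np.nonzero(boundary)
    return float(cc.mean() * pixel_spacing), float(rr.mean() * pixel_spacing)


def rotation_curve(traj: DisplacementTrajectories, endo_mask: np.ndarray,
                   pixel_spacing: float, **meta) -> TwistCurve:
    """Slice rotation angle per frame about the end-diastolic endo centroid.

    Bulk in-plane translation (the frame's mean displacement) is subtracted
    first; each point's signed angle from its end-diastolic radius vector is
    computed with the two-argument arctangent of cross and dot products, and
    the slice angle is the circular mean over points.
    """
    if traj.n_points == 0:
        raise ValueError("no trajectory points")
    cx, cy = endocardial_centroid(endo_mask, pixel_spacing)
    vx0 = traj.x0 - cx
    vy0 = traj.y0 - cy
    angles = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        ux = traj.ux[f] - traj.ux[f].mean()
        uy = traj.uy[f] - traj.uy[f].mean()
        vxt = vx0 + ux
        vyt = vy0 + uy
        cross = vx0 * vyt - vy0 * vxt
        dot = vx0 * vxt + vy0 * vyt
        theta = np.arctan2(cross, dot)
        angles[f] = np.angle(np.mean(np.exp(1j * theta)))
    return TwistCurve(angles_deg=np.rad2deg(angles), **meta)


def slice_distance(basal: TwistCurve, apical: TwistCurve) -> float:
    """Inter-slice distance in cm from plane-position metadata only."""
    if basal.plane_position is None or apical.plane_position is None:
        raise ValueError("plane positions missing")
    d_mm = abs(apical.plane_position - basal.plane_position)
    if d_mm == 0:
        raise ValueError("basal and apical plane positions coincide")
    return d_mm / 10.0


def torsion_curve(basal: TwistCurve, apical: TwistCurve) -> TorsionMeasurement:
    """tau(t) = (phi_apical(t) - phi_basal(t)) / d."""
    if basal.n_frames != apical.n_frames:
        raise ValueError("frame count mismatch between slices")
    d = slice_distance(basal, apical)
    tau = (apical.angles_deg - basal.angles_deg) / d
    return TorsionMeasurement(tau=tau, d_cm=d,
                              basal_ref=basal.acquisition_index,
                              apical_ref=apical.acquisition_index,
                              subject_id=basal.subject_id or apical.subject_id)


def twist_from_acquisition(acq: SliceAcquisition, smooth_sd_px: float = 1.0,
                           fit_order: int = 5) -> TwistCurve:
    """Full per-slice chain: reconstruct trajectories, then the twist curve."""
    traj = build_trajectories(acq, smooth_sd_px=smooth_sd_px,
                              fit_order=fit_order)
    return rotation_curve(
        traj, acq.myocardial_mask, acq.pixel_spacing,
        slice_label=acq.slice_label, plane_position=acq.plane_position,
        subject_id=acq.subject_id, acquisition_index=acq.acquisition_index,
        window_label=acq.window_label, protocol=acq.protocol)
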