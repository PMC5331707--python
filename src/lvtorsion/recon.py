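"""Reconstruction of displacement trajectories from wrapped phase stacks.

Stages: quality-guided path-following phase unwrapping, phase-to-displacement
conversion, mask-restricted spatial smoothing, and temporal polynomial fitting
constrained through zero at the first frame.
"""

from __future__ import annotations

import heapq
import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .phantom import SliceAcquisition, wrap_phase

log = logging.getLogger(__name__)

__all__ = [
    "DisplacementTrajectories",
    "unwrap_phase",
    "phase_to_displacement",
    "spatial_smooth",
    "temporal_fit",
    "build_trajectories",
]

TWO_PI = 2.0 * np.pi

_N4 = ((-1, 0), (1, 0), (0, -1), (0, 1))


@dataclass
class DisplacementTrajectories:
    """Per-point displacement histories for one slice.

    ``x0``/``y0`` are end-diastolic positions in mm (x = column direction,
    y = row direction, pixel centres); ``ux``/``uy`` have shape
    ``(n_frames, n_points)``.
    """

    x0: np.ndarray
    y0: np.ndarray
    ux: np.ndarray
    uy: np.ndarray
    frame_times: np.ndarray
    rows: np.ndarray
    cols: np.ndarray
    mask_provenance: np.ndarray  # (H, W) bool: points actually reconstructed

    @property
    def n_points(self) -> int:
        return self.x0.size

    @property
    def n_frames(self) -> int:
        return self.ux.shape[0]


# ---------------------------------------------------------------------------
# phase unwrapping
# ---------------------------------------------------------------------------

def _quality_map(wrapped: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Negative local variance of the wrapped phase gradients (3x3 window).

    High values mark smooth regions where the unwrapping path should grow
    first.
    """
    gx = np.zeros_like(wrapped)
    gy = np.zeros_like(wrapped)
    gx[:, :-1] = wrap_phase(np.diff(wrapped, axis=1))
    gy[:-1, :] = wrap_phase(np.diff(wrapped, axis=0))
    var = np.zeros_like(wrapped)
    for g in (gx, gy):
        mean = ndimage.uniform_filter(g, size=3, mode="nearest")
        mean_sq = ndimage.uniform_filter(g * g, size=3, mode="nearest")
        var += np.maximum(mean_sq - mean * mean, 0.0)
    return np.where(mask, -var, -np.inf)


def unwrap_phase(wrapped: np.ndarray, mask: np.ndarray,
                 seed_point: tuple[int, int]) -> np.ndarray:
    """Path-following region-growing phase unwrapping.

    Starting from ``seed_point`` the masked region is traversed in order of a
    quality metric (negative local phase-gradient variance).  Each pixel is
    unwrapped against the mean of its already-unwrapped 4-neighbours, choosing
    the 2*pi multiple that puts the difference in [-pi, pi).  Mask pixels not
    4-connected to the seed are left NaN and a warning is emitted.  On smooth
    fields the result differs from the true phase only by one global 2*pi
    integer constant.
    """
    wrapped = np.asarray(wrapped, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    r0, c0 = seed_point
    if not mask[r0, c0]:
        raise ValueError("seed point is outside the mask")
    quality = _quality_map(wrapped, mask)
    h, w = wrapped.shape
    out = np.full((h, w), np.nan)
    visited = np.zeros((h, w), dtype=bool)
    out[r0, c0] = wrapped[r0, c0]
    visited[r0, c0] = True
    heap: list[tuple[float, int, int, int]] = []
    counter = 0

    def push_neighbours(r: int, c: int) -> None:
        nonlocal counter
        for dr, dc in _N4:
            rr, cc = r + dr, c + dc
            if 0 <= rr < h and 0 <= cc < w and mask[rr, cc] and not visited[rr, cc]:
                heapq.heappush(heap, (-quality[rr, cc], counter, rr, cc))
                counter += 1

    push_neighbours(r0, c0)
    while heap:
        _, _, r, c = heapq.heappop(heap)
        if visited[r, c]:
            continue
        total = 0.0
        n_nb = 0
        for dr, dc in _N4:
            rr, cc = r + dr, c + dc
            if 0 <= rr < h and 0 <= cc < w and visited[rr, cc]:
                total += out[rr, cc]
                n_nb += 1
        ref = total / n_nb
        # multiple putting (value - ref) in [-pi, pi)
        m = np.floor((ref - wrapped[r, c]) / TWO_PI + 0.5)
        out[r, c] = wrapped[r, c] + TWO_PI * m
        visited[r, c] = True
        push_neighbours(r, c)

    unreachable = int(np.count_nonzero(mask & ~visited))
    if unreachable:
        warnings.warn(f"{unreachable} mask pixels unreachable from the seed; "
                      "excluded from unwrapping", stacklevel=2)
    return out


def phase_to_displacement(unwrapped_x: np.ndarray, unwrapped_y: np.ndarray,
                          k: float, mask: np.ndarray | None = None):
    """Convert an unwrapped phase pair into displacement (mm): u = phi/(2*pi*k).

    The unavoidable global 2*pi constant of the unwrapping is resolved per
    direction by picking, among offsets m in {-1, 0, 1}, the candidate whose
    spatial-median displacement is smallest in magnitude.
    """
    if k <= 0:
        raise ValueError("encoding frequency k must be > 0")
    out = []
    for phi in (unwrapped_x, unwrapped_y):
        u = np.asarray(phi, dtype=float) / (TWO_PI * k)
        sel = np.isfinite(u)
        if mask is not None:
            sel &= np.asarray(mask, dtype=bool)
        if sel.any():
            med = float(np.median(u[sel]))
            m_best = min((-1, 0, 1), key=lambda m: abs(med + m / k))
            u = u + m_best / k
        out.append(u)
    return out[0], out[1]


# ---------------------------------------------------------------------------
# smoothing and fitting
# ---------------------------------------------------------------------------

def spatial_smooth(field: np.ndarray, mask: np.ndarray,
                   kernel_sd_px: float) -> np.ndarray:
    """Gaussian smoothing restricted to the mask (renormalised at edges).

    Non-finite in-mask values are excluded from the kernel support.  A kernel
    SD of zero is the identity.
    """
    if kernel_sd_px < 0:
        raise ValueError("kernel_sd_px must be >= 0")
    field = np.asarray(field, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if kernel_sd_px == 0:
        return np.where(mask, field, np.nan)
    support = mask & np.isfinite(field)
    num = ndimage.gaussian_filter(np.where(support, field, 0.0), kernel_sd_px,
                                  mode="constant")
    den = ndimage.gaussian_filter(support.astype(float), kernel_sd_px,
                                  mode="constant")
    out = np.full(field.shape, np.nan)
    ok = support & (den > 0)
    out[ok] = num[ok] / den[ok]
    return out


def temporal_fit(series: np.ndarray, frame_times: np.ndarray,
                 basis_order: int) -> np.ndarray:
    """Least-squares polynomial fit through zero at the first frame.

    ``series`` has shape ``(n_frames, ...)``; the basis is t, t^2, ..,
    t^basis_order with t normalised to [0, 1], which forces the fitted value
    at frame 0 to be exactly zero.
    """
    series = np.asarray(series, dtype=float)
    t = np.asarray(frame_times, dtype=float)
    n_frames = series.shape[0]
    if basis_order >= n_frames:
        raise ValueError("basis_order must be < number of frames")
    if basis_order < 1:
        raise ValueError("basis_order must be >= 1")
    tn = (t - t[0]) / (t[-1] - t[0])
    design = tn[:, None] ** np.arange(1, basis_order + 1)
    flat = series.reshape(n_frames, -1)
    coef, *_ = np.linalg.lstsq(design, flat, rcond=None)
    fitted = design @ coef
    return fitted.reshape(series.shape)


# ---------------------------------------------------------------------------
# full per-slice reconstruction
# ---------------------------------------------------------------------------

def _auto_seed(acq: SliceAcquisition) -> tuple[int, int]:
    """Automatic unwrapping seed: masked pixel of maximum frame-0 magnitude."""
    mag = np.where(acq.myocardial_mask, acq.magnitude[0], -np.inf)
    flat = int(np.argmax(mag))
    return np.unravel_index(flat, mag.shape)


def build_trajectories(acq: SliceAcquisition, smooth_sd_px: float = 1.0,
                       fit_order: int = 5,
                       seed_point: tuple[int, int] | None = None
                       ) -> DisplacementTrajectories:
    """Unwrap -> displacement -> smooth -> temporal fit, for one acquisition.

    Points excluded at any frame (unreachable from the seed) are dropped from
    the trajectory set; initial positions are reported in mm using the
    acquisition's pixel spacing.
    """
    mask = np.asarray(acq.myocardial_mask, dtype=bool)
    if seed_point is None:
        seed_point = _auto_seed(acq)
    k = acq.encoding_frequency
    n_frames = acq.phase_x.shape[0]
    ux = np.empty_like(acq.phase_x, dtype=float)
    uy = np.empty_like(acq.phase_y, dtype=float)
    for f in range(n_frames):
        phx = unwrap_phase(acq.phase_x[f], mask, seed_point)
        phy = unwrap_phase(acq.phase_y[f], mask, seed_point)
        ufx, ufy = phase_to_displacement(phx, phy, k, mask=mask)
        ux[f] = spatial_smooth(ufx, mask, smooth_sd_px)
        uy[f] = spatial_smooth(ufy, mask, smooth_sd_px)

    valid = mask & np.all(np.isfinite(ux), axis=0) & np.all(np.isfinite(uy), axis=0)
    n_dropped = int(np.count_nonzero(mask) - np.count_nonzero(valid))
    if n_dropped:
        log.warning("%d masked pixels dropped from trajectories", n_dropped)
    rows, cols = np.nonzero(valid)
    ux_pts = temporal_fit(ux[:, rows, cols], acq.frame_times, fit_order)
    uy_pts = temporal_fit(uy[:, rows, cols], acq.frame_times, fit_order)
    spacing = acq.pixel_spacing
    return DisplacementTrajectories(
        x0=cols.astype(float) * spacing, y0=rows.astype(float) * spacing,
        ux=ux_pts, uy=uy_pts,
        frame_times=np.asarray(acq.frame_times, dtype=float),
        rows=rows, cols=cols, mask_provenance=valid)
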