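"""Synthetic displacement-encoded LV acquisitions under a respiratory-offset model.

The phantom is a short-axis annulus that rotates and contracts with a
prescribed longitudinal twist profile.  Tissue displacement is encoded into
wrapped image phase (one image per in-plane encoding direction), exactly as a
displacement-encoded MR acquisition would, and each acquisition carries a
*hidden* longitudinal offset of the heart caused by the breath-hold
end-expiratory position.  The plane-position metadata never reflects that
offset: it records the planned slice location only, which is the confound
this package models.

Two acquisition protocols are provided:

* ``simulate_experiment1`` -- basal/apical pairs acquired with the navigator
  acceptance window forced to the subject's minimum, middle and maximum
  end-expiratory positions, plus a repeated middle pair (8 acquisitions).
* ``simulate_experiment2`` -- alternating basal/apical acquisitions under a
  free breath-hold protocol (wide window that never rejects) and under a
  navigator-gated protocol with a single narrow acceptance window.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

import numpy as np
from scipy import optimize, stats

__all__ = [
    "PhantomConfig",
    "RespiratoryConfig",
    "AcquisitionPlan",
    "SliceAcquisition",
    "BreathHoldRecord",
    "wrap_phase",
    "cycle_shape",
    "end_systole_frame",
    "twist_angle_at",
    "calibrated_truncation_halfwidth",
    "sample_breathhold_positions",
    "select_min_mid_max",
    "plan_slices",
    "generate_displacement_field",
    "encode_phase",
    "simulate_slice",
    "simulate_experiment1",
    "simulate_experiment2",
]

BASAL = "basal"
APICAL = "apical"


# ---------------------------------------------------------------------------
# configuration containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhantomConfig:
    """Geometric and kinematic ground truth for the synthetic ventricle.

    ``long_axis_length`` is the end-systolic endocardial long-axis length in
    mm (the quantity slice planning spans).  ``twist_gradient`` is the true
    longitudinal gradient of rotation in deg/cm; for the linear profile the
    end-systolic rotation at longitudinal position ``z`` (mm, base -> apex) is
    ``twist_gradient * (z - L/2) / 10`` degrees, so the configured gradient
    holds exactly between any two planes.
    """

    long_axis_length: float = 88.0
    endo_radius_ed: float = 25.0
    epi_radius_ed: float = 33.0
    twist_gradient: float = 3.4
    twist_profile: str = "linear"
    peak_contraction_fraction: float = 0.10
    n_frames: int = 16
    temporal_resolution: float = 34.0
    pixel_spacing: float = 2.8
    grid_size: int = 32
    encoding_frequency: float = 0.06
    phase_noise_sd: float = 0.1
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (self.epi_radius_ed > self.endo_radius_ed > 0):
            raise ValueError("need epi_radius_ed > endo_radius_ed > 0")
        if not np.isfinite(self.twist_gradient):
            raise ValueError("twist_gradient must be finite")
        if not (0.0 <= self.peak_contraction_fraction < 1.0):
            raise ValueError("peak_contraction_fraction must be in [0, 1)")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.pixel_spacing <= 0:
            raise ValueError("pixel_spacing must be > 0")
        if self.encoding_frequency <= 0:
            raise ValueError("encoding_frequency must be > 0")
        if self.twist_profile not in ("linear", "sigmoid"):
            raise ValueError("twist_profile must be 'linear' or 'sigmoid'")
        if self.long_axis_length <= 0:
            raise ValueError("long_axis_length must be > 0")
        if self.grid_size * self.pixel_spacing < 2 * self.epi_radius_ed:
            raise ValueError("grid does not cover the epicardium")


@dataclass(frozen=True)
class RespiratoryConfig:
    """End-expiratory diaphragm position model.

    Positions are drawn from a zero-mean truncated normal whose SD is
    ``end_exp_sd`` and whose truncation half-width is calibrated so the
    expected range of 10 draws matches ``end_exp_range`` (see
    :func:`calibrated_truncation_halfwidth`).  ``diaphragm_to_heart_coupling``
    is the fraction of the diaphragm offset transmitted to the heart's
    long-axis position.  ``between_subject_sd`` controls cohort heterogeneity
    of the per-subject SD when simulating many subjects.
    """

    end_exp_sd: float = 3.3
    end_exp_range: float = 10.2
    navigator_window_halfwidth: float = 3.0
    wide_window_halfwidth: float = 50.0
    diaphragm_to_heart_coupling: float = 1.0
    between_subject_sd: float = 1.4
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("end_exp_sd", "end_exp_range",
                     "navigator_window_halfwidth", "wide_window_halfwidth"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0.0 <= self.diaphragm_to_heart_coupling <= 1.0):
            raise ValueError("coupling must be in [0, 1]")


@dataclass(frozen=True)
class AcquisitionPlan:
    """Five equidistant short-axis planes; basal/apical are slices 2 and 4.

    ``basal_index`` and ``apical_index`` are 1-based slice numbers (the
    second and fourth of the five planned slices).
    """

    slice_positions: tuple
    basal_index: int = 2
    apical_index: int = 4

    def __post_init__(self) -> None:
        pos = np.asarray(self.slice_positions, dtype=float)
        if pos.size != 5:
            raise ValueError("exactly five slice positions required")
        if not np.all(np.diff(pos) > 0):
            raise ValueError("slice positions must be strictly increasing")
        steps = np.diff(pos)
        if not np.allclose(steps, steps[0]):
            raise ValueError("slice positions must be equidistant")
        if self.d_nominal <= 0:
            raise ValueError("d_nominal must be > 0")

    @property
    def basal_position(self) -> float:
        return float(self.slice_positions[self.basal_index - 1])

    @property
    def apical_position(self) -> float:
        return float(self.slice_positions[self.apical_index - 1])

    @property
    def d_nominal(self) -> float:
        """Planned basal-apical separation in mm."""
        return float(self.slice_positions[self.apical_index - 1]
                     - self.slice_positions[self.basal_index - 1])


@dataclass(frozen=True)
class BreathHoldRecord:
    mode_position: float
    window_center: float
    window_halfwidth: float

    @property
    def accepted(self) -> bool:
        return abs(self.mode_position - self.window_center) <= self.window_halfwidth


@dataclass
class SliceAcquisition:
    """One breath-hold's cine stack.

    ``plane_position`` mimics the value read from the image header: it is
    always the *planned* slice position and never reflects the true
    longitudinal offset ``true_diaphragm_offset``.
    """

    magnitude: np.ndarray          # (frames, H, W)
    phase_x: np.ndarray            # (frames, H, W), wrapped to [-pi, pi)
    phase_y: np.ndarray
    myocardial_mask: np.ndarray    # (H, W) bool
    plane_position: float          # mm, metadata (planned)
    true_diaphragm_offset: float   # mm, hidden truth
    slice_label: str               # 'basal' | 'apical'
    acquisition_index: int
    subject_id: str
    pixel_spacing: float
    encoding_frequency: float
    frame_times: np.ndarray        # ms
    window_label: str = ""
    protocol: str = ""


# ---------------------------------------------------------------------------
# kinematics
# ---------------------------------------------------------------------------

def wrap_phase(phase: np.ndarray) -> np.ndarray:
    """Map phase to the half-open interval [-pi, pi)."""
    return np.mod(np.asarray(phase, dtype=float) + np.pi, 2.0 * np.pi) - np.pi


def end_systole_frame(cfg: PhantomConfig) -> int:
    """Frame index of peak contraction (40% of the cycle)."""
    return max(1, round(0.4 * (cfg.n_frames - 1)))


def cycle_shape(cfg: PhantomConfig) -> np.ndarray:
    """Temporal modulation: 0 at frame 0, 1 at end-systole, decaying after.

    Half-sine rise to end-systole, cosine decay back toward zero.  The value
    is exactly 1.0 at the end-systolic frame so that peak quantities are
    sampled, not straddled.
    """
    n = cfg.n_frames
    es = end_systole_frame(cfg)
    f = np.arange(n, dtype=float)
    rise = np.sin(0.5 * np.pi * f / es)
    tail = max(n - 1 - es, 1)
    decay = np.cos(0.5 * np.pi * (f - es) / tail)
    return np.where(f <= es, rise, decay)


def twist_angle_at(cfg: PhantomConfig, z: float) -> float:
    """End-systolic rotation angle (degrees) of the plane at position z (mm)."""
    z_ref = cfg.long_axis_length / 2.0
    if cfg.twist_profile == "linear":
        return cfg.twist_gradient * (z - z_ref) / 10.0
    # sigmoid: same total base-to-apex twist, logistic transition mid-cavity
    half_twist = cfg.twist_gradient * cfg.long_axis_length / 20.0
    return float(half_twist * np.tanh(4.0 * (z - z_ref) / cfg.long_axis_length)
                 / np.tanh(2.0))


def _grid_coordinates(cfg: PhantomConfig):
    """Pixel-center coordinates in mm about the grid centre (x right, y down)."""
    half = (cfg.grid_size - 1) / 2.0
    axis = (np.arange(cfg.grid_size) - half) * cfg.pixel_spacing
    x, y = np.meshgrid(axis, axis)
    return x, y


def myocardial_mask(cfg: PhantomConfig) -> np.ndarray:
    x, y = _grid_coordinates(cfg)
    r = np.hypot(x, y)
    return (r >= cfg.endo_radius_ed) & (r <= cfg.epi_radius_ed)


def generate_displacement_field(cfg: PhantomConfig, z: float, frame: int):
    """True in-plane displacement (mm) of every end-diastolic pixel.

    Returns ``(ux, uy, mask)``.  Motion is a rotation about the slice centroid
    by ``twist_angle_at(cfg, z) * cycle_shape[frame]`` combined with radial
    scaling by ``1 - peak_contraction_fraction * cycle_shape[frame]``.
    """
    if not (0.0 <= z <= cfg.long_axis_length):
        raise ValueError(f"longitudinal position {z} mm outside ventricle "
                         f"[0, {cfg.long_axis_length}]")
    if not (0 <= frame < cfg.n_frames):
        raise ValueError("frame index out of range")
    shape = cycle_shape(cfg)[frame]
    theta = np.deg2rad(twist_angle_at(cfg, z) * shape)
    scale = 1.0 - cfg.peak_contraction_fraction * shape
    x, y = _grid_coordinates(cfg)
    mask = myocardial_mask(cfg)
    c, s = np.cos(theta), np.sin(theta)
    ux = (scale * c - 1.0) * x - scale * s * y
    uy = scale * s * x + (scale * c - 1.0) * y
    return ux, uy, mask


def encode_phase(ux: np.ndarray, uy: np.ndarray, mask: np.ndarray,
                 k: float, noise_sd: float = 0.0,
                 rng: np.random.Generator | int | None = None):
    """Encode a displacement field into a wrapped phase pair.

    ``phase = wrap(2*pi*k*u + eps)`` with ``eps ~ N(0, noise_sd^2)`` i.i.d.
    inside the mask; pixels outside the mask carry zero phase.
    """
    if k <= 0:
        raise ValueError("encoding frequency k must be > 0")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    out = []
    for u in (ux, uy):
        phase = 2.0 * np.pi * k * np.asarray(u, dtype=float)
        if noise_sd > 0:
            phase = phase + noise_sd * rng.standard_normal(phase.shape)
        phase = np.where(mask, phase, 0.0)
        out.append(wrap_phase(phase))
    return out[0], out[1]


# ---------------------------------------------------------------------------
# respiratory model
# ---------------------------------------------------------------------------

def _expected_range(sigma: float, halfwidth: float, n: int,
                    n_grid: int = 1001) -> float:
    """E[max - min] of n i.i.d. draws from truncnorm(0, sigma, +-halfwidth)."""
    if sigma <= 0 or halfwidth <= 0:
        return 0.0
    a = -halfwidth / sigma
    xs = np.linspace(-halfwidth, halfwidth, n_grid)
    cdf = stats.truncnorm.cdf(xs, a, -a, scale=sigma)
    integrand = 1.0 - cdf ** n - (1.0 - cdf) ** n
    return float(np.trapezoid(integrand, xs))


@lru_cache(maxsize=256)
def _calibrated_halfwidth(sigma: float, target_range: float,
                          n_draws: int) -> float:
    if sigma == 0:
        return 0.0
    cap = 8.0 * sigma
    if _expected_range(sigma, cap, n_draws) <= target_range:
        return cap
    return float(optimize.brentq(
        lambda b: _expected_range(sigma, b, n_draws) - target_range,
        1e-3 * sigma, cap))


def calibrated_truncation_halfwidth(resp: RespiratoryConfig,
                                    n_draws: int = 10) -> float:
    """Truncation half-width making E[range of ``n_draws``] = end_exp_range.

    The expected range of a truncated normal is increasing in the truncation
    half-width with supremum ~= 3.08 * sd for 10 draws; if the requested range
    exceeds that supremum the half-width is capped at 8 sd (effectively
    untruncated), which is the closest attainable calibration.
    """
    return _calibrated_halfwidth(resp.end_exp_sd, resp.end_exp_range, n_draws)


def _draw_offsets(resp: RespiratoryConfig, center: float, halfwidth: float,
                  n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw end-expiratory offsets from the respiratory distribution
    conditioned on the acceptance window [center - hw, center + hw]."""
    bound = calibrated_truncation_halfwidth(resp)
    lo = max(center - halfwidth, -bound)
    hi = min(center + halfwidth, bound)
    if resp.end_exp_sd == 0:
        return np.full(n, float(np.clip(0.0, lo, hi)))
    if halfwidth == 0:
        return np.full(n, float(center))
    if lo >= hi:  # window entirely outside the respiratory support
        return np.full(n, float(np.clip(center, -bound, bound)))
    a, b = lo / resp.end_exp_sd, hi / resp.end_exp_sd
    return stats.truncnorm.rvs(a, b, scale=resp.end_exp_sd, size=n,
                               random_state=rng)


def sample_breathhold_positions(resp: RespiratoryConfig, n: int,
                                seed: int | np.random.Generator | None = None
                                ) -> list[BreathHoldRecord]:
    """Mode end-expiratory position of ``n`` consecutive breath-holds.

    These are the ungated navigator *measurements*: the wide window is used so
    every breath-hold is accepted.
    """
    if n < 1:
        raise ValueError("need at least one breath-hold")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    positions = _draw_offsets(resp, 0.0, resp.wide_window_halfwidth, n, rng)
    return [BreathHoldRecord(float(p), 0.0, resp.wide_window_halfwidth)
            for p in positions]


def select_min_mid_max(records: Sequence[BreathHoldRecord]):
    """Subject-specific (minimum, middle, maximum) end-expiratory positions.

    "Middle" is the recorded position closest to the median, ties broken
    toward the smaller value.
    """
    if len(records) < 3:
        raise ValueError("need at least three breath-hold records")
    pos = np.array([r.mode_position for r in records], dtype=float)
    med = float(np.median(pos))
    order = np.lexsort((pos, np.abs(pos - med)))
    return float(pos.min()), float(pos[order[0]]), float(pos.max())


# ---------------------------------------------------------------------------
# slice planning and acquisition synthesis
# ---------------------------------------------------------------------------

def plan_slices(cfg: PhantomConfig) -> AcquisitionPlan:
    """Five equidistant planes across the end-systolic endocardial length."""
    positions = tuple(np.linspace(0.0, cfg.long_axis_length, 5))
    return AcquisitionPlan(slice_positions=positions)


def _magnitude_image(cfg: PhantomConfig, mask: np.ndarray) -> np.ndarray:
    # mid-wall bright, falls off toward both surfaces; air floor outside.
    x, y = _grid_coordinates(cfg)
    r = np.hypot(x, y)
    mid = 0.5 * (cfg.endo_radius_ed + cfg.epi_radius_ed)
    width = 0.5 * (cfg.epi_radius_ed - cfg.endo_radius_ed)
    img = 1.2 - 0.4 * ((r - mid) / width) ** 2
    return np.where(mask, img, 0.05)


def simulate_slice(cfg: PhantomConfig, plane_position: float,
                   true_offset: float, coupling: float, slice_label: str,
                   acquisition_index: int, subject_id: str,
                   rng: np.random.Generator, window_label: str = "",
                   protocol: str = "") -> SliceAcquisition:
    """Synthesize one cine acquisition at a planned plane with a hidden offset.

    The effective sampled longitudinal position is
    ``plane_position + coupling * true_offset`` (clipped to the ventricle);
    the recorded metadata keeps the planned position.
    """
    z_eff = float(np.clip(plane_position + coupling * true_offset,
                          0.0, cfg.long_axis_length))
    mask = myocardial_mask(cfg)
    n, g = cfg.n_frames, cfg.grid_size
    phase_x = np.empty((n, g, g))
    phase_y = np.empty((n, g, g))
    for f in range(n):
        ux, uy, _ = generate_displacement_field(cfg, z_eff, f)
        phase_x[f], phase_y[f] = encode_phase(
            ux, uy, mask, cfg.encoding_frequency, cfg.phase_noise_sd, rng)
    magnitude = np.broadcast_to(_magnitude_image(cfg, mask), (n, g, g)).copy()
    frame_times = np.arange(n, dtype=float) * cfg.temporal_resolution
    return SliceAcquisition(
        magnitude=magnitude, phase_x=phase_x, phase_y=phase_y,
        myocardial_mask=mask, plane_position=float(plane_position),
        true_diaphragm_offset=float(true_offset), slice_label=slice_label,
        acquisition_index=acquisition_index, subject_id=subject_id,
        pixel_spacing=cfg.pixel_spacing,
        encoding_frequency=cfg.encoding_frequency,
        frame_times=frame_times, window_label=window_label, protocol=protocol)


def simulate_experiment1(cfg: PhantomConfig, resp: RespiratoryConfig,
                         plan: AcquisitionPlan, seed: int | None = None,
                         subject_id: str = "s00"):
    """Enforced end-expiratory variability protocol.

    Ten breath-hold mode positions are measured; the navigator window is then
    centred on the subject's minimum, middle and maximum positions, and
    basal + apical slices are acquired at each, with the middle pair repeated
    (8 acquisitions).  Returns ``(acquisitions, truth)``.
    """
    rng = np.random.default_rng(seed)
    records = sample_breathhold_positions(resp, 10, rng)
    lo, mid, hi = select_min_mid_max(records)
    windows = [("min", lo), ("mid", mid), ("max", hi), ("mid_repeat", mid)]
    hw = resp.navigator_window_halfwidth
    coupling = resp.diaphragm_to_heart_coupling
    acquisitions: list[SliceAcquisition] = []
    truth_acqs = []
    idx = 0
    for window_label, center in windows:
        for label, pos in ((BASAL, plan.basal_position),
                           (APICAL, plan.apical_position)):
            offset = float(_draw_offsets(resp, center, hw, 1, rng)[0])
            acq = simulate_slice(cfg, pos, offset, coupling, label, idx,
                                 subject_id, rng, window_label=window_label,
                                 protocol="enforced")
            acquisitions.append(acq)
            truth_acqs.append({
                "acq_index": idx, "slice_label": label,
                "window_label": window_label, "window_center_mm": center,
                "window_halfwidth_mm": hw, "true_offset_mm": offset,
                "plane_position_mm": pos,
            })
            idx += 1
    truth = {
        "experiment": 1, "subject_id": subject_id,
        "phantom": dataclasses.asdict(cfg),
        "respiratory": dataclasses.asdict(resp),
        "breathhold_mode_positions_mm": [r.mode_position for r in records],
        "selected_positions_mm": {"min": lo, "mid": mid, "max": hi},
        "acquisitions": truth_acqs,
    }
    return acquisitions, truth


def simulate_experiment2(cfg: PhantomConfig, resp: RespiratoryConfig,
                         plan: AcquisitionPlan, n_pairs: int = 10,
                         seed: int | None = None, subject_id: str = "s00"):
    """Natural end-expiratory variability protocol.

    For each of the two protocols, ``2 * n_pairs`` acquisitions alternate
    basal, apical, basal, apical, ... in temporal order.  The breath-hold
    protocol monitors (never rejects) offsets through the wide window; the
    navigator protocol constrains offsets to a single narrow window.
    Returns ``({"breathhold": [...], "navigator": [...]}, truth)``.
    """
    if n_pairs < 2:
        raise ValueError("n_pairs must be >= 2")
    rng = np.random.default_rng(seed)
    coupling = resp.diaphragm_to_heart_coupling
    protocols = {
        "breathhold": (0.0, resp.wide_window_halfwidth),
        "navigator": (0.0, resp.navigator_window_halfwidth),
    }
    sessions: dict[str, list[SliceAcquisition]] = {}
    truth_acqs = []
    for protocol, (center, hw) in protocols.items():
        acqs = []
        for idx in range(2 * n_pairs):
            label = BASAL if idx % 2 == 0 else APICAL
            pos = plan.basal_position if label == BASAL else plan.apical_position
            offset = float(_draw_offsets(resp, center, hw, 1, rng)[0])
            acqs.append(simulate_slice(cfg, pos, offset, coupling, label, idx,
                                       subject_id, rng, protocol=protocol))
            truth_acqs.append({
                "acq_index": idx, "protocol": protocol, "slice_label": label,
                "window_center_mm": center, "window_halfwidth_mm": hw,
                "true_offset_mm": offset, "plane_position_mm": pos,
            })
        sessions[protocol] = acqs
    truth = {
        "experiment": 2, "subject_id": subject_id,
        "phantom": dataclasses.asdict(cfg),
        "respiratory": dataclasses.asdict(resp),
        "acquisitions": truth_acqs,
    }
    return sessions, truth
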