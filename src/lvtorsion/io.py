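"""HDF5 session container and JSON truth sidecar.

Layout: one file per simulated session, groups
``/subject/<id>/<protocol>/<acq_NN>`` with datasets ``magnitude``,
``phase_x``, ``phase_y``, ``mask`` and per-acquisition attributes.  The truth
sidecar (configs plus all sampled offsets) exists for oracle tests only; the
analysis path never reads it.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .phantom import SliceAcquisition

__all__ = ["write_session", "read_session", "append_trajectories",
           "write_truth", "read_truth"]

_ACQ_ATTRS = ("plane_position_mm", "slice_label", "acq_index",
              "true_offset_mm", "pixel_spacing_mm", "k_cyc_per_mm",
              "window_label", "protocol")


def write_session(path, acquisitions, experiment: int | None = None,
                  root_attrs: dict | None = None, mode: str = "w") -> None:
    """Write acquisitions (optionally spanning subjects/protocols) to HDF5."""
    path = Path(path)
    with h5py.File(path, mode) as f:
        if experiment is not None:
            f.attrs["experiment"] = experiment
        for key, value in (root_attrs or {}).items():
            f.attrs[key] = value
        for acq in acquisitions:
            protocol = acq.protocol or "default"
            grp = f.require_group(
                f"subject/{acq.subject_id}/{protocol}/acq_{acq.acquisition_index:02d}")
            grp.create_dataset("magnitude", data=acq.magnitude)
            grp.create_dataset("phase_x", data=acq.phase_x)
            grp.create_dataset("phase_y", data=acq.phase_y)
            grp.create_dataset("mask", data=acq.myocardial_mask.astype(np.uint8))
            grp.attrs["plane_position_mm"] = acq.plane_position
            grp.attrs["slice_label"] = acq.slice_label
            grp.attrs["acq_index"] = acq.acquisition_index
            grp.attrs["true_offset_mm"] = acq.true_diaphragm_offset
            grp.attrs["pixel_spacing_mm"] = acq.pixel_spacing
            grp.attrs["k_cyc_per_mm"] = acq.encoding_frequency
            grp.attrs["frame_times_ms"] = np.asarray(acq.frame_times, dtype=float)
            grp.attrs["window_label"] = acq.window_label
            grp.attrs["protocol"] = acq.protocol


def read_session(path) -> list[SliceAcquisition]:
    """Read every acquisition in a session file."""
    acquisitions = []
    with h5py.File(path, "r") as f:
        for sid, subj in f["subject"].items():
            for protocol, prot in subj.items():
                for name in sorted(prot):
                    grp = prot[name]
                    acquisitions.append(SliceAcquisition(
                        magnitude=grp["magnitude"][...],
                        phase_x=grp["phase_x"][...],
                        phase_y=grp["phase_y"][...],
                        myocardial_mask=grp["mask"][...].astype(bool),
                        plane_position=float(grp.attrs["plane_position_mm"]),
                        true_diaphragm_offset=float(grp.attrs["true_offset_mm"]),
                        slice_label=str(grp.attrs["slice_label"]),
                        acquisition_index=int(grp.attrs["acq_index"]),
                        subject_id=str(sid),
                        pixel_spacing=float(grp.attrs["pixel_spacing_mm"]),
                        encoding_frequency=float(grp.attrs["k_cyc_per_mm"]),
                        frame_times=np.asarray(grp.attrs["frame_times_ms"]),
                        window_label=str(grp.attrs["window_label"]),
                        protocol=str(grp.attrs["protocol"]),
                    ))
    return acquisitions


def append_trajectories(path, acq: SliceAcquisition, traj) -> None:
    """Store reconstructed trajectories under the acquisition's group."""
    protocol = acq.protocol or "default"
    with h5py.File(path, "a") as f:
        grp = f[f"subject/{acq.subject_id}/{protocol}/acq_{acq.acquisition_index:02d}"]
        if "trajectories" in grp:
            del grp["trajectories"]
        t = grp.create_group("trajectories")
        t.create_dataset("x0", data=traj.x0)
        t.create_dataset("y0", data=traj.y0)
        t.create_dataset("ux", data=traj.ux)
        t.create_dataset("uy", data=traj.uy)
        t.attrs["frame_times_ms"] = traj.frame_times


def write_truth(path, truth: dict) -> None:
    Path(path).write_text(json.dumps(truth, indent=2, default=float))


def read_truth(path) -> dict:
    return json.loads(Path(path).read_text())
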