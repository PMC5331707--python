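"""End-to-end orchestration: simulate -> recon -> torsion -> analyze -> sample size.

A run is reproducible from its config and master seed alone: every stage and
subject draws from named substreams of one ``numpy.random.SeedSequence``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as session_io
from .phantom import (AcquisitionPlan, PhantomConfig, RespiratoryConfig,
                      plan_slices, sample_breathhold_positions,
                      simulate_experiment1, simulate_experiment2)
from .samplesize import factor_f, required_n, sample_size_table
from .torsion import twist_from_acquisition
from .varstats import (VariabilityReport, analyze_experiment1,
                       analyze_experiment2, build_permutation_set,
                       pair_torsions)

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_experiment", "generate_report",
            "subject_respiratory", "experiment1_subject", "experiment2_subject",
            "experiment1_cohort", "experiment2_cohort"]

TORSION_COLUMNS = ["subject_id", "protocol", "basal_idx", "apical_idx",
                   "d_cm", "peak_torsion_deg_per_cm", "basal_window",
                   "apical_window"]


@dataclass
class RunConfig:
    """Serializable configuration of one full pipeline run."""

    experiment: int = 1
    n_subjects: int = 16
    n_pairs: int = 10
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    respiratory: RespiratoryConfig = field(default_factory=RespiratoryConfig)
    smooth_sd_px: float = 1.0
    fit_order: int = 5
    heterogeneous_subjects: bool = True
    alpha: float = 0.05
    power: float = 0.90
    delta_fraction: float = 0.10
    seed: int = 0
    outdir: str = "."

    def __post_init__(self) -> None:
        if self.experiment not in (1, 2):
            raise ValueError("experiment must be 1 or 2")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if isinstance(self.phantom, dict):
            self.phantom = PhantomConfig(**self.phantom)
        if isinstance(self.respiratory, dict):
            self.respiratory = RespiratoryConfig(**self.respiratory)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(**d)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=float)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# cohort simulation helpers
# ---------------------------------------------------------------------------

def subject_respiratory(resp: RespiratoryConfig,
                        rng: np.random.Generator) -> RespiratoryConfig:
    """Draw a subject-specific respiratory config from the cohort model.

    The per-subject end-expiratory SD is normal about the configured SD with
    the configured between-subject spread (floored at 0.3 mm); the range
    parameter scales proportionally.
    """
    sd = max(0.3, float(rng.normal(resp.end_exp_sd, resp.between_subject_sd)))
    scale = sd / resp.end_exp_sd if resp.end_exp_sd > 0 else 1.0
    return dataclasses.replace(resp, end_exp_sd=sd,
                               end_exp_range=resp.end_exp_range * scale)


def experiment1_subject(cfg: PhantomConfig, resp: RespiratoryConfig,
                        plan: AcquisitionPlan, seed, subject_id: str,
                        smooth_sd_px: float = 1.0, fit_order: int = 5):
    """Simulate and fully process one enforced-variability subject.

    Returns ``(perm_set, observed_range_mm, twists, acquisitions, truth)``.
    The observed range comes from the ten navigator-measured breath-hold
    positions (legitimately observable, unlike the per-acquisition offsets).
    """
    acqs, truth = simulate_experiment1(cfg, resp, plan, seed=seed,
                                       subject_id=subject_id)
    twists = {}
    for acq in acqs:
        tw = twist_from_acquisition(acq, smooth_sd_px=smooth_sd_px,
                                    fit_order=fit_order)
        twists[(acq.slice_label, acq.window_label)] = tw
    perm_set = build_permutation_set(twists, subject_id=subject_id)
    positions = truth["breathhold_mode_positions_mm"]
    observed_range = float(max(positions) - min(positions))
    return perm_set, observed_range, twists, acqs, truth


def experiment2_subject(cfg: PhantomConfig, resp: RespiratoryConfig,
                        plan: AcquisitionPlan, seed, subject_id: str,
                        n_pairs: int = 10, smooth_sd_px: float = 1.0,
                        fit_order: int = 5):
    """Simulate and fully process one natural-variability subject.

    Returns ``(torsions, offset_sds, twists, sessions, truth)`` where
    ``torsions`` maps protocol to the ``2 * n_pairs`` consecutive-pairing peak
    torsions and ``offset_sds`` maps protocol to the SD of the
    navigator-monitored end-expiratory positions.
    """
    sessions, truth = simulate_experiment2(cfg, resp, plan, n_pairs=n_pairs,
                                           seed=seed, subject_id=subject_id)
    torsions, offset_sds, twists = {}, {}, {}
    for protocol, acqs in sessions.items():
        tws = [twist_from_acquisition(a, smooth_sd_px=smooth_sd_px,
                                      fit_order=fit_order) for a in acqs]
        twists[protocol] = tws
        torsions[protocol] = pair_torsions(tws)
        monitored = [a["true_offset_mm"] for a in truth["acquisitions"]
                     if a["protocol"] == protocol]
        offset_sds[protocol] = float(np.std(monitored, ddof=1))
    return torsions, offset_sds, twists, sessions, truth


def experiment1_cohort(cfg: PhantomConfig, resp: RespiratoryConfig,
                       n_subjects: int, seed: int, smooth_sd_px: float = 1.0,
                       fit_order: int = 5, heterogeneous: bool = True):
    """Run ``n_subjects`` enforced-variability subjects in memory.

    Returns ``(perm_sets, observed_ranges)``.
    """
    plan = plan_slices(cfg)
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_subjects)
    perm_sets, ranges = [], []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        resp_i = subject_respiratory(resp, rng) if heterogeneous else resp
        perm_set, rng_mm, *_ = experiment1_subject(
            cfg, resp_i, plan, rng, f"s{i:03d}",
            smooth_sd_px=smooth_sd_px, fit_order=fit_order)
        perm_sets.append(perm_set)
        ranges.append(rng_mm)
    return perm_sets, ranges


def experiment2_cohort(cfg: PhantomConfig, resp: RespiratoryConfig,
                       n_subjects: int, seed: int, n_pairs: int = 10,
                       smooth_sd_px: float = 1.0, fit_order: int = 5,
                       heterogeneous: bool = True):
    """Run ``n_subjects`` natural-variability subjects in memory.

    Returns ``(torsions_by_subject, offset_sds_by_subject)``.
    """
    plan = plan_slices(cfg)
    children = np.random.SeedSequence(seed).spawn(n_subjects)
    torsions_by_subject, offset_sds = {}, {}
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        resp_i = subject_respiratory(resp, rng) if heterogeneous else resp
        sid = f"s{i:03d}"
        torsions, sds, *_ = experiment2_subject(
            cfg, resp_i, plan, rng, sid, n_pairs=n_pairs,
            smooth_sd_px=smooth_sd_px, fit_order=fit_order)
        torsions_by_subject[sid] = torsions
        offset_sds[sid] = sds
    return torsions_by_subject, offset_sds


# ---------------------------------------------------------------------------
# full run with file outputs
# ---------------------------------------------------------------------------

def _torsion_rows_exp1(twists_by_subject) -> list[dict]:
    rows = []
    windows = ("min", "mid", "max", "mid_repeat")
    from .torsion import torsion_curve
    for sid, twists in twists_by_subject.items():
        for wb in windows:
            for wa in windows:
                # permutations use min/mid/max; reference pairs use matching
                # mid / mid_repeat windows
                if (wb in ("mid_repeat",)) != (wa in ("mid_repeat",)):
                    continue
                b = twists[("basal", wb)]
                a = twists[("apical", wa)]
                meas = torsion_curve(b, a)
                rows.append({
                    "subject_id": sid, "protocol": "enforced",
                    "basal_idx": b.acquisition_index,
                    "apical_idx": a.acquisition_index,
                    "d_cm": meas.d_cm,
                    "peak_torsion_deg_per_cm": meas.peak_torsion,
                    "basal_window": wb, "apical_window": wa,
                })
    return rows


def _torsion_rows_exp2(twists_by_subject) -> list[dict]:
    from .torsion import torsion_curve
    from .varstats import consecutive_pairing
    rows = []
    for sid, by_protocol in twists_by_subject.items():
        for protocol, tws in by_protocol.items():
            basal = [(t.acquisition_index, t) for t in tws
                     if t.slice_label == "basal"]
            apical = [(t.acquisition_index, t) for t in tws
                      if t.slice_label == "apical"]
            for b, a in consecutive_pairing(basal, apical):
                meas = torsion_curve(b, a)
                rows.append({
                    "subject_id": sid, "protocol": protocol,
                    "basal_idx": b.acquisition_index,
                    "apical_idx": a.acquisition_index,
                    "d_cm": meas.d_cm,
                    "peak_torsion_deg_per_cm": meas.peak_torsion,
                    "basal_window": "", "apical_window": "",
                })
    return rows


def run_experiment(config: RunConfig) -> dict:
    """Execute every stage of one experiment and write the report bundle.

    Writes ``session.h5``, ``truth.json``, ``torsions.csv``,
    ``navigator.csv``, ``report.json``, ``samplesize.json`` and ``run.log``
    into ``config.outdir`` and returns the report dictionary.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.config_hash()
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
    run_log = logging.getLogger(f"lvtorsion.run.{cfg_hash}")
    run_log.addHandler(handler)
    run_log.setLevel(logging.INFO)
    run_log.info("config hash %s seed %d numpy %s", cfg_hash, config.seed,
                 np.__version__)
    try:
        plan = plan_slices(config.phantom)
        children = np.random.SeedSequence(config.seed).spawn(config.n_subjects)
        all_acqs, truths, navigator_rows = [], [], []
        if config.experiment == 1:
            perm_sets, ranges, twists_by_subject = [], [], {}
            for i, child in enumerate(children):
                rng = np.random.default_rng(child)
                resp_i = (subject_respiratory(config.respiratory, rng)
                          if config.heterogeneous_subjects else config.respiratory)
                sid = f"s{i:03d}"
                perm_set, rng_mm, twists, acqs, truth = experiment1_subject(
                    config.phantom, resp_i, plan, rng, sid,
                    smooth_sd_px=config.smooth_sd_px,
                    fit_order=config.fit_order)
                perm_sets.append(perm_set)
                ranges.append(rng_mm)
                twists_by_subject[sid] = twists
                all_acqs.extend(acqs)
                truths.append(truth)
                for j, pos in enumerate(truth["breathhold_mode_positions_mm"]):
                    navigator_rows.append({"subject_id": sid, "protocol": "prescan",
                                           "index": j, "position_mm": pos})
                run_log.info("subject %s simulated and reconstructed", sid)
            report = analyze_experiment1(perm_sets, offset_ranges=ranges)
            torsion_rows = _torsion_rows_exp1(twists_by_subject)
            loa_sigmas = {"enforced": report.rmse_permutations * np.sqrt(2.0),
                          "navigator": (report.loa_halfwidth or 0.0) / 1.96}
        else:
            torsions_by_subject, offset_sds, twists_by_subject = {}, {}, {}
            for i, child in enumerate(children):
                rng = np.random.default_rng(child)
                resp_i = (subject_respiratory(config.respiratory, rng)
                          if config.heterogeneous_subjects else config.respiratory)
                sid = f"s{i:03d}"
                torsions, sds, twists, sessions, truth = experiment2_subject(
                    config.phantom, resp_i, plan, rng, sid,
                    n_pairs=config.n_pairs,
                    smooth_sd_px=config.smooth_sd_px,
                    fit_order=config.fit_order)
                torsions_by_subject[sid] = torsions
                offset_sds[sid] = sds
                twists_by_subject[sid] = twists
                for acqs in sessions.values():
                    all_acqs.extend(acqs)
                truths.append(truth)
                for a in truth["acquisitions"]:
                    navigator_rows.append({
                        "subject_id": sid, "protocol": a["protocol"],
                        "index": a["acq_index"],
                        "position_mm": a["true_offset_mm"]})
                run_log.info("subject %s simulated and reconstructed", sid)
            report = analyze_experiment2(torsions_by_subject,
                                         offset_sds=offset_sds)
            torsion_rows = _torsion_rows_exp2(twists_by_subject)
            loa_sigmas = {"breathhold": report.loa_breathhold / 1.96,
                          "navigator": report.loa_navigator / 1.96}

        session_io.write_session(outdir / "session.h5", all_acqs,
                                 experiment=config.experiment,
                                 root_attrs={"config_hash": cfg_hash,
                                             "seed": config.seed})
        session_io.write_truth(outdir / "truth.json",
                               {"config_hash": cfg_hash, "subjects": truths})
        df = pd.DataFrame(torsion_rows, columns=TORSION_COLUMNS)
        df.to_csv(outdir / "torsions.csv", index=False)
        pd.DataFrame(navigator_rows).to_csv(outdir / "navigator.csv", index=False)

        delta = config.delta_fraction * (report.mean_torsion or 0.0)
        ss_table = {}
        if delta > 0:
            ss_table = sample_size_table(loa_sigmas, delta,
                                         alpha=config.alpha, power=config.power)
        samplesize_out = {
            "config_hash": cfg_hash,
            "f": factor_f(config.alpha, config.power),
            "delta_deg_per_cm": delta,
            "sigmas_deg_per_cm": loa_sigmas,
            "required_n": ss_table,
        }
        (outdir / "samplesize.json").write_text(
            json.dumps(samplesize_out, indent=2, default=float))

        bundle = {"config_hash": cfg_hash, "config": config.to_dict(),
                  "report": report.to_dict(), "samplesize": samplesize_out}
        (outdir / "report.json").write_text(
            json.dumps(bundle, indent=2, default=float))
        run_log.info("report written")
        return bundle
    finally:
        run_log.removeHandler(handler)
        handler.close()


def generate_report(bundles) -> dict:
    """Aggregate run bundles into mean +- SD torsion and sample-size tables."""
    bundles = list(bundles)
    if not bundles:
        raise ValueError("need at least one report bundle")
    torsion_rows, samplesize_rows = [], []
    by_protocol: dict[str, list[float]] = {}
    for bundle in bundles:
        report = bundle["report"]
        if report.get("mean_torsion") is not None:
            exp = report["experiment"]
            by_protocol.setdefault(f"experiment{exp}", []).append(
                report["mean_torsion"])
        for label, n in bundle["samplesize"].get("required_n", {}).items():
            samplesize_rows.append({"protocol": label, "required_n": n,
                                    "config_hash": bundle["config_hash"]})
    for protocol, values in by_protocol.items():
        if not values:
            log.warning("no torsion values for %s; row omitted", protocol)
            continue
        arr = np.asarray(values, dtype=float)
        torsion_rows.append({
            "protocol": protocol,
            "mean_torsion_deg_per_cm": float(arr.mean()),
            "sd_torsion_deg_per_cm": float(arr.std(ddof=1)) if arr.size > 1 else 0.0,
            "n_runs": int(arr.size),
        })
    return {"torsion_table": torsion_rows, "sample_size_table": samplesize_rows}
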