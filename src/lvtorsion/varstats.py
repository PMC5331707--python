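"""Test-retest variability analysis of torsion measurements.

Implements the permutation/RMSE analysis of the enforced-variability protocol
(nine torsion permutations against a repeated reference pair) and the
consecutive-pairing analysis of the natural-variability protocol, together
with 95% limits of agreement, an exact binomial within-limits test, Pearson
correlation and paired t-tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .torsion import TwistCurve, torsion_curve

__all__ = [
    "PermutationSet",
    "VariabilityReport",
    "nine_permutations",
    "build_permutation_set",
    "rmse_consistent",
    "rmse_permutations",
    "limits_of_agreement",
    "binomial_within_limits",
    "consecutive_pairing",
    "pair_torsions",
    "protocol_sd_comparison",
    "correlate",
    "analyze_experiment1",
    "analyze_experiment2",
]

ENFORCED_WINDOWS = ("min", "mid", "max")


@dataclass
class PermutationSet:
    """Nine permutation torsions plus the repeated-reference pair, one subject."""

    nine_torsions: np.ndarray
    reference_pair: tuple[float, float]
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.nine_torsions = np.asarray(self.nine_torsions, dtype=float)
        if self.nine_torsions.size != 9:
            raise ValueError("exactly nine permutation torsions required")
        if len(self.reference_pair) != 2:
            raise ValueError("exactly two reference torsions required")


@dataclass
class VariabilityReport:
    """Summary statistics of one experiment's torsion variability."""

    experiment: int
    rmse_consistent: float | None = None
    rmse_permutations: float | None = None
    loa_halfwidth: float | None = None
    loa_breathhold: float | None = None
    loa_navigator: float | None = None
    sd_breathhold: float | None = None
    sd_navigator: float | None = None
    binomial_p: float | None = None
    binomial_k: int | None = None
    binomial_n: int | None = None
    pearson_r: float | None = None
    pearson_p: float | None = None
    ttest_p: float | None = None
    mean_torsion: float | None = None
    per_subject: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        out = {}
        for key, value in self.__dict__.items():
            if isinstance(value, np.floating):
                value = float(value)
            out[key] = value
        return out


# ---------------------------------------------------------------------------
# enforced-variability (permutation) statistics
# ---------------------------------------------------------------------------

def nine_permutations(basal, apical, d: float | None = None) -> np.ndarray:
    """Peak torsion for all 3x3 ordered (basal_i, apical_j) combinations.

    Inputs are either three :class:`TwistCurve` per slice (torsion computed
    from the full curves) or three peak twist angles in degrees, in which case
    ``d`` (cm) must be given.
    """
    if len(basal) != 3 or len(apical) != 3:
        raise ValueError("exactly three basal and three apical twists required")
    out = []
    for b in basal:
        for a in apical:
            if isinstance(b, TwistCurve) and isinstance(a, TwistCurve):
                out.append(torsion_curve(b, a).peak_torsion)
            else:
                if d is None:
                    raise ValueError("d (cm) required for scalar twists")
                out.append((float(a) - float(b)) / d)
    return np.asarray(out)


def build_permutation_set(twists: dict, subject_id: str = "") -> PermutationSet:
    """Assemble a :class:`PermutationSet` from per-window twist curves.

    ``twists`` maps ``(slice_label, window_label)`` to a :class:`TwistCurve`
    for windows 'min', 'mid', 'max' and 'mid_repeat'.
    """
    basal = [twists[("basal", w)] for w in ENFORCED_WINDOWS]
    apical = [twists[("apical", w)] for w in ENFORCED_WINDOWS]
    nine = nine_permutations(basal, apical)
    ref1 = torsion_curve(twists[("basal", "mid")],
                         twists[("apical", "mid")]).peak_torsion
    ref2 = torsion_curve(twists[("basal", "mid_repeat")],
                         twists[("apical", "mid_repeat")]).peak_torsion
    return PermutationSet(nine_torsions=nine, reference_pair=(ref1, ref2),
                          subject_id=subject_id)


def rmse_consistent(ref_pair) -> float:
    """Duplicate-measurement RMSE of the repeated reference pair: |x1-x2|/sqrt(2)."""
    x1, x2 = float(ref_pair[0]), float(ref_pair[1])
    return abs(x1 - x2) / np.sqrt(2.0)


def rmse_permutations(nine, ref_pair) -> float:
    """RMSE of the nine permutations against the two reference scans.

    The MSE is computed separately against each reference, the two MSEs are
    averaged, and the square root is taken.
    """
    nine = np.asarray(nine, dtype=float)
    if nine.size != 9:
        raise ValueError("exactly nine permutation torsions required")
    if len(ref_pair) != 2:
        raise ValueError("exactly two reference torsions required")
    mses = [np.mean((nine - float(r)) ** 2) for r in ref_pair]
    return float(np.sqrt(0.5 * (mses[0] + mses[1])))


def limits_of_agreement(differences) -> float:
    """95% limits-of-agreement half-width: 1.96 * SD(differences), ddof=1."""
    diffs = np.asarray(differences, dtype=float)
    if diffs.size < 2:
        raise ValueError("need at least two differences")
    return float(1.96 * np.std(diffs, ddof=1))


def binomial_within_limits(values, loa_halfwidth: float, centers) -> dict:
    """One-sided exact binomial test that values fall within the 95% limits.

    ``centers`` is either a scalar reference or one reference per value.  With
    ``k`` of ``N`` values inside the limits, the p-value is
    ``P(X <= k | N, 0.95)``.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 1:
        raise ValueError("need at least one value")
    centers = np.broadcast_to(np.asarray(centers, dtype=float), values.shape)
    inside = np.abs(values - centers) <= loa_halfwidth
    k = int(np.count_nonzero(inside))
    n = int(values.size)
    p = float(stats.binom.cdf(k, n, 0.95))
    return {"k": k, "n": n, "p": p}


# ---------------------------------------------------------------------------
# natural-variability (consecutive pairing) statistics
# ---------------------------------------------------------------------------

def consecutive_pairing(basal, apical) -> list[tuple]:
    """Pair each basal item with its two temporally closest apical items.

    Inputs are sequences of ``(temporal_slot, item)`` in an alternating
    acquisition order basal, apical, basal, apical, ...; each interior basal
    pairs with the apical acquired just before and just after it, and edge
    basal acquisitions pair with the two nearest available.  Returns ``2n``
    ``(basal_item, apical_item)`` pairings.
    """
    basal = list(basal)
    apical = list(apical)
    if len(basal) != len(apical) or len(basal) < 1:
        raise ValueError("need equal, non-empty basal and apical sequences")
    slots = sorted([(s, "b") for s, _ in basal] + [(s, "a") for s, _ in apical])
    expected = ["b", "a"] * len(basal)
    if [lab for _, lab in slots] != expected:
        raise ValueError("acquisitions must alternate basal, apical, ... in "
                         "temporal order")
    basal = sorted(basal, key=lambda t: t[0])
    apical = sorted(apical, key=lambda t: t[0])
    n = len(basal)
    pairs = []
    for i in range(n):
        if i == 0:
            partners = (0, 1) if n > 1 else (0, 0)
        else:
            partners = (i - 1, i)
        for j in partners:
            pairs.append((basal[i][1], apical[j][1]))
    return pairs


def pair_torsions(twists) -> list[float]:
    """Peak torsions of the consecutive pairings of one session.

    ``twists`` is the full list of :class:`TwistCurve` of one protocol in
    temporal order (alternating basal/apical, per ``acquisition_index``).
    """
    basal = [(t.acquisition_index, t) for t in twists if t.slice_label == "basal"]
    apical = [(t.acquisition_index, t) for t in twists if t.slice_label == "apical"]
    pairs = consecutive_pairing(basal, apical)
    return [torsion_curve(b, a).peak_torsion for b, a in pairs]


def protocol_sd_comparison(sds_a, sds_b) -> float:
    """Paired two-sided t-test p-value on per-subject torsion SDs."""
    a = np.asarray(sds_a, dtype=float)
    b = np.asarray(sds_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("unequal subject sets")
    diffs = a - b
    if np.allclose(np.std(diffs, ddof=0), 0.0):
        warnings.warn("zero variance of paired differences; returning p = 1",
                      stacklevel=2)
        return 1.0
    return float(stats.ttest_rel(a, b).pvalue)


def correlate(x, y) -> tuple[float, float]:
    """Pearson r with two-sided p-value from the t transform."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length inputs of size >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance input")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# experiment-level drivers
# ---------------------------------------------------------------------------

def analyze_experiment1(perm_sets, offset_ranges=None) -> VariabilityReport:
    """Variability report for the enforced-variability protocol.

    ``perm_sets`` is one :class:`PermutationSet` per subject;
    ``offset_ranges`` (optional) the observed per-subject end-expiratory
    position range in mm, for the RMSE-vs-range correlation.
    """
    perm_sets = list(perm_sets)
    if not perm_sets:
        raise ValueError("need at least one subject")
    rmse_c = np.array([rmse_consistent(p.reference_pair) for p in perm_sets])
    rmse_p = np.array([rmse_permutations(p.nine_torsions, p.reference_pair)
                       for p in perm_sets])
    report = VariabilityReport(experiment=1)
    report.rmse_consistent = float(rmse_c.mean())
    report.rmse_permutations = float(rmse_p.mean())
    report.mean_torsion = float(np.mean(
        [np.mean(p.reference_pair) for p in perm_sets]))
    if len(perm_sets) >= 2:
        ref_diffs = [p.reference_pair[0] - p.reference_pair[1] for p in perm_sets]
        report.loa_halfwidth = limits_of_agreement(ref_diffs)
        values = np.concatenate([p.nine_torsions for p in perm_sets])
        centers = np.repeat([np.mean(p.reference_pair) for p in perm_sets], 9)
        binom = binomial_within_limits(values, report.loa_halfwidth, centers)
        report.binomial_p = binom["p"]
        report.binomial_k = binom["k"]
        report.binomial_n = binom["n"]
        if np.std(rmse_p - rmse_c) > 0:
            report.ttest_p = protocol_sd_comparison(rmse_p, rmse_c)
    if offset_ranges is not None and len(perm_sets) >= 3:
        r, p = correlate(np.asarray(offset_ranges, dtype=float), rmse_p)
        report.pearson_r, report.pearson_p = r, p
    report.per_subject = {
        p.subject_id or str(i): {
            "rmse_consistent": float(rmse_c[i]),
            "rmse_permutations": float(rmse_p[i]),
            "reference_pair": [float(v) for v in p.reference_pair],
        }
        for i, p in enumerate(perm_sets)
    }
    return report


def analyze_experiment2(torsions_by_subject, offset_sds=None,
                        diff_mode: str = "successive") -> VariabilityReport:
    """Variability report for the natural-variability protocol.

    ``torsions_by_subject`` maps subject id to
    ``{"breathhold": [torsions...], "navigator": [torsions...]}`` with each
    list in temporal pairing order.  ``offset_sds`` (optional) maps subject id
    to per-protocol SD of the observed end-expiratory positions, for the
    pooled torsion-SD-vs-position-SD correlation.  ``diff_mode`` selects how
    limits of agreement differences are formed: 'successive' (differences of
    successive pairings, 2n-1 per subject) or 'disjoint' (differences of
    disjoint consecutive pairs, n per subject).
    """
    if diff_mode not in ("successive", "disjoint"):
        raise ValueError("diff_mode must be 'successive' or 'disjoint'")
    subjects = list(torsions_by_subject)
    if not subjects:
        raise ValueError("need at least one subject")
    report = VariabilityReport(experiment=2)
    sds = {"breathhold": [], "navigator": []}
    diffs = {"breathhold": [], "navigator": []}
    means = []
    for sid in subjects:
        for protocol in ("breathhold", "navigator"):
            vals = np.asarray(torsions_by_subject[sid][protocol], dtype=float)
            sds[protocol].append(float(np.std(vals, ddof=1)))
            if diff_mode == "successive":
                diffs[protocol].extend(np.diff(vals))
            else:
                pairs = vals[: 2 * (vals.size // 2)].reshape(-1, 2)
                diffs[protocol].extend(pairs[:, 0] - pairs[:, 1])
            means.append(float(vals.mean()))
    report.mean_torsion = float(np.mean(means))
    report.sd_breathhold = float(np.mean(sds["breathhold"]))
    report.sd_navigator = float(np.mean(sds["navigator"]))
    report.loa_breathhold = limits_of_agreement(diffs["breathhold"])
    report.loa_navigator = limits_of_agreement(diffs["navigator"])
    report.loa_halfwidth = report.loa_navigator
    if len(subjects) >= 2:
        report.ttest_p = protocol_sd_comparison(sds["breathhold"],
                                                sds["navigator"])
    if offset_sds is not None and len(subjects) >= 2:
        # pooled over both protocols: 2 points per subject
        x, y = [], []
        for i, sid in enumerate(subjects):
            for j, protocol in enumerate(("breathhold", "navigator")):
                x.append(offset_sds[sid][protocol])
                y.append(sds[protocol][i])
        r, p = correlate(x, y)
        report.pearson_r, report.pearson_p = r, p
    report.per_subject = {
        str(sid): {
            "sd_breathhold": sds["breathhold"][i],
            "sd_navigator": sds["navigator"][i],
        }
        for i, sid in enumerate(subjects)
    }
    return report
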