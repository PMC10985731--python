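"""Comparison statistics for validating the pipeline against raters and truth.

Covers mask IoU and instance matching against ground truth, detection and
live/dead F1, Earth Mover's (Wasserstein-1) distance between viability
distributions, Krippendorff's interval alpha for inter-rater reliability,
Pearson correlation matrices, and optimal binary cutoffs by F1 and by
Youden's J.

Sentinel handling: the -1 "no spheroids" value participates in the
presence/absence (ID) confusion analysis but is excluded from every
distributional statistic (EMD, alpha, Pearson) — it encodes absence, not a
viability.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .errors import ValidationError
from .segmentation import InstanceMask, SegmentationResult
from .viability import SENTINEL_NO_SPHEROID, classify_live_dead


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValidationError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class RaterSeries:
    """Paired per-item viability estimates from two raters/methods.

    Values lie in [0, 100]; the -1 sentinel marks "no spheroids" and is
    dropped by :meth:`paired_values` before any distributional statistic.
    """

    item_ids: list
    values_a: list[float]
    values_b: list[float]

    def __post_init__(self) -> None:
        if not (len(self.item_ids) == len(self.values_a) == len(self.values_b)):
            raise ValidationError("rater series lists must have equal length")

    def paired_values(self) -> tuple[np.ndarray, np.ndarray]:
        a = np.asarray(self.values_a, dtype=float)
        b = np.asarray(self.values_b, dtype=float)
        keep = (a != SENTINEL_NO_SPHEROID) & (b != SENTINEL_NO_SPHEROID) \
            & ~np.isnan(a) & ~np.isnan(b)
        return a[keep], b[keep]


# ---------------------------------------------------------------------------
# masks
# ---------------------------------------------------------------------------

def _as_bool(m) -> np.ndarray:
    if isinstance(m, InstanceMask):
        return m.mask
    return np.asarray(m, dtype=bool)


def mask_iou(a, b) -> float:
    """Intersection over union of two boolean masks; 1.0 when both empty."""
    ma, mb = _as_bool(a), _as_bool(b)
    if ma.shape != mb.shape:
        raise ValidationError(f"mask grids differ: {ma.shape} vs {mb.shape}")
    union = (ma | mb).sum()
    if union == 0:
        return 1.0
    return float((ma & mb).sum() / union)


def match_instances(pred, truth, iou_threshold: float = 0.5
                    ) -> tuple[list[tuple[int, int, float]], ConfusionCounts]:
    """Greedy one-to-one matching of predicted to true instances by IoU.

    ``pred`` is a SegmentationResult or list of masks; ``truth`` a
    GroundTruthScene or list of masks.  Pairs are taken in descending IoU
    (ties broken by prediction then truth index); pairs at or above the
    threshold are true positives, leftover predictions false positives,
    leftover truths false negatives.  Returns ``(pairs, counts)`` with
    pairs as ``(pred_index, truth_index, iou)``.
    """
    pred_masks = [_as_bool(i) for i in
                  (pred.instances if isinstance(pred, SegmentationResult) else pred)]
    truth_masks = [_as_bool(m) for m in getattr(truth, "instance_masks", truth)]
    ious = np.zeros((len(pred_masks), len(truth_masks)))
    for i, pm in enumerate(pred_masks):
        for j, tm in enumerate(truth_masks):
            ious[i, j] = mask_iou(pm, tm)
    order = sorted(
        ((i, j) for i in range(len(pred_masks)) for j in range(len(truth_masks))),
        key=lambda ij: (-ious[ij], ij[0], ij[1]))
    used_p: set[int] = set()
    used_t: set[int] = set()
    pairs: list[tuple[int, int, float]] = []
    for i, j in order:
        if ious[i, j] < iou_threshold:
            break
        if i in used_p or j in used_t:
            continue
        pairs.append((i, j, float(ious[i, j])))
        used_p.add(i)
        used_t.add(j)
    counts = ConfusionCounts(tp=len(pairs),
                             fp=len(pred_masks) - len(pairs),
                             fn=len(truth_masks) - len(pairs))
    return pairs, counts


# ---------------------------------------------------------------------------
# binary classification metrics
# ---------------------------------------------------------------------------

def f1_score(c: ConfusionCounts) -> float:
    """F1 of the positive class: ``2 tp / (2 tp + fp + fn)``."""
    denom = 2 * c.tp + c.fp + c.fn
    if denom == 0:
        raise ValidationError("F1 undefined with no positives in either source")
    return 2.0 * c.tp / denom


def accuracy(c: ConfusionCounts) -> float:
    if c.total == 0:
        raise ValidationError("accuracy undefined on empty counts")
    return (c.tp + c.tn) / c.total


def id_ld_confusion(pred: Mapping, truth: Mapping,
                    ld_threshold: float = 0.0) -> dict[str, ConfusionCounts]:
    """Presence (ID) and live/dead (LD) confusion counts over paired items.

    ``pred`` and ``truth`` map item id -> average viability with the -1
    sentinel for "no spheroids".  ID positive = spheroids present.  LD is
    evaluated only on items where truth has spheroids; a sentinel
    prediction there counts as a "dead" call (nothing viable detected).
    """
    if set(pred) != set(truth):
        raise ValidationError("prediction and truth items do not pair up")
    id_c = {"tp": 0, "fp": 0, "fn": 0, "tn": 0}
    ld_c = {"tp": 0, "fp": 0, "fn": 0, "tn": 0}
    for item in truth:
        t, p = float(truth[item]), float(pred[item])
        t_has, p_has = t != SENTINEL_NO_SPHEROID, p != SENTINEL_NO_SPHEROID
        key = {(True, True): "tp", (False, True): "fp",
               (True, False): "fn", (False, False): "tn"}[(t_has, p_has)]
        id_c[key] += 1
        if t_has:
            t_live = classify_live_dead(t, ld_threshold) == "live"
            p_live = p_has and classify_live_dead(p, ld_threshold) == "live"
            key = {(True, True): "tp", (False, True): "fp",
                   (True, False): "fn", (False, False): "tn"}[(t_live, p_live)]
            ld_c[key] += 1
    return {"ID": ConfusionCounts(**id_c), "LD": ConfusionCounts(**ld_c)}


# ---------------------------------------------------------------------------
# distributional statistics
# ---------------------------------------------------------------------------

def earth_movers_distance(x: Sequence[float], y: Sequence[float]) -> float:
    """Wasserstein-1 distance between viability samples rescaled to [0, 1].

    Rescaling by 1/100 puts the statistic on the unit interval, so two
    point masses at 0% and 100% are at distance exactly 1.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.size == 0 or ya.size == 0:
        raise ValidationError("EMD requires non-empty samples")
    if xa.min() < 0 or xa.max() > 100 or ya.min() < 0 or ya.max() > 100:
        raise ValidationError("viability samples must lie in [0, 100]; "
                              "drop sentinels upstream")
    return float(sps.wasserstein_distance(xa / 100.0, ya / 100.0))


def krippendorff_alpha(ratings, level: str = "interval") -> float:
    """Krippendorff's alpha with the interval (squared-difference) metric.

    ``ratings`` is a RaterSeries or an (items x raters) array with NaN for
    missing values.  Units with fewer than two ratings are dropped.  Alpha
    is ``1 - D_o / D_e`` computed from the coincidence construction; if all
    pairable values are identical the expected disagreement is zero and
    alpha is defined as 1.0.  Values at or below 0 indicate systematic
    disagreement.
    """
    if level != "interval":
        raise ValidationError("only the interval metric is supported")
    if isinstance(ratings, RaterSeries):
        a, b = ratings.paired_values()
        table = np.column_stack([a, b]) if a.size else np.empty((0, 2))
    else:
        table = np.asarray(ratings, dtype=float)
    units = [row[~np.isnan(row)] for row in table]
    units = [u for u in units if u.size >= 2]
    if len(units) < 2:
        raise ValidationError("alpha requires at least two pairable units")

    values = np.concatenate(units)
    n = values.size
    # observed disagreement: within-unit ordered pairs, each unit weighted
    # by 1/(m_u - 1) per the coincidence-matrix construction
    d_obs = 0.0
    for u in units:
        m = u.size
        diff = u[:, None] - u[None, :]
        d_obs += (diff**2).sum() / (m - 1)
    d_obs /= n
    # expected disagreement: all ordered pairs of pairable values
    diff_all = values[:, None] - values[None, :]
    d_exp = (diff_all**2).sum() / (n * (n - 1))
    if d_exp == 0.0:
        return 1.0
    return float(1.0 - d_obs / d_exp)


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation; errors on degenerate input."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.size != ya.size or xa.size < 2:
        raise ValidationError("pearson_r requires paired samples of size >= 2")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise ValidationError("pearson_r undefined for zero-variance input")
    return float(sps.pearsonr(xa, ya).statistic)


def pearson_matrix(methods: Mapping[str, Sequence[float]]):
    """Full method x method Pearson correlation matrix as a DataFrame."""
    import pandas as pd

    names = list(methods)
    mat = np.eye(len(names))
    for i, a in enumerate(names):
        for j, b in enumerate(names):
            if i < j:
                mat[i, j] = mat[j, i] = pearson_r(methods[a], methods[b])
    return pd.DataFrame(mat, index=names, columns=names)


def quantize_expert(viability: float, step: float = 10.0) -> float:
    """Round to the nearest ``step`` percent, emulating coarse expert calls."""
    return float(np.clip(round(viability / step) * step, 0.0, 100.0))


# ---------------------------------------------------------------------------
# threshold scans
# ---------------------------------------------------------------------------

def _candidate_thresholds(scores: np.ndarray) -> np.ndarray:
    """0 plus all midpoints between adjacent distinct scores."""
    distinct = np.unique(scores)
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    return np.unique(np.concatenate([[0.0], mids]))


def _validate_two_class(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    s = np.asarray(scores, dtype=float)
    lab = np.asarray([1 if l in ("live", 1, True) else 0 for l in labels])
    if s.size != lab.size or s.size == 0:
        raise ValidationError("scores and labels must pair up")
    if lab.min() == lab.max():
        raise ValidationError("threshold scans require both classes present")
    return s, lab


def f1_optimal_threshold(scores: Sequence[float],
                         labels: Sequence) -> tuple[float, float]:
    """Scan candidate cutoffs and return ``(threshold, best_f1)``.

    Classification rule: live iff ``score > threshold``.  Candidates are 0
    plus midpoints between adjacent distinct scores; ties resolve to the
    smallest threshold.
    """
    s, lab = _validate_two_class(scores, labels)
    best_t, best_f1 = 0.0, -1.0
    for t in _candidate_thresholds(s):
        pred = s > t
        tp = int((pred & (lab == 1)).sum())
        fp = int((pred & (lab == 0)).sum())
        fn = int((~pred & (lab == 1)).sum())
        denom = 2 * tp + fp + fn
        f1 = 2.0 * tp / denom if denom else 0.0
        if f1 > best_f1 + 1e-12:
            best_t, best_f1 = float(t), f1
    return best_t, best_f1


def youden_optimal_threshold(scores: Sequence[float],
                             labels: Sequence) -> tuple[float, float]:
    """Maximize Youden's J = sensitivity + specificity - 1 over the same grid."""
    s, lab = _validate_two_class(scores, labels)
    n_pos = int((lab == 1).sum())
    n_neg = int((lab == 0).sum())
    best_t, best_j = 0.0, -np.inf
    for t in _candidate_thresholds(s):
        pred = s > t
        sens = int((pred & (lab == 1)).sum()) / n_pos
        spec = int((~pred & (lab == 0)).sum()) / n_neg
        j = sens + spec - 1.0
        if j > best_j + 1e-12:
            best_t, best_j = float(t), j
    return best_t, best_j
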