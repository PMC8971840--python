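"""ROC/AUC machinery and cohort-table statistics.

The AUC is the Mann–Whitney U probability (ties counted 1/2); its variance
and the paired comparison of two correlated AUCs use the DeLong structural
components — the method MedCalc-style ROC software implements.  Summary-
statistic t-tests (pooled Student), Pearson chi-square and Fisher's exact
test cover the cohort-characteristics table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.metrics import roc_auc_score

__all__ = [
    "PredictionSet",
    "RocResult",
    "SummaryStats",
    "roc_auc",
    "threshold_metrics",
    "youden_threshold",
    "delong_test",
    "ttest_from_summary",
    "chi_square_2x2",
    "fisher_exact",
]


@dataclass(frozen=True)
class PredictionSet:
    """Per-case (id, binary label, malignancy score) triples."""

    case_ids: tuple[str, ...]
    labels: np.ndarray  # int {0, 1}
    scores: np.ndarray  # float in [0, 1]

    def __post_init__(self):
        labels = np.asarray(self.labels, dtype=np.int64)
        scores = np.asarray(self.scores, dtype=np.float64)
        if not (len(self.case_ids) == len(labels) == len(scores)):
            raise ValueError("case_ids, labels and scores must have equal length")
        if len(set(self.case_ids)) != len(self.case_ids):
            raise ValueError("case_ids must be unique")
        if not np.isin(labels, (0, 1)).all():
            raise ValueError("labels must be 0 or 1")
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "scores", scores)

    @classmethod
    def from_predictions(cls, preds) -> "PredictionSet":
        """Build from a list of ModelPrediction-like objects."""
        return cls(
            case_ids=tuple(p.case_id for p in preds),
            labels=np.array([p.label for p in preds]),
            scores=np.array([p.score for p in preds]),
        )

    @property
    def n_pos(self) -> int:
        return int(self.labels.sum())

    @property
    def n_neg(self) -> int:
        return int(len(self.labels) - self.labels.sum())


@dataclass(frozen=True)
class RocResult:
    auc: float
    ci_low: float
    ci_high: float
    n_pos: int
    n_neg: int


@dataclass(frozen=True)
class SummaryStats:
    """Group summary (n, mean, sd) as printed in a cohort table."""

    n: int
    mean: float
    sd: float

    def __post_init__(self):
        if self.n < 2:
            raise ValueError("n must be >= 2")
        if self.sd < 0:
            raise ValueError("sd must be nonnegative")


# ---------------------------------------------------------------------------
# DeLong structural components
# ---------------------------------------------------------------------------

def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _delong_components(labels: np.ndarray, scores: np.ndarray):
    """Placement values V10 (per positive) and V01 (per negative)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    all_ranks = _midrank(np.concatenate([pos, neg]))
    pos_ranks = _midrank(pos)
    neg_ranks = _midrank(neg)
    v10 = (all_ranks[:m] - pos_ranks) / n
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m
    auc = v10.mean()
    return auc, v10, v01


def _check_two_classes(preds: PredictionSet):
    if preds.n_pos == 0 or preds.n_neg == 0:
        raise ValueError("ROC requires at least one case of each class")


def roc_auc(preds: PredictionSet, *, ci_level: float = 0.95) -> RocResult:
    """AUC with a DeLong confidence interval.

    The point estimate is the Mann–Whitney statistic (ties 1/2); the CI is
    ``auc ± z * se`` with the DeLong variance, clipped to [0, 1].
    """
    _check_two_classes(preds)
    auc = float(roc_auc_score(preds.labels, preds.scores))
    _, v10, v01 = _delong_components(preds.labels, preds.scores)
    # a class with a single case has no placement variance to estimate
    var_pos = v10.var(ddof=1) / len(v10) if len(v10) > 1 else 0.0
    var_neg = v01.var(ddof=1) / len(v01) if len(v01) > 1 else 0.0
    var = var_pos + var_neg
    z = stats.norm.ppf(0.5 + ci_level / 2)
    half = z * math.sqrt(max(var, 0.0))
    return RocResult(
        auc=auc,
        ci_low=max(0.0, auc - half),
        ci_high=min(1.0, auc + half),
        n_pos=preds.n_pos,
        n_neg=preds.n_neg,
    )


def threshold_metrics(
    preds: PredictionSet, threshold: float = 0.5
) -> tuple[float, float, float]:
    """(sensitivity, specificity, accuracy) with score >= threshold positive."""
    calls = preds.scores >= threshold
    y = preds.labels.astype(bool)
    tp = int(np.count_nonzero(calls & y))
    fn = int(np.count_nonzero(~calls & y))
    tn = int(np.count_nonzero(~calls & ~y))
    fp = int(np.count_nonzero(calls & ~y))
    sens = tp / (tp + fn) if tp + fn else float("nan")
    spec = tn / (tn + fp) if tn + fp else float("nan")
    acc = (tp + tn) / len(y)
    return sens, spec, acc


def youden_threshold(preds: PredictionSet) -> float:
    """Operating point maximizing Youden's J = sensitivity + specificity - 1.

    Candidate thresholds are the observed scores; ties broken toward the
    lower threshold (higher sensitivity).
    """
    _check_two_classes(preds)
    best_t, best_j = 0.5, -np.inf
    for t in sorted(set(preds.scores)):
        sens, spec, _ = threshold_metrics(preds, t)
        j = sens + spec - 1
        if j > best_j:
            best_t, best_j = float(t), j
    return best_t


def metrics_from_counts(tp: int, fn: int, tn: int, fp: int) -> tuple[float, float, float]:
    """Sensitivity/specificity/accuracy straight from confusion counts."""
    return (
        tp / (tp + fn),
        tn / (tn + fp),
        (tp + tn) / (tp + fn + tn + fp),
    )


def delong_test(
    preds_a: PredictionSet, preds_b: PredictionSet
) -> tuple[float, float, float]:
    """Paired DeLong test for two correlated ROC curves on the same cases.

    Returns ``(auc_a, auc_b, p_two_sided)``.  The variance of the AUC
    difference uses the covariance of the placement values; a numerically
    zero variance with zero difference yields p = 1.
    """
    if preds_a.case_ids != preds_b.case_ids or not np.array_equal(
        preds_a.labels, preds_b.labels
    ):
        raise ValueError("prediction sets must cover identical cases and labels")
    _check_two_classes(preds_a)
    auc_a, v10_a, v01_a = _delong_components(preds_a.labels, preds_a.scores)
    auc_b, v10_b, v01_b = _delong_components(preds_b.labels, preds_b.scores)
    m, n = len(v10_a), len(v01_a)
    s10 = np.cov(np.stack([v10_a, v10_b]), ddof=1)
    s01 = np.cov(np.stack([v01_a, v01_b]), ddof=1)
    var = (
        s10[0, 0] / m + s10[1, 1] / m - 2 * s10[0, 1] / m
        + s01[0, 0] / n + s01[1, 1] / n - 2 * s01[0, 1] / n
    )
    diff = auc_a - auc_b
    if not math.isfinite(var) or var <= 1e-16:
        p = 1.0 if abs(diff) < 1e-12 else 0.0
    else:
        z = diff / math.sqrt(var)
        p = float(2 * stats.norm.sf(abs(z)))
    return float(auc_a), float(auc_b), p


# ---------------------------------------------------------------------------
# cohort-table statistics
# ---------------------------------------------------------------------------

def ttest_from_summary(
    a: SummaryStats, b: SummaryStats
) -> tuple[float, int, float]:
    """Pooled-variance Student's t from group summaries.

    Returns ``(t, df, p_two_sided)`` with ``df = n1 + n2 - 2``.  Degenerate
    zero-variance input: equal means give p = 1, unequal means p = 0.
    """
    df = a.n + b.n - 2
    if a.sd == 0 and b.sd == 0:
        return (0.0, df, 1.0) if a.mean == b.mean else (math.inf, df, 0.0)
    t, p = stats.ttest_ind_from_stats(
        a.mean, a.sd, a.n, b.mean, b.sd, b.n, equal_var=True
    )
    return float(t), df, float(p)


def chi_square_2x2(table) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 table, df=1, no continuity correction."""
    tab = np.asarray(table, dtype=np.float64)
    if tab.shape != (2, 2) or (tab < 0).any():
        raise ValueError("table must be 2x2 with nonnegative counts")
    if (tab.sum(axis=0) == 0).any() or (tab.sum(axis=1) == 0).any():
        raise ValueError("chi-square undefined with a zero marginal")
    chi2, p, _, _ = stats.chi2_contingency(tab, correction=False)
    return float(chi2), float(p)


def fisher_exact(table) -> float:
    """Two-sided Fisher exact p on a 2x2 table (hypergeometric)."""
    tab = np.asarray(table, dtype=np.int64)
    if tab.shape != (2, 2) or (tab < 0).any():
        raise ValueError("table must be 2x2 with nonnegative integer counts")
    _, p = stats.fisher_exact(tab, alternative="two-sided")
    return float(p)
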