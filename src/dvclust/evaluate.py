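"""Agreement and error metrics between true and detected cluster labels.

The headline metric is the pair-counting Jaccard index between two
partitions of the probes: over all probe pairs, ``J = n11 / (n11 + n10 +
n01)`` where ``n11`` counts pairs co-clustered in both partitions and
``n10``/``n01`` pairs co-clustered in only one.  It is 1 for identical
clusterings and near its permutation-null mean for chance agreement.
FPR/FNR collapse the three labels to DV (OV or UV) versus non-DV (EV).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.metrics.cluster import pair_confusion_matrix

__all__ = ["EvalMetrics", "jaccard_index", "fpr", "fnr", "wilcoxon_signed_rank", "evaluate_call"]

_DV_LABELS = frozenset({"OV", "UV"})


@dataclass
class EvalMetrics:
    jaccard: float
    fpr: float
    fnr: float


def _check_lengths(a, b):
    a = np.asarray(a, dtype=object)
    b = np.asarray(b, dtype=object)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("label vectors must be 1-D and of equal length")
    return a, b


def jaccard_index(true_labels, pred_labels) -> float:
    """Pair-counting Jaccard index between two partitions."""
    a, b = _check_lengths(true_labels, pred_labels)
    if a.size < 2:
        raise ValueError("need at least 2 items")
    # pair_confusion_matrix counts ordered pairs: C[1,1] = 2 n11, etc.
    c = pair_confusion_matrix(a.astype(str), b.astype(str))
    n11, n10, n01 = c[1, 1], c[1, 0], c[0, 1]
    denom = n11 + n10 + n01
    return float(n11 / denom) if denom else 1.0


def fpr(true_labels, pred_labels) -> float:
    """Fraction of truly non-DV (EV) probes called DV."""
    t, p = _check_lengths(true_labels, pred_labels)
    null = t == "EV"
    if not np.any(null):
        warnings.warn("no true non-DV probes; FPR undefined", stacklevel=2)
        return np.nan
    called_dv = np.isin(p, list(_DV_LABELS))
    return float(np.mean(called_dv[null]))


def fnr(true_labels, pred_labels) -> float:
    """Fraction of truly DV (OV or UV) probes called non-DV."""
    t, p = _check_lengths(true_labels, pred_labels)
    dv = np.isin(t, list(_DV_LABELS))
    if not np.any(dv):
        warnings.warn("no true DV probes; FNR undefined", stacklevel=2)
        return np.nan
    return float(np.mean(p[dv] == "EV"))


def evaluate_call(true_labels, pred_labels) -> EvalMetrics:
    """All three metrics for one detection run."""
    return EvalMetrics(
        jaccard=jaccard_index(true_labels, pred_labels),
        fpr=fpr(true_labels, pred_labels),
        fnr=fnr(true_labels, pred_labels),
    )


def wilcoxon_signed_rank(paired_a, paired_b) -> float:
    """Two-sided Wilcoxon signed-rank p value for paired samples.

    Zero differences are dropped; the null distribution is exact for up to
    25 nonzero differences (falling back to the normal approximation when
    ties make the exact distribution unavailable) and a continuity-corrected
    normal approximation beyond that.  All-zero differences give p = 1.
    """
    a = np.asarray(paired_a, dtype=float)
    b = np.asarray(paired_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired vectors must be 1-D and of equal length")
    d = a - b
    nz = d[d != 0]
    if nz.size == 0:
        warnings.warn("all paired differences are zero", stacklevel=2)
        return 1.0
    if nz.size < 5:
        raise ValueError("need at least 5 nonzero differences")
    method = "exact" if nz.size <= 25 else "approx"
    try:
        res = stats.wilcoxon(
            nz, alternative="two-sided", method=method, correction=(method == "approx")
        )
    except ValueError:  # ties with the exact method
        res = stats.wilcoxon(nz, alternative="two-sided", method="approx", correction=True)
    return float(res.pvalue)
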