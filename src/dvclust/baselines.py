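"""Probe-wise equal-variance tests with BH-FDR adjustment.

These are the classical two-group detectors the model-based method is
compared against: the variance-ratio F test and the Levene family
(mean-, median- and trimmed-mean-centered absolute-deviation ANOVAs).
A probe is called differentially variable when its BH-adjusted p value
falls below alpha; flagged probes are labeled OV or UV by the sign of
``s_c^2 - s_n^2``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .model import DVCall, ExpressionDataset

__all__ = [
    "TestResult",
    "f_test",
    "levene_family_test",
    "bh_adjust",
    "probewise_detect",
    "PROBEWISE_TESTS",
]

_LEVENE_CENTERS = {"mean": "mean", "median": "median", "trimmed_mean": "trimmed"}
#: Test names accepted by :func:`probewise_detect`.
PROBEWISE_TESTS = ("F", "L", "BF", "Ltrim")
_TRIM_FRACTION = 0.1


@dataclass
class TestResult:
    statistic: float
    p_value: float
    direction: int
    p_adjusted: float = np.nan


def _direction(case_values: np.ndarray, control_values: np.ndarray) -> int:
    s_c2 = np.var(case_values, ddof=1)
    s_n2 = np.var(control_values, ddof=1)
    return int(np.sign(s_c2 - s_n2))


def f_test(case_values, control_values) -> TestResult:
    """Two-sided F test of equal variances.

    The statistic is the variance ratio ``s_c^2 / s_n^2``; the two-sided p
    value is twice the smaller tail of ``F(m_c - 1, m_n - 1)``, capped at 1.
    Zero variance in either group yields a NaN p value with a warning.
    """
    x = np.asarray(case_values, dtype=float)
    y = np.asarray(control_values, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 values")
    s_c2, s_n2 = np.var(x, ddof=1), np.var(y, ddof=1)
    if s_c2 == 0 or s_n2 == 0:
        warnings.warn("zero variance in a group; F test undefined", stacklevel=2)
        return TestResult(np.nan, np.nan, _direction(x, y))
    stat = s_c2 / s_n2
    dist = stats.f(x.size - 1, y.size - 1)
    p = min(1.0, 2.0 * min(dist.cdf(stat), dist.sf(stat)))
    return TestResult(float(stat), float(p), _direction(x, y))


def levene_family_test(case_values, control_values, center: str = "median") -> TestResult:
    """Levene-family equal-variance test.

    A one-way ANOVA F test on absolute deviations from a per-group center:
    the group mean (Levene), median (Brown-Forsythe) or 10%-trimmed mean.
    The p value comes from ``F(1, m - 2)``.
    """
    if center not in _LEVENE_CENTERS:
        raise ValueError(f"center must be one of {sorted(_LEVENE_CENTERS)}")
    x = np.asarray(case_values, dtype=float)
    y = np.asarray(control_values, dtype=float)
    if x.size < 3 or y.size < 3:
        raise ValueError("each group needs at least 3 values")
    if np.ptp(x) == 0 and np.ptp(y) == 0:
        warnings.warn("constant groups; Levene test undefined", stacklevel=2)
        return TestResult(np.nan, np.nan, 0)
    stat, p = stats.levene(
        x, y, center=_LEVENE_CENTERS[center], proportiontocut=_TRIM_FRACTION
    )
    return TestResult(float(stat), float(p), _direction(x, y))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values, order preserved.

    NaN entries are excluded from the adjustment and restored as NaN.
    """
    p = np.asarray(p_values, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    if np.any((p[ok] < 0) | (p[ok] > 1)):
        raise ValueError("p values must lie in [0, 1]")
    if ok.sum():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def probewise_detect(
    data: ExpressionDataset, test: str = "F", alpha: float = 0.05
) -> tuple[DVCall, np.ndarray]:
    """Run one probe-wise test on every probe and flag DV probes.

    Probes with BH-adjusted p < ``alpha`` are flagged; flagged probes are
    labeled OV when the case sample variance exceeds the control one and UV
    otherwise, so the call is comparable to the three-cluster output of the
    model-based detector.  Returns the call and the adjusted p values
    (NaN where the test was undefined; such probes are never flagged).
    """
    if test not in PROBEWISE_TESTS:
        raise ValueError(f"test must be one of {PROBEWISE_TESTS}")
    case, control = data.case_values, data.control_values
    if test == "F":
        s_c2 = case.var(axis=1, ddof=1)
        s_n2 = control.var(axis=1, ddof=1)
        p = np.full(data.n_probes, np.nan)
        good = (s_c2 > 0) & (s_n2 > 0)
        stat = s_c2[good] / s_n2[good]
        dist = stats.f(data.m_c - 1, data.m_n - 1)
        p[good] = np.minimum(1.0, 2.0 * np.minimum(dist.cdf(stat), dist.sf(stat)))
    else:
        center = {"L": "mean", "BF": "median", "Ltrim": "trimmed_mean"}[test]
        p = np.empty(data.n_probes)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for g in range(data.n_probes):
                p[g] = levene_family_test(case[g], control[g], center=center).p_value
    p_adj = bh_adjust(p)
    s_c2, s_n2 = data.sample_variances()
    directions = np.sign(s_c2 - s_n2).astype(int)
    flagged = np.zeros(data.n_probes, dtype=bool)
    ok = ~np.isnan(p_adj)
    flagged[ok] = p_adj[ok] < alpha
    labels = np.full(data.n_probes, "EV", dtype=object)
    labels[flagged & (directions > 0)] = "OV"
    labels[flagged & (directions < 0)] = "UV"
    dv_flags = labels != "EV"
    return DVCall(list(data.probe_ids), labels, dv_flags, directions), p_adj
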