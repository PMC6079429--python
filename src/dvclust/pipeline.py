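"""Preprocessing and the discovery-to-validation workflow.

Raw expression matrices are made approximately normal by one shared Box-Cox
transform (a single lambda estimated by profile maximum likelihood over all
matrix entries, after shifting if any value is nonpositive), then each probe
row is centered to mean 0 and scaled to unit variance.

A probe detected as differentially variable (DV) in a discovery cohort
counts as validated when it is DV in the validation cohort with the same
sign of the sample-variance difference; the validation rate is
``pValid = n12 / n1``.  Its sampling variation is assessed by resampling
subjects with replacement within each group, independently in both cohorts,
and rerunning the detection end to end.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
import numpy as np
import pandas as pd
from scipy import stats

from .baselines import PROBEWISE_TESTS, probewise_detect
from .em import FitConfig, detect_dv
from .model import DVCall, ExpressionDataset

__all__ = [
    "PreprocessRecord",
    "ValidationResult",
    "preprocess",
    "row_standardize",
    "validate_dv",
    "bootstrap_validation_rates",
    "run_detector",
]

logger = logging.getLogger(__name__)


@dataclass
class PreprocessRecord:
    """What preprocessing did, sufficient to reapply or audit it."""

    boxcox_lambda: float
    shift: float
    per_probe_center: np.ndarray
    per_probe_scale: np.ndarray
    dropped_probes: list[str]


@dataclass
class ValidationResult:
    """Discovery-vs-validation agreement summary.

    ``n1`` discovery DV probes, ``n12`` of them DV with matching variance
    sign in validation, ``p_valid = n12/n1`` (NaN when n1 = 0).
    """

    n1: int
    n12: int
    p_valid: float
    per_probe: pd.DataFrame


def preprocess(data: ExpressionDataset) -> tuple[ExpressionDataset, PreprocessRecord]:
    """Box-Cox transform (one pooled lambda) then per-probe center/scale.

    Rows that are constant after the transform have no defined scale and
    are dropped with a warning.
    """
    flat = data.values.ravel()
    shift = 0.0
    if flat.min() <= 0:
        shift = 1.0 - flat.min()
    transformed, lam = stats.boxcox(flat + shift)
    values = transformed.reshape(data.values.shape)
    center = values.mean(axis=1)
    scale = values.std(axis=1, ddof=1)
    keep = scale > 0
    dropped = [p for p, k in zip(data.probe_ids, keep) if not k]
    if dropped:
        warnings.warn(
            f"dropping {len(dropped)} constant probe rows: {dropped[:5]}", stacklevel=2
        )
    values = (values[keep] - center[keep, None]) / scale[keep, None]
    out = ExpressionDataset(
        values, [p for p, k in zip(data.probe_ids, keep) if k], data.group.copy()
    )
    record = PreprocessRecord(float(lam), shift, center, scale, dropped)
    return out, record


def row_standardize(data: ExpressionDataset) -> ExpressionDataset:
    """Re-center and re-scale each probe row to mean 0, variance 1."""
    center = data.values.mean(axis=1)
    scale = data.values.std(axis=1, ddof=1)
    scale[scale == 0] = 1.0
    return ExpressionDataset(
        (data.values - center[:, None]) / scale[:, None],
        list(data.probe_ids),
        data.group.copy(),
    )


def validate_dv(discovery: DVCall, validation: DVCall) -> ValidationResult:
    """Count discovery DV probes replicated (same sign) in validation.

    Probes are matched by id; only the intersection is scored and any
    mismatch is logged.
    """
    disc = {p: i for i, p in enumerate(discovery.probe_ids)}
    vali = {p: i for i, p in enumerate(validation.probe_ids)}
    shared = [p for p in discovery.probe_ids if p in vali]
    n_only = (len(disc) - len(shared)) + (len(vali) - len(shared))
    if n_only:
        logger.info("validate_dv: %d probes outside the id intersection ignored", n_only)
    rows = []
    for p in shared:
        i, j = disc[p], vali[p]
        dv_d = bool(discovery.dv_flags[i])
        dv_v = bool(validation.dv_flags[j])
        s_d = int(discovery.directions[i])
        s_v = int(validation.directions[j])
        rows.append((p, dv_d, dv_v, s_d, s_v, dv_d and dv_v and s_d == s_v))
    per_probe = pd.DataFrame(
        rows,
        columns=[
            "probe_id",
            "dv_discovery",
            "dv_validation",
            "sign_discovery",
            "sign_validation",
            "validated",
        ],
    )
    n1 = int(per_probe["dv_discovery"].sum())
    n12 = int(per_probe["validated"].sum())
    if n1 == 0:
        warnings.warn("no DV probes in discovery; validation rate undefined", stacklevel=2)
        p_valid = np.nan
    else:
        p_valid = n12 / n1
    return ValidationResult(n1, n12, p_valid, per_probe)


def run_detector(
    data: ExpressionDataset,
    method: str = "gs",
    alpha: float = 0.05,
    config: FitConfig | None = None,
) -> DVCall:
    """Dispatch to the model-based detector ("gs") or a probe-wise test."""
    if method == "gs":
        call, _ = detect_dv(data, config)
        return call
    if method in PROBEWISE_TESTS:
        call, _ = probewise_detect(data, test=method, alpha=alpha)
        return call
    raise ValueError(f"unknown method {method!r}; choose 'gs' or one of {PROBEWISE_TESTS}")


def bootstrap_validation_rates(
    discovery: ExpressionDataset,
    validation: ExpressionDataset,
    method: str = "gs",
    B: int = 100,
    seed: int = 0,
    alpha: float = 0.05,
    config: FitConfig | None = None,
    resample: bool = True,
) -> np.ndarray:
    """Bootstrap distribution of the validation rate pValid.

    Each replicate resamples subjects with replacement within each group,
    independently in the discovery and validation cohorts, re-standardizes
    probe rows, reruns the detector on both, and recomputes pValid.  The
    pooled Box-Cox step is not repeated; both inputs are expected to be
    preprocessed already.  ``resample=False`` keeps the original subjects
    (a consistency hook: B identical non-bootstrap rates).
    """
    if B < 1:
        raise ValueError("B must be at least 1")
    rng = np.random.default_rng(seed)
    rates = np.empty(B)
    for b in range(B):
        pair = []
        for ds in (discovery, validation):
            if resample:
                cols = np.arange(ds.m)
                case_idx = cols[ds.group == "case"]
                ctrl_idx = cols[ds.group == "control"]
                take = np.concatenate(
                    [rng.choice(case_idx, size=case_idx.size, replace=True),
                     rng.choice(ctrl_idx, size=ctrl_idx.size, replace=True)]
                )
                ds = ExpressionDataset(
                    ds.values[:, take], list(ds.probe_ids), ds.group[take]
                )
            pair.append(row_standardize(ds))
        fit_cfg = config
        if method == "gs":
            sub_seed = int(rng.integers(2**31))
            fit_cfg = FitConfig(seed=sub_seed) if config is None else FitConfig(
                tol=config.tol,
                max_iter=config.max_iter,
                n_starts=config.n_starts,
                seed=sub_seed,
                init_method=config.init_method,
            )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            call_d = run_detector(pair[0], method, alpha, fit_cfg)
            call_v = run_detector(pair[1], method, alpha, fit_cfg)
            rates[b] = validate_dv(call_d, call_v).p_valid
    return rates
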