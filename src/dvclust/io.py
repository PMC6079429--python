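"""Reading and writing the flat-file formats used by the workflow.

Expression matrices travel as TSV/CSV with probe ids in the first column
and sample ids in the header.  Group membership comes either from a
two-column sample-annotation file (sample_id, group) or from a naming
convention: a sample id whose first underscore-separated token is ``case``
or ``control`` (e.g. ``case_01``).
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .model import CASE, CONTROL, DVCall, ExpressionDataset, MixtureModel

__all__ = [
    "read_expression_tsv",
    "write_expression_tsv",
    "read_labels_tsv",
    "write_labels_tsv",
    "write_call_tsv",
    "write_model_params",
    "read_sample_annotation",
]

logger = logging.getLogger(__name__)


def _sep_for(path: str | Path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def read_sample_annotation(path: str | Path) -> dict[str, str]:
    """Two-column (sample_id, group) table; groups must be case/control."""
    df = pd.read_csv(path, sep=_sep_for(path), header=None, comment="#", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (sample_id, group)")
    if set(df.iloc[0]) & {"sample_id", "group"}:
        df = df.iloc[1:]
    mapping = dict(zip(df.iloc[:, 0], df.iloc[:, 1]))
    bad = sorted({g for g in mapping.values() if g not in (CASE, CONTROL)})
    if bad:
        raise ValueError(f"{path}: unknown group labels {bad}")
    return mapping


def _group_from_name(sample_id: str) -> str | None:
    head = sample_id.split("_")[0].lower()
    return head if head in (CASE, CONTROL) else None


def read_expression_tsv(
    path: str | Path, annotation: str | Path | dict[str, str] | None = None
) -> ExpressionDataset:
    """Read a probe-by-sample matrix with group labels.

    Raises a descriptive error on duplicate probe ids, non-numeric cells or
    samples whose group cannot be determined.
    """
    sep = _sep_for(path)
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    dupes = df.index[df.index.duplicated()].unique().tolist()
    if dupes:
        raise ValueError(f"{path}: duplicate probe ids {dupes[:5]}")
    try:
        values = df.to_numpy(dtype=float)
    except ValueError:
        for i, row in enumerate(df.itertuples(index=True)):
            for cell in row[1:]:
                try:
                    float(cell)
                except (TypeError, ValueError):
                    raise ValueError(
                        f"{path}: non-numeric cell {cell!r} at data line {i + 2} "
                        f"(probe {row[0]!r})"
                    ) from None
        raise
    if isinstance(annotation, (str, Path)):
        annotation = read_sample_annotation(annotation)
    groups = []
    missing = []
    for sid in df.columns:
        g = annotation.get(sid) if annotation else _group_from_name(sid)
        if g is None:
            missing.append(sid)
        groups.append(g)
    if missing:
        raise ValueError(f"{path}: no group annotation for samples {missing[:5]}")
    return ExpressionDataset(values, [str(p) for p in df.index], np.array(groups, dtype=object))


def write_expression_tsv(path: str | Path, data: ExpressionDataset) -> None:
    """Write a dataset so that read_expression_tsv round-trips it."""
    counters = {CASE: 0, CONTROL: 0}
    cols = []
    for g in data.group:
        counters[g] += 1
        cols.append(f"{g}_{counters[g]:02d}")
    df = pd.DataFrame(data.values, index=data.probe_ids, columns=cols)
    df.index.name = "probe_id"
    df.to_csv(path, sep=_sep_for(path), float_format="%.17g")


def read_labels_tsv(path: str | Path) -> tuple[list[str], np.ndarray]:
    df = pd.read_csv(path, sep=_sep_for(path))
    return df.iloc[:, 0].astype(str).tolist(), df.iloc[:, 1].to_numpy(dtype=object)


def write_labels_tsv(path: str | Path, probe_ids, labels) -> None:
    pd.DataFrame({"probe_id": probe_ids, "label": labels}).to_csv(
        path, sep=_sep_for(path), index=False
    )


def write_call_tsv(path: str | Path, call: DVCall, extra: dict | None = None) -> None:
    """Per-probe detection table: label, DV flag, variance-difference sign."""
    table = {
        "probe_id": call.probe_ids,
        "label": call.labels,
        "dv": call.dv_flags.astype(int),
        "direction": call.directions,
    }
    if extra:
        table.update(extra)
    pd.DataFrame(table).to_csv(path, sep=_sep_for(path), index=False)


def write_model_params(path: str | Path, model: MixtureModel) -> None:
    """Flat key=value dump of the fitted mixture parameters."""
    lines = [f"m_c={model.m_c}", f"m_n={model.m_n}"]
    for k, c in zip((1, 2, 3), model.clusters):
        lines.append(f"pi_{k}={model.pi[k - 1]!r}")
        lines.append(f"kind_{k}={c.kind}")
        for grp in ("c", "n"):
            for name in ("mu", "sigma2", "rho"):
                lines.append(f"{name}_{k}{grp}={getattr(c, f'{name}_{grp}')!r}")
    Path(path).write_text("\n".join(lines) + "\n")
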