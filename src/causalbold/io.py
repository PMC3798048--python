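"""File formats and feature-table assembly.

Conventions: tab-separated text for time series (columns = ROI labels,
rows = volumes), whitespace-delimited six-column text for motion traces
(SPM ``rp_*.txt`` dialect — translations in mm, rotations stored in
radians on disk and converted to degrees in memory), CSV for feature
tables (``subject_id``, ``label``, then feature columns), JSON for
manifests/results and YAML for configuration.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from causalbold.qc import MotionTrace
from causalbold.rce import FeatureTable
from causalbold.rois import CANONICAL_ROIS

_SCALAR_COLUMNS = ("AQ", "RME", "FA")


def write_roi_timeseries(
    path: str | Path,
    series: np.ndarray,
    labels: tuple[str, ...] | list[str],
) -> None:
    """Write an (n_rois, n_volumes) series as TSV with ROI-label header."""
    series = np.asarray(series, dtype=float)
    if series.ndim != 2 or series.shape[0] != len(labels):
        raise ValueError("series must be (n_rois, n_volumes) matching labels")
    frame = pd.DataFrame(series.T, columns=list(labels))
    frame.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_roi_timeseries(
    path: str | Path,
    strict: bool = True,
) -> tuple[np.ndarray, tuple[str, ...]]:
    """Read a ROI time-series TSV; returns ``(series, labels)``.

    In strict mode the header must contain exactly the canonical 18 ROI
    labels (any order); columns are realigned to canonical order.
    Ragged rows and non-numeric cells raise with the line number.
    """
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        labels = tuple(h.strip() for h in header)
        rows: list[list[float]] = []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            cells = line.rstrip("\n").split("\t")
            if len(cells) != len(labels):
                raise ValueError(
                    f"{path}:{lineno}: expected {len(labels)} columns, got {len(cells)}"
                )
            try:
                rows.append([float(c) for c in cells])
            except ValueError as err:
                raise ValueError(f"{path}:{lineno}: non-numeric cell ({err})") from None
    if not rows:
        raise ValueError(f"{path}: no data rows")
    series = np.asarray(rows).T  # (n_rois, n_volumes)
    if strict:
        missing = [r for r in CANONICAL_ROIS if r not in labels]
        unknown = [l for l in labels if l not in CANONICAL_ROIS]
        if missing or unknown:
            raise ValueError(
                f"{path}: header does not match the canonical ROI set; "
                f"missing={missing} unknown={unknown}"
            )
        order = [labels.index(r) for r in CANONICAL_ROIS]
        series = series[order]
        labels = CANONICAL_ROIS
    return series, labels


def write_motion_trace(path: str | Path, trace: MotionTrace) -> None:
    """Write a motion trace in the SPM rp dialect (rotations in radians)."""
    data = trace.data.copy()
    data[:, 3:] = np.deg2rad(data[:, 3:])
    np.savetxt(path, data, fmt="%.10e")


def read_motion_trace(path: str | Path) -> MotionTrace:
    """Read an rp-style motion file; rotations converted radians -> degrees."""
    data = np.loadtxt(path)
    data = np.atleast_2d(data)
    if data.shape[1] != 6:
        raise ValueError(f"{path}: motion trace must have 6 columns")
    data = data.copy()
    data[:, 3:] = np.rad2deg(data[:, 3:])
    return MotionTrace(data=data)


def assemble_feature_table(
    ec_features: pd.DataFrame,
    fc_features: pd.DataFrame,
    aq: pd.Series,
    rme: pd.Series,
    fa: pd.Series,
    labels: pd.Series,
) -> FeatureTable:
    """Combine per-subject features into one classification table.

    All inputs are indexed by subject id.  The column order is
    deterministic: effective-connectivity paths (source-major), then
    functional-connectivity pairs, then AQ, RME and FA — 462 columns for
    the default 18-ROI cohort.  Subjects missing from any input raise
    with the offending ids listed.
    """
    index = ec_features.index
    pieces = {
        "fc_features": fc_features,
        "AQ": aq,
        "RME": rme,
        "FA": fa,
        "labels": labels,
    }
    for name, piece in pieces.items():
        missing = index.difference(piece.index)
        extra = piece.index.difference(index)
        if len(missing) or len(extra):
            raise ValueError(
                f"subject mismatch in {name}: missing={list(missing)} "
                f"unexpected={list(extra)}"
            )
    matrix = np.hstack(
        [
            ec_features.to_numpy(dtype=float),
            fc_features.loc[index].to_numpy(dtype=float),
            aq.loc[index].to_numpy(dtype=float)[:, None],
            rme.loc[index].to_numpy(dtype=float)[:, None],
            fa.loc[index].to_numpy(dtype=float)[:, None],
        ]
    )
    names = list(ec_features.columns) + list(fc_features.columns) + list(_SCALAR_COLUMNS)
    return FeatureTable(
        matrix=matrix,
        feature_names=names,
        labels=labels.loc[index].to_numpy(),
        subject_ids=[str(s) for s in index],
    )


def write_feature_table(path: str | Path, table: FeatureTable) -> None:
    frame = pd.DataFrame(table.matrix, columns=table.feature_names)
    frame.insert(0, "label", table.labels)
    ids = table.subject_ids or [f"sub-{i + 1:03d}" for i in range(table.n_subjects)]
    frame.insert(0, "subject_id", ids)
    frame.to_csv(path, index=False, float_format="%.17g")


def read_feature_table(path: str | Path) -> FeatureTable:
    frame = pd.read_csv(path, float_precision="round_trip")
    if "subject_id" not in frame.columns or "label" not in frame.columns:
        raise ValueError(f"{path}: feature CSV needs subject_id and label columns")
    names = [c for c in frame.columns if c not in ("subject_id", "label")]
    return FeatureTable(
        matrix=frame[names].to_numpy(dtype=float),
        feature_names=names,
        labels=frame["label"].to_numpy(),
        subject_ids=frame["subject_id"].astype(str).tolist(),
    )


# ---------------------------------------------------------------------------
# Configuration and JSON helpers
# ---------------------------------------------------------------------------


def _dataclass_to_dict(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {
            f.name: _dataclass_to_dict(getattr(obj, f.name))
            for f in dataclasses.fields(obj)
        }
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _dataclass_to_dict(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_dataclass_to_dict(v) for v in obj]
    return obj


def config_to_yaml(config: Any, path: str | Path) -> None:
    """Serialize any of the package's config dataclasses to YAML."""
    Path(path).write_text(yaml.safe_dump(_dataclass_to_dict(config), sort_keys=False))


def dataclass_from_dict(cls: type, data: dict[str, Any]) -> Any:
    """Build a (possibly nested) config dataclass from a plain dict."""
    if data is None:
        return cls()
    kwargs: dict[str, Any] = {}
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(fields)
    if unknown:
        raise ValueError(f"unknown {cls.__name__} fields: {sorted(unknown)}")
    for name, value in data.items():
        if isinstance(value, dict):
            nested = _resolve_nested_type(cls, name)
            if nested is not None:
                value = dataclass_from_dict(nested, value)
        kwargs[name] = value
    return cls(**kwargs)


def _resolve_nested_type(cls: type, field_name: str) -> type | None:
    import typing

    from causalbold import cohort, hemodynamics, rce

    hints = typing.get_type_hints(
        cls,
        {
            **vars(cohort),
            **vars(hemodynamics),
            **vars(rce),
            "np": np,
        },
    )
    hint = hints.get(field_name)
    candidates = [hint] + list(typing.get_args(hint) or [])
    for cand in candidates:
        if isinstance(cand, type) and dataclasses.is_dataclass(cand):
            return cand
    return None


def load_yaml_config(cls: type, path: str | Path) -> Any:
    data = yaml.safe_load(Path(path).read_text()) or {}
    return dataclass_from_dict(cls, data)


def write_json(path: str | Path, payload: Any) -> None:
    Path(path).write_text(json.dumps(_dataclass_to_dict(payload), indent=2, sort_keys=True))


def read_json(path: str | Path) -> Any:
    return json.loads(Path(path).read_text())
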