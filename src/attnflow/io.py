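"""TSV/JSON serialization for the pipeline's artifacts.

Time series travel as TSV with a leading ``time_s`` column and one
column per region; designs, model spaces, and result reports travel as
JSON.  Round-trips are lossless for finite values at 12 significant
digits, and parsing is locale independent (dot decimal only).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import BlockDesign, TimeSeriesSet

__all__ = [
    "read_timeseries_tsv",
    "write_timeseries_tsv",
    "read_design_json",
    "write_design_json",
    "write_report_json",
    "read_report_json",
]


def write_timeseries_tsv(ts: TimeSeriesSet, path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(ts.data.T, columns=list(ts.region_labels))
    df.insert(0, "time_s", ts.times)
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")
    return path


def read_timeseries_tsv(path: str | Path) -> TimeSeriesSet:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:  # pragma: no cover - pandas reports the line
        raise ValueError(f"malformed TSV {path}: {exc}") from exc
    if "time_s" not in df.columns:
        raise ValueError(f"{path}: missing required 'time_s' column")
    df = df.apply(pd.to_numeric, errors="coerce")
    if df.isna().any().any():
        bad = int(df.isna().any(axis=1).idxmax()) + 2  # 1-based incl. header
        raise ValueError(f"{path}: missing/unparseable value near line {bad}")
    times = df["time_s"].to_numpy(float)
    if len(times) < 2:
        raise ValueError(f"{path}: need at least two samples")
    tr = float(np.median(np.diff(times)))
    regions = [c for c in df.columns if c != "time_s"]
    return TimeSeriesSet(
        tuple(regions), df[regions].to_numpy(float).T, tr, {"path": str(path)}
    )


def write_design_json(design: BlockDesign, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(design.to_dict(), indent=2) + "\n")
    return path


def read_design_json(path: str | Path) -> BlockDesign:
    return BlockDesign.from_dict(json.loads(Path(path).read_text()))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    if hasattr(obj, "to_dict"):
        return _jsonable(obj.to_dict())
    return obj


def write_report_json(report: dict, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(_jsonable(report), indent=2, sort_keys=True) + "\n")
    return path


def read_report_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
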