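"""Plain-text readers/writers for streams, truth tables, beat tables and
reports.

Stream files are two-column delimited text (sample_index, value) with
``#``-prefixed header comments; a JSON sidecar (``<stem>.meta.json``)
carries the sample rate, seed and stage schedule.  All writers accept an
optional config hash that is embedded in the output.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "write_stream",
    "read_stream",
    "write_table",
    "read_table",
    "write_json",
    "read_json",
    "sidecar_path",
]


def sidecar_path(stream_path: str | Path) -> Path:
    return Path(stream_path).with_suffix(".meta.json")


def _comment_lines(config_hash: Optional[str]) -> str:
    return f"# config_hash={config_hash}\n" if config_hash else ""


def write_stream(
    path: str | Path,
    samples: np.ndarray,
    sample_rate: float,
    meta: Optional[dict] = None,
    config_hash: Optional[str] = None,
) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_comment_lines(config_hash))
        fh.write(f"# sample_rate={sample_rate:g}\n")
        fh.write("sample_index,value\n")
        for i, v in enumerate(np.asarray(samples, dtype=float)):
            fh.write(f"{i},{v:.10g}\n")
    side = dict(meta or {})
    side["sample_rate"] = sample_rate
    if config_hash:
        side["config_hash"] = config_hash
    with open(sidecar_path(path), "w") as fh:
        json.dump(side, fh, indent=2, sort_keys=True)


def read_stream(path: str | Path) -> tuple[np.ndarray, dict]:
    """Read a stream file; returns (samples, metadata).  Metadata comes
    from the JSON sidecar when present, else from header comments."""
    path = Path(path)
    df = pd.read_csv(path, comment="#")
    samples = df["value"].to_numpy(dtype=float)
    meta: dict = {}
    side = sidecar_path(path)
    if side.exists():
        with open(side) as fh:
            meta = json.load(fh)
    else:
        with open(path) as fh:
            for line in fh:
                if not line.startswith("#"):
                    break
                if "=" in line:
                    key, val = line.lstrip("# ").strip().split("=", 1)
                    try:
                        meta[key] = float(val)
                    except ValueError:
                        meta[key] = val
    return samples, meta


def write_table(path: str | Path, df: pd.DataFrame, config_hash: Optional[str] = None) -> None:
    with open(path, "w") as fh:
        fh.write(_comment_lines(config_hash))
        df.to_csv(fh, index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def write_json(path: str | Path, payload: dict, config_hash: Optional[str] = None) -> None:
    out = dict(payload)
    if config_hash:
        out["config_hash"] = config_hash
    with open(path, "w") as fh:
        json.dump(out, fh, indent=2, sort_keys=True, default=_jsonify)
        fh.write("\n")


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)!r}")


def read_json(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
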