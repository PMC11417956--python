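"""CSV/JSON file handling and structured run logging.

One dialect everywhere: comma-separated, UTF-8, header row, "." decimal,
ISO-8601 dates.  Readers validate schemas and round-trip what the writers
emit without loss.  Run logs are machine-parseable (one JSON object per
line) and carry the counts of every filtering rule applied.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import asdict, is_dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "read_individuals", "read_forearm", "read_urine",
    "write_standardization", "read_standardization",
    "JsonlLogger", "provenance_record",
]

_SCHEMAS = {
    "individuals": ["id", "sex", "birthdate", "site_id"],
    "forearm": ["id", "date", "length_cm"],
    "urine": ["id", "date", "time_hhmm", "ctx_ng_ml", "sg"],
}


def _read_checked(path, kind) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"id": str, "time_hhmm": str})
    missing = [c for c in _SCHEMAS[kind] if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing} "
                         f"(expected {_SCHEMAS[kind]})")
    return df


def read_individuals(path) -> pd.DataFrame:
    df = _read_checked(path, "individuals")
    bad = ~df["sex"].isin(["F", "M"])
    if bad.any():
        raise ValueError(f"{path}: invalid sex codes {df.loc[bad, 'sex'].unique()}")
    return df


def read_forearm(path) -> pd.DataFrame:
    return _read_checked(path, "forearm")


def read_urine(path) -> pd.DataFrame:
    return _read_checked(path, "urine")


def write_standardization(params: dict, path) -> None:
    """Persist StandardizationParams per variable as JSON."""
    out = {k: {"center": p.center, "scale": p.scale}
           for k, p in params.items()}
    Path(path).write_text(json.dumps(out, indent=2))


def read_standardization(path) -> dict:
    return json.loads(Path(path).read_text())


class JsonlLogger:
    """Append-only JSON-lines event log for a pipeline run."""

    def __init__(self, path):
        self.path = Path(path)
        self.path.parent.mkdir(parents=True, exist_ok=True)
        self.path.write_text("")

    def event(self, stage: str, **fields) -> None:
        rec = {"stage": stage}
        rec.update({k: _jsonable(v) for k, v in fields.items()})
        with open(self.path, "a") as fh:
            fh.write(json.dumps(rec) + "\n")


def _jsonable(v):
    if isinstance(v, (np.floating, np.integer)):
        return v.item()
    if isinstance(v, np.ndarray):
        return v.tolist()
    if is_dataclass(v) and not isinstance(v, type):
        return asdict(v)
    return v


def provenance_record(config, seed: int) -> dict:
    """Config hash + versions + seed, written with every run."""
    cfg = json.dumps(config, sort_keys=True, default=str)
    return {
        "config_sha256": hashlib.sha256(cfg.encode()).hexdigest()[:16],
        "seed": int(seed),
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
    }
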