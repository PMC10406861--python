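"""Plain-text readers/writers for traces, manifests, and run configs.

Trace files are CSV with columns frame, time_s, phase, i_cy3_raw,
i_cy5_raw, i_cy55_raw (one file per molecule); corrected traces append
i_cy3, i_cy5, i_cy55, fret_cy5, fret_cy55, undefined_flag.  Manifests are
JSON-lines, one record per molecule.  Configs are YAML.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterator, Optional

import pandas as pd
import yaml

RAW_COLUMNS = ["frame", "time_s", "phase", "i_cy3_raw", "i_cy5_raw", "i_cy55_raw"]
CORRECTED_EXTRA = ["i_cy3", "i_cy5", "i_cy55", "fret_cy5", "fret_cy55",
                   "undefined_flag"]

_FLOAT_FMT = "%.6f"


def write_trace_csv(trace, path) -> None:
    from .simulate import RawTrace  # noqa: F401  (documents expected type)

    df = trace.frames if hasattr(trace, "frames") else trace
    cols = [c for c in RAW_COLUMNS + CORRECTED_EXTRA + ["negative_flag", "clip_flag"]
            if c in df.columns]
    df.to_csv(path, index=False, columns=cols, float_format=_FLOAT_FMT)


def read_trace_csv(path, meta: Optional[dict] = None):
    from .simulate import RawTrace

    df = pd.read_csv(path)
    missing = [c for c in RAW_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing trace columns {missing}")
    return RawTrace(frames=df, meta=dict(meta or {}))


def write_manifest(manifest: pd.DataFrame, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for rec in manifest.to_dict(orient="records"):
            fh.write(json.dumps(rec, sort_keys=True) + "\n")


def read_manifest(path) -> pd.DataFrame:
    records = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line:
                records.append(json.loads(line))
    return pd.DataFrame(records)


def iter_trace_files(directory) -> Iterator[Path]:
    yield from sorted(Path(directory).glob("*.csv"))


def load_yaml_config(path) -> dict:
    with open(path, encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a YAML mapping")
    return cfg
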