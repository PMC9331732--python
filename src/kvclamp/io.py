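"""Tidy-CSV trace I/O and provenance sidecars.

Traces are stored long-form with columns ``cell_id, sweep_label, time_ms,
command_mV, current``; generator settings travel in a JSON sidecar so a run
can be reproduced bit-exactly.  Leading ``#`` comment lines in the CSV carry
the config hash and seed.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .simulate import Trace

__all__ = ["traces_to_frame", "frame_to_traces", "write_traces_csv", "read_traces_csv", "config_hash"]


def config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:16]


def traces_to_frame(traces: Sequence[Trace]) -> pd.DataFrame:
    parts = []
    for tr in traces:
        parts.append(
            pd.DataFrame(
                {
                    "cell_id": tr.cell_id,
                    "sweep_label": tr.sweep_label,
                    "time_ms": tr.time_ms,
                    "command_mV": tr.command_mV,
                    "current": tr.current,
                }
            )
        )
    return pd.concat(parts, ignore_index=True)


def frame_to_traces(df: pd.DataFrame) -> list[Trace]:
    traces = []
    for (cell, label), grp in df.groupby(["cell_id", "sweep_label"], sort=False):
        traces.append(
            Trace(
                time_ms=grp["time_ms"].to_numpy(),
                current=grp["current"].to_numpy(),
                command_mV=grp["command_mV"].to_numpy(),
                sweep_label=str(label),
                cell_id=str(cell),
            )
        )
    return traces


def write_traces_csv(
    traces: Sequence[Trace], path, meta: Optional[dict] = None
) -> None:
    path = Path(path)
    header = ""
    if meta:
        header = "".join(f"# {k}={v}\n" for k, v in meta.items())
    with path.open("w") as fh:
        fh.write(header)
        traces_to_frame(traces).to_csv(fh, index=False)


def read_traces_csv(path) -> list[Trace]:
    df = pd.read_csv(path, comment="#")
    return frame_to_traces(df)
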