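"""Tab-separated table dialect with '#'-prefixed metadata headers.

Every tabular artifact in the package (traces, DLS series, metric tables,
reports) is plain TSV preceded by metadata lines of the form ``# key=value``.
Values are JSON-encoded so structured metadata (schedules, parameter maps)
round-trips losslessly.
"""

from __future__ import annotations

import io
import json
from typing import Any

import pandas as pd


def write_table(path, frame: pd.DataFrame, meta: dict[str, Any] | None = None) -> None:
    with open(path, "w") as fh:
        for key, value in (meta or {}).items():
            fh.write(f"# {key}={json.dumps(value)}\n")
        frame.to_csv(fh, sep="\t", index=False, lineterminator="\n")


def read_table(path) -> tuple[pd.DataFrame, dict[str, Any]]:
    meta: dict[str, Any] = {}
    body: list[str] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                stripped = line[1:].strip()
                if "=" in stripped:
                    key, _, raw = stripped.partition("=")
                    try:
                        meta[key.strip()] = json.loads(raw)
                    except json.JSONDecodeError:
                        meta[key.strip()] = raw
            else:
                body.append(line)
    frame = pd.read_csv(io.StringIO("".join(body)), sep="\t",
                        float_precision="round_trip")
    return frame, meta
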