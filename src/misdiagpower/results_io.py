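"""Result serialization: long-format CSV and JSON with embedded run config.

Every output embeds the fully resolved configuration (all defaults
materialised, seed included), so a results file can be re-run bit-for-bit.
CSV files carry the config as leading ``# key: value`` comment lines above
an RFC-4180 body; JSON files hold ``{"config": ..., "results": ...}``.
Missing thresholds serialize as empty CSV cells / JSON nulls.
"""

from __future__ import annotations

import json
from io import StringIO
from pathlib import Path
from typing import Any

import pandas as pd

__all__ = [
    "write_results_csv",
    "read_results_csv",
    "write_results_json",
    "read_results_json",
]

_CONFIG_PREFIX = "# "


def write_results_csv(df: pd.DataFrame, config: dict[str, Any], path: str | Path) -> None:
    buf = StringIO()
    for key, value in config.items():
        buf.write(f"{_CONFIG_PREFIX}{key}: {json.dumps(value)}\n")
    df.to_csv(buf, index=False)
    Path(path).write_text(buf.getvalue())


def read_results_csv(path: str | Path) -> tuple[dict[str, Any], pd.DataFrame]:
    """Inverse of :func:`write_results_csv`."""
    text = Path(path).read_text()
    config: dict[str, Any] = {}
    body_start = 0
    for line in text.splitlines(keepends=True):
        if not line.startswith(_CONFIG_PREFIX):
            break
        key, _, raw = line[len(_CONFIG_PREFIX):].partition(": ")
        config[key] = json.loads(raw)
        body_start += len(line)
    df = pd.read_csv(StringIO(text[body_start:]))
    return config, df


def write_results_json(results: Any, config: dict[str, Any], path: str | Path) -> None:
    Path(path).write_text(
        json.dumps({"config": config, "results": results}, indent=2) + "\n"
    )


def read_results_json(path: str | Path) -> tuple[dict[str, Any], Any]:
    payload = json.loads(Path(path).read_text())
    return payload["config"], payload["results"]
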