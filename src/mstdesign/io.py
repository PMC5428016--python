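"""Structured output writers and run manifests for the command line.

Everything the CLI writes is deterministic: identical resolved parameters
produce byte-identical CSV/JSON outputs.  The manifest records the resolved
parameter bundle and output list so a run can be audited and reproduced;
its timestamp is informational and kept out of the data files themselves.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Any, Sequence

import pandas as pd

from . import __version__

__all__ = ["RunManifest", "write_table", "write_json"]


@dataclass
class RunManifest:
    """Record of one CLI invocation."""

    command: str
    parameters: dict[str, Any]
    outputs: list[str] = field(default_factory=list)
    version: str = __version__
    timestamp: str = field(
        default_factory=lambda: datetime.now(timezone.utc).isoformat()
    )

    def register(self, path: str | Path) -> None:
        self.outputs.append(str(path))

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "command": self.command,
            "parameters": self.parameters,
            "outputs": self.outputs,
            "version": self.version,
            "timestamp": self.timestamp,
        }, indent=2, sort_keys=True, default=str) + "\n")


def write_json(payload: dict[str, Any], path: str | Path,
               manifest: RunManifest | None = None) -> None:
    """UTF-8 JSON with sorted keys; registers with the manifest."""
    Path(path).write_text(
        json.dumps(payload, indent=2, sort_keys=True, default=float) + "\n"
    )
    if manifest is not None:
        manifest.register(path)


def write_table(records: Sequence[dict[str, Any]] | pd.DataFrame,
                path: str | Path, fmt: str = "csv",
                manifest: RunManifest | None = None) -> None:
    """Write tabular records as CSV (RFC 4180) or JSON records.

    Column order follows the first record / the DataFrame; an empty record
    list yields a header-only file for CSV and an empty list for JSON.
    """
    if fmt not in ("csv", "json"):
        raise ValueError(f"format must be 'csv' or 'json', got {fmt!r}")
    df = records if isinstance(records, pd.DataFrame) else pd.DataFrame(list(records))
    if fmt == "csv":
        df.to_csv(path, index=False, lineterminator="\n")
    else:
        Path(path).write_text(
            json.dumps(df.to_dict("records"), indent=2, default=float) + "\n"
        )
    if manifest is not None:
        manifest.register(path)
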