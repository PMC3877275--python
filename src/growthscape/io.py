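"""Table readers/writers and run manifests.

All pipeline tables are UTF-8 CSV with a single header row and '.'
decimals. ``read_table`` validates required columns and numeric types up
front so downstream stages can assume clean frames; ``write_manifest``
records the seed and a config hash with every run so two runs with equal
manifests produce identical outputs.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

__all__ = ["read_table", "write_table", "write_manifest", "config_hash"]


def read_table(
    path: str | Path,
    required: dict[str, type] | None = None,
) -> pd.DataFrame:
    """Read a CSV, checking required columns and their numeric parseability.

    ``required`` maps column name -> python type (float, int, str).
    Unknown extra columns are preserved. Raises ValueError naming the
    missing column, or the first malformed row for a numeric column.
    """
    df = pd.read_csv(path)
    for col, typ in (required or {}).items():
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column '{col}'")
        if typ in (float, int):
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = df[col].notna() & coerced.isna()
            if bad.any():
                row = int(bad.idxmax()) + 2  # header is line 1
                raise ValueError(f"{path}: malformed numeric in '{col}' at line {row}")
            df[col] = coerced
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def config_hash(config: dict) -> str:
    """Stable short hash of a JSON-serializable configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_manifest(out_dir: str | Path, seed: int, config: dict) -> Path:
    """Record seed, config and its hash alongside a stage's outputs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    path = out / "manifest.json"
    payload = {"seed": seed, "config_hash": config_hash(config), "config": config}
    path.write_text(json.dumps(payload, indent=2, sort_keys=True, default=str))
    return path
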