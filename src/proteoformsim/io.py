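"""Tabular and configuration I/O conventions.

All tables are TSV (tab-separated, UTF-8, LF), with missing values encoded
as the literal ``NA`` - never empty cells - so files round-trip exactly and
are locale-safe. Configurations are YAML/JSON; every simulation output
directory receives a config echo including the seed.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

__all__ = ["write_tsv", "read_tsv", "write_config_echo", "write_json_summary"]

NA_TOKEN = "NA"


def write_tsv(df: pd.DataFrame, path: str | Path, index: bool = True) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", na_rep=NA_TOKEN, index=index, lineterminator="\n")
    return path


def read_tsv(path: str | Path, index_col: int | None = 0) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", na_values=[NA_TOKEN], keep_default_na=False, index_col=index_col
    )


def _to_plain(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_plain(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (set, frozenset)):
        return sorted(_to_plain(v) for v in obj)
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    if hasattr(obj, "item"):  # numpy scalars
        return obj.item()
    return obj


def write_config_echo(config: Any, path: str | Path) -> Path:
    """Echo the resolved configuration (seed included) as YAML."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(yaml.safe_dump(_to_plain(config), sort_keys=False))
    return path


def write_json_summary(summary: dict, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(_to_plain(summary), indent=2, sort_keys=True) + "\n")
    return path
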