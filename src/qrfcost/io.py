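"""Reading and writing episode tables and run artifacts (plain text only)."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import pandas as pd
import yaml

from . import schema
from .synthetic import GeneratorConfig

__all__ = [
    "read_episode_table",
    "write_episode_table",
    "write_generator_echo",
    "write_json",
]


def read_episode_table(path: str | Path, require_cost: bool = True) -> pd.DataFrame:
    """Read and validate a comma-separated episode table (UTF-8, header row).

    Raises :class:`qrfcost.schema.TableValidationError` listing every
    offense (missing columns, unknown category labels with row indices,
    negative costs, missing values).
    """
    df = pd.read_csv(path, dtype=str, encoding="utf-8")
    schema.validate_table(df, require_cost=require_cost)
    for col in schema.CONTINUOUS:
        df[col] = pd.to_numeric(df[col])
    if schema.RESPONSE in df.columns:
        df[schema.RESPONSE] = pd.to_numeric(df[schema.RESPONSE])
    return df


def write_episode_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write an episode table as UTF-8 CSV with header, costs as decimal dollars."""
    df.to_csv(path, index=False, encoding="utf-8")


def write_generator_echo(config: GeneratorConfig, path: str | Path) -> None:
    """Echo a generator configuration as a key-value text document (provenance)."""
    doc = dataclasses.asdict(config)
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False, allow_unicode=True)


def write_json(obj, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, ensure_ascii=False, default=_coerce)
        fh.write("\n")


def _coerce(o):
    if hasattr(o, "item"):
        return o.item()
    if isinstance(o, (set, tuple)):
        return list(o)
    raise TypeError(f"not JSON serializable: {type(o)}")
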