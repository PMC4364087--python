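"""Delimited-table readers/writers and run configuration.

Input tables are delimited text with a header.  CFQ-R data may arrive as
raw item columns ``item_1..item_50`` or as pre-scored domain columns (any
alias style); EQ-5D data as a 5-digit state-string column ``eq5d_state``,
five per-dimension level columns, or a precomputed ``utility`` column.
Validation is strict: ordinal ranges, utility bounds and malformed rows
raise errors naming the offending rows, and a per-column missingness
report is attached to the frame.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import value_sets as vs

__all__ = ["RunConfig", "read_respondent_table", "write_table",
           "load_config", "save_config", "TableValidationError"]

log = logging.getLogger(__name__)


class TableValidationError(ValueError):
    """Input table failed validation; the message lists row numbers."""


@dataclass
class RunConfig:
    """Configuration for a full pipeline run (24-model grid + validation).

    A single structured file drives a run; CLI flags override fields.
    Every seed is recorded in the outputs so runs are reconstructible.
    """

    input: str | None = None          # respondent table; None -> simulate
    out_dir: str | None = None
    n: int = 401                      # cohort size when simulating
    seed: int = 0
    families: tuple = ("ols", "tobit", "tpm")
    model_numbers: tuple = (1, 2, 3, 4, 5, 6, 7, 8)
    cv_specs: tuple = ((3, "ols"), (3, "tpm"))
    cv_folds: int = 4
    bootstrap_reps: int = 2000
    screen_alpha: float = 0.10
    clamp: bool = False
    bands: tuple = (-0.594, 0.1, 0.3, 0.6, 0.7, 0.8, 0.9, 1.0)
    value_set: str = "uk_tto"
    item_map: str | None = None
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path: str | Path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    cfg = RunConfig(**{k: v for k, v in raw.items()
                       if k in RunConfig.__dataclass_fields__})
    unknown = set(raw) - set(RunConfig.__dataclass_fields__)
    if unknown:
        raise KeyError(f"unknown config keys: {sorted(unknown)}")
    for name in ("families", "model_numbers", "bands"):
        setattr(cfg, name, tuple(getattr(cfg, name)))
    cfg.cv_specs = tuple((int(m), str(f)) for m, f in cfg.cv_specs)
    return cfg


def save_config(cfg: RunConfig, path: str | Path) -> None:
    d = cfg.to_dict()
    d["cv_specs"] = [list(x) for x in d["cv_specs"]]
    for name in ("families", "model_numbers", "bands"):
        d[name] = list(d[name])
    Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def _bad_rows(mask: pd.Series) -> str:
    rows = list(np.flatnonzero(np.asarray(mask))[:10] + 2)  # 1-based + header
    return f"rows {rows}" + (" ..." if mask.sum() > 10 else "")


def read_respondent_table(path: str | Path, sep: str | None = None) -> pd.DataFrame:
    """Read and validate a respondent table.

    Returns the typed frame; ``frame.attrs["missingness"]`` holds the
    per-column missing counts.  The delimiter is sniffed unless given.
    """
    if sep is None:
        import csv

        sample = Path(path).open().readline()
        try:
            sep = csv.Sniffer().sniff(sample, delimiters=",\t;").delimiter
        except csv.Error:
            sep = ","
    try:
        df = pd.read_csv(path, sep=sep)
    except Exception as exc:
        raise TableValidationError(f"cannot parse {path}: {exc}") from exc
    log.info("read %d rows x %d columns from %s", len(df), df.shape[1], path)

    for col in df.columns:
        if col.startswith("item_"):
            vals = pd.to_numeric(df[col], errors="coerce")
            bad = vals.notna() & ~vals.isin([1, 2, 3, 4])
            if bad.any():
                raise TableValidationError(
                    f"column {col}: responses outside 1-4 at {_bad_rows(bad)}")
            df[col] = vals
        elif col in vs.DIMENSIONS:
            vals = pd.to_numeric(df[col], errors="coerce")
            bad = vals.notna() & ~vals.isin([1, 2, 3])
            if bad.any():
                raise TableValidationError(
                    f"column {col}: levels outside 1-3 at {_bad_rows(bad)}")
            df[col] = vals
        elif col == "utility":
            vals = pd.to_numeric(df[col], errors="coerce")
            bad = vals.notna() & ((vals < -0.594 - 1e-9) | (vals > 1 + 1e-9))
            if bad.any():
                raise TableValidationError(
                    f"column utility: values outside [-0.594, 1] at "
                    f"{_bad_rows(bad)}")
            df[col] = vals
        elif col == "eq5d_state":
            s = df[col].astype(str).str.strip()
            bad = s.notna() & ~s.str.fullmatch(r"[123]{5}")
            if bad.any():
                raise TableValidationError(
                    f"column eq5d_state: malformed states at {_bad_rows(bad)}")
            df[col] = s
    df.attrs["missingness"] = df.isna().sum().to_dict()
    return df


def write_table(df: pd.DataFrame, path: str | Path, sep: str = ",") -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep=sep, index=False)
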