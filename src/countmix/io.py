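"""Readers and writers for the tidy data tables and configuration files.

CountTable CSV: columns site, species, year, survey, count (a ``restored``
column is written by this package and accepted on read; alternatively a
separate site table supplies the treatment flags). HistoryTable CSV:
site, species, year, h111 ... h001 (one column per observable detection
history, descending binary order), n. Validation errors name the offending
rows.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .inference import EngineConfig, PriorSpec
from .simulate import history_columns

COUNT_COLUMNS = ["site", "species", "year", "survey", "count"]
HISTORY_KEY_COLUMNS = ["site", "species", "year"]


class DataValidationError(ValueError):
    pass


def _attach_restored(df, sites, what):
    if "restored" in df.columns:
        return df
    if sites is None:
        raise DataValidationError(
            f"{what} has no 'restored' column and no site table was given"
        )
    sites = pd.DataFrame(sites)
    mapping = dict(zip(sites["site"], sites["restored"]))
    missing = sorted(set(df["site"]) - set(mapping))
    if missing:
        raise DataValidationError(f"site table lacks restored flags for {missing}")
    out = df.copy()
    out["restored"] = out["site"].map(mapping).astype(int)
    return out


def read_counts(path, sites=None) -> pd.DataFrame:
    """Read and validate a CountTable CSV."""
    df = pd.read_csv(path)
    missing = [c for c in COUNT_COLUMNS if c not in df.columns]
    if missing:
        raise DataValidationError(f"{path}: missing columns {missing}")
    bad = df.index[df["count"] < 0].tolist()
    if bad:
        raise DataValidationError(f"{path}: negative counts at rows {bad[:10]}")
    return _attach_restored(df, sites, str(path))


def read_histories(path, sites=None) -> pd.DataFrame:
    """Read and validate a HistoryTable CSV (tallies must sum to n)."""
    df = pd.read_csv(path)
    hcols = [
        c for c in df.columns if c.startswith("h") and len(c) > 1 and set(c[1:]) <= {"0", "1"}
    ]
    if not hcols:
        raise DataValidationError(f"{path}: no detection-history columns found")
    J = len(hcols[0]) - 1
    expected = history_columns(J)
    missing = [c for c in HISTORY_KEY_COLUMNS + expected + ["n"] if c not in df.columns]
    if missing:
        raise DataValidationError(f"{path}: missing columns {missing}")
    tallies = df[expected].to_numpy()
    if (tallies < 0).any():
        bad = df.index[(tallies < 0).any(axis=1)].tolist()
        raise DataValidationError(f"{path}: negative tallies at rows {bad[:10]}")
    mismatch = df.index[tallies.sum(axis=1) != df["n"].to_numpy()].tolist()
    if mismatch:
        raise DataValidationError(
            f"{path}: history tallies do not sum to n at rows {mismatch[:10]}"
        )
    return _attach_restored(df, sites, str(path))


def write_counts(df: pd.DataFrame, path) -> None:
    cols = COUNT_COLUMNS + [c for c in ("restored",) if c in df.columns]
    df[cols].to_csv(path, index=False)


def write_histories(df: pd.DataFrame, path) -> None:
    hcols = [c for c in df.columns if c.startswith("h") and set(c[1:]) <= {"0", "1"}]
    cols = HISTORY_KEY_COLUMNS + [c for c in ("restored",) if c in df.columns] + hcols + ["n"]
    df[cols].to_csv(path, index=False)


def load_config(path) -> tuple[PriorSpec, EngineConfig]:
    """Load priors and engine settings from a YAML/JSON config file.

    Recognized top-level keys: ``priors`` (mapping of parameter name to
    [family, hyperparameters...]) and ``engine`` (EngineConfig fields).
    """
    path = Path(path)
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    priors = PriorSpec.from_dict(cfg.get("priors", {}))
    engine = EngineConfig(**cfg.get("engine", {}))
    return priors, engine


def write_manifest(path, **payload) -> None:
    """Write a JSON run manifest (config, seeds, package version)."""
    from . import __version__

    payload = dict(payload)
    payload.setdefault("countmix_version", __version__)

    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        return str(o)

    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=_default)
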