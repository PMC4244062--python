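"""Readers, writers and run configuration.

The raw input is a plain CSV/TSV assay table — sample_id, snp_id, the two
channel areas and uncertainties, and an optional platform call — because
two-channel area data has no standard bioinformatics container.  All
outputs are CSV (floats at six significant digits, deterministic row
order) or JSON so that a rerun with the same config and seed is
byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from snpquant.intensity import SnpParams

logger = logging.getLogger("snpquant")

ASSAY_COLUMNS = ["sample_id", "snp_id", "a1", "u1", "a2", "u2"]
NA_CALLS = {"", "NA", ".", "nan", "None"}
FLOAT_FORMAT = "%.6g"


@dataclass
class RunConfig:
    """Pipeline thresholds; the defaults are the method's published constants."""

    min_intensity: float = 3.0
    min_snps: int = 10
    call_threshold: float = 0.98
    error_floor: float = 0.01
    lod_threshold: float = 3.0
    delta_threshold: float = 3.0
    max_mismatches: int = 0
    restarts: int = 5000
    max_mates: int | None = 1
    min_class_n: int = 3
    sigma_floor: float = 1e-3
    seed: int = 0
    methods: tuple[str, ...] = ("quantitative",)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "methods" in raw:
            raw["methods"] = tuple(raw["methods"])
        return cls(**raw)

    def log_settings(self) -> None:
        for key, value in asdict(self).items():
            logger.info("config %s = %r", key, value)


@dataclass
class ReadReport:
    n_rows: int
    n_records: int
    errors: list[str] = field(default_factory=list)


def read_assay_table(
    path: str | Path, id_column: str = "sample_id"
) -> tuple[pd.DataFrame, ReadReport]:
    """Read and validate an assay table (CSV or TSV, delimiter sniffed).

    Malformed rows (non-numeric or negative areas/uncertainties) are
    dropped and reported with their line numbers; a missing required column
    is fatal.  The calls column accepts NA spellings {NA, "", "."}.
    Returns (records, report).
    """
    df = pd.read_csv(path, sep=None, engine="python", dtype=str, keep_default_na=False)
    required = [id_column] + ASSAY_COLUMNS[1:]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    errors: list[str] = []
    numeric = {}
    for col in ("a1", "u1", "a2", "u2"):
        numeric[col] = pd.to_numeric(df[col], errors="coerce")
    bad = pd.Series(False, index=df.index)
    for col, vals in numeric.items():
        col_bad = vals.isna() | (vals < 0) | ~np.isfinite(vals.fillna(0))
        for idx in df.index[col_bad & ~bad]:
            errors.append(f"line {idx + 2}: invalid {col}={df.at[idx, col]!r}")
        bad |= col_bad
    out = df.loc[~bad, [id_column, "snp_id"]].copy()
    for col, vals in numeric.items():
        out[col] = vals[~bad]
    if "call" in df.columns:
        calls = df.loc[~bad, "call"].astype(str).str.strip()
        out["call"] = calls.where(~calls.isin(NA_CALLS), None)
        out.loc[~out["call"].isin(["AA", "AB", "BB"]), "call"] = None
    else:
        out["call"] = None
    report = ReadReport(n_rows=len(df), n_records=len(out), errors=errors)
    if errors:
        logger.warning("%s: rejected %d malformed row(s)", path, len(errors))
    return out.reset_index(drop=True), report


def write_table(df: pd.DataFrame, path: str | Path, sort_by: list[str] | None = None) -> None:
    """Write a CSV with six-significant-digit floats and sorted rows."""
    out = df.copy()
    if sort_by:
        out = out.sort_values(sort_by, kind="mergesort")
    out.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def panel_to_frame(panel: dict[str, SnpParams]) -> pd.DataFrame:
    rows = [asdict(p) for p in panel.values()]
    return pd.DataFrame(rows).sort_values("snp_id").reset_index(drop=True)


def frame_to_panel(df: pd.DataFrame) -> dict[str, SnpParams]:
    panel = {}
    for _, row in df.iterrows():
        d = row.to_dict()
        d["usable"] = bool(d["usable"])
        for k in ("n_aa", "n_ab", "n_bb"):
            d[k] = int(d[k])
        panel[str(d["snp_id"])] = SnpParams(**d)
    return panel


def write_panel(panel: dict[str, SnpParams], path: str | Path) -> None:
    write_table(panel_to_frame(panel), path)


def read_panel(path: str | Path) -> dict[str, SnpParams]:
    return frame_to_panel(pd.read_csv(path))


def write_json(obj, path: str | Path) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serialisable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=default)
        fh.write("\n")
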