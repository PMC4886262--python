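"""Tabular I/O: the cohort CSV trio, ground-truth JSON and run configs.

A cohort on disk is three CSV files — concentrations, per-cell status codes
and sample metadata — plus an optional ground-truth spec JSON and a sidecar
schema JSON, so an output directory is self-describing.  Round trips are
lossless: concentrations serialize at full double precision and status
codes verbatim.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .synthetic import AnalyteMatrix, EffectSpec, STATUS_CODES

SCHEMA_VERSION = 1

REQUIRED_META_COLUMNS = (
    "cohort", "group", "plate", "fasting", "exclusion_flags",
)

VALUES_FILE = "values.csv"
STATUS_FILE = "status.csv"
META_FILE = "metadata.csv"
SPEC_FILE = "effect_spec.json"
SCHEMA_FILE = "schema.json"


def write_cohort(outdir: str | Path, matrix: AnalyteMatrix,
                 meta: pd.DataFrame, spec: EffectSpec | None = None) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    matrix.values.to_csv(outdir / VALUES_FILE, float_format="%.17g")
    matrix.status.to_csv(outdir / STATUS_FILE)
    meta.to_csv(outdir / META_FILE)
    if spec is not None:
        (outdir / SPEC_FILE).write_text(spec.to_json())
    schema = {
        "schema_version": SCHEMA_VERSION,
        "files": {VALUES_FILE: "samples x analytes concentrations",
                  STATUS_FILE: "samples x analytes status codes",
                  META_FILE: "per-sample metadata"},
        "status_codes": list(STATUS_CODES),
        "required_metadata_columns": list(REQUIRED_META_COLUMNS),
        "analyte_ids": list(matrix.values.columns),
    }
    (outdir / SCHEMA_FILE).write_text(json.dumps(schema, indent=1))
    return outdir


def read_cohort(indir: str | Path) -> tuple[AnalyteMatrix, pd.DataFrame]:
    """Read a cohort directory; validates schema, status codes and values."""
    indir = Path(indir)
    for f in (VALUES_FILE, STATUS_FILE, META_FILE):
        if not (indir / f).exists():
            raise FileNotFoundError(indir / f)
    values = pd.read_csv(indir / VALUES_FILE, index_col=0)
    status = pd.read_csv(indir / STATUS_FILE, index_col=0)
    meta = pd.read_csv(indir / META_FILE, index_col=0,
                       keep_default_na=True)
    meta["exclusion_flags"] = meta.get(
        "exclusion_flags", pd.Series("", index=meta.index)
    ).fillna("")

    missing = [c for c in REQUIRED_META_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"metadata schema mismatch; missing columns: {missing}")
    if list(values.columns) != list(status.columns) or not values.index.equals(
        status.index
    ):
        raise ValueError("values and status tables are not aligned")

    bad = ~status.isin(STATUS_CODES)
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"unknown status code {status.iat[r, c]!r} at sample "
            f"{status.index[r]!r}, analyte {status.columns[c]!r}"
        )
    for col in values.columns:
        if not pd.api.types.is_numeric_dtype(values[col]):
            coerced = pd.to_numeric(values[col], errors="coerce")
            bad_rows = values.index[coerced.isna() & values[col].notna()]
            raise ValueError(
                f"non-numeric concentration at sample {bad_rows[0]!r}, "
                f"analyte {col!r}"
            )
    return AnalyteMatrix(values, status), meta


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def dump_config(config: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)


def write_json(obj, path: str | Path) -> None:
    def _default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, pd.DataFrame):
            return o.to_dict()
        if isinstance(o, pd.Series):
            return o.to_dict()
        return str(o)

    Path(path).write_text(json.dumps(obj, indent=1, default=_default))
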