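"""CSV schema for the tidy transect table, validation, and config I/O.

The interchange format between pipeline stages is one tidy UTF-8 CSV with
a header row; one row per leaf sample, site covariates repeated per row.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import numpy as np
import pandas as pd
import yaml

from .constants import FractionationConstants

#: column -> (dtype kind, unit, plausible range or None)
SCHEMA: dict[str, tuple[str, str, Optional[tuple[float, float]]]] = {
    "sample_id": ("str", "-", None),
    "site_id": ("str", "-", None),
    "species_id": ("str", "-", None),
    "pathway": ("str", "C3|C4", None),
    "d13C_leaf": ("float", "permil vs PDB", (-40.0, -5.0)),
    "d18O_leaf": ("float", "permil vs SMOW", (0.0, 60.0)),
    "elevation_m": ("float", "m", (-500.0, 9000.0)),
    "mat_c": ("float", "degC", (-30.0, 45.0)),
    "map_mm": ("float", "mm", (0.0, 12000.0)),
    "vpd_kpa": ("float", "kPa", (0.0, 10.0)),
    "ai": ("float", "-", (0.0, 10.0)),
    "leaf_c": ("float", "mg/g", (100.0, 700.0)),
    "leaf_n": ("float", "mg/g", (1.0, 80.0)),
    "leaf_p": ("float", "mg/g", (0.05, 10.0)),
    "soil_soc": ("float", "g/kg", (0.0, 600.0)),
    "soil_stn": ("float", "g/kg", (0.0, 60.0)),
}

MANDATORY = [
    "sample_id", "site_id", "species_id", "pathway", "d13C_leaf",
    "elevation_m", "mat_c", "map_mm", "vpd_kpa", "ai",
]


class SchemaError(ValueError):
    """The table violates the documented CSV schema."""


@dataclass
class ValidationReport:
    """Row-level findings from ``validate_table``."""

    n_rows: int
    errors: list[str] = field(default_factory=list)     # fatal, row-level
    warnings: list[str] = field(default_factory=list)   # range/plausibility

    @property
    def ok(self) -> bool:
        return not self.errors


def validate_table(
    path_or_df: Path | str | pd.DataFrame, strict: bool = True
) -> tuple[pd.DataFrame, ValidationReport]:
    """Load and validate a transect CSV against the schema.

    Missing mandatory columns raise ``SchemaError`` naming them.
    Non-numeric cells in numeric columns are reported with their line
    number (fatal under ``strict``); out-of-range values produce warnings
    only.  Returns the typed table and a report.
    """
    if isinstance(path_or_df, pd.DataFrame):
        df = path_or_df.copy()
    else:
        path = Path(path_or_df)
        if not path.exists():
            raise FileNotFoundError(path)
        df = pd.read_csv(path, encoding="utf-8")
    missing = [c for c in MANDATORY if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {', '.join(missing)}")

    report = ValidationReport(n_rows=len(df))
    for col, (kind, unit, rng) in SCHEMA.items():
        if col not in df.columns:
            continue
        if kind == "float":
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = df[col].notna() & coerced.isna()
            for idx in df.index[bad]:
                # +2: header line plus 1-based indexing
                report.errors.append(
                    f"line {idx + 2}: non-numeric value {df.loc[idx, col]!r} "
                    f"in column {col!r} ({unit})"
                )
            df[col] = coerced
            if rng is not None:
                out = coerced.notna() & ((coerced < rng[0]) | (coerced > rng[1]))
                for idx in df.index[out]:
                    report.warnings.append(
                        f"line {idx + 2}: {col} = {coerced[idx]:.4g} outside "
                        f"plausible range {rng} {unit}"
                    )
    bad_pathway = ~df["pathway"].astype(str).str.upper().isin(["C3", "C4"])
    for idx in df.index[bad_pathway]:
        report.errors.append(
            f"line {idx + 2}: pathway {df.loc[idx, 'pathway']!r} is not C3 or C4"
        )
    if strict and report.errors:
        raise SchemaError(
            f"{len(report.errors)} row-level error(s); first: {report.errors[0]}"
        )
    return df, report


@dataclass
class PipelineConfig:
    """End-to-end pipeline configuration; round-trips through YAML."""

    out_dir: str = "results/pipeline"
    seed: int = 0
    formulation: str = "photoresp"
    ca: float = 415.0
    delta13c_air: float = -8.5
    constants: dict[str, Any] = field(default_factory=dict)  # overrides
    input_csv: Optional[str] = None     # skip simulation when given
    drop_out_of_range: bool = False
    stages: dict[str, bool] = field(
        default_factory=lambda: {
            "simulate": True, "compute_iwue": True, "fit": True, "attribute": True,
        }
    )
    generator: dict[str, Any] = field(default_factory=dict)  # TransectConfig overrides

    def fractionation_constants(self) -> FractionationConstants:
        return FractionationConstants(**self.constants)

    def to_yaml(self, path: Path | str) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: Path | str) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)


def write_json(obj: Any, path: Path | str) -> None:
    """JSON writer tolerant of numpy scalars/arrays and dataclasses."""

    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        if isinstance(o, Path):
            return str(o)
        return str(o)

    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=default))
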