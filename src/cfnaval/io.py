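"""File formats and configuration.

Interchange dialect: tab-separated UTF-8 text with '.' decimals, mirroring
vendor-export style without binding to a proprietary schema. Thresholds and
generator profiles travel as YAML; reports as JSON.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Sequence

import pandas as pd
import yaml

from .charts import ControlLimits, ControlSeries
from .qc import QCThresholds
from .synthetic import AssayProfile

__all__ = [
    "ParseError",
    "RunManifest",
    "read_call_table",
    "write_call_table",
    "read_metrics_table",
    "write_metrics_table",
    "read_thresholds",
    "write_thresholds",
    "read_profile",
    "write_profile",
    "read_manifest",
    "read_baseline_series",
    "write_limits_json",
]

CALL_TABLE_REQUIRED = ("sample_id", "target_id", "variant_kind", "measurement")
METRICS_REQUIRED = (
    "sample_id",
    "total_mapped_reads",
    "coverage_uniformity",
    "median_molecular_coverage",
    "molecular_uniformity",
    "mean_read_length",
    "aq20_fraction",
    "mapd",
)
_VARIANT_KINDS = {"fusion", "cna"}


class ParseError(ValueError):
    """A malformed input table or config file."""


@dataclass(frozen=True)
class RunManifest:
    """One batch's worth of file pointers.

    ``samples`` maps sample_id -> role; the batch must contain exactly one
    ``positive_control`` and one ``ntc``.
    """

    batch_id: str
    samples: dict[str, str]
    call_table: str
    metrics_table: str
    thresholds_path: str | None = None
    profile_path: str | None = None

    def __post_init__(self) -> None:
        roles = list(self.samples.values())
        for role in ("positive_control", "ntc"):
            if roles.count(role) != 1:
                raise ParseError(
                    f"manifest {self.batch_id!r} must contain exactly one {role}, "
                    f"found {roles.count(role)}"
                )


def _require_columns(df: pd.DataFrame, required: Sequence[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{what} is missing required column(s): {', '.join(missing)}")


def _coerce_numeric(df: pd.DataFrame, column: str, what: str) -> pd.Series:
    raw = df[column]
    coerced = pd.to_numeric(raw, errors="coerce")
    # a value that was present but did not parse is an error; true blanks are NaN
    bad = coerced.isna() & raw.notna() & (raw.astype(str).str.strip() != "")
    bad &= ~raw.astype(str).str.strip().str.lower().isin({"nan", "na", ""})
    if bad.any():
        lines = [i + 2 for i in df.index[bad]]  # +2: header line and 1-based numbering
        raise ParseError(
            f"{what}: non-numeric {column!r} value(s) at line(s) {lines[:5]}"
        )
    return coerced


def read_call_table(path: str | Path) -> pd.DataFrame:
    """Read a variant-call TSV; validate schema, preserve unknown columns."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(df, CALL_TABLE_REQUIRED, f"call table {path}")
    unknown_kinds = set(df["variant_kind"].dropna()) - _VARIANT_KINDS
    if unknown_kinds:
        raise ParseError(
            f"call table {path}: unknown variant_kind value(s) {sorted(unknown_kinds)}"
        )
    df["measurement"] = _coerce_numeric(df, "measurement", f"call table {path}")
    for col in ("p_value", "tbp", "hmbs", "met_e6_e7", "met_e11_e12"):
        if col in df.columns:
            df[col] = _coerce_numeric(df, col, f"call table {path}")
    return df


def write_call_table(df: pd.DataFrame, path: str | Path) -> None:
    _require_columns(df, CALL_TABLE_REQUIRED, "call table to write")
    df.to_csv(path, sep="\t", index=False)


def read_metrics_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(df, METRICS_REQUIRED, f"metrics table {path}")
    for col in METRICS_REQUIRED[1:]:
        df[col] = _coerce_numeric(df, col, f"metrics table {path}")
    return df


def write_metrics_table(df: pd.DataFrame, path: str | Path) -> None:
    _require_columns(df, METRICS_REQUIRED, "metrics table to write")
    df.to_csv(path, sep="\t", index=False)


# --- YAML configs -----------------------------------------------------------

_CONFIG_SCHEMA_VERSION = 1


def _load_yaml_section(path: str | Path, section: str) -> dict[str, Any]:
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh) or {}
    if not isinstance(doc, dict):
        raise ParseError(f"{path}: expected a mapping at top level")
    version = doc.get("schema_version", _CONFIG_SCHEMA_VERSION)
    if version != _CONFIG_SCHEMA_VERSION:
        raise ParseError(f"{path}: unsupported schema_version {version}")
    payload = doc.get(section, doc)
    if not isinstance(payload, dict):
        raise ParseError(f"{path}: section {section!r} must be a mapping")
    return {k: v for k, v in payload.items() if k != "schema_version"}


def _from_mapping(cls, payload: dict[str, Any], path) -> Any:
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(payload) - known
    if unknown:
        raise ParseError(f"{path}: unknown {cls.__name__} field(s) {sorted(unknown)}")
    # YAML lists become tuples where the dataclass expects them
    coerced = {
        k: tuple(v) if isinstance(v, list) else v for k, v in payload.items()
    }
    try:
        return cls(**coerced)
    except (TypeError, ValueError) as exc:
        raise ParseError(f"{path}: invalid {cls.__name__}: {exc}") from exc


def read_thresholds(path: str | Path) -> QCThresholds:
    return _from_mapping(QCThresholds, _load_yaml_section(path, "thresholds"), path)


def write_thresholds(thresholds: QCThresholds, path: str | Path) -> None:
    doc = {
        "schema_version": _CONFIG_SCHEMA_VERSION,
        "thresholds": dataclasses.asdict(thresholds),
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def read_profile(path: str | Path) -> AssayProfile:
    return _from_mapping(AssayProfile, _load_yaml_section(path, "profile"), path)


def write_profile(profile: AssayProfile, path: str | Path) -> None:
    payload = {
        k: (list(v) if isinstance(v, tuple) else v)
        for k, v in dataclasses.asdict(profile).items()
    }
    doc = {"schema_version": _CONFIG_SCHEMA_VERSION, "profile": payload}
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def read_manifest(path: str | Path) -> RunManifest:
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh) or {}
    try:
        return RunManifest(
            batch_id=doc["batch_id"],
            samples=dict(doc["samples"]),
            call_table=doc["call_table"],
            metrics_table=doc["metrics_table"],
            thresholds_path=doc.get("thresholds"),
            profile_path=doc.get("profile"),
        )
    except KeyError as exc:
        raise ParseError(f"manifest {path}: missing key {exc}") from exc


# --- control-chart IO -------------------------------------------------------


def read_baseline_series(path: str | Path) -> list[ControlSeries]:
    """Baseline TSV (analyte_id, kind, run_date, value) -> one series per analyte."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(df, ("analyte_id", "kind", "value"), f"baseline series {path}")
    df["value"] = _coerce_numeric(df, "value", f"baseline series {path}")
    out: list[ControlSeries] = []
    for (analyte, kind), grp in df.groupby(["analyte_id", "kind"], sort=True):
        out.append(
            ControlSeries(
                analyte_id=str(analyte),
                kind=str(kind),
                values=tuple(float(v) for v in grp["value"]),
                run_dates=tuple(grp["run_date"]) if "run_date" in grp.columns else (),
            )
        )
    return out


def write_limits_json(limits: Sequence[ControlLimits], path: str | Path) -> None:
    payload = [dataclasses.asdict(l) for l in limits]
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")
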