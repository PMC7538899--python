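"""Cohort table file contract, run configuration, and output sidecars.

The long-format cohort CSV carries one thickness observation per row:
patient_id, group, eye, visit_index, years_since_baseline, source, layer,
subfield, thickness_um. Units are µm and years throughout; missing
thickness is an empty cell, never 0. Outputs are accompanied by a JSON
sidecar recording package version, seed and a config hash so every file
is traceable to the run that produced it.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path

import pandas as pd
import yaml

from .layers import ALL_LAYERS, EYES, GROUPS, RAW_SUBLAYERS, SOURCES, SUBFIELDS

logger = logging.getLogger(__name__)

__all__ = ["read_cohort", "write_cohort", "RunConfig", "load_config"]

COHORT_COLUMNS = [
    "patient_id", "group", "eye", "visit_index", "years_since_baseline",
    "source", "layer", "subfield", "thickness_um",
]

KEY_COLUMNS = ["patient_id", "eye", "visit_index", "source", "layer", "subfield"]

_VALID = {
    "group": set(GROUPS),
    "eye": set(EYES),
    "source": set(SOURCES),
    "layer": set(ALL_LAYERS) | set(RAW_SUBLAYERS),
    "subfield": set(SUBFIELDS),
}


def _package_version() -> str:
    try:
        return version("octlayers")
    except PackageNotFoundError:  # pragma: no cover
        return "unknown"


def read_cohort(path: str | Path) -> pd.DataFrame:
    """Read and validate a long-format cohort CSV.

    Empty thickness cells become NaN (missing, not 0). Duplicate
    observation keys, unknown enum values, missing columns, and
    years_since_baseline violations are errors.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"patient_id": str})
    missing_cols = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"cohort file missing columns: {missing_cols}")
    df = df[COHORT_COLUMNS]

    for col, allowed in _VALID.items():
        bad = sorted(set(df[col].dropna().unique()) - allowed)
        if bad:
            raise ValueError(f"unknown {col} values: {bad[:10]}")

    dup = df.duplicated(subset=KEY_COLUMNS, keep=False)
    if dup.any():
        offenders = df.loc[dup, KEY_COLUMNS].drop_duplicates().head(10)
        raise ValueError(
            "duplicate observation keys:\n" + offenders.to_string(index=False)
        )

    neg = df["years_since_baseline"] < 0
    if neg.any():
        raise ValueError("years_since_baseline must be >= 0")
    base = df.loc[df["visit_index"] == 0, "years_since_baseline"]
    if (base != 0).any():
        raise ValueError("years_since_baseline must be 0 at visit_index 0")
    grp_per_pat = df.groupby("patient_id")["group"].nunique()
    if (grp_per_pat > 1).any():
        bad_pat = grp_per_pat[grp_per_pat > 1].index.tolist()[:10]
        raise ValueError(f"group must be constant within patient; offenders: {bad_pat}")

    n_missing = int(df["thickness_um"].isna().sum())
    logger.info("read %d rows from %s (%d missing thickness values)",
                len(df), path, n_missing)
    return df


def write_cohort(df: pd.DataFrame, path: str | Path, seed: int | None = None,
                 config_hash: str | None = None) -> Path:
    """Write a cohort table as CSV with a JSON provenance sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.6f", na_rep="")
    write_sidecar(path, seed=seed, config_hash=config_hash,
                  extra={"n_rows": int(len(df))})
    return path


def write_sidecar(path: str | Path, seed: int | None = None,
                  config_hash: str | None = None, extra: dict | None = None) -> None:
    meta = {
        "package": "octlayers",
        "version": _package_version(),
        "seed": seed,
        "config_hash": config_hash,
        "file": Path(path).name,
    }
    if extra:
        meta.update(extra)
    Path(str(path) + ".meta.json").write_text(json.dumps(meta, indent=2))


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

_CONFIG_SCHEMA = {
    "seed": int,
    "out_dir": str,
    "cohort": {
        "n_patients_control": int,
        "n_patients_stgd": int,
        "p_both_eyes": float,
        "followup_years_range": list,
        "n_visits": int,
        "variance_components": {
            "sd_patient_intercept": float, "sd_patient_slope": float,
            "corr_patient": float, "sd_eye_intercept": float,
            "sd_eye_slope": float, "corr_eye": float, "sd_residual": float,
        },
        "grader_model": {
            "sd_uncorrected": float, "sd_grader": float,
            "uncorrected_bias": dict,
        },
    },
    "grid": {
        "center_radius_mm": float, "inner_radius_mm": float,
        "outer_radius_mm": float, "min_coverage_fraction": float,
    },
    "bootstrap": {"n_boot": int, "comparison": str, "stratify": str},
    "analysis": {
        "alpha": float, "m": int, "include_laterality": bool,
        "average_laterality": bool, "source": str,
    },
}


@dataclass
class RunConfig:
    """Validated run configuration (see the YAML schema in the docs)."""

    seed: int = 0
    out_dir: str = "octlayers_out"
    cohort: dict = field(default_factory=dict)
    grid: dict = field(default_factory=dict)
    bootstrap: dict = field(default_factory=dict)
    analysis: dict = field(default_factory=dict)

    def hash(self) -> str:
        payload = json.dumps(
            {"seed": self.seed, "cohort": self.cohort, "grid": self.grid,
             "bootstrap": self.bootstrap, "analysis": self.analysis},
            sort_keys=True, default=str,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _validate_block(block: dict, schema: dict, path: str) -> None:
    for key, val in block.items():
        if key not in schema:
            raise ValueError(f"unknown config key: {path}{key}")
        expect = schema[key]
        if isinstance(expect, dict):
            if not isinstance(val, dict):
                raise ValueError(f"config key {path}{key} must be a mapping")
            _validate_block(val, expect, f"{path}{key}.")
        elif expect is float:
            if not isinstance(val, (int, float)) or isinstance(val, bool):
                raise ValueError(f"config key {path}{key} must be a number")
        elif expect is int:
            if not isinstance(val, int) or isinstance(val, bool):
                raise ValueError(f"config key {path}{key} must be an integer")
        elif not isinstance(val, expect):
            raise ValueError(f"config key {path}{key} must be {expect.__name__}")


def load_config(path: str | Path) -> RunConfig:
    """Load and schema-validate a YAML run configuration; unknown keys
    are rejected."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError("config must be a YAML mapping")
    _validate_block(raw, _CONFIG_SCHEMA, "")
    return RunConfig(
        seed=raw.get("seed", 0),
        out_dir=raw.get("out_dir", "octlayers_out"),
        cohort=raw.get("cohort", {}),
        grid=raw.get("grid", {}),
        bootstrap=raw.get("bootstrap", {}),
        analysis=raw.get("analysis", {}),
    )


def cohort_params_from_config(cfg: RunConfig):
    """Build CohortParams from the config's cohort block plus the seed."""
    from .simulate import CohortParams, GraderModel, VarianceComponents

    block = dict(cfg.cohort)
    vc = block.pop("variance_components", {})
    gm = dict(block.pop("grader_model", {}))
    if "uncorrected_bias" in gm:
        gm["uncorrected_bias"] = {
            (tuple(k.split("|")) if "|" in k else k): float(v)
            for k, v in gm["uncorrected_bias"].items()
        }
    if "followup_years_range" in block:
        block["followup_years_range"] = tuple(block["followup_years_range"])
    return CohortParams(
        seed=cfg.seed,
        variance_components=VarianceComponents(**vc),
        grader_model=GraderModel(**gm) if gm else GraderModel(),
        **block,
    )
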