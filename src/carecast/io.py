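"""Delimited-file input/output for every pipeline artifact.

All files are UTF-8 comma-separated with a header row, period decimal
mark and LF line endings; every writer here is round-trippable through
the matching reader.
"""
from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd
import yaml

_CSV_KW = dict(index=False, lineterminator="\n")

DATA_DICTIONARY = {
    "panel.csv": {
        "person_id": "individual identifier",
        "wave": "survey wave (1-based, waves two years apart)",
        "age": "age in years at the wave",
        "gender": "male|female",
        "tenure": "owner|rented",
        "education": "none|nvq_gce_cse|degree_or_below",
        "income": "equivalised weekly income, GBP",
        "housing_problems": "count of housing problems, 0-12",
        "cesd_1..cesd_6": "negative-statement CES-D items (1=yes)",
        "cesd_7..cesd_8": "positive-statement CES-D items (1=yes)",
        "adl_count": "number of ADL difficulties",
        "iadl_count": "number of IADL difficulties",
        "unpaid_care": "receives unpaid care (bool)",
        "home_care": "receives formal home care (bool)",
        "unpaid_hours_week": "weekly unpaid-care hours (0 if no care)",
        "home_hours_week": "weekly home-care hours (0 if no care)",
        "alive": "record belongs to a living respondent",
    },
    "population.csv": {"age": "single year of age", "gender": "male|female",
                       "count": "base-year persons"},
    "mortality.csv": {"age": "single year of age", "gender": "male|female",
                      "q": "annual death probability"},
    "unit_costs.csv": {"year": "calendar year",
                       "unit_cost": "GBP per hour, 2022 prices"},
}


def write_table(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, **_CSV_KW)
    return path


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_series(series: pd.Series, path, index_name: str = "year") -> Path:
    df = series.rename_axis(index_name).reset_index()
    return write_table(df, path)


def read_unit_cost_path(path) -> pd.Series:
    df = pd.read_csv(path)
    return pd.Series(df["unit_cost"].to_numpy(), index=df["year"].to_numpy(),
                     name="unit_cost")


def write_data_dictionary(path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lines = ["# Data dictionary", ""]
    for fname, cols in DATA_DICTIONARY.items():
        lines.append(f"## {fname}")
        for col, desc in cols.items():
            lines.append(f"- `{col}`: {desc}")
        lines.append("")
    path.write_text("\n".join(lines), encoding="utf-8")
    return path


def write_config(config: dict, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
    return path


def read_config(path) -> dict:
    with open(path, encoding="utf-8") as fh:
        return yaml.safe_load(fh)


def config_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_run_log(path, config: dict, seeds: dict, extra: dict | None = None) -> Path:
    """Run log with config hash and seeds, enough to reproduce outputs."""
    import carecast
    log = {
        "package_version": carecast.__version__,
        "config_hash": config_hash(config),
        "seeds": seeds,
        "config": config,
    }
    if extra:
        log.update(extra)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(log, fh, sort_keys=True)
    return path
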