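"""Cohort file formats and run manifests.

All tables are tab-separated text with a header row, UTF-8, missing values
as empty fields (TSV avoids the decimal-comma ambiguity of CSV in the
clinical locale this data comes from).  Timestamps are decimal hours
post-inset (t3 = 0; intraoperative events negative).
"""

from __future__ import annotations

import json
import logging
from importlib.metadata import version
from pathlib import Path

import pandas as pd

from .config import RunConfig
from .hsi import Thresholds
from .records import CLINICAL_COLUMNS, Cohort, FLAP_COLUMNS, HSI_COLUMNS

logger = logging.getLogger(__name__)

FLAPS_FILE = "flaps.tsv"
HSI_FILE = "hsi_measurements.tsv"
CLINICAL_FILE = "clinical_observations.tsv"
DELTAS_FILE = "deltas.tsv"
DETECTIONS_FILE = "detections.tsv"
SCORES_FILE = "clinical_scores.tsv"
THRESHOLDS_FILE = "thresholds.json"
MANIFEST_FILE = "manifest.json"
REPORT_FILE = "report.txt"


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(Path(path), sep="\t", index=False, na_rep="")


def read_table(path, bool_columns: tuple[str, ...] = ()) -> pd.DataFrame:
    df = pd.read_csv(
        Path(path), sep="\t", keep_default_na=False, na_values=[""], float_precision="round_trip"
    )
    for col in bool_columns:
        if col in df.columns and df[col].dtype == object:
            df[col] = df[col].map({"True": True, "False": False})
    return df


def write_cohort(cohort: Cohort, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_table(cohort.flaps, directory / FLAPS_FILE)
    write_table(cohort.hsi, directory / HSI_FILE)
    write_table(cohort.clinical, directory / CLINICAL_FILE)


def read_cohort(directory) -> Cohort:
    directory = Path(directory)
    for name in (FLAPS_FILE, HSI_FILE, CLINICAL_FILE):
        if not (directory / name).exists():
            raise FileNotFoundError(f"cohort file {name} not found in {directory}")
    flaps = read_table(directory / FLAPS_FILE, bool_columns=("irradiated", "failed"))
    hsi = read_table(directory / HSI_FILE)
    clinical = read_table(directory / CLINICAL_FILE)
    for df, cols, what in (
        (flaps, FLAP_COLUMNS, FLAPS_FILE),
        (hsi, HSI_COLUMNS, HSI_FILE),
        (clinical, CLINICAL_COLUMNS, CLINICAL_FILE),
    ):
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise ValueError(f"{what} is missing required columns {missing}")
    return Cohort(flaps=flaps, hsi=hsi, clinical=clinical)


def write_thresholds(thresholds: Thresholds, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(thresholds.as_dict(), fh, indent=2)
        fh.write("\n")


def read_thresholds(path) -> Thresholds:
    with open(path, "r", encoding="utf-8") as fh:
        return Thresholds(**json.load(fh))


def write_manifest(config: RunConfig, directory, **extra) -> dict:
    """Record seed, config hash and package version next to the outputs."""
    try:
        pkg_version = version("flapmon")
    except Exception:  # not installed (e.g. direct source use)
        pkg_version = "unknown"
    manifest = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "package_version": pkg_version,
        **extra,
    }
    with open(Path(directory) / MANIFEST_FILE, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
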