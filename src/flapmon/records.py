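"""Domain records and table schemas.

Cohort data travels as three pandas DataFrames (flaps, HSI measurements,
clinical observations) whose columns match the dataclass fields below
one-to-one; the dataclasses are the single-record view used by the scoring
and detection rules.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from typing import Optional

import pandas as pd

# ---------------------------------------------------------------------------
# categorical vocabularies

FLAP_TYPES = ("RFF", "UFF", "OMFF", "LDF", "OMSF", "UAF")
REGIMES = ("primary", "secondary")
ARTERIES = ("superior_thyroid", "lingual", "external_carotid", "facial")
GROUPS = ("R_minus", "R_plus")
CAUSES = ("none", "venous_thrombosis", "arterial_thrombosis", "haematoma", "kinking")

COLORS = ("pale_white", "pink", "red", "blue")
TEMPERATURES = ("cold", "body", "superheated")
RECAPS = ("approx_1s", "gt_2s", "lt_1s", "none")
TURGORS = ("soft", "elastic", "plump")

HSI_PARAMETERS = ("sto2", "npi", "thi", "twi")


@dataclass
class FlapRecord:
    """Metadata of one free flap."""

    flap_id: str
    flap_type: str
    regime: str
    irradiated: bool
    recipient_artery: str
    surgery_duration: float  # minutes
    group: str  # R_minus / R_plus
    cause: str
    failed: bool
    clinical_detection_time: Optional[float] = None  # hours post-inset
    hsi_crossing_time: Optional[float] = None  # hours post-inset

    def __post_init__(self) -> None:
        if self.flap_type not in FLAP_TYPES:
            raise ValueError(f"unknown flap_type {self.flap_type!r}")
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        if self.cause not in CAUSES:
            raise ValueError(f"unknown cause {self.cause!r}")
        if (self.cause == "none") != (self.group == "R_minus"):
            raise ValueError("cause == 'none' must coincide with group R_minus")
        if self.failed and self.group != "R_plus":
            raise ValueError("a failed flap must belong to the revised group")
        if (self.clinical_detection_time is not None) != (self.group == "R_plus"):
            raise ValueError("clinical_detection_time present iff group R_plus")
        if self.hsi_crossing_time is not None and self.clinical_detection_time is not None:
            if self.hsi_crossing_time > self.clinical_detection_time:
                raise ValueError("HSI crossing must not be later than clinical detection")


@dataclass
class HsiMeasurement:
    """One hyperspectral monitoring event: flap-side and reference-site values.

    All eight parameter values live on the device's 0-100 scales (StO2 in
    percent, NPI/THI/TWI in arbitrary units); reference values are strictly
    positive so relative changes against them are defined.
    """

    flap_id: str
    timestamp: float  # hours post-inset, <= 0 for intraoperative points
    timepoint: str
    sto2: float
    npi: float
    thi: float
    twi: float
    ref_sto2: float
    ref_npi: float
    ref_thi: float
    ref_twi: float

    def __post_init__(self) -> None:
        for name in ("sto2", "npi", "thi", "twi", "ref_sto2", "ref_npi", "ref_thi", "ref_twi"):
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"{name}={v} outside the 0-100 parameter scale")
            if name.startswith("ref_") and v <= 0.0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass
class ClinicalObservation:
    """One bedside assessment of the four categorical perfusion signs.

    ``abnormal_color_duration`` is the number of minutes the flap colour has
    continuously been pale-white or blue up to this observation; it carries
    the cross-observation memory the re-exploration rule needs, so the rule
    itself stays stateless.
    """

    flap_id: str
    timestamp: float  # hours post-inset
    color: str
    temperature: str
    recap: str
    turgor: str
    abnormal_color_duration: float = 0.0  # minutes

    def __post_init__(self) -> None:
        if self.color not in COLORS:
            raise ValueError(f"unknown color {self.color!r}")
        if self.temperature not in TEMPERATURES:
            raise ValueError(f"unknown temperature {self.temperature!r}")
        if self.recap not in RECAPS:
            raise ValueError(f"unknown recap {self.recap!r}")
        if self.turgor not in TURGORS:
            raise ValueError(f"unknown turgor {self.turgor!r}")
        if self.color in ("pink", "red") and self.abnormal_color_duration != 0:
            raise ValueError("abnormal_color_duration must be 0 for pink/red flaps")


FLAP_COLUMNS = [f.name for f in fields(FlapRecord)]
HSI_COLUMNS = [f.name for f in fields(HsiMeasurement)]
CLINICAL_COLUMNS = [f.name for f in fields(ClinicalObservation)]


@dataclass
class Cohort:
    """A monitored flap cohort: one row per flap / HSI event / bedside check."""

    flaps: pd.DataFrame
    hsi: pd.DataFrame
    clinical: pd.DataFrame

    def __post_init__(self) -> None:
        for df, cols, what in (
            (self.flaps, FLAP_COLUMNS, "flaps"),
            (self.hsi, HSI_COLUMNS, "hsi"),
            (self.clinical, CLINICAL_COLUMNS, "clinical"),
        ):
            missing = [c for c in cols if c not in df.columns]
            if missing:
                raise ValueError(f"{what} table is missing columns {missing}")

    @property
    def n_flaps(self) -> int:
        return len(self.flaps)

    def subset(self, flap_ids) -> "Cohort":
        ids = list(flap_ids)
        return Cohort(
            flaps=self.flaps[self.flaps.flap_id.isin(ids)].reset_index(drop=True),
            hsi=self.hsi[self.hsi.flap_id.isin(ids)].reset_index(drop=True),
            clinical=self.clinical[self.clinical.flap_id.isin(ids)].reset_index(drop=True),
        )

    def equals(self, other: "Cohort") -> bool:
        return (
            self.flaps.equals(other.flaps)
            and self.hsi.equals(other.hsi)
            and self.clinical.equals(other.clinical)
        )
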