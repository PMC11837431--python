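"""Domain types and I/O for long-format mAb concentration-time datasets.

The interchange dialect is the NONMEM-style long format that popPK tools
exchange: one row per dose event (EVID=1) or observation (EVID=0), with a
separate per-subject covariate table.  Route is carried as an explicit ROUTE
column ("IV"/"SC") instead of compartment numbering, which differs between
tools.  Time is in days throughout; an optional TIME_UNIT column ("days",
"hours" or "weeks") is converted on read.

Observations below the assay lower limit of quantification (LLoQ) are kept
with ``blq=True`` rather than dropped; the fitting module decides how to treat
them (discard or censored likelihood).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .errors import IntegrityError, SchemaError, ValidationError

__all__ = [
    "Subject",
    "DoseEvent",
    "ConcRecord",
    "TrialDataset",
    "read_dataset",
    "write_dataset",
    "cockcroft_gault",
    "apply_inclusion_filters",
    "LLOQ_BAMA",
    "LLOQ_ELISA",
]

#: Lower limits of quantification of the two validated serum assays (µg/mL).
LLOQ_BAMA = 0.0457
LLOQ_ELISA = 1.0

_SEXES = ("female", "male")
_GROUPS = ("combination", "single")
_ROUTES = ("IV", "SC")


def cockcroft_gault(weight_kg, age_years, serum_creatinine_mg_dl, sex) -> float | np.ndarray:
    """Creatinine clearance (mL/min) by the Cockcroft-Gault equation.

    CrCl = (140 - age) * weight / (72 * SCr), multiplied by 0.85 for female
    sex at birth.  Accepts scalars or aligned arrays.
    """
    weight = np.asarray(weight_kg, dtype=float)
    age = np.asarray(age_years, dtype=float)
    scr = np.asarray(serum_creatinine_mg_dl, dtype=float)
    if np.any(weight <= 0) or np.any(age <= 0) or np.any(scr <= 0):
        raise ValueError("weight, age and serum creatinine must all be positive")
    if np.any(age >= 140):
        raise ValueError("age must be below 140 years (Cockcroft-Gault domain)")
    sex_arr = np.asarray(sex)
    female = np.char.lower(sex_arr.astype(str)) == "female"
    crcl = (140.0 - age) * weight / (72.0 * scr) * np.where(female, 0.85, 1.0)
    return float(crcl) if crcl.ndim == 0 else crcl


@dataclass
class Subject:
    """One trial participant with baseline covariates."""

    id: str
    weight: float  # kg
    age: float  # years
    sex: str  # "female" | "male"
    crcl: float  # mL/min
    group: str  # "combination" | "single"
    study: str = ""
    serum_creatinine: Optional[float] = None  # mg/dL

    def __post_init__(self) -> None:
        if self.weight <= 0:
            raise ValidationError(f"subject {self.id}: weight must be positive")
        if self.crcl <= 0:
            raise ValidationError(f"subject {self.id}: crcl must be positive")
        if self.sex not in _SEXES:
            raise ValidationError(f"subject {self.id}: sex must be one of {_SEXES}")
        if self.group not in _GROUPS:
            raise ValidationError(f"subject {self.id}: group must be one of {_GROUPS}")


@dataclass
class DoseEvent:
    subject_id: str
    time: float  # days
    amount: float  # mg
    route: str  # "IV" | "SC"

    def __post_init__(self) -> None:
        if self.amount <= 0:
            raise ValidationError(f"dose for {self.subject_id}: amount must be positive")
        if self.time < 0:
            raise ValidationError(f"dose for {self.subject_id}: time must be non-negative")
        if self.route not in _ROUTES:
            raise ValidationError(
                f"dose for {self.subject_id}: unknown route {self.route!r}; expected IV or SC"
            )


@dataclass
class ConcRecord:
    subject_id: str
    time: float  # days
    conc: float  # µg/mL (0 for below-LLoQ records without a reported value)
    blq: bool = False
    lloq: float = LLOQ_BAMA

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValidationError(f"observation for {self.subject_id}: time must be non-negative")
        if not self.blq and self.conc < 0:
            raise ValidationError(
                f"observation for {self.subject_id}: concentration must be non-negative"
            )


@dataclass
class TrialDataset:
    """Validated container tying subjects, doses and observations together."""

    subjects: list[Subject]
    doses: list[DoseEvent]
    observations: list[ConcRecord]

    def __post_init__(self) -> None:
        ids = [s.id for s in self.subjects]
        if len(set(ids)) != len(ids):
            raise IntegrityError("duplicate subject ids")
        known = set(ids)
        for d in self.doses:
            if d.subject_id not in known:
                raise IntegrityError(f"dose references unknown subject {d.subject_id!r}")
        for o in self.observations:
            if o.subject_id not in known:
                raise IntegrityError(f"observation references unknown subject {o.subject_id!r}")
        per_subject: dict[str, list[float]] = {}
        for d in self.doses:
            per_subject.setdefault(d.subject_id, []).append(d.time)
        for sid in known:
            times = sorted(per_subject.get(sid, []))
            if not times:
                raise IntegrityError(f"subject {sid!r} has no dose events")
            if any(b <= a for a, b in zip(times, times[1:])):
                raise IntegrityError(f"subject {sid!r}: dose times must be distinct")

    # -- frame conversion -------------------------------------------------
    def pk_frame(self) -> pd.DataFrame:
        rows = []
        for d in self.doses:
            rows.append(
                dict(ID=d.subject_id, TIME=d.time, AMT=d.amount, EVID=1, DV=np.nan, MDV=1,
                     ROUTE=d.route, BLQ=0, LLOQ=np.nan)
            )
        for o in self.observations:
            rows.append(
                dict(ID=o.subject_id, TIME=o.time, AMT=0.0, EVID=0, DV=o.conc,
                     MDV=int(o.blq), ROUTE="", BLQ=int(o.blq), LLOQ=o.lloq)
            )
        df = pd.DataFrame(rows)
        return df.sort_values(["ID", "TIME", "EVID"], ascending=[True, True, False],
                              kind="stable").reset_index(drop=True)

    def covariate_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            dict(
                ID=[s.id for s in self.subjects],
                WT=[s.weight for s in self.subjects],
                AGE=[s.age for s in self.subjects],
                SEX=[s.sex for s in self.subjects],
                SCR=[s.serum_creatinine for s in self.subjects],
                CRCL=[s.crcl for s in self.subjects],
                GROUP=[s.group for s in self.subjects],
                STUDY=[s.study for s in self.subjects],
            )
        )

    def subject_map(self) -> dict[str, Subject]:
        return {s.id: s for s in self.subjects}


_TIME_FACTORS = {"days": 1.0, "day": 1.0, "d": 1.0, "hours": 1.0 / 24.0, "hour": 1.0 / 24.0,
                 "h": 1.0 / 24.0, "weeks": 7.0, "week": 7.0, "w": 7.0}


def _normalise_columns(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    df.columns = [str(c).strip().upper() for c in df.columns]
    return df


def _require(df: pd.DataFrame, cols: Iterable[str], what: str) -> None:
    for col in cols:
        if col not in df.columns:
            raise SchemaError(f"{what} table is missing required column {col!r}")


def _parse_sex(value) -> str:
    s = str(value).strip().lower()
    if s in ("female", "f", "0"):
        return "female"
    if s in ("male", "m", "1"):
        return "male"
    raise SchemaError(f"cannot interpret sex code {value!r} (expected female/male/F/M/0/1)")


def read_dataset(pk_csv_path, covariate_csv_path) -> TrialDataset:
    """Read the PK long-format CSV plus the covariate CSV into a TrialDataset.

    Column names are case-insensitive.  EVID=1 rows become dose events, EVID=0
    rows become observations; MDV=1 observation rows with BLQ=1 are kept as
    censored records, MDV=1 without BLQ are treated as missing and skipped.
    CRCL is computed by Cockcroft-Gault from SCR when absent.
    """
    pk = _normalise_columns(pd.read_csv(pk_csv_path))
    cov = _normalise_columns(pd.read_csv(covariate_csv_path))
    _require(pk, ("ID", "TIME", "AMT", "EVID", "DV", "MDV", "ROUTE"), "PK")
    _require(cov, ("ID", "WT", "AGE", "SEX", "GROUP"), "covariate")
    if "CRCL" not in cov.columns and "SCR" not in cov.columns:
        raise SchemaError("covariate table is missing required column 'CRCL' (or 'SCR')")

    factor = np.ones(len(pk))
    if "TIME_UNIT" in pk.columns:
        units = pk["TIME_UNIT"].astype(str).str.strip().str.lower()
        bad = set(units) - set(_TIME_FACTORS)
        if bad:
            raise SchemaError(f"unknown TIME_UNIT values {sorted(bad)}")
        factor = units.map(_TIME_FACTORS).to_numpy()
    times = pk["TIME"].astype(float).to_numpy() * factor

    subjects = []
    for _, row in cov.iterrows():
        sex = _parse_sex(row["SEX"])
        scr = float(row["SCR"]) if "SCR" in cov.columns and pd.notna(row.get("SCR")) else None
        if "CRCL" in cov.columns and pd.notna(row.get("CRCL")):
            crcl = float(row["CRCL"])
        elif scr is not None:
            crcl = cockcroft_gault(float(row["WT"]), float(row["AGE"]), scr, sex)
        else:
            raise SchemaError(f"subject {row['ID']}: neither CRCL nor SCR available")
        group = str(row["GROUP"]).strip().lower()
        subjects.append(
            Subject(
                id=str(row["ID"]),
                weight=float(row["WT"]),
                age=float(row["AGE"]),
                sex=sex,
                crcl=crcl,
                group=group,
                study=str(row["STUDY"]) if "STUDY" in cov.columns and pd.notna(row.get("STUDY")) else "",
                serum_creatinine=scr,
            )
        )

    doses, observations = [], []
    for i, row in pk.iterrows():
        sid = str(row["ID"])
        t = float(times[i])
        if int(row["EVID"]) == 1:
            route = str(row["ROUTE"]).strip().upper()
            if route not in _ROUTES:
                raise ValidationError(f"unknown route code {row['ROUTE']!r} for subject {sid}")
            doses.append(DoseEvent(sid, t, float(row["AMT"]), route))
        else:
            blq = bool(int(row["BLQ"])) if "BLQ" in pk.columns and pd.notna(row.get("BLQ")) else False
            if int(row["MDV"]) == 1 and not blq:
                continue  # missing, not censored
            lloq = float(row["LLOQ"]) if "LLOQ" in pk.columns and pd.notna(row.get("LLOQ")) else LLOQ_BAMA
            dv = float(row["DV"]) if pd.notna(row["DV"]) else 0.0
            observations.append(ConcRecord(sid, t, dv, blq=blq, lloq=lloq))
    return TrialDataset(subjects, doses, observations)


def write_dataset(dataset: TrialDataset, pk_csv_path, covariate_csv_path) -> None:
    """Write the dataset back to the two-CSV interchange format."""
    dataset.pk_frame().to_csv(pk_csv_path, index=False)
    dataset.covariate_frame().to_csv(covariate_csv_path, index=False)


def apply_inclusion_filters(roster: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply the cross-protocol inclusion criteria to a participant roster.

    The roster has one row per enrolled participant with (case-insensitive)
    columns ID, ROUTE (IV/SC/IM), ARM (active/placebo) and RECEIVED (whether
    the participant actually received the analysed mAb).  Participants dosed
    intramuscularly, randomised to placebo, or who never received the product
    are excluded, in that order of precedence.

    Returns the retained roster rows and an exclusion tally whose categories
    partition the input (total = retained + excluded).
    """
    df = _normalise_columns(roster)
    _require(df, ("ID", "ROUTE", "ARM", "RECEIVED"), "roster")
    routes = df["ROUTE"].astype(str).str.strip().str.upper()
    unknown = set(routes) - {"IV", "SC", "IM"}
    if unknown:
        raise ValidationError(f"unknown route code(s) {sorted(unknown)} in roster")
    arm = df["ARM"].astype(str).str.strip().str.lower()
    received = df["RECEIVED"].astype(bool)

    is_im = routes == "IM"
    is_placebo = ~is_im & (arm == "placebo")
    not_received = ~is_im & ~is_placebo & ~received
    keep = ~(is_im | is_placebo | not_received)

    tally = {
        "total": int(len(df)),
        "retained": int(keep.sum()),
        "excluded_im_route": int(is_im.sum()),
        "excluded_placebo": int(is_placebo.sum()),
        "excluded_not_received": int(not_received.sum()),
    }
    return df.loc[keep].reset_index(drop=True), tally
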