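"""Longitudinal trial table: dose events, biomarker observations, covariates.

The on-disk dialect is a NONMEM-style rectangular CSV, one row per dose
event (``EVID=1``) or observation (``EVID=0``, ``MDV=0``), with subject-level
covariates repeated on every row.  Biomarker codes (``DVID``): 1 = troponin T
(ng/L), 2 = LVEF (fraction), 3 = NT-proBNP (pg/mL).  Time is in days since
the first anthracycline dose throughout the package; LVEF is stored as a
fraction.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from math import isnan
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DOXORUBICIN = "doxorubicin"
EPIRUBICIN = "epirubicin"
TRASTUZUMAB = "trastuzumab"
DRUGS = (DOXORUBICIN, EPIRUBICIN, TRASTUZUMAB)

TROPONIN_T = "troponin_t"
LVEF = "lvef"
NTPROBNP = "ntprobnp"
BIOMARKERS = (TROPONIN_T, LVEF, NTPROBNP)

#: DVID code <-> biomarker name
DVID_CODES = {1: TROPONIN_T, 2: LVEF, 3: NTPROBNP}
DVID_OF = {v: k for k, v in DVID_CODES.items()}

#: DRUG column code <-> drug name (dose rows only)
DRUG_CODES = {1: DOXORUBICIN, 2: EPIRUBICIN, 3: TRASTUZUMAB}
DRUG_OF = {v: k for k, v in DRUG_CODES.items()}

#: Assay lower limits of quantification, in each biomarker's native unit.
#: LVEF is never censored.
DEFAULT_LLOQ = {TROPONIN_T: 3.0, NTPROBNP: 5.0}

REQUIRED_COLUMNS = ("ID", "TIME", "AMT", "DV", "DVID", "EVID", "MDV")

COVARIATE_COLUMNS = (
    "AGE", "ACTYPE", "RTX", "RTXLAT", "HTN", "HTNSTAT", "ARM", "WT",
    "LVEFBL", "ACGAP",
)

RTXLAT_CODES = {0: "none", 1: "left", 2: "right"}
HTNSTAT_CODES = {0: "none", 1: "past", 2: "dormant", 3: "active"}
ARM_CODES = {0: "placebo", 1: "candesartan"}


class SchemaError(ValueError):
    """A required column is missing or mis-declared."""


class ValidationError(ValueError):
    """A row violates the dataset invariants."""


@dataclass
class DoseEvent:
    subject_id: str
    time: float                  # days since first anthracycline dose
    drug: str                    # one of DRUGS
    amount: float                # mg (trastuzumab: mg/kg x body weight)
    infusion_duration: float = 0.0  # days; 0 = bolus

    def __post_init__(self) -> None:
        if self.drug not in DRUGS:
            raise ValidationError(f"unknown drug {self.drug!r}")
        if self.time < 0:
            raise ValidationError("dose time must be >= 0")
        if self.amount <= 0:
            raise ValidationError("dose amount must be > 0")
        if self.infusion_duration < 0:
            raise ValidationError("infusion duration must be >= 0")


@dataclass
class ObservationRecord:
    subject_id: str
    time: float                  # days
    biomarker: str               # one of BIOMARKERS
    value: float                 # biomarker units (LVEF as fraction)
    below_lloq: bool = False
    lloq: float = float("nan")

    def __post_init__(self) -> None:
        if self.biomarker not in BIOMARKERS:
            raise ValidationError(f"unknown biomarker {self.biomarker!r}")
        if self.time < 0:
            raise ValidationError("observation time must be >= 0")
        if self.value <= 0:
            raise ValidationError("observed value must be > 0")


@dataclass
class SubjectCovariates:
    subject_id: str
    age: float = 50.0
    anthracycline_type: str = DOXORUBICIN
    prior_radiotherapy: bool = False
    radiotherapy_laterality: str = "none"   # left | right | none
    hypertension_dx: bool = False
    hypertension_status: str = "none"       # past | dormant | active | none
    treatment_arm: str = "placebo"          # candesartan | placebo
    body_weight: float = 70.0               # kg
    baseline_lvef_pre_trastuzumab: float = 0.6   # fraction
    ac_to_trastuzumab_gap: float = 21.0     # days

    def __post_init__(self) -> None:
        if self.anthracycline_type not in (DOXORUBICIN, EPIRUBICIN):
            raise ValidationError(
                f"anthracycline_type {self.anthracycline_type!r} invalid")
        if self.radiotherapy_laterality not in RTXLAT_CODES.values():
            raise ValidationError("invalid radiotherapy laterality")
        if self.hypertension_status not in HTNSTAT_CODES.values():
            raise ValidationError("invalid hypertension status")
        if self.treatment_arm not in ARM_CODES.values():
            raise ValidationError("invalid treatment arm")
        if self.ac_to_trastuzumab_gap < 0:
            raise ValidationError("anthracycline-to-trastuzumab gap must be >= 0")


def covariates_to_frame(covs: Sequence[SubjectCovariates]) -> pd.DataFrame:
    """Subject-level covariates as one row per subject (coded columns)."""
    rows = []
    for c in covs:
        rows.append({
            "ID": c.subject_id,
            "AGE": c.age,
            "ACTYPE": 0 if c.anthracycline_type == DOXORUBICIN else 1,
            "RTX": int(c.prior_radiotherapy),
            "RTXLAT": {v: k for k, v in RTXLAT_CODES.items()}[c.radiotherapy_laterality],
            "HTN": int(c.hypertension_dx),
            "HTNSTAT": {v: k for k, v in HTNSTAT_CODES.items()}[c.hypertension_status],
            "ARM": {v: k for k, v in ARM_CODES.items()}[c.treatment_arm],
            "WT": c.body_weight,
            "LVEFBL": c.baseline_lvef_pre_trastuzumab,
            "ACGAP": c.ac_to_trastuzumab_gap,
        })
    return pd.DataFrame(rows, columns=["ID", *COVARIATE_COLUMNS])


def covariates_from_frame(df: pd.DataFrame) -> list[SubjectCovariates]:
    out = []
    for _, r in df.iterrows():
        out.append(SubjectCovariates(
            subject_id=str(r["ID"]),
            age=float(r["AGE"]),
            anthracycline_type=DOXORUBICIN if int(r["ACTYPE"]) == 0 else EPIRUBICIN,
            prior_radiotherapy=bool(int(r["RTX"])),
            radiotherapy_laterality=RTXLAT_CODES[int(r["RTXLAT"])],
            hypertension_dx=bool(int(r["HTN"])),
            hypertension_status=HTNSTAT_CODES[int(r["HTNSTAT"])],
            treatment_arm=ARM_CODES[int(r["ARM"])],
            body_weight=float(r["WT"]),
            baseline_lvef_pre_trastuzumab=float(r["LVEFBL"]),
            ac_to_trastuzumab_gap=float(r["ACGAP"]),
        ))
    return out


def read_dataset(
    path,
    schema: Mapping[str, str] | None = None,
    lvef_as_percent: bool = False,
) -> tuple[list[DoseEvent], list[ObservationRecord], pd.DataFrame]:
    """Read a NONMEM-style rectangular CSV.

    Parameters
    ----------
    path:
        CSV file with at least ``ID, TIME, AMT, DV, DVID, EVID, MDV``.
        Dose rows additionally need ``DRUG`` (1=doxorubicin, 2=epirubicin,
        3=trastuzumab) and may carry ``DUR`` (infusion duration, days).
    schema:
        optional mapping from canonical column names to the file's names.
    lvef_as_percent:
        if True, LVEF observations in the file are percent and are divided
        by 100 on read.

    Returns
    -------
    (doses, observations, covariates) where covariates is one row per
    subject (columns as in :data:`COVARIATE_COLUMNS`, possibly empty).
    """
    df = pd.read_csv(path)
    if schema:
        df = df.rename(columns={v: k for k, v in schema.items()})
    if df.empty:
        logger.warning("dataset %s is empty", path)
        warnings.warn(f"dataset {path} is empty", stacklevel=2)
        return [], [], pd.DataFrame(columns=["ID", *COVARIATE_COLUMNS])

    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required columns: {missing}")
    if (df["TIME"] < 0).any():
        raise ValidationError("negative TIME in dataset")
    # row order within subject must be non-decreasing in time
    for sid, g in df.groupby("ID", sort=False):
        t = g["TIME"].to_numpy(float)
        if np.any(np.diff(t) < 0):
            raise ValidationError(f"TIME decreases within subject {sid}")

    doses: list[DoseEvent] = []
    observations: list[ObservationRecord] = []
    for _, r in df.iterrows():
        sid = str(r["ID"])
        if int(r["EVID"]) == 1:
            drug_code = int(r["DRUG"]) if "DRUG" in df.columns and not _isna(r["DRUG"]) else 1
            if drug_code not in DRUG_CODES:
                raise ValidationError(f"unknown DRUG code {drug_code}")
            dur = float(r["DUR"]) if "DUR" in df.columns and not _isna(r["DUR"]) else 0.0
            doses.append(DoseEvent(sid, float(r["TIME"]), DRUG_CODES[drug_code],
                                   float(r["AMT"]), dur))
        elif int(r["EVID"]) == 0 and int(r["MDV"]) == 0:
            dvid = int(r["DVID"])
            if dvid not in DVID_CODES:
                raise ValidationError(f"unknown DVID code {dvid}")
            biomarker = DVID_CODES[dvid]
            value = float(r["DV"])
            if biomarker == LVEF and lvef_as_percent:
                value /= 100.0
            below = bool(int(r["BLQ"])) if "BLQ" in df.columns and not _isna(r.get("BLQ")) else False
            lloq = float(r["LLOQ"]) if "LLOQ" in df.columns and not _isna(r.get("LLOQ")) else float("nan")
            observations.append(ObservationRecord(sid, float(r["TIME"]), biomarker,
                                                  value, below, lloq))

    cov_cols = [c for c in COVARIATE_COLUMNS if c in df.columns]
    if cov_cols:
        covariates = df.groupby("ID", sort=False)[cov_cols].first().reset_index()
    else:
        covariates = pd.DataFrame({"ID": df["ID"].astype(str).unique()})
    covariates["ID"] = covariates["ID"].astype(str)
    return doses, observations, covariates


def _isna(x) -> bool:
    try:
        return bool(pd.isna(x))
    except (TypeError, ValueError):
        return False


def write_dataset(
    path,
    doses: Sequence[DoseEvent],
    observations: Sequence[ObservationRecord],
    covariates: pd.DataFrame | Sequence[SubjectCovariates] | None = None,
) -> None:
    """Write the NONMEM-style CSV (inverse of :func:`read_dataset`).

    Events are emitted per subject in time order (doses before observations
    at ties), preserving numeric values exactly (full float repr).
    """
    if covariates is not None and not isinstance(covariates, pd.DataFrame):
        covariates = covariates_to_frame(covariates)
    rows = []
    for d in doses:
        rows.append({"ID": d.subject_id, "TIME": d.time, "AMT": d.amount,
                     "DV": 0.0, "DVID": 0, "EVID": 1, "MDV": 1,
                     "DRUG": DRUG_OF[d.drug], "DUR": d.infusion_duration,
                     "BLQ": 0, "LLOQ": float("nan"), "_k": 0})
    for o in observations:
        rows.append({"ID": o.subject_id, "TIME": o.time, "AMT": 0.0,
                     "DV": o.value, "DVID": DVID_OF[o.biomarker], "EVID": 0,
                     "MDV": 0, "DRUG": 0, "DUR": 0.0,
                     "BLQ": int(o.below_lloq), "LLOQ": o.lloq, "_k": 1})
    df = pd.DataFrame(rows)
    if df.empty:
        df = pd.DataFrame(columns=[*REQUIRED_COLUMNS, "DRUG", "DUR", "BLQ", "LLOQ"])
        df.to_csv(path, index=False)
        return
    order = {sid: i for i, sid in enumerate(dict.fromkeys(df["ID"]))}
    df["_s"] = df["ID"].map(order)
    df = df.sort_values(["_s", "TIME", "_k"], kind="stable").drop(columns=["_s", "_k"])
    if covariates is not None and not covariates.empty:
        covariates = covariates.copy()
        covariates["ID"] = covariates["ID"].astype(str)
        df["ID"] = df["ID"].astype(str)
        df = df.merge(covariates, on="ID", how="left")
    df.to_csv(path, index=False)


def apply_lloq_rule(
    observations: Iterable[ObservationRecord],
    lloq: Mapping[str, float] | None = None,
) -> list[ObservationRecord]:
    """Substitute below-LLOQ values by LLOQ/2 and flag them.

    Values strictly below the assay LLOQ are replaced by half the LLOQ;
    values at or above it (and all LVEF records) are returned unchanged.
    Idempotent: an already-substituted record (value = LLOQ/2, flagged) is
    left as is.
    """
    if lloq is None:
        lloq = DEFAULT_LLOQ
    for v in lloq.values():
        if v <= 0:
            raise ValueError("LLOQ must be positive")
    out = []
    for rec in observations:
        limit = lloq.get(rec.biomarker)
        if limit is None:
            out.append(rec)
            continue
        if rec.below_lloq:
            out.append(replace(rec, lloq=limit, value=limit / 2.0))
        elif rec.value < limit:
            out.append(replace(rec, below_lloq=True, lloq=limit, value=limit / 2.0))
        else:
            out.append(replace(rec, lloq=limit))
    return out
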