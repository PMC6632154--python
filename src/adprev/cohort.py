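"""Person-level cohort data model, CSV I/O, validation, and nested-cohort assembly.

The study design is three nested cohorts drawn from an enumerated population
aged 60 and over:

* the **clinical cohort** — in-person (actively ascertained) participants with
  a consensus clinical diagnosis, plus individuals with dementia found by
  passive medical-record review among nonparticipants;
* the **amyloid PET cohort** — the subset of active participants with an
  amyloid PET scan;
* the **tau PET cohort** — the subset of amyloid-PET participants who also
  underwent tau PET.

Records are held in a pandas DataFrame with one row per person; the column
schema is :data:`REQUIRED_COLUMNS` (+ optional extras).  CSV is the exchange
format: UTF-8, comma-separated, header row required, missing values written as
empty fields and read from "" or "NA".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

TAU_ROIS = ["temporal_meta", "entorhinal", "inferior_temporal", "lateral_parietal"]
TAU_COLUMNS = [f"tau_suvr_{roi}" for roi in TAU_ROIS]

SEXES = ["female", "male"]
ASCERTAINMENT = ["active", "passive", "nonparticipant", "excluded"]
CLINICAL_STATUSES = ["CU", "MCI", "dementia_probable_AD", "dementia_other", "unknown"]
DEMENTIA_STATUSES = ["dementia_probable_AD", "dementia_other"]
EDUCATION_LEVELS = ["<12", "12", "13-16", ">16"]

REQUIRED_COLUMNS = [
    "id",
    "age",
    "sex",
    "education",
    "ascertainment",
    "clinical_status",
    "enrolled",
    "has_amyloid_pet",
    "has_tau_pet",
    "amyloid_suvr",
    *TAU_COLUMNS,
]
#: accepted beyond the required schema; written back out when present
OPTIONAL_COLUMNS = ["education_years", "apoe_e4", "stratum_weight"]

_MISSING_TOKENS = {"", "NA", "NaN", "nan", "None"}
_FLAG_TRUE = {"1", "true", "True", "TRUE"}
_FLAG_FALSE = {"0", "false", "False", "FALSE"}

#: education-years to category binning (used when only years are supplied)
def bin_education_years(years) -> str | float:
    if years is None or (isinstance(years, float) and np.isnan(years)):
        return np.nan
    y = float(years)
    if y < 12:
        return "<12"
    if y == 12:
        return "12"
    if y <= 16:
        return "13-16"
    return ">16"


class CohortValidationError(ValueError):
    """Raised when records violate the cohort schema or nesting invariants.

    ``problems`` holds one human-readable message per offending row/field.
    """

    def __init__(self, problems: list[str]):
        self.problems = problems
        preview = "\n".join(problems[:20])
        more = f"\n... and {len(problems) - 20} more" if len(problems) > 20 else ""
        super().__init__(f"{len(problems)} validation problem(s):\n{preview}{more}")


@dataclass
class PersonRecord:
    """One enumerated individual (row-level convenience view of the frame)."""

    id: str
    age: int
    sex: str
    education: str | None
    ascertainment: str
    clinical_status: str
    enrolled: bool
    has_amyloid_pet: bool
    has_tau_pet: bool
    amyloid_suvr: float | None = None
    tau_suvr: dict = field(default_factory=dict)

    @classmethod
    def from_row(cls, row: pd.Series) -> "PersonRecord":
        tau = {
            roi: (None if pd.isna(row[f"tau_suvr_{roi}"]) else float(row[f"tau_suvr_{roi}"]))
            for roi in TAU_ROIS
        }
        return cls(
            id=str(row["id"]),
            age=int(row["age"]),
            sex=row["sex"],
            education=None if pd.isna(row["education"]) else row["education"],
            ascertainment=row["ascertainment"],
            clinical_status=row["clinical_status"],
            enrolled=bool(row["enrolled"]),
            has_amyloid_pet=bool(row["has_amyloid_pet"]),
            has_tau_pet=bool(row["has_tau_pet"]),
            amyloid_suvr=None if pd.isna(row["amyloid_suvr"]) else float(row["amyloid_suvr"]),
            tau_suvr=tau,
        )


def _offenders(frame: pd.DataFrame, mask: np.ndarray, message: str, problems: list[str]) -> None:
    if mask.any():
        ids = frame.loc[mask, "id"].astype(str).tolist()
        shown = ", ".join(ids[:10]) + (" ..." if len(ids) > 10 else "")
        problems.append(f"{message} (ids: {shown})")


def validate_records(frame: pd.DataFrame) -> None:
    """Validate schema values and nesting invariants; raise on any violation.

    Invariants enforced:

    * unique ids; age integer >= 60; categorical fields within vocabulary;
    * has_tau_pet => has_amyloid_pet => enrolled;
    * SUVR present exactly when the corresponding PET flag is set
      (tau: the primary temporal meta-ROI channel, the others follow it);
    * passive ascertainment => dementia diagnosis, not enrolled, no imaging;
    * enrolled => actively ascertained.
    """
    problems: list[str] = []
    missing_cols = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing_cols:
        raise CohortValidationError([f"missing required column(s): {missing_cols}"])

    if frame["id"].duplicated().any():
        dups = frame.loc[frame["id"].duplicated(), "id"].astype(str).unique()[:10]
        problems.append(f"duplicate ids: {', '.join(map(str, dups))}")

    age = frame["age"].to_numpy()
    _offenders(frame, ~np.isfinite(age.astype(float)) | (age.astype(float) < 60), "age missing or < 60", problems)
    _offenders(frame, ~frame["sex"].isin(SEXES).to_numpy(), "sex not in {female, male}", problems)
    edu_ok = frame["education"].isin(EDUCATION_LEVELS) | frame["education"].isna()
    _offenders(frame, ~edu_ok.to_numpy(), "education not a valid category", problems)
    _offenders(frame, ~frame["ascertainment"].isin(ASCERTAINMENT).to_numpy(), "invalid ascertainment", problems)
    _offenders(frame, ~frame["clinical_status"].isin(CLINICAL_STATUSES).to_numpy(), "invalid clinical_status", problems)

    enrolled = frame["enrolled"].astype(bool).to_numpy()
    amy = frame["has_amyloid_pet"].astype(bool).to_numpy()
    tau = frame["has_tau_pet"].astype(bool).to_numpy()
    _offenders(frame, tau & ~amy, "has_tau_pet without has_amyloid_pet", problems)
    _offenders(frame, amy & ~enrolled, "has_amyloid_pet without enrollment", problems)

    active = (frame["ascertainment"] == "active").to_numpy()
    passive = (frame["ascertainment"] == "passive").to_numpy()
    _offenders(frame, enrolled & ~active, "enrolled but not actively ascertained", problems)
    dem = frame["clinical_status"].isin(DEMENTIA_STATUSES).to_numpy()
    _offenders(frame, passive & ~dem, "passive ascertainment without dementia diagnosis", problems)
    _offenders(frame, passive & enrolled, "passive ascertainment but enrolled", problems)

    amy_suvr_present = frame["amyloid_suvr"].notna().to_numpy()
    _offenders(frame, amy_suvr_present != amy, "amyloid_suvr presence must match has_amyloid_pet", problems)
    tau_suvr_present = frame["tau_suvr_temporal_meta"].notna().to_numpy()
    _offenders(frame, tau_suvr_present != tau, "tau SUVR presence must match has_tau_pet", problems)
    _offenders(frame, amy_suvr_present & (frame["amyloid_suvr"].fillna(1.0).to_numpy() <= 0), "non-positive amyloid_suvr", problems)
    for col in TAU_COLUMNS:
        present = frame[col].notna().to_numpy()
        _offenders(frame, present & (frame[col].fillna(1.0).to_numpy() <= 0), f"non-positive {col}", problems)

    if problems:
        raise CohortValidationError(problems)


def _parse_flag(raw: pd.Series, col: str, problems: list[str]) -> pd.Series:
    out = pd.Series(np.zeros(len(raw), dtype=bool), index=raw.index)
    for i, v in raw.items():
        if v in _FLAG_TRUE:
            out.loc[i] = True
        elif v in _FLAG_FALSE or v is None:
            out.loc[i] = False
        else:
            problems.append(f"row {i + 2}, column {col}: cannot parse flag {v!r}")
    return out


def read_cohort(path, dialect: dict | None = None) -> pd.DataFrame:
    """Read person records from CSV with row-numbered parse diagnostics.

    Header names are matched case-insensitively; missing-value tokens
    ("", "NA") map to missing.  Raises :class:`CohortValidationError` on
    malformed numeric fields (naming row and column) or violated invariants.
    """
    opts = {"sep": ",", "encoding": "utf-8"}
    if dialect:
        opts.update(dialect)
    raw = pd.read_csv(path, dtype=str, keep_default_na=False, **opts)
    raw.columns = [c.strip().lower() for c in raw.columns]
    raw = raw.map(lambda v: None if v.strip() in _MISSING_TOKENS else v.strip())

    missing = [c for c in REQUIRED_COLUMNS if c not in raw.columns]
    if missing:
        raise CohortValidationError([f"missing required column(s): {missing}"])

    problems: list[str] = []
    out = pd.DataFrame(index=raw.index)
    out["id"] = raw["id"]
    for i, v in raw["id"].items():
        if v is None:
            problems.append(f"row {i + 2}, column id: missing id")

    def parse_num(col, caster, required=False):
        vals = []
        for i, v in raw[col].items():
            if v is None:
                if required:
                    problems.append(f"row {i + 2}, column {col}: missing value")
                vals.append(np.nan)
                continue
            try:
                vals.append(caster(v))
            except (TypeError, ValueError):
                problems.append(f"row {i + 2}, column {col}: cannot parse {v!r}")
                vals.append(np.nan)
        return np.asarray(vals, dtype=float)

    out["age"] = parse_num("age", lambda v: int(float(v)), required=True)
    for col in ["sex", "education", "ascertainment", "clinical_status"]:
        out[col] = raw[col].map(lambda v: np.nan if v is None else v)
    for col in ["enrolled", "has_amyloid_pet", "has_tau_pet"]:
        out[col] = _parse_flag(raw[col], col, problems)
    out["amyloid_suvr"] = parse_num("amyloid_suvr", float)
    for col in TAU_COLUMNS:
        out[col] = parse_num(col, float)
    for col in OPTIONAL_COLUMNS:
        if col in raw.columns:
            if col in ("education_years", "stratum_weight"):
                out[col] = parse_num(col, float)
            else:
                out[col] = raw[col].map(lambda v: np.nan if v is None else v)

    if problems:
        raise CohortValidationError(problems)
    # bin years into categories where the category itself is absent
    if "education_years" in out.columns:
        need = out["education"].isna() & out["education_years"].notna()
        out.loc[need, "education"] = out.loc[need, "education_years"].map(bin_education_years)
    out["age"] = out["age"].astype(int)
    validate_records(out)
    return out


def write_cohort(frame: pd.DataFrame, path) -> None:
    """Write records to CSV (missing as empty fields); round-trips with read_cohort."""
    cols = REQUIRED_COLUMNS + [c for c in OPTIONAL_COLUMNS if c in frame.columns]
    out = frame[cols].copy()
    for col in ["enrolled", "has_amyloid_pet", "has_tau_pet"]:
        out[col] = out[col].astype(bool).astype(int)
    out.to_csv(path, index=False, na_rep="")


@dataclass
class NestedCohorts:
    """The three nested analysis cohorts (clinical ⊇ amyloid ⊇ tau)."""

    clinical: pd.DataFrame
    amyloid: pd.DataFrame
    tau: pd.DataFrame

    @property
    def sizes(self) -> dict:
        return {"clinical": len(self.clinical), "amyloid": len(self.amyloid), "tau": len(self.tau)}


def assemble_nested_cohorts(records: pd.DataFrame) -> NestedCohorts:
    """Select the three nested cohorts from a validated record frame.

    clinical = active participants with a known diagnosis, plus passive
    dementia cases; amyloid/tau = flag-selected imaging subsets.
    """
    validate_records(records)
    active_known = (records["ascertainment"] == "active") & (records["clinical_status"] != "unknown")
    passive = records["ascertainment"] == "passive"
    clinical = records[active_known | passive]
    amyloid = records[records["has_amyloid_pet"].astype(bool)]
    tau = records[records["has_tau_pet"].astype(bool)]
    return NestedCohorts(clinical=clinical, amyloid=amyloid, tau=tau)
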