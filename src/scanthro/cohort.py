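"""Participant-level cohort table: I/O, derived indices, lifestyle coding, descriptives.

The cohort is a per-participant table combining bioelectrical-impedance (BIA)
body-composition outcomes -- relative fat mass (RFM, % of body weight),
visceral adipose tissue (VAT, kg) and skeletal muscle mass (SMM, kg) -- with
~30 continuous measures taken from a 3D surface scanner (girths and lengths in
cm, segment volumes in litres), plus age, sex and self-reported lifestyle
answers.  Everything downstream (stability selection, validation, the model
ladder) consumes a :class:`CohortTable`.

Heights are stored in cm and converted to metres only inside index formulas;
volumes are litres, matching scanner-output conventions.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from collections.abc import Iterator, Mapping, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import DomainError, EmptyStratumError, SchemaError, UsageError

log = logging.getLogger(__name__)

SEXES = ("male", "female")
OUTCOME_COLUMNS = {"rfm": "rfm_pct", "vat": "vat_kg", "smm": "smm_kg"}
FOOD_GROUPS = ("fruits", "vegetables", "wholegrain", "meat", "snacks")
FOOD_FLAG_COLUMNS = tuple(f"diet_{g}" for g in FOOD_GROUPS)
LIFESTYLE_RAW_COLUMNS = ("education_raw", "activity_raw") + FOOD_FLAG_COLUMNS

#: default scanner-derived measure set (name -> unit).  The concrete measure
#: list is config-driven; this default is named after the standard girth /
#: length / volume outputs of anthropometric scanner software.
DEFAULT_SCAN_MEASURES: dict[str, str] = {
    "waist_girth": "cm",
    "high_waist_girth": "cm",
    "hip_girth": "cm",
    "seat_girth": "cm",
    "maximum_belly_circumference": "cm",
    "bust_chest_girth_horizontal": "cm",
    "mid_neck_girth": "cm",
    "upper_arm_girth": "cm",
    "forearm_girth": "cm",
    "wrist_girth": "cm",
    "thigh_girth_horizontal": "cm",
    "knee_girth": "cm",
    "calf_girth": "cm",
    "ankle_girth": "cm",
    "volume_belly": "l",
    "volume_hip": "l",
    "volume_chest": "l",
    "volume_thigh": "l",
    "volume_arm": "l",
    "volume_forearm": "l",
    "volume_leg": "l",
    "volume_calf": "l",
    "volume_torso": "l",
    "volume_total": "l",
    "neck_to_waist_center_back": "cm",
    "cross_shoulder_over_neck": "cm",
    "arm_length": "cm",
    "inside_leg_length": "cm",
    "shoulder_width": "cm",
    "back_width": "cm",
}

_CORE_UNITS = {
    "id": None,
    "sex": None,
    "age": "years",
    "height_cm": "cm",
    "weight_kg": "kg",
    "rfm_pct": "%",
    "vat_kg": "kg",
    "smm_kg": "kg",
    "education_raw": None,
    "activity_raw": None,
}

MANDATORY_COLUMNS = tuple(_CORE_UNITS) + FOOD_FLAG_COLUMNS


# ---------------------------------------------------------------------------
# derived anthropometric indices
# ---------------------------------------------------------------------------

def compute_bmi(weight_kg: float, height_m: float) -> float:
    """Body mass index, weight / height**2 (kg/m^2)."""
    weight_kg = np.asarray(weight_kg, dtype=float)
    height_m = np.asarray(height_m, dtype=float)
    if np.any(weight_kg <= 0) or np.any(height_m <= 0):
        raise DomainError("BMI requires weight > 0 kg and height > 0 m")
    return weight_kg / height_m**2


def compute_smi(smm_kg: float, height_m: float) -> float:
    """Skeletal muscle mass index: SMM (kg) divided by squared height (m)."""
    smm_kg = np.asarray(smm_kg, dtype=float)
    height_m = np.asarray(height_m, dtype=float)
    if np.any(smm_kg < 0):
        raise DomainError("SMI requires skeletal muscle mass >= 0 kg")
    if np.any(height_m <= 0):
        raise DomainError("SMI requires height > 0 m")
    return smm_kg / height_m**2


def compute_ratios(wc_cm: float, hip_cm: float, height_cm: float):
    """Waist-to-height and waist-to-hip ratios, both dimensionless (cm/cm)."""
    wc_cm = np.asarray(wc_cm, dtype=float)
    hip_cm = np.asarray(hip_cm, dtype=float)
    height_cm = np.asarray(height_cm, dtype=float)
    if np.any(wc_cm <= 0) or np.any(hip_cm <= 0) or np.any(height_cm <= 0):
        raise DomainError("ratios require positive waist, hip and height (cm)")
    return wc_cm / height_cm, wc_cm / hip_cm


def diet_quality_index(food_flags: Sequence[bool]) -> int:
    """Diet Quality Index: count of the five food-group targets attained (0-5).

    One point per food group (fruits, vegetables, wholegrain products, meat,
    sweet/salty snacks) whose recommended weekly intake was achieved.
    """
    flags = list(food_flags)
    if len(flags) != len(FOOD_GROUPS):
        raise UsageError(
            f"diet_quality_index expects {len(FOOD_GROUPS)} flags, got {len(flags)}"
        )
    return int(sum(bool(f) for f in flags))


@dataclass(frozen=True)
class LifestyleCoding:
    """Grouped lifestyle covariates as they enter the regression models."""

    education: str  # primary_secondary | tertiary
    activity: str  # light | moderate | heavy
    diet_score: int  # 0..5
    diet: str  # unhealthy | medium | healthy


EDUCATION_LEVELS = ("primary_secondary", "tertiary")
ACTIVITY_LEVELS = ("light", "moderate", "heavy")
DIET_LEVELS = ("unhealthy", "medium", "healthy")


def code_lifestyle(education_raw: int, activity_raw: int, diet_score: int) -> LifestyleCoding:
    """Collapse raw questionnaire answers into the grouped lifestyle categories.

    Education answers 1-4 (mandatory through high school) are coded
    primary/secondary, 5-7 tertiary.  Leisure physical activity 1-2 -> light,
    3 -> moderate, 4-5 -> heavy.  Diet Quality Index 0-1 -> unhealthy,
    2-3 -> medium, 4-5 -> healthy.
    """
    education_raw = int(education_raw)
    activity_raw = int(activity_raw)
    diet_score = int(diet_score)
    if not 1 <= education_raw <= 7:
        raise DomainError(f"education_raw must be in 1..7, got {education_raw}")
    if not 1 <= activity_raw <= 5:
        raise DomainError(f"activity_raw must be in 1..5, got {activity_raw}")
    if not 0 <= diet_score <= 5:
        raise DomainError(f"diet_score must be in 0..5, got {diet_score}")
    education = "primary_secondary" if education_raw <= 4 else "tertiary"
    activity = "light" if activity_raw <= 2 else ("moderate" if activity_raw == 3 else "heavy")
    diet = "unhealthy" if diet_score <= 1 else ("medium" if diet_score <= 3 else "healthy")
    return LifestyleCoding(education, activity, diet_score, diet)


# ---------------------------------------------------------------------------
# WHO-style risk categories
# ---------------------------------------------------------------------------

# Printed ranges are closed on the left; the next category starts at its
# printed value, so e.g. waist 94.0 cm for men falls in "94.0-101.9" and
# 102.0 in ">=102.0".  The women's WHR ladder is resolved contiguously as
# [0.80, 0.85) then >=0.85.
_WHO_SEXLESS = {
    "bmi": ((18.5, "<18.5"), (25.0, "18.5–24.9"), (30.0, "25.0–29.9"), (None, "≥30")),
    # WHtR's first band is printed "<=0.5", i.e. closed on the RIGHT
    "whtr": (),
}
_WHO_SEXED = {
    ("wc", "male"): ((94.0, "<94.0"), (102.0, "94.0–101.9"), (None, "≥102.0")),
    ("wc", "female"): ((80.0, "<80.0"), (88.0, "80.0–87.9"), (None, "≥88.0")),
    ("whr", "male"): ((0.90, "<0.90"), (1.00, "0.90–0.99"), (None, "≥1.00")),
    ("whr", "female"): ((0.80, "<0.80"), (0.85, "0.80–0.84"), (None, "≥0.85")),
}


def who_category(measure: str, value: float, sex: str | None = None) -> str:
    """WHO-style risk category label for BMI, WHtR, WC or WHR.

    ``sex`` is required for the sex-specific WC and WHR cut-offs.  The
    category partition is exhaustive and mutually exclusive over positive
    values.
    """
    measure = measure.lower()
    value = float(value)
    if not np.isfinite(value) or value <= 0:
        raise DomainError(f"{measure} must be a positive finite value, got {value}")
    if measure == "bmi":
        bands = _WHO_SEXLESS["bmi"]
    elif measure == "whtr":
        if value <= 0.5:
            return "≤0.5"
        return "0.51–0.6" if value <= 0.6 else ">0.6"
    elif measure in ("wc", "whr"):
        if sex not in SEXES:
            raise UsageError(f"sex (male/female) is required for {measure} categories")
        bands = _WHO_SEXED[(measure, sex)]
    else:
        raise UsageError(f"unknown measure {measure!r}; expected bmi, whtr, wc or whr")
    for upper, label in bands:
        if upper is None or value < upper:
            return label
    raise AssertionError("unreachable: category bands are exhaustive")


# ---------------------------------------------------------------------------
# cohort container
# ---------------------------------------------------------------------------

@dataclass
class Participant:
    id: str
    sex: str
    age: int
    height: float  # cm
    weight: float  # kg
    scan_measures: dict[str, float]
    rfm: float  # % of body weight
    vat: float  # kg
    smm: float  # kg
    education_raw: int
    activity_raw: int
    food_flags: tuple[bool, bool, bool, bool, bool]

    @property
    def lifestyle(self) -> LifestyleCoding:
        return code_lifestyle(
            self.education_raw, self.activity_raw, diet_quality_index(self.food_flags)
        )


class CohortTable:
    """Ordered collection of participants backed by a pandas DataFrame.

    Parameters
    ----------
    data
        One row per participant using the canonical column names (``id``,
        ``sex``, ``age``, ``height_cm``, ``weight_kg``, outcome columns,
        lifestyle columns and one column per scanner measure).
    variable_dictionary
        Maps measure name -> (unit, role) where role is one of
        ``scan`` / ``outcome`` / ``lifestyle`` / ``demographic``.
    """

    def __init__(self, data: pd.DataFrame, variable_dictionary: Mapping[str, tuple[str, str]] | None = None):
        df = data.reset_index(drop=True).copy()
        missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"cohort table is missing mandatory columns: {missing}")
        if df["id"].duplicated().any():
            dupes = df.loc[df["id"].duplicated(), "id"].tolist()
            raise SchemaError(f"duplicate participant ids: {dupes}")
        bad_sex = set(df["sex"].dropna().unique()) - set(SEXES)
        if bad_sex:
            raise SchemaError(f"unknown sex labels {sorted(bad_sex)}; expected {SEXES}")
        if variable_dictionary is None:
            scan_cols = [c for c in df.columns if c in DEFAULT_SCAN_MEASURES]
            variable_dictionary = {c: (DEFAULT_SCAN_MEASURES[c], "scan") for c in scan_cols}
        self.variable_dictionary = dict(variable_dictionary)
        missing_scan = [m for m in self.scan_measures if m not in df.columns]
        if missing_scan:
            raise SchemaError(f"scan measure columns absent from table: {missing_scan}")
        self._validate_values(df)
        if "_incomplete" not in df.columns:
            df["_incomplete"] = self._incomplete_mask(df)
        if "_artefact" not in df.columns:
            df["_artefact"] = False
        self.data = df

    # -- basic structure ----------------------------------------------------
    @property
    def scan_measures(self) -> list[str]:
        return [m for m, (_, role) in self.variable_dictionary.items() if role == "scan"]

    @property
    def n(self) -> int:
        return len(self.data)

    def __len__(self) -> int:
        return self.n

    def stratum(self, sex: str) -> "CohortTable":
        if sex not in SEXES:
            raise UsageError(f"unknown stratum {sex!r}")
        sub = self.data[self.data["sex"] == sex]
        if sub.empty:
            raise EmptyStratumError(f"stratum {sex!r} is empty")
        return CohortTable(sub, self.variable_dictionary)

    def participants(self) -> Iterator[Participant]:
        for _, row in self.data.iterrows():
            yield Participant(
                id=str(row["id"]),
                sex=row["sex"],
                age=int(row["age"]),
                height=float(row["height_cm"]),
                weight=float(row["weight_kg"]),
                scan_measures={m: float(row[m]) for m in self.scan_measures},
                rfm=float(row["rfm_pct"]),
                vat=float(row["vat_kg"]),
                smm=float(row["smm_kg"]),
                education_raw=int(row["education_raw"]),
                activity_raw=int(row["activity_raw"]),
                food_flags=tuple(bool(row[c]) for c in FOOD_FLAG_COLUMNS),
            )

    # -- validation ---------------------------------------------------------
    def _validate_values(self, df: pd.DataFrame) -> None:
        checks = [
            ("height_cm", df["height_cm"] <= 0),
            ("weight_kg", df["weight_kg"] <= 0),
            ("rfm_pct", (df["rfm_pct"] < 0) | (df["rfm_pct"] > 100)),
            ("vat_kg", df["vat_kg"] < 0),
            ("smm_kg", df["smm_kg"] < 0),
            ("age", df["age"] < 18),
        ]
        for m in self.scan_measures:
            checks.append((m, df[m] <= 0))
        for col, bad in checks:
            bad = bad.fillna(False)
            if bad.any():
                ids = df.loc[bad, "id"].tolist()
                raise DomainError(f"column {col!r} violates its range for ids {ids}")

    def _incomplete_mask(self, df: pd.DataFrame) -> pd.Series:
        cols = list(LIFESTYLE_RAW_COLUMNS) + self.scan_measures + list(OUTCOME_COLUMNS.values())
        cols = [c for c in cols if c in df.columns]
        return df[cols].isna().any(axis=1)

    # -- derived indices ----------------------------------------------------
    def with_derived_indices(self) -> "CohortTable":
        """Return a copy with bmi, whtr, whr and smi columns appended."""
        df = self.data.copy()
        h_m = df["height_cm"] / 100.0
        df["bmi"] = compute_bmi(df["weight_kg"].to_numpy(), h_m.to_numpy())
        df["smi"] = compute_smi(df["smm_kg"].to_numpy(), h_m.to_numpy())
        if "waist_girth" in df.columns and "hip_girth" in df.columns:
            whtr, whr = compute_ratios(
                df["waist_girth"].to_numpy(),
                df["hip_girth"].to_numpy(),
                df["height_cm"].to_numpy(),
            )
            df["whtr"] = whtr
            df["whr"] = whr
        vd = dict(self.variable_dictionary)
        for name, unit in (("bmi", "kg/m2"), ("smi", "kg/m2"), ("whtr", "cm/cm"), ("whr", "cm/cm")):
            if name in df.columns:
                vd.setdefault(name, (unit, "scan"))
        out = CohortTable(df, vd)
        out.data["_incomplete"] = df["_incomplete"].to_numpy()
        out.data["_artefact"] = df["_artefact"].to_numpy()
        return out

    def to_csv(self, path: str | Path) -> None:
        self.data.drop(columns=["_incomplete", "_artefact"], errors="ignore").to_csv(
            path, index=False
        )


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def _parse_mapping(dictionary: Mapping | str | Path) -> dict[str, dict]:
    if isinstance(dictionary, (str, Path)):
        with open(dictionary) as fh:
            dictionary = yaml.safe_load(fh)
    if "columns" in dictionary:
        dictionary = dictionary["columns"]
    mapping = {}
    for canonical, entry in dictionary.items():
        if isinstance(entry, str):
            mapping[canonical] = {"column": entry, "unit": None}
        else:
            mapping[canonical] = {"column": entry["column"], "unit": entry.get("unit")}
    return mapping


def load_cohort(path: str | Path, dictionary: Mapping | str | Path | None = None) -> CohortTable:
    """Read a participant CSV into a typed :class:`CohortTable`.

    ``dictionary`` maps canonical variable names to CSV columns (plain string
    or ``{column: ..., unit: ...}``); omit it if the CSV already uses the
    canonical names.  Declared units are checked against the canonical unit
    for that variable.  Rows with missing lifestyle, scan or outcome values
    are retained but flagged incomplete; an optional ``scan_artefact`` column
    flags imperfect scans.
    """
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"cohort file not found: {path}")
    raw = pd.read_csv(path)
    if dictionary is not None:
        mapping = _parse_mapping(dictionary)
        missing = [m["column"] for m in mapping.values() if m["column"] not in raw.columns]
        if missing:
            raise SchemaError(f"CSV is missing mapped columns: {missing}")
        for canonical, entry in mapping.items():
            expected = _CORE_UNITS.get(canonical, DEFAULT_SCAN_MEASURES.get(canonical))
            if entry["unit"] is not None and expected is not None and entry["unit"] != expected:
                raise SchemaError(
                    f"column {entry['column']!r} declares unit {entry['unit']!r} "
                    f"but {canonical!r} is stored in {expected!r}"
                )
        raw = raw.rename(columns={m["column"]: canonical for canonical, m in mapping.items()})
        keep = [c for c in raw.columns if c in mapping or c == "scan_artefact"]
        raw = raw[keep]
    missing = [c for c in MANDATORY_COLUMNS if c not in raw.columns]
    if missing:
        raise SchemaError(f"cohort CSV is missing mandatory columns: {missing}")
    raw["sex"] = raw["sex"].astype(str).str.strip().str.lower()
    numeric_cols = [c for c in raw.columns if c not in ("id", "sex", "scan_artefact")]
    for col in numeric_cols:
        try:
            raw[col] = pd.to_numeric(raw[col])
        except (ValueError, TypeError) as exc:
            bad = raw.loc[pd.to_numeric(raw[col], errors="coerce").isna() & raw[col].notna(), "id"]
            raise SchemaError(
                f"unparseable values in column {col!r} for ids {bad.tolist()}"
            ) from exc
    artefact = raw.pop("scan_artefact").fillna(False).astype(bool) if "scan_artefact" in raw else None
    scan_cols = [c for c in raw.columns if c in DEFAULT_SCAN_MEASURES]
    vd = {c: (DEFAULT_SCAN_MEASURES[c], "scan") for c in scan_cols}
    cohort = CohortTable(raw, vd)
    if artefact is not None:
        cohort.data["_artefact"] = artefact.to_numpy()
    return cohort


# ---------------------------------------------------------------------------
# exclusions
# ---------------------------------------------------------------------------

@dataclass
class ExclusionReport:
    n_input: int
    n_retained: int
    n_missing_data: int
    n_scan_artefact: int
    excluded_ids: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(dataclasses.asdict(self), indent=2)
        if path is not None:
            Path(path).write_text(payload)
        return payload


def apply_exclusions(cohort: CohortTable) -> tuple[CohortTable, ExclusionReport]:
    """Drop flagged rows (complete-case analysis) and account for every row.

    Rows flagged as imperfect scans are counted as artefacts; of the
    remainder, rows with any missing lifestyle/scan/outcome value are counted
    as missing-data exclusions.  Retained + excluded always equals the input
    size.
    """
    df = cohort.data
    artefact = df["_artefact"].astype(bool)
    missing = df["_incomplete"].astype(bool) & ~artefact
    keep = ~(artefact | missing)
    report = ExclusionReport(
        n_input=len(df),
        n_retained=int(keep.sum()),
        n_missing_data=int(missing.sum()),
        n_scan_artefact=int(artefact.sum()),
        excluded_ids=df.loc[~keep, "id"].astype(str).tolist(),
    )
    if report.n_retained == 0:
        log.warning("apply_exclusions removed every row (%d excluded)", report.n_input)
        retained = CohortTable(df.iloc[:0], cohort.variable_dictionary)
    else:
        retained = CohortTable(df[keep], cohort.variable_dictionary)
    return retained, report


# ---------------------------------------------------------------------------
# descriptives
# ---------------------------------------------------------------------------

def cohort_descriptives(cohort: CohortTable, stratify_by: str = "sex") -> dict[str, pd.DataFrame]:
    """Per-stratum descriptive statistics.

    Continuous variables get mean and SD (SD of a single observation is
    reported as NaN, not 0); lifestyle and WHO categories get counts and
    relative frequencies summing to the stratum size.
    """
    df = cohort.with_derived_indices().data
    strata = sorted(df[stratify_by].dropna().unique())
    if not strata:
        raise EmptyStratumError(f"no strata found for {stratify_by!r}")
    cont_vars = ["age", "height_cm", "weight_kg", "bmi", "smi", "rfm_pct", "vat_kg", "smm_kg"]
    cont_vars += [c for c in ("whtr", "whr") if c in df.columns]
    cont_vars += cohort.scan_measures
    cont_rows, cat_rows = [], []
    for s in strata:
        sub = df[df[stratify_by] == s]
        if sub.empty:
            raise EmptyStratumError(f"stratum {s!r} is empty")
        for v in cont_vars:
            vals = sub[v].dropna()
            cont_rows.append(
                {
                    "stratum": s,
                    "variable": v,
                    "n": len(vals),
                    "mean": vals.mean() if len(vals) else np.nan,
                    "sd": vals.std(ddof=1) if len(vals) > 1 else np.nan,
                }
            )
        cats = _categorical_frame(sub)
        for var, series in cats.items():
            counts = series.value_counts()
            for level, count in counts.items():
                cat_rows.append(
                    {
                        "stratum": s,
                        "variable": var,
                        "level": level,
                        "n": int(count),
                        "pct": 100.0 * count / len(series),
                    }
                )
    return {"continuous": pd.DataFrame(cont_rows), "categorical": pd.DataFrame(cat_rows)}


def _categorical_frame(sub: pd.DataFrame) -> dict[str, pd.Series]:
    complete = sub.dropna(subset=[c for c in LIFESTYLE_RAW_COLUMNS if c in sub.columns])
    out: dict[str, pd.Series] = {}
    if not complete.empty:
        codes = [
            code_lifestyle(
                r["education_raw"],
                r["activity_raw"],
                diet_quality_index([r[c] for c in FOOD_FLAG_COLUMNS]),
            )
            for _, r in complete.iterrows()
        ]
        out["education"] = pd.Series([c.education for c in codes])
        out["activity"] = pd.Series([c.activity for c in codes])
        out["diet"] = pd.Series([c.diet for c in codes])
    for measure, col in (("bmi", "bmi"), ("whtr", "whtr"), ("wc", "waist_girth"), ("whr", "whr")):
        if col in sub.columns:
            vals = sub.dropna(subset=[col])
            if not vals.empty:
                out[f"{measure}_category"] = pd.Series(
                    [who_category(measure, v, s) for v, s in zip(vals[col], vals["sex"])]
                )
    return out


def add_lifestyle_dummies(df: pd.DataFrame) -> pd.DataFrame:
    """Append treatment-coded dummies for the three lifestyle categoricals.

    Reference levels: primary/secondary education, light activity, unhealthy
    diet.  Produces ``edu_tertiary``, ``act_moderate``, ``act_heavy``,
    ``diet_medium``, ``diet_healthy``.
    """
    df = df.copy()
    codes = [
        code_lifestyle(
            r["education_raw"],
            r["activity_raw"],
            diet_quality_index([r[c] for c in FOOD_FLAG_COLUMNS]),
        )
        for _, r in df.iterrows()
    ]
    df["edu_tertiary"] = [1.0 if c.education == "tertiary" else 0.0 for c in codes]
    df["act_moderate"] = [1.0 if c.activity == "moderate" else 0.0 for c in codes]
    df["act_heavy"] = [1.0 if c.activity == "heavy" else 0.0 for c in codes]
    df["diet_medium"] = [1.0 if c.diet == "medium" else 0.0 for c in codes]
    df["diet_healthy"] = [1.0 if c.diet == "healthy" else 0.0 for c in codes]
    return df


#: dummy-column blocks for the lifestyle categoricals; these enter and leave
#: variable selection as whole blocks.
LIFESTYLE_GROUPS = {
    "education": ("edu_tertiary",),
    "activity": ("act_moderate", "act_heavy"),
    "diet": ("diet_medium", "diet_healthy"),
}
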