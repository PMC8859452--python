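"""Longitudinal cohort tables: loading, validation, selection, normative reference.

The universal input of the pipeline is a long-format table with one row per
subject-visit carrying the biomarker SUVR and covariates.  This module
validates that contract, applies the AD-continuum inclusion rule (keep anyone
amyloid-positive at least once, and anyone who stays cognitively normal
throughout follow-up), derives the normative reference (mean/SD of the
biomarker in amyloid-negative, always-CN subjects) used for time-zero
anchoring and z-transformation, and turns the reference into a positivity
cutoff at a given z magnitude.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import (
    CohortValidationError,
    InsufficientNormativeGroupError,
    SuvtrajError,
)

logger = logging.getLogger(__name__)

#: canonical column order of an observation table
COLUMNS = [
    "subject_id",
    "visit_time",
    "suvr",
    "sex",
    "apoe4_carrier",
    "diagnosis",
    "amyloid_positive",
]

SEX_VALUES = {"female", "male", "unknown"}
DIAGNOSIS_VALUES = {"CN", "MCI", "Dementia"}

_TRUE_STRINGS = {"true", "t", "1", "yes", "y"}
_FALSE_STRINGS = {"false", "f", "0", "no", "n"}
_UNKNOWN_STRINGS = {"", "unknown", "na", "nan", "none"}


def _coerce_flag(series: pd.Series, name: str) -> pd.Series:
    """Coerce a column to pandas nullable boolean, mapping unknown markers to NA."""
    if series.dtype == bool:
        return series.astype("boolean")
    if str(series.dtype) == "boolean":
        return series

    def one(v):
        if v is None or (isinstance(v, float) and np.isnan(v)):
            return pd.NA
        if isinstance(v, (bool, np.bool_)):
            return bool(v)
        s = str(v).strip().lower()
        if s in _TRUE_STRINGS:
            return True
        if s in _FALSE_STRINGS:
            return False
        if s in _UNKNOWN_STRINGS:
            return pd.NA
        raise CohortValidationError(f"cannot interpret {name!r} value {v!r} as a flag")

    return pd.Series([one(v) for v in series], index=series.index, dtype="boolean")


def validate_table(df: pd.DataFrame) -> pd.DataFrame:
    """Validate and normalise an observation table.

    Checks the column set, numeric types, strictly positive finite SUVR,
    uniqueness of (subject, time), and constancy of sex/APOE within subject.
    Returns a copy sorted by (subject_id, visit_time).
    """
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise CohortValidationError(f"missing required columns: {missing}")
    out = df.loc[:, COLUMNS].copy()

    for col in ("visit_time", "suvr"):
        coerced = pd.to_numeric(out[col], errors="coerce")
        bad = coerced.isna() & out[col].notna()
        if bad.any():
            idx = int(np.flatnonzero(bad.to_numpy())[0])
            raise CohortValidationError(
                f"non-numeric {col} at row index {out.index[idx]}: {out[col].iloc[idx]!r}"
            )
        if coerced.isna().any():
            idx = int(np.flatnonzero(coerced.isna().to_numpy())[0])
            raise CohortValidationError(f"missing {col} at row index {out.index[idx]}")
        out[col] = coerced.astype(float)

    if not np.all(np.isfinite(out["suvr"])) or (out["suvr"] <= 0).any():
        bad = out.loc[~np.isfinite(out["suvr"]) | (out["suvr"] <= 0)]
        raise CohortValidationError(
            f"suvr must be finite and > 0; offending subjects: "
            f"{sorted(bad['subject_id'].astype(str).unique())[:5]}"
        )

    out["subject_id"] = out["subject_id"].astype(str)
    out["sex"] = (
        out["sex"].astype(object).where(out["sex"].notna(), "unknown").astype(str).str.lower()
    )
    bad_sex = set(out["sex"].unique()) - SEX_VALUES
    if bad_sex:
        raise CohortValidationError(f"invalid sex values: {sorted(bad_sex)}")

    out["diagnosis"] = out["diagnosis"].astype(str)
    bad_dx = set(out["diagnosis"].unique()) - DIAGNOSIS_VALUES
    if bad_dx:
        raise CohortValidationError(f"invalid diagnosis values: {sorted(bad_dx)}")

    out["apoe4_carrier"] = _coerce_flag(out["apoe4_carrier"], "apoe4_carrier")
    out["amyloid_positive"] = _coerce_flag(out["amyloid_positive"], "amyloid_positive")

    dup = out.duplicated(subset=["subject_id", "visit_time"], keep=False)
    if dup.any():
        subj = out.loc[dup, "subject_id"].iloc[0]
        raise CohortValidationError(
            f"duplicate (subject, visit_time) pair for subject {subj!r}"
        )

    # sex and APOE carrier status must not change across a subject's visits
    for col in ("sex", "apoe4_carrier"):
        n_per = out.groupby("subject_id")[col].nunique(dropna=False)
        if (n_per > 1).any():
            subj = n_per.index[n_per > 1][0]
            raise CohortValidationError(
                f"covariate {col!r} varies within subject {subj!r}"
            )

    out = out.sort_values(["subject_id", "visit_time"], kind="mergesort").reset_index(
        drop=True
    )
    return out


def load_long_table(
    path: str | Path,
    column_map: dict[str, str] | None = None,
    sep: str = ",",
) -> pd.DataFrame:
    """Read a delimited long-format table and validate it.

    ``column_map`` maps canonical names (see :data:`COLUMNS`) to the file's
    column names; omitted entries default to the canonical name itself.
    Empty fields in covariate columns are preserved as unknown.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = pd.read_csv(path, sep=sep, comment="#", dtype=object, keep_default_na=True)
    column_map = dict(column_map or {})
    rename = {}
    for canonical in COLUMNS:
        source = column_map.get(canonical, canonical)
        if source not in raw.columns:
            raise CohortValidationError(
                f"column {source!r} (for {canonical!r}) not found in {path.name}"
            )
        rename[source] = canonical
    return validate_table(raw.rename(columns=rename))


def write_long_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write an observation table as CSV (unknown flags become empty fields)."""
    out = df.loc[:, COLUMNS].copy()
    for col in ("apoe4_carrier", "amyloid_positive"):
        out[col] = out[col].map(
            lambda v: "" if pd.isna(v) else ("true" if v else "false")
        )
    out.to_csv(path, index=False)


def select_ad_continuum(table: pd.DataFrame) -> pd.DataFrame:
    """Restrict a cohort to the AD continuum.

    Keeps (a) every subject amyloid-positive at >= 1 visit regardless of
    cognition and (b) every subject cognitively normal at every visit
    regardless of amyloid status.  Subjects ever cognitively impaired but
    never amyloid-positive are dropped; impaired subjects whose amyloid
    status is wholly unknown are dropped with a logged warning.
    """
    grp = table.groupby("subject_id", sort=False)
    ever_positive = grp["amyloid_positive"].agg(lambda s: bool((s == True).any()))  # noqa: E712
    always_cn = grp["diagnosis"].agg(lambda s: bool((s == "CN").all()))
    all_unknown = grp["amyloid_positive"].agg(lambda s: bool(s.isna().all()))

    keep = ever_positive | always_cn
    dropped_unknown = sorted(keep.index[(~keep) & all_unknown])
    if dropped_unknown:
        logger.warning(
            "excluding %d cognitively impaired subject(s) with wholly unknown "
            "amyloid status: %s",
            len(dropped_unknown),
            dropped_unknown[:10],
        )
    kept_ids = set(keep.index[keep])
    return table[table["subject_id"].isin(kept_ids)].reset_index(drop=True)


@dataclass(frozen=True)
class NormativeReference:
    """Normative mean/SD of a biomarker in amyloid-negative, always-CN subjects."""

    biomarker_name: str
    n: int
    mean: float
    sd: float

    def __post_init__(self):
        if self.n < 2:
            raise InsufficientNormativeGroupError(
                f"normative group needs >= 2 subjects, got {self.n}"
            )
        if not self.sd > 0:
            raise SuvtrajError(f"normative sd must be > 0, got {self.sd}")

    def z_score(self, level):
        """Standardize a level (or array of levels) against this reference."""
        return (np.asarray(level, dtype=float) - self.mean) / self.sd

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, indent=2)
        if path is not None:
            Path(path).write_text(payload + "\n")
        return payload

    @classmethod
    def from_json(cls, source: str | Path) -> "NormativeReference":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        d = json.loads(text)
        return cls(**d)


def derive_normative_reference(
    table: pd.DataFrame, biomarker_name: str = "suvr"
) -> NormativeReference:
    """Mean/SD of baseline SUVR over amyloid-negative, always-CN subjects.

    Only each qualifying subject's first visit enters the statistics, so the
    subject count ``n`` is not inflated by within-subject correlation.
    Subjects must be CN at every visit and explicitly amyloid-negative at
    every visit (unknown status does not qualify).
    """
    grp = table.groupby("subject_id", sort=False)
    always_cn = grp["diagnosis"].agg(lambda s: bool((s == "CN").all()))
    always_negative = grp["amyloid_positive"].agg(lambda s: bool((s == False).all()))  # noqa: E712
    ids = set(always_cn.index[always_cn & always_negative])
    if len(ids) < 2:
        raise InsufficientNormativeGroupError(
            f"only {len(ids)} amyloid-negative always-CN subject(s); need >= 2"
        )
    sub = table[table["subject_id"].isin(ids)].sort_values(
        ["subject_id", "visit_time"]
    )
    baseline = sub.groupby("subject_id", sort=True)["suvr"].first()
    return NormativeReference(
        biomarker_name=biomarker_name,
        n=int(baseline.size),
        mean=float(baseline.mean()),
        sd=float(baseline.std(ddof=1)),
    )


@dataclass(frozen=True)
class CutoffSpec:
    """Positivity cutoff expressed as a z magnitude above the normative mean.

    The convention in part of the PET literature writes such cutoffs with a
    negative z sign; here the magnitude is stored and the cutoff always lies
    ``z_magnitude`` SDs above the mean for an accumulating biomarker.
    """

    z_magnitude: float
    cutoff_value: float

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, indent=2)
        if path is not None:
            Path(path).write_text(payload + "\n")
        return payload

    @classmethod
    def from_json(cls, source: str | Path) -> "CutoffSpec":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        return cls(**json.loads(text))


def compute_cutoff(ref: NormativeReference, z_magnitude: float = 2.0) -> CutoffSpec:
    """Cutoff value = normative mean + z_magnitude * normative SD."""
    if not ref.sd > 0:
        raise SuvtrajError(f"invalid normative reference: sd={ref.sd}")
    if z_magnitude < 0:
        raise ValueError(f"z_magnitude must be >= 0, got {z_magnitude}")
    return CutoffSpec(
        z_magnitude=float(z_magnitude),
        cutoff_value=float(ref.mean + z_magnitude * ref.sd),
    )


def flag_amyloid_positive(table: pd.DataFrame, cutoff: CutoffSpec) -> pd.DataFrame:
    """Fill unknown per-visit amyloid flags as ``suvr >= cutoff`` (convenience path)."""
    out = table.copy()
    unknown = out["amyloid_positive"].isna()
    out.loc[unknown, "amyloid_positive"] = (
        out.loc[unknown, "suvr"] >= cutoff.cutoff_value
    )
    out["amyloid_positive"] = out["amyloid_positive"].astype("boolean")
    return out
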