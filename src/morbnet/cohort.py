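"""Study-design stage: index dates, exact matching, follow-up, comorbidity
profiles, the prevalence filter and the multimorbidity flag.

The design mirrors a retrospective matched-cohort EHR study: the index date is
the first qualifying index-disease record; comparators are selected by 1:1
exact matching on sex and index age (in whole years); comorbid conditions are
diagnosis codes recorded on or after the index date, restricted to ICD-10
Chapters I-XIV, excluding the index disease itself; and a condition enters the
analysis only if its prevalence is at least 1% within the diabetes-type
cohort.  Multimorbidity means two or more retained conditions.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError
from .icd import DEFAULT_CHAPTER_WHITELIST

_DAYS_PER_YEAR = 365.25


@dataclass(frozen=True)
class ComorbidityProfile:
    """Retained comorbid conditions of one patient."""

    patient_id: str
    conditions: frozenset[str]

    @property
    def is_multimorbid(self) -> bool:
        return len(self.conditions) >= 2


@dataclass
class MatchedCohort:
    """Result of 1:1 exact matching: (case, comparator) id pairs + unmatched."""

    pairs: list[tuple[str, str]] = field(default_factory=list)
    unmatched: list[tuple[str, str]] = field(default_factory=list)  # (id, reason)

    @property
    def case_ids(self) -> list[str]:
        return [a for a, _ in self.pairs]

    @property
    def comparator_ids(self) -> list[str]:
        return [b for _, b in self.pairs]


def assign_index_date(
    diagnoses: pd.DataFrame, patient_id: str, index_codes: Iterable[str]
) -> dt.date:
    """Earliest diagnosis date of any index-disease code for one patient.

    Raises :class:`DataError` if the patient has no qualifying record (callers
    exclude such patients with a logged reason rather than aborting a run).
    """
    codes = set(index_codes)
    rows = diagnoses[
        (diagnoses["patient_id"] == patient_id)
        & (diagnoses["condition_code"].isin(codes))
    ]
    if rows.empty:
        raise DataError(
            f"patient {patient_id}: no index-disease diagnosis record"
        )
    return _as_date(rows["diagnosis_date"].min())


def assign_index_dates(
    diagnoses: pd.DataFrame, index_codes: Iterable[str]
) -> pd.Series:
    """Vectorised variant: patient_id -> earliest index-code diagnosis date."""
    codes = set(index_codes)
    rows = diagnoses[diagnoses["condition_code"].isin(codes)]
    return rows.groupby("patient_id")["diagnosis_date"].min()


def observed_followup(
    index_date, last_visit_date, patient_id: str | None = None
) -> float:
    """Observed follow-up in years: calendar days between dates / 365.25."""
    d0, d1 = _as_date(index_date), _as_date(last_visit_date)
    days = (d1 - d0).days
    if days < 0:
        who = f" for patient {patient_id}" if patient_id else ""
        raise DataError(
            f"last_visit_date precedes index_date{who} ({d1} < {d0})"
        )
    return days / _DAYS_PER_YEAR


def match_cohorts(
    cases: pd.DataFrame, comparators: pd.DataFrame, seed: int = 0
) -> MatchedCohort:
    """1:1 exact matching on (sex, index_age_years).

    Within each stratum, ``min(n_cases, n_comparators)`` pairs are formed;
    when one side outnumbers the other, the participants kept are drawn
    uniformly without replacement from the ids sorted lexicographically, so
    the result is deterministic for a fixed seed and independent of input row
    order.  Cases left without a comparator are reported unmatched, not
    raised.
    """
    for name, df in (("cases", cases), ("comparators", comparators)):
        if df.empty:
            raise DataError(f"{name} table is empty")
        for col in ("patient_id", "sex", "index_age_years"):
            if col not in df.columns:
                raise DataError(f"{name} table missing required column {col!r}")

    rng = np.random.default_rng(seed)
    result = MatchedCohort()

    def strata(df):
        return {
            key: sorted(grp["patient_id"].astype(str))
            for key, grp in df.groupby(["sex", "index_age_years"], sort=True)
        }

    case_strata = strata(cases)
    comp_strata = strata(comparators)

    for key in sorted(case_strata):
        case_ids = case_strata[key]
        comp_ids = comp_strata.get(key, [])
        k = min(len(case_ids), len(comp_ids))
        if k == 0:
            result.unmatched.extend(
                (pid, "no_comparator_in_stratum") for pid in case_ids
            )
            continue
        chosen_cases = case_ids if len(case_ids) == k else sorted(
            rng.choice(case_ids, size=k, replace=False)
        )
        chosen_comps = comp_ids if len(comp_ids) == k else sorted(
            rng.choice(comp_ids, size=k, replace=False)
        )
        result.pairs.extend(zip(chosen_cases, chosen_comps))
        result.unmatched.extend(
            (pid, "case_not_selected")
            for pid in case_ids if pid not in set(chosen_cases)
        )
        result.unmatched.extend(
            (pid, "comparator_not_selected")
            for pid in comp_ids if pid not in set(chosen_comps)
        )
    for key in sorted(set(comp_strata) - set(case_strata)):
        result.unmatched.extend(
            (pid, "no_case_in_stratum") for pid in comp_strata[key]
        )
    return result


def extract_comorbidities(
    patient_id: str,
    index_date,
    diagnoses: pd.DataFrame,
    catalog: pd.DataFrame,
    chapters: frozenset[str] = DEFAULT_CHAPTER_WHITELIST,
) -> frozenset[str]:
    """Comorbid condition codes of one patient.

    A code qualifies if it is recorded on or after the index date (same-day
    codes at the index visit count), maps to a whitelisted ICD-10 chapter, and
    is not flagged as the index disease.  Diabetes-specific complications are
    ordinary conditions here: only the generic diabetes labels are excluded.
    """
    _check_catalog_covers(diagnoses, catalog)
    rows = diagnoses[diagnoses["patient_id"] == patient_id]
    return _filter_codes(rows, _as_date(index_date), catalog, chapters)


def build_profiles(
    patients: pd.DataFrame,
    diagnoses: pd.DataFrame,
    catalog: pd.DataFrame,
    chapters: frozenset[str] = DEFAULT_CHAPTER_WHITELIST,
) -> dict[str, ComorbidityProfile]:
    """Vectorised comorbidity extraction for every patient in ``patients``.

    ``patients`` must carry patient_id and index_date.  Patients with no
    qualifying diagnosis get an empty profile.
    """
    _check_catalog_covers(diagnoses, catalog)
    cat = catalog.set_index("condition_code")
    eligible_codes = set(
        cat.index[(cat["icd10_chapter"].isin(chapters)) & (cat["is_index_disease"] == 0)]
    )
    idx_dates = patients.set_index("patient_id")["index_date"].map(_as_date)
    dx = diagnoses[diagnoses["patient_id"].isin(idx_dates.index)].copy()
    dx = dx[dx["condition_code"].isin(eligible_codes)]
    dx["diagnosis_date"] = dx["diagnosis_date"].map(_as_date)
    dx["_index_date"] = dx["patient_id"].map(idx_dates)
    dx = dx[dx["diagnosis_date"] >= dx["_index_date"]]
    grouped = dx.groupby("patient_id")["condition_code"].agg(frozenset)
    return {
        pid: ComorbidityProfile(pid, grouped.get(pid, frozenset()))
        for pid in idx_dates.index
    }


def prevalence_filter(
    profiles: Mapping[str, ComorbidityProfile],
    cohort_n: int | None = None,
    threshold: float = 0.01,
) -> tuple[list[str], dict[str, float], dict[str, ComorbidityProfile]]:
    """Retain codes with prevalence >= threshold (inclusive) in this cohort.

    Returns (retained codes sorted, per-code prevalence over *all* codes seen,
    profiles rewritten to retained codes only).  ``cohort_n`` defaults to the
    number of profiles; the filter is meant to be applied within each
    diabetes-type cohort independently.
    """
    if cohort_n is None:
        cohort_n = len(profiles)
    if cohort_n <= 0:
        raise DataError("cohort_n must be positive")
    counts: dict[str, int] = {}
    for prof in profiles.values():
        for code in prof.conditions:
            counts[code] = counts.get(code, 0) + 1
    prevalence = {code: c / cohort_n for code, c in sorted(counts.items())}
    retained = sorted(c for c, p in prevalence.items() if p >= threshold)
    keep = set(retained)
    filtered = {
        pid: ComorbidityProfile(pid, frozenset(prof.conditions & keep))
        for pid, prof in profiles.items()
    }
    return retained, prevalence, filtered


def flag_multimorbidity(profile: ComorbidityProfile) -> bool:
    """True iff the (filtered) profile carries two or more conditions."""
    return profile.is_multimorbid


# --------------------------------------------------------------------------


def _filter_codes(rows, index_date, catalog, chapters):
    cat = catalog.set_index("condition_code")
    out = set()
    for _, row in rows.iterrows():
        code = row["condition_code"]
        if _as_date(row["diagnosis_date"]) < index_date:
            continue
        if cat.loc[code, "is_index_disease"]:
            continue
        if cat.loc[code, "icd10_chapter"] not in chapters:
            continue
        out.add(code)
    return frozenset(out)


def _check_catalog_covers(diagnoses: pd.DataFrame, catalog: pd.DataFrame) -> None:
    known = set(catalog["condition_code"])
    seen = set(diagnoses["condition_code"].unique())
    unknown = sorted(seen - known)
    if unknown:
        raise ConfigurationError(
            f"condition catalog does not cover codes: {unknown}"
        )


def _as_date(value) -> dt.date:
    if isinstance(value, dt.datetime):
        return value.date()
    if isinstance(value, dt.date):
        return value
    if isinstance(value, pd.Timestamp):
        return value.date()
    return dt.date.fromisoformat(str(value))


def age_band_label(age: int) -> str:
    """Descriptive age band (10-17 / 18-39 / 40-59 / 60-79 years)."""
    from .config import AGE_BANDS

    for lo, hi in AGE_BANDS:
        if lo <= age <= hi:
            return f"{lo}-{hi}"
    raise DataError(f"index age {age} outside the eligible 10-79 range")
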