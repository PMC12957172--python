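"""Synthetic two-cohort EHR extract with planted co-occurrence structure.

The generator draws, per diabetes-type x sex subgroup, independent Bernoulli
indicators for each condition at its configured marginal prevalence, then
re-samples each planted pair's two indicator columns jointly from the 2x2
distribution that preserves both marginals while matching the configured odds
ratio.  This keeps marginal prevalences interpretable while pairwise
association is controlled exactly.

All randomness flows from a single root seed through named substreams
(demographics, dates, labs, one stream per (subgroup, condition) and per
planted pair), so adding a condition or a lab does not perturb unrelated
draws and identical configurations are bit-reproducible.
"""

from __future__ import annotations

import datetime as dt
import zlib
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .config import (
    DIABETES_TYPES,
    SEXES,
    SUBGROUPS,
    AGE_BANDS,
    SyntheticConfig,
    subgroup_label,
)

_DAYS_PER_YEAR = 365.25

# stage tags for substream derivation
_STAGE_DEMOGRAPHICS = 1
_STAGE_DATES = 2
_STAGE_LABS = 3
_STAGE_CONDITIONS = 4
_STAGE_PAIRS = 5
_STAGE_UNMATCHED = 6


def _crc(text: str) -> int:
    return zlib.crc32(text.encode("utf-8"))


def _rng(config: SyntheticConfig, *key: int) -> np.random.Generator:
    """Deterministic substream keyed by (seed, stage, ...)."""
    seq = np.random.SeedSequence(entropy=config.seed, spawn_key=tuple(key))
    return np.random.default_rng(seq)


@dataclass(frozen=True)
class PlantedTruth:
    """Ground truth implied by a configuration, independent of sampling.

    ``pairs_by_subgroup`` maps each of the four subgroup labels to the set of
    planted (code_i, code_j) pairs (sorted within pair); ``lab_directions``
    gives the sign of the true T1DM-minus-T2DM location shift per lab.
    """

    pairs_by_subgroup: Mapping[str, frozenset[tuple[str, str]]]
    lab_directions: Mapping[str, int]


def planted_truth(config: SyntheticConfig) -> PlantedTruth:
    """Re-key the configured planted pairs by subgroup; derive lab shift signs."""
    config.validate()
    by_sg: dict[str, set[tuple[str, str]]] = {sg: set() for sg in SUBGROUPS}
    for pair in config.planted_pairs:
        for sg in pair.subgroups:
            by_sg[sg].add(pair.key)
    directions = {}
    for lab in config.labs:
        delta = lab.type_shifts.get("T1DM", 0.0) - lab.type_shifts.get("T2DM", 0.0)
        directions[lab.name] = int(np.sign(delta))
    return PlantedTruth(
        pairs_by_subgroup={sg: frozenset(v) for sg, v in by_sg.items()},
        lab_directions=directions,
    )


def joint_cell_probability(p_i: float, p_j: float, odds_ratio: float) -> float:
    """P(both conditions) in a 2x2 table with given marginals and odds ratio.

    The unique admissible root of the quadratic
    ``p11 (1 - p_i - p_j + p11) = OR (p_i - p11)(p_j - p11)`` — the fixed
    point that iterative proportional fitting of the 2x2 table converges to.
    """
    if odds_ratio <= 0:
        raise ValueError("odds_ratio must be positive")
    if odds_ratio == 1.0:
        return p_i * p_j
    w = odds_ratio - 1.0
    s = 1.0 + (p_i + p_j) * w
    disc = s * s - 4.0 * odds_ratio * w * p_i * p_j
    p11 = (s - np.sqrt(disc)) / (2.0 * w)
    lo, hi = max(0.0, p_i + p_j - 1.0), min(p_i, p_j)
    return float(np.clip(p11, lo, hi))


def _draw_pair(
    rng: np.random.Generator, n: int, p_i: float, p_j: float, odds_ratio: float
) -> tuple[np.ndarray, np.ndarray]:
    """Joint Bernoulli draw for one planted pair (n x 2 indicators)."""
    p11 = joint_cell_probability(p_i, p_j, odds_ratio)
    p10 = p_i - p11
    p01 = p_j - p11
    u = rng.random(n)
    both = u < p11
    only_i = (u >= p11) & (u < p11 + p10)
    only_j = (u >= p11 + p10) & (u < p11 + p10 + p01)
    return both | only_i, both | only_j


def _draw_ages(
    rng: np.random.Generator, n: int, weights: tuple[float, ...]
) -> np.ndarray:
    w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    bands = rng.choice(len(AGE_BANDS), size=n, p=w)
    lo = np.array([b[0] for b in AGE_BANDS])
    hi = np.array([b[1] for b in AGE_BANDS])
    # integer age uniform within the band, inclusive
    u = rng.random(n)
    return (lo[bands] + np.floor(u * (hi[bands] - lo[bands] + 1))).astype(int)


def _draw_followup_years(
    rng: np.random.Generator, n: int, spec
) -> np.ndarray:
    y = np.exp(rng.normal(spec.log_mean, spec.log_sd, size=n))
    return np.clip(y, spec.min_years, spec.max_years)


def _condition_matrix(
    config: SyntheticConfig, dtype: str, sex: str, n: int
) -> pd.DataFrame:
    """Indicator matrix (n x conditions) for one subgroup."""
    sg = subgroup_label(dtype, sex)
    sg_idx = SUBGROUPS.index(sg)
    cols: dict[str, np.ndarray] = {}
    for cond in config.conditions:
        r = _rng(config, _STAGE_CONDITIONS, sg_idx, _crc(cond.code))
        cols[cond.code] = r.random(n) < cond.marginal(dtype, sex)
    for pair in config.planted_pairs:
        if sg not in pair.subgroups:
            continue
        ci, cj = pair.code_i, pair.code_j
        p_i = config.condition(ci).marginal(dtype, sex)
        p_j = config.condition(cj).marginal(dtype, sex)
        r = _rng(config, _STAGE_PAIRS, sg_idx, _crc(ci), _crc(cj))
        cols[ci], cols[cj] = _draw_pair(r, n, p_i, p_j, pair.odds_multiplier)
    return pd.DataFrame(cols, columns=[c.code for c in config.conditions])


def generate_cohort(
    config: SyntheticConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate (patients, diagnoses, catalog) tables.

    Returns
    -------
    patients : DataFrame
        One row per patient: patient_id, sex, diabetes_type, index_age_years,
        index_date, last_visit_date (ISO dates) and one column per lab.
    diagnoses : DataFrame
        Long format: patient_id, condition_code, diagnosis_date.  Includes one
        index-disease record per patient dated at the index date; comorbidity
        records are dated uniformly within [index_date, last_visit_date].
    catalog : DataFrame
        condition_code, label, icd10_chapter, is_index_disease.
    """
    config.validate()
    n = config.n_per_cohort

    # --- demographics -----------------------------------------------------
    rng_demo = _rng(config, _STAGE_DEMOGRAPHICS)
    t1_sex = np.where(rng_demo.random(n) < config.sex_fraction_female, "female", "male")
    t1_age = _draw_ages(rng_demo, n, config.age_band_weights)
    # T2DM comparators copy the T1DM (sex, age) multiset, permuted, so 1:1
    # exact matching always succeeds by default.
    perm = rng_demo.permutation(n)
    t2_sex = t1_sex[perm].copy()
    t2_age = t1_age[perm].copy()
    if config.unmatched_fraction > 0:
        rng_un = _rng(config, _STAGE_UNMATCHED)
        k = int(round(config.unmatched_fraction * n))
        idx = rng_un.choice(n, size=k, replace=False)
        t2_age[idx] = rng_un.integers(80, 95, size=k)  # outside any T1DM stratum

    frames = []
    diag_frames = []
    window_start, window_end = config.index_window
    window_days = (window_end - window_start).days
    for dtype, sexes, ages, prefix in (
        ("T1DM", t1_sex, t1_age, "T1"),
        ("T2DM", t2_sex, t2_age, "T2"),
    ):
        pids = np.array([f"{prefix}-{i:06d}" for i in range(n)])
        rng_dates = _rng(config, _STAGE_DATES, DIABETES_TYPES.index(dtype))
        index_offset = rng_dates.integers(0, window_days + 1, size=n)
        index_dates = np.array(
            [window_start + dt.timedelta(days=int(d)) for d in index_offset]
        )
        fu_years = _draw_followup_years(rng_dates, n, config.followup[dtype])
        fu_days = np.round(fu_years * _DAYS_PER_YEAR).astype(int)
        last_visit = np.array(
            [d + dt.timedelta(days=int(k)) for d, k in zip(index_dates, fu_days)]
        )

        pat = pd.DataFrame(
            {
                "patient_id": pids,
                "sex": sexes,
                "diabetes_type": dtype,
                "index_age_years": ages,
                "index_date": index_dates,
                "last_visit_date": last_visit,
            }
        )

        # --- labs ---------------------------------------------------------
        for lab in config.labs:
            r = _rng(config, _STAGE_LABS, DIABETES_TYPES.index(dtype), _crc(lab.name))
            vals = np.empty(n)
            for sex in SEXES:
                mask = sexes == sex
                draw = r.normal(lab.location(dtype, sex), lab.sd, size=int(mask.sum()))
                if lab.family == "lognormal":
                    draw = np.exp(draw)
                else:
                    draw = np.clip(draw, 0.0, None)
                vals[mask] = draw
            pat[lab.name] = np.round(vals, 4)
        frames.append(pat)

        # --- index-disease diagnosis rows ----------------------------------
        diag_frames.append(
            pd.DataFrame(
                {
                    "patient_id": pids,
                    "condition_code": dtype,
                    "diagnosis_date": index_dates,
                }
            )
        )

        # --- comorbid condition rows ---------------------------------------
        for sex in SEXES:
            mask = sexes == sex
            sub_n = int(mask.sum())
            if sub_n == 0:
                continue
            indicators = _condition_matrix(config, dtype, sex, sub_n)
            sg_idx = SUBGROUPS.index(subgroup_label(dtype, sex))
            rng_dx = _rng(config, _STAGE_DATES, 10 + sg_idx)
            sub_pids = pids[mask]
            sub_index = index_dates[mask]
            sub_span = fu_days[mask]
            for code in indicators.columns:
                has = indicators[code].to_numpy()
                if not has.any():
                    continue
                offs = np.floor(
                    rng_dx.random(sub_n) * (sub_span + 1)
                ).astype(int)  # one draw per patient keeps streams aligned
                sel = np.flatnonzero(has)
                diag_frames.append(
                    pd.DataFrame(
                        {
                            "patient_id": sub_pids[sel],
                            "condition_code": code,
                            "diagnosis_date": [
                                d + dt.timedelta(days=int(o))
                                for d, o in zip(sub_index[sel], offs[sel])
                            ],
                        }
                    )
                )

    patients = pd.concat(frames, ignore_index=True)
    diagnoses = (
        pd.concat(diag_frames, ignore_index=True)
        .sort_values(["patient_id", "condition_code", "diagnosis_date"])
        .reset_index(drop=True)
    )
    catalog = build_catalog(config)
    return patients, diagnoses, catalog


def build_catalog(config: SyntheticConfig) -> pd.DataFrame:
    """Condition catalog covering every generated code, index diseases flagged."""
    rows = [
        {"condition_code": "T1DM", "label": "Type 1 diabetes mellitus",
         "icd10_chapter": "IV", "is_index_disease": 1},
        {"condition_code": "T2DM", "label": "Type 2 diabetes mellitus",
         "icd10_chapter": "IV", "is_index_disease": 1},
    ]
    for cond in config.conditions:
        rows.append(
            {"condition_code": cond.code, "label": cond.label,
             "icd10_chapter": cond.chapter, "is_index_disease": 0}
        )
    return pd.DataFrame(rows)


def write_extract(
    out_dir, patients: pd.DataFrame, diagnoses: pd.DataFrame, catalog: pd.DataFrame
) -> None:
    """Write the three CSVs with ISO-8601 dates."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    patients.to_csv(out / "patients.csv", index=False)
    diagnoses.to_csv(out / "diagnoses.csv", index=False)
    catalog.to_csv(out / "catalog.csv", index=False)
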