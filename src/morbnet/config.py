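"""Configuration objects for the synthetic cohort generator and the pipeline.

The generator emulates a two-cohort EHR extract: patients with type 1 diabetes
(T1DM) and a same-size pool of type 2 diabetes (T2DM) comparators, each with a
sex, an index age, an index date, a last-visit date, laboratory values, and a
set of coded comorbid conditions.  Pairwise disease co-occurrence can be
"planted" in chosen diabetes-type x sex subgroups at a configured odds
multiplier, giving every downstream stage a known ground truth.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

from .errors import ConfigurationError
from .icd import DEFAULT_CHAPTER_WHITELIST, is_valid_chapter

DIABETES_TYPES: tuple[str, str] = ("T1DM", "T2DM")
SEXES: tuple[str, str] = ("male", "female")

#: The four analysis subgroups, in canonical order.
SUBGROUPS: tuple[str, ...] = (
    "T1DM_male", "T1DM_female", "T2DM_male", "T2DM_female",
)

#: Descriptive age bands (inclusive bounds, years).
AGE_BANDS: tuple[tuple[int, int], ...] = ((10, 17), (18, 39), (40, 59), (60, 79))


def subgroup_label(diabetes_type: str, sex: str) -> str:
    if diabetes_type not in DIABETES_TYPES:
        raise ConfigurationError(f"diabetes_type: unknown value {diabetes_type!r}")
    if sex not in SEXES:
        raise ConfigurationError(f"sex: unknown value {sex!r}")
    return f"{diabetes_type}_{sex}"


@dataclass(frozen=True)
class ConditionSpec:
    """One grouped condition: code, label, ICD-10 chapter and prevalence model.

    The marginal probability of the condition in a subgroup is
    ``prevalence * type_multipliers[type] * sex_multipliers[sex]`` (multipliers
    default to 1).
    """

    code: str
    label: str
    chapter: str
    prevalence: float
    sex_multipliers: Mapping[str, float] = field(default_factory=dict)
    type_multipliers: Mapping[str, float] = field(default_factory=dict)

    def marginal(self, diabetes_type: str, sex: str) -> float:
        return (
            self.prevalence
            * self.type_multipliers.get(diabetes_type, 1.0)
            * self.sex_multipliers.get(sex, 1.0)
        )


@dataclass(frozen=True)
class PlantedPair:
    """A condition pair whose co-occurrence odds ratio is raised in target subgroups."""

    code_i: str
    code_j: str
    subgroups: tuple[str, ...]
    odds_multiplier: float

    @property
    def key(self) -> tuple[str, str]:
        return tuple(sorted((self.code_i, self.code_j)))  # type: ignore[return-value]


@dataclass(frozen=True)
class LabSpec:
    """A laboratory variable: distribution family plus group location shifts.

    ``family`` is ``"normal"`` (mean/sd on the natural scale) or ``"lognormal"``
    (mean/sd of the natural log).  Shifts are additive on the same scale as
    ``mean``, so a log-normal shift of ``ln r`` multiplies the median by ``r``.
    """

    name: str
    family: str  # "normal" | "lognormal"
    mean: float
    sd: float
    type_shifts: Mapping[str, float] = field(default_factory=dict)
    sex_shifts: Mapping[str, float] = field(default_factory=dict)

    def location(self, diabetes_type: str, sex: str) -> float:
        return (
            self.mean
            + self.type_shifts.get(diabetes_type, 0.0)
            + self.sex_shifts.get(sex, 0.0)
        )


@dataclass(frozen=True)
class FollowupSpec:
    """Observed-follow-up distribution for one cohort, in years.

    Log-normal with parameters on the log scale, truncated to
    ``[min_years, max_years]`` to keep last-visit dates plausible.
    """

    log_mean: float
    log_sd: float
    min_years: float = 0.02
    max_years: float = 11.0


@dataclass(frozen=True)
class SyntheticConfig:
    n_per_cohort: int = 2000
    sex_fraction_female: float = 0.494
    age_band_weights: tuple[float, float, float, float] = (0.036, 0.277, 0.329, 0.359)
    conditions: tuple[ConditionSpec, ...] = ()
    planted_pairs: tuple[PlantedPair, ...] = ()
    labs: tuple[LabSpec, ...] = ()
    followup: Mapping[str, FollowupSpec] = field(default_factory=dict)
    index_window: tuple[dt.date, dt.date] = (dt.date(2014, 1, 1), dt.date(2023, 12, 31))
    #: Fraction of T2DM comparators whose index age is re-drawn, breaking exact
    #: matchability (0 keeps the T2DM (sex, age) multiset identical to T1DM's).
    unmatched_fraction: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_per_cohort <= 0:
            raise ConfigurationError("n_per_cohort: must be a positive integer")
        if not 0.0 <= self.sex_fraction_female <= 1.0:
            raise ConfigurationError("sex_fraction_female: must lie in [0, 1]")
        if len(self.age_band_weights) != len(AGE_BANDS):
            raise ConfigurationError(
                f"age_band_weights: expected {len(AGE_BANDS)} weights"
            )
        if any(w < 0 for w in self.age_band_weights):
            raise ConfigurationError("age_band_weights: weights must be nonnegative")
        if sum(self.age_band_weights) <= 0:
            raise ConfigurationError("age_band_weights: weights must not all be zero")
        if not 0.0 <= self.unmatched_fraction <= 1.0:
            raise ConfigurationError("unmatched_fraction: must lie in [0, 1]")
        codes = [c.code for c in self.conditions]
        if len(set(codes)) != len(codes):
            raise ConfigurationError("conditions: duplicate condition codes")
        for cond in self.conditions:
            if not is_valid_chapter(cond.chapter):
                raise ConfigurationError(
                    f"conditions[{cond.code}].chapter: unknown chapter {cond.chapter!r}"
                )
            if not 0.0 <= cond.prevalence <= 1.0:
                raise ConfigurationError(
                    f"conditions[{cond.code}].prevalence: must lie in [0, 1]"
                )
            for dtype in DIABETES_TYPES:
                for sex in SEXES:
                    p = cond.marginal(dtype, sex)
                    if not 0.0 <= p <= 1.0:
                        raise ConfigurationError(
                            f"conditions[{cond.code}]: marginal prevalence {p:.4f} "
                            f"for {subgroup_label(dtype, sex)} outside [0, 1]"
                        )
        known = set(codes)
        used: dict[str, set[str]] = {sg: set() for sg in SUBGROUPS}
        for pair in self.planted_pairs:
            for code in (pair.code_i, pair.code_j):
                if code not in known:
                    raise ConfigurationError(
                        f"planted_pairs: code {code!r} not in condition_specs"
                    )
            if pair.code_i == pair.code_j:
                raise ConfigurationError(
                    f"planted_pairs: self-pair {pair.code_i!r}"
                )
            if pair.odds_multiplier <= 1.0:
                raise ConfigurationError(
                    f"planted_pairs[{pair.key}].odds_multiplier: must exceed 1"
                )
            for sg in pair.subgroups:
                if sg not in SUBGROUPS:
                    raise ConfigurationError(
                        f"planted_pairs[{pair.key}].subgroups: unknown subgroup {sg!r}"
                    )
                overlap = used[sg] & {pair.code_i, pair.code_j}
                if overlap:
                    raise ConfigurationError(
                        f"planted_pairs: codes {sorted(overlap)} appear in more "
                        f"than one planted pair within subgroup {sg}"
                    )
                used[sg] |= {pair.code_i, pair.code_j}
        lab_names = [lab.name for lab in self.labs]
        if len(set(lab_names)) != len(lab_names):
            raise ConfigurationError("lab_specs: duplicate lab names")
        for lab in self.labs:
            if lab.family not in ("normal", "lognormal"):
                raise ConfigurationError(
                    f"lab_specs[{lab.name}].family: must be 'normal' or 'lognormal'"
                )
            if lab.sd < 0:
                raise ConfigurationError(f"lab_specs[{lab.name}].sd: must be >= 0")
        for dtype in DIABETES_TYPES:
            if dtype not in self.followup:
                raise ConfigurationError(f"followup_spec: missing cohort {dtype}")
        if self.index_window[1] < self.index_window[0]:
            raise ConfigurationError("index_window: end precedes start")

    def condition(self, code: str) -> ConditionSpec:
        for cond in self.conditions:
            if cond.code == code:
                return cond
        raise KeyError(code)

    def with_seed(self, seed: int) -> "SyntheticConfig":
        return replace(self, seed=seed)


# --------------------------------------------------------------------------
# Default study conditions
# --------------------------------------------------------------------------

def _cond(code, label, chapter, prev, sex=None, typ=None):
    return ConditionSpec(
        code=code, label=label, chapter=chapter, prevalence=prev,
        sex_multipliers=sex or {}, type_multipliers=typ or {},
    )


#: Illustrative grouped-condition catalog (chapters I-XIV).  Labels mirror the
#: conditions that recur in diabetes multimorbidity studies; per-condition
#: prevalences are plausible tertiary-care values, not estimates from any
#: specific registry.
DEFAULT_CONDITIONS: tuple[ConditionSpec, ...] = (
    _cond("HTN", "Hypertension", "IX", 0.28, typ={"T2DM": 1.15}),
    _cond("DLD", "Dyslipidemia", "IV", 0.26, typ={"T2DM": 1.15}),
    _cond("IHD", "Ischemic heart disease", "IX", 0.12, sex={"male": 1.2, "female": 0.9}),
    _cond("CVD", "Cerebrovascular disease", "IX", 0.10),
    _cond("STROKE", "Stroke", "IX", 0.06),
    _cond("DNEPH", "Diabetic nephropathy", "IV", 0.09, typ={"T1DM": 1.2}),
    _cond("DNEURO", "Diabetic neuropathy", "IV", 0.08, typ={"T1DM": 1.2}),
    _cond("DEYE", "Diabetic eye complications", "IV", 0.10, typ={"T1DM": 1.3}),
    _cond("PVD", "Peripheral vascular disease", "IX", 0.06),
    _cond("NAFLD", "Nonalcoholic fatty liver disease", "XI", 0.12, typ={"T2DM": 1.3}),
    _cond("CGAST", "Chronic gastritis", "XI", 0.08),
    _cond("ASTHMA", "Asthma", "X", 0.05),
    _cond("OSTEO", "Osteoporosis", "XIII", 0.05, sex={"female": 1.6, "male": 0.6}),
    _cond("CHEP", "Chronic viral hepatitis", "I", 0.04, sex={"male": 1.3}),
    _cond("CIRR", "Cirrhosis of liver", "XI", 0.02, sex={"male": 1.4}),
    _cond("ANXDEP", "Anxiety or depression", "V", 0.04, sex={"female": 1.8, "male": 0.5}),
    _cond("CKD", "Chronic kidney disease", "XIV", 0.07),
    _cond("UTI", "Urinary tract infection", "XIV", 0.04, sex={"female": 1.5}),
    _cond("ANEMIA", "Anemia", "III", 0.05, sex={"female": 1.4}),
    _cond("THYROID", "Thyroid disorder", "IV", 0.08, sex={"female": 1.7}, typ={"T1DM": 1.3}),
    _cond("COPD", "Chronic obstructive pulmonary disease", "X", 0.04, sex={"male": 1.5}),
    _cond("CATARACT", "Cataract", "VII", 0.07),
    _cond("OARTH", "Osteoarthritis", "XIII", 0.06, sex={"female": 1.3}),
    _cond("GERD", "Gastroesophageal reflux disease", "XI", 0.05),
)

#: Default planted structure: one cardiovascular pair boosted everywhere plus
#: subgroup-unique pairs emulating sex-specific co-occurrence signatures
#: (eye complications-stroke and PVD-NAFLD in T1DM males; nephropathy-chronic
#: gastritis and neuropathy-osteoporosis in T1DM females; hypertension-asthma
#: in T2DM females).
DEFAULT_PLANTED_PAIRS: tuple[PlantedPair, ...] = (
    PlantedPair("IHD", "CVD", SUBGROUPS, 4.0),
    PlantedPair("DEYE", "STROKE", ("T1DM_male",), 6.0),
    PlantedPair("PVD", "NAFLD", ("T1DM_male",), 6.0),
    PlantedPair("DNEPH", "CGAST", ("T1DM_female",), 6.0),
    PlantedPair("DNEURO", "OSTEO", ("T1DM_female",), 6.0),
    PlantedPair("HTN", "ASTHMA", ("T2DM_female",), 5.0),
)

#: Default labs: HbA1c and HDL-C approximately normal; triglyceride and ALT
#: log-normal (right-skewed).  Group shifts reproduce the qualitative clinical
#: picture: higher HbA1c and HDL-C but lower TG and ALT in T1DM than T2DM.
DEFAULT_LABS: tuple[LabSpec, ...] = (
    LabSpec("hba1c_mmol_mol", "normal", 58.0, 20.0,
            type_shifts={"T1DM": 5.0}, sex_shifts={"female": -3.0}),
    LabSpec("hdl_mmol_l", "normal", 1.11, 0.37,
            type_shifts={"T1DM": 0.12}, sex_shifts={"female": 0.21}),
    LabSpec("tc_mmol_l", "normal", 4.40, 1.26,
            type_shifts={"T1DM": 0.08}, sex_shifts={"female": 0.42}),
    LabSpec("ldl_mmol_l", "normal", 2.63, 0.99,
            type_shifts={"T1DM": 0.04}, sex_shifts={"female": 0.21}),
    LabSpec("tg_mmol_l", "lognormal", math.log(1.40), 0.55,
            type_shifts={"T1DM": math.log(1.12 / 1.40)}),
    LabSpec("alt_u_l", "lognormal", math.log(22.6), 0.59,
            type_shifts={"T1DM": -0.13}, sex_shifts={"female": -0.14}),
)

#: Follow-up: markedly shorter observed follow-up in the (recently diagnosed)
#: T1DM cohort than in T2DM comparators — medians ~3.8 vs ~8.3 years.
DEFAULT_FOLLOWUP: dict[str, FollowupSpec] = {
    "T1DM": FollowupSpec(log_mean=math.log(3.8), log_sd=1.23),
    "T2DM": FollowupSpec(log_mean=math.log(8.28), log_sd=0.56),
}


def default_config(n_per_cohort: int = 2000, seed: int = 0, **overrides) -> SyntheticConfig:
    """A ready-to-run configuration emulating the study conditions."""
    cfg = SyntheticConfig(
        n_per_cohort=n_per_cohort,
        conditions=DEFAULT_CONDITIONS,
        planted_pairs=DEFAULT_PLANTED_PAIRS,
        labs=DEFAULT_LABS,
        followup=dict(DEFAULT_FOLLOWUP),
        seed=seed,
    )
    if overrides:
        cfg = replace(cfg, **overrides)
    cfg.validate()
    return cfg


def recovery_config(n_per_cohort: int = 10000, seed: int = 0) -> SyntheticConfig:
    """Planted-pair recovery protocol: one unique pair per subgroup + a shared pair.

    Marginal prevalences of the planted conditions are set to 0.12 and the odds
    multipliers to 8 (unique pairs) / 6 (shared pair).  These sit above the
    minimal interesting condition (odds multiplier 5, marginals 5%) because the
    significance statistic draws its degrees of freedom from the joint count:
    at 5,000 patients per subgroup a pair needs a joint count near 200 and an
    SCI above the largest independence-driven SCI (~0.30 for the most prevalent
    condition pair) to enter the top-e edge set reliably.  At these settings the
    planted pairs have expected SCI 0.36-0.41 and t of 4-6, so recovery failures
    are sampling accidents, not design artifacts.
    """
    boosted = {
        "DEYE", "STROKE", "DNEURO", "OSTEO", "PVD", "NAFLD",
        "CGAST", "ASTHMA", "IHD", "CVD",
    }
    conditions = tuple(
        replace(c, prevalence=0.12, sex_multipliers={}, type_multipliers={})
        if c.code in boosted else c
        for c in DEFAULT_CONDITIONS
    )
    planted = (
        PlantedPair("DEYE", "STROKE", ("T1DM_male",), 8.0),
        PlantedPair("DNEURO", "OSTEO", ("T1DM_female",), 8.0),
        PlantedPair("PVD", "NAFLD", ("T2DM_male",), 8.0),
        PlantedPair("CGAST", "ASTHMA", ("T2DM_female",), 8.0),
        PlantedPair("IHD", "CVD", SUBGROUPS, 6.0),
    )
    cfg = SyntheticConfig(
        n_per_cohort=n_per_cohort,
        sex_fraction_female=0.5,
        conditions=conditions,
        planted_pairs=planted,
        labs=DEFAULT_LABS,
        followup=dict(DEFAULT_FOLLOWUP),
        seed=seed,
    )
    cfg.validate()
    return cfg


def null_lab_config(n_per_cohort: int = 2000, seed: int = 0) -> SyntheticConfig:
    """Default conditions but labs without any group shift (SMD calibration)."""
    labs = tuple(
        replace(lab, type_shifts={}, sex_shifts={}) for lab in DEFAULT_LABS
    )
    cfg = SyntheticConfig(
        n_per_cohort=n_per_cohort,
        conditions=DEFAULT_CONDITIONS,
        planted_pairs=DEFAULT_PLANTED_PAIRS,
        labs=labs,
        followup=dict(DEFAULT_FOLLOWUP),
        seed=seed,
    )
    cfg.validate()
    return cfg


@dataclass(frozen=True)
class RunConfig:
    """End-to-end pipeline configuration."""

    out_dir: str = "morbnet_out"
    input_dir: str | None = None
    synthetic: SyntheticConfig | None = None
    prevalence_threshold: float = 0.01
    t_threshold: float = 1.96
    chapters: frozenset[str] = DEFAULT_CHAPTER_WHITELIST
    damping: float = 0.85
    hub_k: int = 10
    seed: int = 0
    #: Optional mapping lab column -> "continuous_normal" | "continuous_skewed";
    #: labs not listed are classified by sample skewness (> 1 means skewed).
    lab_kinds: Mapping[str, str] = field(default_factory=dict)

    def validate(self) -> None:
        if not 0.0 <= self.prevalence_threshold <= 1.0:
            raise ConfigurationError("prevalence_threshold: must lie in [0, 1]")
        if self.t_threshold < 0:
            raise ConfigurationError("t_threshold: must be >= 0")
        if not 0.0 < self.damping < 1.0:
            raise ConfigurationError("damping: must lie in (0, 1)")
        if self.hub_k < 1:
            raise ConfigurationError("hub_k: must be >= 1")
        for ch in self.chapters:
            if not is_valid_chapter(ch):
                raise ConfigurationError(f"chapters: unknown chapter {ch!r}")
        if self.input_dir is None and self.synthetic is None:
            raise ConfigurationError(
                "input_dir: provide an input directory or a synthetic config"
            )
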