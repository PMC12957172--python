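import datetime as dt

import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from morbnet.config import (  # noqa: E402
    ConditionSpec,
    FollowupSpec,
    LabSpec,
    PlantedPair,
    SyntheticConfig,
)

SMALL_CONDITIONS = (
    ConditionSpec("HTN", "Hypertension", "IX", 0.25),
    ConditionSpec("DLD", "Dyslipidemia", "IV", 0.22),
    ConditionSpec("IHD", "Ischemic heart disease", "IX", 0.12),
    ConditionSpec("CVD", "Cerebrovascular disease", "IX", 0.10),
    ConditionSpec("NAFLD", "Nonalcoholic fatty liver disease", "XI", 0.12),
    ConditionSpec("OSTEO", "Osteoporosis", "XIII", 0.08,
                  sex_multipliers={"female": 1.5, "male": 0.5}),
    ConditionSpec("ASTHMA", "Asthma", "X", 0.06),
    ConditionSpec("CKD", "Chronic kidney disease", "XIV", 0.07),
)

SMALL_LABS = (
    LabSpec("hba1c_mmol_mol", "normal", 58.0, 20.0, type_shifts={"T1DM": 5.0}),
    LabSpec("tg_mmol_l", "lognormal", 0.34, 0.55, type_shifts={"T1DM": -0.22}),
)

FOLLOWUP = {
    "T1DM": FollowupSpec(log_mean=1.34, log_sd=1.0),
    "T2DM": FollowupSpec(log_mean=2.11, log_sd=0.56),
}


def make_config(n=400, seed=0, planted=(), conditions=SMALL_CONDITIONS, **kw):
    cfg = SyntheticConfig(
        n_per_cohort=n,
        conditions=conditions,
        planted_pairs=tuple(planted),
        labs=SMALL_LABS,
        followup=FOLLOWUP,
        seed=seed,
        **kw,
    )
    cfg.validate()
    return cfg


@pytest.fixture
def small_config():
    return make_config()


@pytest.fixture
def planted_config():
    return make_config(
        n=2000,
        planted=[
            PlantedPair("IHD", "CVD", ("T1DM_male",), 6.0),
            PlantedPair("HTN", "NAFLD", ("T2DM_female",), 5.0),
        ],
    )


@pytest.fixture
def tiny_catalog():
    return pd.DataFrame(
        {
            "condition_code": ["T1DM", "T2DM", "A", "B", "C", "X15"],
            "label": [
                "Type 1 diabetes", "Type 2 diabetes",
                "Cond A", "Cond B", "Cond C", "Pregnancy-related",
            ],
            "icd10_chapter": ["IV", "IV", "IX", "IV", "XI", "XV"],
            "is_index_disease": [1, 1, 0, 0, 0, 0],
        }
    )


def d(iso: str) -> dt.date:
    return dt.date.fromisoformat(iso)
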