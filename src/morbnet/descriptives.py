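"""Baseline-table summaries and standardized mean differences (SMDs).

Conventions follow common matched-cohort reporting practice: approximately
normal continuous variables are summarized as mean +/- SD and compared on the
raw scale; skewed continuous variables are summarized as median (Q1, Q3) and
compared after a natural-log transform (log(x+1) when zeros are present);
categorical variables are summarized as counts (percentages) and compared
per category with the binary-proportion SMD.  |SMD| < 0.10 is conventionally
read as a small difference.

The SMD uses the two-group average-variance pooled SD:

    SMD = (mean_a - mean_b) / sqrt((sd_a^2 + sd_b^2) / 2)
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

KIND_NORMAL = "continuous_normal"
KIND_SKEWED = "continuous_skewed"
KIND_CATEGORICAL = "categorical"


@dataclass(frozen=True)
class VariableSpec:
    name: str
    kind: str
    units: str = ""
    zero_possible: bool = False


@dataclass(frozen=True)
class SmdResult:
    variable: str
    smd: float
    transform_used: str  # "none" | "log" | "log1p"
    group_ns: tuple[int, int]


def summarize(values: Sequence[float], kind: str) -> dict:
    """Summary record for one continuous variable.

    normal -> {"mean", "sd"} (SD with n-1 denominator); skewed ->
    {"median", "q1", "q3"} with linear-interpolation quantiles.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot summarize an empty value list")
    if kind == KIND_NORMAL:
        sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
        return {"mean": float(arr.mean()), "sd": sd}
    if kind == KIND_SKEWED:
        q1, med, q3 = np.quantile(arr, [0.25, 0.5, 0.75])
        return {"median": float(med), "q1": float(q1), "q3": float(q3)}
    raise ValueError(f"summarize: unsupported kind {kind!r}")


def summarize_categorical(values: Sequence) -> list[tuple[str, int, float]]:
    """(category, count, percentage) per observed category, sorted by category."""
    vals = list(values)
    if not vals:
        raise ValueError("cannot summarize an empty value list")
    n = len(vals)
    out = []
    for cat in sorted(set(map(str, vals))):
        c = sum(1 for v in vals if str(v) == cat)
        out.append((cat, c, 100.0 * c / n))
    return out


def smd_continuous(
    group_a: Sequence[float],
    group_b: Sequence[float],
    kind: str = KIND_NORMAL,
    zero_possible: bool | None = None,
    variable: str = "",
) -> SmdResult:
    """SMD between two groups of a continuous variable.

    For skewed variables both groups are natural-log transformed first;
    log(x+1) is used when a zero is present in either group (or when
    ``zero_possible`` forces it).  Negative values under the skewed path are
    an error — the log is undefined.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("smd_continuous: both groups must be nonempty")
    transform = "none"
    if kind == KIND_SKEWED:
        if (a < 0).any() or (b < 0).any():
            raise ValueError("smd_continuous: negative values under log transform")
        use_log1p = bool(zero_possible) or (a == 0).any() or (b == 0).any()
        if use_log1p:
            a, b, transform = np.log1p(a), np.log1p(b), "log1p"
        else:
            a, b, transform = np.log(a), np.log(b), "log"
    elif kind != KIND_NORMAL:
        raise ValueError(f"smd_continuous: unsupported kind {kind!r}")
    smd = _pooled_smd(a, b)
    return SmdResult(variable, smd, transform, (a.size, b.size))


def smd_binary(p_a: float, n_a: int, p_b: float, n_b: int) -> float:
    """SMD between two proportions; 0 whenever p_a == p_b (guarded division)."""
    for p in (p_a, p_b):
        if not 0.0 <= p <= 1.0:
            raise ValueError("smd_binary: proportions must lie in [0, 1]")
    if p_a == p_b:
        return 0.0
    denom = math.sqrt((p_a * (1 - p_a) + p_b * (1 - p_b)) / 2.0)
    if denom == 0.0:
        # degenerate 0-vs-1 proportions: unbounded standardized difference
        return math.copysign(math.inf, p_a - p_b)
    return (p_a - p_b) / denom


def ngsp_percent(ifcc_mmol_mol: float) -> float:
    """Convert HbA1c from IFCC (mmol/mol) to NGSP (%) by the master equation."""
    return 0.09148 * ifcc_mmol_mol + 2.152


def _pooled_smd(a: np.ndarray, b: np.ndarray) -> float:
    sd_a = a.std(ddof=1) if a.size > 1 else 0.0
    sd_b = b.std(ddof=1) if b.size > 1 else 0.0
    pooled = math.sqrt((sd_a**2 + sd_b**2) / 2.0)
    diff = float(a.mean() - b.mean())
    if pooled == 0.0:
        return 0.0 if diff == 0.0 else math.copysign(math.inf, diff)
    return diff / pooled
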