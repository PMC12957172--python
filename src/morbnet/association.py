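"""Pairwise disease co-occurrence statistics and the SCI cut-off procedure.

For two conditions *i* and *j* within a subgroup of *N* patients, with
patient counts ``c_i``, ``c_j`` and joint count ``c_ij``:

* Salton Cosine Index (edge strength, sample-size free):

      SCI_ij = c_ij / sqrt(c_i * c_j)                         in [0, 1]

* Phi coefficient — the Pearson correlation of the two binary indicator
  vectors, adjusting for prevalence imbalance:

      Phi_ij = (c_ij*N - c_i*c_j)
               / sqrt(c_i * c_j * (N - c_i) * (N - c_j))      in [-1, 1]

* A t-like significance statistic with degrees of freedom taken from the
  joint count:

      t_ij = Phi_ij * sqrt(c_ij - 2) / sqrt(1 - Phi_ij^2)

  (the conventional choice would use N - 2; the joint-count form is kept as
  the default and a ``df_from_n`` switch exposes the conventional one).

The SCI cut-off for a subgroup is derived from the relationship between SCI
and Phi, on the principle that the SCI network should keep as many edges as
there are positively correlated, significant pairs:

  (i)   compute SCI and Phi for every pair;
  (ii)  count the pairs with c_ij > 0 (``q``);
  (iii) count the pairs (``e``) with t > 1.96 (p < 0.05) and c_ij above the
        mean joint count  sum(c_ij)/q  over the q pairs;
  (iv)  keep the top-``e`` pairs ranked by SCI; the cut-off is the e-th
        ranked SCI.

Ties at the cut-off rank are broken by higher joint count, then by
lexicographic pair identity, so exactly ``e`` edges are kept
deterministically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .cohort import ComorbidityProfile


@dataclass(frozen=True)
class PairStats:
    """Contingency counts and association statistics for one unordered pair."""

    code_i: str
    code_j: str
    c_i: int
    c_j: int
    c_ij: int
    n: int
    sci: float
    phi: float | None
    t: float | None

    @property
    def key(self) -> tuple[str, str]:
        return (self.code_i, self.code_j)


@dataclass(frozen=True)
class CutoffResult:
    """Derived SCI threshold for one subgroup."""

    q: int
    e: int
    sci_cutoff: float
    n_edges: int


def sci(c_i: int, c_j: int, c_ij: int) -> float:
    """Salton Cosine Index; requires positive marginal counts."""
    _check_counts(c_i, c_j, c_ij)
    if c_i <= 0 or c_j <= 0:
        raise ValueError("sci undefined for zero marginal counts")
    return c_ij / math.sqrt(c_i * c_j)


def phi(c_i: int, c_j: int, c_ij: int, n: int) -> float | None:
    """Phi coefficient; None when a margin is degenerate (0 or N)."""
    _check_counts(c_i, c_j, c_ij, n)
    if c_i in (0, n) or c_j in (0, n):
        return None
    num = c_ij * n - c_i * c_j
    den = math.sqrt(c_i * c_j * (n - c_i) * (n - c_j))
    return num / den


def t_value(phi_value: float | None, c_ij: int) -> float | None:
    """Significance statistic t = phi*sqrt(c_ij-2)/sqrt(1-phi^2).

    None (undefined, treated as non-significant) when phi is undefined or
    c_ij < 3; a signed infinity when |phi| = 1 (perfect association).
    """
    if phi_value is None or c_ij < 3:
        return None
    if abs(phi_value) >= 1.0:
        return math.copysign(math.inf, phi_value)
    return phi_value * math.sqrt(c_ij - 2) / math.sqrt(1.0 - phi_value**2)


def t_value_conventional(phi_value: float | None, n: int) -> float | None:
    """Alternative t with the conventional N-2 degrees of freedom."""
    if phi_value is None or n < 3:
        return None
    if abs(phi_value) >= 1.0:
        return math.copysign(math.inf, phi_value)
    return phi_value * math.sqrt(n - 2) / math.sqrt(1.0 - phi_value**2)


def count_pairs(
    profiles: Mapping[str, ComorbidityProfile] | Iterable[ComorbidityProfile],
    codes: Sequence[str],
    df_from_n: bool = False,
) -> list[PairStats]:
    """Exact contingency counts + statistics for every unordered code pair.

    ``N`` is the number of patients in the subgroup (profiles), including
    patients with no retained condition.  Pairs whose marginal count is zero
    are skipped (SCI undefined; cannot arise after the prevalence filter).
    Pairs are returned in lexicographic order of (code_i, code_j), i < j.
    """
    profs = list(profiles.values()) if isinstance(profiles, Mapping) else list(profiles)
    codes = sorted(codes)
    n = len(profs)
    k = len(codes)
    x = np.zeros((n, k), dtype=np.int64)
    pos = {c: idx for idx, c in enumerate(codes)}
    for row, prof in enumerate(profs):
        for code in prof.conditions:
            if code in pos:
                x[row, pos[code]] = 1
    joint = x.T @ x  # diagonal: marginal counts
    out: list[PairStats] = []
    for a in range(k):
        c_a = int(joint[a, a])
        if c_a == 0:
            continue
        for b in range(a + 1, k):
            c_b = int(joint[b, b])
            if c_b == 0:
                continue
            c_ab = int(joint[a, b])
            phi_v = phi(c_a, c_b, c_ab, n)
            t_v = (
                t_value_conventional(phi_v, n)
                if df_from_n
                else t_value(phi_v, c_ab)
            )
            out.append(
                PairStats(
                    code_i=codes[a], code_j=codes[b],
                    c_i=c_a, c_j=c_b, c_ij=c_ab, n=n,
                    sci=sci(c_a, c_b, c_ab), phi=phi_v, t=t_v,
                )
            )
    return out


def _ranking_key(p: PairStats):
    # descending SCI, ties: higher joint count, then lexicographic pair
    return (-p.sci, -p.c_ij, p.code_i, p.code_j)


def derive_cutoff(
    pairs: Sequence[PairStats], t_threshold: float = 1.96
) -> CutoffResult:
    """Derive the subgroup's SCI cut-off (steps i-iv above).

    An empty co-occurrence structure (q = 0) yields an empty network, not an
    exception; the cut-off is then +inf.
    """
    positive = [p for p in pairs if p.c_ij > 0]
    q = len(positive)
    if q == 0:
        return CutoffResult(q=0, e=0, sci_cutoff=math.inf, n_edges=0)
    mean_joint = sum(p.c_ij for p in positive) / q
    e = sum(
        1
        for p in positive
        if p.t is not None and p.t > t_threshold and p.c_ij > mean_joint
    )
    if e == 0:
        return CutoffResult(q=q, e=0, sci_cutoff=math.inf, n_edges=0)
    ranked = sorted(positive, key=_ranking_key)
    cutoff = ranked[e - 1].sci
    return CutoffResult(q=q, e=e, sci_cutoff=cutoff, n_edges=e)


def significant_edges(
    pairs: Sequence[PairStats], cutoff: CutoffResult
) -> list[tuple[str, str, float]]:
    """The subgroup's significant edge set: top-e pairs by SCI.

    Returns exactly ``cutoff.e`` edges as (code_i, code_j, weight = SCI),
    deterministically under SCI ties (higher c_ij first, then lexicographic
    pair identity).
    """
    if cutoff.e == 0:
        return []
    positive = [p for p in pairs if p.c_ij > 0]
    ranked = sorted(positive, key=_ranking_key)
    return [(p.code_i, p.code_j, p.sci) for p in ranked[: cutoff.e]]


def _check_counts(c_i: int, c_j: int, c_ij: int, n: int | None = None) -> None:
    if c_ij < 0 or c_i < 0 or c_j < 0:
        raise ValueError("counts must be nonnegative")
    if c_ij > min(c_i, c_j):
        raise ValueError("joint count exceeds a marginal count")
    if n is not None and max(c_i, c_j) > n:
        raise ValueError("marginal count exceeds subgroup size")
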