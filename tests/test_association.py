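"""Pair statistics (SCI, phi, t) and the cut-off procedure, checked against
independent brute-force oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from morbnet.association import (
    count_pairs,
    derive_cutoff,
    phi,
    sci,
    significant_edges,
    t_value,
)
from morbnet.cohort import ComorbidityProfile


# --------------------------------------------------------------------------
# independent oracles
# --------------------------------------------------------------------------

def brute_force_counts(patient_sets, codes):
    """O(N * k^2) double loop over patients and unordered code pairs."""
    codes = sorted(codes)
    out = {}
    for a_idx, a in enumerate(codes):
        for b in codes[a_idx + 1:]:
            c_a = sum(a in s for s in patient_sets)
            c_b = sum(b in s for s in patient_sets)
            c_ab = sum(a in s and b in s for s in patient_sets)
            out[(a, b)] = (c_a, c_b, c_ab)
    return out


def brute_force_cutoff(pairs, t_threshold=1.96):
    """Exhaustive re-derivation of (q, e, edge set) from first principles."""
    positive = [p for p in pairs if p.c_ij > 0]
    q = len(positive)
    if q == 0:
        return 0, 0, set()
    mean_joint = sum(p.c_ij for p in positive) / q
    e = 0
    for p in positive:
        if p.t is not None and p.t > t_threshold and p.c_ij > mean_joint:
            e += 1
    ranked = sorted(
        positive, key=lambda p: (-p.sci, -p.c_ij, p.code_i, p.code_j)
    )
    return q, e, {(p.code_i, p.code_j) for p in ranked[:e]}


def random_profiles(rng, n_patients, codes, p=0.4):
    sets = [
        frozenset(c for c in codes if rng.random() < p) for _ in range(n_patients)
    ]
    return [ComorbidityProfile(f"p{i}", s) for i, s in enumerate(sets)]


# --------------------------------------------------------------------------
# scalar statistics
# --------------------------------------------------------------------------

@pytest.mark.parametrize(
    "c_i, c_j, c_ij, expected",
    [
        (6, 6, 6, 1.0),          # identical patient sets
        (4, 9, 0, 0.0),          # disjoint conditions
        (4, 9, 3, 0.5),          # 3 / sqrt(36)
    ],
)
def test_sci_known_values(c_i, c_j, c_ij, expected):
    assert sci(c_i, c_j, c_ij) == pytest.approx(expected)


def test_sci_requires_positive_marginals():
    with pytest.raises(ValueError):
        sci(0, 5, 0)


def test_phi_independence_and_perfect_association():
    # c_ij * N == c_i * c_j -> exactly zero
    assert phi(10, 10, 1, 100) == pytest.approx(0.0)
    # identical indicator vectors -> +1
    assert phi(5, 5, 5, 10) == pytest.approx(1.0)


def test_phi_degenerate_margins_are_undefined():
    assert phi(0, 5, 0, 10) is None
    assert phi(5, 10, 5, 10) is None


@given(
    st.integers(min_value=6, max_value=40),
    st.data(),
)
def test_phi_equals_pearson_correlation_of_indicators(n, data):
    """Phi must agree with np.corrcoef of the two binary indicator vectors."""
    rng = np.random.default_rng(data.draw(st.integers(0, 10_000)))
    x = rng.random(n) < 0.4
    y = rng.random(n) < 0.5
    c_i, c_j, c_ij = int(x.sum()), int(y.sum()), int((x & y).sum())
    result = phi(c_i, c_j, c_ij, n)
    if c_i in (0, n) or c_j in (0, n):
        assert result is None
    else:
        expected = np.corrcoef(x.astype(float), y.astype(float))[0, 1]
        assert result == pytest.approx(expected, abs=1e-12)


def test_t_value_known_and_degenerate_cases():
    assert t_value(0.0, 10) == pytest.approx(0.0)
    # 0.5 * sqrt(9) / sqrt(0.75)
    assert t_value(0.5, 11) == pytest.approx(0.5 * 3 / math.sqrt(0.75))
    assert t_value(1.0, 10) == math.inf
    assert t_value(-1.0, 10) == -math.inf
    assert t_value(0.5, 2) is None          # c_ij < 3: undefined
    assert t_value(None, 50) is None


@given(
    st.floats(min_value=-0.99, max_value=0.99),
    st.integers(min_value=3, max_value=500),
)
def test_t_sign_matches_phi_sign(phi_v, c_ij):
    t = t_value(phi_v, c_ij)
    assert math.copysign(1.0, t) == math.copysign(1.0, phi_v) or t == 0.0


@given(st.integers(min_value=2, max_value=30))
def test_duplication_invariance(scale):
    """SCI and phi are unchanged when the whole subgroup is duplicated."""
    c_i, c_j, c_ij, n = 14, 9, 5, 60
    assert sci(c_i * scale, c_j * scale, c_ij * scale) == pytest.approx(
        sci(c_i, c_j, c_ij)
    )
    assert phi(c_i * scale, c_j * scale, c_ij * scale, n * scale) == pytest.approx(
        phi(c_i, c_j, c_ij, n)
    )


def test_monotonicity_in_joint_count():
    """With marginals and N fixed, SCI and phi strictly increase with c_ij."""
    c_i, c_j, n = 20, 15, 100
    scis = [sci(c_i, c_j, c) for c in range(0, 16)]
    phis = [phi(c_i, c_j, c, n) for c in range(0, 16)]
    assert all(b > a for a, b in zip(scis, scis[1:]))
    assert all(b > a for a, b in zip(phis, phis[1:]))


# --------------------------------------------------------------------------
# pair counting
# --------------------------------------------------------------------------

def test_count_pairs_enumeration():
    profiles = [
        ComorbidityProfile("A", frozenset({"x", "y"})),
        ComorbidityProfile("B", frozenset({"x"})),
    ]
    (p,) = count_pairs(profiles, ["x", "y"])
    assert (p.c_i, p.c_j, p.c_ij, p.n) == (2, 1, 1, 2)
    assert p.sci == pytest.approx(1 / math.sqrt(2))


def test_count_pairs_matches_brute_force_on_random_fixture():
    rng = np.random.default_rng(42)
    codes = [f"c{i}" for i in range(8)]
    profiles = random_profiles(rng, 50, codes)
    expected = brute_force_counts([p.conditions for p in profiles], codes)
    result = {p.key: (p.c_i, p.c_j, p.c_ij) for p in count_pairs(profiles, codes)}
    for key, counts in expected.items():
        if counts[0] == 0 or counts[1] == 0:
            assert key not in result  # zero-marginal pairs are skipped
        else:
            assert result[key] == counts


def test_count_pairs_symmetric_in_code_order():
    rng = np.random.default_rng(7)
    codes = ["a", "b", "c", "d"]
    profiles = random_profiles(rng, 30, codes)
    fwd = {p.key: p for p in count_pairs(profiles, codes)}
    rev = {p.key: p for p in count_pairs(profiles, list(reversed(codes)))}
    assert fwd.keys() == rev.keys()
    for key in fwd:
        assert fwd[key].sci == rev[key].sci
        assert fwd[key].c_ij == rev[key].c_ij


# --------------------------------------------------------------------------
# cut-off derivation and edge selection
# --------------------------------------------------------------------------

def test_cutoff_all_zero_joint_counts():
    profiles = [
        ComorbidityProfile("A", frozenset({"x"})),
        ComorbidityProfile("B", frozenset({"y"})),
    ]
    pairs = count_pairs(profiles, ["x", "y"])
    cut = derive_cutoff(pairs)
    assert (cut.q, cut.e, cut.n_edges) == (0, 0, 0)
    assert significant_edges(pairs, cut) == []


def test_mean_joint_count_rule_excludes_the_smallest_pair():
    """The strict c_ij > mean(c_ij) criterion can never admit every positive
    pair (the minimum of a set cannot exceed its mean), so e < q whenever
    q >= 1; with one dominant pair, exactly that pair becomes the edge set."""
    from morbnet.association import PairStats

    def mk(i, j, c_i, c_j, c_ij, n=1000):
        phi_v = phi(c_i, c_j, c_ij, n)
        return PairStats(i, j, c_i, c_j, c_ij, n, sci(c_i, c_j, c_ij),
                         phi_v, t_value(phi_v, c_ij))

    dominant = mk("x", "y", 120, 120, 100)   # phi ~ 0.82, far above the mean
    minor = mk("x", "z", 30, 30, 12)         # strongly associated but below mean
    pairs = [dominant, minor]
    cut = derive_cutoff(pairs)
    assert cut.q == 2
    assert cut.e == 1
    edges = significant_edges(pairs, cut)
    assert [(i, j) for i, j, _ in edges] == [("x", "y")]
    assert cut.sci_cutoff == pytest.approx(dominant.sci)

    # single positive pair: mean equals its own joint count, so no edge ever
    (single,) = [dominant]
    cut1 = derive_cutoff([single])
    assert (cut1.q, cut1.e) == (1, 0)


@pytest.mark.parametrize("seed", range(25))
def test_cutoff_matches_exhaustive_enumeration(seed):
    """Six conditions, 40 patients: q, e and the edge set agree with the
    brute-force re-derivation of every criterion."""
    rng = np.random.default_rng(seed)
    codes = [f"c{i}" for i in range(6)]
    profiles = random_profiles(rng, 40, codes, p=0.45)
    pairs = count_pairs(profiles, codes)
    cut = derive_cutoff(pairs)
    q, e, edge_keys = brute_force_cutoff(pairs)
    assert (cut.q, cut.e) == (q, e)
    edges = significant_edges(pairs, cut)
    assert len(edges) == e == cut.n_edges
    assert {(i, j) for i, j, _ in edges} == edge_keys
    if e:
        assert cut.sci_cutoff == pytest.approx(min(w for _, _, w in edges))


def test_tie_break_at_cutoff_rank_is_deterministic():
    """Two pairs tied on SCI at the boundary: higher c_ij wins, then the
    lexicographically smaller pair."""
    from morbnet.association import PairStats

    def mk(i, j, c_i, c_j, c_ij, n=1000):
        phi_v = phi(c_i, c_j, c_ij, n)
        return PairStats(i, j, c_i, c_j, c_ij, n, sci(c_i, c_j, c_ij),
                         phi_v, t_value(phi_v, c_ij))

    # same SCI = 0.5: (a,b) with c_ij 50 and (c,d) with c_ij 10
    tied_big = mk("a", "b", 100, 100, 50)
    tied_small = mk("c", "d", 20, 20, 10)
    strong = mk("e", "f", 40, 40, 36)  # SCI 0.9, clearly significant
    pairs = [tied_small, tied_big, strong]
    cut = derive_cutoff(pairs)
    assert cut.e == 2
    edges = significant_edges(pairs, cut)
    assert [(i, j) for i, j, _ in edges] == [("e", "f"), ("a", "b")]
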