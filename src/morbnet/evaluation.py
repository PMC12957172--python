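"""Evaluation protocols: known-truth recovery studies on synthetic cohorts.

These routines quantify how reliably the full analysis chain recovers the
structure the generator plants:

* :func:`planted_recovery` — over seeded replicates at study scale (four
  subgroups of ~5,000 patients), the fraction of planted pairs recovered as
  significant edges in their target subgroup, and the fraction of
  subgroup-unique planted pairs that surface in the unique-pair report.
* :func:`smd_calibration` — with no planted laboratory shifts, the fraction
  of replicates in which every lab's |SMD| stays below the conventional 0.10
  smallness bound.
* :func:`network_scale_metrics` — density and average degree implied by a
  node/edge count, computed by building an actual graph and summarizing it
  (these metrics depend on the counts alone, not on which edges exist).
"""

from __future__ import annotations

from typing import Mapping

import numpy as np

from .association import count_pairs, derive_cutoff, significant_edges
from .cohort import build_profiles, prevalence_filter
from .config import (
    SUBGROUPS,
    SyntheticConfig,
    null_lab_config,
    recovery_config,
)
from .descriptives import KIND_NORMAL, KIND_SKEWED, smd_continuous
from .network import build_network, summarize_network
from .synthetic import generate_cohort, planted_truth

#: Node and edge counts of the four sex-stratified networks at the scale
#: reported for a large tertiary-care diabetes cohort; used as worked-example
#: inputs for count-determined metrics.
REFERENCE_NETWORK_SCALES: dict[str, tuple[int, int]] = {
    "T1DM_male": (22, 82),
    "T1DM_female": (22, 92),
    "T2DM_male": (22, 78),
    "T2DM_female": (20, 89),
}


def subgroup_edge_sets(
    config: SyntheticConfig,
    prevalence_threshold: float = 0.01,
    t_threshold: float = 1.96,
) -> dict[str, set[tuple[str, str]]]:
    """Generate one cohort and run the association chain per subgroup."""
    patients, diagnoses, catalog = generate_cohort(config)
    out: dict[str, set[tuple[str, str]]] = {}
    for dtype in ("T1DM", "T2DM"):
        sub = patients[patients["diabetes_type"] == dtype]
        profiles = build_profiles(sub, diagnoses, catalog)
        retained, _, filtered = prevalence_filter(
            profiles, cohort_n=len(sub), threshold=prevalence_threshold
        )
        for sex in ("male", "female"):
            sg = f"{dtype}_{sex}"
            ids = sub.loc[sub["sex"] == sex, "patient_id"]
            pairs = count_pairs([filtered[p] for p in sorted(ids)], retained)
            cutoff = derive_cutoff(pairs, t_threshold=t_threshold)
            out[sg] = {
                (i, j) for i, j, _ in significant_edges(pairs, cutoff)
            }
    return out


def planted_recovery(
    n_replicates: int = 20,
    n_per_cohort: int = 10_000,
    base_seed: int = 0,
) -> dict[str, float]:
    """Planted-pair recovery rates over seeded replicates.

    Returns percentages: ``recovery`` (planted pair significant in its target
    subgroup), ``unique`` (subgroup-unique planted pair reported as unique,
    i.e. present in the target edge set and absent from the other three).
    """
    recovered = attempted = 0
    unique_ok = unique_attempted = 0
    for rep in range(n_replicates):
        cfg = recovery_config(
            n_per_cohort=n_per_cohort, seed=int(base_seed) + rep
        )
        truth = planted_truth(cfg)
        edge_sets = subgroup_edge_sets(cfg)
        for sg in SUBGROUPS:
            others = [o for o in SUBGROUPS if o != sg]
            only_here = truth.pairs_by_subgroup[sg] - frozenset().union(
                *(truth.pairs_by_subgroup[o] for o in others)
            )
            for pair in truth.pairs_by_subgroup[sg]:
                attempted += 1
                recovered += pair in edge_sets[sg]
            for pair in only_here:
                unique_attempted += 1
                unique_ok += pair in edge_sets[sg] and not any(
                    pair in edge_sets[o] for o in others
                )
    return {
        "recovery": 100.0 * recovered / attempted,
        "unique": 100.0 * unique_ok / unique_attempted,
        "n_replicates": n_replicates,
    }


def smd_calibration(
    n_replicates: int = 20,
    n_per_cohort: int = 2_000,
    base_seed: int = 0,
) -> dict[str, float]:
    """Fraction of replicates with every lab |SMD| < 0.10 under no true shift."""
    ok = 0
    worst = 0.0
    for rep in range(n_replicates):
        cfg = null_lab_config(
            n_per_cohort=n_per_cohort, seed=int(base_seed) + 10_000 + rep
        )
        patients, _, _ = generate_cohort(cfg)
        t1 = patients[patients["diabetes_type"] == "T1DM"]
        t2 = patients[patients["diabetes_type"] == "T2DM"]
        max_abs = 0.0
        for lab in cfg.labs:
            kind = KIND_NORMAL if lab.family == "normal" else KIND_SKEWED
            res = smd_continuous(t1[lab.name], t2[lab.name], kind=kind)
            max_abs = max(max_abs, abs(res.smd))
        ok += max_abs < 0.10
        worst = max(worst, max_abs)
    return {
        "calibrated": 100.0 * ok / n_replicates,
        "worst_abs_smd": worst,
        "n_replicates": n_replicates,
    }


def network_scale_metrics(
    scales: Mapping[str, tuple[int, int]] | None = None,
    seed: int = 0,
) -> dict[str, dict[str, float]]:
    """Density and average degree for given node/edge counts.

    Both metrics are functions of the counts alone; they are nevertheless
    computed by materialising a random simple graph with exactly those counts
    and summarising it through the normal network path.
    """
    scales = dict(REFERENCE_NETWORK_SCALES if scales is None else scales)
    rng = np.random.default_rng(seed)
    out = {}
    for sg, (n_nodes, n_edges) in scales.items():
        nodes = [f"n{i:02d}" for i in range(n_nodes)]
        possible = [
            (nodes[i], nodes[j])
            for i in range(n_nodes)
            for j in range(i + 1, n_nodes)
        ]
        chosen = rng.choice(len(possible), size=n_edges, replace=False)
        edges = [
            (*possible[k], float(rng.uniform(0.05, 1.0))) for k in sorted(chosen)
        ]
        summary = summarize_network(build_network(nodes, edges, label=sg))
        out[sg] = {
            "density": summary.density,
            "avg_degree": summary.avg_degree,
        }
    return out
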