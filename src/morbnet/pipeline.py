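"""End-to-end pipeline: simulate -> cohort -> describe -> associate ->
network -> contrast, with plain-CSV interchange between stages.

Each stage reads its inputs from the run's output directory (or the
configured input directory for the raw extract) and writes its own outputs,
so stages compose: running them one by one reproduces exactly what
:func:`run_pipeline` produces, and a run can resume from cached stage
outputs.  A ``manifest.json`` records the configuration, seed and per-stage
row/edge counts; outputs are deterministic for a fixed (config, seed).
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import json
import logging
import math
from pathlib import Path
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd

from . import __version__ as _version
from .association import (
    count_pairs,
    derive_cutoff,
    significant_edges,
)
from .cohort import (
    ComorbidityProfile,
    age_band_label,
    assign_index_dates,
    build_profiles,
    match_cohorts,
    observed_followup,
    prevalence_filter,
)
from .config import DIABETES_TYPES, SEXES, SUBGROUPS, RunConfig, subgroup_label
from .contrast import difference_network, unique_pairs
from .descriptives import (
    KIND_NORMAL,
    KIND_SKEWED,
    smd_binary,
    smd_continuous,
    summarize,
)
from .errors import DataError
from .network import (
    MultimorbidityNetwork,
    build_network,
    node_metrics,
    pagerank_hubs,
    summarize_network,
    system_aggregates,
)
from .synthetic import generate_cohort, write_extract

logger = logging.getLogger("morbnet")

_CORE_PATIENT_COLUMNS = (
    "patient_id", "sex", "diabetes_type", "index_age_years",
    "index_date", "last_visit_date",
)

_EXTRACT_SCHEMAS = {
    "patients.csv": _CORE_PATIENT_COLUMNS,
    "diagnoses.csv": ("patient_id", "condition_code", "diagnosis_date"),
    "catalog.csv": ("condition_code", "label", "icd10_chapter", "is_index_disease"),
}


# --------------------------------------------------------------------------
# Extract IO
# --------------------------------------------------------------------------

def load_extract(directory) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Load and schema-check the three-extract CSVs."""
    directory = Path(directory)
    frames = []
    for fname, required in _EXTRACT_SCHEMAS.items():
        path = directory / fname
        if not path.exists():
            raise DataError(f"{path}: file not found")
        df = pd.read_csv(path, dtype={"patient_id": str, "condition_code": str})
        for col in required:
            if col not in df.columns:
                raise DataError(f"{path}: missing required column {col!r}")
        frames.append(df)
    return tuple(frames)  # type: ignore[return-value]


def lab_columns(patients: pd.DataFrame) -> list[str]:
    return [c for c in patients.columns if c not in _CORE_PATIENT_COLUMNS]


# --------------------------------------------------------------------------
# Stages
# --------------------------------------------------------------------------

def stage_simulate(cfg: RunConfig) -> dict:
    """Generate the synthetic extract into the run directory."""
    if cfg.synthetic is None:
        raise DataError("stage_simulate requires a synthetic configuration")
    patients, diagnoses, catalog = generate_cohort(cfg.synthetic)
    write_extract(cfg.out_dir, patients, diagnoses, catalog)
    return {
        "patients": len(patients),
        "diagnoses": len(diagnoses),
        "catalog": len(catalog),
    }


def stage_cohort(cfg: RunConfig) -> dict:
    """Index dates, 1:1 exact matching, follow-up, profiles, prevalence filter."""
    out = Path(cfg.out_dir)
    patients, diagnoses, catalog = load_extract(cfg.input_dir or cfg.out_dir)

    index_codes = set(
        catalog.loc[catalog["is_index_disease"] == 1, "condition_code"]
    )
    idx = assign_index_dates(diagnoses, index_codes)
    patients = patients[patients["patient_id"].isin(idx.index)].copy()
    patients["index_date"] = patients["patient_id"].map(idx)

    cases = patients[patients["diabetes_type"] == "T1DM"]
    comparators = patients[patients["diabetes_type"] == "T2DM"]
    matched = match_cohorts(cases, comparators, seed=cfg.seed)

    matched_ids = set(matched.case_ids) | set(matched.comparator_ids)
    cohort = patients[patients["patient_id"].isin(matched_ids)].copy()
    cohort["followup_years"] = [
        observed_followup(i, l, patient_id=p)
        for p, i, l in zip(
            cohort["patient_id"], cohort["index_date"], cohort["last_visit_date"]
        )
    ]
    cohort["subgroup"] = [
        subgroup_label(t, s) for t, s in zip(cohort["diabetes_type"], cohort["sex"])
    ]
    cohort = cohort.sort_values("patient_id").reset_index(drop=True)

    # comorbidity profiles + per-cohort prevalence filter (sexes pooled)
    profile_rows, prev_rows = [], []
    for dtype in DIABETES_TYPES:
        sub = cohort[cohort["diabetes_type"] == dtype]
        profiles = build_profiles(sub, diagnoses, catalog, chapters=cfg.chapters)
        retained, prevalence, filtered = prevalence_filter(
            profiles, cohort_n=len(sub), threshold=cfg.prevalence_threshold
        )
        keep = set(retained)
        for code, p in prevalence.items():
            prev_rows.append(
                {
                    "cohort": dtype,
                    "condition_code": code,
                    "count": int(round(p * len(sub))),
                    "prevalence": p,
                    "retained": int(code in keep),
                }
            )
        for pid in sorted(filtered):
            prof = filtered[pid]
            profile_rows.append(
                {
                    "patient_id": pid,
                    "conditions": ";".join(sorted(prof.conditions)),
                    "n_conditions": len(prof.conditions),
                    "is_multimorbid": int(prof.is_multimorbid),
                }
            )

    cohort.to_csv(out / "cohort.csv", index=False)
    pd.DataFrame(matched.pairs, columns=["t1dm_patient_id", "t2dm_patient_id"]).to_csv(
        out / "matched_pairs.csv", index=False
    )
    pd.DataFrame(matched.unmatched, columns=["patient_id", "reason"]).to_csv(
        out / "unmatched.csv", index=False
    )
    pd.DataFrame(profile_rows).to_csv(out / "profiles.csv", index=False)
    pd.DataFrame(prev_rows).to_csv(out / "prevalence.csv", index=False)
    return {
        "matched_pairs": len(matched.pairs),
        "unmatched": len(matched.unmatched),
        "cohort": len(cohort),
    }


def _resolve_lab_kind(cfg: RunConfig, cohort: pd.DataFrame, lab: str) -> str:
    if lab in cfg.lab_kinds:
        return cfg.lab_kinds[lab]
    values = cohort[lab].dropna().to_numpy(dtype=float)
    if values.size < 3 or values.std(ddof=1) == 0:
        return KIND_NORMAL
    z = (values - values.mean()) / values.std(ddof=1)
    return KIND_SKEWED if np.abs((z**3).mean()) > 1.0 else KIND_NORMAL


def _fmt_summary(values, kind) -> str:
    rec = summarize(values, kind)
    if kind == KIND_NORMAL:
        return f"{rec['mean']:.2f} ± {rec['sd']:.2f}"
    return f"{rec['median']:.2f} ({rec['q1']:.2f}, {rec['q3']:.2f})"


def stage_describe(cfg: RunConfig) -> dict:
    """Baseline table: summaries and SMDs, overall and per sex."""
    out = Path(cfg.out_dir)
    cohort = pd.read_csv(out / "cohort.csv", dtype={"patient_id": str})
    labs = [
        c for c in lab_columns(cohort)
        if c not in ("followup_years", "subgroup")
    ]
    rows = []
    strata = [("overall", cohort)] + [
        (sex, cohort[cohort["sex"] == sex]) for sex in SEXES
    ]
    for stratum, frame in strata:
        t1 = frame[frame["diabetes_type"] == "T1DM"]
        t2 = frame[frame["diabetes_type"] == "T2DM"]
        if t1.empty or t2.empty:
            continue

        # age bands: per-band binary SMD
        for lo_hi in ("10-17", "18-39", "40-59", "60-79"):
            in_band_1 = t1["index_age_years"].map(age_band_label) == lo_hi
            in_band_2 = t2["index_age_years"].map(age_band_label) == lo_hi
            p1, p2 = in_band_1.mean(), in_band_2.mean()
            rows.append(
                {
                    "variable": f"age_band_{lo_hi}", "stratum": stratum,
                    "t1dm": f"{int(in_band_1.sum())} ({100 * p1:.1f})",
                    "t2dm": f"{int(in_band_2.sum())} ({100 * p2:.1f})",
                    "smd": round(smd_binary(p1, len(t1), p2, len(t2)), 2),
                    "transform": "none",
                }
            )
        if stratum == "overall":
            p1 = (t1["sex"] == "female").mean()
            p2 = (t2["sex"] == "female").mean()
            rows.append(
                {
                    "variable": "sex_female", "stratum": stratum,
                    "t1dm": f"{int((t1['sex'] == 'female').sum())} ({100 * p1:.1f})",
                    "t2dm": f"{int((t2['sex'] == 'female').sum())} ({100 * p2:.1f})",
                    "smd": round(smd_binary(p1, len(t1), p2, len(t2)), 2),
                    "transform": "none",
                }
            )

        continuous = [("index_age_years", KIND_NORMAL), ("followup_years", KIND_SKEWED)]
        continuous += [(lab, _resolve_lab_kind(cfg, cohort, lab)) for lab in labs]
        for var, kind in continuous:
            a = t1[var].dropna().to_numpy(dtype=float)
            b = t2[var].dropna().to_numpy(dtype=float)
            res = smd_continuous(a, b, kind=kind, variable=var)
            rows.append(
                {
                    "variable": var, "stratum": stratum,
                    "t1dm": _fmt_summary(a, kind),
                    "t2dm": _fmt_summary(b, kind),
                    "smd": round(res.smd, 2),
                    "transform": res.transform_used,
                }
            )
    table1 = pd.DataFrame(rows)
    table1.to_csv(out / "table1.csv", index=False)
    return {"table1_rows": len(table1)}


def _load_profiles(out: Path) -> dict[str, ComorbidityProfile]:
    df = pd.read_csv(out / "profiles.csv", dtype={"patient_id": str})
    profiles = {}
    for _, row in df.iterrows():
        conds = row["conditions"]
        codes = frozenset() if pd.isna(conds) or conds == "" else frozenset(
            str(conds).split(";")
        )
        profiles[row["patient_id"]] = ComorbidityProfile(row["patient_id"], codes)
    return profiles


def _retained_codes(out: Path) -> dict[str, list[str]]:
    prev = pd.read_csv(out / "prevalence.csv")
    return {
        dtype: sorted(
            prev.loc[
                (prev["cohort"] == dtype) & (prev["retained"] == 1), "condition_code"
            ]
        )
        for dtype in DIABETES_TYPES
    }


def stage_associate(cfg: RunConfig) -> dict:
    """Per-subgroup pair statistics, cut-off derivation and edge sets."""
    out = Path(cfg.out_dir)
    cohort = pd.read_csv(out / "cohort.csv", dtype={"patient_id": str})
    profiles = _load_profiles(out)
    retained = _retained_codes(out)

    counts = {}
    for sg in SUBGROUPS:
        dtype, sex = sg.split("_")
        ids = cohort.loc[cohort["subgroup"] == sg, "patient_id"]
        sub_profiles = [profiles[p] for p in sorted(ids) if p in profiles]
        pairs = count_pairs(sub_profiles, retained[dtype])
        cutoff = derive_cutoff(pairs, t_threshold=cfg.t_threshold)
        edges = significant_edges(pairs, cutoff)
        edge_keys = {(i, j) for i, j, _ in edges}
        pd.DataFrame(
            [
                {
                    "code_i": p.code_i, "code_j": p.code_j,
                    "c_i": p.c_i, "c_j": p.c_j, "c_ij": p.c_ij, "n": p.n,
                    "sci": p.sci,
                    "phi": np.nan if p.phi is None else p.phi,
                    "t": np.nan if p.t is None else p.t,
                    "passes": int((p.code_i, p.code_j) in edge_keys),
                }
                for p in pairs
            ]
        ).to_csv(out / f"pairs_{sg}.csv", index=False)
        with open(out / f"cutoff_{sg}.json", "w") as fh:
            json.dump(
                {
                    "subgroup": sg, "q": cutoff.q, "e": cutoff.e,
                    "sci_cutoff": None if math.isinf(cutoff.sci_cutoff)
                    else cutoff.sci_cutoff,
                    "n_edges": cutoff.n_edges,
                },
                fh, indent=2, sort_keys=True,
            )
        counts[sg] = cutoff.e
    return {"edges_per_subgroup": counts}


def _load_subgroup_network(out: Path, sg: str) -> MultimorbidityNetwork:
    g = nx.read_graphml(out / f"network_{sg}.graphml")
    edges = [(u, v, float(d["sci_weight"])) for u, v, d in g.edges(data=True)]
    return build_network(sorted(g.nodes), edges, label=sg)


def stage_network(cfg: RunConfig) -> dict:
    """Build subgroup networks; export metrics, hubs and chapter aggregates."""
    out = Path(cfg.out_dir)
    _, _, catalog = load_extract(cfg.input_dir or cfg.out_dir)
    chapter_map = dict(
        zip(catalog["condition_code"], catalog["icd10_chapter"])
    )
    label_map = dict(zip(catalog["condition_code"], catalog["label"]))
    retained = _retained_codes(out)

    summaries, agg_rows = [], []
    for sg in SUBGROUPS:
        dtype, _ = sg.split("_")
        pairs = pd.read_csv(out / f"pairs_{sg}.csv")
        edges = [
            (r.code_i, r.code_j, r.sci)
            for r in pairs.itertuples()
            if r.passes == 1
        ]
        net = build_network(retained[dtype], edges, label=sg)

        g = nx.Graph()
        for v in net.nodes:
            g.add_node(v, label=label_map.get(v, v), chapter=chapter_map.get(v, ""))
        for u, v, w in net.edges:
            g.add_edge(u, v, sci_weight=w)
        nx.write_graphml(g, out / f"network_{sg}.graphml")

        node_metrics(net, damping=cfg.damping).to_csv(
            out / f"node_metrics_{sg}.csv", index=False
        )
        hubs = pd.DataFrame(
            [
                {"rank": i + 1, "code": c, "label": label_map.get(c, c), "pagerank": s}
                for i, (c, s) in enumerate(
                    pagerank_hubs(net, k=cfg.hub_k, damping=cfg.damping)
                )
            ]
        )
        hubs.to_csv(out / f"hubs_{sg}.csv", index=False)

        s = summarize_network(net)
        summaries.append(
            {
                "subgroup": sg,
                "n_nodes": s.n_nodes,
                "n_edges": s.n_edges,
                "density": round(s.density, 3),
                "avg_degree": round(s.avg_degree, 3),
                "avg_weighted_degree": round(s.avg_weighted_degree, 3),
                "avg_harmonic_centrality": round(s.avg_harmonic_centrality, 3),
            }
        )
        agg = system_aggregates(net, chapter_map)
        agg.insert(0, "subgroup", sg)
        agg_rows.append(agg)

    pd.DataFrame(summaries).to_csv(out / "summary_all.csv", index=False)
    pd.concat(agg_rows, ignore_index=True).to_csv(
        out / "system_aggregates.csv", index=False
    )
    return {"networks": len(summaries)}


def stage_contrast(cfg: RunConfig) -> dict:
    """All 12 ordered difference networks plus the subgroup-unique pairs."""
    out = Path(cfg.out_dir)
    nets = {sg: _load_subgroup_network(out, sg) for sg in SUBGROUPS}
    n_diff = 0
    for a in SUBGROUPS:
        for b in SUBGROUPS:
            if a == b:
                continue
            diff = difference_network(nets[a], nets[b])
            pd.DataFrame(
                list(diff.edges), columns=["code_i", "code_j", "sci"]
            ).to_csv(out / f"difference_{a}_not_{b}.csv", index=False)
            n_diff += len(diff.edges)
    uniq = unique_pairs(nets)
    rows = [
        {"subgroup": sg, "code_i": i, "code_j": j, "sci": w}
        for sg in SUBGROUPS
        for i, j, w in uniq[sg]
    ]
    pd.DataFrame(rows, columns=["subgroup", "code_i", "code_j", "sci"]).to_csv(
        out / "unique_pairs.csv", index=False
    )
    return {"difference_edges": n_diff, "unique_pairs": len(rows)}


_STAGES = (
    ("cohort", stage_cohort),
    ("describe", stage_describe),
    ("associate", stage_associate),
    ("network", stage_network),
    ("contrast", stage_contrast),
)


def run_pipeline(cfg: RunConfig) -> dict:
    """Run every stage and write ``manifest.json``; returns the manifest."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage_counts = {}
    if cfg.synthetic is not None and cfg.input_dir is None:
        stage_counts["simulate"] = stage_simulate(cfg)
        logger.info("stage simulate: %s", stage_counts["simulate"])
    for name, fn in _STAGES:
        stage_counts[name] = fn(cfg)
        logger.info("stage %s: %s", name, stage_counts[name])
    manifest = {
        "package": "morbnet",
        "version": _version,
        "seed": cfg.seed,
        "config": _jsonable(cfg),
        "stages": stage_counts,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {
            f.name: _jsonable(getattr(obj, f.name))
            for f in dataclasses.fields(obj)
        }
    if isinstance(obj, (dt.date, dt.datetime)):
        return obj.isoformat()
    if isinstance(obj, (frozenset, set)):
        return sorted(obj)
    if isinstance(obj, (list, tuple)):
        return [_jsonable(x) for x in obj]
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    return obj
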