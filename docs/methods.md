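# Methods

## Study design being reconstructed

The pipeline mirrors a retrospective matched-cohort multimorbidity study on
coded EHR data. Patients aged 10–79 with a first index-disease (T1DM)
diagnosis between 2014-01-01 and 2023-12-31 define the case cohort; the
index date is the earliest qualifying diagnosis record. Comparators (T2DM)
are chosen by 1:1 **exact matching on sex and index age in whole years**:
within each (sex, age) stratum, `min(n_cases, n_comparators)` pairs are
formed; when one side outnumbers the other, the kept participants are drawn
uniformly without replacement from lexicographically sorted ids, making the
result deterministic for a fixed seed and independent of input row order.
Observed follow-up is `(last_visit − index_date) in days / 365.25`.

Comorbid conditions are diagnosis codes recorded **on or after** the index
date (same-day codes at the index encounter count — first-visit coding
commonly includes concurrent diagnoses, and a strict "after" would discard
the index encounter), restricted to ICD-10 Chapters I–XIV and excluding the
generic index-disease labels (diabetes-specific complications remain
eligible as ordinary conditions). A condition is retained when its
prevalence is **≥ 1% (inclusive)** within the diabetes-type cohort, sexes
pooled; the retained list is shared by that cohort's male and female
networks. Multimorbidity means ≥ 2 retained conditions. Two points here are
assumptions, since the source design leaves them open: the 1% filter could
alternatively be applied per sex-specific subgroup (which would allow the
two sexes of one cohort to have different node counts), and same-day
index-visit diagnoses could be excluded.

## Pair association and the SCI cut-off

Definitions as in the README. Numerical conventions:

* Φ is undefined (`None`) when a margin is 0 or N; such pairs can never be
  significant. Pairs with a zero marginal count are skipped entirely (SCI
  undefined; impossible after the prevalence filter).
* t is undefined when c_ij < 3 (the √(c_ij − 2) term would be ≤ 0 wherever
  phi ≠ 0 matters); undefined t counts as non-significant. |Φ| = 1 maps to a
  signed infinity, so perfect positive association is always significant.
* The degrees of freedom for t come from the **joint count** c_ij, not from
  N. This is the printed form of the source procedure and is kept as the
  default; `t_value_conventional` provides the N−2 variant. The choice
  matters: with joint-count degrees of freedom, significance requires joint
  counts of order 10², so meaningful networks need thousands of patients per
  subgroup.
* Cut-off derivation per subgroup: q = #{pairs with c_ij > 0};
  e = #{pairs with t > 1.96 and c_ij > mean joint count over the q pairs};
  the edge set is the **top-e pairs ranked by SCI** (the unique reading that
  makes the SCI network's edge count equal e), and the cut-off is the e-th
  ranked SCI (+∞ when e = 0). Ties at the boundary are broken by higher
  c_ij, then lexicographic pair identity, so exactly e edges are kept
  deterministically.
* A consequence worth knowing: the strict `c_ij > mean` criterion can never
  admit *every* co-occurring pair (a set's minimum cannot exceed its mean),
  so e < q always, and a subgroup with a single co-occurring pair has e = 0.
* No additional Φ > 0 condition is imposed in the significance screen:
  t > 1.96 already enforces positivity.

## Network metrics

Networks are simple, weighted, undirected; the node set is the cohort's
retained-condition list, so isolated conditions stay as degree-0 nodes.
Density = m / (n(n−1)/2), average degree = 2m/n. Harmonic centrality uses
unweighted hop-count shortest paths, `(1/(n−1))·Σ 1/d(u,v)` with unreachable
pairs contributing 0 — the (n−1) normalization (values in [0, 1]) is an
assumption; the source reports values consistent with *some* normalization
but does not state it. SCI weights enter only weighted degree and PageRank.
PageRank runs on the weighted graph with damping 0.85 (configurable),
isolated nodes redistributing uniformly, converged to an L1 change below
1e-9 (tolerance set well below that); hub diseases are the top-10 by score,
ties broken lexicographically. Chapter-level aggregates sum degree and
weighted degree over member nodes.

Contrasts operate on unordered pair identity: A-not-in-B keeps A's
significant edges absent from B (with A's weights); a subgroup-unique pair
has membership count exactly 1 across the four networks. Uniqueness is
evaluated over post-cut-off edge sets, not raw SCI > 0.

## Descriptive statistics

Mean ± SD (sample SD, n−1) for approximately normal variables; median (Q1,
Q3) with linear-interpolation quantiles for skewed ones; counts (%) for
categorical. SMD uses the average-variance pooled SD,
`(m_a − m_b)/√((s_a² + s_b²)/2)` — the standard matched-cohort form; the
source names SMD without a formula, so this is a documented assumption, as
is reporting one binary SMD per age-band row rather than a pooled
categorical SMD. Skewed variables are log-transformed before the SMD
(log(x+1) when zeros occur in either group; negative values are an error).
Degenerate guards: equal proportions → 0; both SDs zero with equal means →
0. HbA1c can be displayed in NGSP % via `NGSP = 0.09148·IFCC + 2.152`
(display-layer conversion only). In the pipeline, a lab's summary form is
taken from configuration when given, otherwise from sample skewness
(|skew| > 1 → skewed).

## Synthetic cohort generator

The generator emulates the study conditions, not any real registry:

* **Demographics.** Sex Bernoulli (female fraction default 0.494) and the
  four age bands 10–17/18–39/40–59/60–79 weighted 0.036/0.277/0.329/0.359,
  ages uniform within band. The T2DM cohort copies the T1DM (sex, age)
  multiset (permuted), so exact matching succeeds by default; an
  `unmatched_fraction` flag re-draws some comparator ages out of range to
  exercise the unmatched path.
* **Conditions.** Per subgroup, independent Bernoulli indicators at marginal
  prevalence `baseline × type multiplier × sex multiplier`; the default
  24-condition catalog (chapters I–XIV) carries plausible tertiary-care
  prevalences (hypertension 0.28 down to cirrhosis 0.02) with clinically
  oriented sex/type multipliers. The catalog is illustrative and fully
  user-configurable — the real study's grouping dictionary is not public.
* **Planted pairs.** For each planted pair the two indicator columns are
  re-drawn jointly from the unique 2×2 distribution that preserves both
  marginals and attains the configured odds ratio (closed-form root of the
  IPF fixed-point quadratic), in the target subgroups only. Pairs within one
  subgroup must be code-disjoint, since the joint draw replaces both
  columns. Defaults plant one cardiovascular pair in all four subgroups plus
  the sex-specific signature pairs of interest (eye complications–stroke and
  PVD–NAFLD in T1DM males; nephropathy–chronic gastritis and
  neuropathy–osteoporosis in T1DM females; hypertension–asthma in T2DM
  females).
* **Dates, follow-up, labs.** Index dates uniform over the 2014–2023
  window; follow-up log-normal per cohort (log-medians ln 3.8 vs ln 8.28
  years, truncated to [0.02, 11]), converted to a last-visit date; diagnosis
  dates uniform within [index, last visit]. Labs are normal or log-normal
  with additive location shifts per diabetes type and sex; defaults give
  T1DM higher HbA1c and HDL-C and lower TG and ALT, mirroring the
  qualitative clinical picture. Last-visit dates may extend past the index
  window (follow-up is drawn independently of the index date) — harmless
  for every downstream computation, which uses durations, not calendar
  cut-offs.
* **Seeding.** A single root seed spawns named substreams per stage and per
  (subgroup, condition) — keyed by a CRC of the code, so adding a condition
  or lab does not perturb unrelated draws; identical (config, seed) gives
  bit-identical tables.

What the generator does **not** emulate: visit-level utilization, coding
intensity that varies with follow-up length, ICD hierarchies below the
grouped-condition level, mortality, and — deliberately — any *global*
positive dependence among conditions (a patient-level frailty). Real
multimorbidity data show broad positive correlation between most condition
pairs, which is why the real study's networks have 78–92 edges while
synthetic networks at the same scale have only the planted ones. Passing
recovery tests therefore shows the chain detects controlled association
against an independence background; it does not certify behaviour under
dense correlation.

## Evaluation protocols and problem sizes

* **Count-determined metrics.** Density and average degree depend only on
  (n_nodes, n_edges); the reference scales (22/82, 22/92, 22/78, 20/89) are
  materialised as random simple graphs and summarised through the normal
  network path. Note the per-cohort shared node list in this package forces
  both sexes of one cohort to the same node count; reference scales with
  differing male/female node counts in one cohort would require the per-sex
  filter variant discussed above.
* **Oracle equivalence.** 120 random fixtures (5–50 patients, 2–8
  conditions) against a brute-force double-loop re-derivation of counts,
  SCI, Φ (also against `np.corrcoef` of the indicators), t and the full
  cut-off; agreement is exact.
* **Planted recovery.** 20 seeded replicates, two cohorts of 10,000 (four
  subgroups of ~5,000). The protocol plants pairs at marginals 0.12 and odds
  ratio 8 (shared pair 6). These satisfy the minimal interesting condition
  (odds ≥ 5, marginals ≥ 5%) with margin, chosen by an a-priori power
  analysis: with joint-count degrees of freedom, a pair at the minimum (odds
  5, 5% marginals, N = 5,000) has expected t ≈ 0.9 — undetectable by
  design — and a recovered pair must also out-rank the largest
  independence-driven SCI (≈ √(p_i·p_j) ≈ 0.30 for the most prevalent
  pair). At the chosen settings expected SCI is 0.36–0.41 and expected t is
  4–6, so failures are sampling accidents. SMD calibration uses 20
  replicates of 2,000 per cohort with all lab shifts removed; the null SMD
  has SD ≈ √(2/n) ≈ 0.032, so |SMD| < 0.10 is a ≈ 3 SD event per lab.
* **Determinism.** Two full pipeline runs at identical (config, seed) are
  compared file by file, byte for byte (the manifest is excluded only where
  it embeds the differing output paths).

## Known limitations

* The independence background (no frailty) makes synthetic networks far
  sparser than real multimorbidity networks; edge-count-dependent behaviour
  (e.g. cut-off values around 0.2–0.3) should not be extrapolated to real
  data.
* The joint-count t statistic has low power for rare conditions regardless
  of effect size; users analysing rare comorbidities should consider the
  N−2 variant and interpret its liberal behaviour accordingly.
* The matching stage implements exact matching only (no calipers or
  propensity scores), and condition status is time-invariant after the
  index date.
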