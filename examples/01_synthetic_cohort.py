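"""Generate a synthetic two-cohort EHR extract and inspect what was planted.

The generator emulates a matched diabetes study: a T1DM cohort and a
same-size T2DM comparator pool with identical (sex, index age) composition,
per-subgroup condition prevalences, and condition pairs whose co-occurrence
odds are raised only in chosen diabetes-type x sex subgroups.
"""

from morbnet import generate_cohort, planted_truth
from morbnet.config import default_config

cfg = default_config(n_per_cohort=2000, seed=42)
patients, diagnoses, catalog = generate_cohort(cfg)

print(f"patients: {len(patients)}  diagnosis rows: {len(diagnoses)}  "
      f"catalogued conditions: {len(catalog)}")

# realized vs target prevalence for a few conditions (T1DM cohort)
t1_ids = set(patients.loc[patients["diabetes_type"] == "T1DM", "patient_id"])
carriers = (
    diagnoses[diagnoses["patient_id"].isin(t1_ids)]
    .groupby("condition_code")["patient_id"].nunique()
)
print("\ncondition  target  realized (T1DM, sexes pooled)")
for code in ("HTN", "DLD", "DEYE", "ASTHMA"):
    spec = cfg.condition(code)
    target = (spec.marginal("T1DM", "male") + spec.marginal("T1DM", "female")) / 2
    print(f"{code:<9}  {target:.3f}   {carriers.get(code, 0) / len(t1_ids):.3f}")

truth = planted_truth(cfg)
print("\nplanted co-occurrence structure (ground truth for recovery tests):")
for sg, pairs in truth.pairs_by_subgroup.items():
    if pairs:
        print(f"  {sg}: {sorted(pairs)}")
# Realized prevalences should sit within sampling error of the targets, and
# the planted pairs are the associations downstream stages should rediscover.
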