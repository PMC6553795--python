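"""Generate a synthetic study cohort and write its input file set.

The generator plants a known interaction signal: drugs carry latent
cluster memberships, interactions are enriched within clusters, and the
clusters leave traces in every data modality (shared MedDRA terms,
paralog-family targets, synergistic yeast GI scores between family
homologs).  The matching `.null()` configuration disables every effect,
giving a negative control with identically structured inputs.
"""

from giddi import CohortConfig, generate_cohort

cfg = CohortConfig(n_drugs=60, prevalence=0.1, seed=7)
cohort = generate_cohort(cfg)

print(f"drugs:               {len(cohort.drugs)}")
print(f"pairs:               {len(cohort.all_pairs())}")
print(f"interacting pairs:   {len(cohort.positives)}")
print(f"excluded pairs:      {len(cohort.exclusions)}")
print(f"MedDRA paths:        {len(cohort.hierarchy.paths)}")
print(f"target genes:        {len(cohort.gene_sequences())}")
print(f"GI measurements:     {len(cohort.measurements)}")

paths = cohort.to_files("out/cohort")
print("\nwrote input files:")
for name, path in paths.items():
    print(f"  {name:<14}{path}")
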