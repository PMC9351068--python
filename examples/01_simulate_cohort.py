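"""Simulate a small multifocal tumor cohort with known ground truth.

Each patient gets several independent primary tumors (disjoint somatic
variant sets), a few metastases that inherit ~90% of one parent primary's
variants, a matched normal, and whole-chromosome copy-number events with a
recorded affected haplotype.
"""

from clonemap import SimConfig, simulate_cohort

config = SimConfig(seed=42, n_patients=3, het_snps_per_chrom=500)
cohort = simulate_cohort(config)

for patient in cohort.patients:
    print(f"\npatient {patient.patient_id}:")
    print(f"  primaries:  {patient.primary_ids}")
    print(f"  metastases: {patient.metastasis_ids}")
    for sid in patient.tumor_ids:
        truth = patient.truth.tumors[sid]
        events = ", ".join(
            f"{e.chrom}:{e.scope}:{e.direction}(hap {e.affected_hap})"
            for e in truth.events
        ) or "none"
        parent = f" parent={truth.parent}" if truth.parent else ""
        print(
            f"    {sid}: {len(truth.variant_keys)} variants, "
            f"purity {truth.purity:.2f}, CNAs: {events}{parent}"
        )

# The variant counts (~12 per tumor on the 30-Mb toy genome) reflect the
# 0.41 mutations/Mb burden; each CNA records which parental haplotype it
# affected, which is the recovery target for chromosome mapping.
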