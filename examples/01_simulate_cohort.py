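"""Simulate a case-control cohort with a planted haplotype effect.

Builds a 5-SNP haplotype pool, plants a per-copy odds ratio of 1.5 on one
common haplotype, draws 500 cases and 500 controls under Hardy-Weinberg
pair sampling, and prints the ground truth alongside the realized data.
"""

import numpy as np

import hapscan as hs

pool = hs.generate_haplotype_pool(n_snps=5, n_haplotypes=8, dirichlet_conc=1.0, seed=7)
risk = pool.haplotypes[int(np.argmax(pool.pool_freqs))]
model = hs.DiseaseModel(risk_haplotype=risk, risk_start=0, beta_h=np.log(1.5))
cohort = hs.generate_cohort(pool, n_cases=500, n_controls=500, model=model, seed=1)

print("pool haplotypes and frequencies:")
for h, f in zip(pool.haplotypes, pool.pool_freqs):
    marker = "  <- risk (per-copy OR 1.5)" if h == risk else ""
    print(f"  {h}  {f:.3f}{marker}")

gm = cohort.genotypes
dosage_true = (cohort.true_pairs == pool.haplotypes.index(risk)).sum(axis=1)
print(f"\ncohort: {gm.n_samples} samples x {gm.n_snps} SNPs, "
      f"{int(cohort.labels.sum())} cases / {int((1 - cohort.labels).sum())} controls")
print(f"risk-haplotype carrier frequency: cases "
      f"{dosage_true[cohort.labels == 1].mean() / 2:.3f}, controls "
      f"{dosage_true[cohort.labels == 0].mean() / 2:.3f}")
print("(cases carry the risk haplotype more often, as planted)")
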