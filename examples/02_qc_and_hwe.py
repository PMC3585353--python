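"""Sample and SNP quality control, plus the Hardy-Weinberg exact screen.

Generates the QC fixture (5,984 samples with disjoint exclusion flags
matching printed removal counts), applies sample QC then SNP QC, and shows
the exact HWE test on a few genotype tables.  HWE deviation is flagged, not
filtered: in an admixed population out-of-HWE SNPs are expected and a strong
deviation is a genotyping-quality signal to review, not an automatic drop.
"""

import hapscan as hs

cohort = hs.generate_qc_fixture(seed=0)
gm = cohort.genotypes
print(f"input: {gm.n_samples} samples "
      f"({int(cohort.labels.sum())} cases / {int((1 - cohort.labels).sum())} controls)")

clean, report = hs.sample_qc(gm, cohort.exclusion_flags, min_call_rate=0.95)
print("sample removals by reason:", report.samples_removed)
print(f"survivors: {clean.n_samples} "
      f"({int(clean.labels.sum())} cases / {int((1 - clean.labels).sum())} controls)")

clean2, snp_report = hs.snp_qc(clean, min_call_rate=0.95, min_maf=0.01)
print("SNP removals by reason:", snp_report.snps_removed,
      "| HWE-flagged:", len(snp_report.hwe_flagged))

print("\nexact HWE test examples (hom1, het, hom2) -> p:")
for table in [(25, 50, 25), (40, 20, 40), (30, 0, 30)]:
    print(f"  {table} -> {hs.hwe_exact_test(*table):.3g}")
print("(50% heterozygotes is the HWE expectation at allele frequency 1/2;")
print(" a total heterozygote deficit is essentially impossible under HWE)")
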