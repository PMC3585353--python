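"""Genotype file I/O, sample/SNP quality control, and the Hardy-Weinberg exact test.

The central container is :class:`GenotypeMatrix`: a samples x SNPs matrix of
allele-count calls (copies of ``allele1``, with -1 for missing) together with a
SNP map, per-sample phenotype labels and an optional covariate table.

Supported on-disk formats are PLINK bed/bim/fam (variant-major bed) and plain
VCF 4.2 with unphased GT calls.  Only biallelic autosomal SNPs are retained on
read; other records are skipped and counted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import gammaln

log = logging.getLogger(__name__)

MISSING = -1

# exclusion reasons in the order removals are itemized
SAMPLE_QC_REASONS = ("low_dna", "related", "call_rate", "ancestry", "sex")
_FLAG_TO_REASON = {
    "low_dna": "low_dna",
    "related": "related",
    "low_ancestry": "ancestry",
    "ambiguous_sex": "sex",
}


@dataclass
class GenotypeMatrix:
    """Samples x SNPs allele-count matrix with SNP map and sample metadata.

    Attributes
    ----------
    calls:
        int8 array of shape (n_samples, n_snps); entries in {0, 1, 2} count
        copies of ``allele1``; -1 marks a missing call.
    snps:
        DataFrame with columns ``snp_id, chrom, pos, allele1, allele2``,
        sorted by (chrom, pos); positions are 1-based.
    samples:
        DataFrame with columns ``sample_id, phenotype`` (case=1, control=0,
        NaN when unknown).
    covariates:
        optional DataFrame aligned row-by-row with ``samples``.
    """

    calls: np.ndarray
    snps: pd.DataFrame
    samples: pd.DataFrame
    covariates: pd.DataFrame | None = None
    skipped_records: int = 0

    @property
    def n_samples(self) -> int:
        return self.calls.shape[0]

    @property
    def n_snps(self) -> int:
        return self.calls.shape[1]

    @property
    def labels(self) -> np.ndarray:
        """Phenotype as an int array (raises if any label is missing)."""
        ph = self.samples["phenotype"].to_numpy()
        if np.any(pd.isna(ph)):
            raise ValueError("phenotype labels contain missing values")
        return ph.astype(int)

    def validate(self) -> None:
        if self.calls.shape != (len(self.samples), len(self.snps)):
            raise ValueError("calls shape does not match samples/snps tables")
        bad = ~np.isin(self.calls, [0, 1, 2, MISSING])
        if bad.any():
            raise ValueError("calls outside {0,1,2,missing}")
        for _, sub in self.snps.groupby("chrom", sort=False):
            pos = sub["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError("bp positions not strictly increasing within a chromosome")
        ph = self.samples["phenotype"]
        ok = ph.isna() | ph.isin([0, 1])
        if not ok.all():
            raise ValueError("phenotype must be 0/1 or missing")

    def subset_samples(self, keep: np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        cov = self.covariates.iloc[keep].reset_index(drop=True) if self.covariates is not None else None
        return replace(
            self,
            calls=self.calls[keep],
            samples=self.samples.iloc[keep].reset_index(drop=True),
            covariates=cov,
        )

    def subset_snps(self, keep: np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return replace(
            self,
            calls=self.calls[:, keep],
            snps=self.snps.iloc[keep].reset_index(drop=True),
        )

    def sample_call_rates(self) -> np.ndarray:
        return (self.calls != MISSING).mean(axis=1)

    def snp_call_rates(self) -> np.ndarray:
        return (self.calls != MISSING).mean(axis=0)

    def snp_column(self, snp_id: str) -> np.ndarray:
        idx = self.snps.index[self.snps["snp_id"] == snp_id]
        if len(idx) == 0:
            raise KeyError(f"SNP {snp_id!r} not in map")
        return self.calls[:, idx[0]].astype(float)


@dataclass
class QcReport:
    """Removal counts per reason plus survivor totals."""

    samples_removed: dict = field(default_factory=dict)
    snps_removed: dict = field(default_factory=dict)
    n_samples_in: int = 0
    n_samples_out: int = 0
    n_snps_in: int = 0
    n_snps_out: int = 0
    hwe_flagged: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = [("sample", k, v) for k, v in self.samples_removed.items()]
        rows += [("snp", k, v) for k, v in self.snps_removed.items()]
        rows += [
            ("sample", "survivors", self.n_samples_out),
            ("snp", "survivors", self.n_snps_out),
        ]
        return pd.DataFrame(rows, columns=["level", "reason", "count"])


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _is_autosome(chrom) -> bool:
    c = str(chrom)
    if c.lower().startswith("chr"):
        c = c[3:]
    return c.isdigit() and 1 <= int(c) <= 22


def _norm_chrom(chrom) -> str:
    c = str(chrom)
    if c.lower().startswith("chr"):
        c = c[3:]
    return c


def read_genotypes(path, format: str) -> GenotypeMatrix:
    """Read a PLINK fileset (``format='plink'``, path = prefix or .bed file)
    or a VCF (``format='vcf'``).

    Calls are coded as copies of allele1 (PLINK A1; VCF ALT).  Multiallelic or
    non-SNP records and non-autosomal records are skipped with a logged count;
    SNPs are returned sorted by (chromosome, position).
    """
    if format == "plink":
        return _read_plink(path)
    if format == "vcf":
        return _read_vcf(path)
    raise ValueError(f"unknown format {format!r}")


# PLINK .bed 2-bit codes (variant-major): 00 hom A1, 01 missing, 10 het, 11 hom A2
_BED_DECODE = np.array([2, MISSING, 1, 0], dtype=np.int8)
_BED_ENCODE = {2: 0b00, MISSING: 0b01, 1: 0b10, 0: 0b11}


def _read_plink(path) -> GenotypeMatrix:
    prefix = Path(path)
    if prefix.suffix == ".bed":
        prefix = prefix.with_suffix("")
    bim = pd.read_csv(
        prefix.with_suffix(".bim"), sep=r"\s+", header=None,
        names=["chrom", "snp_id", "cm", "pos", "allele1", "allele2"],
        dtype={"chrom": str, "snp_id": str, "allele1": str, "allele2": str},
    )
    fam = pd.read_csv(
        prefix.with_suffix(".fam"), sep=r"\s+", header=None,
        names=["fid", "iid", "father", "mother", "sex", "pheno"],
        dtype={"fid": str, "iid": str},
    )
    raw = np.fromfile(prefix.with_suffix(".bed"), dtype=np.uint8)
    if raw.size < 3 or raw[0] != 0x6C or raw[1] != 0x1B:
        raise ValueError(f"{prefix}.bed is not a PLINK bed file")
    if raw[2] != 0x01:
        raise ValueError("only variant-major bed files are supported")
    n_samples, n_snps = len(fam), len(bim)
    nb = (n_samples + 3) // 4
    body = raw[3:]
    if body.size != nb * n_snps:
        raise ValueError("bed file size inconsistent with bim/fam")
    codes = body.reshape(n_snps, nb)
    shifts = np.arange(4, dtype=np.uint8) * 2
    expanded = (codes[:, :, None] >> shifts) & 3        # (snps, nb, 4)
    expanded = expanded.reshape(n_snps, nb * 4)[:, :n_samples]
    calls = _BED_DECODE[expanded].T.copy()               # (samples, snps)

    keep = bim["chrom"].map(_is_autosome).to_numpy()
    is_snp = (bim["allele1"].str.len() == 1) & (bim["allele2"].str.len() == 1)
    keep &= is_snp.to_numpy()
    skipped = int((~keep).sum())
    if skipped:
        log.info("skipped %d non-autosomal/non-SNP PLINK records", skipped)
    bim = bim.loc[keep].reset_index(drop=True)
    calls = calls[:, keep]
    bim["chrom"] = bim["chrom"].map(_norm_chrom)

    pheno = fam["pheno"].astype(float)
    phenotype = pd.Series(np.where(pheno == 2, 1.0, np.where(pheno == 1, 0.0, np.nan)))
    samples = pd.DataFrame({"sample_id": fam["iid"], "phenotype": phenotype})
    gm = GenotypeMatrix(
        calls=calls.astype(np.int8),
        snps=bim[["snp_id", "chrom", "pos", "allele1", "allele2"]].copy(),
        samples=samples,
        skipped_records=skipped,
    )
    return _sort_snps(gm)


def _read_vcf(path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    rows, cols, skipped = [], [], 0
    for v in vcf:
        if len(v.ALT) != 1 or not v.is_snp or not _is_autosome(v.CHROM):
            skipped += 1
            continue
        g = np.asarray(v.genotypes, dtype=object)
        a = np.array([[int(x[0]), int(x[1])] for x in g], dtype=np.int8)
        call = np.where((a < 0).any(axis=1), MISSING, (a == 1).sum(axis=1)).astype(np.int8)
        cols.append(call)
        rows.append((v.ID or f"{v.CHROM}:{v.POS}", _norm_chrom(v.CHROM), v.POS, v.ALT[0], v.REF))
    if skipped:
        log.info("skipped %d multiallelic/non-SNP/non-autosomal VCF records", skipped)
    snps = pd.DataFrame(rows, columns=["snp_id", "chrom", "pos", "allele1", "allele2"])
    calls = (
        np.stack(cols, axis=1) if cols else np.empty((len(sample_ids), 0), dtype=np.int8)
    )
    samples = pd.DataFrame({"sample_id": sample_ids, "phenotype": np.nan})
    gm = GenotypeMatrix(calls=calls, snps=snps, samples=samples, skipped_records=skipped)
    return _sort_snps(gm)


def _sort_snps(gm: GenotypeMatrix) -> GenotypeMatrix:
    key = gm.snps.assign(_c=gm.snps["chrom"].astype(int))
    order = key.sort_values(["_c", "pos"], kind="mergesort").index.to_numpy()
    return gm.subset_snps(order)


def write_plink(gm: GenotypeMatrix, prefix) -> None:
    """Write bed/bim/fam (variant-major bed)."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    bim = gm.snps
    with open(prefix.with_suffix(".bim"), "w") as fh:
        for r in bim.itertuples(index=False):
            fh.write(f"{r.chrom}\t{r.snp_id}\t0\t{r.pos}\t{r.allele1}\t{r.allele2}\n")
    with open(prefix.with_suffix(".fam"), "w") as fh:
        for r in gm.samples.itertuples(index=False):
            ph = -9 if pd.isna(r.phenotype) else int(r.phenotype) + 1
            fh.write(f"{r.sample_id}\t{r.sample_id}\t0\t0\t0\t{ph}\n")
    n = gm.n_samples
    nb = (n + 3) // 4
    # lookup indexed by call+1 (missing=-1 -> 0)
    lut = np.empty(4, dtype=np.uint8)
    for call, code in _BED_ENCODE.items():
        lut[call + 1] = code
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(bytes([0x6C, 0x1B, 0x01]))
        for j in range(gm.n_snps):
            codes = lut[gm.calls[:, j].astype(int) + 1]
            padded = np.zeros(nb * 4, dtype=np.uint8)
            padded[:n] = codes
            padded = padded.reshape(nb, 4)
            packed = (
                padded[:, 0] | (padded[:, 1] << 2) | (padded[:, 2] << 4) | (padded[:, 3] << 6)
            )
            fh.write(packed.astype(np.uint8).tobytes())


_GT = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(gm: GenotypeMatrix, path) -> None:
    """Write a plain VCF 4.2 with unphased GT; REF=allele2, ALT=allele1 so
    allele counts round-trip (calls count copies of allele1 = ALT)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=hapscan\n")
        for chrom in gm.snps["chrom"].unique():
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        header = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT"]
        header += list(gm.samples["sample_id"].astype(str))
        fh.write("\t".join(header) + "\n")
        for j, r in enumerate(gm.snps.itertuples(index=False)):
            gts = "\t".join(_GT[int(c)] for c in gm.calls[:, j])
            fh.write(f"{r.chrom}\t{r.pos}\t{r.snp_id}\t{r.allele2}\t{r.allele1}\t.\tPASS\t.\tGT\t{gts}\n")


def write_covariates(covariates: pd.DataFrame, sample_ids, path) -> None:
    """Tab-separated covariate table with a sample_id first column."""
    out = covariates.copy()
    out.insert(0, "sample_id", list(sample_ids))
    out.to_csv(path, sep="\t", index=False)


def read_covariates(path) -> pd.DataFrame:
    tab = pd.read_csv(path, sep="\t")
    return tab


# ---------------------------------------------------------------------------
# quality control
# ---------------------------------------------------------------------------

def sample_qc(
    gm: GenotypeMatrix,
    exclusion_flags: dict | pd.Series | None = None,
    min_call_rate: float = 0.95,
) -> tuple[GenotypeMatrix, QcReport]:
    """Remove flagged samples and samples with call rate below threshold.

    ``exclusion_flags`` maps sample_id -> reason, with reasons drawn from
    {low_dna, related, low_ancestry, ambiguous_sex}.  Removals are itemized in
    the order low_dna, related, call_rate, ancestry, sex; each sample counts
    under the first reason that applies.  Call rate at exactly the threshold is
    kept (strict ``<`` removal).
    """
    flags = dict(exclusion_flags) if exclusion_flags is not None else {}
    bad = set(flags.values()) - set(_FLAG_TO_REASON)
    if bad:
        raise ValueError(f"unknown exclusion reasons: {sorted(bad)}")
    ids = gm.samples["sample_id"].to_numpy()
    call_rates = gm.sample_call_rates()
    reason_of: dict[int, str] = {}
    for stage in ("low_dna", "related"):
        for i, sid in enumerate(ids):
            if i not in reason_of and flags.get(sid) == stage:
                reason_of[i] = _FLAG_TO_REASON[stage]
    for i in range(len(ids)):
        if i not in reason_of and call_rates[i] < min_call_rate:
            reason_of[i] = "call_rate"
    for stage in ("low_ancestry", "ambiguous_sex"):
        for i, sid in enumerate(ids):
            if i not in reason_of and flags.get(sid) == stage:
                reason_of[i] = _FLAG_TO_REASON[stage]

    counts = {r: 0 for r in SAMPLE_QC_REASONS}
    for r in reason_of.values():
        counts[r] += 1
    keep = np.array([i not in reason_of for i in range(len(ids))])
    out = gm.subset_samples(keep)
    report = QcReport(
        samples_removed=counts,
        n_samples_in=gm.n_samples,
        n_samples_out=out.n_samples,
        n_snps_in=gm.n_snps,
        n_snps_out=gm.n_snps,
    )
    log.info("sample QC: %s -> %d survivors", counts, out.n_samples)
    return out, report


def snp_qc(
    gm: GenotypeMatrix,
    min_call_rate: float = 0.95,
    min_maf: float = 0.01,
    hwe_flag_threshold: float = 1e-6,
) -> tuple[GenotypeMatrix, QcReport]:
    """Remove SNPs with call rate < threshold, then SNPs with MAF < threshold.

    MAF is computed on non-missing calls of the current (post-sample-QC)
    samples, cases and controls pooled.  Hardy-Weinberg deviation is *flagged*
    (exact-test p below ``hwe_flag_threshold``), never used for removal.
    """
    call_rates = gm.snp_call_rates()
    low_cr = call_rates < min_call_rate

    obs = gm.calls != MISSING
    n_alleles = 2 * obs.sum(axis=0)
    a1 = np.where(gm.calls == MISSING, 0, gm.calls).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        f1 = np.where(n_alleles > 0, a1 / np.maximum(n_alleles, 1), 0.0)
    maf = np.minimum(f1, 1.0 - f1)
    low_maf = (~low_cr) & (maf < min_maf)

    keep = ~(low_cr | low_maf)
    out = gm.subset_snps(keep)

    flagged = []
    for j in np.flatnonzero(keep):
        c = gm.calls[:, j]
        n2 = int((c == 2).sum()); n1 = int((c == 1).sum()); n0 = int((c == 0).sum())
        if hwe_exact_test(n2, n1, n0) < hwe_flag_threshold:
            flagged.append(gm.snps["snp_id"].iloc[j])
    report = QcReport(
        snps_removed={"call_rate": int(low_cr.sum()), "maf": int(low_maf.sum())},
        n_samples_in=gm.n_samples,
        n_samples_out=gm.n_samples,
        n_snps_in=gm.n_snps,
        n_snps_out=out.n_snps,
        hwe_flagged=flagged,
    )
    log.info("SNP QC: %s -> %d survivors (%d HWE-flagged)",
             report.snps_removed, out.n_snps, len(flagged))
    return out, report


def _hwe_het_probs(n: int, n_rare: int) -> tuple[np.ndarray, np.ndarray]:
    """Conditional probabilities of every heterozygote count compatible with
    ``n`` diploid samples carrying ``n_rare`` copies of the rarer allele."""
    hets = np.arange(n_rare % 2, n_rare + 1, 2)
    hom_r = (n_rare - hets) // 2
    hom_c = n - hets - hom_r
    ok = hom_c >= 0
    hets, hom_r, hom_c = hets[ok], hom_r[ok], hom_c[ok]
    logp = (
        hets * np.log(2.0)
        - gammaln(hom_r + 1) - gammaln(hets + 1) - gammaln(hom_c + 1)
    )
    logp -= logp.max()
    p = np.exp(logp)
    p /= p.sum()
    return hets, p


def hwe_exact_test(n_hom1: int, n_het: int, n_hom2: int) -> float:
    """Exact two-sided Hardy-Weinberg test.

    Conditions on the observed allele counts and sums, over all heterozygote
    counts compatible with them, the conditional probabilities that do not
    exceed that of the observed table.  Monomorphic input returns 1.
    """
    if min(n_hom1, n_het, n_hom2) < 0 or (n_hom1 + n_het + n_hom2) < 1:
        raise ValueError("counts must be nonnegative with a positive total")
    n = n_hom1 + n_het + n_hom2
    n_a = 2 * n_hom1 + n_het
    n_rare = min(n_a, 2 * n - n_a)
    if n_rare == 0:
        return 1.0
    hets, probs = _hwe_het_probs(n, n_rare)
    p_obs = probs[hets == n_het]
    if p_obs.size == 0:
        raise ValueError("heterozygote count incompatible with allele counts")
    return float(min(1.0, probs[probs <= p_obs[0] * (1 + 1e-12)].sum()))
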