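"""Synthetic admixed case-control cohorts with known haplotype structure.

The generator is a haplotype-pool model: each "LD block" is a small pool of
distinct haplotypes with Dirichlet frequencies, each individual draws two
pool haplotypes independently per block (Hardy-Weinberg), and the unphased
genotype is the allele-count sum of the pair.  Disease status follows a
logistic model with an additive per-copy effect of a designated risk
haplotype plus covariate effects; rejection sampling continues until the
requested case and control counts are met exactly, mirroring a fixed
case-control design.  An admixture variant draws each chromosome copy as a
Markov mosaic over two ancestral pools and records both a per-sample global
ancestry proportion and known-truth local-ancestry posteriors.

Everything is deterministic given the seed, and the simulated truth (the
haplotype pair per sample, the planted effect, the ancestry tracks) is kept
alongside the genotypes so downstream inference can be scored exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .em import string_to_bits
from .io_qc import MISSING, GenotypeMatrix

log = logging.getLogger(__name__)

_BASES = np.array(list("ACGT"))

#: study labels and sizes of the nine source studies used as default
#: categorical weights for the study covariate
STUDY_SIZES = {
    "MEC": 1737, "CARE": 604, "WCHS": 512, "SFBCS": 403, "NC-BCFR": 493,
    "CBCS": 1264, "PLCO": 197, "NBHS": 496, "WFBC": 278,
}


class GenerationError(RuntimeError):
    """Exact case/control quotas could not be reached."""


@dataclass
class HaplotypePool:
    """A pool of distinct haplotypes with population frequencies."""

    n_snps: int
    alleles: list[tuple[str, str]]
    haplotypes: list[str]
    pool_freqs: np.ndarray

    def __post_init__(self):
        self.pool_freqs = np.asarray(self.pool_freqs, dtype=float)
        if abs(self.pool_freqs.sum() - 1.0) > 1e-12:
            raise ValueError("pool frequencies must sum to 1")
        if len(set(self.haplotypes)) != len(self.haplotypes):
            raise ValueError("haplotypes must be distinct")
        if any(len(h) != self.n_snps for h in self.haplotypes):
            raise ValueError("haplotype length must equal n_snps")

    @property
    def k(self) -> int:
        return len(self.haplotypes)

    @property
    def bits(self) -> np.ndarray:
        """(k, n_snps) 0/1 array; 1 marks a copy of allele1."""
        return np.array([string_to_bits(h, self.alleles) for h in self.haplotypes],
                        dtype=np.int8)

    def marginal_allele1_freqs(self) -> np.ndarray:
        return self.pool_freqs @ self.bits


@dataclass
class DiseaseModel:
    """Logistic disease model with an additive per-copy haplotype effect.

    ``risk_haplotype`` is an allele string planted at SNP indices
    [risk_start, risk_start + len); ``beta_h`` is its log-odds per copy.
    ``covariate_effects`` maps numeric covariate columns to log-odds per unit.
    """

    intercept: float = 0.0
    risk_haplotype: str | None = None
    risk_start: int = 0
    beta_h: float = 0.0
    covariate_effects: dict = field(default_factory=dict)


@dataclass
class LocalAncestryTrack:
    """Per-sample, per-SNP posterior triples of carrying 0/1/2 European alleles."""

    sample_ids: list
    snp_ids: list
    posteriors: np.ndarray            # (n_samples, n_snps, 3)

    def __post_init__(self):
        p = np.asarray(self.posteriors, dtype=float)
        if p.ndim != 3 or p.shape[2] != 3:
            raise ValueError("posteriors must have shape (n_samples, n_snps, 3)")
        if np.any(p < -1e-12) or np.any(p > 1 + 1e-12):
            raise ValueError("posterior entries must lie in [0, 1]")
        if np.max(np.abs(p.sum(axis=2) - 1.0)) > 1e-9:
            raise ValueError("posterior triples must sum to 1")
        self.posteriors = p

    def expected_european_dosage(self, snp_ids) -> np.ndarray:
        """(n_samples, len(snp_ids)) expected European-allele counts P1 + 2 P2."""
        index = {s: j for j, s in enumerate(self.snp_ids)}
        try:
            cols = [index[s] for s in snp_ids]
        except KeyError as e:
            raise KeyError(f"SNP {e.args[0]!r} not in local-ancestry track") from None
        p = self.posteriors[:, cols, :]
        return p[:, :, 1] + 2.0 * p[:, :, 2]


@dataclass
class SyntheticCohort:
    """Generated genotypes plus the ground truth that produced them."""

    genotypes: GenotypeMatrix
    true_pairs: np.ndarray | None     # (n, 2) single pool; (n, blocks, 2) else
    labels: np.ndarray
    covariates: pd.DataFrame
    local_ancestry: LocalAncestryTrack | None
    seed: int
    model: DiseaseModel
    pools: list[HaplotypePool] | None = None
    exclusion_flags: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# pool and covariate generation
# ---------------------------------------------------------------------------

def generate_haplotype_pool(n_snps: int, n_haplotypes: int,
                            dirichlet_conc: float = 1.0, seed: int = 0) -> HaplotypePool:
    """Random pool of distinct haplotypes with Dirichlet frequencies."""
    if n_snps < 1:
        raise ValueError("n_snps must be >= 1")
    if not (2 <= n_haplotypes <= 2 ** n_snps):
        raise ValueError(f"n_haplotypes must be in [2, 2^{n_snps}]")
    rng = np.random.default_rng(seed)
    alleles = []
    for _ in range(n_snps):
        pair = rng.choice(4, size=2, replace=False)
        alleles.append((str(_BASES[pair[0]]), str(_BASES[pair[1]])))
    if n_snps <= 30:
        codes = rng.choice(2 ** n_snps, size=n_haplotypes, replace=False)
        bit_rows = [(int(c) >> np.arange(n_snps)) & 1 for c in codes]
    else:
        seen, bit_rows = set(), []
        while len(bit_rows) < n_haplotypes:
            row = rng.integers(0, 2, size=n_snps)
            key = row.tobytes()
            if key not in seen:
                seen.add(key)
                bit_rows.append(row)
    haps = ["".join(alleles[j][0] if b else alleles[j][1]
                    for j, b in enumerate(row)) for row in bit_rows]
    freqs = rng.dirichlet(np.full(n_haplotypes, float(dirichlet_conc)))
    return HaplotypePool(n_snps, alleles, haps, freqs)


def default_covariates(n: int, rng: np.random.Generator) -> pd.DataFrame:
    """Age ~ U(35, 75), a nine-level study factor at the source-study
    proportions, and ten standard-normal eigenvector stand-ins."""
    studies = list(STUDY_SIZES)
    w = np.array([STUDY_SIZES[s] for s in studies], dtype=float)
    w /= w.sum()
    cov = {"age": rng.uniform(35, 75, size=n),
           "study": rng.choice(studies, size=n, p=w)}
    for j in range(1, 11):
        cov[f"pc{j}"] = rng.standard_normal(n)
    return pd.DataFrame(cov)


def _covariate_eta(model: DiseaseModel, cov: pd.DataFrame) -> np.ndarray:
    eta = np.zeros(len(cov))
    for name, coef in model.covariate_effects.items():
        if name not in cov.columns:
            raise ValueError(f"covariate effect on unknown column {name!r}")
        col = cov[name]
        if col.dtype == object:
            raise ValueError(f"covariate effect on non-numeric column {name!r}")
        eta += coef * col.to_numpy(dtype=float)
    return eta


def _risk_block(model: DiseaseModel, block_sizes: list[int]) -> tuple[int, int]:
    """Locate the block containing the planted haplotype; the run must not
    cross a block boundary."""
    L = len(model.risk_haplotype)
    start = model.risk_start
    off = 0
    for b, size in enumerate(block_sizes):
        if off <= start and start + L <= off + size:
            return b, start - off
        off += size
    raise ValueError("risk haplotype must lie inside a single block")


def _snp_table(n_snps: int, alleles, chrom: str, positions) -> pd.DataFrame:
    if positions is None:
        positions = 1 + 2000 * np.arange(n_snps)
    positions = np.asarray(positions)
    if np.any(np.diff(positions) <= 0):
        raise ValueError("positions must be strictly increasing")
    return pd.DataFrame({
        "snp_id": [f"snp{j + 1:05d}" for j in range(n_snps)],
        "chrom": str(chrom),
        "pos": positions.astype(int),
        "allele1": [a[0] for a in alleles],
        "allele2": [a[1] for a in alleles],
    })


def _finish_cohort(rng, store, n_cases, n_controls, assemble):
    """Take exact quotas from accumulated case/control draws, shuffle, build."""
    case_idx = store["case"][:n_cases]
    ctrl_idx = store["control"][:n_controls]
    idx = np.concatenate([case_idx, ctrl_idx])
    y = np.concatenate([np.ones(n_cases, dtype=int), np.zeros(n_controls, dtype=int)])
    order = rng.permutation(len(idx))
    return assemble(idx[order], y[order])


# ---------------------------------------------------------------------------
# cohort generators
# ---------------------------------------------------------------------------

def generate_cohort(pool, n_cases: int, n_controls: int, model: DiseaseModel,
                    seed: int = 0, chrom: str = "1", positions=None,
                    max_batches: int = 500) -> SyntheticCohort:
    """Case-control cohort drawn from one haplotype pool or a list of
    independent block pools (block LD, no LD between blocks).

    Haplotype pairs are drawn independently per chromosome copy with the pool
    frequencies (HWE); disease status follows the logistic model; rejection
    sampling continues until the exact case/control counts are reached.
    """
    pools = [pool] if isinstance(pool, HaplotypePool) else list(pool)
    block_sizes = [p.n_snps for p in pools]
    n_snps = sum(block_sizes)
    alleles = [a for p in pools for a in p.alleles]
    bits = [p.bits for p in pools]

    if model.beta_h != 0.0:
        if model.risk_haplotype is None:
            raise ValueError("beta_h != 0 requires a risk haplotype")
        rb_block, rb_off = _risk_block(model, block_sizes)
        rbits = np.array(string_to_bits(
            model.risk_haplotype,
            pools[rb_block].alleles[rb_off:rb_off + len(model.risk_haplotype)],
        ), dtype=np.int8)
        match = (bits[rb_block][:, rb_off:rb_off + len(rbits)] == rbits).all(axis=1)
        if not match.any():
            raise ValueError("risk haplotype absent from its pool")

    N = n_cases + n_controls
    if N < 2:
        raise ValueError("need at least two samples")
    rng = np.random.default_rng(seed)
    batch = max(1024, 2 * N)
    got_cases = got_controls = 0
    pair_chunks, cov_chunks, y_chunks = [], [], []
    for _ in range(max_batches):
        pairs = np.stack(
            [rng.choice(p.k, size=(batch, 2), p=p.pool_freqs) for p in pools],
            axis=1,
        )  # (batch, n_blocks, 2)
        cov = default_covariates(batch, rng)
        if model.beta_h != 0.0:
            m = match[pairs[:, rb_block, :]]
            dosage = m.sum(axis=1).astype(float)
        else:
            dosage = np.zeros(batch)
        eta = model.intercept + model.beta_h * dosage + _covariate_eta(model, cov)
        prob = 1.0 / (1.0 + np.exp(-eta))
        y = (rng.random(batch) < prob).astype(int)
        pair_chunks.append(pairs)
        cov_chunks.append(cov)
        y_chunks.append(y)
        got_cases += int(y.sum())
        got_controls += int((1 - y).sum())
        if got_cases >= n_cases and got_controls >= n_controls:
            break
    else:
        raise GenerationError(
            f"failed to reach {n_cases} cases / {n_controls} controls "
            f"after {max_batches} batches")

    pairs = np.concatenate(pair_chunks)
    cov = pd.concat(cov_chunks, ignore_index=True)
    y_all = np.concatenate(y_chunks)
    store = {"case": np.flatnonzero(y_all == 1), "control": np.flatnonzero(y_all == 0)}

    def assemble(idx, y):
        P = pairs[idx]                                  # (N, n_blocks, 2)
        calls = np.concatenate(
            [bits[b][P[:, b, 0]] + bits[b][P[:, b, 1]] for b in range(len(pools))],
            axis=1,
        ).astype(np.int8)
        covariates = cov.iloc[idx].reset_index(drop=True)
        samples = pd.DataFrame({
            "sample_id": [f"S{i + 1:06d}" for i in range(len(idx))],
            "phenotype": y.astype(float),
        })
        gm = GenotypeMatrix(calls=calls, snps=_snp_table(n_snps, alleles, chrom, positions),
                            samples=samples, covariates=covariates)
        tp = P[:, 0, :] if len(pools) == 1 else P
        return SyntheticCohort(
            genotypes=gm, true_pairs=tp, labels=y, covariates=covariates,
            local_ancestry=None, seed=seed, model=model, pools=pools,
        )

    return _finish_cohort(rng, store, n_cases, n_controls, assemble)


def generate_admixed_cohort(pool_a: HaplotypePool, pool_b: HaplotypePool,
                            switch_rate: float, admixture_prop: float,
                            positions, model: DiseaseModel,
                            n_cases: int, n_controls: int, seed: int = 0,
                            chrom: str = "1", max_batches: int = 500) -> SyntheticCohort:
    """Two-way admixed cohort with known-truth local-ancestry posteriors.

    Each chromosome copy is a Markov mosaic over ancestries {A, B} with
    transition probability 1 - exp(-switch_rate * Δbp / 1e6) between adjacent
    SNPs and stationary P(A) = ``admixture_prop``; alleles are drawn from the
    active pool's marginal allele frequencies.  Pool B plays the European-like
    ancestry: the recorded posteriors are the indicator triples of carrying
    0/1/2 B-ancestry alleles, and the per-sample ``ancestry_prop`` covariate
    is the B-ancestry fraction.
    """
    if pool_a.n_snps != pool_b.n_snps or pool_a.alleles != pool_b.alleles:
        raise ValueError("pools must share n_snps and allele codes")
    S = pool_a.n_snps
    positions = np.asarray(positions, dtype=float)
    if positions.shape != (S,) or np.any(np.diff(positions) <= 0):
        raise ValueError("positions must be strictly increasing, one per SNP")
    pA = pool_a.marginal_allele1_freqs()
    pB = pool_b.marginal_allele1_freqs()
    switch = 1.0 - np.exp(-switch_rate * np.diff(positions) / 1e6)

    risk_bits = None
    if model.beta_h != 0.0:
        if model.risk_haplotype is None:
            raise ValueError("beta_h != 0 requires a risk haplotype")
        L = len(model.risk_haplotype)
        risk_bits = np.array(string_to_bits(
            model.risk_haplotype,
            pool_a.alleles[model.risk_start:model.risk_start + L]), dtype=np.int8)

    N = n_cases + n_controls
    rng = np.random.default_rng(seed)
    batch = max(1024, 2 * N)
    chunks = {"anc": [], "hap": [], "cov": [], "y": []}
    got_cases = got_controls = 0
    for _ in range(max_batches):
        anc = np.empty((batch, 2, S), dtype=bool)       # True = ancestry A
        anc[:, :, 0] = rng.random((batch, 2)) < admixture_prop
        for j in range(1, S):
            redraw = rng.random((batch, 2)) < switch[j - 1]
            fresh = rng.random((batch, 2)) < admixture_prop
            anc[:, :, j] = np.where(redraw, fresh, anc[:, :, j - 1])
        p_active = np.where(anc, pA[None, None, :], pB[None, None, :])
        hap = (rng.random((batch, 2, S)) < p_active).astype(np.int8)
        cov = default_covariates(batch, rng)
        cov["ancestry_prop"] = 1.0 - anc.mean(axis=(1, 2))   # B-ancestry fraction
        if risk_bits is not None:
            sl = slice(model.risk_start, model.risk_start + len(risk_bits))
            m = (hap[:, :, sl] == risk_bits).all(axis=2)
            dosage = m.sum(axis=1).astype(float)
        else:
            dosage = np.zeros(batch)
        eta = model.intercept + model.beta_h * dosage + _covariate_eta(model, cov)
        y = (rng.random(batch) < 1.0 / (1.0 + np.exp(-eta))).astype(int)
        chunks["anc"].append(anc)
        chunks["hap"].append(hap)
        chunks["cov"].append(cov)
        chunks["y"].append(y)
        got_cases += int(y.sum())
        got_controls += int((1 - y).sum())
        if got_cases >= n_cases and got_controls >= n_controls:
            break
    else:
        raise GenerationError("failed to reach the requested case/control counts")

    anc = np.concatenate(chunks["anc"])
    hap = np.concatenate(chunks["hap"])
    cov = pd.concat(chunks["cov"], ignore_index=True)
    y_all = np.concatenate(chunks["y"])
    store = {"case": np.flatnonzero(y_all == 1), "control": np.flatnonzero(y_all == 0)}

    snps = _snp_table(S, pool_a.alleles, chrom, positions.astype(int))

    def assemble(idx, y):
        calls = hap[idx].sum(axis=1).astype(np.int8)
        covariates = cov.iloc[idx].reset_index(drop=True)
        samples = pd.DataFrame({
            "sample_id": [f"S{i + 1:06d}" for i in range(len(idx))],
            "phenotype": y.astype(float),
        })
        gm = GenotypeMatrix(calls=calls, snps=snps.copy(), samples=samples,
                            covariates=covariates)
        n_b = (~anc[idx]).sum(axis=1)                   # B-ancestry copies per SNP
        post = np.zeros((len(idx), S, 3))
        for c in range(3):
            post[:, :, c] = n_b == c
        track = LocalAncestryTrack(
            sample_ids=list(samples["sample_id"]),
            snp_ids=list(snps["snp_id"]),
            posteriors=post,
        )
        return SyntheticCohort(
            genotypes=gm, true_pairs=None, labels=y, covariates=covariates,
            local_ancestry=track, seed=seed, model=model, pools=[pool_a, pool_b],
        )

    return _finish_cohort(rng, store, n_cases, n_controls, assemble)


# ---------------------------------------------------------------------------
# QC fixture
# ---------------------------------------------------------------------------

#: printed exclusion counts of the source cohort, in filtering order
QC_FIXTURE_COUNTS = {"low_dna": 52, "related": 29, "call_rate": 100,
                     "low_ancestry": 36, "ambiguous_sex": 6}
_QC_N_CASES, _QC_N_CONTROLS = 3153, 2831
_QC_REMOVED_CASES, _QC_REMOVED_CONTROLS = 137, 86
_QC_N_SNPS = 60
_QC_MISSING_PER_LOWCALL = 6      # 54/60 = 90% call rate, below the 95% screen


def generate_qc_fixture(seed: int = 0) -> SyntheticCohort:
    """A 5,984-sample cohort with disjoint exclusion flags matching the
    printed counts (52 low-DNA, 29 related, 100 low call rate via injected
    missingness, 36 low ancestry, 6 ambiguous sex), leaving 5,761 survivors
    (3,016 cases and 2,745 controls)."""
    rng = np.random.default_rng(seed)
    n = _QC_N_CASES + _QC_N_CONTROLS
    y = np.concatenate([np.ones(_QC_N_CASES, dtype=int),
                        np.zeros(_QC_N_CONTROLS, dtype=int)])
    y = y[rng.permutation(n)]

    freqs = rng.uniform(0.05, 0.5, size=_QC_N_SNPS)
    calls = rng.binomial(2, freqs[None, :], size=(n, _QC_N_SNPS)).astype(np.int8)

    cases = rng.permutation(np.flatnonzero(y == 1))[:_QC_REMOVED_CASES]
    controls = rng.permutation(np.flatnonzero(y == 0))[:_QC_REMOVED_CONTROLS]
    removed = rng.permutation(np.concatenate([cases, controls]))
    flags: dict[str, str] = {}
    pos = 0
    lowcall: list[int] = []
    for reason, count in QC_FIXTURE_COUNTS.items():
        block = removed[pos:pos + count]
        pos += count
        if reason == "call_rate":
            lowcall = list(block)
        else:
            for i in block:
                flags[f"S{i + 1:06d}"] = reason
    for i in lowcall:
        miss = rng.choice(_QC_N_SNPS, size=_QC_MISSING_PER_LOWCALL, replace=False)
        calls[i, miss] = MISSING

    alleles = [("A", "G")] * _QC_N_SNPS
    samples = pd.DataFrame({
        "sample_id": [f"S{i + 1:06d}" for i in range(n)],
        "phenotype": y.astype(float),
    })
    cov = default_covariates(n, rng)
    gm = GenotypeMatrix(calls=calls, snps=_snp_table(_QC_N_SNPS, alleles, "1", None),
                        samples=samples, covariates=cov)
    return SyntheticCohort(
        genotypes=gm, true_pairs=None, labels=y, covariates=cov,
        local_ancestry=None, seed=seed, model=DiseaseModel(),
        exclusion_flags=flags,
    )


# ---------------------------------------------------------------------------
# serialization helpers
# ---------------------------------------------------------------------------

def write_local_ancestry(track: LocalAncestryTrack, path) -> None:
    """Long tab-separated format: sample_id, snp_id, p0, p1, p2."""
    with open(path, "w") as fh:
        fh.write("sample_id\tsnp_id\tp0\tp1\tp2\n")
        for i, sid in enumerate(track.sample_ids):
            for j, snp in enumerate(track.snp_ids):
                p0, p1, p2 = track.posteriors[i, j]
                fh.write(f"{sid}\t{snp}\t{p0:.6g}\t{p1:.6g}\t{p2:.6g}\n")


def read_local_ancestry(path) -> LocalAncestryTrack:
    tab = pd.read_csv(path, sep="\t")
    sample_ids = list(dict.fromkeys(tab["sample_id"]))
    snp_ids = list(dict.fromkeys(tab["snp_id"]))
    si = {s: i for i, s in enumerate(sample_ids)}
    vi = {s: j for j, s in enumerate(snp_ids)}
    post = np.zeros((len(sample_ids), len(snp_ids), 3))
    for r in tab.itertuples(index=False):
        post[si[r.sample_id], vi[r.snp_id]] = (r.p0, r.p1, r.p2)
    return LocalAncestryTrack(sample_ids, snp_ids, post)
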