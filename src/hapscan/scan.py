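"""Genome-wide sliding-window scan: fixed-width windows, per-window E-M, and
the covariate-adjusted global haplotype test.

Windows of w consecutive SNPs advance one SNP at a time and never span
chromosomes, so a chromosome with n SNPs yields max(0, n - w + 1) windows.
Each window is phased once by E-M (phenotype-blind) and tested with the
likelihood-ratio global test on its common-haplotype dosages.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2

from . import em
from .io_qc import GenotypeMatrix
from .models import design_from_covariates, _irls, select_common

log = logging.getLogger(__name__)

OK = "ok"
SKIP_MONO = "skipped_monomorphic"
SKIP_UNCONV = "skipped_unconverged"
SKIP_DF0 = "skipped_df0"


@dataclass(frozen=True)
class WindowSpec:
    chromosome: str
    snp_index_start: int          # 0-based inclusive, within the chromosome
    snp_index_end: int
    snp_ids: tuple | None = None
    bp_start: int | None = None
    bp_end: int | None = None

    @property
    def size(self) -> int:
        return self.snp_index_end - self.snp_index_start + 1


@dataclass
class WindowResult:
    window: WindowSpec
    k_common: int
    df: int
    p_global: float
    status: str


def make_windows(snp_counts_per_chromosome, w: int = 5) -> list[WindowSpec]:
    """Index-level window specs from per-chromosome SNP counts.

    ``snp_counts_per_chromosome`` is a mapping chromosome -> SNP count (or an
    iterable of (chromosome, count) pairs).  Stride is 1; a chromosome with
    n SNPs yields max(0, n - w + 1) windows.
    """
    if w < 2:
        raise ValueError("window size must be at least 2")
    items = snp_counts_per_chromosome.items() if hasattr(snp_counts_per_chromosome, "items") \
        else list(snp_counts_per_chromosome)
    out = []
    for chrom, n in items:
        for s in range(max(0, int(n) - w + 1)):
            out.append(WindowSpec(str(chrom), s, s + w - 1))
    return out


def windows_for_matrix(gm: GenotypeMatrix, w: int = 5):
    """Full window specs for a genotype matrix, with the absolute column range.

    Returns a list of (WindowSpec, col_start) where col_start is the first
    column of the window in ``gm.calls``.
    """
    out = []
    snps = gm.snps
    for chrom, sub in snps.groupby("chrom", sort=False):
        idx = sub.index.to_numpy()
        ids = sub["snp_id"].to_numpy()
        pos = sub["pos"].to_numpy()
        n = len(idx)
        for s in range(max(0, n - w + 1)):
            spec = WindowSpec(
                chromosome=str(chrom),
                snp_index_start=s,
                snp_index_end=s + w - 1,
                snp_ids=tuple(ids[s:s + w]),
                bp_start=int(pos[s]),
                bp_end=int(pos[s + w - 1]),
            )
            out.append((spec, int(idx[s])))
    return out


@dataclass
class _PreparedWindow:
    spec: WindowSpec
    status: str                   # pre-test status; OK means testable
    D: np.ndarray | None = None   # (n_samples, df) non-reference common dosages
    df: int = 0
    k_common: int = 0
    keep: np.ndarray | None = None  # None when every sample is retained


def prepare_windows(gm: GenotypeMatrix, w: int = 5, freq_threshold: float = 0.01,
                    tol: float = 1e-8, max_iter: int = 1000) -> list[_PreparedWindow]:
    """Run E-M once per window and extract the global-test dosage designs.

    This is the phenotype-free half of the scan; phenotype permutations reuse
    it without re-running the E-M.
    """
    prepared = []
    alleles_all = list(zip(gm.snps["allele1"], gm.snps["allele2"]))
    for spec, c0 in windows_for_matrix(gm, w):
        calls = gm.calls[:, c0:c0 + w]
        gw = em.GenotypeWindow(calls=calls, window=spec, alleles=alleles_all[c0:c0 + w])
        try:
            hs = em.em_fit(gw, tol=tol, max_iter=max_iter)
        except em.EmptyWindowError:
            prepared.append(_PreparedWindow(spec, SKIP_UNCONV))
            continue
        if not hs.converged:
            prepared.append(_PreparedWindow(spec, SKIP_UNCONV))
            continue
        if hs.k == 1:
            prepared.append(_PreparedWindow(spec, SKIP_MONO, k_common=1))
            continue
        order, ref = select_common(hs, freq_threshold)
        k = len(order)
        if k <= 1:
            prepared.append(_PreparedWindow(spec, SKIP_DF0, k_common=k))
            continue
        non_ref = [j for j in order if j != ref]
        D = hs.dosages[:, non_ref]
        keep = None
        if hs.dropped_samples:
            keep = ~np.isnan(D).any(axis=1)
            D = D[keep]
        prepared.append(_PreparedWindow(spec, OK, D=D, df=k - 1, k_common=k, keep=keep))
    return prepared


def _global_lr_pvalue(y, Xc, null_beta, null_ll, pw: _PreparedWindow,
                      covariates=None):
    """LR p-value of one prepared window for a given label vector.

    The null fit (covariates only) is shared across windows; windows that
    dropped samples refit the null on their retained subset.
    """
    if pw.keep is not None:
        y_w = y[pw.keep]
        Xc_w = Xc[pw.keep]
        b0, _, ll0, _, conv0 = _irls(y_w, Xc_w)
        if not conv0:
            return None
    else:
        y_w, Xc_w, b0, ll0 = y, Xc, null_beta, null_ll
    X = np.column_stack([Xc_w, pw.D])
    warm = np.concatenate([b0, np.zeros(pw.df)])
    b1, _, ll1, _, conv1 = _irls(y_w, X, beta0=warm)
    if not conv1:
        return None
    stat = max(0.0, 2.0 * (ll1 - ll0))
    return float(max(chi2.sf(stat, pw.df), 5e-324))


def scan_chromosome(gm: GenotypeMatrix, covariates: pd.DataFrame | None = None,
                    w: int = 5, freq_threshold: float = 0.01,
                    exclude_snps=None) -> list[WindowResult]:
    """Sliding-window global-test scan over every chromosome in ``gm``.

    Per-window failures downgrade to status flags and never abort the scan.
    ``exclude_snps`` optionally drops a set of SNP ids before windowing (e.g.
    probes failing a genotype-intensity review).
    """
    if exclude_snps:
        drop = set(exclude_snps)
        gm = gm.subset_snps(~gm.snps["snp_id"].isin(drop).to_numpy())
    if covariates is None:
        covariates = gm.covariates
    y = gm.labels.astype(float)
    Xc, _ = design_from_covariates(covariates, gm.n_samples)
    null_beta, _, null_ll, _, conv = _irls(y, Xc)
    if not conv:
        raise RuntimeError("covariates-only null model did not converge")
    results = []
    for pw in prepare_windows(gm, w, freq_threshold):
        if pw.status != OK:
            results.append(WindowResult(pw.spec, pw.k_common, 0, float("nan"), pw.status))
            continue
        p = _global_lr_pvalue(y, Xc, null_beta, null_ll, pw)
        if p is None:
            results.append(WindowResult(pw.spec, pw.k_common, pw.df, float("nan"), SKIP_UNCONV))
        else:
            results.append(WindowResult(pw.spec, pw.k_common, pw.df, p, OK))
    return results


def scan_table(results: list[WindowResult]) -> pd.DataFrame:
    """Tidy scan results: one row per window."""
    rows = []
    for r in results:
        s = r.window
        rows.append({
            "chrom": s.chromosome,
            "bp_start": s.bp_start,
            "bp_end": s.bp_end,
            "snp_ids": ",".join(s.snp_ids) if s.snp_ids else "",
            "k_common": r.k_common,
            "df": r.df,
            "p_global": r.p_global,
            "status": r.status,
        })
    return pd.DataFrame(rows)


def plot_scan(results: list[WindowResult], path) -> None:
    """Manhattan-style plot of -log10 global p against window midpoint."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    tab = scan_table(results)
    ok = tab[tab["status"] == OK].copy()
    ok["mid"] = (ok["bp_start"] + ok["bp_end"]) / 2
    fig, ax = plt.subplots(figsize=(9, 3))
    for i, (chrom, sub) in enumerate(ok.groupby("chrom", sort=False)):
        ax.scatter(sub["mid"], -np.log10(sub["p_global"]), s=4,
                   color="C0" if i % 2 == 0 else "C1", label=None)
    ax.set_xlabel("position (bp)")
    ax.set_ylabel(r"$-\log_{10} p$ (global test)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
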