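"""Permutation-based calibration of the sliding-window scan.

With overlapping windows the global tests are strongly dependent, so a naive
Bonferroni correction over all windows is conservative.  Instead case-control
labels are permuted B times (preserving the case count), the scan's minimum
global-test p-value is recorded per replicate, and the effective number of
independent tests n_eff is read off the distribution of those minima: for n
independent uniform p-values the minimum follows Beta(1, n), so n_eff is
estimated (i) from the empirical fifth percentile t as 0.05 / t, (ii) by the
constrained maximum-likelihood Beta(1, b) fit, and (iii) by the half-of-total
heuristic round(n_windows / 2).  Goodness of fit of candidate Beta(a, b)
references is assessed with EDF statistics (Kolmogorov-Smirnov,
Cramér-von Mises, Anderson-Darling) after the probability-integral transform.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special, stats

from .io_qc import GenotypeMatrix
from .models import design_from_covariates, _irls
from .scan import OK, prepare_windows, _global_lr_pvalue

log = logging.getLogger(__name__)


@dataclass
class PermutationResult:
    B: int
    seed: int
    min_p: np.ndarray
    n_windows: int

    def __post_init__(self):
        self.min_p = np.asarray(self.min_p, dtype=float)


@dataclass
class BetaFit:
    a: float
    b: float
    loglik: float
    constrained_a1: bool


@dataclass
class GofResult:
    ks_stat: float
    ks_p: float
    cvm_stat: float
    cvm_p: float
    ad_stat: float
    ad_p: float


@dataclass
class CalibrationResult:
    threshold_t: float
    neff_percentile: float
    neff_percentile_exact: float
    neff_mle: float
    neff_half: int
    alpha_chromosome: float
    alpha_genome: float
    n_windows: int
    beta_fit: BetaFit | None = None
    extras: dict = field(default_factory=dict)


def permute_labels(labels, B: int, seed: int) -> np.ndarray:
    """B uniform random permutations of the label vector (case count exact).

    Replicate b uses an independent child stream of the master seed, so any
    single replicate can be regenerated without producing the others.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    y = np.asarray(labels)
    children = np.random.SeedSequence(seed).spawn(B)
    out = np.empty((B, y.size), dtype=y.dtype)
    for b, child in enumerate(children):
        rng = np.random.default_rng(child)
        out[b] = y[rng.permutation(y.size)]
    return out


def replicate_min_p(prepared, y, Xc) -> float | None:
    """Minimum global-test p over prepared windows for one label vector.

    Windows with skip statuses or failed fits are excluded from the minimum;
    returns None if no window yields a p-value.
    """
    y = np.asarray(y, dtype=float)
    null_beta, _, null_ll, _, conv = _irls(y, Xc)
    if not conv:
        return None
    best = None
    for pw in prepared:
        if pw.status != OK:
            continue
        p = _global_lr_pvalue(y, Xc, null_beta, null_ll, pw)
        if p is not None and (best is None or p < best):
            best = p
    return best


def permutation_min_p(gm: GenotypeMatrix, covariates=None, w: int = 5,
                      B: int = 1000, seed: int = 0,
                      freq_threshold: float = 0.01) -> PermutationResult:
    """Label-shuffling permutation analysis of the minimum global-test p.

    The E-M dosage designs are computed once; each replicate refits every
    window's global test with permuted labels (covariates unchanged).
    Replicates in which every window fails are dropped with a log entry.
    """
    if covariates is None:
        covariates = gm.covariates
    y0 = gm.labels
    Xc, _ = design_from_covariates(covariates, gm.n_samples)
    prepared = prepare_windows(gm, w, freq_threshold)
    n_windows = len(prepared)
    perms = permute_labels(y0, B, seed)
    minima = []
    n_missing = 0
    for b in range(B):
        m = replicate_min_p(prepared, perms[b], Xc)
        if m is None:
            n_missing += 1
            log.warning("permutation replicate %d produced no testable window", b)
        else:
            minima.append(m)
    if n_missing:
        log.warning("%d of %d replicates recorded as missing", n_missing, B)
    return PermutationResult(B=B, seed=seed, min_p=np.array(minima), n_windows=n_windows)


def fit_beta_mle(pvals, constrain_a1: bool = False) -> BetaFit:
    """Maximum-likelihood Beta fit to values strictly inside (0, 1).

    Constrained (a = 1): closed form b = -n / sum(log(1 - p)).  Unconstrained:
    the digamma score equations are solved numerically to tolerance 1e-10.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size < 1 or (constrain_a1 is False and p.size < 2):
        raise ValueError("need at least two p-values for the unconstrained fit")
    if np.any((p <= 0.0) | (p >= 1.0)):
        raise ValueError("p-values must lie strictly inside (0, 1)")
    n = p.size
    mean_lp = float(np.mean(np.log(p)))
    mean_l1p = float(np.mean(np.log1p(-p)))
    if constrain_a1:
        b = -1.0 / mean_l1p
        ll = float(np.sum(stats.beta.logpdf(p, 1.0, b)))
        return BetaFit(a=1.0, b=b, loglik=ll, constrained_a1=True)

    def score(theta):
        a, b = np.exp(theta)
        dg = special.digamma
        return [
            dg(a) - dg(a + b) - mean_lp,
            dg(b) - dg(a + b) - mean_l1p,
        ]

    # method-of-moments start
    m, v = float(np.mean(p)), float(np.var(p))
    v = max(v, 1e-12)
    common = max(m * (1 - m) / v - 1.0, 1e-6)
    x0 = np.log([max(m * common, 1e-6), max((1 - m) * common, 1e-6)])
    sol = optimize.root(score, x0, tol=1e-10)
    if not sol.success:
        sol = optimize.root(score, x0, method="lm", tol=1e-10)
    a, b = np.exp(sol.x)
    ll = float(np.sum(stats.beta.logpdf(p, a, b)))
    return BetaFit(a=float(a), b=float(b), loglik=ll, constrained_a1=False)


def _ad_asymptotic_p(z: float) -> float:
    """Asymptotic p-value of the Anderson-Darling A^2 statistic for a fully
    specified null (Marsaglia & Marsaglia's double-precision approximation of
    the limiting distribution)."""
    if z <= 0:
        return 1.0
    if z < 2.0:
        cdf = (
            math.exp(-1.2337141 / z) / math.sqrt(z)
            * (2.00012 + (0.247105 - (0.0649821 - (0.0347962 - (0.011672 - 0.00168691 * z) * z) * z) * z) * z)
        )
    else:
        cdf = math.exp(
            -math.exp(1.0776 - (2.30695 - (0.43424 - (0.082433 - (0.008056 - 0.0003146 * z) * z) * z) * z) * z)
        )
    return float(min(max(1.0 - cdf, 0.0), 1.0))


def edf_gof(pvals, a: float, b: float) -> GofResult:
    """EDF goodness-of-fit tests of ``pvals`` against a fixed Beta(a, b).

    The probability-integral transform u = I_p(a, b) reduces the problem to a
    uniformity test; K-S, Cramér-von Mises and Anderson-Darling statistics are
    reported with standard fully-specified-null asymptotic p-values.
    """
    p = np.asarray(pvals, dtype=float)
    u = stats.beta.cdf(p, a, b)
    ks = stats.kstest(u, "uniform")
    cvm = stats.cramervonmises(u, "uniform")
    us = np.sort(u)
    n = us.size
    us = np.clip(us, 1e-300, 1 - 1e-16)
    i = np.arange(1, n + 1)
    a2 = -n - np.mean((2 * i - 1) * (np.log(us) + np.log1p(-us[::-1])))
    return GofResult(
        ks_stat=float(ks.statistic), ks_p=float(ks.pvalue),
        cvm_stat=float(cvm.statistic), cvm_p=float(cvm.pvalue),
        ad_stat=float(a2), ad_p=_ad_asymptotic_p(float(a2)),
    )


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def calibrate(pr: PermutationResult, total_windows_genome: int,
              percentile: float = 0.05, neff_for_alpha: str = "half",
              half_ratio: float = 0.5) -> CalibrationResult:
    """Derive n_eff estimates and significance thresholds from permutations.

    * ``threshold_t``: empirical ``percentile`` of the sorted minimum p-values
      (order statistic at ceil(percentile * B)), the permutation-based
      chromosome-wide threshold at that type-I error rate.
    * ``neff_percentile``: the simple ratio percentile / t; the exact
      Beta(1, n) inversion log(1 - percentile) / log(1 - t) is also reported.
    * ``neff_mle``: the constrained Beta(1, b) maximum-likelihood b.
    * ``neff_half``: round(n_windows / 2), half away from zero.
    * ``alpha_chromosome``: 0.05 / n_eff with the estimate chosen by
      ``neff_for_alpha`` in {"half", "mle", "percentile"}.
    * ``alpha_genome``: 0.05 / (half_ratio * total_windows_genome).
    """
    mp = np.sort(pr.min_p)
    if mp.size == 0:
        raise ValueError("empty permutation result")
    k = max(1, math.ceil(percentile * mp.size))
    t = float(mp[k - 1])
    neff_pct = percentile / t
    neff_pct_exact = math.log1p(-percentile) / math.log1p(-t)
    bf = fit_beta_mle(mp, constrain_a1=True)
    neff_half = _round_half_away(pr.n_windows / 2.0)
    chosen = {"half": float(neff_half), "mle": bf.b, "percentile": neff_pct}[neff_for_alpha]
    return CalibrationResult(
        threshold_t=t,
        neff_percentile=float(neff_pct),
        neff_percentile_exact=float(neff_pct_exact),
        neff_mle=float(bf.b),
        neff_half=neff_half,
        alpha_chromosome=0.05 / chosen,
        alpha_genome=0.05 / (half_ratio * total_windows_genome),
        n_windows=pr.n_windows,
        beta_fit=bf,
    )
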