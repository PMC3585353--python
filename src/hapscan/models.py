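"""Expectation-substitution logistic association tests.

Expected haplotype dosages E[n_h | G] replace the unobserved true haplotype
counts in ordinary logistic regressions of case-control status:

* haplotype-specific test — 1-df Wald (or LR) test of a single dosage term,
  adjusted for covariates; reported as a per-copy odds ratio with 95% CI;
* global test — likelihood-ratio test of the k-1 common-haplotype dosage
  terms jointly against the covariates-only model (reference coding with the
  most frequent haplotype as reference, so df = k-1);
* SNP-adjusted test — 1-df LR test of the haplotype dosage with one or more
  additively coded SNP genotypes (and covariates) present in both the full
  and the nested model, used to ask whether a haplotype signal survives
  conditioning on its best single SNP and/or an established index SNP.

Fitting is by iteratively reweighted least squares with step halving; the
same engine is reused by the permutation machinery where warm starts matter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg
from scipy.stats import chi2, norm

Z975 = 1.959963984540054


def _safe_exp(x: float) -> float:
    """exp that saturates at inf/0 without overflow warnings (separated fits
    can produce arbitrarily large coefficients or standard errors)."""
    if x > 700.0:
        return float("inf")
    if x < -700.0:
        return 0.0
    return float(np.exp(x))


class CollinearityError(ValueError):
    def __init__(self, term: str):
        super().__init__(f"design is rank deficient; collinear term: {term}")
        self.term = term


@dataclass
class LogisticFit:
    coefficients: np.ndarray
    standard_errors: np.ndarray
    loglik: float
    converged: bool
    n_iter: int
    n_samples: int
    names: list[str] = field(default_factory=list)


@dataclass
class AssocResult:
    term: str
    odds_ratio: float
    ci_low: float
    ci_high: float
    p: float
    df: int
    test: str                       # "wald" or "lr"
    adjusted_for: list[str] = field(default_factory=list)
    statistic: float = float("nan")
    collinear: bool = False
    fit: LogisticFit | None = None


def design_from_covariates(covariates: pd.DataFrame | None, n_samples: int):
    """Build an intercept-led design matrix from a covariate table.

    Numeric columns enter as-is; object/categorical columns are expanded to
    drop-first indicator contrasts (e.g. the study factor).
    """
    cols = [np.ones(n_samples)]
    names = ["intercept"]
    if covariates is not None:
        if len(covariates) != n_samples:
            raise ValueError("covariate table not aligned with samples")
        for name in covariates.columns:
            col = covariates[name]
            if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
                dummies = pd.get_dummies(col, prefix=name, drop_first=True, dtype=float)
                for dname in dummies.columns:
                    cols.append(dummies[dname].to_numpy())
                    names.append(dname)
            else:
                cols.append(col.to_numpy(dtype=float))
                names.append(name)
    return np.column_stack(cols), names


def _loglik(y: np.ndarray, eta: np.ndarray) -> float:
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def _irls(y, X, beta0=None, tol: float = 1e-8, max_iter: int = 50):
    """IRLS for the logistic MLE.  Returns (beta, cov, loglik, n_iter, converged).

    Convergence is |Δloglik| < tol; quasi-complete separation is detected via
    a diverging coefficient (|β| > 30) and reported as non-convergence.
    """
    n, p = X.shape
    beta = np.zeros(p) if beta0 is None else beta0.copy()
    eta = X @ beta
    ll = _loglik(y, eta)
    converged = False
    it = 0
    cov = None
    for it in range(1, max_iter + 1):
        mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))
        w = np.maximum(mu * (1.0 - mu), 1e-10)
        XtW = X.T * w
        H = XtW @ X
        g = X.T @ (y - mu)
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, g, rcond=None)[0]
        scale = 1.0
        for _ in range(25):
            beta_new = beta + scale * step
            eta_new = X @ beta_new
            ll_new = _loglik(y, eta_new)
            if ll_new >= ll - 1e-12:
                break
            scale *= 0.5
        beta, eta = beta_new, eta_new
        if abs(ll_new - ll) < tol:
            ll = ll_new
            converged = True
            break
        ll = ll_new
    if np.any(np.abs(beta) > 30):
        converged = False
    mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))
    w = np.maximum(mu * (1.0 - mu), 1e-10)
    H = (X.T * w) @ X
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(H)
    return beta, cov, ll, it, converged


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    R, perm = linalg.qr(X, mode="r", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = max(X.shape) * np.finfo(float).eps * (diag[0] if diag.size else 0.0)
    deficient = np.flatnonzero(diag <= tol)
    if deficient.size:
        raise CollinearityError(names[perm[deficient[0]]])


def fit_logistic(labels, design, names: list[str] | None = None,
                 tol: float = 1e-8, max_iter: int = 50,
                 check_rank: bool = True) -> LogisticFit:
    """Maximum-likelihood logistic fit of 0/1 labels on a design matrix.

    The design must include its intercept column.  A rank-deficient design
    raises :class:`CollinearityError` naming a redundant term.
    """
    y = np.asarray(labels, dtype=float)
    X = np.asarray(design, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("design shape does not match labels")
    if names is None:
        names = [f"x{j}" for j in range(X.shape[1])]
    if y.sum() < 1 or (1 - y).sum() < 1:
        raise ValueError("need at least one case and one control")
    if check_rank:
        _check_rank(X, names)
    beta, cov, ll, it, converged = _irls(y, X, tol=tol, max_iter=max_iter)
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    return LogisticFit(beta, se, ll, converged, it, len(y), list(names))


def haplotype_specific_test(dosage, covariates, labels, test: str = "wald") -> AssocResult:
    """1-df test of a single haplotype dosage, covariate-adjusted.

    The per-copy odds ratio is exp(β) with CI exp(β ± 1.96 se).  ``test`` may
    be "wald" (default) or "lr"; the OR/CI always come from the full fit.
    """
    d = np.asarray(dosage, dtype=float)
    if np.nanmin(d) < -1e-9 or np.nanmax(d) > 2 + 1e-9:
        raise ValueError("dosage outside [0, 2]")
    y = np.asarray(labels, dtype=float)
    keep = ~np.isnan(d)
    d, y = d[keep], y[keep]
    cov = covariates.iloc[np.flatnonzero(keep)].reset_index(drop=True) if covariates is not None else None
    Xc, names = design_from_covariates(cov, len(y))
    X = np.column_stack([Xc, d])
    fit = fit_logistic(y, X, names + ["haplotype"])
    b, se = fit.coefficients[-1], fit.standard_errors[-1]
    if test == "wald":
        z = b / se if se > 0 else np.inf
        p = float(2.0 * norm.sf(abs(z)))
        stat = float(z * z)
    elif test == "lr":
        fit0 = fit_logistic(y, Xc, names)
        stat = max(0.0, 2.0 * (fit.loglik - fit0.loglik))
        p = float(chi2.sf(stat, 1))
    else:
        raise ValueError("test must be 'wald' or 'lr'")
    return AssocResult(
        term="haplotype",
        odds_ratio=_safe_exp(b),
        ci_low=_safe_exp(b - Z975 * se),
        ci_high=_safe_exp(b + Z975 * se),
        p=max(p, 5e-324),
        df=1,
        test=test,
        statistic=stat,
        fit=fit,
    )


def select_common(hs, freq_threshold: float = 0.01):
    """Indices of common haplotypes (f > threshold) with the reference first.

    The reference is the most frequent common haplotype; frequency ties are
    broken by the lexicographically smallest allele string.
    """
    common = np.flatnonzero(hs.common_mask(freq_threshold))
    if common.size == 0:
        return common, None
    order = sorted(common, key=lambda j: (-hs.freqs[j], hs.haplotypes[j]))
    return np.array(order), order[0]


def global_haplotype_test(hs, covariates, labels, freq_threshold: float = 0.01) -> AssocResult | None:
    """Joint LR test of all common haplotypes in a window (df = k-1).

    Haplotypes at or below the frequency threshold are discarded; the most
    frequent survivor serves as reference and its dosage is excluded from the
    design.  Returns None when fewer than two common haplotypes remain (no
    degrees of freedom to test).
    """
    order, ref = select_common(hs, freq_threshold)
    k = len(order)
    if k <= 1:
        return None
    non_ref = [j for j in order if j != ref]
    D = hs.dosages[:, non_ref]
    y = np.asarray(labels, dtype=float)
    keep = ~np.isnan(D).any(axis=1)
    D, y = D[keep], y[keep]
    cov = covariates.iloc[np.flatnonzero(keep)].reset_index(drop=True) if covariates is not None else None
    Xc, names = design_from_covariates(cov, len(y))
    fit0 = fit_logistic(y, Xc, names)
    full_names = names + [f"hap:{hs.haplotypes[j]}" for j in non_ref]
    fit1 = fit_logistic(y, np.column_stack([Xc, D]), full_names)
    stat = max(0.0, 2.0 * (fit1.loglik - fit0.loglik))
    p = float(chi2.sf(stat, k - 1))
    return AssocResult(
        term="global",
        odds_ratio=float("nan"),
        ci_low=float("nan"),
        ci_high=float("nan"),
        p=max(p, 5e-324),
        df=k - 1,
        test="lr",
        statistic=stat,
        fit=fit1,
    )


def snp_adjusted_lr_test(dosage, adjust_snps, covariates, labels,
                         snp_names: list[str] | None = None) -> AssocResult:
    """1-df LR test of a haplotype dosage conditioning on SNP effects.

    Every genotype vector in ``adjust_snps`` (additively coded copies of the
    counted allele; missing calls mean-imputed) enters both the full and the
    nested model along with the covariates; the likelihood ratio then isolates
    the haplotype effect net of those SNPs.  A dosage numerically collinear
    with the adjustment set yields a collinearity signal with statistic 0.
    """
    d = np.asarray(dosage, dtype=float)
    y = np.asarray(labels, dtype=float)
    snps = [np.asarray(s, dtype=float).copy() for s in adjust_snps]
    if snp_names is None:
        snp_names = [f"snp{j}" for j in range(len(snps))]
    keep = ~np.isnan(d)
    d, y = d[keep], y[keep]
    idx = np.flatnonzero(keep)
    cov = covariates.iloc[idx].reset_index(drop=True) if covariates is not None else None
    Xc, names = design_from_covariates(cov, len(y))
    cols = []
    for s in snps:
        s = s[keep]
        miss = (s < 0) | np.isnan(s)
        if miss.any():
            s[miss] = s[~miss].mean() if (~miss).any() else 0.0
        cols.append(s)
    X0 = np.column_stack([Xc] + cols) if cols else Xc
    names0 = names + list(snp_names)

    # condition check: does the dosage add anything beyond the nested design?
    resid = d - X0 @ np.linalg.lstsq(X0, d, rcond=None)[0]
    if np.linalg.norm(resid) <= 1e-8 * max(1.0, np.linalg.norm(d)):
        return AssocResult(
            term="haplotype", odds_ratio=float("nan"),
            ci_low=float("nan"), ci_high=float("nan"),
            p=1.0, df=1, test="lr", adjusted_for=list(snp_names),
            statistic=0.0, collinear=True,
        )
    fit0 = fit_logistic(y, X0, names0)
    fit1 = fit_logistic(y, np.column_stack([X0, d]), names0 + ["haplotype"])
    stat = max(0.0, 2.0 * (fit1.loglik - fit0.loglik))
    p = float(chi2.sf(stat, 1))
    b, se = fit1.coefficients[-1], fit1.standard_errors[-1]
    return AssocResult(
        term="haplotype",
        odds_ratio=_safe_exp(b),
        ci_low=_safe_exp(b - Z975 * se),
        ci_high=_safe_exp(b + Z975 * se),
        p=max(p, 5e-324),
        df=1,
        test="lr",
        adjusted_for=list(snp_names),
        statistic=stat,
        fit=fit1,
    )


def snp_additive_test(genotype, covariates, labels) -> AssocResult:
    """Additive single-SNP Wald test (used to pick 'best SNP' adjustments)."""
    g = np.asarray(genotype, dtype=float).copy()
    miss = (g < 0) | np.isnan(g)
    if miss.any():
        g[miss] = g[~miss].mean() if (~miss).any() else 0.0
    y = np.asarray(labels, dtype=float)
    Xc, names = design_from_covariates(covariates, len(y))
    fit = fit_logistic(y, np.column_stack([Xc, g]), names + ["snp"])
    b, se = fit.coefficients[-1], fit.standard_errors[-1]
    z = b / se if se > 0 else np.inf
    return AssocResult(
        term="snp",
        odds_ratio=_safe_exp(b),
        ci_low=_safe_exp(b - Z975 * se),
        ci_high=_safe_exp(b + Z975 * se),
        p=float(max(2.0 * norm.sf(abs(z)), 5e-324)),
        df=1,
        test="wald",
        statistic=float(z * z),
        fit=fit,
    )
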