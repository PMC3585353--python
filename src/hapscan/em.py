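"""E-M estimation of within-window haplotype frequencies and expected dosages.

Given unphased genotypes over a small window of w SNPs, the observed-data
likelihood for a sample with genotype G is

    P(G) = sum over unordered haplotype pairs (h1, h2) compatible with G of
           f_h1 * f_h2 * (2 if h1 != h2 else 1),

the Hardy-Weinberg product over a vector f of population haplotype
frequencies.  The E-step computes, per sample, the posterior weight of each
compatible pair and from it the expected number of copies E[n_h | G] of every
haplotype h; the M-step replaces f_h by the mean expected dosage over samples
divided by 2.  Iteration continues until the largest frequency change drops
below tolerance.  The final expected dosages are the quantities substituted
into the downstream logistic regressions.

Haplotypes are represented internally as tuples of {0,1} per SNP, 1 meaning a
copy of allele1 (the counted allele of the genotype coding).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

MISSING = -1

#: compatible-pair enumeration cap; a sample whose window genotype expands to
#: more pairs than this is dropped from the window rather than enumerated
PAIR_CAP = 2 ** 20


@dataclass
class GenotypeWindow:
    """Genotype calls restricted to one window of SNPs.

    ``alleles`` optionally carries the (allele1, allele2) pair per SNP so that
    haplotypes can be rendered as allele strings; without it bits are rendered
    as '1'/'0'.
    """

    calls: np.ndarray                     # (n_samples, w), values {0,1,2,-1}
    window: object | None = None          # WindowSpec, when built from a scan
    alleles: list[tuple[str, str]] | None = None

    @property
    def w(self) -> int:
        return self.calls.shape[1]

    @property
    def n_samples(self) -> int:
        return self.calls.shape[0]

    def het_counts(self) -> np.ndarray:
        """Number m of ambiguous (heterozygous or missing) sites per sample."""
        return ((self.calls == 1) | (self.calls == MISSING)).sum(axis=1)


@dataclass
class HaplotypeSet:
    """E-M output for one window: haplotypes, frequencies f_h, and the
    samples x haplotypes matrix of expected dosages E[n_h | G]."""

    haplotypes: list[str]
    bits: list[tuple[int, ...]]
    freqs: np.ndarray
    dosages: np.ndarray                   # NaN rows for dropped samples
    loglik: float
    n_iter: int
    converged: bool
    dropped_samples: list[int] = field(default_factory=list)
    loglik_path: list[float] = field(default_factory=list)

    @property
    def k(self) -> int:
        return len(self.haplotypes)

    def common_mask(self, freq_threshold: float = 0.01) -> np.ndarray:
        """Haplotypes strictly above the frequency threshold."""
        return self.freqs > freq_threshold


def hap_to_string(bits: tuple[int, ...], alleles=None) -> str:
    if alleles is None:
        return "".join("1" if b else "0" for b in bits)
    return "".join(a[0] if b else a[1] for b, a in zip(bits, alleles))


def string_to_bits(hap: str, alleles) -> tuple[int, ...]:
    out = []
    for ch, (a1, a2) in zip(hap, alleles):
        if ch == a1:
            out.append(1)
        elif ch == a2:
            out.append(0)
        else:
            raise ValueError(f"allele {ch!r} not in {{{a1},{a2}}}")
    return tuple(out)


def enumerate_compatible_pairs(genotype_vector, pair_cap: int = PAIR_CAP):
    """All unordered haplotype pairs whose allele sums reproduce the genotype.

    Heterozygous sites contribute a factor 2 each (halved once overall by the
    unordered convention); missing sites expand over all allele completions.
    Returns an empty list when the enumeration would exceed ``pair_cap``
    (the caller is expected to flag the sample).
    """
    g = np.asarray(genotype_vector)
    het = np.flatnonzero(g == 1)
    mis = np.flatnonzero(g == MISSING)
    n_ordered = 2 ** len(het) * 4 ** len(mis)
    if n_ordered // 2 > pair_cap and (len(het) + len(mis)) > 0:
        return []
    base = np.where(g == 2, 1, 0).astype(np.int8)
    base[mis] = 0
    pairs = set()
    for het_bits in itertools.product((0, 1), repeat=len(het)):
        for m1 in itertools.product((0, 1), repeat=len(mis)):
            for m2 in itertools.product((0, 1), repeat=len(mis)):
                h1 = base.copy()
                h2 = base.copy()
                h1[het] = het_bits
                h2[het] = 1 - np.asarray(het_bits, dtype=np.int8)
                h1[mis] = m1
                h2[mis] = m2
                t1, t2 = tuple(int(x) for x in h1), tuple(int(x) for x in h2)
                pairs.add((t1, t2) if t1 <= t2 else (t2, t1))
    return sorted(pairs)


class EmptyWindowError(ValueError):
    """No retained samples in the window."""


def _initial_freqs(calls: np.ndarray, haplotypes: list[tuple[int, ...]]) -> np.ndarray:
    """Product of observed per-SNP allele-1 frequencies, normalized over the
    haplotype universe (deterministic initialization).

    A tiny fixed golden-ratio perturbation breaks the exact symmetry of
    configurations such as all-double-heterozygote windows, where the
    unperturbed allele-frequency product is a stationary saddle point of the
    E-M map; the perturbation is deterministic so fits remain reproducible.
    """
    obs = calls != MISSING
    with np.errstate(invalid="ignore"):
        p1 = np.where(
            obs.sum(axis=0) > 0,
            np.where(calls == MISSING, 0, calls).sum(axis=0) / np.maximum(2 * obs.sum(axis=0), 1),
            0.5,
        )
    H = np.array(haplotypes)
    f = np.prod(np.where(H == 1, p1, 1.0 - p1), axis=1)
    f = np.maximum(f, 1e-9)
    phi = 0.6180339887498949
    jitter = np.modf(phi * (np.arange(len(haplotypes)) + 1))[0]
    f = f * (1.0 + 1e-3 * jitter)
    return f / f.sum()


def em_fit(gw: GenotypeWindow, tol: float = 1e-8, max_iter: int = 1000,
           pair_cap: int = PAIR_CAP) -> HaplotypeSet:
    """Fit haplotype frequencies by E-M and compute expected dosages.

    Cases and controls are pooled (the fit never sees phenotype).  Genotype
    rows are grouped so each distinct configuration is enumerated once.
    Haplotypes with final frequency below 1e-12 are pruned.
    """
    calls = np.asarray(gw.calls)
    uniq, inverse, counts = np.unique(calls, axis=0, return_inverse=True, return_counts=True)
    inverse = np.asarray(inverse).reshape(-1)

    pair_lists = [enumerate_compatible_pairs(row, pair_cap) for row in uniq]
    dropped_cfg = {u for u, pl in enumerate(pair_lists) if not pl}
    dropped_samples = sorted(int(i) for i in np.flatnonzero(np.isin(inverse, list(dropped_cfg)))) if dropped_cfg else []
    kept_cfg = [u for u in range(len(uniq)) if u not in dropped_cfg]
    if not kept_cfg:
        raise EmptyWindowError("no retained samples in window")
    # samples are dropped by whole genotype configuration, so kept counts are exact
    cfg_counts = counts[kept_cfg].astype(float)
    n_retained = cfg_counts.sum()

    hap_index: dict[tuple[int, ...], int] = {}
    for u in kept_cfg:
        for h1, h2 in pair_lists[u]:
            for h in (h1, h2):
                if h not in hap_index:
                    hap_index[h] = len(hap_index)
    haplotypes = list(hap_index)
    K = len(haplotypes)

    idx1, idx2, mult, cfg_of = [], [], [], []
    for ci, u in enumerate(kept_cfg):
        for h1, h2 in pair_lists[u]:
            idx1.append(hap_index[h1])
            idx2.append(hap_index[h2])
            mult.append(2.0 if h1 != h2 else 1.0)
            cfg_of.append(ci)
    idx1 = np.array(idx1); idx2 = np.array(idx2)
    mult = np.array(mult); cfg_of = np.array(cfg_of)
    n_cfg = len(kept_cfg)

    f = _initial_freqs(calls, haplotypes)
    loglik_path: list[float] = []
    converged = False
    n_iter = 0

    def _estep(f):
        wts = f[idx1] * f[idx2] * mult
        denom = np.bincount(cfg_of, weights=wts, minlength=n_cfg)
        return wts, denom

    for n_iter in range(1, max_iter + 1):
        wts, denom = _estep(f)
        loglik_path.append(float(np.dot(cfg_counts, np.log(np.maximum(denom, 1e-300)))))
        post = wts / denom[cfg_of]
        contrib = post * cfg_counts[cfg_of]
        dosage_sum = np.bincount(idx1, weights=contrib, minlength=K)
        dosage_sum += np.bincount(idx2, weights=contrib, minlength=K)
        f_new = dosage_sum / (2.0 * n_retained)
        delta = np.max(np.abs(f_new - f))
        f = f_new
        if delta < tol:
            converged = True
            break

    wts, denom = _estep(f)
    final_ll = float(np.dot(cfg_counts, np.log(np.maximum(denom, 1e-300))))
    loglik_path.append(final_ll)

    # per-configuration dosages at the final frequencies
    post = wts / denom[cfg_of]
    cfg_dosage = np.zeros((n_cfg, K))
    np.add.at(cfg_dosage, (cfg_of, idx1), post)
    np.add.at(cfg_dosage, (cfg_of, idx2), post)

    keep = f > 1e-12
    f_kept = f[keep]
    hap_kept = [h for h, k in zip(haplotypes, keep) if k]
    cfg_dosage = cfg_dosage[:, keep]

    dosages = np.full((gw.n_samples, len(hap_kept)), np.nan)
    cfg_pos = {u: ci for ci, u in enumerate(kept_cfg)}
    for i in range(gw.n_samples):
        u = inverse[i]
        if u in cfg_pos:
            dosages[i] = cfg_dosage[cfg_pos[u]]

    return HaplotypeSet(
        haplotypes=[hap_to_string(h, gw.alleles) for h in hap_kept],
        bits=hap_kept,
        freqs=f_kept,
        dosages=dosages,
        loglik=final_ll,
        n_iter=n_iter,
        converged=converged,
        dropped_samples=dropped_samples,
        loglik_path=loglik_path,
    )


def expected_dosages(freqs, haplotypes, genotype_vector) -> dict:
    """One E-step at fixed frequencies: E[n_h | G] for a single genotype.

    Returns a dict mapping each haplotype (bit tuple) with positive posterior
    dosage to its expected copy number.  Pairs involving haplotypes outside
    ``haplotypes`` carry zero weight.
    """
    bits = [tuple(h) for h in haplotypes]
    f = dict(zip(bits, np.asarray(freqs, dtype=float)))
    weights = {}
    total = 0.0
    for h1, h2 in enumerate_compatible_pairs(genotype_vector):
        if h1 in f and h2 in f:
            w = f[h1] * f[h2] * (2.0 if h1 != h2 else 1.0)
            weights[(h1, h2)] = w
            total += w
    if total <= 0:
        raise ValueError("genotype incompatible with the haplotype set")
    out: dict = {}
    for (h1, h2), w in weights.items():
        out[h1] = out.get(h1, 0.0) + w / total
        out[h2] = out.get(h2, 0.0) + w / total
    return out


def observed_loglik(freqs, haplotypes, gw: GenotypeWindow) -> float:
    """Observed-data log-likelihood of ``gw`` under explicit frequencies.

    ``haplotypes`` may be bit tuples or allele strings (the latter requires
    ``gw.alleles``).  A sample with zero likelihood yields -inf.
    """
    bits = [
        string_to_bits(h, gw.alleles) if isinstance(h, str) else tuple(h)
        for h in haplotypes
    ]
    f = dict(zip(bits, np.asarray(freqs, dtype=float)))
    total = 0.0
    for row in np.asarray(gw.calls):
        s = 0.0
        for h1, h2 in enumerate_compatible_pairs(row):
            if h1 in f and h2 in f:
                s += f[h1] * f[h2] * (2.0 if h1 != h2 else 1.0)
        if s <= 0.0:
            return float("-inf")
        total += np.log(s)
    return float(total)
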