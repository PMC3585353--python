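"""Region follow-up: extension of hit regions, exhaustive variable-length
haplotype search, SNP-adjusted verification, and local-ancestry adjustment.

A region flagged by the 5-SNP scan is first widened by half its width on each
side, then every contiguous run of 2..10 SNPs inside it is phased by E-M and
each common haplotype is tested individually.  The top haplotype is verified
by a 1-df likelihood-ratio test conditioning on its best single SNP (and, in
known-risk regions, the established index SNP), and optionally re-tested with
a local-ancestry covariate — the mean expected count of European-origin
alleles over the haplotype's constituent SNPs — appended to the model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from . import em
from .io_qc import GenotypeMatrix
from .models import (
    AssocResult,
    haplotype_specific_test,
    snp_additive_test,
    snp_adjusted_lr_test,
)

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class Region:
    chromosome: str
    bp_start: int
    bp_end: int

    def __post_init__(self):
        if self.bp_start > self.bp_end:
            raise ValueError("bp_start must not exceed bp_end")


@dataclass
class HaplotypeHit:
    snp_ids: tuple
    snp_indices: tuple                  # absolute columns in the source matrix
    allele_string: str
    frequency: float
    dosage: np.ndarray
    unadjusted: AssocResult
    adjusted: AssocResult | None = None
    local_ancestry_adjusted: AssocResult | None = None
    best_snp: str | None = None
    adjusting_snps: list = field(default_factory=list)

    @property
    def length(self) -> int:
        return len(self.snp_ids)


def extend_region(r: Region, factor: float = 0.5) -> Region:
    """Widen a region by ``factor`` of its width on each side (floored at 1),
    so the default factor makes the extended region twice as long."""
    width = r.bp_end - r.bp_start
    pad = int(round(factor * width))
    return Region(r.chromosome, max(1, r.bp_start - pad), r.bp_end + pad)


def _region_columns(gm: GenotypeMatrix, r: Region) -> np.ndarray:
    snps = gm.snps
    mask = (snps["chrom"].astype(str) == str(r.chromosome)) \
        & (snps["pos"] >= r.bp_start) & (snps["pos"] <= r.bp_end)
    return np.flatnonzero(mask.to_numpy())


def candidate_runs(n_region_snps: int, len_min: int = 2, len_max: int = 10):
    """Contiguous (start, length) runs evaluated by the exhaustive search."""
    return [
        (s, L)
        for L in range(len_min, min(len_max, n_region_snps) + 1)
        for s in range(n_region_snps - L + 1)
    ]


def exhaustive_haplotype_search(gm: GenotypeMatrix, r: Region, covariates, labels,
                                len_min: int = 2, len_max: int = 10,
                                freq_threshold: float = 0.01) -> list[HaplotypeHit]:
    """Test every common haplotype on every contiguous SNP run in a region.

    Runs span len_min .. min(len_max, R) SNPs for the R genotyped SNPs inside
    the region; each run is phased by E-M and each haplotype with pooled
    frequency above the threshold gets a covariate-adjusted 1-df test.  Hits
    are ranked by unadjusted p ascending, ties broken by longer haplotype and
    then lexicographic allele string.
    """
    cols = _region_columns(gm, r)
    if cols.size < 2:
        raise ValueError("region contains fewer than 2 genotyped SNPs")
    ids = gm.snps["snp_id"].to_numpy()
    alleles = list(zip(gm.snps["allele1"], gm.snps["allele2"]))
    hits: list[HaplotypeHit] = []
    R = cols.size
    for s, L in candidate_runs(R, len_min, len_max):
        run = cols[s:s + L]
        gw = em.GenotypeWindow(
            calls=gm.calls[:, run],
            alleles=[alleles[c] for c in run],
        )
        try:
            hs = em.em_fit(gw)
        except em.EmptyWindowError:
            continue
        for j in np.flatnonzero(hs.common_mask(freq_threshold)):
            dosage = hs.dosages[:, j]
            try:
                res = haplotype_specific_test(dosage, covariates, labels)
            except ValueError:
                continue
            hits.append(HaplotypeHit(
                snp_ids=tuple(ids[c] for c in run),
                snp_indices=tuple(int(c) for c in run),
                allele_string=hs.haplotypes[j],
                frequency=float(hs.freqs[j]),
                dosage=dosage,
                unadjusted=res,
            ))
    hits.sort(key=lambda h: (h.unadjusted.p, -h.length, h.allele_string))
    return hits


def verify_top_hit(hit: HaplotypeHit, gm: GenotypeMatrix, covariates, labels,
                   index_snps=None, best_snp_scope: str = "contained",
                   candidate_snp_ids=None, la_track=None) -> HaplotypeHit:
    """SNP-adjusted LR verification of a haplotype hit.

    The 'best SNP' is the constituent SNP with the smallest additive Wald p
    (``best_snp_scope='contained'``); with scope ``'region'`` the candidates
    are ``candidate_snp_ids`` instead.  The adjustment set is {best SNP} plus
    any ``index_snps``.  When ``la_track`` is supplied the adjusted test is
    re-run with the local-ancestry covariate appended and stored in
    ``local_ancestry_adjusted``.
    """
    if best_snp_scope == "contained":
        candidates = list(hit.snp_ids)
    elif best_snp_scope == "region":
        if candidate_snp_ids is None:
            raise ValueError("regional scope requires candidate_snp_ids")
        candidates = list(candidate_snp_ids)
    else:
        raise ValueError("best_snp_scope must be 'contained' or 'region'")
    best, best_p = None, np.inf
    for sid in candidates:
        res = snp_additive_test(gm.snp_column(sid), covariates, labels)
        if res.p < best_p:
            best, best_p = sid, res.p
    adjust_ids = [best] + [s for s in (index_snps or []) if s != best]
    snp_vecs = [gm.snp_column(s) for s in adjust_ids]
    adjusted = snp_adjusted_lr_test(hit.dosage, snp_vecs, covariates, labels,
                                    snp_names=adjust_ids)
    la_res = None
    if la_track is not None:
        la_cov = local_ancestry_covariate(la_track, hit.snp_ids)
        cov2 = covariates.copy() if covariates is not None else None
        if cov2 is None:
            import pandas as pd
            cov2 = pd.DataFrame(index=range(len(la_cov)))
        cov2 = cov2.assign(local_ancestry=la_cov)
        la_res = snp_adjusted_lr_test(hit.dosage, snp_vecs, cov2, labels,
                                      snp_names=adjust_ids)
    return replace(hit, adjusted=adjusted, best_snp=best,
                   adjusting_snps=adjust_ids, local_ancestry_adjusted=la_res)


def local_ancestry_covariate(track, snp_ids) -> np.ndarray:
    """Mean expected European-allele dosage over constituent SNPs.

    Per SNP the expected dosage is P1 + 2 P2 from the posterior triple
    (P0, P1, P2) of carrying 0/1/2 European alleles; the covariate averages
    it over the haplotype's SNPs.
    """
    return track.expected_european_dosage(snp_ids).mean(axis=1)


def known_region_scan(gm: GenotypeMatrix, index_snps, covariates, labels,
                      flank: int = 250_000, wide_flank_regions: dict | None = None,
                      len_min: int = 2, len_max: int = 10,
                      freq_threshold: float = 0.01, n_verify: int = 1) -> dict:
    """Follow-up scan around established risk SNPs.

    ``index_snps`` is a list of (snp_id, chromosome, bp) triples (bp may be
    None when the SNP is genotyped and can be positioned from the map).  Each
    index SNP anchors a +/- ``flank`` region, overridable per SNP id through
    ``wide_flank_regions`` (e.g. a 2 Mb flank for a gene desert).  The top
    ``n_verify`` hits per region are verified with the index SNP in the
    adjustment set.  Returns {snp_id: ranked hit list}.
    """
    wide = wide_flank_regions or {}
    out = {}
    for entry in index_snps:
        sid, chrom, bp = entry
        if bp is None:
            row = gm.snps[gm.snps["snp_id"] == sid]
            if row.empty:
                log.warning("index SNP %s absent from map and unpositioned; skipped", sid)
                continue
            chrom, bp = str(row["chrom"].iloc[0]), int(row["pos"].iloc[0])
        f = int(wide.get(sid, flank))
        region = Region(str(chrom), max(1, int(bp) - f), int(bp) + f)
        try:
            hits = exhaustive_haplotype_search(gm, region, covariates, labels,
                                               len_min, len_max, freq_threshold)
        except ValueError:
            log.warning("region around %s has fewer than 2 SNPs; skipped", sid)
            continue
        genotyped = set(gm.snps["snp_id"])
        idx = [sid] if sid in genotyped else []
        if not idx:
            log.warning("index SNP %s not genotyped; adjusting for best SNP only", sid)
        verified = [
            verify_top_hit(h, gm, covariates, labels, index_snps=idx)
            for h in hits[:n_verify]
        ]
        out[sid] = verified + hits[n_verify:]
    return out


def merge_overlapping_regions(regions: list[Region]) -> list[Region]:
    """Merge regions whose spans overlap on the same chromosome (used to
    report 'independent' regions in top-table summaries)."""
    by_chrom: dict[str, list[Region]] = {}
    for r in regions:
        by_chrom.setdefault(r.chromosome, []).append(r)
    merged = []
    for chrom, rs in by_chrom.items():
        rs = sorted(rs, key=lambda r: r.bp_start)
        cur = rs[0]
        for r in rs[1:]:
            if r.bp_start <= cur.bp_end:
                cur = Region(chrom, cur.bp_start, max(cur.bp_end, r.bp_end))
            else:
                merged.append(cur)
                cur = r
        merged.append(cur)
    return merged


def hits_table(hits: list[HaplotypeHit]):
    """Ranked hit table mirroring the follow-up report layout."""
    import pandas as pd

    rows = []
    for h in hits:
        row = {
            "snp_ids": ",".join(h.snp_ids),
            "haplotype": h.allele_string,
            "frequency": h.frequency,
            "or_unadj": h.unadjusted.odds_ratio,
            "ci_unadj": f"({h.unadjusted.ci_low:.2f}-{h.unadjusted.ci_high:.2f})",
            "p_unadj": h.unadjusted.p,
        }
        if h.adjusted is not None:
            row.update({
                "or_adj": h.adjusted.odds_ratio,
                "ci_adj": f"({h.adjusted.ci_low:.2f}-{h.adjusted.ci_high:.2f})",
                "p_adj": h.adjusted.p,
                "adjusting_snps": ",".join(h.adjusting_snps),
            })
        rows.append(row)
    return pd.DataFrame(rows)
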