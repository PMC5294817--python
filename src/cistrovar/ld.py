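"""Allele frequencies, pairwise r-squared and LD proxy expansion.

The panel is a matrix of phased biallelic haplotypes (one row per haplotype,
one column per site, entries 0 = reference allele, 1 = alternate).  The
linkage-disequilibrium statistic is the gametic r^2,

    r^2 = D^2 / (p_i q_i p_j q_j),   D = f_11 - p_i p_j,

where p is the alternate-allele frequency at a site, q = 1 - p, and f_11 is
the frequency of haplotypes carrying the alternate allele at both sites.
This is the estimator appropriate to phased data; for unphased genotypes the
squared Pearson correlation of allele dosages is available as a fallback.

Lead SNPs from a GWAS catalog are expanded into lead + proxy sets: every panel
site within a window around the lead with r^2 at or above the threshold and
minor allele frequency at or above the MAF floor becomes a proxy carrying its
lead linkage (lead id and r^2) as provenance.  Leads themselves are never
MAF-filtered (the catalog already vetted them), and leads absent from the
panel are retained without proxies and reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np

LEAD = "LEAD"
PROXY = "PROXY"


class MonomorphicSiteError(ValueError):
    """r^2 is undefined when either site is monomorphic in the panel."""


@dataclass(frozen=True)
class Site:
    """A biallelic panel site."""

    chrom: str
    pos: int
    ref: str
    alt: str
    snp_id: str = ""


@dataclass(frozen=True)
class SnpRecord:
    """A lead or proxy SNP with lead-linkage provenance."""

    snp_id: str
    chrom: str
    pos: int
    ref: str = "N"
    alt: str = "N"
    maf: Optional[float] = None
    provenance: str = LEAD
    lead_id: Optional[str] = None
    r2_to_lead: Optional[float] = None

    def __post_init__(self):
        if self.maf is not None and not (0.0 <= self.maf <= 0.5 + 1e-12):
            raise ValueError(f"maf {self.maf} outside [0, 0.5] for {self.snp_id}")
        if self.provenance not in (LEAD, PROXY):
            raise ValueError(f"provenance must be {LEAD} or {PROXY}")
        if self.provenance == PROXY and self.lead_id is None:
            raise ValueError("proxy records require a lead_id")


@dataclass
class LdConfig:
    """Thresholds for proxy selection.

    r2_min
        minimum r^2 with the lead (inclusive), default 0.8.
    maf_min
        minimum proxy minor allele frequency (inclusive), default 0.05.
    window_bp
        half-window: proxies are searched within +/- window_bp of the lead
        (default 500 kb, i.e. a 1 Mb span).
    """

    r2_min: float = 0.8
    maf_min: float = 0.05
    window_bp: int = 500_000

    def __post_init__(self):
        if not (0 < self.r2_min <= 1):
            raise ValueError("r2_min must be in (0, 1]")
        if not (0 <= self.maf_min < 0.5):
            raise ValueError("maf_min must be in [0, 0.5)")
        if self.window_bp <= 0:
            raise ValueError("window_bp must be positive")


class HaplotypePanel:
    """Phased biallelic haplotypes: (n_haplotypes x n_sites) 0/1 matrix."""

    def __init__(self, sites: Sequence[Site], haplotypes: np.ndarray):
        haplotypes = np.asarray(haplotypes, dtype=np.uint8)
        if haplotypes.ndim != 2:
            raise ValueError("haplotype matrix must be 2-dimensional")
        if haplotypes.shape[0] < 2:
            raise ValueError("panel requires at least 2 haplotypes")
        if haplotypes.shape[1] != len(sites):
            raise ValueError(
                f"{haplotypes.shape[1]} haplotype columns for {len(sites)} sites"
            )
        if haplotypes.size and haplotypes.max() > 1:
            raise ValueError("haplotype codes must be 0/1 (biallelic)")
        self.sites = list(sites)
        self.haplotypes = haplotypes
        self._id_index = {s.snp_id: i for i, s in enumerate(self.sites) if s.snp_id}
        self._pos_index = {(s.chrom, s.pos): i for i, s in enumerate(self.sites)}

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_sites(self) -> int:
        return self.haplotypes.shape[1]

    def find(self, snp_id: str = None, chrom: str = None, pos: int = None):
        """Locate a site by id, falling back to (chrom, pos); None if absent."""
        if snp_id is not None and snp_id in self._id_index:
            return self._id_index[snp_id]
        if chrom is not None and pos is not None:
            return self._pos_index.get((chrom, pos))
        return None

    def alt_freq(self, site_index: int) -> float:
        return float(self.haplotypes[:, site_index].mean())

    def allele_freq(self, site_index: int) -> float:
        """Minor allele frequency at a site; monomorphic sites return 0."""
        f = self.alt_freq(site_index)
        return min(f, 1.0 - f)

    def mafs(self) -> np.ndarray:
        f = self.haplotypes.mean(axis=0)
        return np.minimum(f, 1.0 - f)

    def r2(self, i: int, j: int) -> float:
        """Gametic r^2 between two sites; raises MonomorphicSiteError if undefined."""
        x = self.haplotypes[:, i].astype(float)
        y = self.haplotypes[:, j].astype(float)
        pi, pj = x.mean(), y.mean()
        denom = pi * (1 - pi) * pj * (1 - pj)
        if denom == 0.0:
            raise MonomorphicSiteError(
                f"r^2 undefined: site {i if pi in (0.0, 1.0) else j} is monomorphic"
            )
        f11 = (x * y).mean()
        d = f11 - pi * pj
        return float(min(1.0, d * d / denom))

    def r2_dosage(self, i: int, j: int) -> float:
        """Squared Pearson correlation of per-individual allele dosages.

        Consecutive haplotype rows (2k, 2k+1) are paired into individuals;
        this is the unphased fallback estimator.
        """
        if self.n_haplotypes % 2:
            raise ValueError("dosage r^2 requires an even number of haplotypes")
        h = self.haplotypes.astype(float)
        dos = h[0::2] + h[1::2]
        x, y = dos[:, i], dos[:, j]
        if x.std() == 0 or y.std() == 0:
            raise MonomorphicSiteError("dosage r^2 undefined for invariant site")
        r = np.corrcoef(x, y)[0, 1]
        return float(min(1.0, r * r))


def allele_freq(panel: HaplotypePanel, site_index: int) -> float:
    return panel.allele_freq(site_index)


def r2(panel: HaplotypePanel, i: int, j: int) -> float:
    return panel.r2(i, j)


def expand_leads(
    leads: Iterable[SnpRecord],
    panel: HaplotypePanel,
    cfg: LdConfig = None,
    method: str = "haplotype",
):
    """Expand lead SNPs into lead + proxy records under the LD thresholds.

    Returns ``(records, unmatched)`` where records contains every lead
    (provenance LEAD) followed by its proxies (provenance PROXY carrying
    ``lead_id`` and ``r2_to_lead``), and unmatched lists ids of leads not
    found in the panel (these are still present in records, without proxies).
    A site proxying several leads yields one record per lead relationship;
    deduplication by snp_id is the caller's concern when building a universe.
    """
    if cfg is None:
        cfg = LdConfig()
    if method not in ("haplotype", "dosage"):
        raise ValueError("method must be 'haplotype' or 'dosage'")
    positions = np.array([s.pos for s in panel.sites], dtype=np.int64)
    chroms = np.array([s.chrom for s in panel.sites])
    mafs = panel.mafs()
    H = panel.haplotypes.astype(float)
    records: list[SnpRecord] = []
    unmatched: list[str] = []
    for lead in leads:
        li = panel.find(lead.snp_id, lead.chrom, lead.pos)
        if li is None:
            records.append(lead)
            unmatched.append(lead.snp_id)
            continue
        site = panel.sites[li]
        # catalog rows rarely carry alleles; fill them from the panel
        records.append(
            replace(
                lead,
                ref=site.ref,
                alt=site.alt,
                maf=float(min(mafs[li], 0.5)),
            )
        )
        lead_pos = panel.sites[li].pos
        cand = np.nonzero(
            (chroms == panel.sites[li].chrom)
            & (np.abs(positions - lead_pos) <= cfg.window_bp)
        )[0]
        cand = cand[cand != li]
        if cand.size == 0:
            continue
        x = H[:, li]
        pi = x.mean()
        if pi in (0.0, 1.0):
            continue  # monomorphic lead: r^2 undefined with every neighbor
        if method == "haplotype":
            pj = H[:, cand].mean(axis=0)
            f11 = (H[:, cand] * x[:, None]).mean(axis=0)
            denom = pi * (1 - pi) * pj * (1 - pj)
            with np.errstate(divide="ignore", invalid="ignore"):
                rsq = np.where(denom > 0, (f11 - pi * pj) ** 2 / denom, np.nan)
        else:
            rsq = np.array(
                [
                    _safe_dosage_r2(panel, li, int(c))
                    for c in cand
                ]
            )
        rsq = np.minimum(rsq, 1.0)
        keep = (~np.isnan(rsq)) & (rsq >= cfg.r2_min) & (mafs[cand] >= cfg.maf_min)
        for c, rr in zip(cand[keep], rsq[keep]):
            site = panel.sites[int(c)]
            records.append(
                SnpRecord(
                    snp_id=site.snp_id or f"{site.chrom}:{site.pos}",
                    chrom=site.chrom,
                    pos=site.pos,
                    ref=site.ref,
                    alt=site.alt,
                    maf=float(mafs[int(c)]),
                    provenance=PROXY,
                    lead_id=lead.snp_id,
                    r2_to_lead=float(rr),
                )
            )
    return records, unmatched


def _safe_dosage_r2(panel: HaplotypePanel, i: int, j: int) -> float:
    try:
        return panel.r2_dosage(i, j)
    except MonomorphicSiteError:
        return float("nan")
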