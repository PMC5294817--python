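"""Per-phenotype hypergeometric enrichment of SNPs under binding peaks.

Parameterization: the population is the deduplicated universe of GWAS + LD
SNPs (size N); successes are the SNPs associated with the trait (K); the draw
is the set of SNPs under the peak set (n); observed is the number of trait
SNPs under the peak set (k).  The enrichment p-value is the inclusive upper
tail P(X >= k); the lower tail P(X <= k) is reported alongside for
under-representation.  Bonferroni correction multiplies by the number of
phenotypes tested (policy-dependent) and caps at 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class TraitAssociation:
    """One (trait, SNP) association; lead_id is the SNP itself for leads."""

    trait: str
    snp_id: str
    lead_id: str = ""

    def __post_init__(self):
        if not self.lead_id:
            object.__setattr__(self, "lead_id", self.snp_id)


@dataclass
class EnrichmentResult:
    trait: str
    peak_set_name: str
    N: int
    K: int
    n: int
    k: int
    p_raw: float
    p_lower: float
    p_corrected: float
    m: int
    snps_under_peaks: list = field(default_factory=list)

    def __post_init__(self):
        if self.k != len(self.snps_under_peaks):
            raise ValueError("k must equal the number of listed under-peak SNPs")


def _validate_counts(N: int, K: int, n: int, k: int) -> None:
    for name, v in (("N", N), ("K", K), ("n", n), ("k", k)):
        if v < 0 or int(v) != v:
            raise ValueError(f"{name} must be a non-negative integer, got {v}")
    if not (k <= n <= N):
        raise ValueError(f"need k <= n <= N, got k={k}, n={n}, N={N}")
    if not (k <= K <= N):
        raise ValueError(f"need k <= K <= N, got k={k}, K={K}, N={N}")


def hypergeom_upper_tail(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) for X ~ Hypergeom(N, K, n), computed in log-space internally."""
    _validate_counts(N, K, n, k)
    if k == 0:
        return 1.0
    return float(min(1.0, stats.hypergeom.sf(k - 1, N, K, n)))


def hypergeom_lower_tail(N: int, K: int, n: int, k: int) -> float:
    """P(X <= k) for X ~ Hypergeom(N, K, n)."""
    _validate_counts(N, K, n, k)
    return float(min(1.0, stats.hypergeom.cdf(k, N, K, n)))


def bonferroni(p_raw: float, m: int) -> float:
    """Bonferroni-adjusted p-value min(1, m * p_raw)."""
    if m < 1:
        raise ValueError("m must be >= 1")
    if not (0 <= p_raw <= 1):
        raise ValueError("p_raw must be a probability")
    return min(1.0, m * p_raw)


def fisher_exact_one_tailed(a: int, b: int, c: int, d: int) -> float:
    """One-tailed (enrichment direction) Fisher exact p for table [[a,b],[c,d]].

    Tests whether the first row's success proportion a/(a+b) exceeds the
    second row's c/(c+d), summing the hypergeometric tail over tables at the
    observed margins.
    """
    for v in (a, b, c, d):
        if v < 0 or int(v) != v:
            raise ValueError("table entries must be non-negative integers")
    if a + b + c + d == 0:
        raise ValueError("all-zero 2x2 table")
    return float(stats.fisher_exact([[a, b], [c, d]], alternative="greater")[1])


def trait_enrichment(
    assocs: Iterable[TraitAssociation],
    snps_under: Mapping[str, Iterable[str]],
    m_policy: str = "tested",
) -> list[EnrichmentResult]:
    """Hypergeometric enrichment of every trait against every peak set.

    Parameters
    ----------
    assocs : (trait, snp_id, lead_id) associations; duplicated pairs are
        deduplicated, so repeating an association never changes the result.
    snps_under : mapping peak-set name -> ids of SNPs under that set's loci
        (the output of :func:`cistrovar.intervals.overlap_snps` per set).
    m_policy : "tested" corrects for the number of phenotypes with at least
        one SNP under any of the supplied peak sets; "all" corrects for every
        phenotype in the association table.

    Returns results sortable by p_corrected; traits with k = 0 get p_raw = 1.
    """
    if m_policy not in ("tested", "all"):
        raise ValueError("m_policy must be 'tested' or 'all'")
    pairs: dict[tuple[str, str], str] = {}
    for rec in assocs:
        pairs.setdefault((rec.trait, rec.snp_id), rec.lead_id)
    if not pairs:
        raise ValueError("empty association universe")
    universe = {s for (_, s) in pairs}
    N = len(universe)
    trait_snps: dict[str, dict[str, str]] = {}
    for (trait, snp), lead in pairs.items():
        trait_snps.setdefault(trait, {})[snp] = lead
    under_sets = {name: set(ids) & universe for name, ids in snps_under.items()}
    any_under = set().union(*under_sets.values()) if under_sets else set()
    if m_policy == "tested":
        m = sum(1 for snps in trait_snps.values() if set(snps) & any_under)
        m = max(m, 1)
    else:
        m = len(trait_snps)
    results = []
    for name, under in sorted(under_sets.items()):
        n = len(under)
        for trait in sorted(trait_snps):
            snps = trait_snps[trait]
            K = len(snps)
            hit = sorted(set(snps) & under)
            k = len(hit)
            p_raw = hypergeom_upper_tail(N, K, n, k)
            p_low = hypergeom_lower_tail(N, K, n, k)
            results.append(
                EnrichmentResult(
                    trait=trait,
                    peak_set_name=name,
                    N=N,
                    K=K,
                    n=n,
                    k=k,
                    p_raw=p_raw,
                    p_lower=p_low,
                    p_corrected=bonferroni(p_raw, m),
                    m=m,
                    snps_under_peaks=[(s, snps[s]) for s in hit],
                )
            )
    results.sort(key=lambda r: (r.p_corrected, r.p_raw, r.peak_set_name, r.trait))
    return results


def results_to_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append(
            {
                "trait": r.trait,
                "peak_set": r.peak_set_name,
                "N": r.N,
                "K": r.K,
                "n": r.n,
                "k": r.k,
                "snps": ";".join(f"{s}/{l}" for s, l in r.snps_under_peaks),
                "p_raw": r.p_raw,
                "p_lower": r.p_lower,
                "m": r.m,
                "p_corrected": r.p_corrected,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "trait", "peak_set", "N", "K", "n", "k", "snps",
            "p_raw", "p_lower", "m", "p_corrected",
        ],
    )
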