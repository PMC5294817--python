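"""Interval algebra for ChIP-seq peak sets.

All coordinates are 0-based half-open (BED-native): an interval ``[start, end)``
covers bases ``start .. end-1``.  Abutting intervals (``[0,100)`` and
``[100,200)``) share zero base pairs and therefore never merge — a "consensus"
cistrome here means the non-overlapping union of peaks across datasets, with
each merged locus remembering which datasets contributed a peak to it.

Chromosome names are normalized to the ``chr``-prefixed dialect on
construction, so ``"1"`` and ``"chr1"`` denote the same sequence.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

STRANDS = {"+", "-", "."}


def normalize_chrom(name: str) -> str:
    """Return the ``chr``-prefixed form of a chromosome name."""
    name = str(name).strip()
    if not name:
        raise ValueError("empty chromosome name")
    low = name.lower()
    if low.startswith("chr"):
        return "chr" + name[3:]
    return "chr" + name


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic span ``[start, end)`` on a chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))
        if self.start < 0:
            raise ValueError(f"negative start in {self.chrom}:{self.start}-{self.end}")
        if self.end <= self.start:
            raise ValueError(
                f"end <= start in interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_bp(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains_point(self, chrom: str, pos: int) -> bool:
        return normalize_chrom(chrom) == self.chrom and self.start <= pos < self.end


class PeakSet:
    """A named, sorted, duplicate-free collection of peaks from one dataset."""

    def __init__(self, name: str, intervals: Iterable[GenomicInterval]):
        if not name:
            raise ValueError("PeakSet requires a non-empty name")
        self.name = str(name)
        uniq = sorted(set(intervals), key=lambda iv: (iv.chrom, iv.start, iv.end))
        self.intervals: list[GenomicInterval] = uniq

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, PeakSet)
            and self.name == other.name
            and self.intervals == other.intervals
        )

    def __repr__(self) -> str:
        return f"PeakSet({self.name!r}, n={len(self.intervals)})"

    def covered_bp(self) -> int:
        """Union of covered base pairs (peaks within one set may overlap)."""
        return sum(len(loc) for loc in merge_consensus([self]))


@dataclass(frozen=True)
class ConsensusLocus:
    """A non-overlapping merged binding locus with dataset provenance."""

    interval: GenomicInterval
    sources: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        if not self.sources:
            raise ValueError("ConsensusLocus requires at least one source dataset")
        object.__setattr__(self, "sources", frozenset(self.sources))

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end

    def __len__(self) -> int:
        return len(self.interval)


def merge_consensus(peak_sets: Sequence[PeakSet]) -> list[ConsensusLocus]:
    """Merge peak sets into a consensus cistrome of non-overlapping loci.

    Two peaks merge iff they share at least one base pair; half-open abutment
    does not merge.  Each output locus carries the set of dataset names with
    >= 1 bp overlap, and the union of covered base pairs is preserved exactly.
    """
    records: list[tuple[str, int, int, str]] = []
    for ps in peak_sets:
        for iv in ps:
            records.append((iv.chrom, iv.start, iv.end, ps.name))
    records.sort(key=lambda r: (r[0], r[1], r[2]))
    loci: list[ConsensusLocus] = []
    cur = None  # [chrom, start, end, sources]
    for chrom, start, end, src in records:
        if cur is not None and chrom == cur[0] and start < cur[2]:
            cur[2] = max(cur[2], end)
            cur[3].add(src)
        else:
            if cur is not None:
                loci.append(
                    ConsensusLocus(
                        GenomicInterval(cur[0], cur[1], cur[2]), frozenset(cur[3])
                    )
                )
            cur = [chrom, start, end, {src}]
    if cur is not None:
        loci.append(
            ConsensusLocus(GenomicInterval(cur[0], cur[1], cur[2]), frozenset(cur[3]))
        )
    return loci


def _loci_arrays(loci: Sequence[ConsensusLocus]) -> dict[str, tuple[np.ndarray, np.ndarray, list[int]]]:
    """Per-chromosome sorted (starts, ends, original indices) for binary search."""
    by_chrom: dict[str, list[tuple[int, int, int]]] = {}
    for idx, loc in enumerate(loci):
        by_chrom.setdefault(loc.chrom, []).append((loc.start, loc.end, idx))
    out = {}
    for chrom, triples in by_chrom.items():
        triples.sort()
        starts = np.array([t[0] for t in triples], dtype=np.int64)
        ends = np.array([t[1] for t in triples], dtype=np.int64)
        idxs = [t[2] for t in triples]
        out[chrom] = (starts, ends, idxs)
    return out


def overlap_snps(snps, loci: Sequence[ConsensusLocus]):
    """Assign SNPs (point variants) to consensus loci.

    A SNP at position ``p`` belongs to locus ``[s, e)`` iff ``s <= p < e``.
    SNPs on chromosomes with no loci are simply unassigned.

    Parameters
    ----------
    snps : iterable of objects with ``snp_id``, ``chrom``, ``pos`` attributes
        (or ``(snp_id, chrom, pos)`` tuples).
    loci : non-overlapping consensus loci.

    Returns
    -------
    (assignments, n_unique) : assignments is a DataFrame with one row per
        assigned SNP (snp_id, chrom, pos, locus_start, locus_end, sources);
        n_unique is the deduplicated count of distinct SNP ids under any locus.
    """
    index = _loci_arrays(loci)
    rows = []
    seen: set[str] = set()
    for snp in snps:
        if isinstance(snp, tuple):
            snp_id, chrom, pos = snp[0], snp[1], snp[2]
        else:
            snp_id, chrom, pos = snp.snp_id, snp.chrom, snp.pos
        chrom = normalize_chrom(chrom)
        entry = index.get(chrom)
        if entry is None:
            continue
        starts, ends, idxs = entry
        j = int(np.searchsorted(starts, pos, side="right")) - 1
        if j >= 0 and pos < ends[j]:
            loc = loci[idxs[j]]
            rows.append(
                {
                    "snp_id": snp_id,
                    "chrom": chrom,
                    "pos": int(pos),
                    "locus_start": loc.start,
                    "locus_end": loc.end,
                    "sources": ",".join(sorted(loc.sources)),
                }
            )
            seen.add(snp_id)
    assignments = pd.DataFrame(
        rows,
        columns=["snp_id", "chrom", "pos", "locus_start", "locus_end", "sources"],
    )
    return assignments, len(seen)


@dataclass
class CobindingSummary:
    """Result of a fractional-overlap intersection of two cistromes.

    ``n_shared`` counts loci of A meeting the overlap criterion against B
    (query convention); ``n_shared_b`` is the same criterion applied from the
    B side.  ``n_shared + n_only_a == |A|`` and ``n_shared_b + n_only_b == |B|``.
    """

    n_shared: int
    n_only_a: int
    n_only_b: int
    shared_loci: list
    min_fraction: float
    n_shared_b: int = 0
    reciprocal: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "n_shared": self.n_shared,
                    "n_only_a": self.n_only_a,
                    "n_shared_b": self.n_shared_b,
                    "n_only_b": self.n_only_b,
                    "min_fraction": self.min_fraction,
                    "reciprocal": self.reciprocal,
                }
            ]
        )


def _shared_mask(
    query: Sequence[ConsensusLocus],
    subject: Sequence[ConsensusLocus],
    min_fraction: float,
    reciprocal: bool,
) -> list[bool]:
    subj_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for loc in subject:
        subj_by_chrom.setdefault(loc.chrom, []).append((loc.start, loc.end))
    for v in subj_by_chrom.values():
        v.sort()
    mask = []
    for loc in query:
        spans = subj_by_chrom.get(loc.chrom, [])
        starts = [s for s, _ in spans]
        # first candidate: last subject starting at or before loc.end
        lo = bisect.bisect_left(starts, loc.start) - 1
        lo = max(lo, 0)
        total = 0
        ok_recip = False
        for s, e in spans[lo:]:
            if s >= loc.end:
                break
            ov = min(loc.end, e) - max(loc.start, s)
            if ov > 0:
                total += ov
                if ov >= min_fraction * (loc.end - loc.start) and ov >= min_fraction * (e - s):
                    ok_recip = True
        if reciprocal:
            mask.append(ok_recip)
        else:
            mask.append(total >= min_fraction * len(loc))
    return mask


def fractional_intersect(
    a: Sequence[ConsensusLocus],
    b: Sequence[ConsensusLocus],
    min_fraction: float = 0.25,
    reciprocal: bool = False,
) -> CobindingSummary:
    """Intersect two cistromes requiring a minimum fractional overlap.

    A locus of A is shared iff the total number of base pairs it overlaps with
    B is at least ``min_fraction`` of its own length (inclusive threshold: a
    100-bp locus with 25 overlapped bp passes at 0.25).  With
    ``reciprocal=True`` some single B locus must satisfy the fraction with
    respect to both partners' lengths.
    """
    if not (0 < min_fraction <= 1):
        raise ValueError("min_fraction must be in (0, 1]")
    a = list(a)
    b = list(b)
    mask_a = _shared_mask(a, b, min_fraction, reciprocal)
    mask_b = _shared_mask(b, a, min_fraction, reciprocal)
    shared = [loc for loc, m in zip(a, mask_a) if m]
    n_shared = len(shared)
    n_shared_b = sum(mask_b)
    return CobindingSummary(
        n_shared=n_shared,
        n_only_a=len(a) - n_shared,
        n_only_b=len(b) - n_shared_b,
        shared_loci=shared,
        min_fraction=min_fraction,
        n_shared_b=n_shared_b,
        reciprocal=reciprocal,
    )
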