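"""DR3 direct-repeat motif model, scanning and allele-aware scoring.

The vitamin-D-receptor class of nuclear receptors binds a direct repeat of
two hexameric half-sites separated by a 3-bp spacer (DR3), canonically
AGGTCA nnn AGGTCA.  The model here is a position weight matrix over the two
hexamers; the spacer columns carry no weight, so the motif width is
2*6 + spacer = 15 for DR3.

Scores are log2 odds against a background base distribution, summed over the
12 scored columns (additive).  A window scores identically on either strand
of its reverse complement, and hit coordinates always refer to the + strand
of the genome; a hit's ``sequence`` is reported in the motif's reading
orientation (reverse-complemented for - strand hits).

The allele effect of a SNP inside a hit is the change in log-odds
Delta LOD = LOD(alternate allele) - LOD(reference allele): negative means the
reference sequence is the better predicted binding site, positive means the
alternate is.  SNPs falling in spacer columns have Delta LOD exactly 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

BASES = "ACGT"
_CODE = {b: i for i, b in enumerate(BASES)}
_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")

# IUPAC sets used to build the default half-site from its consensus.
_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "K": "GT", "M": "AC", "S": "CG", "W": "AT",
}


class RefMismatchError(ValueError):
    """The supplied reference allele disagrees with the genome sequence."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass
class MotifModel:
    """Direct-repeat PWM: one 4x6 half-site matrix applied to both hexamers.

    Rows are A, C, G, T; columns are half-site positions.  ``score_threshold``
    is the minimum summed log2-odds (bits) for a scan hit.  A pseudocount is
    added to every cell (and columns renormalized) before taking log-odds, so
    zero-probability cells score finitely.
    """

    half_site_pwm: np.ndarray
    spacer_len: int = 3
    background: np.ndarray = None
    score_threshold: float = 0.0
    pseudocount: float = 0.01

    def __post_init__(self):
        self.half_site_pwm = np.asarray(self.half_site_pwm, dtype=float)
        if self.half_site_pwm.shape != (4, 6):
            raise ValueError("half_site_pwm must be 4x6 (rows A,C,G,T)")
        if not np.allclose(self.half_site_pwm.sum(axis=0), 1.0, atol=1e-9):
            raise ValueError("PWM columns must each sum to 1")
        if self.spacer_len < 0:
            raise ValueError("spacer_len must be >= 0")
        if self.background is None:
            self.background = np.full(4, 0.25)
        self.background = np.asarray(self.background, dtype=float)
        if self.background.shape != (4,) or not np.isclose(self.background.sum(), 1.0):
            raise ValueError("background must be a 4-vector summing to 1")

    @property
    def width(self) -> int:
        return 12 + self.spacer_len

    def weight_matrix(self) -> np.ndarray:
        """(width x 4) log2-odds matrix; spacer rows are all zero."""
        p = self.half_site_pwm + self.pseudocount
        p = p / p.sum(axis=0, keepdims=True)
        half = np.log2(p / self.background[:, None]).T  # (6, 4)
        W = np.zeros((self.width, 4))
        W[:6] = half
        W[6 + self.spacer_len:] = half
        return W

    def scored_offsets(self) -> list[int]:
        """0-based in-motif offsets carrying weight (the two hexamers)."""
        return list(range(6)) + list(range(6 + self.spacer_len, self.width))

    def consensus_core(self) -> str:
        """Highest-probability base per half-site column (ties: ACGT order)."""
        return "".join(BASES[i] for i in self.half_site_pwm.argmax(axis=0))

    def max_score(self) -> float:
        """Score of the best possible window."""
        return float(self.weight_matrix().max(axis=1).sum())

    def score_window(self, seq: str, strand: str = "+") -> float:
        """Log2-odds score of one width-length window; N scores -inf."""
        if len(seq) != self.width:
            raise ValueError(f"window must have length {self.width}")
        if strand == "-":
            seq = reverse_complement(seq)
        W = self.weight_matrix()
        total = 0.0
        for j, base in enumerate(seq.upper()):
            i = _CODE.get(base)
            if i is None:
                return float("-inf")
            total += W[j, i]
        return total


def default_dr3_model(score_threshold: Optional[float] = None) -> MotifModel:
    """The packaged DR3 half-site model built from the consensus RGKTSA.

    Each column puts probability 0.85 on the consensus base(s) (split evenly
    when degenerate) and spreads the remaining 0.15 over the other bases.
    The default hit threshold is 80% of the maximal window score.
    """
    pwm = np.zeros((4, 6))
    for col, code in enumerate("RGKTSA"):
        allowed = _IUPAC[code]
        rest = [b for b in BASES if b not in allowed]
        for b in allowed:
            pwm[_CODE[b], col] = 0.85 / len(allowed)
        for b in rest:
            pwm[_CODE[b], col] = 0.15 / len(rest)
    model = MotifModel(half_site_pwm=pwm, spacer_len=3)
    model.score_threshold = (
        0.8 * model.max_score() if score_threshold is None else score_threshold
    )
    return model


@dataclass(frozen=True)
class MotifHit:
    """A scan hit: half-open genomic span of motif width on the + strand."""

    chrom: str
    start: int
    end: int
    strand: str
    score: float
    sequence: str  # in the hit's reading orientation


@dataclass(frozen=True)
class SnpMotifAnnotation:
    """A SNP overlapping a motif hit.

    position_in_motif is 1-based in the hit's reading orientation: for a
    - strand hit, position 1 is the end-most genomic base.
    """

    snp_id: str
    hit: MotifHit
    position_in_motif: int
    delta_lod: Optional[float] = None

    def __post_init__(self):
        width = self.hit.end - self.hit.start
        if not (1 <= self.position_in_motif <= width):
            raise ValueError("position_in_motif outside the motif")


def scan(
    sequence: str,
    model: MotifModel,
    chrom: str = "chr1",
    origin: int = 0,
    both_strands: bool = True,
) -> list[MotifHit]:
    """Report every window scoring at or above the model threshold.

    ``origin`` is the genomic coordinate of ``sequence[0]``; hit coordinates
    are + strand genomic.  Windows containing N are skipped.  Overlapping
    hits are allowed.
    """
    seq = sequence.upper()
    w = model.width
    L = len(seq)
    if L < w:
        return []
    code = np.full(L, 4, dtype=np.int8)
    for b, i in _CODE.items():
        code[np.frombuffer(seq.encode(), dtype=np.uint8) == ord(b)] = i
    W = model.weight_matrix()
    # pad with a -inf column so any N in a window sinks its score
    Wn = np.hstack([W, np.full((w, 1), -np.inf)])
    n_win = L - w + 1
    plus = np.zeros(n_win)
    for j in range(w):
        plus = plus + Wn[j, code[j : j + n_win]]
    strands = [("+", plus)]
    if both_strands:
        # minus-strand score of window = score of its reverse complement:
        # weight for genomic base b at window offset j is W[w-1-j, 3-b]
        Wm = W[::-1, ::-1]
        Wmn = np.hstack([Wm, np.full((w, 1), -np.inf)])
        minus = np.zeros(n_win)
        for j in range(w):
            minus = minus + Wmn[j, code[j : j + n_win]]
        strands.append(("-", minus))
    hits = []
    for strand, scores in strands:
        for i in np.nonzero(scores >= model.score_threshold)[0]:
            window = seq[i : i + w]
            hits.append(
                MotifHit(
                    chrom=chrom,
                    start=origin + int(i),
                    end=origin + int(i) + w,
                    strand=strand,
                    score=float(scores[i]),
                    sequence=window if strand == "+" else reverse_complement(window),
                )
            )
    hits.sort(key=lambda h: (h.chrom, h.start, h.strand))
    return hits


def snp_in_motif(snps, hits: Sequence[MotifHit]) -> list[SnpMotifAnnotation]:
    """Annotate each SNP with every motif hit it falls inside.

    ``snps`` is an iterable of objects with snp_id/chrom/pos attributes or
    (snp_id, chrom, pos) tuples.  One annotation per (snp, overlapping hit).
    """
    by_chrom: dict[str, list[MotifHit]] = {}
    for h in hits:
        by_chrom.setdefault(h.chrom, []).append(h)
    out = []
    for snp in snps:
        if isinstance(snp, tuple):
            snp_id, chrom, pos = snp[0], snp[1], snp[2]
        else:
            snp_id, chrom, pos = snp.snp_id, snp.chrom, snp.pos
        for h in by_chrom.get(chrom, []):
            if h.start <= pos < h.end:
                if h.strand == "+":
                    position = pos - h.start + 1
                else:
                    position = h.end - pos
                out.append(SnpMotifAnnotation(snp_id, h, position))
    return out


def delta_lod(
    model: MotifModel,
    context_sequence: str,
    snp,
    hit: MotifHit,
    context_origin: int = 0,
) -> float:
    """LOD(alt) - LOD(ref) in bits for a SNP inside a motif hit.

    ``context_sequence`` is + strand genomic sequence with coordinate origin
    ``context_origin`` and must cover the hit.  The SNP's ref allele must
    match the genome (alleles are given on the + strand).  SNPs in spacer
    columns return exactly 0.
    """
    if isinstance(snp, tuple):
        snp_id, chrom, pos, ref, alt = snp
    else:
        snp_id, chrom, pos, ref, alt = snp.snp_id, snp.chrom, snp.pos, snp.ref, snp.alt
    if not (hit.start <= pos < hit.end):
        raise ValueError(f"SNP {snp_id} at {chrom}:{pos} outside hit {hit.start}-{hit.end}")
    lo, hi = hit.start - context_origin, hit.end - context_origin
    if lo < 0 or hi > len(context_sequence):
        raise ValueError("context sequence does not cover the hit")
    window = context_sequence[lo:hi].upper()
    offset = pos - hit.start
    genome_base = window[offset]
    if genome_base != ref.upper():
        raise RefMismatchError(
            f"{snp_id}: reference allele {ref} does not match genome base "
            f"{genome_base} at {chrom}:{pos}"
        )
    alt = alt.upper()
    if alt == ref.upper():
        return 0.0
    alt_window = window[:offset] + alt + window[offset + 1 :]
    s_ref = model.score_window(window, hit.strand)
    s_alt = model.score_window(alt_window, hit.strand)
    return float(s_alt - s_ref)
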