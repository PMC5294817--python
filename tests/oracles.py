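"""Independent brute-force oracles used to pin expected values.

Everything here is deliberately naive (O(n^2) scans, exact rational
arithmetic, per-window rescoring) and shares no code with the implementation
paths it checks.
"""

from fractions import Fraction
from math import comb


def naive_union(spans):
    """O(n^2) union of (start, end) half-open spans on one chromosome."""
    spans = [list(s) for s in spans]
    changed = True
    while changed:
        changed = False
        out = []
        while spans:
            cur = spans.pop()
            merged = False
            for other in spans:
                if cur[0] < other[1] and other[0] < cur[1]:  # strict overlap
                    other[0] = min(other[0], cur[0])
                    other[1] = max(other[1], cur[1])
                    merged = True
                    changed = True
                    break
            if not merged:
                out.append(cur)
        spans = out
    return sorted(tuple(s) for s in spans)


def covered_bp(spans):
    return sum(e - s for s, e in naive_union(spans))


def naive_point_overlap(points, spans):
    """Linear scan: ids of points falling inside any half-open span."""
    hit = set()
    for pid, pos in points:
        for s, e in spans:
            if s <= pos < e:
                hit.add(pid)
    return hit


def hypergeom_upper_exact(N, K, n, k) -> Fraction:
    """Exact P(X >= k) for X ~ Hypergeom(N, K, n) by big-integer enumeration."""
    total = comb(N, n)
    s = sum(comb(K, i) * comb(N - K, n - i) for i in range(k, min(K, n) + 1))
    return Fraction(s, total)


def fisher_greater_exact(a, b, c, d) -> Fraction:
    """Exact one-tailed (first row enriched) Fisher p by tail summation."""
    return hypergeom_upper_exact(a + b + c + d, a + c, a + b, a)


def score_window_brute(seq, half_site_pwm, spacer_len, background, pseudocount):
    """Per-column log-odds rescoring of one window, spacer columns skipped."""
    import math

    bases = "ACGT"
    p = [
        [
            (half_site_pwm[i][j] + pseudocount)
            / sum(half_site_pwm[r][j] + pseudocount for r in range(4))
            for j in range(6)
        ]
        for i in range(4)
    ]
    total = 0.0
    for j, base in enumerate(seq.upper()):
        if 6 <= j < 6 + spacer_len:
            continue
        col = j if j < 6 else j - 6 - spacer_len
        if base not in bases:
            return float("-inf")
        i = bases.index(base)
        total += math.log2(p[i][col] / background[i])
    return total
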