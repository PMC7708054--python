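"""Independent brute-force oracles for the motif scanner.

These recompute thresholds and hit sets by exhaustive enumeration, sharing
nothing with the dynamic-programming scan path except the discretization
contract (log-odds rounded to a 1/grid-bit lattice), which is re-derived here
from first principles.
"""

from itertools import product

import numpy as np

GRID = 1000


def oracle_discretized(motif, bg):
    """Integer log-odds matrix recomputed directly from the PPM."""
    return np.rint(np.log2(motif.ppm / bg.as_array()[None, :]) * GRID).astype(np.int64)


def oracle_threshold(motif, bg, p):
    """Exhaustive-enumeration threshold over all 4^W words, in grid units.

    Smallest integer score t with P(random background word scores >= t) <= p;
    max score + 1 when no word is rare enough.
    """
    q = oracle_discretized(motif, bg)
    p_bg = bg.as_array()
    w = motif.width
    weights = {}
    for word in product(range(4), repeat=w):
        score = int(sum(q[i, b] for i, b in enumerate(word)))
        prob = float(np.prod([p_bg[b] for b in word]))
        weights[score] = weights.get(score, 0.0) + prob
    # smallest integer t with P(>= t) <= p: one above the largest attained
    # score whose tail still exceeds p (max + 1 when even the best word is too
    # common, min attained when every word passes)
    tail = 0.0
    for score in sorted(weights, reverse=True):
        tail += weights[score]
        if tail > p:
            return score + 1
    return min(weights)


_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_COMP = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq):
    return seq.translate(_COMP)[::-1]


def oracle_scan(seq, motif, bg, p):
    """Score every window on both strands directly; return hit tuples
    (start, end, strand, grid_score) in forward coordinates."""
    q = oracle_discretized(motif, bg)
    t = oracle_threshold(motif, bg, p)
    w = motif.width
    hits = []
    for strand, s in (("+", seq), ("-", _revcomp(seq))):
        for j in range(len(s) - w + 1):
            window = s[j : j + w]
            if any(c not in _CODE for c in window):
                continue
            score = int(sum(q[i, _CODE[c]] for i, c in enumerate(window)))
            if score >= t:
                if strand == "+":
                    start = j
                else:
                    start = len(seq) - (j + w)
                hits.append((start, start + w, strand, score))
    return sorted(hits)
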