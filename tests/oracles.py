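"""Independent brute-force oracles used by the test suite.

Each oracle re-derives an expected result by direct search or summation,
independently of the implementation path it checks: structures are
enumerated rather than optimised, genomes are scanned at every position
rather than seeded, tails are summed term by term rather than evaluated
in closed form.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.special import gammaln

from mitosrna._seq import encode, revcomp, to_rna
from mitosrna.energy import default_model


# -- folding ---------------------------------------------------------------

def enumerate_structures(seq, model=None):
    """Yield every pseudoknot-free structure (tuples of (i, j) pairs)."""
    model = model or default_model()
    rna = to_rna(seq)
    n = len(rna)
    minloop = model.min_hairpin_loop

    def ok(i, j):
        return model.pair_ok(rna[i], rna[j]) and j - i - 1 >= minloop

    def rec(i, j):
        if i >= j:
            yield ()
            return
        yield from rec(i + 1, j)
        for k in range(i + 1 + minloop, j + 1):
            if ok(i, k):
                for inner in rec(i + 1, k - 1):
                    for outer in rec(k + 1, j):
                        yield ((i, k),) + inner + outer

    yield from rec(0, n - 1)


def min_energy_exhaustive(seq, model=None):
    """Minimum structure energy by exhaustive enumeration."""
    from mitosrna.energy import structure_energy
    model = model or default_model()
    best = 0.0
    for pairs in enumerate_structures(seq, model):
        e = structure_energy(seq, pairs, model)
        if e < best:
            best = e
    return best


# -- mapping ---------------------------------------------------------------

def bruteforce_hits(contigs: dict[str, str], tag_seq: str, max_mismatch: int):
    """All (contig, start, strand, mismatches) by scanning every position."""
    out = []
    for name, seq in contigs.items():
        ref = encode(seq)
        L = len(tag_seq)
        if len(seq) < L:
            continue
        windows = np.lib.stride_tricks.sliding_window_view(ref, L)
        for strand, q in (("+", tag_seq), ("-", revcomp(tag_seq))):
            mm = (windows != encode(q)).sum(axis=1)
            for pos in np.flatnonzero(mm <= max_mismatch):
                out.append((name, int(pos), strand, int(mm[pos])))
    return sorted(out)


# -- adapter trimming ------------------------------------------------------

def bruteforce_junction(read: str, adapter3: str, min_exact=6, min_mm=10):
    """Best junction offset by scoring every offset (matches - mismatches)."""
    best_score, best_off = -1, -1
    for off in range(0, len(read) - min_exact + 1):
        m = min(len(adapter3), len(read) - off)
        mm = sum(a != b for a, b in zip(read[off:off + m], adapter3[:m]))
        if mm > 1:
            continue
        if (mm == 0 and m >= min_exact) or (mm <= 1 and m >= min_mm):
            score = (m - mm) - mm
            if score > best_score:
                best_score, best_off = score, off
    return best_off


# -- exact test ------------------------------------------------------------

def ac_pvalue_by_summation(x: int, y: int, n1: int, n2: int) -> float:
    """Audic-Claverie two-sided p by explicit log-gamma term summation."""
    r = n2 / n1

    def logterm(t):
        return (t * math.log(r) + gammaln(x + t + 1) - gammaln(x + 1)
                - gammaln(t + 1) - (x + t + 1) * math.log1p(r))

    lower = float(np.exp([logterm(t) for t in range(0, y + 1)]).sum())
    # upper tail summed directly until terms vanish
    upper = 0.0
    t = y
    while True:
        term = math.exp(logterm(t))
        upper += term
        t += 1
        if term < 1e-18 * max(upper, 1e-300) and t > y + 10:
            break
        if t > y + 4_000_000:  # safety
            break
    return min(1.0, 2.0 * min(lower, upper))


# -- clustering ------------------------------------------------------------

def union_find_clusters(spans, max_gap: int):
    """Cluster (start, end) spans by transitive <=max_gap adjacency."""
    parent = list(range(len(spans)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(spans)):
        for j in range(i + 1, len(spans)):
            (s1, e1), (s2, e2) = spans[i], spans[j]
            gap = max(s1, s2) - min(e1, e2)
            if gap <= max_gap:
                parent[find(i)] = find(j)
    groups = {}
    for i in range(len(spans)):
        groups.setdefault(find(i), []).append(i)
    return sorted(sorted(g) for g in groups.values())


# -- intervals -------------------------------------------------------------

def overlap_1based(seg_a, seg_b) -> bool:
    (s1, e1), (s2, e2) = seg_a, seg_b
    return s1 <= e2 and s2 <= e1
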