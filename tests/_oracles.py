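"""Independent brute-force oracles used by the test suite.

These deliberately re-derive scores with plain Python loops, independent of
the vectorised implementation they check.
"""

from __future__ import annotations

import numpy as np

from lasagna.core import GAP_CODE, PSSM, Alignment, Site, encode


def brute_plain_score(pssm: PSSM, codes: np.ndarray) -> float:
    """Pair-aware score of a gap-free window by explicit loops."""
    l = pssm.l
    total = 0.0
    for i in range(l):
        total += pssm.scores[i, codes[i]]
    for k in sorted(pssm.pair_scores):
        block = pssm.pair_scores[k]
        for i in range(l - k):
            total += block[i, codes[i], codes[i + k]]
    return total


def brute_gap_aware_score(pssm: PSSM, codes: np.ndarray) -> float:
    """Gap-aware score: gap letters contribute the column/pair minima."""
    l = pssm.l
    total = 0.0
    for i in range(l):
        if codes[i] == GAP_CODE:
            total += pssm.scores[i].min()
        else:
            total += pssm.scores[i, codes[i]]
    for k in sorted(pssm.pair_scores):
        block = pssm.pair_scores[k]
        for i in range(l - k):
            u, v = codes[i], codes[i + k]
            if u == GAP_CODE or v == GAP_CODE:
                total += block[i].min()
            else:
                total += block[i, u, v]
    return total


def brute_sliding(pssm: PSSM, codes: np.ndarray):
    """Enumerate every augmented window; return (best score, offset, scores)."""
    l = pssm.l
    aug = [GAP_CODE] * (l - 1) + list(codes) + [GAP_CODE] * (l - 1)
    scores = [
        brute_gap_aware_score(pssm, np.array(aug[i : i + l]))
        for i in range(len(codes) + l - 1)
    ]
    best = max(scores)
    return best, scores.index(best), scores


def brute_column_frequencies(alignment: Alignment, pseudocount: float):
    """Count-based column frequencies, recomputed with dict counters."""
    l = alignment.length
    out = np.zeros((l, 4))
    for i in range(l):
        counts = {u: 0 for u in range(4)}
        for site in alignment:
            c = encode(site.seq)[i]
            if c != GAP_CODE:
                counts[int(c)] += 1
        n = sum(counts.values())
        for u in range(4):
            out[i, u] = (counts[u] + pseudocount) / (n + 4 * pseudocount)
    return out


def brute_pair_frequencies(alignment: Alignment, k: int, pseudocount: float):
    l = alignment.length
    out = np.zeros((l - k, 4, 4))
    for i in range(l - k):
        counts = np.zeros((4, 4))
        for site in alignment:
            codes = encode(site.seq)
            u, v = codes[i], codes[i + k]
            if u != GAP_CODE and v != GAP_CODE:
                counts[int(u), int(v)] += 1
        out[i] = (counts + pseudocount) / (counts.sum() + 16 * pseudocount)
    return out


def random_sites(rng: np.random.Generator, n: int, lo: int = 4, hi: int = 15):
    """Random gap-free sites of variable length."""
    sites = []
    for i in range(n):
        length = int(rng.integers(lo, hi + 1))
        seq = "".join("ACGT"[c] for c in rng.integers(0, 4, size=length))
        sites.append(Site(f"r{i:03d}", seq))
    return sites


def random_alignment(rng: np.random.Generator, n: int, l: int) -> Alignment:
    """Random gap-free rectangular alignment."""
    rows = [
        Site(f"a{i:03d}", "".join("ACGT"[c] for c in rng.integers(0, 4, size=l)))
        for i in range(n)
    ]
    return Alignment(rows)


def random_pssm(rng: np.random.Generator, l: int, K: int) -> PSSM:
    return PSSM.from_alignment(random_alignment(rng, int(rng.integers(3, 9)), l), K)
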