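"""Seeded generators for planted-motif fixtures with recorded ground truth.

Real binding-site databases store a conserved core with irrelevant flanking
bases on one or both sides; ChIP-seq peaks bury the core in a hundred or more
bases of flank, with the true site usually close to the point-source signal
peak.  These generators emulate both situations: a ground-truth per-column
letter distribution (PWM) is sampled, sites are core draws wrapped in random
flanks (optionally reverse-complemented), and peaks plant one core near a
recorded point source.  Every generator is a pure function of its seed, and
the recorded truth (core interval and strand per sequence) suffices to score
alignment recovery with no external data.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .chip import Peak
from .core import ALPHABET, Alignment, GAP, Site, decode, reverse_complement
from .evaluate import MarkovChain


@dataclass
class SyntheticSiteSet:
    """Planted-motif site set: sequences plus per-site ground truth.

    ``truth`` has one row per site with ``site_id``, ``core_start``,
    ``core_end`` (0-based half-open, in the emitted sequence's coordinates)
    and ``strand`` ('-' when the whole site was reverse-complemented, so the
    core matches the reverse complement of the PWM).
    """

    pwm: Optional[np.ndarray]
    sites: List[Site]
    truth: pd.DataFrame
    seed: int
    pair_rules: Optional[List[np.ndarray]] = None


def _column_ic(p: np.ndarray) -> float:
    nz = p[p > 0]
    return float(2.0 + np.sum(nz * np.log2(nz)))


def make_pwm(length: int, ic_per_column: float, seed: int = 0) -> np.ndarray:
    """A PWM whose every column has the requested information content.

    Each column mixes a random dominant letter with the uniform distribution;
    the mixture weight is solved by bisection, so the realised IC matches the
    target to floating-point accuracy (well inside the 0.1-bit tolerance).
    """
    if not 0.0 <= ic_per_column <= 2.0:
        raise ValueError("per-column information content must be within [0, 2] bits")
    rng = np.random.default_rng(seed)
    pwm = np.empty((length, 4))
    for i in range(length):
        dominant = int(rng.integers(4))
        lo, hi = 0.0, 1.0
        for _ in range(80):
            mid = 0.5 * (lo + hi)
            p = np.full(4, (1.0 - mid) / 4.0)
            p[dominant] += mid
            if _column_ic(p) < ic_per_column:
                lo = mid
            else:
                hi = mid
        w = 0.5 * (lo + hi)
        p = np.full(4, (1.0 - w) / 4.0)
        p[dominant] += w
        pwm[i] = p / p.sum()
    return pwm


def pwm_consensus(pwm: np.ndarray) -> str:
    return decode(np.argmax(np.asarray(pwm), axis=1))


def _draw_core(pwm: np.ndarray, rng: np.random.Generator) -> str:
    return "".join(ALPHABET[rng.choice(4, p=col)] for col in pwm)


def _draw_flank(n: int, background: np.ndarray, rng: np.random.Generator) -> str:
    if n == 0:
        return ""
    return decode(rng.choice(4, size=n, p=background).astype(np.int8))


def sample_site_set(
    pwm: np.ndarray,
    n: int = 30,
    flank_range: Tuple[int, int] = (0, 6),
    revcomp_prob: float = 0.2,
    background: Optional[Sequence[float]] = None,
    seed: int = 0,
) -> SyntheticSiteSet:
    """Sample ``n`` sites: a PWM core with i.i.d. background flanks per side.

    Per-side flank lengths are uniform over ``flank_range``; each finished
    site is reverse-complemented with probability ``revcomp_prob``.  Same
    seed, same sites — byte for byte.
    """
    rng = np.random.default_rng(seed)
    bg = np.full(4, 0.25) if background is None else np.asarray(background, dtype=float)
    bg = bg / bg.sum()
    lo, hi = flank_range
    core_len = np.asarray(pwm).shape[0]
    sites, rows = [], []
    for i in range(n):
        left, right = int(rng.integers(lo, hi + 1)), int(rng.integers(lo, hi + 1))
        seq = _draw_flank(left, bg, rng) + _draw_core(pwm, rng) + _draw_flank(right, bg, rng)
        cs, ce, strand = left, left + core_len, "+"
        if rng.random() < revcomp_prob:
            seq = reverse_complement(seq)
            cs, ce, strand = len(seq) - ce, len(seq) - cs, "-"
        sid = f"site{i:03d}"
        sites.append(Site(sid, seq))
        rows.append({"site_id": sid, "core_start": cs, "core_end": ce, "strand": strand})
    return SyntheticSiteSet(np.asarray(pwm), sites, pd.DataFrame(rows), seed)


def sample_paired_site_set(
    core_length: int = 10,
    n: int = 30,
    flank_range: Tuple[int, int] = (0, 2),
    fidelity: float = 0.95,
    revcomp_prob: float = 0.0,
    seed: int = 0,
) -> SyntheticSiteSet:
    """Sites whose core carries adjacent-pair dependence but uniform marginals.

    The first core letter is uniform; each subsequent letter follows a fixed
    random permutation of its predecessor with probability ``fidelity`` and
    is uniform over the other three letters otherwise.  Permutations preserve
    uniform marginals, so a scope-0 PSSM sees almost no signal while pair
    terms at distance 1 capture nearly all of it.
    """
    rng = np.random.default_rng(seed)
    perms = [rng.permutation(4) for _ in range(core_length - 1)]
    lo, hi = flank_range
    bg = np.full(4, 0.25)
    sites, rows = [], []
    for i in range(n):
        letters = [int(rng.integers(4))]
        for j in range(core_length - 1):
            if rng.random() < fidelity:
                letters.append(int(perms[j][letters[-1]]))
            else:
                choices = [c for c in range(4) if c != int(perms[j][letters[-1]])]
                letters.append(int(choices[rng.integers(3)]))
        core = "".join(ALPHABET[c] for c in letters)
        left, right = int(rng.integers(lo, hi + 1)), int(rng.integers(lo, hi + 1))
        seq = _draw_flank(left, bg, rng) + core + _draw_flank(right, bg, rng)
        cs, ce, strand = left, left + core_length, "+"
        if rng.random() < revcomp_prob:
            seq = reverse_complement(seq)
            cs, ce, strand = len(seq) - ce, len(seq) - cs, "-"
        sid = f"site{i:03d}"
        sites.append(Site(sid, seq))
        rows.append({"site_id": sid, "core_start": cs, "core_end": ce, "strand": strand})
    return SyntheticSiteSet(None, sites, pd.DataFrame(rows), seed, pair_rules=perms)


def sample_peak_set(
    pwm: np.ndarray,
    n: int = 300,
    peak_len_range: Tuple[int, int] = (100, 400),
    motif_offset_jitter: int = 30,
    revcomp_prob: float = 0.5,
    seed: int = 0,
) -> Tuple[List[Peak], pd.DataFrame]:
    """Peaks with one planted core near the recorded point source.

    The point source is drawn away from the peak edges; the motif midpoint
    sits within ``motif_offset_jitter`` bases of it (mirroring the empirical
    observation that most true sites fall within 50 bp of the called peak).
    Truth rows give the motif interval (peak-local coordinates) and strand.
    """
    rng = np.random.default_rng(seed)
    pwm = np.asarray(pwm)
    m = pwm.shape[0]
    lo, hi = peak_len_range
    margin = m + motif_offset_jitter
    if lo < 2 * margin + 1:
        raise ValueError("peaks too short for the motif plus jitter margin")
    bg = np.full(4, 0.25)
    peaks, rows = [], []
    genome_pos = 0
    for i in range(n):
        plen = int(rng.integers(lo, hi + 1))
        seq = list(_draw_flank(plen, bg, rng))
        p = int(rng.integers(margin, plen - margin))
        delta = int(rng.integers(-motif_offset_jitter, motif_offset_jitter + 1))
        mid = p + delta
        ms = mid - m // 2
        core = _draw_core(pwm, rng)
        strand = "+"
        if rng.random() < revcomp_prob:
            core = reverse_complement(core)
            strand = "-"
        seq[ms : ms + m] = core
        name = f"peak{i:04d}"
        peaks.append(
            Peak(
                chrom="chrSYN", start=genome_pos, end=genome_pos + plen, name=name,
                signal=float(rng.uniform(1.0, 10.0)), peak_offset=p, seq="".join(seq),
            )
        )
        rows.append(
            {"peak_id": name, "motif_start": ms, "motif_end": ms + m, "strand": strand}
        )
        genome_pos += plen + 50
    return peaks, pd.DataFrame(rows)


def shuffle_sites(sites: Sequence[Site], seed: int = 0) -> List[Site]:
    """Negative control: permute the letters within every site (motif destroyed)."""
    rng = np.random.default_rng(seed)
    out = []
    for s in sites:
        letters = list(s.ungapped)
        rng.shuffle(letters)
        out.append(Site(s.id, "".join(letters)))
    return out


def core_recovery_fraction(alignment: Alignment, truth: pd.DataFrame) -> float:
    """Fraction of sites whose planted core lands on the modal core columns.

    For every aligned row the planted core's alignment columns and
    orientation are derived from the truth table (accounting for rows the
    aligner stored reverse-complemented); the recovery fraction is the share
    of rows agreeing with the most common (start column, orientation) pair.
    """
    table = truth.set_index("site_id")
    keys = []
    for site in alignment:
        ungapped = site.ungapped
        if not ungapped:
            continue
        rec = table.loc[site.id]
        left_pad = len(site.seq) - len(site.seq.lstrip(GAP))
        cs, ce, strand = int(rec["core_start"]), int(rec["core_end"]), str(rec["strand"])
        if site.source_strand == "+":
            start = left_pad + cs
            orient = strand
        else:
            start = left_pad + (len(ungapped) - ce)
            orient = "-" if strand == "+" else "+"
        keys.append((start, orient))
    if not keys:
        return 0.0
    _, modal_count = Counter(keys).most_common(1)[0]
    return modal_count / len(alignment)


def promoter_like_chain() -> MarkovChain:
    """A synthetic first-order background with promoter-like dinucleotide bias.

    A fixed, mildly GC-skewed transition table with a depleted CpG step —
    qualitatively the composition of mammalian promoter sequence.  Purely
    synthetic: a stand-in study condition, not trained on genomic data.
    """
    transition = np.array(
        [
            [0.30, 0.21, 0.28, 0.21],  # from A
            [0.31, 0.30, 0.08, 0.31],  # from C (CpG depleted)
            [0.26, 0.24, 0.28, 0.22],  # from G
            [0.18, 0.25, 0.29, 0.28],  # from T
        ]
    )
    return MarkovChain(transition)
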