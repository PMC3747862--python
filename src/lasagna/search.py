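"""PSSM scanning for putative binding sites, cutoffs and empirical p-values.

A scan scores every ``l``-mer of a sequence on both strands and keeps the
higher of the two scores (genomic windows are gap-free, so the plain pair-
aware score applies).  The default prediction cutoff is the minimal sliding
score of the binding sites the matrix was built from — by construction every
constituting site is recovered at that cutoff.

Because pair terms make the score a sum of dependent variables, p-values are
estimated empirically: a long random sequence is simulated from the
background letter distribution, every window is scored on both strands, and
only the upper 5% tail of scores is retained.  Scores below the 95th
percentile report the sentinel ``"0.05+"``; the smallest assignable nonzero
p-value is ``1 / n_windows`` (2.5e-5 at the 40000-window default), and 0
means smaller than that.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Optional, Sequence, Union

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .core import Alignment, PSSM, encode, revcomp_codes

PVALUE_SENTINEL = "0.05+"
DEFAULT_N_WINDOWS = 40000
TAIL_FRACTION = 0.05

PValue = Union[float, str]


@dataclass
class ScanHit:
    """A predicted binding site on the forward coordinate system."""

    seq_id: str
    start: int
    end: int
    strand: str
    score: float
    p_value: Optional[PValue] = None


def scan_sequence(
    seq: str,
    pssm: PSSM,
    cutoff: Optional[float] = None,
    seq_id: str = "seq",
) -> List[ScanHit]:
    """Score every ``l``-mer on both strands; return hits sorted by score.

    Each window receives the higher of its forward and reverse-complement
    scores.  Hits scoring at least ``cutoff`` (all windows when ``cutoff`` is
    None) are returned sorted by descending score, ties by position.
    """
    codes = encode(seq, allow_gap=False)
    l = pssm.l
    if codes.shape[0] < l:
        warnings.warn(
            f"sequence {seq_id!r} is shorter than the PSSM ({codes.shape[0]} < {l})"
        )
        return []
    windows = sliding_window_view(codes, l)
    fwd = pssm.score_windows(windows)
    rev = pssm.score_windows((3 - windows)[:, ::-1])
    scores = np.maximum(fwd, rev)
    strands = np.where(fwd >= rev, "+", "-")
    positions = np.arange(scores.shape[0])
    if cutoff is not None:
        keep = scores >= cutoff
        scores, strands, positions = scores[keep], strands[keep], positions[keep]
    order = np.lexsort((positions, -scores))
    return [
        ScanHit(seq_id, int(positions[i]), int(positions[i]) + l, str(strands[i]),
                float(scores[i]))
        for i in order
    ]


def min_site_cutoff(pssm: PSSM, constituting_sites: Alignment) -> float:
    """Minimal sliding score of the sites the PSSM was built from.

    Every constituting site rescanned at this cutoff is recovered.  Rows
    whose letters were entirely trimmed away are skipped.
    """
    best = []
    for site in constituting_sites:
        seq = site.ungapped
        if not seq:
            continue
        codes = encode(seq, allow_gap=False)
        score = max(
            float(pssm.sliding_scores(codes).max()),
            float(pssm.sliding_scores(revcomp_codes(codes)).max()),
        )
        best.append(score)
    if not best:
        raise ValueError("no non-empty constituting sites")
    return min(best)


@dataclass
class ScoreDistribution:
    """Upper tail of the empirical null score distribution of a PSSM."""

    tail: np.ndarray  # ascending
    n_windows: int

    @property
    def threshold(self) -> float:
        """The 95th-percentile score; anything below reports the sentinel."""
        return float(self.tail[0])

    @property
    def resolution(self) -> float:
        """Smallest assignable nonzero p-value, ``1 / n_windows``."""
        return 1.0 / self.n_windows


def empirical_score_distribution(
    pssm: PSSM,
    background: Optional[Sequence[float]] = None,
    n_windows: int = DEFAULT_N_WINDOWS,
    seed: int = 0,
) -> ScoreDistribution:
    """Simulate the null score distribution and keep its upper 5% tail.

    An i.i.d. random sequence long enough to yield ``n_windows`` windows is
    drawn from the background letter distribution (the PSSM's own stored
    background by default, i.e. the letter composition of the sites it was
    built from).  Every window is scored on both strands and the higher score
    kept.
    """
    f = pssm.background if background is None else np.asarray(background, dtype=float)
    if f.shape != (4,) or abs(float(f.sum()) - 1.0) > 1e-6:
        raise ValueError("background must be 4 probabilities summing to 1")
    rng = np.random.default_rng(seed)
    codes = rng.choice(4, size=n_windows + pssm.l - 1, p=f / f.sum()).astype(np.int8)
    windows = sliding_window_view(codes, pssm.l)
    scores = np.maximum(
        pssm.score_windows(windows), pssm.score_windows((3 - windows)[:, ::-1])
    )
    tail_size = max(1, int(round(TAIL_FRACTION * n_windows)))
    tail = np.sort(scores)[-tail_size:]
    return ScoreDistribution(tail, n_windows)


def empirical_pvalue(dist: ScoreDistribution, score: float) -> PValue:
    """Empirical p-value of a score against the retained null tail.

    Returns the sentinel ``"0.05+"`` for scores below the 95th percentile,
    the fraction of null windows scoring at least ``score`` otherwise, and
    0.0 for scores above every retained null score (i.e. below the
    distribution's resolution).
    """
    if score < dist.threshold:
        return PVALUE_SENTINEL
    count = dist.tail.shape[0] - int(np.searchsorted(dist.tail, score, side="left"))
    return count / dist.n_windows
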