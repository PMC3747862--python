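"""Length-aware progressive alignment of variable-length binding sites.

Binding sites of a transcription factor share a short conserved core flanked
by irrelevant bases; shorter sites tend to carry fewer irrelevant bases.  The
aligner therefore seeds the alignment with a shortest site and repeatedly
aligns the next shortest unaligned site against the pair-aware, gap-aware
PSSM of the current partial alignment, considering both strands.  The result
is a gapless-interior alignment: rows are end-padded only.

End-trimming by column coverage and information content is provided
separately (:func:`trim_alignment`) and is applied by callers before building
a final scoring matrix.
"""

from __future__ import annotations

from typing import List, NamedTuple, Optional, Sequence, Tuple, Union

import numpy as np

from .core import (
    GAP,
    Alignment,
    PSSM,
    Site,
    column_stats,
    encode,
    reverse_complement,
    revcomp_codes,
)

DEFAULT_PSEUDOCOUNT = 0.25
DEFAULT_PAIR_PSEUDOCOUNT = 0.0625
MIN_SITE_LENGTH = 4


class Placement(NamedTuple):
    """Best scoring window for one site against a PSSM.

    ``offset`` indexes the ``l + l_s - 1`` windows of the gap-augmented
    sequence (0-based); ``strand`` is '+' if the site was placed as given and
    '-' if its reverse complement was placed.
    """

    site_id: str
    offset: int
    strand: str
    score: float


def place_site(site: Union[Site, str], pssm: PSSM) -> Placement:
    """Best placement of a gap-free site over both strands.

    The forward strand wins exact score ties, then the leftmost offset.
    """
    if isinstance(site, Site):
        site_id, seq = site.id, site.ungapped
    else:
        site_id, seq = "site", site
    codes = encode(seq, allow_gap=False)
    fwd = pssm.sliding_scores(codes)
    rev = pssm.sliding_scores(revcomp_codes(codes))
    best_f, best_r = float(fwd.max()), float(rev.max())
    if best_f >= best_r:
        return Placement(site_id, int(np.argmax(fwd)), "+", best_f)
    return Placement(site_id, int(np.argmax(rev)), "-", best_r)


def choose_next_site(
    unaligned: Sequence[Site],
    pssm: PSSM,
    *,
    tie_sample: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> int:
    """Index of the next site to align: shortest first, profile score breaks ties.

    Among equally short sites the one whose best sliding score against the
    current profile is highest wins; residual ties go to input order.  When
    ``tie_sample`` is set and more candidates than that are tied on length,
    only a seeded random sample of them competes (the ChIP-seq variant).
    """
    if not unaligned:
        raise ValueError("no unaligned sites left")
    lengths = [len(s.ungapped) for s in unaligned]
    shortest = min(lengths)
    candidates = [i for i, n in enumerate(lengths) if n == shortest]
    if len(candidates) == 1:
        return candidates[0]
    if tie_sample is not None and len(candidates) > tie_sample:
        if rng is None:
            rng = np.random.default_rng(0)
        picked = rng.choice(len(candidates), size=tie_sample, replace=False)
        candidates = sorted(candidates[i] for i in picked)
    best_i, best_score = candidates[0], -np.inf
    for i in candidates:
        score = place_site(unaligned[i], pssm).score
        if score > best_score:
            best_i, best_score = i, score
    return best_i


def merge_placement(alignment: Alignment, site: Site, placement: Placement) -> Alignment:
    """Add a placed site to the alignment, growing it on overhang.

    Window offset ``i`` in the augmented sequence corresponds to the site
    starting at alignment column ``l - 1 - i`` (possibly negative, i.e. left
    overhang).  Existing rows are end-padded so the result is rectangular.
    """
    l = alignment.length
    seq = site.ungapped
    if placement.strand == "-":
        seq = reverse_complement(seq)
    L = len(seq)
    s0 = (l - 1) - placement.offset
    start, end = min(0, s0), max(l, s0 + L)
    pad_left, pad_right = -start, end - l
    rows = [
        Site(s.id, GAP * pad_left + s.seq + GAP * pad_right, s.source_strand)
        for s in alignment.sites
    ]
    strand = placement.strand if site.source_strand == "+" else (
        "+" if placement.strand == "-" else "-"
    )
    rows.append(Site(site.id, GAP * (s0 - start) + seq + GAP * (end - s0 - L), strand))
    return Alignment.from_rows(rows)


def trim_alignment(alignment: Alignment, c_min: float = 0.4, ic_min: float = 0.0) -> Alignment:
    """End-trim columns failing the coverage/information thresholds.

    Scanning inward from each end, columns are removed up to (exclusive) the
    first column with coverage strictly above ``c_min`` *and* information
    content strictly above ``ic_min``.  Idempotent.  Raises if no column
    qualifies.
    """
    coverage, ic = column_stats(alignment)
    ok = (coverage > c_min) & (ic > ic_min)
    if not ok.any():
        raise ValueError(
            f"trimming with C_min={c_min} and IC_min={ic_min} would remove every column"
        )
    j0 = int(np.argmax(ok))
    j1 = alignment.length - int(np.argmax(ok[::-1]))
    if (j0, j1) == (0, alignment.length):
        return alignment
    return alignment.slice_columns(j0, j1)


class AlignmentStep(NamedTuple):
    """One event of the progressive-alignment log."""

    site_id: str
    site_length: int
    offset: int
    strand: str
    score: float
    alignment_length: int


def lasagna_align(
    sites: Sequence[Site],
    ka: int,
    *,
    trim: Optional[Tuple[float, float]] = None,
    seed_index: Optional[int] = None,
    tie_sample: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    adaptive_trimmer=None,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    pair_pseudocount: float = DEFAULT_PAIR_PSEUDOCOUNT,
    min_site_length: int = MIN_SITE_LENGTH,
    history: Optional[List[AlignmentStep]] = None,
) -> Alignment:
    """Progressively align gap-free binding sites, shortest first.

    Parameters
    ----------
    sites
        Gap-free input sites; each must be at least ``min_site_length`` bases.
    ka
        Scope of the pair-aware PSSM used during alignment; must be smaller
        than the shortest site.
    trim
        Optional ``(C_min, IC_min)`` applied to the finished alignment.
    seed_index
        Index of the seed site; defaults to the first shortest site in input
        order.
    tie_sample, rng
        ChIP-seq tie handling: cap on the number of equally short candidates
        competing at each step, sampled with ``rng``.
    adaptive_trimmer
        Optional callable applied to the partial alignment before each PSSM
        rebuild once it holds more than two sequences (the ChIP-seq variant).
    history
        Optional list collecting one :class:`AlignmentStep` per merge, in
        processing order.
    """
    sites = list(sites)
    if not sites:
        raise ValueError("no input sites")
    for s in sites:
        if GAP in s.seq:
            raise ValueError(f"site {s.id!r}: input sites must be gap-free")
        if len(s.seq) < min_site_length:
            raise ValueError(
                f"site {s.id!r} has {len(s.seq)} bases; at least {min_site_length} required"
            )
    shortest = min(len(s.seq) for s in sites)
    if not 0 <= ka < shortest:
        raise ValueError(f"scope ka={ka} must be smaller than the shortest site ({shortest})")

    if seed_index is None:
        seed_index = min(range(len(sites)), key=lambda i: (len(sites[i].seq), i))
    seed = sites[seed_index]
    alignment = Alignment([Site(seed.id, seed.seq, "+")])
    if history is not None:
        history.append(
            AlignmentStep(seed.id, len(seed.seq), 0, "+", 0.0, alignment.length)
        )
    unaligned = [s for i, s in enumerate(sites) if i != seed_index]

    while unaligned:
        if adaptive_trimmer is not None and len(alignment) > 2:
            alignment = adaptive_trimmer(alignment)
        ka_eff = min(ka, alignment.length - 1)
        pssm = PSSM.from_alignment(
            alignment, ka_eff, pseudocount=pseudocount, pair_pseudocount=pair_pseudocount
        )
        idx = choose_next_site(unaligned, pssm, tie_sample=tie_sample, rng=rng)
        site = unaligned.pop(idx)
        placement = place_site(site, pssm)
        alignment = merge_placement(alignment, site, placement)
        if history is not None:
            history.append(
                AlignmentStep(
                    site.id, len(site.seq), placement.offset, placement.strand,
                    placement.score, alignment.length,
                )
            )

    if trim is not None:
        alignment = trim_alignment(alignment, *trim)
    return alignment
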