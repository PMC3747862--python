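"""DNA alphabet, alignment containers, frequency models and pair-aware PSSMs.

The scoring model extends the classical log-odds position-specific scoring
matrix (PSSM) with nucleotide-pair terms.  A *scope* parameter ``K`` controls
how far apart a scored pair of positions may be: the score of an ``l``-mer
``s`` is

    score(s) = sum_i M_i(s_i) + sum_{k=1..K} sum_i M_{i,i+k}(s_i, s_{i+k})

so ``K = 0`` recovers the ordinary additive PSSM.  A gap-aware variant
substitutes the column (or pair-table) minimum whenever a window letter is the
gap character; this is what lets binding sites of different lengths compete
for every relative placement against the matrix during alignment.

All scores are in bits (log base 2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, Iterator, List, NamedTuple, Optional, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

GAP = "-"
ALPHABET = "ACGT"
GAP_CODE = 4
_LETTERS = ALPHABET + GAP

_ENCODE_TABLE = np.full(256, -1, dtype=np.int8)
for _i, _c in enumerate(_LETTERS):
    _ENCODE_TABLE[ord(_c)] = _i
    _ENCODE_TABLE[ord(_c.lower())] = _i
_DECODE_TABLE = np.frombuffer(_LETTERS.encode("ascii"), dtype=np.uint8)


class AlphabetError(ValueError):
    """A sequence contains a letter outside {A, C, G, T, -}."""


def encode(seq: str, *, allow_gap: bool = True) -> np.ndarray:
    """Encode a DNA string as int8 codes (A=0, C=1, G=2, T=3, '-'=4)."""
    raw = np.frombuffer(seq.encode("ascii", "replace"), dtype=np.uint8)
    codes = _ENCODE_TABLE[raw]
    bad = (codes < 0) if allow_gap else (codes < 0) | (codes == GAP_CODE)
    if bad.any():
        pos = int(np.argmax(bad))
        raise AlphabetError(f"unsupported letter {seq[pos]!r} at position {pos}")
    return codes


def decode(codes: np.ndarray) -> str:
    return bytes(_DECODE_TABLE[np.asarray(codes)]).decode("ascii")


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    """Reverse complement on the code level; the gap code maps to itself."""
    out = np.asarray(codes)[::-1].copy()
    mask = out != GAP_CODE
    out[mask] = 3 - out[mask]
    return out


def reverse_complement(seq: str) -> str:
    """Reverse-complement a DNA string; gap letters are preserved in place.

    An involution: ``reverse_complement(reverse_complement(s)) == s``.
    """
    return decode(revcomp_codes(encode(seq)))


@dataclass(frozen=True)
class Site:
    """A binding-site sequence, possibly end-padded with gaps once aligned.

    ``source_strand`` records whether the stored sequence is the input
    sequence itself (``+``) or its reverse complement (``-``); stripping the
    gaps and undoing the strand always recovers the original input.
    """

    id: str
    seq: str
    source_strand: str = "+"

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"site {self.id!r}: empty sequence")
        object.__setattr__(self, "seq", self.seq.upper())
        encode(self.seq)  # alphabet validation
        if self.source_strand not in ("+", "-"):
            raise ValueError(f"site {self.id!r}: bad strand {self.source_strand!r}")
        if GAP in self.seq.strip(GAP):
            raise ValueError(f"site {self.id!r}: gaps must be confined to the ends")

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def ungapped(self) -> str:
        return self.seq.strip(GAP)

    def original(self) -> str:
        """The input sequence this row came from (gap-stripped, strand undone)."""
        s = self.ungapped
        return s if self.source_strand == "+" else reverse_complement(s)


class Alignment:
    """A rectangular, gapless-interior multiple alignment of binding sites.

    Every row has the same padded length and every column contains at least
    one non-gap letter.
    """

    __slots__ = ("sites", "codes", "_counts")

    def __init__(self, sites: Iterable[Site]):
        sites = list(sites)
        if not sites:
            raise ValueError("an alignment needs at least one site")
        width = len(sites[0].seq)
        if any(len(s.seq) != width for s in sites):
            raise ValueError("alignment is not rectangular")
        codes = np.stack([encode(s.seq) for s in sites])
        if (codes == GAP_CODE).all(axis=0).any():
            raise ValueError("alignment has an all-gap column")
        self.sites: List[Site] = sites
        self.codes: np.ndarray = codes
        self._counts: Optional[np.ndarray] = None

    @classmethod
    def from_rows(cls, rows: Iterable[Site]) -> "Alignment":
        """Build an alignment, silently dropping all-gap columns.

        All-gap columns can only occur outside every row's letter span, so
        removing them never splits a row's contiguous letters.
        """
        rows = list(rows)
        codes = np.stack([encode(s.seq) for s in rows])
        keep = ~(codes == GAP_CODE).all(axis=0)
        if keep.all():
            return cls(rows)
        kept = codes[:, keep]
        return cls(
            [Site(s.id, decode(kept[i]), s.source_strand) for i, s in enumerate(rows)]
        )

    def __len__(self) -> int:
        return len(self.sites)

    def __iter__(self) -> Iterator[Site]:
        return iter(self.sites)

    @property
    def length(self) -> int:
        """Number of columns."""
        return self.codes.shape[1]

    @property
    def column_counts(self) -> np.ndarray:
        """Per-column counts of A, C, G, T (gaps excluded); shape (l, 4)."""
        if self._counts is None:
            self._counts = (self.codes[:, :, None] == np.arange(4)).sum(axis=0)
        return self._counts

    def slice_columns(self, start: int, stop: int) -> "Alignment":
        if not 0 <= start < stop <= self.length:
            raise ValueError(f"bad column slice [{start}, {stop})")
        return Alignment(
            [Site(s.id, s.seq[start:stop], s.source_strand) for s in self.sites]
        )

    def consensus(self) -> str:
        """Majority letter per column; ties resolved alphabetically."""
        return decode(np.argmax(self.column_counts, axis=1))


def small_sample_correction(n) -> np.ndarray:
    """Approximate sampling error of the entropy estimate, ``3 / (2 ln2 n)``."""
    return 3.0 / (2.0 * math.log(2.0) * np.asarray(n, dtype=float))


def column_stats(alignment: Alignment) -> tuple[np.ndarray, np.ndarray]:
    """Per-column coverage ``C_i`` and information content ``IC_i``.

    ``C_i`` is the fraction of non-gap letters in column ``i``.  ``IC_i`` is
    the 2-bit maximum entropy minus the plug-in column entropy (pseudocount
    0), reduced by the small-sample correction for ``n_i`` observed letters,
    clamped at zero.
    """
    counts = alignment.column_counts.astype(float)
    n = counts.sum(axis=1)
    coverage = n / len(alignment)
    freqs = counts / n[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(freqs > 0.0, freqs * np.log2(np.where(freqs > 0, freqs, 1.0)), 0.0)
    ic = 2.0 + plogp.sum(axis=1) - small_sample_correction(n)
    return coverage, np.maximum(ic, 0.0)


class FrequencyModel:
    """Column, pair and background letter probabilities of an alignment.

    ``probs[i, u]`` is the probability of letter ``u`` in column ``i``
    (estimated from non-gap letters plus a pseudocount).  ``pair_probs[k]``
    holds the joint distribution of letters at positions ``(i, i + k)`` for
    every ``1 <= k <= K``, estimated from rows that are non-gap at both
    positions.  The background is either supplied or pooled from all non-gap
    letters of the alignment; the pair background is the independence product
    ``f(u) f(v)``.
    """

    def __init__(
        self,
        probs: np.ndarray,
        pair_probs: Dict[int, np.ndarray],
        background: np.ndarray,
        n: np.ndarray,
        pseudocount: float,
        pair_pseudocount: float,
    ):
        self.probs = np.asarray(probs, dtype=float)
        self.pair_probs = {int(k): np.asarray(v, dtype=float) for k, v in pair_probs.items()}
        self.background = np.asarray(background, dtype=float)
        self.n = np.asarray(n, dtype=float)
        self.pseudocount = float(pseudocount)
        self.pair_pseudocount = float(pair_pseudocount)

    @property
    def length(self) -> int:
        return self.probs.shape[0]

    @property
    def K(self) -> int:
        return max(self.pair_probs, default=0)

    @property
    def background_pair(self) -> np.ndarray:
        return np.outer(self.background, self.background)

    @classmethod
    def from_alignment(
        cls,
        alignment: Alignment,
        K: int = 0,
        pseudocount: float = 0.25,
        pair_pseudocount: float = 0.0625,
        background: Optional[Sequence[float]] = None,
    ) -> "FrequencyModel":
        l = alignment.length
        if not 0 <= K < l:
            raise ValueError(f"scope K={K} must satisfy 0 <= K < l={l}")
        counts = alignment.column_counts.astype(float)
        n = counts.sum(axis=1)
        probs = (counts + pseudocount) / (n + 4.0 * pseudocount)[:, None]

        codes = alignment.codes
        pair_probs: Dict[int, np.ndarray] = {}
        for k in range(1, K + 1):
            left, right = codes[:, : l - k], codes[:, k:]
            valid = (left != GAP_CODE) & (right != GAP_CODE)
            cnt = np.zeros((l - k, 4, 4))
            rr, cc = np.nonzero(valid)
            np.add.at(cnt, (cc, left[rr, cc], right[rr, cc]), 1.0)
            tot = cnt.sum(axis=(1, 2))
            pair_probs[k] = (cnt + pair_pseudocount) / (
                tot + 16.0 * pair_pseudocount
            )[:, None, None]

        if background is None:
            pooled = counts.sum(axis=0)
            bg = (pooled + pseudocount) / (pooled.sum() + 4.0 * pseudocount)
        else:
            bg = np.asarray(background, dtype=float)
            if bg.shape != (4,) or not math.isclose(float(bg.sum()), 1.0, abs_tol=1e-6):
                raise ValueError("background must be 4 probabilities summing to 1")
            bg = bg / bg.sum()
        return cls(probs, pair_probs, bg, n, pseudocount, pair_pseudocount)

    def reverse_complement(self) -> "FrequencyModel":
        """The model of the column-reversed, letter-complemented alignment."""
        probs = self.probs[::-1, ::-1].copy()
        pair = {
            k: p[::-1].swapaxes(1, 2)[:, ::-1, ::-1].copy()
            for k, p in self.pair_probs.items()
        }
        return FrequencyModel(
            probs, pair, self.background[::-1].copy(), self.n[::-1].copy(),
            self.pseudocount, self.pair_pseudocount,
        )


class SlidingHit(NamedTuple):
    score: float
    offset: int
    window: str


class PSSM:
    """Pair-aware log-odds scoring matrix with a gap-aware variant.

    ``scores[i, u] = log2(f_i(u) / f(u))`` and, for ``1 <= k <= K``,
    ``pair_scores[k][i, u, v] = log2(f_{i,i+k}(u, v) / (f(u) f(v)))``.
    The gap-aware variant scores a gap letter with the precomputed minimum of
    its column (or of its pair table when either member of a pair is a gap).
    """

    def __init__(
        self,
        scores: np.ndarray,
        pair_scores: Optional[Dict[int, np.ndarray]] = None,
        background: Optional[Sequence[float]] = None,
    ):
        self.scores = np.asarray(scores, dtype=float)
        if self.scores.ndim != 2 or self.scores.shape[1] != 4:
            raise ValueError("scores must have shape (l, 4)")
        l = self.scores.shape[0]
        self.pair_scores: Dict[int, np.ndarray] = {}
        for k, arr in (pair_scores or {}).items():
            arr = np.asarray(arr, dtype=float)
            if arr.shape != (l - int(k), 4, 4):
                raise ValueError(f"pair block k={k} must have shape ({l - int(k)}, 4, 4)")
            self.pair_scores[int(k)] = arr
        self.background = (
            np.full(4, 0.25) if background is None else np.asarray(background, dtype=float)
        )
        # Gap-extended lookup tables: index 4 holds the gap minima.
        self._single5 = np.concatenate(
            [self.scores, self.scores.min(axis=1, keepdims=True)], axis=1
        )
        self._pair5: Dict[int, np.ndarray] = {}
        for k, arr in self.pair_scores.items():
            mins = arr.min(axis=(1, 2))
            ext = np.empty((arr.shape[0], 5, 5))
            ext[:, :4, :4] = arr
            ext[:, 4, :] = mins[:, None]
            ext[:, :, 4] = mins[:, None]
            self._pair5[k] = ext

    @property
    def l(self) -> int:
        return self.scores.shape[0]

    @property
    def K(self) -> int:
        return max(self.pair_scores, default=0)

    @property
    def gap_single(self) -> np.ndarray:
        """Per-column minima used for gap letters; shape (l,)."""
        return self.scores.min(axis=1)

    def gap_pair(self, k: int) -> np.ndarray:
        """Per-position pair minima at distance ``k``; shape (l - k,)."""
        return self.pair_scores[k].min(axis=(1, 2))

    @classmethod
    def from_frequencies(cls, freq: FrequencyModel) -> "PSSM":
        if (freq.probs <= 0.0).any() or (freq.background <= 0.0).any() or any(
            (p <= 0.0).any() for p in freq.pair_probs.values()
        ):
            raise ValueError(
                "log-odds scores are undefined for zero probabilities; "
                "estimate the frequency model with a positive pseudocount"
            )
        scores = np.log2(freq.probs / freq.background)
        bg_pair = freq.background_pair
        pair = {k: np.log2(p / bg_pair) for k, p in freq.pair_probs.items()}
        return cls(scores, pair, freq.background)

    @classmethod
    def from_alignment(
        cls,
        alignment: Alignment,
        K: int = 0,
        pseudocount: float = 0.25,
        pair_pseudocount: float = 0.0625,
        background: Optional[Sequence[float]] = None,
    ) -> "PSSM":
        return cls.from_frequencies(
            FrequencyModel.from_alignment(
                alignment, K, pseudocount, pair_pseudocount, background
            )
        )

    # ------------------------------------------------------------------ scoring

    def score_windows(self, codes: np.ndarray, gap_aware: bool = False) -> np.ndarray:
        """Score a batch of ``l``-letter windows; shape (n, l) -> (n,)."""
        W = np.atleast_2d(np.asarray(codes))
        if W.shape[1] != self.l:
            raise ValueError(f"window length {W.shape[1]} != PSSM length {self.l}")
        if not gap_aware and (W == GAP_CODE).any():
            raise AlphabetError("gap letters require gap_aware scoring")
        l = self.l
        total = self._single5[np.arange(l), W].sum(axis=1)
        for k, ext in self._pair5.items():
            total = total + ext[np.arange(l - k), W[:, : l - k], W[:, k:]].sum(axis=1)
        return total

    def score_window(self, window, gap_aware: bool = False) -> float:
        """Score one ``l``-mer (a string or a code vector)."""
        codes = encode(window) if isinstance(window, str) else np.asarray(window)
        if codes.ndim != 1 or codes.shape[0] != self.l:
            raise ValueError(f"window length {codes.shape} != PSSM length {self.l}")
        return float(self.score_windows(codes[None, :], gap_aware=gap_aware)[0])

    def _augment(self, codes: np.ndarray) -> np.ndarray:
        aug = np.full(codes.shape[0] + 2 * (self.l - 1), GAP_CODE, dtype=np.int8)
        aug[self.l - 1 : self.l - 1 + codes.shape[0]] = codes
        return aug

    def sliding_scores(self, codes: np.ndarray) -> np.ndarray:
        """Gap-aware scores of all ``l + l_s - 1`` windows of the augmented sequence."""
        aug = self._augment(np.asarray(codes))
        return self.score_windows(sliding_window_view(aug, self.l), gap_aware=True)

    def sliding_score(self, seq) -> SlidingHit:
        """Best placement of a sequence of any length against this matrix.

        The sequence is padded with ``l - 1`` gap letters on each end and all
        windows are scored gap-aware; ties go to the leftmost window.
        """
        codes = encode(seq, allow_gap=False) if isinstance(seq, str) else np.asarray(seq)
        scores = self.sliding_scores(codes)
        offset = int(np.argmax(scores))
        aug = self._augment(codes)
        return SlidingHit(float(scores[offset]), offset, decode(aug[offset : offset + self.l]))


def best_alignment_scores(pssm: PSSM, windows: np.ndarray) -> np.ndarray:
    """Vectorised sliding score for a batch of equal-length sequences.

    ``windows`` has shape (n, L); each row is padded with ``l - 1`` gap codes
    on both ends, every sub-window is scored gap-aware, and the row maximum is
    returned — the batch analogue of :meth:`PSSM.sliding_score`.
    """
    W = np.atleast_2d(np.asarray(windows))
    n, L = W.shape
    l = pssm.l
    aug = np.full((n, L + 2 * (l - 1)), GAP_CODE, dtype=np.int8)
    aug[:, l - 1 : l - 1 + L] = W
    sub = sliding_window_view(aug, l, axis=1)
    flat = sub.reshape(-1, l)
    return pssm.score_windows(flat, gap_aware=True).reshape(n, -1).max(axis=1)
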