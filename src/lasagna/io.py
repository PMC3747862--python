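"""Readers and writers: FASTA, narrowPeak, BED hit lists, matrix files.

All coordinates are 0-based half-open throughout.  IUPAC ambiguity codes are
rejected with the offending record and position (the scoring model defines
no score for them); ``drop_ambiguous`` discards such records instead.

The matrix file is a plain-text dialect carrying the single-letter score
block (4 x l) plus one 16 x (l - k) pair-score block per distance k, with
enough metadata (background, pseudocounts, scope) to rebuild the PSSM
exactly.  A MEME-minimal exporter is provided for the single-letter
probabilities only.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from Bio import SeqIO

from .chip import Peak
from .core import ALPHABET, Alignment, AlphabetError, GAP, PSSM, Site
from .search import PVALUE_SENTINEL, ScanHit

PathLike = Union[str, Path]


# ----------------------------------------------------------------------- FASTA


def read_fasta(
    path: PathLike, *, aligned: bool = False, drop_ambiguous: bool = False
) -> List[Site]:
    """Read sites (or aligned, gap-padded rows) from FASTA, upper-cased.

    Letters outside A, C, G, T (plus '-' in aligned mode) raise an
    :class:`AlphabetError` naming the record and position, or drop the
    record when ``drop_ambiguous`` is set.
    """
    allowed = set(ALPHABET + (GAP if aligned else ""))
    sites: List[Site] = []
    for record in SeqIO.parse(str(path), "fasta"):
        seq = str(record.seq).upper()
        bad = next((i for i, c in enumerate(seq) if c not in allowed), None)
        if bad is not None:
            if drop_ambiguous:
                warnings.warn(f"dropping record {record.id!r}: letter {seq[bad]!r}")
                continue
            raise AlphabetError(
                f"record {record.id!r}: unsupported letter {seq[bad]!r} at position {bad}"
            )
        sites.append(Site(record.id, seq))
    return sites


def write_fasta(sites: Union[Alignment, Sequence[Site]], path: PathLike) -> None:
    rows = sites.sites if isinstance(sites, Alignment) else list(sites)
    with open(path, "w") as fh:
        for s in rows:
            fh.write(f">{s.id}\n{s.seq}\n")


# ------------------------------------------------------------------ narrowPeak


def read_narrowpeak(
    path: PathLike, sequences: Optional[Dict[str, str]] = None
) -> List[Peak]:
    """Parse a narrowPeak (BED6+4) file; column 10 is the point-source offset.

    A point source of -1 falls back to the interval midpoint.  ``sequences``
    optionally maps peak names (column 4) to their sequences.
    """
    peaks: List[Peak] = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) != 10:
                raise ValueError(
                    f"{path}:{line_no}: narrowPeak needs 10 tab-separated columns, "
                    f"got {len(fields)}"
                )
            chrom, start, end, name, score, strand, signal, pval, qval, offset = fields
            peak = Peak(
                chrom=chrom,
                start=int(start),
                end=int(end),
                name=name,
                score=int(score),
                strand=strand,
                signal=float(signal),
                pvalue=float(pval),
                qvalue=float(qval),
                peak_offset=int(offset),
                seq=sequences.get(name) if sequences else None,
            )
            peaks.append(peak)
    return peaks


def write_narrowpeak(peaks: Sequence[Peak], path: PathLike) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            fh.write(
                "\t".join(
                    [
                        p.chrom, str(p.start), str(p.end), p.name, str(p.score),
                        p.strand, f"{p.signal:g}", f"{p.pvalue:g}", f"{p.qvalue:g}",
                        str(p.peak_offset),
                    ]
                )
                + "\n"
            )


# ------------------------------------------------------------------- hit lists


def write_hits_bed(hits: Sequence[ScanHit], path: PathLike, name: str = "site") -> None:
    """BED6+2: chrom, start, end, name, score, strand, score again, p-value.

    The p-value column preserves the ``"0.05+"`` sentinel verbatim; hits
    without p-values write '.'.
    """
    with open(path, "w") as fh:
        for h in hits:
            if h.p_value is None:
                pcol = "."
            elif isinstance(h.p_value, str):
                pcol = h.p_value
            else:
                pcol = f"{h.p_value:.6g}"
            bed_score = int(np.clip(round(h.score * 100), 0, 1000))
            fh.write(
                f"{h.seq_id}\t{h.start}\t{h.end}\t{name}\t{bed_score}\t{h.strand}\t"
                f"{h.score:.6g}\t{pcol}\n"
            )


def read_hits_bed(path: PathLike) -> List[ScanHit]:
    hits: List[ScanHit] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            p_value: Optional[Union[float, str]]
            if f[7] == ".":
                p_value = None
            elif f[7] == PVALUE_SENTINEL:
                p_value = PVALUE_SENTINEL
            else:
                p_value = float(f[7])
            hits.append(
                ScanHit(f[0], int(f[1]), int(f[2]), f[5], float(f[6]), p_value)
            )
    return hits


# ---------------------------------------------------------------- matrix files

_PAIR_LABELS = [a + b for a in ALPHABET for b in ALPHABET]


def write_matrix(
    pssm: PSSM,
    path: PathLike,
    name: str = "motif",
    meta: Optional[Dict[str, object]] = None,
) -> None:
    """Serialise a PSSM (scores, pair blocks, background) as tab-separated text."""
    with open(path, "w") as fh:
        fh.write("# lasagna-pssm v1\n")
        fh.write(f"# name: {name}\n")
        fh.write(f"# l: {pssm.l}\n")
        fh.write(f"# K: {pssm.K}\n")
        for key, value in (meta or {}).items():
            fh.write(f"# {key}: {value}\n")
        fh.write("# background: " + " ".join(f"{b:.17g}" for b in pssm.background) + "\n")
        for u, letter in enumerate(ALPHABET):
            fh.write(letter + "\t" + "\t".join(f"{v:.17g}" for v in pssm.scores[:, u]) + "\n")
        for k in sorted(pssm.pair_scores):
            fh.write(f"# pair k={k}\n")
            block = pssm.pair_scores[k]
            for idx, label in enumerate(_PAIR_LABELS):
                u, v = divmod(idx, 4)
                fh.write(
                    label + "\t" + "\t".join(f"{x:.17g}" for x in block[:, u, v]) + "\n"
                )


def read_matrix(path: PathLike) -> Tuple[PSSM, Dict[str, str]]:
    """Read the matrix dialect back into a PSSM plus its metadata strings."""
    meta: Dict[str, str] = {}
    background = None
    single: Dict[str, List[float]] = {}
    pair_blocks: Dict[int, Dict[str, List[float]]] = {}
    current_pair: Optional[int] = None
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if body.startswith("pair k="):
                    current_pair = int(body.split("=", 1)[1])
                    pair_blocks[current_pair] = {}
                elif ":" in body:
                    key, value = body.split(":", 1)
                    key, value = key.strip(), value.strip()
                    if key == "background":
                        background = np.array([float(x) for x in value.split()])
                    else:
                        meta[key] = value
                continue
            label, *values = line.split("\t")
            values = [float(v) for v in values]
            if current_pair is None:
                single[label] = values
            else:
                pair_blocks[current_pair][label] = values
    l = len(next(iter(single.values())))
    scores = np.column_stack([single[c] for c in ALPHABET])
    pair_scores = {}
    for k, block in pair_blocks.items():
        arr = np.empty((l - k, 4, 4))
        for idx, label in enumerate(_PAIR_LABELS):
            u, v = divmod(idx, 4)
            arr[:, u, v] = block[label]
        pair_scores[k] = arr
    return PSSM(scores, pair_scores, background), meta


def write_meme_minimal(
    probs: np.ndarray, path: PathLike, name: str = "motif",
    background: Optional[np.ndarray] = None, nsites: int = 20,
) -> None:
    """MEME minimal-format export of the single-letter probabilities only."""
    probs = np.asarray(probs, dtype=float)
    bg = np.full(4, 0.25) if background is None else np.asarray(background, dtype=float)
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write("Background letter frequencies\n")
        fh.write(" ".join(f"{c} {b:.5f}" for c, b in zip(ALPHABET, bg)) + "\n\n")
        fh.write(f"MOTIF {name}\n")
        fh.write(
            f"letter-probability matrix: alength= 4 w= {probs.shape[0]} "
            f"nsites= {nsites} E= 0\n"
        )
        for row in probs:
            fh.write(" ".join(f"{x:.6f}" for x in row) + "\n")


# -------------------------------------------------------------------- TSV misc


def write_truth_tsv(truth: pd.DataFrame, path: PathLike) -> None:
    truth.to_csv(path, sep="\t", index=False)


def read_truth_tsv(path: PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
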