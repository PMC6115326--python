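"""Double-strand promoter scanning for short cis-regulatory elements.

A motif is either an IUPAC consensus (matched with at most
``max_mismatches`` mismatches) or a position probability matrix (matched by
log-odds score against a uniform background, thresholded at a fraction of
the maximum attainable score).  Typical use is scanning 2-kb upstream
windows for a 16–17-nt root hair-specific element; the element itself is
always supplied by the user, never built in.

Offset convention: position 0 is the farthest-upstream base of the promoter
window, so position ``L − 1`` abuts the transcription start; reports also
carry ``distance_to_tss = L − offset − w`` for readability.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np

from typing import TYPE_CHECKING

if TYPE_CHECKING:  # pragma: no cover
    from .data_io import PromoterSet

#: IUPAC nucleotide codes → the set of concrete bases each matches.
IUPAC_CODES: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"),
    "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"),
    "S": frozenset("CG"), "W": frozenset("AT"),
    "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"),
    "H": frozenset("ACT"), "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


def reverse_complement(seq: str) -> str:
    """Reverse complement of a (possibly IUPAC-ambiguous) sequence."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class Motif:
    """A short cis-element, as an IUPAC consensus or a probability matrix.

    Exactly one of ``consensus`` / ``matrix`` must be given.  ``matrix`` is
    length × 4 (columns A, C, G, T) with rows summing to 1.
    """

    name: str = "motif"
    consensus: str | None = None
    matrix: np.ndarray | None = None
    max_mismatches: int = 0
    score_fraction: float = 0.85

    def __post_init__(self) -> None:
        if (self.consensus is None) == (self.matrix is None):
            raise ValueError("give exactly one of consensus or matrix")
        if self.consensus is not None:
            self.consensus = self.consensus.upper()
            bad = set(self.consensus) - set(IUPAC_CODES)
            if bad:
                raise ValueError(f"invalid IUPAC characters {sorted(bad)}")
        else:
            self.matrix = np.asarray(self.matrix, dtype=float)
            if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
                raise ValueError("matrix must be length × 4 (A, C, G, T)")
            if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-9):
                raise ValueError("matrix rows must each sum to 1")
            if not 0.0 < self.score_fraction <= 1.0:
                raise ValueError("score_fraction must be in (0, 1]")
        if not 4 <= len(self) <= 30:
            raise ValueError("motif length must be in [4, 30]")

    def __len__(self) -> int:
        return len(self.consensus) if self.consensus is not None \
            else self.matrix.shape[0]

    def max_probability_sequence(self) -> str:
        """The single highest-probability concrete sequence of the motif."""
        if self.consensus is not None:
            return "".join(sorted(IUPAC_CODES[c])[0] for c in self.consensus)
        return "".join("ACGT"[j] for j in self.matrix.argmax(axis=1))


class MotifHit(NamedTuple):
    gene_id: str
    offset: int          # leftmost base of the match on the forward strand
    strand: str          # '+' or '-'
    matched_sequence: str
    score: float         # mismatch count (consensus) or log-odds (matrix)


class ScanSummary(NamedTuple):
    total_hits: int
    genes_with_hit: int
    fraction_genes_with_hit: float


# ---------------------------------------------------------------------------
# scanning
# ---------------------------------------------------------------------------

def _encode(seq: str) -> np.ndarray:
    return np.fromiter((_BASE_INDEX[c] for c in seq), dtype=np.int8,
                       count=len(seq))


def _consensus_mismatch_counts(enc: np.ndarray, consensus: str) -> np.ndarray:
    """Mismatches of every window of ``enc`` against the consensus.

    An N in the promoter never matches any consensus position.
    """
    w = len(consensus)
    # allowed[pos, base] — base 4 (N) is never allowed
    allowed = np.zeros((w, 5), dtype=bool)
    for i, c in enumerate(consensus):
        for b in IUPAC_CODES[c]:
            allowed[i, _BASE_INDEX[b]] = True
    windows = np.lib.stride_tricks.sliding_window_view(enc, w)
    return (~allowed[np.arange(w), windows]).sum(axis=1)


def _matrix_scores(enc: np.ndarray, matrix: np.ndarray) -> np.ndarray:
    """Log-odds (base 2, uniform background) of every window; N scores −inf."""
    w = matrix.shape[0]
    with np.errstate(divide="ignore"):
        logodds = np.log2(matrix / 0.25)
    # pad an N column scoring -inf
    padded = np.hstack([logodds, np.full((w, 1), -np.inf)])
    windows = np.lib.stride_tricks.sliding_window_view(enc, w)
    return padded[np.arange(w), windows].sum(axis=1)


def scan_promoter(promoter: str, motif: Motif,
                  gene_id: str = "") -> list[MotifHit]:
    """Scan one promoter on both strands; hits sorted by offset, '+' first.

    A '−' strand hit at offset ``o`` means the reverse complement of the
    motif occurs at forward-strand positions ``[o, o + w)``.  A motif longer
    than the promoter yields an empty result.
    """
    promoter = promoter.upper()
    w = len(motif)
    L = len(promoter)
    if w > L:
        return []
    enc = _encode(promoter)
    hits: list[MotifHit] = []
    if motif.consensus is not None:
        for strand, pattern in (("+", motif.consensus),
                                ("-", reverse_complement(motif.consensus))):
            mm = _consensus_mismatch_counts(enc, pattern)
            for off in np.flatnonzero(mm <= motif.max_mismatches):
                off = int(off)
                hits.append(MotifHit(gene_id, off, strand,
                                     promoter[off:off + w], float(mm[off])))
    else:
        with np.errstate(divide="ignore"):
            max_score = np.log2(motif.matrix.max(axis=1) / 0.25).sum()
        threshold = motif.score_fraction * max_score
        rc_matrix = motif.matrix[::-1, ::-1]
        for strand, mat in (("+", motif.matrix), ("-", rc_matrix)):
            scores = _matrix_scores(enc, mat)
            for off in np.flatnonzero(scores >= threshold):
                off = int(off)
                hits.append(MotifHit(gene_id, off, strand,
                                     promoter[off:off + w],
                                     float(scores[off])))
    hits.sort(key=lambda h: (h.offset, h.strand))  # '+' < '-' in ASCII
    return hits


def scan_gene_set(promoters: "PromoterSet | Iterable[tuple[str, str]]",
                  motif: Motif) -> tuple[list[MotifHit], ScanSummary]:
    """Scan every promoter; summarize (total hits, genes with ≥1 hit, fraction)."""
    all_hits: list[MotifHit] = []
    n_genes = 0
    genes_with_hit = 0
    for gene_id, seq in promoters:
        n_genes += 1
        hits = scan_promoter(seq, motif, gene_id=gene_id)
        if hits:
            genes_with_hit += 1
        all_hits.extend(hits)
    fraction = genes_with_hit / n_genes if n_genes else 0.0
    return all_hits, ScanSummary(len(all_hits), genes_with_hit, fraction)


# ---------------------------------------------------------------------------
# motif file I/O
# ---------------------------------------------------------------------------

def read_motif(path: str | Path, max_mismatches: int = 0,
               score_fraction: float = 0.85) -> Motif:
    """Read a motif from a one-line IUPAC file or a minimal MEME file.

    Files containing a ``MEME version`` header are parsed as minimal MEME
    (letter-probability matrix) via Biopython; anything else is treated as a
    bare IUPAC consensus on the first non-comment line.
    """
    text = Path(path).read_text(encoding="utf-8")
    if "MEME version" in text:
        from Bio import motifs as bio_motifs

        with open(path, encoding="utf-8") as fh:
            records = bio_motifs.parse(fh, "minimal")
        record = records[0]
        counts = np.array([[record.counts[b][i] for b in "ACGT"]
                           for i in range(record.length)], dtype=float)
        matrix = counts / counts.sum(axis=1, keepdims=True)
        return Motif(name=record.name or "motif", matrix=matrix,
                     score_fraction=score_fraction)
    for line in text.splitlines():
        line = line.strip()
        if line and not line.startswith("#") and not line.startswith(">"):
            return Motif(name=Path(path).stem, consensus=line,
                         max_mismatches=max_mismatches)
    raise ValueError(f"no motif found in {path}")


def write_hits(hits: Sequence[MotifHit], promoter_lengths: dict[str, int],
               motif: Motif, path: str | Path) -> None:
    """Tab-separated hit report with a distance-to-TSS column."""
    w = len(motif)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("gene_id\toffset\tdistance_to_tss\tstrand\tsequence\tscore\n")
        for h in hits:
            dist = promoter_lengths[h.gene_id] - h.offset - w
            fh.write(f"{h.gene_id}\t{h.offset}\t{dist}\t{h.strand}\t"
                     f"{h.matched_sequence}\t{h.score:g}\n")
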