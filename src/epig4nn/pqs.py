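"""Genome-wide discovery of putative G-quadruplex-forming sequences (PQS).

Three broadened motif grammars are scanned on both strands:

* canonical — ``[G3+ L1-12]3+ G3+`` (four runs of >=3 G, loops of 1–12 nt,
  loop alphabet {A,T,C,G});
* bulged — ``[G N0-1 G N0-1 G L1-3]3+ G N0-1 G N0-1 G`` (G-runs broken by
  single non-G bulges, N in {A,T,C}, loops 1–3 nt);
* irregular — ``[G1-2 N1-2]7+ G1-2`` (short alternating G-runs).

Matches are found with conventional leftmost, non-overlapping, greedy regex
semantics. Every motif must contain at least 12 guanines (three stacked
tetrads). Overlapping or adjacent motifs across classes and strands are
resolved 5'-first: scanning each chromosome left to right, a motif is kept
only if it starts at least one nucleotide after the end of the last kept
motif.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence, Tuple

from .genomio import Genome, GenomicInterval, revcomp

MIN_G_COUNT = 12

MOTIF_CLASSES = ("canonical", "bulged", "irregular")

#: Precedence when motifs of different classes start at the same position.
CLASS_RANK = {"canonical": 0, "bulged": 1, "irregular": 2}

PATTERNS: Dict[str, "re.Pattern[str]"] = {
    "canonical": re.compile(r"(?:G{3,}[ACGT]{1,12}){3,}G{3,}"),
    "bulged": re.compile(r"(?:G[ACT]?G[ACT]?G[ACGT]{1,3}){3,}G[ACT]?G[ACT]?G"),
    "irregular": re.compile(r"(?:G{1,2}[ACT]{1,2}){7,}G{1,2}"),
}


@dataclass(frozen=True)
class PQSMotif:
    """A matched motif with its class, motif-strand sequence and G-count."""

    interval: GenomicInterval
    sequence: str
    motif_class: str
    g_count: int

    def __post_init__(self) -> None:
        if self.motif_class not in MOTIF_CLASSES:
            raise ValueError(f"unknown motif class {self.motif_class!r}")
        if self.interval.strand not in ("+", "-"):
            raise ValueError("PQS motifs must be stranded")
        if len(self.sequence) != len(self.interval):
            raise ValueError("sequence length must equal interval length")

    @property
    def motif_id(self) -> str:
        iv = self.interval
        return f"{iv.chrom}:{iv.start}-{iv.end}({iv.strand})"


def _find(pattern: "re.Pattern[str]", seq: str) -> List[Tuple[int, int]]:
    return [(m.start(), m.end()) for m in pattern.finditer(seq)]


def find_canonical(seq: str) -> List[Tuple[int, int]]:
    """Leftmost non-overlapping canonical matches in ``seq``."""
    return _find(PATTERNS["canonical"], seq)


def find_bulged(seq: str) -> List[Tuple[int, int]]:
    """Leftmost non-overlapping bulged matches in ``seq``."""
    return _find(PATTERNS["bulged"], seq)


def find_irregular(seq: str) -> List[Tuple[int, int]]:
    """Leftmost non-overlapping irregular matches in ``seq``."""
    return _find(PATTERNS["irregular"], seq)


def _sort_key(motif: PQSMotif) -> Tuple[int, int, int, int]:
    iv = motif.interval
    return (iv.start, CLASS_RANK[motif.motif_class], 0 if iv.strand == "+" else 1,
            -(iv.end))


def resolve_overlaps(motifs: Iterable[PQSMotif]) -> List[PQSMotif]:
    """5'-first resolution of overlapping or adjacent motifs.

    Per chromosome (strands pooled, forward coordinates), motifs are swept
    in ascending start order; a motif survives iff it is separated from the
    last surviving motif by at least one nucleotide (``start >= kept_end + 1``
    on half-open intervals). At equal starts, class precedence
    canonical > bulged > irregular, then '+' before '-', then the longer
    motif, decides who is encountered first. Sequences are never merged.
    """
    by_chrom: Dict[str, List[PQSMotif]] = {}
    for m in motifs:
        by_chrom.setdefault(m.interval.chrom, []).append(m)
    out: List[PQSMotif] = []
    for chrom in sorted(by_chrom):
        kept_end = None
        for m in sorted(by_chrom[chrom], key=_sort_key):
            if kept_end is None or m.interval.start >= kept_end + 1:
                out.append(m)
                kept_end = m.interval.end
    return out


def scan_genome(
    genome: Genome,
    classes: Sequence[str] = MOTIF_CLASSES,
    min_g: int = MIN_G_COUNT,
) -> List[PQSMotif]:
    """Scan both strands of a genome for PQS motifs.

    The plus strand is scanned on the forward sequence; the minus strand on
    the reverse complement, with match coordinates mapped back to
    forward-strand intervals. Motifs with fewer than ``min_g`` guanines
    (counted on the motif strand) are discarded, and the survivors are
    overlap-resolved 5'-first and returned sorted by (chrom, start).
    """
    for cls in classes:
        if cls not in MOTIF_CLASSES:
            raise ValueError(f"unknown motif class {cls!r}")
    candidates: List[PQSMotif] = []
    for chrom in genome.chroms():
        fwd = genome[chrom]
        rev = revcomp(fwd)
        n = len(fwd)
        for cls in classes:
            pattern = PATTERNS[cls]
            for s, e in _find(pattern, fwd):
                seq = fwd[s:e]
                g = seq.count("G")
                if g >= min_g:
                    candidates.append(
                        PQSMotif(GenomicInterval(chrom, s, e, "+"), seq, cls, g)
                    )
            for s, e in _find(pattern, rev):
                seq = rev[s:e]
                g = seq.count("G")
                if g >= min_g:
                    candidates.append(
                        PQSMotif(
                            GenomicInterval(chrom, n - e, n - s, "-"), seq, cls, g
                        )
                    )
    return resolve_overlaps(candidates)


def class_counts(motifs: Iterable[PQSMotif]) -> Dict[str, int]:
    """Per-class motif counts plus a total, as reported by the scanner CLI."""
    counts = {cls: 0 for cls in MOTIF_CLASSES}
    total = 0
    for m in motifs:
        counts[m.motif_class] += 1
        total += 1
    counts["total"] = total
    return counts
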