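"""Genomic file formats and coordinate primitives.

All coordinates in the package are 0-based half-open (the BED/bedGraph
native convention). This module is the single home for interval algebra,
genome sequence access and piecewise-constant signal tracks, plus the
FASTA / BED6 / bedGraph readers and writers the pipeline touches.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Iterator, List, Mapping, Sequence, Tuple

import numpy as np
from Bio import SeqIO

VALID_STRANDS = ("+", "-", ".")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_TO_N = str.maketrans(
    {c: "N" for c in "BDEFHIJKLMOPQRSUVWXYZ"}
)


def revcomp(seq: str) -> str:
    """Reverse complement of a sequence over {A,C,G,T,N}."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval [start, end) on ``chrom``.

    ``strand`` is one of ``+``, ``-`` or ``.`` (unstranded).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


class Genome:
    """Mapping from chromosome name to an upper-case {A,C,G,T,N} sequence."""

    def __init__(self, sequences: Mapping[str, str]):
        self._seqs: Dict[str, str] = {}
        for name, seq in sequences.items():
            s = seq.upper().translate(_TO_N)
            bad = set(s) - set("ACGTN")
            if bad:
                raise ValueError(f"chromosome {name} has invalid characters {bad}")
            self._seqs[name] = s

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._seqs

    def __getitem__(self, chrom: str) -> str:
        return self._seqs[chrom]

    def __iter__(self) -> Iterator[str]:
        return iter(self._seqs)

    def __len__(self) -> int:
        return len(self._seqs)

    def chroms(self) -> List[str]:
        return list(self._seqs)

    def length(self, chrom: str) -> int:
        return len(self._seqs[chrom])

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Exact sequence of [start, end); out-of-range access is an error."""
        seq = self._seqs[chrom]
        if start < 0 or end > len(seq) or start >= end:
            raise IndexError(
                f"range {chrom}:{start}-{end} outside chromosome of length {len(seq)}"
            )
        return seq[start:end]

    def fetch_padded(self, chrom: str, start: int, end: int) -> str:
        """Sequence of [start, end) with positions outside the chromosome as N."""
        seq = self._seqs[chrom]
        if start >= end:
            raise ValueError("start must be < end")
        left = max(0, -start)
        right = max(0, end - len(seq))
        core = seq[max(0, start):min(len(seq), end)]
        return "N" * left + core + "N" * right

    def fetch_interval(self, iv: GenomicInterval) -> str:
        """Motif-strand sequence of an interval (reverse-complemented for '-')."""
        s = self.fetch(iv.chrom, iv.start, iv.end)
        return revcomp(s) if iv.strand == "-" else s


class SignalTrack:
    """Per-chromosome piecewise-constant, non-negative signal.

    Runs are sorted, non-overlapping (start, end, value) triples; querying
    any position returns a value, 0.0 where no run covers it.
    """

    def __init__(
        self,
        runs: Mapping[str, Sequence[Tuple[int, int, float]]],
        normalized: bool = False,
    ):
        self._data: Dict[str, Tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, rs in runs.items():
            if len(rs) == 0:
                continue
            arr = sorted(rs)
            starts = np.array([r[0] for r in arr], dtype=np.int64)
            ends = np.array([r[1] for r in arr], dtype=np.int64)
            values = np.array([r[2] for r in arr], dtype=np.float64)
            if np.any(starts >= ends):
                raise ValueError(f"{chrom}: run with start >= end")
            if np.any(starts < 0):
                raise ValueError(f"{chrom}: negative run start")
            if np.any(values < 0):
                raise ValueError(f"{chrom}: negative signal value")
            if np.any(starts[1:] < ends[:-1]):
                raise ValueError(f"{chrom}: overlapping runs")
            self._data[chrom] = (starts, ends, values)
        self.normalized = normalized

    def chroms(self) -> List[str]:
        return list(self._data)

    def runs(self, chrom: str) -> List[Tuple[int, int, float]]:
        if chrom not in self._data:
            return []
        starts, ends, values = self._data[chrom]
        return [(int(s), int(e), float(v)) for s, e, v in zip(starts, ends, values)]

    def iter_runs(self) -> Iterator[Tuple[str, int, int, float]]:
        for chrom in self._data:
            for s, e, v in self.runs(chrom):
                yield chrom, s, e, v

    def value_at(self, chrom: str, pos: int) -> float:
        if chrom not in self._data:
            return 0.0
        starts, ends, values = self._data[chrom]
        i = int(np.searchsorted(starts, pos, side="right")) - 1
        if i >= 0 and pos < ends[i]:
            return float(values[i])
        return 0.0

    def mean(self, chrom: str, start: int, end: int) -> float:
        """Per-base mean over [start, end), uncovered positions counting as 0."""
        if start >= end:
            raise ValueError("start must be < end")
        if chrom not in self._data:
            return 0.0
        starts, ends, values = self._data[chrom]
        lo = int(np.searchsorted(ends, start, side="right"))
        hi = int(np.searchsorted(starts, end, side="left"))
        if lo >= hi:
            return 0.0
        ov = np.minimum(ends[lo:hi], end) - np.maximum(starts[lo:hi], start)
        return float(np.sum(ov * values[lo:hi]) / (end - start))

    def to_array(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Dense per-base values over [start, end); 0 outside coverage.

        ``start`` may be negative (positions before the chromosome read 0),
        so callers can expand windows that hang off the edge.
        """
        if start >= end:
            raise ValueError("start must be < end")
        out = np.zeros(end - start, dtype=np.float64)
        if chrom not in self._data:
            return out
        starts, ends, values = self._data[chrom]
        lo = int(np.searchsorted(ends, start, side="right"))
        hi = int(np.searchsorted(starts, end, side="left"))
        for s, e, v in zip(starts[lo:hi], ends[lo:hi], values[lo:hi]):
            out[max(s, start) - start:min(e, end) - start] = v
        return out

    def covers(self, chrom: str, start: int, end: int) -> bool:
        """True iff every position of [start, end) lies inside a run."""
        if start < 0:
            return False
        if chrom not in self._data:
            return False
        starts, ends, values = self._data[chrom]
        i = int(np.searchsorted(starts, start, side="right")) - 1
        if i < 0 or starts[i] > start:
            return False
        pos = start
        while pos < end:
            if i >= len(starts) or starts[i] > pos:
                return False
            pos = int(ends[i])
            i += 1
        return True

    def value_stats(self) -> Tuple[float, float]:
        """(min, max) over run values; (0, 0) for an empty track."""
        mins, maxs = [], []
        for starts, ends, values in self._data.values():
            mins.append(values.min())
            maxs.append(values.max())
        if not mins:
            return 0.0, 0.0
        return float(min(mins)), float(max(maxs))

    def covered_length(self) -> int:
        return int(
            sum((ends - starts).sum() for starts, ends, _ in self._data.values())
        )

    def background_mean(self) -> float:
        """Length-weighted mean signal over covered positions."""
        total, length = 0.0, 0
        for starts, ends, values in self._data.values():
            lens = ends - starts
            total += float((lens * values).sum())
            length += int(lens.sum())
        return total / length if length else 0.0

    def weighted_quantile(self, q: float) -> float:
        """Quantile of the per-base value distribution over covered positions."""
        pairs: List[Tuple[float, int]] = []
        for starts, ends, values in self._data.values():
            pairs.extend(zip(values.tolist(), (ends - starts).tolist()))
        if not pairs:
            return 0.0
        pairs.sort()
        vals = np.array([p[0] for p in pairs])
        weights = np.array([p[1] for p in pairs], dtype=np.float64)
        cum = np.cumsum(weights)
        # tiny shrink guards against float fuzz in q/100 * total
        target = q / 100.0 * cum[-1] * (1 - 1e-12)
        idx = int(np.searchsorted(cum, target, side="left"))
        return float(vals[min(idx, len(vals) - 1)])

    def map_values(self, fn, normalized: bool) -> "SignalTrack":
        """New track with ``fn`` applied to every run value."""
        runs = {
            chrom: [(s, e, fn(v)) for s, e, v in self.runs(chrom)]
            for chrom in self._data
        }
        return SignalTrack(runs, normalized=normalized)


def _data_lines(path: str) -> Iterator[Tuple[int, str]]:
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            yield lineno, line


def read_fasta(path: str) -> Genome:
    """Read a (multi-record) FASTA into a Genome.

    Sequences are upper-cased; IUPAC characters outside {A,C,G,T} collapse
    to N. Empty files and duplicate record ids are errors.
    """
    seqs: Dict[str, str] = {}
    for record in SeqIO.parse(path, "fasta"):
        if record.id in seqs:
            raise ValueError(f"duplicate FASTA record id {record.id!r}")
        seqs[record.id] = str(record.seq)
    if not seqs:
        raise ValueError(f"no FASTA records in {path}")
    return Genome(seqs)


def write_fasta(genome: Genome, path: str, line_width: int = 70) -> None:
    with open(path, "w") as fh:
        for chrom in genome.chroms():
            fh.write(f">{chrom}\n")
            seq = genome[chrom]
            for i in range(0, len(seq), line_width):
                fh.write(seq[i:i + line_width] + "\n")


def read_bedgraph(path: str) -> SignalTrack:
    """Read a UCSC 4-column bedGraph (0-based half-open) into a SignalTrack.

    Malformed lines, negative values, start >= end and overlapping runs are
    errors; comment/track lines are tolerated. An empty file yields a track
    reading 0.0 everywhere.
    """
    runs: Dict[str, List[Tuple[int, int, float]]] = {}
    for lineno, line in _data_lines(path):
        fields = line.split()
        if len(fields) != 4:
            raise ValueError(f"{path}:{lineno}: expected 4 columns, got {len(fields)}")
        chrom, start_s, end_s, value_s = fields
        try:
            start, end, value = int(start_s), int(end_s), float(value_s)
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: malformed bedGraph line") from exc
        if value < 0:
            raise ValueError(f"{path}:{lineno}: negative signal value")
        if start >= end:
            raise ValueError(f"{path}:{lineno}: start >= end")
        runs.setdefault(chrom, []).append((start, end, value))
    return SignalTrack(runs)


def write_bedgraph(track: SignalTrack, path: str) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, value in track.iter_runs():
            # shortest round-trippable float representation
            fh.write(f"{chrom}\t{start}\t{end}\t{value!r}\n")


def read_bed(path: str) -> List[GenomicInterval]:
    """Read BED3–BED6 into intervals; header/comment lines are skipped."""
    out: List[GenomicInterval] = []
    for lineno, line in _data_lines(path):
        fields = line.split()
        if len(fields) < 3:
            raise ValueError(f"{path}:{lineno}: expected >=3 BED columns")
        chrom, start, end = fields[0], int(fields[1]), int(fields[2])
        strand = fields[5] if len(fields) >= 6 else "."
        out.append(GenomicInterval(chrom, start, end, strand))
    return out


def write_bed(records: Iterable, path: str) -> None:
    """Write motifs or intervals as BED6.

    For PQS motifs the name column carries the motif class and the score
    column the motif's G-count; bare intervals get name '.' and score 0.
    """
    with open(path, "w") as fh:
        for rec in records:
            iv = getattr(rec, "interval", rec)
            name = getattr(rec, "motif_class", ".")
            score = getattr(rec, "g_count", 0)
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t{iv.strand}\n"
            )
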