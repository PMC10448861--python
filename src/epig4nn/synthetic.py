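"""Synthetic genomes, G4 score tracks and epigenetic tracks for testing.

The generator emulates the statistical structure the pipeline assumes:

* a small multi-chromosome genome with planted PQS of all three motif
  classes, half on the minus strand, whose background provably contains no
  unplanned motif on either strand, so the scanner's output equals the
  planted ground truth exactly;
* a G4 score track with a heavy mass at exactly zero and a high-score tail,
  so that upper-percentile labeling recovers the planted labels;
* epigenetic tracks whose peaks sit on positive motifs over a noise floor —
  including, optionally, sequence-identical motif pairs whose labels differ
  only through the track, so that sequence alone carries no signal for them.

Ground-truth exactness rests on two construction rules. Background
sequence caps G-runs (and, for the minus strand, C-runs) at two bases and
enforces a four-base G-free (C-free) cooldown after every run, which makes
all three grammars unmatchable in background and blocks any extension of a
planted motif across its flanks; segment boundaries carry A/T-only
margins. Motif samplers use A/T-only loops and spacers and are shaped so
the class the scanner's precedence rules assign is the planted class
(bulged samples carry at least two broken G-runs so no canonical sub-match
exists; irregular samples use two-base spacers the bulged grammar cannot
cross). Backgrounds are therefore slightly more G/C-sparse than the
nominal GC content.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .genomio import Genome, GenomicInterval, SignalTrack, revcomp
from .pqs import PQSMotif, scan_genome

_MIN_GAP = 20


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a synthetic study fixture.

    ``n_canonical``/``n_bulged``/``n_irregular`` are genome-wide planted
    counts (pair members included); ``paired_identical`` counts
    sequence-identical discordant pairs, drawn two at a time from the class
    pools. ``window_width`` is the encoding window the fixture is built
    for: identical pairs duplicate the whole window and chromosome ends
    keep at least half a window of background.
    """

    n_chroms: int = 4
    chrom_length: int = 20000
    gc_content: float = 0.4
    n_canonical: int = 10
    n_bulged: int = 10
    n_irregular: int = 10
    positive_fraction: float = 0.1
    epi_shape: str = "gaussian"
    epi_height: float = 0.8
    epi_width_nt: int = 300
    epi_noise_sd: float = 0.05
    g4_noise_floor: float = 0.05
    paired_identical: int = 0
    window_width: int = 250
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.positive_fraction < 1:
            raise ValueError("positive_fraction must be in (0, 1)")
        if self.epi_shape not in ("gaussian", "box"):
            raise ValueError("epi_shape must be 'gaussian' or 'box'")

    @property
    def n_motifs(self) -> int:
        return self.n_canonical + self.n_bulged + self.n_irregular

    def chrom_names(self) -> List[str]:
        return [f"chr{i + 1}" for i in range(self.n_chroms)]


# -- background ------------------------------------------------------------

def _background(rng: np.random.Generator, length: int, gc: float) -> str:
    """Motif-free background on both strands (see module docstring)."""
    p_gc = gc / 2.0
    p_at = (1.0 - gc) / 2.0
    uniforms = rng.random(length)
    chars = []
    grun = crun = gcool = ccool = 0
    for i in range(length):
        margin = i < 4 or i >= length - 4
        allowed = ["A", "T"]
        probs = [p_at, p_at]
        if not margin:
            if grun < 2 and gcool == 0:
                allowed.append("G")
                probs.append(p_gc)
            if crun < 2 and ccool == 0:
                allowed.append("C")
                probs.append(p_gc)
        r = uniforms[i] * sum(probs)
        acc = 0.0
        ch = allowed[-1]
        for a, p in zip(allowed, probs):
            acc += p
            if r < acc:
                ch = a
                break
        chars.append(ch)
        if ch == "G":
            grun += 1
            ccool = 4 if crun > 0 else max(0, ccool - 1)
            crun = 0
        elif ch == "C":
            crun += 1
            gcool = 4 if grun > 0 else max(0, gcool - 1)
            grun = 0
        else:
            gcool = 4 if grun > 0 else max(0, gcool - 1)
            ccool = 4 if crun > 0 else max(0, ccool - 1)
            grun = crun = 0
    return "".join(chars)


# -- motif samplers --------------------------------------------------------

def _loop(rng: np.random.Generator, lo: int, hi: int) -> str:
    n = int(rng.integers(lo, hi + 1))
    return "".join(rng.choice(["A", "T"], size=n))


def sample_canonical(rng: np.random.Generator) -> str:
    """Four G-runs of 3–4 G separated by 1–7 nt A/T loops."""
    parts = []
    for i in range(4):
        parts.append("G" * int(rng.integers(3, 5)))
        if i < 3:
            parts.append(_loop(rng, 1, 7))
    return "".join(parts)


def sample_bulged(rng: np.random.Generator) -> str:
    """Four 3-G units, at least two carrying a single A/T bulge."""
    bulged = rng.random(4) < 0.75
    while bulged.sum() < 2:
        bulged[int(rng.integers(0, 4))] = True
    parts = []
    for i in range(4):
        if bulged[i]:
            pos = int(rng.integers(0, 2))  # bulge after first or second G
            b = str(rng.choice(["A", "T"]))
            unit = "G" + b + "GG" if pos == 0 else "GG" + b + "G"
        else:
            unit = "GGG"
        parts.append(unit)
        if i < 3:
            parts.append(_loop(rng, 1, 3))
    return "".join(parts)


def sample_irregular(rng: np.random.Generator) -> str:
    """8–11 G-runs of 1–2 G with two-base A/T spacers, >= 12 G total."""
    while True:
        n_units = int(rng.integers(8, 12))
        runs = rng.integers(1, 3, size=n_units + 1)
        if runs.sum() >= 12:
            break
    parts = []
    for i, g in enumerate(runs):
        parts.append("G" * int(g))
        if i < n_units:
            parts.append(_loop(rng, 2, 2))
    return "".join(parts)


_SAMPLERS = {
    "canonical": sample_canonical,
    "bulged": sample_bulged,
    "irregular": sample_irregular,
}


# -- genome assembly -------------------------------------------------------

@dataclass
class _PlantUnit:
    seq: str            # forward-strand sequence inserted into the chromosome
    motif_offset: int   # motif start within seq
    motif_len: int
    motif_class: str
    strand: str
    pair_id: Optional[int] = None


def _make_units(spec: FixtureSpec, rng: np.random.Generator) -> List[_PlantUnit]:
    counts = {
        "canonical": spec.n_canonical,
        "bulged": spec.n_bulged,
        "irregular": spec.n_irregular,
    }
    units: List[_PlantUnit] = []
    # identical pairs duplicate the full encoding window plus margin
    for pair in range(spec.paired_identical):
        cls = ["canonical", "bulged", "irregular"][pair % 3]
        eligible = [c for c in counts if counts[c] >= 2]
        if cls not in eligible:
            if not eligible:
                raise ValueError("paired_identical exceeds planted motif budget")
            cls = eligible[0]
        counts[cls] -= 2
        strand = str(rng.choice(["+", "-"]))
        motif = _SAMPLERS[cls](rng)
        flank = max(spec.window_width - len(motif), 0)
        left = flank - flank // 2 + 8
        right = flank // 2 + 8
        block = (
            _background(rng, left, spec.gc_content)
            + (revcomp(motif) if strand == "-" else motif)
            + _background(rng, right, spec.gc_content)
        )
        for _ in range(2):
            units.append(
                _PlantUnit(block, left, len(motif), cls, strand, pair_id=pair)
            )
    singles: List[Tuple[str, str]] = []
    for cls, n in counts.items():
        if n < 0:
            raise ValueError("paired_identical exceeds planted motif budget")
        singles.extend((cls, "") for _ in range(n))
    rng.shuffle(singles)
    for cls, _ in singles:
        strand = str(rng.choice(["+", "-"]))
        motif = _SAMPLERS[cls](rng)
        seq = revcomp(motif) if strand == "-" else motif
        units.append(_PlantUnit(seq, 0, len(motif), cls, strand))
    order = rng.permutation(len(units))
    return [units[i] for i in order]


def _assemble_chrom(
    chrom: str,
    units: Sequence[_PlantUnit],
    spec: FixtureSpec,
    rng: np.random.Generator,
) -> Tuple[str, List[PQSMotif], Dict[int, List[int]]]:
    edge = spec.window_width // 2 + 10
    parts = [_background(rng, edge, spec.gc_content)]
    pos = edge
    motifs: List[PQSMotif] = []
    pair_members: Dict[int, List[int]] = {}
    for unit in units:
        start = pos + unit.motif_offset
        iv = GenomicInterval(chrom, start, start + unit.motif_len, unit.strand)
        forward = unit.seq[unit.motif_offset:unit.motif_offset + unit.motif_len]
        seq = revcomp(forward) if unit.strand == "-" else forward
        motifs.append(PQSMotif(iv, seq, unit.motif_class, seq.count("G")))
        if unit.pair_id is not None:
            pair_members.setdefault(unit.pair_id, []).append(len(motifs) - 1)
        parts.append(unit.seq)
        pos += len(unit.seq)
        gap = int(rng.integers(_MIN_GAP, 3 * _MIN_GAP))
        parts.append(_background(rng, gap, spec.gc_content))
        pos += gap
    if pos + edge > spec.chrom_length:
        raise ValueError(
            f"{chrom}: planting density infeasible "
            f"({pos + edge} nt needed, chrom_length={spec.chrom_length})"
        )
    parts.append(_background(rng, spec.chrom_length - pos, spec.gc_content))
    return "".join(parts), motifs, pair_members


def make_genome(
    spec: FixtureSpec, rng: Optional[np.random.Generator] = None
) -> Tuple[Genome, List[PQSMotif], List[Tuple[int, int]]]:
    """Build the fixture genome with its planted ground truth.

    Returns the genome, the planted motifs sorted by (chrom, start), and
    the index pairs of sequence-identical motifs. The assembled genome is
    verified against the scanner: found motifs must equal planted motifs on
    intervals, classes and strands.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    units = _make_units(spec, rng)
    names = spec.chrom_names()
    per_chrom: List[List[_PlantUnit]] = [[] for _ in names]
    for i, u in enumerate(units):
        per_chrom[i % len(names)].append(u)
    seqs: Dict[str, str] = {}
    motifs: List[PQSMotif] = []
    pair_members: Dict[int, List[int]] = {}
    for chrom, chrom_units in zip(names, per_chrom):
        seq, chrom_motifs, members = _assemble_chrom(chrom, chrom_units, spec, rng)
        seqs[chrom] = seq
        offset = len(motifs)
        motifs.extend(chrom_motifs)
        for pid, idxs in members.items():
            pair_members.setdefault(pid, []).extend(i + offset for i in idxs)
    genome = Genome(seqs)
    found = scan_genome(genome)
    expected = {
        (m.interval.chrom, m.interval.start, m.interval.end, m.interval.strand,
         m.motif_class)
        for m in motifs
    }
    got = {
        (m.interval.chrom, m.interval.start, m.interval.end, m.interval.strand,
         m.motif_class)
        for m in found
    }
    if expected != got:
        raise RuntimeError(
            "synthetic genome failed ground-truth verification: "
            f"{len(expected - got)} missing, {len(got - expected)} unplanned"
        )
    order = sorted(range(len(motifs)),
                   key=lambda i: (motifs[i].interval.chrom, motifs[i].interval.start))
    rank = {old: new for new, old in enumerate(order)}
    motifs = [motifs[i] for i in order]
    pairs = [tuple(sorted(rank[i] for i in idxs))
             for idxs in pair_members.values()]
    return genome, motifs, sorted(pairs)


def assign_labels(
    n_motifs: int,
    pairs: Sequence[Tuple[int, int]],
    positive_fraction: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """0/1 labels: one positive per identical pair, the rest sampled to
    reach the requested overall positive fraction."""
    labels = np.zeros(n_motifs, dtype=np.int64)
    paired = set()
    for a, b in pairs:
        pos = a if rng.random() < 0.5 else b
        labels[pos] = 1
        paired.update((a, b))
    target = int(round(positive_fraction * n_motifs))
    remaining = max(0, target - len(pairs))
    free = np.array([i for i in range(n_motifs) if i not in paired])
    if remaining > len(free):
        raise ValueError("positive_fraction infeasible with this pair count")
    if remaining:
        chosen = rng.choice(free, size=remaining, replace=False)
        labels[chosen] = 1
    return labels


def make_g4_signal(
    planted: Sequence[PQSMotif],
    labels: Sequence[int],
    spec: FixtureSpec,
    rng: Optional[np.random.Generator] = None,
) -> SignalTrack:
    """Experimental-score track: positives high, negatives mostly exactly 0.

    Positive motifs receive a constant run of value U(0.6, 1.0) over their
    interval; 20% of negatives get a small noise run below
    ``g4_noise_floor`` and the rest score exactly zero, reproducing the
    zero-inflated score distribution upper-percentile labeling assumes.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed + 1)
    runs: Dict[str, List[Tuple[int, int, float]]] = {}
    for m, label in zip(planted, labels):
        iv = m.interval
        if label == 1:
            v = float(rng.uniform(0.6, 1.0))
        elif spec.g4_noise_floor > 0 and rng.random() < 0.2:
            v = float(rng.uniform(0.0, spec.g4_noise_floor))
            if v == 0.0:
                continue
        else:
            continue
        runs.setdefault(iv.chrom, []).append((iv.start, iv.end, v))
    return SignalTrack(runs)


def make_epi_track(
    planted: Sequence[PQSMotif],
    labels: Sequence[int],
    spec: FixtureSpec,
    chrom_lengths: Dict[str, int],
    rng: Optional[np.random.Generator] = None,
) -> SignalTrack:
    """Epigenetic track: peaks on positive motifs over a noise floor.

    Every position carries |N(0, noise_sd)| noise; positive motifs add a
    peak of the configured shape (height at the motif midpoint, width
    ``epi_width_nt``); values are clipped to [0, 1] and the track covers
    every chromosome fully, so coverage filtering keeps all motifs.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed + 2)
    runs: Dict[str, List[Tuple[int, int, float]]] = {}
    by_chrom: Dict[str, List[Tuple[PQSMotif, int]]] = {}
    for m, label in zip(planted, labels):
        by_chrom.setdefault(m.interval.chrom, []).append((m, int(label)))
    for chrom, length in chrom_lengths.items():
        arr = np.abs(rng.normal(0.0, spec.epi_noise_sd, size=length)) \
            if spec.epi_noise_sd > 0 else np.zeros(length)
        for m, label in by_chrom.get(chrom, []):
            if label != 1:
                continue
            mid = (m.interval.start + m.interval.end) // 2
            if spec.epi_shape == "gaussian":
                sigma = spec.epi_width_nt / 6.0
                lo = max(0, mid - spec.epi_width_nt)
                hi = min(length, mid + spec.epi_width_nt + 1)
                x = np.arange(lo, hi)
                arr[lo:hi] += spec.epi_height * np.exp(
                    -0.5 * ((x - mid) / sigma) ** 2
                )
            else:
                lo = max(0, mid - spec.epi_width_nt // 2)
                hi = min(length, mid + spec.epi_width_nt // 2)
                arr[lo:hi] += spec.epi_height
        np.clip(arr, 0.0, 1.0, out=arr)
        # compress equal adjacent values into runs
        change = np.flatnonzero(np.diff(arr) != 0)
        starts = np.concatenate([[0], change + 1])
        ends = np.concatenate([change + 1, [length]])
        runs[chrom] = [
            (int(s), int(e), float(arr[s])) for s, e in zip(starts, ends)
        ]
    return SignalTrack(runs, normalized=True)


@dataclass
class Fixture:
    """A complete synthetic study: genome, ground truth, labels and tracks."""

    spec: FixtureSpec
    genome: Genome
    motifs: List[PQSMotif]
    pairs: List[Tuple[int, int]]
    labels: np.ndarray
    g4_track: SignalTrack
    epi_track: SignalTrack


def make_fixture(spec: FixtureSpec) -> Fixture:
    """End-to-end fixture construction, deterministic under ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    genome, motifs, pairs = make_genome(spec, rng)
    labels = assign_labels(len(motifs), pairs, spec.positive_fraction, rng)
    g4 = make_g4_signal(motifs, labels, spec, rng)
    lengths = {c: genome.length(c) for c in genome.chroms()}
    epi = make_epi_track(motifs, labels, spec, lengths, rng)
    return Fixture(spec, genome, motifs, pairs, labels, g4, epi)


def write_fixture(fixture: Fixture, outdir: str) -> None:
    """Write genome.fa, pqs_truth.bed, g4.bedgraph, epi.bedgraph, labels.tsv."""
    import os

    from .genomio import write_bed, write_bedgraph, write_fasta

    os.makedirs(outdir, exist_ok=True)
    write_fasta(fixture.genome, os.path.join(outdir, "genome.fa"))
    write_bed(fixture.motifs, os.path.join(outdir, "pqs_truth.bed"))
    write_bedgraph(fixture.g4_track, os.path.join(outdir, "g4.bedgraph"))
    write_bedgraph(fixture.epi_track, os.path.join(outdir, "epi.bedgraph"))
    with open(os.path.join(outdir, "labels.tsv"), "w") as fh:
        fh.write("motif_id\tclass\tlabel\n")
        for m, label in zip(fixture.motifs, fixture.labels):
            fh.write(f"{m.motif_id}\t{m.motif_class}\t{int(label)}\n")
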