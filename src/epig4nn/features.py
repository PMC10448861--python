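"""Turn PQS, experimental G4 signal and epigenetic tracks into training samples.

Each putative quadruplex sequence is scored by the per-base mean of the
experimental G4 bedGraph over its interval, labeled positive when its score
strictly exceeds an upper-percentile threshold, and encoded as a fixed-width
window (default 1000 nt) of one-hot sequence rows (A, T, C, G; N is the zero
vector) optionally stacked with one normalized epigenetic channel.
"""

from __future__ import annotations

import json
import logging
import math
import os
from dataclasses import dataclass, replace
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .genomio import Genome, GenomicInterval, SignalTrack, revcomp
from .pqs import PQSMotif

logger = logging.getLogger(__name__)

#: Channel order of the one-hot encoding (N encodes as the zero row).
BASE_ORDER = "ATCG"
_BASE_INDEX = {b: i for i, b in enumerate(BASE_ORDER)}


@dataclass(frozen=True)
class LabeledPQS:
    """A motif with its experimental G4 score and (optionally) its label."""

    motif: PQSMotif
    g4_score: float
    label: Optional[int] = None


@dataclass
class Sample:
    """One encoded training example.

    ``matrix`` has shape (W, C) with C = 4 (sequence only) or 5 (sequence
    plus one normalized epigenetic channel); values lie in [0, 1].
    """

    matrix: np.ndarray
    label: int
    window: GenomicInterval
    motif_id: str

    @property
    def chrom(self) -> str:
        return self.window.chrom


def score_pqs(motifs: Sequence[PQSMotif], g4_signal: SignalTrack) -> List[LabeledPQS]:
    """Score each motif by the per-base mean G4 signal over its interval.

    Positions without signal count as 0; a motif on a chromosome absent from
    the track scores 0.0. Labels are left unset.
    """
    out = []
    for m in motifs:
        iv = m.interval
        out.append(LabeledPQS(m, g4_signal.mean(iv.chrom, iv.start, iv.end)))
    return out


def percentile_threshold(scores: Sequence[float], upper_pct: float) -> float:
    """The (100 - upper_pct)-th percentile of the scores."""
    if not 0 < upper_pct < 100:
        raise ValueError("upper_pct must be in (0, 100)")
    if len(scores) == 0:
        raise ValueError("no scores")
    return float(np.percentile(np.asarray(scores, dtype=np.float64), 100 - upper_pct))


def label_by_percentile(
    scored: Sequence[LabeledPQS], upper_pct: float
) -> List[LabeledPQS]:
    """Label the upper ``upper_pct`` percentiles of scores as positive.

    The threshold is the (100 - upper_pct)-th percentile of all scores and
    the comparison is strict, so ties at the threshold are negative; with the
    typical heavy mass of exact zeros this selects the top-ranked nonzero
    scores.
    """
    t = percentile_threshold([s.g4_score for s in scored], upper_pct)
    return [replace(s, label=int(s.g4_score > t)) for s in scored]


def normalize_track(
    track: SignalTrack,
    clip_percentile: Optional[float] = None,
    genome: Optional[Genome] = None,
) -> SignalTrack:
    """Min–max normalize a track to [0, 1] genome-wide.

    Uncovered positions are treated as 0 before normalization; since a
    bedGraph does not declare chromosome extents, the minimum is taken as 0
    unless a genome is supplied and the track fully covers it, in which case
    the minimum over covered values is used. A constant fully-covering track
    (min == max) normalizes to all zeros. With ``clip_percentile`` set, the
    divisor is that per-base percentile of the covered values and values
    above it saturate at 1.0.
    """
    vmin_runs, vmax = track.value_stats()
    vmin = 0.0
    if genome is not None:
        full = all(
            chrom in track.chroms() and track.covers(chrom, 0, genome.length(chrom))
            for chrom in genome.chroms()
        )
        if full:
            vmin = vmin_runs
    if clip_percentile is not None:
        vmax = track.weighted_quantile(clip_percentile)
    if vmax <= vmin:
        return track.map_values(lambda v: 0.0, normalized=True)
    span = vmax - vmin
    return track.map_values(
        lambda v: min(max((v - vmin) / span, 0.0), 1.0), normalized=True
    )


def window_span(motif: PQSMotif, width: int) -> Tuple[int, int]:
    """Forward-axis (start, end) of the encoding window, unclipped.

    The motif is centered; of the ``width - len(motif)`` flanking
    nucleotides, the 5' side *on the motif strand* receives the ceiling
    half. The span may extend past chromosome bounds (N/zero padding
    happens at extraction time).
    """
    iv = motif.interval
    flank = width - len(iv)
    if flank < 0:
        raise ValueError(f"motif {motif.motif_id} longer than window width {width}")
    left5 = math.ceil(flank / 2)
    right3 = flank // 2
    if iv.strand == "-":
        return iv.start - right3, iv.end + left5
    return iv.start - left5, iv.end + right3


def coverage_filter(
    motifs: Sequence[PQSMotif],
    tracks: Sequence[SignalTrack],
    window: int,
) -> List[PQSMotif]:
    """Keep motifs whose full encoding window is covered by every track.

    Windows hanging off the chromosome start (or past the end of a track's
    runs) are not fully covered and are dropped, ensuring continuous data
    availability for every retained motif. With no tracks this is the
    identity.
    """
    if not tracks:
        return list(motifs)
    out = []
    for m in motifs:
        if len(m.interval) > window:
            continue
        ws, we = window_span(m, window)
        if all(t.covers(m.interval.chrom, ws, we) for t in tracks):
            out.append(m)
    return out


def one_hot(seq: str) -> np.ndarray:
    """One-hot encode a sequence as a (len, 4) matrix in A, T, C, G order.

    N encodes as the all-zero row; any other character is an error.
    """
    mat = np.zeros((len(seq), 4), dtype=np.float32)
    for i, base in enumerate(seq):
        if base == "N":
            continue
        try:
            mat[i, _BASE_INDEX[base]] = 1.0
        except KeyError:
            raise ValueError(f"invalid base {base!r} at position {i}") from None
    return mat


def build_window(
    motif: PQSMotif, genome: Genome, width: int = 1000
) -> Tuple[str, GenomicInterval]:
    """Motif-centered window sequence of length ``width`` on the motif strand.

    Chromosome edges pad with N. For minus-strand motifs the returned
    sequence is the reverse complement of the forward-strand extraction.
    The returned interval is the window clipped to the chromosome.
    """
    ws, we = window_span(motif, width)
    chrom = motif.interval.chrom
    seq = genome.fetch_padded(chrom, ws, we)
    if motif.interval.strand == "-":
        seq = revcomp(seq)
    window = GenomicInterval(
        chrom, max(0, ws), min(genome.length(chrom), we), motif.interval.strand
    )
    return seq, window


def assemble_samples(
    labeled: Sequence[LabeledPQS],
    genome: Genome,
    track: Optional[SignalTrack] = None,
    width: int = 1000,
) -> List[Sample]:
    """Encode labeled motifs into fixed-width sample matrices.

    Channels are the 4 one-hot sequence rows, plus, when a track is given,
    one channel of per-position normalized signal over the window (reversed
    for minus-strand motifs so it stays positionally aligned with the
    motif-strand sequence). Motifs longer than the window are skipped with a
    logged warning.
    """
    if track is not None and not track.normalized:
        raise ValueError("epigenetic track must be normalized before assembly")
    out: List[Sample] = []
    for item in labeled:
        if item.label is None:
            raise ValueError(f"motif {item.motif.motif_id} has no label")
        if len(item.motif.interval) > width:
            logger.warning(
                "skipping motif %s: longer than window width %d",
                item.motif.motif_id,
                width,
            )
            continue
        seq, window = build_window(item.motif, genome, width)
        mat = one_hot(seq)
        if track is not None:
            ws, we = window_span(item.motif, width)
            epi = track.to_array(item.motif.interval.chrom, ws, we)
            if item.motif.interval.strand == "-":
                epi = epi[::-1]
            mat = np.concatenate([mat, epi[:, None].astype(np.float32)], axis=1)
        out.append(Sample(mat, int(item.label), window, item.motif.motif_id))
    return out


def stack_samples(samples: Sequence[Sample]) -> Tuple[np.ndarray, np.ndarray]:
    """Stack samples into (N, W, C) inputs and an (N,) label vector."""
    X = np.stack([s.matrix for s in samples]).astype(np.float32)
    y = np.array([s.label for s in samples], dtype=np.int64)
    return X, y


def save_dataset(samples: Sequence[Sample], path: str, meta: Optional[dict] = None):
    """Persist samples as an .npz array bundle plus a JSON manifest."""
    os.makedirs(path, exist_ok=True)
    X, y = stack_samples(samples)
    chroms = np.array([s.chrom for s in samples])
    starts = np.array([s.window.start for s in samples], dtype=np.int64)
    ends = np.array([s.window.end for s in samples], dtype=np.int64)
    strands = np.array([s.window.strand for s in samples])
    ids = np.array([s.motif_id for s in samples])
    np.savez_compressed(
        os.path.join(path, "samples.npz"),
        X=X, y=y, chrom=chroms, start=starts, end=ends, strand=strands,
        motif_id=ids,
    )
    manifest = {
        "n_samples": len(samples),
        "width": int(X.shape[1]),
        "channels": int(X.shape[2]),
        "positives": int(y.sum()),
    }
    if meta:
        manifest.update(meta)
    with open(os.path.join(path, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)


def load_dataset(path: str) -> List[Sample]:
    data = np.load(os.path.join(path, "samples.npz"), allow_pickle=False)
    out = []
    for i in range(len(data["y"])):
        window = GenomicInterval(
            str(data["chrom"][i]), int(data["start"][i]), int(data["end"][i]),
            str(data["strand"][i]),
        )
        out.append(
            Sample(data["X"][i], int(data["y"][i]), window, str(data["motif_id"][i]))
        )
    return out
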