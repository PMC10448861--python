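"""Metagene-style signal profiles at G4 loci and per-nucleotide prediction tracks.

``mean_profile`` aggregates a normalized epigenetic track in anchor-centered
windows (column-wise mean across loci) against the genome-wide background
level; ``top_profiles`` ranks individual locus profiles by intensity for
heatmap-style analysis, and ``predict_track`` slides the trained classifier
across a region to emit a per-nucleotide probability pseudo-track.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .features import one_hot
from .genomio import Genome, GenomicInterval, SignalTrack
from .model import PredictiveModel


@dataclass
class ProfileMatrix:
    """Per-locus signal profiles: one row per anchor, columns -H..+H."""

    values: np.ndarray          # (n_anchors, 2H + 1)
    anchors: List[GenomicInterval]
    halfwidth: int

    def row_means(self) -> np.ndarray:
        return self.values.mean(axis=1)


def _anchor_center(iv: GenomicInterval) -> int:
    return (iv.start + iv.end) // 2


def profile_matrix(
    track: SignalTrack, anchors: Sequence[GenomicInterval], halfwidth: int
) -> ProfileMatrix:
    """Anchor-centered windows of the track, one row per anchor.

    The anchor is the interval midpoint (floor); windows span
    [mid - H, mid + H] inclusive (2H + 1 columns) on the forward strand and
    read 0 outside coverage or off the chromosome edge.
    """
    if not anchors:
        raise ValueError("no anchors")
    rows = np.empty((len(anchors), 2 * halfwidth + 1), dtype=np.float64)
    for i, iv in enumerate(anchors):
        mid = _anchor_center(iv)
        rows[i] = track.to_array(iv.chrom, mid - halfwidth, mid + halfwidth + 1)
    return ProfileMatrix(rows, list(anchors), halfwidth)


def mean_profile(
    track: SignalTrack, anchors: Sequence[GenomicInterval], halfwidth: int
) -> Tuple[np.ndarray, float]:
    """Column-wise mean signal around anchors, plus the genome-wide background.

    The background is the length-weighted mean of the track over covered
    positions, the dashed reference line of a metagene plot.
    """
    mat = profile_matrix(track, anchors, halfwidth)
    return mat.values.mean(axis=0), track.background_mean()


def top_profiles(
    track: SignalTrack,
    anchors: Sequence[GenomicInterval],
    halfwidth: int,
    n: int = 6000,
) -> ProfileMatrix:
    """The ``n`` highest-intensity locus profiles, sorted descending.

    Rows are ranked by per-row mean signal; ties keep anchor order (stable
    sort), and fewer than ``n`` anchors simply truncates.
    """
    mat = profile_matrix(track, anchors, halfwidth)
    order = np.argsort(-mat.row_means(), kind="stable")[:n]
    return ProfileMatrix(
        mat.values[order], [mat.anchors[i] for i in order], halfwidth
    )


def intensity_decay(matrix: ProfileMatrix) -> np.ndarray:
    """Mean intensity per rank of a sorted profile matrix (non-increasing)."""
    return matrix.row_means()


def predict_track(
    model: PredictiveModel,
    genome: Genome,
    region: GenomicInterval,
    track: Optional[SignalTrack] = None,
    width: Optional[int] = None,
    stride: int = 1,
    batch_size: int = 256,
) -> List[Tuple[str, int, int, float]]:
    """Per-nucleotide fold-probability pseudo-track over a region.

    For each position p (every ``stride``-th position; values are
    step-held in between), the model scores the ``width``-window whose
    forward-strand span is [p - width//2, p - width//2 + width), N/zero
    padded at chromosome edges. Returns merged bedGraph-style runs.
    """
    if width is None:
        width = model.config.input_width
    if (track is None) != (model.config.input_channels == 4):
        raise ValueError("track presence must match the model's input channels")
    if region.end > genome.length(region.chrom):
        raise ValueError("region outside chromosome")
    positions = list(range(region.start, region.end, stride))
    chrom = region.chrom
    probs = np.empty(len(positions), dtype=np.float64)
    for i0 in range(0, len(positions), batch_size):
        chunk = positions[i0:i0 + batch_size]
        mats = []
        for p in chunk:
            ws = p - width // 2
            seq = genome.fetch_padded(chrom, ws, ws + width)
            mat = one_hot(seq)
            if track is not None:
                epi = track.to_array(chrom, ws, ws + width)
                mat = np.concatenate(
                    [mat, epi[:, None].astype(np.float32)], axis=1
                )
            mats.append(mat)
        probs[i0:i0 + len(chunk)] = model.predict_proba(np.stack(mats))
    runs: List[Tuple[str, int, int, float]] = []
    for p, prob in zip(positions, probs):
        end = min(p + stride, region.end)
        if runs and runs[-1][3] == prob and runs[-1][2] == p:
            runs[-1] = (chrom, runs[-1][1], end, prob)
        else:
            runs.append((chrom, p, end, float(prob)))
    return runs
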