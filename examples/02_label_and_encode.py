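"""Score PQS against an experimental G4 track and encode training samples.

Each motif is scored by the per-base mean of the G4 bedGraph signal over
its interval; the upper percentiles of the scores become the positive
class. Samples are 250-position windows of one-hot sequence (A/T/C/G rows,
N = zero) stacked with the normalized epigenetic channel.
"""

import numpy as np

from epig4nn import (FixtureSpec, assemble_samples, label_by_percentile,
                     make_fixture, score_pqs)

fx = make_fixture(FixtureSpec(n_chroms=4, chrom_length=16000, n_canonical=14,
                              n_bulged=13, n_irregular=13,
                              positive_fraction=0.2, seed=2))

scored = score_pqs(fx.motifs, fx.g4_track)
labeled = label_by_percentile(scored, upper_pct=20)

scores = np.array([s.g4_score for s in scored])
labels = np.array([s.label for s in labeled])
print(f"{len(scored)} motifs scored; {np.mean(scores == 0):.0%} score exactly 0")
print(f"upper 20 percentiles labeled positive: {labels.sum()} motifs")
print(f"positive scores span [{scores[labels == 1].min():.3f}, "
      f"{scores[labels == 1].max():.3f}]")

samples = assemble_samples(labeled, fx.genome, fx.epi_track, width=250)
mat = samples[0].matrix
print(f"\nsample matrix: {mat.shape} (250 positions x 4 sequence + 1 track)")
print(f"one-hot rows sum to 1 per position: "
      f"{bool(np.all(mat[:, :4].sum(axis=1) <= 1))}")
print("The track channel is min-max normalized to [0,1] and reversed for"
      "\nminus-strand motifs so it stays aligned with the motif-strand "
      "sequence.")
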