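"""Chromosome-holdout training of the G4 classifier.

The test set holds complete chromosomes (by default 1, 3, 5, 7, 9) so that
no positional signal leaks between training and evaluation; one training
chromosome is set aside for validation. Because genome-scale datasets are
large, an epoch walks the training chromosomes in ascending name order and
one chromosome's shuffled, batched samples constitute one iteration. The
loss is class-weighted binary cross-entropy with weights computed once on
the full training set; the checkpoint with the best validation AUPRC is
retained.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, FrozenSet, List, Optional, Sequence, Tuple

import numpy as np

from .evaluation import pr_auc
from .features import Sample, stack_samples
from .model import PredictiveModel, class_weights
from .nn import Adam, weighted_bce_with_logits

DEFAULT_TEST_CHROMS = ("chr1", "chr3", "chr5", "chr7", "chr9")
DEFAULT_VALIDATION_CHROM = "chr22"


def _human_chroms(prefix: str = "chr") -> List[str]:
    return [f"{prefix}{i}" for i in range(1, 23)] + [f"{prefix}X", f"{prefix}Y"]


@dataclass(frozen=True)
class SplitSpec:
    """Chromosome-holdout split specification.

    ``test_chroms`` and ``train_chroms`` partition the data;
    ``validation_chrom`` names one member of the training set whose samples
    are carved out for validation (preserving the train/test firewall).
    """

    test_chroms: FrozenSet[str]
    train_chroms: FrozenSet[str]
    validation_chrom: Optional[str] = None

    def __post_init__(self) -> None:
        if self.test_chroms & self.train_chroms:
            raise ValueError("test and train chromosome sets overlap")
        if (
            self.validation_chrom is not None
            and self.validation_chrom not in self.train_chroms
        ):
            raise ValueError("validation chromosome must belong to the train set")

    @classmethod
    def default(cls, prefix: str = "chr") -> "SplitSpec":
        """The human split: test = {1,3,5,7,9}, train = the 19 others."""
        test = frozenset(f"{prefix}{i}" for i in (1, 3, 5, 7, 9))
        train = frozenset(_human_chroms(prefix)) - test
        return cls(test, train, f"{prefix}22")


@dataclass(frozen=True)
class TrainConfig:
    """Optimizer and loop settings; only the learning rate and batch size
    are method-prescribed, the rest are the canonical Adam defaults."""

    batch_size: int = 64
    learning_rate: float = 0.001
    epochs: int = 10
    seed: int = 0
    class_weighting: bool = True
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-7

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")


def chromosome_split(
    samples: Sequence[Sample], spec: SplitSpec
) -> Tuple[List[Sample], List[Sample], List[Sample]]:
    """Partition samples into (train, validation, test) by chromosome.

    Every sample's chromosome must appear in the spec; the three parts are
    disjoint and exhaustive.
    """
    train: List[Sample] = []
    val: List[Sample] = []
    test: List[Sample] = []
    for s in samples:
        if s.chrom in spec.test_chroms:
            test.append(s)
        elif s.chrom == spec.validation_chrom:
            val.append(s)
        elif s.chrom in spec.train_chroms:
            train.append(s)
        else:
            raise ValueError(f"chromosome {s.chrom} not covered by the split spec")
    return train, val, test


def train(
    model: PredictiveModel,
    train_samples: Sequence[Sample],
    val_samples: Sequence[Sample],
    cfg: TrainConfig,
) -> Tuple[PredictiveModel, Dict[str, list]]:
    """Train the classifier; returns the best-validation model and history.

    History records the mean weighted loss of every iteration (one training
    chromosome) and the validation AUPRC after every epoch. With a
    non-empty validation set the parameters giving the best validation
    AUPRC are restored before returning; with no validation samples the
    final parameters are kept.
    """
    if cfg.epochs > 0 and not train_samples:
        raise ValueError("empty training set")
    labels = np.array([s.label for s in train_samples], dtype=np.int64)
    if cfg.class_weighting and cfg.epochs > 0:
        w_neg, w_pos = class_weights(labels)
    else:
        w_neg, w_pos = 1.0, 1.0

    by_chrom: Dict[str, List[Sample]] = {}
    for s in train_samples:
        by_chrom.setdefault(s.chrom, []).append(s)
    chrom_order = sorted(by_chrom)
    stacked = {}
    for chrom in chrom_order:
        X, y = stack_samples(by_chrom[chrom])
        stacked[chrom] = (X.transpose(0, 2, 1), y)

    if val_samples:
        X_val, y_val = stack_samples(val_samples)

    rng = np.random.default_rng(cfg.seed)
    optimizer = Adam(model.layers(), lr=cfg.learning_rate,
                     beta1=cfg.beta1, beta2=cfg.beta2, eps=cfg.eps)
    history: Dict[str, list] = {"iteration_loss": [], "epoch_val_auprc": []}
    best_auprc, best_state = -np.inf, None

    for _epoch in range(cfg.epochs):
        for chrom in chrom_order:
            X, y = stacked[chrom]
            order = rng.permutation(len(y))
            losses = []
            for i in range(0, len(order), cfg.batch_size):
                idx = order[i:i + cfg.batch_size]
                xb, yb = X[idx], y[idx]
                wb = np.where(yb == 1, w_pos, w_neg)
                logits = model.forward_logits(xb, training=True)
                loss, dz = weighted_bce_with_logits(logits, yb, wb)
                model.backward(dz)
                optimizer.step()
                losses.append(loss)
            history["iteration_loss"].append(float(np.mean(losses)))
        if val_samples:
            probs = model.predict_proba(X_val)
            if 0 < y_val.sum() < len(y_val):
                _, auprc = pr_auc(probs, y_val)
            else:  # single-class validation chromosome: AUPRC undefined
                auprc = float("nan")
            history["epoch_val_auprc"].append(auprc)
            if auprc > best_auprc:
                best_auprc = auprc
                best_state = model.state_dict()

    if best_state is not None:
        model.load_state_dict(best_state)
    return model, history
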