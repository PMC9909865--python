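"""Alternating discriminator/generator optimization.

Each minibatch cycle draws 500 labeled, 500 unlabeled and 500 synthetic
variants (all sizes configurable), updates the discriminator on the sum of
the supervised cross-entropy and the unsupervised real/fake loss, then
updates the generator on the feature-matching loss against the same
unlabeled minibatch.  Both networks get their own Adam optimizer at the
same learning rate (default 0.0095).

An epoch is one pass over the unlabeled pool in ``unlabeled_batch``-sized
slices; labeled minibatches are re-drawn with replacement every step, with
the two classes sampled at equal probability when ``rebalance`` is on (the
labeled pool is ~1:3 imbalanced, and the resampling counteracts that).
Fresh generator noise is drawn for the discriminator and the generator
updates separately.  Everything is reproducible from the config seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from . import nn, sgan_core
from .feature_pipeline import EncodedMatrix
from .sgan_core import (Generator, Discriminator, GeneratorSpec,
                        DiscriminatorSpec)

__all__ = ["TrainingConfig", "TrainingHistory", "SGANModel",
           "SupervisedModel", "sample_labeled_minibatch",
           "select_label_budget", "train", "train_supervised"]


@dataclass(frozen=True)
class TrainingConfig:
    labeled_batch: int = 500
    unlabeled_batch: int = 500
    synthetic_batch: int = 500
    learning_rate: float = 0.0095
    adam_betas: tuple[float, float] = (0.9, 0.999)
    epochs: int = 2000
    seed: int = 0
    rebalance: bool = True

    def validate(self) -> None:
        if min(self.labeled_batch, self.unlabeled_batch, self.synthetic_batch) < 1:
            raise ValueError("batch sizes must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")
        if self.epochs < 0:
            raise ValueError("epochs must be non-negative")


@dataclass
class TrainingHistory:
    supervised: list[float] = field(default_factory=list)
    unsupervised: list[float] = field(default_factory=list)
    generator: list[float] = field(default_factory=list)

    def record(self, sup: float, unsup: float, gen: float) -> None:
        self.supervised.append(sup)
        self.unsupervised.append(unsup)
        self.generator.append(gen)

    @property
    def n_epochs(self) -> int:
        return len(self.supervised)


class SGANModel:
    """Trained generator + discriminator bound to a column manifest."""

    def __init__(self, generator: Generator, discriminator: Discriminator,
                 columns: list[str]) -> None:
        self.generator = generator
        self.discriminator = discriminator
        self.columns = list(columns)

    def _check(self, matrix: np.ndarray) -> np.ndarray:
        matrix = np.asarray(matrix, dtype=np.float64)
        if matrix.ndim != 2 or matrix.shape[1] != len(self.columns):
            raise ValueError(
                f"matrix has {matrix.shape[1] if matrix.ndim == 2 else '?'} "
                f"columns; the model manifest has {len(self.columns)}")
        return matrix

    def predict_proba(self, matrix: np.ndarray) -> np.ndarray:
        """(n, 2) class probabilities (benign, oncogenic), evaluation mode."""
        matrix = self._check(matrix)
        out = self.discriminator.forward(matrix, train=False)
        return sgan_core.class_probabilities(out.logits)


class SupervisedModel:
    """Discriminator trained with the supervised loss only (ablation)."""

    def __init__(self, discriminator: Discriminator, columns: list[str]) -> None:
        self.discriminator = discriminator
        self.columns = list(columns)

    predict_proba = SGANModel.predict_proba
    _check = SGANModel._check


def sample_labeled_minibatch(labels: np.ndarray, size: int, rebalance: bool,
                             rng: np.random.Generator) -> np.ndarray:
    """Indices of a labeled minibatch, drawn with replacement.

    With ``rebalance`` the class is tossed fairly per slot so the expected
    composition is 50/50 regardless of pool imbalance.
    """
    labels = np.asarray(labels)
    if rebalance:
        idx_by_class = [np.flatnonzero(labels == c) for c in (0, 1)]
        if any(len(ix) == 0 for ix in idx_by_class):
            raise ValueError("rebalanced sampling needs both classes present")
        cls = rng.integers(0, 2, size=size)
        out = np.empty(size, dtype=np.int64)
        for c in (0, 1):
            mask = cls == c
            pool = idx_by_class[c]
            out[mask] = pool[rng.integers(0, pool.size, size=int(mask.sum()))]
        return out
    return rng.integers(0, labels.size, size=size)


def select_label_budget(labeled: EncodedMatrix, budget: int,
                        rng: np.random.Generator) -> EncodedMatrix:
    """Subsample the labeled pool to ``budget`` rows, preserving the class
    ratio (rounded)."""
    if budget > labeled.n:
        raise ValueError(f"label budget {budget} exceeds pool size {labeled.n}")
    y = labeled.label_ints()
    pos = np.flatnonzero(y == 1)
    neg = np.flatnonzero(y == 0)
    n_pos = min(len(pos), max(1, round(budget * len(pos) / labeled.n)))
    n_neg = budget - n_pos
    idx = np.concatenate([rng.choice(pos, n_pos, replace=False),
                          rng.choice(neg, n_neg, replace=False)])
    return labeled.subset_rows(np.sort(idx))


def _check_labeled(labeled: EncodedMatrix) -> np.ndarray:
    y = labeled.label_ints()
    if (y < 0).any():
        raise ValueError("labeled set contains unlabeled rows")
    return y


def discriminator_step(model: SGANModel, optimizer: nn.Adam,
                       x_lab: np.ndarray, y_lab: np.ndarray,
                       x_unl: np.ndarray, x_fake: np.ndarray,
                       ) -> tuple[float, float]:
    """One Adam update of the discriminator on sup + unsup loss; returns the
    pre-update (sup, unsup) loss values.  Generator parameters untouched.

    The three minibatches ride one concatenated forward/backward pass; the
    discriminator treats rows independently, so this is exactly equivalent
    to three separate passes.
    """
    disc = model.discriminator
    disc.zero_grad()
    n_lab, n_unl = x_lab.shape[0], x_unl.shape[0]
    out = disc.forward(np.vstack([x_lab, x_unl, x_fake]), train=True)
    lab_logits = out.logits[:n_lab]
    unl_logits = out.logits[n_lab:n_lab + n_unl]
    fake_logits = out.logits[n_lab + n_unl:]
    sup, grad_sup = sgan_core.supervised_loss_grad(lab_logits, y_lab)
    unsup, grad_real, grad_fake = sgan_core.unsupervised_loss_grad(
        unl_logits, fake_logits)
    disc.backward(grad_logits=np.vstack([grad_sup, grad_real, grad_fake]))
    optimizer.step()
    return sup, unsup


def generator_step(model: SGANModel, optimizer: nn.Adam,
                   x_unl: np.ndarray, n_fake: int,
                   rng: np.random.Generator) -> float:
    """One Adam update of the generator on the feature-matching loss against
    the real (unlabeled) minibatch.  Discriminator parameters untouched;
    gradients that flow through the discriminator are discarded."""
    gen, disc = model.generator, model.discriminator
    gen.zero_grad()
    disc.zero_grad()
    n_unl = x_unl.shape[0]
    fake = gen.sample(n_fake, rng)
    out = disc.forward(np.vstack([x_unl, fake]), train=True)
    real = sgan_core.DiscriminatorOutput(out.logits[:n_unl],
                                         out.features[:n_unl])
    fake_out = sgan_core.DiscriminatorOutput(out.logits[n_unl:],
                                             out.features[n_unl:])
    value, grad_feat = sgan_core.feature_matching_loss_grad(real, fake_out)
    # the real rows are constants of the generator objective
    grad_x = disc.backward(grad_features=np.vstack(
        [np.zeros_like(real.features), grad_feat]))
    gen.backward(grad_x[n_unl:])
    optimizer.step()
    disc.zero_grad()
    return value


def _steps_per_epoch(n_unlabeled: int, batch: int) -> int:
    return max(1, math.ceil(n_unlabeled / batch))


def train(labeled: EncodedMatrix, unlabeled: EncodedMatrix,
          config: TrainingConfig,
          gen_spec: GeneratorSpec | None = None,
          disc_spec: DiscriminatorSpec | None = None,
          ) -> tuple[SGANModel, TrainingHistory]:
    """Full alternating training; returns the model and per-epoch history."""
    config.validate()
    if labeled.columns != unlabeled.columns:
        raise ValueError("labeled and unlabeled matrices use different manifests")
    y = _check_labeled(labeled)
    if config.rebalance and len(np.unique(y)) < 2:
        raise ValueError("rebalanced sampling needs both classes in the pool")

    dim = labeled.matrix.shape[1]
    gen_spec = replace(gen_spec or GeneratorSpec(), output_dim=dim)
    disc_spec = replace(disc_spec or DiscriminatorSpec(), input_dim=dim)

    ss = np.random.SeedSequence(config.seed).spawn(3)
    generator = Generator(gen_spec, np.random.default_rng(ss[0]))
    discriminator = Discriminator(disc_spec, np.random.default_rng(ss[1]))
    rng = np.random.default_rng(ss[2])
    model = SGANModel(generator, discriminator, labeled.columns)

    opt_d = nn.Adam(discriminator.parameters(), lr=config.learning_rate,
                    betas=config.adam_betas)
    opt_g = nn.Adam(generator.parameters(), lr=config.learning_rate,
                    betas=config.adam_betas)

    x_lab, x_unl_all = labeled.matrix, unlabeled.matrix
    n_unl = x_unl_all.shape[0]
    steps = _steps_per_epoch(n_unl, config.unlabeled_batch)
    history = TrainingHistory()

    for _epoch in range(config.epochs):
        perm = rng.permutation(n_unl)
        sup_sum = unsup_sum = gen_sum = 0.0
        for s in range(steps):
            sl = perm[s * config.unlabeled_batch:(s + 1) * config.unlabeled_batch]
            if sl.size == 0:
                sl = perm[:config.unlabeled_batch]
            x_unl = x_unl_all[sl]
            lab_idx = sample_labeled_minibatch(
                y, config.labeled_batch, config.rebalance, rng)
            x_fake = generator.sample(config.synthetic_batch, rng)
            sup, unsup = discriminator_step(
                model, opt_d, x_lab[lab_idx], y[lab_idx], x_unl, x_fake)
            gen_loss = generator_step(model, opt_g, x_unl,
                                      config.synthetic_batch, rng)
            sup_sum += sup
            unsup_sum += unsup
            gen_sum += gen_loss
        history.record(sup_sum / steps, unsup_sum / steps, gen_sum / steps)
    return model, history


def train_supervised(labeled: EncodedMatrix, config: TrainingConfig,
                     disc_spec: DiscriminatorSpec | None = None,
                     n_steps: int | None = None,
                     ) -> tuple[SupervisedModel, TrainingHistory]:
    """Matched supervised-only baseline: the same discriminator architecture
    trained on labeled minibatches only (no generator, no unlabeled data).

    ``n_steps`` defaults to epochs x one nominal step per epoch; pass the
    SGAN run's total step count for a compute-matched comparison.
    """
    config.validate()
    y = _check_labeled(labeled)
    if config.rebalance and len(np.unique(y)) < 2:
        raise ValueError("rebalanced sampling needs both classes in the pool")
    dim = labeled.matrix.shape[1]
    disc_spec = replace(disc_spec or DiscriminatorSpec(), input_dim=dim)
    ss = np.random.SeedSequence(config.seed).spawn(3)
    discriminator = Discriminator(disc_spec, np.random.default_rng(ss[1]))
    rng = np.random.default_rng(ss[2])
    model = SupervisedModel(discriminator, labeled.columns)
    opt = nn.Adam(discriminator.parameters(), lr=config.learning_rate,
                  betas=config.adam_betas)
    steps = config.epochs if n_steps is None else n_steps
    history = TrainingHistory()
    for _ in range(steps):
        idx = sample_labeled_minibatch(y, config.labeled_batch,
                                       config.rebalance, rng)
        discriminator.zero_grad()
        out = discriminator.forward(labeled.matrix[idx], train=True)
        sup, grad = sgan_core.supervised_loss_grad(out.logits, y[idx])
        discriminator.backward(grad_logits=grad)
        opt.step()
        history.record(sup, 0.0, 0.0)
    return model, history
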