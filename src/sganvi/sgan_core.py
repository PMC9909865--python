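"""Generator/discriminator networks and the adversarial loss quantities.

The discriminator is a two-logit network: softmax over the two logits gives
the benign/oncogenic class probabilities, while the same logits double as a
real-vs-synthetic detector through

    D(x) = Z(x) / (Z(x) + 1),    Z(x) = exp(l1) + exp(l2).

This is the K+1-class trick with the synthetic-class logit pinned at zero:
appending a third logit fixed at 0 and taking a 3-way softmax gives a
synthetic-class probability of exactly 1 - D(x), so no extra output unit is
needed.  The discriminator minimizes supervised cross-entropy plus the
unsupervised real/fake loss; the generator minimizes feature matching — the
squared distance between mean intermediate-layer activations of real and
generated minibatches.

All log/exp arithmetic is routed through log-sum-exp so that extreme logits
neither overflow nor lose the gradient.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp, softmax

from . import nn

__all__ = [
    "GeneratorSpec",
    "DiscriminatorSpec",
    "Generator",
    "Discriminator",
    "DiscriminatorOutput",
    "class_probabilities",
    "supervised_loss",
    "real_fake_probability",
    "unsupervised_loss",
    "discriminator_loss",
    "feature_matching_loss",
]

N_INPUT = 71  # 12 evidence scores one-hot over 4 levels + 23 continuous scores


@dataclass
class GeneratorSpec:
    """Architecture of the noise-to-variant generator.

    Four linear maps; each hidden one is followed by batch normalization, a
    leaky rectifier and dropout.  The output passes through tanh and the
    affine map (t+1)/2 so synthetic features land in [0, 1], the range of
    the min-max-scaled real features.
    """

    noise_dim: int = 100
    hidden_sizes: tuple[int, ...] = (128, 256, 512)
    output_dim: int = N_INPUT
    leaky_slope: float = 0.2
    dropout_rate: float = 0.6
    dtype: str = "float64"


@dataclass
class DiscriminatorSpec:
    """Three 1-d convolution stages over the feature vector, then a linear
    head mapping the flattened (and rectified) feature map to two logits."""

    input_dim: int = N_INPUT
    channels: tuple[int, ...] = (32, 64, 128)
    kernel: int = 3
    stride: int = 2
    leaky_slope: float = 0.2
    feature_source: str = "penultimate"  # "penultimate" | "logits"
    dtype: str = "float64"


@dataclass
class DiscriminatorOutput:
    """Two class logits plus the intermediate features used for matching."""

    logits: np.ndarray    # (batch, 2)
    features: np.ndarray  # (batch, n_features)


class Generator:
    def __init__(self, spec: GeneratorSpec, rng: np.random.Generator) -> None:
        self.spec = spec
        dtype = np.dtype(spec.dtype).type
        layers: list[nn.Layer] = []
        prev = spec.noise_dim
        for width in spec.hidden_sizes:
            layers += [
                nn.Linear(prev, width, rng, dtype=dtype),
                nn.BatchNorm1d(width, dtype=dtype),
                nn.LeakyReLU(spec.leaky_slope),
                nn.Dropout(spec.dropout_rate),
            ]
            prev = width
        layers += [nn.Linear(prev, spec.output_dim, rng, dtype=dtype), nn.Tanh()]
        self.net = nn.Sequential(*layers)

    def forward(self, z: np.ndarray, train: bool = True,
                rng: np.random.Generator | None = None) -> np.ndarray:
        z = np.asarray(z)
        if z.ndim != 2 or z.shape[1] != self.spec.noise_dim:
            raise ValueError(
                f"noise must be (batch, {self.spec.noise_dim}), got {z.shape}")
        t = self.net.forward(z, train=train, rng=rng)
        return (t + 1.0) / 2.0

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        dtype = self.net.layers[0].weight.value.dtype
        return self.net.backward(np.asarray(grad_out, dtype=dtype) / 2.0)

    def parameters(self) -> list[nn.Parameter]:
        return self.net.parameters()

    def zero_grad(self) -> None:
        self.net.zero_grad()

    def sample(self, n: int, rng: np.random.Generator,
               train: bool = True) -> np.ndarray:
        """Draw n standard-Gaussian noise vectors and push them through."""
        z = rng.standard_normal((n, self.spec.noise_dim))
        return self.forward(z, train=train, rng=rng)


class Discriminator:
    def __init__(self, spec: DiscriminatorSpec, rng: np.random.Generator) -> None:
        self.spec = spec
        dtype = np.dtype(spec.dtype).type
        layers: list[nn.Layer] = []
        prev_ch, length = 1, spec.input_dim
        for ch in spec.channels:
            conv = nn.Conv1d(prev_ch, ch, spec.kernel, spec.stride, rng,
                             dtype=dtype)
            layers += [conv, nn.LeakyReLU(spec.leaky_slope)]
            length = conv._out_length(length)
            if length < 1:
                raise ValueError("input too short for the convolution stack")
            prev_ch = ch
        layers.append(nn.Flatten())
        self.trunk = nn.Sequential(*layers)
        self.n_features = prev_ch * length
        self.head = nn.Linear(self.n_features, 2, rng, dtype=dtype)

    def forward(self, x: np.ndarray, train: bool = True,
                rng: np.random.Generator | None = None) -> DiscriminatorOutput:
        x = np.asarray(x)
        if x.ndim != 2 or x.shape[1] != self.spec.input_dim:
            raise ValueError(
                f"input must be (batch, {self.spec.input_dim}), got {x.shape}")
        feats = self.trunk.forward(x[:, None, :], train=train, rng=rng)
        logits = self.head.forward(feats, train=train, rng=rng)
        features = logits if self.spec.feature_source == "logits" else feats
        return DiscriminatorOutput(logits=logits, features=features)

    def backward(self, grad_logits: np.ndarray | None = None,
                 grad_features: np.ndarray | None = None) -> np.ndarray:
        """Backprop through head and trunk; returns gradient w.r.t. the
        (batch, input_dim) input.  Either gradient may be omitted."""
        grad_feats = np.zeros((grad_logits.shape[0] if grad_logits is not None
                               else grad_features.shape[0], self.n_features),
                              dtype=self.head.weight.value.dtype)
        dtype = self.head.weight.value.dtype
        if grad_logits is not None:
            grad_feats += self.head.backward(np.asarray(grad_logits, dtype=dtype))
        if grad_features is not None:
            if self.spec.feature_source == "logits":
                grad_feats += self.head.backward(
                    np.asarray(grad_features, dtype=dtype))
            else:
                grad_feats += np.asarray(grad_features, dtype=dtype)
        grad_x = self.trunk.backward(grad_feats)
        return grad_x[:, 0, :]

    def parameters(self) -> list[nn.Parameter]:
        return self.trunk.parameters() + self.head.parameters()

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()


# ---------------------------------------------------------------------------
# Loss quantities.  Each has a value form and (where training needs it) a
# companion returning the gradient with respect to its logit inputs.
# ---------------------------------------------------------------------------

def class_probabilities(logits: np.ndarray) -> np.ndarray:
    """Softmax over the two logits: column 0 = benign, column 1 = oncogenic."""
    logits = np.atleast_2d(np.asarray(logits, dtype=np.float64))
    return softmax(logits, axis=1)


def supervised_loss(logits: np.ndarray, labels: np.ndarray) -> float:
    """Mean cross-entropy -log p(y_true | x) over a labeled batch.

    ``labels`` is an integer vector with 0 = benign, 1 = oncogenic.
    """
    value, _ = supervised_loss_grad(logits, labels)
    return value


def supervised_loss_grad(logits: np.ndarray,
                         labels: np.ndarray) -> tuple[float, np.ndarray]:
    logits = np.atleast_2d(np.asarray(logits, dtype=np.float64))
    labels = np.asarray(labels)
    if logits.shape[0] == 0:
        raise ValueError("empty labeled batch")
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be 0 (benign) or 1 (oncogenic); "
                         "unlabeled rows are not allowed here")
    n = logits.shape[0]
    log_z = logsumexp(logits, axis=1)
    value = float(np.mean(log_z - logits[np.arange(n), labels]))
    grad = softmax(logits, axis=1)
    grad[np.arange(n), labels] -= 1.0
    return value, grad / n


def real_fake_probability(logits: np.ndarray) -> np.ndarray:
    """D(x) = Z/(Z+1) with Z = exp(l1) + exp(l2), evaluated stably.

    log D = lse(l1, l2) - lse(l1, l2, 0); large logits give D -> 1, very
    negative logits give D -> 0 (the sample looks synthetic).
    """
    logits = np.atleast_2d(np.asarray(logits, dtype=np.float64))
    log_d = _log_d(logits)
    return np.exp(log_d)


def _log_d(logits: np.ndarray) -> np.ndarray:
    padded = np.concatenate([logits, np.zeros((logits.shape[0], 1))], axis=1)
    return logsumexp(logits, axis=1) - logsumexp(padded, axis=1)


def _log_one_minus_d(logits: np.ndarray) -> np.ndarray:
    padded = np.concatenate([logits, np.zeros((logits.shape[0], 1))], axis=1)
    return -logsumexp(padded, axis=1)


def unsupervised_loss(real_logits: np.ndarray, fake_logits: np.ndarray) -> float:
    """-{ E log D(x_real) + E log(1 - D(G(z))) }, minibatch means."""
    value, _, _ = unsupervised_loss_grad(real_logits, fake_logits)
    return value


def unsupervised_loss_grad(
    real_logits: np.ndarray, fake_logits: np.ndarray,
) -> tuple[float, np.ndarray, np.ndarray]:
    real_logits = np.atleast_2d(np.asarray(real_logits, dtype=np.float64))
    fake_logits = np.atleast_2d(np.asarray(fake_logits, dtype=np.float64))
    if real_logits.shape[0] == 0 or fake_logits.shape[0] == 0:
        raise ValueError("both batches must be non-empty")
    value = float(-np.mean(_log_d(real_logits))
                  - np.mean(_log_one_minus_d(fake_logits)))
    # d(-log D)/dl_i = softmax3_i - softmax2_i ; d(-log(1-D))/dl_i = softmax3_i
    def _sm3(lg):
        padded = np.concatenate([lg, np.zeros((lg.shape[0], 1))], axis=1)
        return softmax(padded, axis=1)[:, :2]

    grad_real = (_sm3(real_logits) - softmax(real_logits, axis=1)) / real_logits.shape[0]
    grad_fake = _sm3(fake_logits) / fake_logits.shape[0]
    return value, grad_real, grad_fake


def discriminator_loss(sup: float, unsup: float) -> float:
    """L = L_supervised + L_unsupervised, unweighted."""
    return sup + unsup


def feature_matching_loss(real: DiscriminatorOutput,
                          fake: DiscriminatorOutput) -> float:
    value, _ = feature_matching_loss_grad(real, fake)
    return value


def feature_matching_loss_grad(
    real: DiscriminatorOutput, fake: DiscriminatorOutput,
) -> tuple[float, np.ndarray]:
    """||E f(x_real) - E f(G(z))||_2^2 and its gradient w.r.t. the fake
    batch's feature rows (the real batch is treated as constant)."""
    fr, ff = real.features, fake.features
    if fr.shape[0] == 0 or ff.shape[0] == 0:
        raise ValueError("both batches must be non-empty")
    if fr.shape[1] != ff.shape[1]:
        raise ValueError(
            f"feature dimensionality mismatch: {fr.shape[1]} vs {ff.shape[1]}")
    diff = fr.mean(axis=0) - ff.mean(axis=0)
    value = float(diff @ diff)
    grad_fake_features = np.broadcast_to(
        -2.0 * diff / ff.shape[0], ff.shape).copy()
    return value, grad_fake_features
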