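"""Compact CNN decoder and the cross-experiment training harness.

The network follows the EEGNet-4,2 layer stack: a temporal convolution bank,
a max-norm-constrained depthwise spatial convolution, and a separable
convolution, each followed by batch normalization, ELU, average pooling and
dropout, ending in a two-class softmax. Training pools epochs from several
experiments and uses multiplicative class x experiment sample weights so each
(class, experiment) cell contributes equally to the loss.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import _nn
from . import constants as C
from .preprocess import EpochSet

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ModelConfig:
    n_channels: int = 64
    n_samples: int = 128
    n_classes: int = 2
    n_temporal_filters: int = C.N_TEMPORAL_FILTERS          # F1
    temporal_kernel_len: int = C.TEMPORAL_KERNEL_LEN
    depth_multiplier: int = C.DEPTH_MULTIPLIER              # D
    separable_kernel_len: int = C.SEPARABLE_KERNEL_LEN
    pool1: int = C.POOL1
    pool2: int = C.POOL2
    dropout_p: float = C.DROPOUT_P

    @property
    def n_separable_filters(self) -> int:  # F2 = F1 * D
        return self.n_temporal_filters * self.depth_multiplier

    def __post_init__(self) -> None:
        if self.temporal_kernel_len > self.n_samples:
            raise ValueError(
                f"temporal kernel ({self.temporal_kernel_len}) longer than input "
                f"({self.n_samples} samples)"
            )
        if self.n_samples % (self.pool1 * self.pool2):
            raise ValueError("n_samples must be divisible by pool1*pool2")
        if self.dropout_p < 0 or self.dropout_p >= 1:
            raise ValueError("dropout_p must be in [0, 1)")


class Decoder:
    """An (initially untrained) decoder: parameters + batch-norm state."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        self.config = config
        self.seed = seed
        rng = np.random.default_rng(seed)
        self.params = _nn.init_params(config, rng)
        self.bn_state = _nn.init_bn_state(config)

    def n_parameters(self) -> int:
        return _nn.n_parameters(self.params)

    def predict_proba(self, x: np.ndarray, chunk: int = 128) -> np.ndarray:
        """Class probabilities (n, 2) in inference mode; column 1 is the target class."""
        x = np.asarray(x, dtype=np.float32)
        if x.ndim == 2:
            x = x[None]
        out = np.empty((x.shape[0], self.config.n_classes))
        for i in range(0, x.shape[0], chunk):
            out[i : i + chunk], _ = _nn.forward(
                x[i : i + chunk], self.params, self.bn_state, self.config, training=False
            )
        return out

    def copy(self) -> "Decoder":
        dup = Decoder.__new__(Decoder)
        dup.config = self.config
        dup.seed = self.seed
        dup.params = {k: v.copy() for k, v in self.params.items()}
        dup.bn_state = {k: v.copy() for k, v in self.bn_state.items()}
        return dup


@dataclass
class TrainedDecoder:
    """A decoder plus the manifest describing how it was fit."""

    config: ModelConfig
    weights: dict
    bn_state: dict
    training_manifest: dict

    def predict_proba(self, x: np.ndarray, chunk: int = 128) -> np.ndarray:
        dec = Decoder.__new__(Decoder)
        dec.config = self.config
        dec.params = self.weights
        dec.bn_state = self.bn_state
        return Decoder.predict_proba(dec, x, chunk=chunk)

    @property
    def loss_history(self) -> list[float]:
        return self.training_manifest["loss_history"]


def build_model(config: ModelConfig, seed: int = 0) -> Decoder:
    """Instantiate the network with framework-style random initialization."""
    return Decoder(config, seed=seed)


def compute_sample_weights(
    labels: np.ndarray, experiment_ids: Sequence[str] | np.ndarray
) -> np.ndarray:
    """Inverse-proportion class x experiment weights with equal cell sums.

    Every (class, experiment) cell receives weight anchor/count_cell, where the
    anchor is the largest per-experiment majority-class count. Hence the sum of
    weights is identical in every cell ("each class and experiment contributes
    equally"), the majority class of the anchoring experiment gets weight 1,
    and a single experiment with a 1:4 target:background mix yields target
    weight 4 and background weight 1. When all experiments share the same class
    mix this equals the product of a majority-anchored class weight and an
    experiment-size weight.
    """
    labels = np.asarray(labels)
    experiment_ids = np.asarray(experiment_ids)
    if labels.shape != experiment_ids.shape:
        raise ValueError("labels and experiment_ids must align")
    classes = np.unique(labels)
    exps = np.unique(experiment_ids)
    cell_counts: dict[tuple, int] = {}
    for e in exps:
        in_e = experiment_ids == e
        for c in classes:
            n_ce = int(np.sum(in_e & (labels == c)))
            if n_ce == 0:
                raise ValueError(f"no trials for class {c!r} in experiment {e!r}")
            cell_counts[(e, c)] = n_ce
    anchor = max(
        max(cell_counts[(e, c)] for c in classes) for e in exps
    )
    weights = np.empty(len(labels), dtype=float)
    for (e, c), n_ce in cell_counts.items():
        weights[(experiment_ids == e) & (labels == c)] = anchor / n_ce
    return weights


def pool_epochs(epoch_sets: Sequence[EpochSet]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Concatenate epoch sets into (X, y, experiment_ids)."""
    xs, ys, es = [], [], []
    for ep in epoch_sets:
        if len(ep) == 0:
            continue
        xs.append(ep.data)
        ys.append(ep.labels)
        es.append(ep.meta["experiment"].to_numpy())
    if not xs:
        raise ValueError("empty training pool")
    return np.concatenate(xs), np.concatenate(ys), np.concatenate(es)


def train(
    decoder: Decoder,
    x: np.ndarray,
    y: np.ndarray,
    sample_weights: np.ndarray,
    n_iterations: int = C.N_TRAIN_ITERATIONS,
    batch_size: int = C.BATCH_SIZE,
    seed: int = 0,
    experiments: Sequence[str] = (),
) -> TrainedDecoder:
    """Fit with Adam on weighted categorical cross-entropy.

    ``n_iterations`` counts full passes (epochs) over the pool. The returned
    manifest records the experiments used, the seed and the per-pass loss.
    """
    x = np.asarray(x, dtype=np.float32)
    y = np.asarray(y, dtype=np.int64)
    if len(x) == 0:
        raise ValueError("empty training pool")
    if len(np.unique(y)) < 2:
        raise ValueError("training pool must contain both classes")
    sample_weights = np.asarray(sample_weights, dtype=float)

    dec = decoder.copy()
    rng = np.random.default_rng(seed)
    opt = _nn.Adam(list(dec.params.keys()))
    loss_history: list[float] = []
    n = len(x)
    for _ in range(n_iterations):
        order = rng.permutation(n)
        losses, batch_ns = [], []
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            probs, cache = _nn.forward(
                x[idx], dec.params, dec.bn_state, dec.config, training=True, drop_rng=rng
            )
            loss, dlogits = _nn.weighted_ce_loss_grad(probs, y[idx], sample_weights[idx])
            grads = _nn.backward(dlogits, dec.params, cache, dec.config)
            opt.step(dec.params, grads)
            _nn.apply_constraints(dec.params)
            losses.append(loss)
            batch_ns.append(len(idx))
        loss_history.append(float(np.average(losses, weights=batch_ns)))
    manifest = {
        "experiments": sorted(set(map(str, experiments))),
        "n_trials": int(n),
        "n_iterations": int(n_iterations),
        "batch_size": int(batch_size),
        "seed": int(seed),
        "loss_history": loss_history,
        "final_loss": loss_history[-1] if loss_history else None,
    }
    return TrainedDecoder(dec.config, dec.params, dec.bn_state, manifest)


def train_on_epochs(
    decoder: Decoder,
    epoch_sets: Sequence[EpochSet],
    n_iterations: int = C.N_TRAIN_ITERATIONS,
    batch_size: int = C.BATCH_SIZE,
    seed: int = 0,
) -> TrainedDecoder:
    """Pool epoch sets, derive sample weights, and fit."""
    x, y, exps = pool_epochs(epoch_sets)
    w = compute_sample_weights(y, exps)
    for e in np.unique(exps):
        for c in np.unique(y):
            sel = (exps == e) & (y == c)
            logger.info(
                "sample weights: experiment=%s class=%d n=%d weight=%.4f",
                e, c, int(sel.sum()), float(w[sel][0]),
            )
    return train(
        decoder, x, y, w,
        n_iterations=n_iterations, batch_size=batch_size, seed=seed,
        experiments=list(np.unique(exps)),
    )


def train_leave_one_experiment_out(
    epoch_sets_by_experiment: Mapping[str, Sequence[EpochSet]],
    heldout_experiment_id: str,
    config: ModelConfig | None = None,
    n_iterations: int = C.N_TRAIN_ITERATIONS,
    batch_size: int = C.BATCH_SIZE,
    seed: int = 0,
) -> TrainedDecoder:
    """Train on every experiment except the held-out one.

    Sample weights are computed on the training pool only; the manifest lists
    exactly the training experiments.
    """
    if heldout_experiment_id not in epoch_sets_by_experiment:
        raise KeyError(f"held-out experiment {heldout_experiment_id!r} not in pool")
    train_ids = [e for e in epoch_sets_by_experiment if e != heldout_experiment_id]
    if not train_ids:
        raise ValueError("need at least 2 experiments for leave-one-experiment-out")
    pool = [ep for e in train_ids for ep in epoch_sets_by_experiment[e]]
    x, y, exps = pool_epochs(pool)
    if heldout_experiment_id in set(exps):
        raise ValueError("held-out trials leaked into the training pool")
    cfg = config or ModelConfig(n_channels=pool[0].data.shape[1], n_samples=pool[0].data.shape[2])
    decoder = build_model(cfg, seed=seed)
    w = compute_sample_weights(y, exps)
    trained = train(
        decoder, x, y, w,
        n_iterations=n_iterations, batch_size=batch_size, seed=seed,
        experiments=train_ids,
    )
    trained.training_manifest["heldout_experiment"] = heldout_experiment_id
    return trained
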