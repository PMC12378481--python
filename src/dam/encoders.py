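"""Cellular and tumor-marker aggregators.

Both encoders turn an irregularly sampled observation stream into a
masked, time-stamped sequence of D-dimensional embeddings:

* cellular aggregator — an 18-layer residual CNN extracts per-crop
  features; attention pooling with a learnable aggregation token fuses
  the variable-size cell set of each timepoint (stage 1); continuous
  sinusoidal time encodings are added and a self-attention block
  refines the sequence across timepoints (stage 2, length-preserving);
* marker aggregator — a two-layer perceptron embeds each standardised
  six-marker panel, then the same two-stage attention recipe runs
  across timepoints.

Marker standardisation is log1p followed by per-marker z-scoring with
statistics fitted on training folds only; missing values are imputed
with training-fold medians before the transform.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cohort import MARKER_NAMES, CellObservation, MarkerObservation
from .nn.autograd import Tensor, concat, stack
from .nn.layers import Linear, Module, PoolingAttention, ResNet18, TransformerBlock

__all__ = ["ModelConfig", "SequenceEmbedding", "MarkerScaler", "time_encode",
           "CellEncoder", "MarkerEncoder"]


@dataclass(frozen=True)
class ModelConfig:
    embed_dim: int = 128
    n_heads: int = 4
    cnn_width: int = 16          # base channels of the 18-layer residual CNN
    marker_hidden: int = 64
    dropout: float = 0.0
    max_cells: int = 64          # padding cap for per-timepoint cell sets
    seed: int = 0

    def __post_init__(self):
        if self.embed_dim % self.n_heads:
            raise ValueError("embed_dim must be divisible by n_heads")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0,1)")


@dataclass
class SequenceEmbedding:
    """Masked, time-stamped stack of per-timepoint embeddings.

    ``vectors`` is a (T, D) autograd tensor; rows with ``mask`` false are
    all-zero padding and inert to every consumer.
    """

    vectors: Tensor
    times: np.ndarray
    mask: np.ndarray
    modality: str = "cells"

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        T = self.vectors.shape[0]
        if not (len(self.times) == len(self.mask) == T) or T < 1:
            raise ValueError("inconsistent sequence lengths")

    @property
    def n_real(self) -> int:
        return int(self.mask.sum())

    def padded(self, T: int) -> "SequenceEmbedding":
        """Zero-pad to length T (mask false on the new rows)."""
        T0, D = self.vectors.shape
        if T < T0:
            raise ValueError("cannot pad to a shorter length")
        if T == T0:
            return self
        pad = Tensor(np.zeros((T - T0, D)))
        return SequenceEmbedding(
            vectors=concat([self.vectors, pad], axis=0),
            times=np.concatenate([self.times, np.zeros(T - T0)]),
            mask=np.concatenate([self.mask, np.zeros(T - T0, bool)]),
            modality=self.modality)


def time_encode(t_days: float, D: int,
                tau_min: float = 1.0, tau_max: float = 1000.0) -> np.ndarray:
    """Continuous sinusoidal encoding of days-since-baseline.

    D/2 timescales geometrically spaced from `tau_min` to `tau_max`
    days; even slots sin(t/τ), odd slots cos(t/τ). Bounded in [-1, 1]
    and well defined for any finite t, so irregular (and negative,
    pre-baseline) sampling times are handled uniformly.
    """
    if not np.isfinite(t_days):
        raise ValueError("time must be finite")
    k = D // 2
    taus = tau_min * (tau_max / tau_min) ** (np.arange(k) / max(k - 1, 1))
    enc = np.empty(D)
    enc[0::2] = np.sin(t_days / taus)
    enc[1::2] = np.cos(t_days / taus)
    return enc


class MarkerScaler:
    """log1p + per-marker z-score; statistics from training folds only."""

    def __init__(self):
        self.median_: np.ndarray | None = None
        self.mean_: np.ndarray | None = None
        self.sd_: np.ndarray | None = None

    def fit(self, panels: list) -> "MarkerScaler":
        raw = np.array([p.as_array() for p in panels])  # (n, 6), NaN = missing
        if raw.size == 0:
            raise ValueError("cannot fit scaler on zero panels")
        self.median_ = np.nanmedian(raw, axis=0)
        self.median_ = np.where(np.isnan(self.median_), 0.0, self.median_)
        filled = np.where(np.isnan(raw), self.median_, raw)
        logged = np.log1p(filled)
        self.mean_ = logged.mean(axis=0)
        sd = logged.std(axis=0, ddof=0)
        self.sd_ = np.where(sd < 1e-12, 1.0, sd)
        return self

    def transform(self, panel) -> np.ndarray:
        if self.mean_ is None:
            raise RuntimeError("scaler not fitted")
        raw = panel.as_array()
        filled = np.where(np.isnan(raw), self.median_, raw)
        return (np.log1p(filled) - self.mean_) / self.sd_


class CellEncoder(Module):
    """CNN feature extraction + two-stage attention over a cell stream."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        D = cfg.embed_dim
        self.cfg = cfg
        self.cnn = ResNet18(cfg.cnn_width, D, rng)
        self.pool = PoolingAttention(D, cfg.n_heads, rng)
        self.stage2 = TransformerBlock(D, cfg.n_heads, rng)

    # -- per-image ----------------------------------------------------
    def extract_cell_features(self, img: np.ndarray) -> Tensor:
        """Project one preprocessed crop (H, W, 3) to a D-vector."""
        arr = np.asarray(img, dtype=float)
        if not np.isfinite(arr).all():
            raise ValueError("non-finite pixels in input image")
        x = Tensor(arr.transpose(2, 0, 1)[None])
        return self.cnn(x).reshape(self.cfg.embed_dim)

    def pooled_cnn_features(self, imgs: np.ndarray) -> np.ndarray:
        """Pooled (pre-projection) CNN features for (n, H, W, 3) crops.

        Returned as a plain array — this is the cache the frozen-CNN
        training path stores per timepoint.
        """
        x = Tensor(np.asarray(imgs, dtype=float).transpose(0, 3, 1, 2))
        return self.cnn.pooled(x).data

    # -- per-timepoint ------------------------------------------------
    def aggregate_cells(self, cell_vectors: Tensor) -> Tensor:
        """Fuse an (n, D) cell set into one D-vector (permutation-invariant)."""
        if cell_vectors.shape[0] == 0:
            raise ValueError("empty timepoint: no cells to aggregate")
        return self.pool(cell_vectors)

    def cell_importances(self) -> np.ndarray:
        """Softmax weights over cells from the most recent aggregation."""
        return self.pool.member_weights()

    # -- per-stream ---------------------------------------------------
    def encode_stream(self, per_tp: list, pooled: bool = False,
                      pad_to: int | None = None) -> SequenceEmbedding:
        """Encode [(t_days, features)] into a SequenceEmbedding.

        `features` is (n_cells, H, W, 3) preprocessed pixels, or — when
        ``pooled`` — a cached (n_cells, 8w) pooled-CNN feature matrix.
        With ``pad_to`` the sequence is zero-padded (mask false) before
        the cross-time stage, which is mask-aware and length-preserving.
        Importance weights of each timepoint's cell set are kept in
        ``last_importances``.
        """
        if not per_tp:
            raise ValueError("empty cell stream")
        D = self.cfg.embed_dim
        rows = []
        self.last_importances = []
        for t, feats in per_tp:
            if len(feats) > self.cfg.max_cells:  # per-timepoint set cap
                feats = feats[: self.cfg.max_cells]
            if pooled:
                vecs = self.cnn.fc(Tensor(np.asarray(feats, dtype=float)))
            else:
                x = Tensor(np.asarray(feats, dtype=float).transpose(0, 3, 1, 2))
                vecs = self.cnn(x)
            agg = self.aggregate_cells(vecs)
            self.last_importances.append(self.cell_importances())
            rows.append(agg + Tensor(time_encode(t, D)))
        T = len(per_tp)
        times = np.array([t for t, _ in per_tp], dtype=float)
        mask = np.ones(T, dtype=bool)
        if pad_to is not None and pad_to > T:
            rows += [Tensor(np.zeros(D))] * (pad_to - T)
            times = np.concatenate([times, np.zeros(pad_to - T)])
            mask = np.concatenate([mask, np.zeros(pad_to - T, bool)])
        seq = stack(rows, axis=0)
        out = self.stage2(seq, key_mask=mask)
        out = out * Tensor(mask[:, None].astype(float))
        return SequenceEmbedding(vectors=out, times=times, mask=mask,
                                 modality="cells")


class MarkerEncoder(Module):
    """Panel MLP + two-stage attention over the marker stream."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        D = cfg.embed_dim
        self.cfg = cfg
        self.fc1 = Linear(len(MARKER_NAMES), cfg.marker_hidden, rng)
        self.fc2 = Linear(cfg.marker_hidden, D, rng)
        self.stage1 = TransformerBlock(D, cfg.n_heads, rng)
        self.stage2 = TransformerBlock(D, cfg.n_heads, rng)
        self.scaler = MarkerScaler()

    def embed_panel(self, panel) -> Tensor:
        z = self.scaler.transform(panel)
        return self.fc2(self.fc1(Tensor(z)).relu())

    def encode_stream(self, obs: list,
                      pad_to: int | None = None) -> SequenceEmbedding:
        if not obs:
            raise ValueError("empty marker stream")
        D = self.cfg.embed_dim
        rows = [self.embed_panel(o.panel) + Tensor(time_encode(o.t_days, D))
                for o in obs]
        T = len(obs)
        times = np.array([o.t_days for o in obs], dtype=float)
        mask = np.ones(T, dtype=bool)
        if pad_to is not None and pad_to > T:
            rows += [Tensor(np.zeros(D))] * (pad_to - T)
            times = np.concatenate([times, np.zeros(pad_to - T)])
            mask = np.concatenate([mask, np.zeros(pad_to - T, bool)])
        seq = stack(rows, axis=0)
        out = self.stage2(self.stage1(seq, key_mask=mask), key_mask=mask)
        out = out * Tensor(mask[:, None].astype(float))
        return SequenceEmbedding(vectors=out, times=times, mask=mask,
                                 modality="markers")
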