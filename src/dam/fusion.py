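"""Temporal interaction, patient-level aggregation, and prediction.

The temporal interaction module (TIM) aligns the two asynchronously
sampled streams by cross-attention: cellular timepoint embeddings act
as queries over the marker timepoint embeddings (keys/values), and the
attended marker context is added residually to the cellular stream —
so the fused sequence keeps the cellular time axis. The temporal
aggregator then collapses the sequence into one patient vector with a
learnable patient token attending through four stacked self-attention
layers, and a three-layer MLP produces the two-class logits.

Variant dispatch mirrors the published ablations: ``tim`` (full
model), ``tci_only`` (images only), ``tm_only`` (markers only), and
patient-vector-level ``concat`` / ``sum`` fusion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cohort import PatientRecord
from .encoders import (CellEncoder, MarkerEncoder, ModelConfig,
                       SequenceEmbedding)
from .imageprep import AugmentConfig, preprocess_eval
from .nn.autograd import Tensor, concat
from .nn.layers import (LayerNorm, Linear, Module, MultiHeadAttention,
                        TransformerBlock)

__all__ = ["FusionConfig", "Prediction", "TemporalInteraction",
           "TemporalAggregator", "PredictorHead", "DAMNet", "FUSION_MODES"]

FUSION_MODES = ("tim", "tci_only", "tm_only", "concat", "sum")


@dataclass(frozen=True)
class FusionConfig:
    mode: str = "tim"
    n_layers_temporal: int = 4
    cells_query_markers: bool = True  # cross-attention direction

    def __post_init__(self):
        if self.mode not in FUSION_MODES:
            raise ValueError(f"mode must be one of {FUSION_MODES}")


@dataclass(frozen=True)
class Prediction:
    logits: np.ndarray            # (2,): [non-responder, responder]
    prob_responder: float

    @property
    def probs(self) -> np.ndarray:
        z = self.logits - self.logits.max()
        e = np.exp(z)
        return e / e.sum()


class TemporalInteraction(Module):
    """Cross-attention alignment of the two streams (mask-aware)."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        D = cfg.embed_dim
        self.ln_q = LayerNorm(D)
        self.ln_kv = LayerNorm(D)
        self.attn = MultiHeadAttention(D, cfg.n_heads, rng)

    def __call__(self, queries: SequenceEmbedding,
                 keys: SequenceEmbedding) -> SequenceEmbedding:
        ctx = self.attn(self.ln_q(queries.vectors),
                        self.ln_kv(keys.vectors), key_mask=keys.mask)
        fused = queries.vectors + ctx
        fused = fused * Tensor(queries.mask[:, None].astype(float))
        return SequenceEmbedding(vectors=fused, times=queries.times,
                                 mask=queries.mask, modality="fused")


class TemporalAggregator(Module):
    """Patient token + stacked self-attention layers; returns the token."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator,
                 n_layers: int = 4):
        D = cfg.embed_dim
        from .nn.layers import Parameter
        self.token = Parameter(rng.normal(0.0, 0.02, size=(1, D)))
        self.layers = [TransformerBlock(D, cfg.n_heads, rng)
                       for _ in range(n_layers)]

    def __call__(self, seq: SequenceEmbedding) -> Tensor:
        if seq.n_real == 0:
            raise ValueError("cannot aggregate a fully masked sequence")
        x = concat([self.token, seq.vectors], axis=0)
        mask = np.concatenate([[True], seq.mask])
        for layer in self.layers:
            x = layer(x, key_mask=mask)
        return x[0]


class PredictorHead(Module):
    """Three-layer MLP D → D/2 → D/4 → 2 with ReLU between."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        D = cfg.embed_dim
        self.fc1 = Linear(D, max(D // 2, 2), rng)
        self.fc2 = Linear(max(D // 2, 2), max(D // 4, 2), rng)
        self.fc3 = Linear(max(D // 4, 2), 2, rng)

    def __call__(self, feature: Tensor) -> Tensor:
        return self.fc3(self.fc2(self.fc1(feature).relu()).relu())


class DAMNet(Module):
    """The full dynamic-aware network over one patient's record.

    ``forward_streams`` consumes already-encoded inputs (used by the
    training loop, which handles elimination/augmentation/caching);
    ``predict_record`` is the turnkey inference path on a
    :class:`~dam.cohort.PatientRecord`.
    """

    def __init__(self, model_cfg: ModelConfig, fusion_cfg: FusionConfig):
        self.cfg = model_cfg
        self.fusion_cfg = fusion_cfg
        rng = np.random.default_rng(model_cfg.seed)
        self.cell_encoder = CellEncoder(model_cfg, rng)
        self.marker_encoder = MarkerEncoder(model_cfg, rng)
        self.tim = TemporalInteraction(model_cfg, rng)
        self.temporal = TemporalAggregator(model_cfg, rng,
                                           fusion_cfg.n_layers_temporal)
        self.head = PredictorHead(model_cfg, rng)
        D = model_cfg.embed_dim
        self.concat_proj = Linear(2 * D, D, rng)  # for the concat ablation
        self._drop_rng = np.random.default_rng(model_cfg.seed + 1)

    # -- core ----------------------------------------------------------
    def forward_streams(self, cells: SequenceEmbedding | None,
                        markers: SequenceEmbedding | None,
                        training: bool = False) -> Tensor:
        """Two-class logits from encoded streams, per the fusion mode."""
        mode = self.fusion_cfg.mode
        if mode == "tim" and cells is None and markers is None:
            raise ValueError("mode tim requires at least one modality")
        if mode in ("tci_only", "concat", "sum") and cells is None:
            raise ValueError(f"mode {mode} requires the cell-image modality")
        if mode in ("tm_only", "concat", "sum") and markers is None:
            raise ValueError(f"mode {mode} requires the marker modality")

        if mode == "tim":
            # degraded modes: with one stream missing, fall back to
            # aggregating the other alone
            if markers is None:
                fused = cells
            elif cells is None:
                fused = markers
            elif self.fusion_cfg.cells_query_markers:
                fused = self.tim(cells, markers)
            else:
                fused = self.tim(markers, cells)
            feature = self.temporal(fused)
        elif mode == "tci_only":
            feature = self.temporal(cells)
        elif mode == "tm_only":
            feature = self.temporal(markers)
        else:
            f_c = self.temporal(cells)
            f_m = self.temporal(markers)
            if mode == "concat":
                feature = self.concat_proj(concat([f_c, f_m], axis=0)
                                           .reshape(1, -1)).reshape(-1)
            else:
                feature = f_c + f_m
        if training and self.cfg.dropout > 0:
            keep = (self._drop_rng.random(feature.shape)
                    >= self.cfg.dropout).astype(float)
            feature = feature * Tensor(keep / (1.0 - self.cfg.dropout))
        return self.head(feature)

    # -- inference ------------------------------------------------------
    def encode_record(self, record: PatientRecord,
                      aug_cfg: AugmentConfig | None = None):
        """Deterministically encode both modalities of a record."""
        aug_cfg = aug_cfg or AugmentConfig(out_size=64)
        cells = None
        if record.cell_series and self.fusion_cfg.mode != "tm_only":
            per_tp = [(obs.t_days,
                       np.stack([preprocess_eval(im, aug_cfg)
                                 for im in obs.images]))
                      for obs in record.cell_series]
            cells = self.cell_encoder.encode_stream(per_tp)
        markers = None
        if record.marker_series and self.fusion_cfg.mode != "tci_only":
            markers = self.marker_encoder.encode_stream(record.marker_series)
        return cells, markers

    def predict_record(self, record: PatientRecord,
                       aug_cfg: AugmentConfig | None = None) -> Prediction:
        cells, markers = self.encode_record(record, aug_cfg)
        logits = self.forward_streams(cells, markers)
        return prediction_from_logits(logits.data)

    # -- persistence ----------------------------------------------------
    def save(self, path) -> None:
        """Checkpoint: parameter arrays (stable traversal order) plus an
        embedded copy of the model/fusion configs and scaler statistics."""
        import json
        from dataclasses import asdict

        arrays = {f"p{i:04d}": p.data for i, p in
                  enumerate(self.parameters())}
        sc = self.marker_encoder.scaler
        if sc.mean_ is not None:
            arrays["scaler"] = np.stack([sc.median_, sc.mean_, sc.sd_])
        meta = {"model": asdict(self.cfg), "fusion": asdict(self.fusion_cfg)}
        np.savez(path, __meta__=np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path) -> "DAMNet":
        import json

        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            net = cls(ModelConfig(**meta["model"]),
                      FusionConfig(**meta["fusion"]))
            for i, p in enumerate(net.parameters()):
                p.data = data[f"p{i:04d}"]
            if "scaler" in data:
                sc = net.marker_encoder.scaler
                sc.median_, sc.mean_, sc.sd_ = data["scaler"]
        return net


def prediction_from_logits(logits: np.ndarray) -> Prediction:
    z = logits - logits.max()
    e = np.exp(z)
    p = e / e.sum()
    return Prediction(logits=np.asarray(logits, float).copy(),
                      prob_responder=float(p[1]))
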