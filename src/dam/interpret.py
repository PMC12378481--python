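"""Grad-CAM focus-area interpretability and feature-level analysis.

Grad-CAM on the final convolutional layer of the cellular aggregator
yields a non-negative attention map per cell image. Binarising each
map at its 75th percentile (strictly greater) defines the focus area
F_i (foreground pixel count) and the connected-domain count D_i
(8-connectivity). Across a patient's N images the six dynamic
focus-area features are

    AvgFA = (1/N) Σ F_i            VarFA = 1/(N-1) Σ (F_i - AvgFA)²
    MinFA = min F_i                MaxFA = max F_i
    MedFA = median F_i             DisFA = Σ D_i

(VarFA is defined as 0 for N = 1, where the sample variance is
undefined.) A small three-layer MLP (6 → 16 → 8 → 2) trained on the
z-scored features under the same threefold protocol probes how much
response signal the focus-area statistics alone carry, and permutation
importance attributes that signal to individual features.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.measure import label as cc_label
from skimage.transform import resize as _sk_resize

from .cohort import PatientRecord
from .fusion import DAMNet
from .imageprep import AugmentConfig, preprocess_eval
from .metrics import auc, bootstrap_ci, roc_points
from .nn.autograd import Tensor
from .nn.layers import Adam, MLP
from .training import FOLDS, EvalReport, SplitPlan

__all__ = ["AttentionMap", "FocusMask", "DynamicFAFeatures", "gradcam",
           "gradcam_from_graph", "focus_mask", "dynamic_features",
           "patient_focus_features", "cell_importance_scores", "fa_mlp",
           "permutation_importance", "FA_FEATURE_NAMES"]

FA_FEATURE_NAMES = ("VarFA", "MinFA", "MaxFA", "AvgFA", "MedFA", "DisFA")


@dataclass
class AttentionMap:
    values: np.ndarray          # (H, W) non-negative, input-sized
    source_image_ref: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.min() < 0:
            raise ValueError("attention map must be non-negative")


@dataclass
class FocusMask:
    mask: np.ndarray            # (H, W) booleans
    F: int                      # foreground pixel count
    D: int                      # connected components (8-connectivity)


@dataclass(frozen=True)
class DynamicFAFeatures:
    VarFA: float
    MinFA: float
    MaxFA: float
    AvgFA: float
    MedFA: float
    DisFA: int
    N: int

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in FA_FEATURE_NAMES],
                        dtype=float)


# ---------------------------------------------------------------------------
# Grad-CAM

def gradcam_from_graph(activations: Tensor, out_size: tuple,
                       source_ref: str = "") -> AttentionMap:
    """Grad-CAM given conv activations whose ``.grad`` is populated.

    Channel weight = spatial mean of the gradient; map = ReLU of the
    weighted activation sum, bilinearly upsampled to `out_size`.
    """
    act = activations.data[0]                       # (C, H', W')
    grad = activations.grad
    if grad is None:
        grad = np.zeros_like(activations.data)
    weights = grad[0].mean(axis=(1, 2))             # (C,)
    cam = np.maximum((weights[:, None, None] * act).sum(axis=0), 0.0)
    if cam.shape != tuple(out_size):
        cam = _sk_resize(cam, out_size, order=1, mode="edge",
                         anti_aliasing=False, preserve_range=True)
        cam = np.maximum(cam, 0.0)
    return AttentionMap(values=cam, source_image_ref=source_ref)


def gradcam(net: DAMNet, img: np.ndarray, target_class: int = 1,
            source_ref: str = "") -> AttentionMap:
    """Grad-CAM for one preprocessed crop through the cellular pathway.

    The crop is treated as a single-cell, single-timepoint record and
    the gradient of the target-class logit (1 = responder) is taken at
    the final convolutional layer of the cellular aggregator.
    """
    net.zero_grad()
    enc = net.cell_encoder
    cells = enc.encode_stream([(0.0, np.asarray(img, dtype=float)[None])])
    acts = enc.cnn._last_conv_act
    logits = net.head(net.temporal(cells))
    logits[target_class].backward()
    return gradcam_from_graph(acts, img.shape[:2], source_ref)


def gradcam_record(net: DAMNet, record: PatientRecord,
                   aug_cfg: AugmentConfig | None = None,
                   target_class: int = 1) -> list:
    """Per-image attention maps via one backward pass of the full
    pipeline's target logit (responder by default) for a record."""
    aug_cfg = aug_cfg or AugmentConfig(out_size=64)
    net.zero_grad()
    enc = net.cell_encoder
    maps: list = []
    per_tp, act_refs = [], []
    for obs in record.cell_series:
        imgs = np.stack([preprocess_eval(im, aug_cfg) for im in obs.images])
        per_tp.append((obs.t_days, imgs))
    # one timepoint at a time so each batch's conv activations survive
    rows = []
    for t, imgs in per_tp:
        x = Tensor(imgs.transpose(0, 3, 1, 2))
        vecs = enc.cnn(x)
        act_refs.append((enc.cnn._last_conv_act, imgs.shape[1:3]))
        agg = enc.aggregate_cells(vecs)
        from .encoders import time_encode
        rows.append(agg + Tensor(time_encode(t, net.cfg.embed_dim)))
    from .nn.autograd import stack as _stack
    seq = enc.stage2(_stack(rows, axis=0),
                     key_mask=np.ones(len(rows), bool))
    from .encoders import SequenceEmbedding
    cells = SequenceEmbedding(vectors=seq,
                              times=np.array([t for t, _ in per_tp]),
                              mask=np.ones(len(rows), bool))
    markers = None
    if record.marker_series and net.fusion_cfg.mode not in ("tci_only",):
        markers = net.marker_encoder.encode_stream(record.marker_series)
    logits = net.forward_streams(cells, markers)
    logits[target_class].backward()
    for (acts, size), (t, imgs) in zip(act_refs, per_tp):
        for i in range(imgs.shape[0]):
            act_i = Tensor(acts.data[i][None])
            act_i.grad = (acts.grad[i][None] if acts.grad is not None
                          else None)
            maps.append(gradcam_from_graph(act_i, size,
                                           source_ref=f"t={t:g}/cell{i}"))
    return maps


# ---------------------------------------------------------------------------
# focus areas

def focus_mask(amap: AttentionMap, percentile: float = 75.0,
               connectivity: int = 2) -> FocusMask:
    """Binarise an attention map at its percentile threshold.

    Foreground = strictly greater than the linear-interpolation
    percentile of all pixels; components counted with 8-connectivity.
    """
    theta = np.percentile(amap.values, percentile)
    fg = amap.values > theta
    F = int(fg.sum())
    D = int(cc_label(fg, connectivity=connectivity).max()) if F else 0
    return FocusMask(mask=fg, F=F, D=D)


def dynamic_features(masks: list) -> DynamicFAFeatures:
    """The six focus-area statistics over a patient's images."""
    if not masks:
        raise ValueError("need at least one focus mask")
    F = np.array([m.F for m in masks], dtype=float)
    N = len(F)
    avg = float(F.mean())
    var = float(((F - avg) ** 2).sum() / (N - 1)) if N > 1 else 0.0
    return DynamicFAFeatures(
        VarFA=var, MinFA=float(F.min()), MaxFA=float(F.max()),
        AvgFA=avg, MedFA=float(np.median(F)),
        DisFA=int(sum(m.D for m in masks)), N=N)


def patient_focus_features(net: DAMNet, record: PatientRecord,
                           aug_cfg: AugmentConfig | None = None,
                           percentile: float = 75.0) -> DynamicFAFeatures:
    maps = gradcam_record(net, record, aug_cfg)
    return dynamic_features([focus_mask(m, percentile) for m in maps])


# ---------------------------------------------------------------------------
# cell importance

def cell_importance_scores(net: DAMNet, record: PatientRecord,
                           aug_cfg: AugmentConfig | None = None) -> list:
    """(image_ref, cell_class, score): the aggregation token's softmax
    weight over each timepoint's cells, head-averaged; per-timepoint
    scores sum to one."""
    aug_cfg = aug_cfg or AugmentConfig(out_size=64)
    enc = net.cell_encoder
    out = []
    for obs in record.cell_series:
        imgs = np.stack([preprocess_eval(im, aug_cfg) for im in obs.images])
        vecs = enc.cnn(Tensor(imgs.transpose(0, 3, 1, 2)))
        enc.aggregate_cells(vecs)
        w = enc.cell_importances()
        for i, (im, s) in enumerate(zip(obs.images, w)):
            ref = im.source_path or f"t={obs.t_days:g}/cell{i}"
            out.append((ref, im.cell_class.value, float(s)))
    return out


# ---------------------------------------------------------------------------
# feature-MLP + permutation importance

def _fit_mlp(X: np.ndarray, y: np.ndarray, seed: int,
             epochs: int = 400, lr: float = 1e-2):
    rng = np.random.default_rng(seed)
    net = MLP([X.shape[1], 16, 8, 2], rng)
    opt = Adam(net.parameters(), lr=lr)
    for _ in range(epochs):
        opt.zero_grad()
        logits = net(Tensor(X))
        logp = logits.log_softmax(axis=-1)
        loss = logp[np.arange(len(y)), y].mean() * -1.0
        loss.backward()
        opt.step()
    return net


def _mlp_probs(net: MLP, X: np.ndarray) -> np.ndarray:
    return net(Tensor(X)).softmax(axis=-1).data[:, 1]


def _safe_report(ids, probs, ys, seed) -> EvalReport:
    per_pat = list(zip(ids, probs.tolist(), ys.astype(bool).tolist()))
    try:
        return EvalReport(auc=auc(probs, ys.astype(bool)),
                          ci95=bootstrap_ci(probs, ys.astype(bool),
                                            seed=seed),
                          roc_points=roc_points(probs, ys.astype(bool)),
                          per_patient=per_pat, n=len(ids))
    except ValueError:  # single-class evaluation set → flagged
        return EvalReport(auc=float("nan"),
                          ci95=(float("nan"), float("nan")),
                          roc_points=[], per_patient=per_pat, n=len(ids))


def fa_mlp(features: dict, labels: dict, split: SplitPlan,
           seed: int = 0) -> tuple:
    """Three-layer MLP on the six focus-area features, threefold CV.

    `features`: patient_id -> DynamicFAFeatures (or 6-array);
    `labels`: patient_id -> bool. Returns (cv_reports, test_report,
    fold_models) with features z-scored on each training fold.
    """
    ids = [pid for pid in features if pid in labels]

    def xy(pids):
        X = np.stack([np.asarray(
            features[i].as_array() if hasattr(features[i], "as_array")
            else features[i], dtype=float) for i in pids])
        y = np.array([int(labels[i]) for i in pids])
        return X, y

    cv_reports, fold_models = [], []
    for fold in FOLDS:
        val_ids = [i for i in split.members(fold) if i in features]
        train_ids = [i for f in FOLDS if f != fold
                     for i in split.members(f) if i in features]
        Xtr, ytr = xy(train_ids)
        if len(np.unique(ytr)) < 2:
            raise ValueError(f"single-class training set for fold {fold}")
        mu, sd = Xtr.mean(0), Xtr.std(0)
        sd = np.where(sd < 1e-12, 1.0, sd)
        net = _fit_mlp((Xtr - mu) / sd, ytr, seed=seed)
        fold_models.append((net, mu, sd))
        Xv, yv = xy(val_ids)
        probs = _mlp_probs(net, (Xv - mu) / sd)
        cv_reports.append(_safe_report(val_ids, probs, yv, seed))

    test_ids = [i for i in split.members("test") if i in features]
    if test_ids:
        Xt, yt = xy(test_ids)
        probs = np.mean([_mlp_probs(net, (Xt - mu) / sd)
                         for net, mu, sd in fold_models], axis=0)
        test_report = _safe_report(test_ids, probs, yt, seed)
    else:
        test_report = EvalReport(float("nan"), (float("nan"),) * 2, [], [],
                                 n=0)
    return cv_reports, test_report, fold_models


def permutation_importance(fold_models: list, features: dict, labels: dict,
                           eval_ids: list, n_reps: int = 20,
                           seed: int = 0) -> dict:
    """Mean (± sd) AUC drop when one feature column is shuffled.

    Evaluated with the ensemble of fitted fold models on `eval_ids`.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    X = np.stack([np.asarray(
        features[i].as_array() if hasattr(features[i], "as_array")
        else features[i], dtype=float) for i in eval_ids])
    y = np.array([bool(labels[i]) for i in eval_ids])

    def ens_auc(Xq):
        probs = np.mean([_mlp_probs(net, (Xq - mu) / sd)
                         for net, mu, sd in fold_models], axis=0)
        return auc(probs, y)

    base = ens_auc(X)
    rng = np.random.default_rng(seed)
    out = {}
    for j, name in enumerate(FA_FEATURE_NAMES):
        drops = np.empty(n_reps)
        for r in range(n_reps):
            Xp = X.copy()
            Xp[:, j] = rng.permutation(Xp[:, j])
            drops[r] = base - ens_auc(Xp)
        out[name] = (float(drops.mean()), float(drops.std(ddof=0)))
    return out
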