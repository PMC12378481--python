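"""Training strategies and evaluation protocol.

The protocol mirrors the study design: a random stratified test
holdout (17/91 by default), threefold cross-validation on the
remainder yielding three trained models, and an ensemble (mean softmax
probability) for test-set prediction. Training minimises class-
weighted cross-entropy and applies *dynamic longitudinal elimination*:
at every step, each modality of a patient is independently thinned to
an 80% random subset of its timepoints (chronological order kept,
never emptied) — a data-level dropout that teaches the model to cope
with missing follow-ups. Validation and testing always use the full
sequences.

By default the convolutional extractor stays frozen at its seeded
random initialisation and its pooled features are cached per image:
random convolutional projections already separate the morphological
signal (nucleus size, punctum count), and small cohorts cannot
usefully fine-tune a CNN. Set ``TrainConfig.freeze_cnn=False`` for
end-to-end fine-tuning with per-step augmentation.

Also here: the windowed early-prediction evaluation and the
cell-counting baseline (gradient-boosted trees on baseline CTC/CEC
counts), the comparator dynamic modelling is meant to beat.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .cohort import (Cohort, PatientRecord, ResponseLabel, TimeWindow,
                     restrict_time_window)
from .encoders import ModelConfig
from .fusion import DAMNet, FusionConfig, Prediction, prediction_from_logits
from .imageprep import AugmentConfig, augment, preprocess_eval
from .metrics import auc, bootstrap_ci, roc_points
from .nn.autograd import Tensor
from .nn.layers import Adam

__all__ = ["SplitPlan", "TrainConfig", "EvalReport", "TrainResult",
           "split_threefold", "longitudinal_eliminate", "train_fold",
           "ensemble_predict", "evaluate", "counting_baseline",
           "windowed_evaluation", "run_cross_validation", "CVResult"]

FOLDS = ("F1", "F2", "F3")


@dataclass(frozen=True)
class SplitPlan:
    fold_assignment: dict  # patient_id -> "F1" | "F2" | "F3" | "test"
    seed: int

    def members(self, group: str) -> list:
        return sorted(pid for pid, g in self.fold_assignment.items()
                      if g == group)


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 60
    learning_rate: float = 3e-3
    batch_size: int = 8
    elimination_frac: float = 0.8
    class_weighting: bool = True
    seed: int = 0
    freeze_cnn: bool = True
    image_out_size: int = 64   # eval/caching resize target
    weight_decay: float = 1e-4

    def __post_init__(self):
        if not 0.0 < self.elimination_frac <= 1.0:
            raise ValueError("elimination_frac must be in (0,1]")


@dataclass
class EvalReport:
    auc: float
    ci95: tuple
    roc_points: list
    per_patient: list          # (patient_id, prob_responder, label_bool)
    window: str = "all"
    n: int = 0


@dataclass
class TrainResult:
    model: DAMNet
    report: EvalReport
    loss_history: list = field(default_factory=list)


@dataclass
class CVResult:
    split: SplitPlan
    fold_results: list         # three TrainResult
    test_report: EvalReport
    caches: dict | None = None  # pooled-CNN feature cache (frozen path)

    @property
    def models(self) -> list:
        return [fr.model for fr in self.fold_results]

    @property
    def cv_aucs(self) -> list:
        return [fr.report.auc for fr in self.fold_results]


# ---------------------------------------------------------------------------
# splitting

def split_threefold(cohort: Cohort, seed: int,
                    test_frac: float = 17 / 91) -> SplitPlan:
    """Stratified test holdout + stratified near-equal threefold split."""
    labelled = cohort.labelled()
    if len(labelled) < 6:
        raise ValueError("need at least 6 labelled patients to split")
    rng = np.random.default_rng(seed)
    assignment: dict = {}
    by_class: dict = {}
    for p in labelled:
        by_class.setdefault(p.label, []).append(p.patient_id)

    train_ids_by_class = {}
    for lab, ids in sorted(by_class.items(), key=lambda kv: kv[0].value):
        ids = sorted(ids)
        rng.shuffle(ids)
        n_test = int(round(test_frac * len(ids)))
        for pid in ids[:n_test]:
            assignment[pid] = "test"
        train_ids_by_class[lab] = ids[n_test:]

    # deal each class round-robin into the three folds, random offset
    for lab, ids in train_ids_by_class.items():
        offset = int(rng.integers(3))
        for i, pid in enumerate(ids):
            assignment[pid] = FOLDS[(i + offset) % 3]
    return SplitPlan(fold_assignment=assignment, seed=seed)


# ---------------------------------------------------------------------------
# dynamic longitudinal elimination

def _keep_indices(T: int, frac: float, rng: np.random.Generator) -> np.ndarray:
    k = max(1, round(frac * T))  # round-half-to-even, floored at one
    if k >= T:
        return np.arange(T)
    return np.sort(rng.choice(T, size=k, replace=False))


def longitudinal_eliminate(record: PatientRecord, frac: float,
                           rng: np.random.Generator) -> PatientRecord:
    """Random temporal thinning, independent per modality.

    Keeps ``max(1, round(frac * T))`` timepoints per modality without
    replacement, preserving chronological order. A training-time
    regulariser only — evaluation always sees the full sequences.
    """
    if not 0.0 < frac <= 1.0:
        raise ValueError("frac must be in (0,1]")
    cells = record.cell_series
    markers = record.marker_series
    if cells:
        cells = [cells[i] for i in _keep_indices(len(cells), frac, rng)]
    if markers:
        markers = [markers[i] for i in _keep_indices(len(markers), frac, rng)]
    return replace(record, cell_series=cells, marker_series=markers)


# ---------------------------------------------------------------------------
# training

def _class_weights(patients: list) -> dict:
    n_pos = sum(p.label is ResponseLabel.RESPONDER for p in patients)
    n_neg = len(patients) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("training set must contain both classes")
    n = len(patients)
    return {True: n / (2.0 * n_pos), False: n / (2.0 * n_neg)}


def _cache_patient(net: DAMNet, record: PatientRecord,
                   aug_cfg: AugmentConfig):
    """Pooled-CNN feature cache: [(t, (n_cells, 8w) array)] per timepoint."""
    cache = []
    for obs in record.cell_series:
        imgs = np.stack([preprocess_eval(im, aug_cfg) for im in obs.images])
        cache.append((obs.t_days, net.cell_encoder.pooled_cnn_features(imgs)))
    return cache


def _encode_for_training(net: DAMNet, record: PatientRecord, cell_cache,
                         tcfg: TrainConfig, aug_cfg: AugmentConfig,
                         rng: np.random.Generator):
    mode = net.fusion_cfg.mode
    cells = markers = None
    if mode != "tm_only" and record.cell_series:
        T = len(cell_cache) if tcfg.freeze_cnn else len(record.cell_series)
        idx = _keep_indices(T, tcfg.elimination_frac, rng)
        if tcfg.freeze_cnn:
            per_tp = [cell_cache[i] for i in idx]
            cells = net.cell_encoder.encode_stream(per_tp, pooled=True)
        else:
            per_tp = []
            for i in idx:
                obs = record.cell_series[i]
                imgs = np.stack([augment(im, aug_cfg, rng)
                                 for im in obs.images])
                per_tp.append((obs.t_days, imgs))
            cells = net.cell_encoder.encode_stream(per_tp)
    if mode != "tci_only" and record.marker_series:
        T = len(record.marker_series)
        idx = _keep_indices(T, tcfg.elimination_frac, rng)
        markers = net.marker_encoder.encode_stream(
            [record.marker_series[i] for i in idx])
    return cells, markers


def _cache_cohort(net: DAMNet, patients: list,
                  aug_cfg: AugmentConfig) -> dict:
    return {p.patient_id: _cache_patient(net, p, aug_cfg) for p in patients}


def train_fold(train_patients: list, val_patients: list,
               model_cfg: ModelConfig, fusion_cfg: FusionConfig,
               tcfg: TrainConfig, caches: dict | None = None) -> TrainResult:
    """Train one model on `train_patients`, evaluate on `val_patients`.

    Deterministic under fixed seeds: model init from ``model_cfg.seed``,
    data order/elimination/augmentation from ``tcfg.seed``. `caches`
    may carry precomputed pooled-CNN features (frozen-CNN path only;
    valid for any model sharing this ``model_cfg.seed``).
    """
    if not train_patients or not val_patients:
        raise ValueError("train and validation sets must be non-empty")
    weights = _class_weights(train_patients)

    net = DAMNet(model_cfg, fusion_cfg)
    net.marker_encoder.scaler.fit(
        [o.panel for p in train_patients for o in p.marker_series])
    aug_cfg = AugmentConfig(out_size=tcfg.image_out_size)

    if caches is None:
        caches = {}
    if fusion_cfg.mode != "tm_only" and tcfg.freeze_cnn:
        for p in train_patients:
            if p.patient_id not in caches:
                caches[p.patient_id] = _cache_patient(net, p, aug_cfg)

    params = net.parameters()
    if tcfg.freeze_cnn:
        cnn_ids = {id(q) for q in net.cell_encoder.cnn.parameters()}
        params = [q for q in params if id(q) not in cnn_ids]
    opt = Adam(params, lr=tcfg.learning_rate, weight_decay=tcfg.weight_decay)

    rng = np.random.default_rng(tcfg.seed)
    order = np.arange(len(train_patients))
    losses = []
    for _ in range(tcfg.epochs):
        rng.shuffle(order)
        epoch_loss = 0.0
        for start in range(0, len(order), tcfg.batch_size):
            batch = order[start:start + tcfg.batch_size]
            opt.zero_grad()
            for pi in batch:
                p = train_patients[pi]
                cells, markers = _encode_for_training(
                    net, p, caches.get(p.patient_id), tcfg, aug_cfg, rng)
                logits = net.forward_streams(cells, markers, training=True)
                y = 1 if p.label is ResponseLabel.RESPONDER else 0
                w = weights[y == 1] if tcfg.class_weighting else 1.0
                loss = logits.log_softmax()[y] * (-w / len(batch))
                loss.backward()
                epoch_loss += loss.data.item() * len(batch)
            opt.step()
        losses.append(epoch_loss / len(order))

    if tcfg.freeze_cnn:
        for p in val_patients:
            if p.patient_id not in caches and p.cell_series:
                caches[p.patient_id] = _cache_patient(net, p, aug_cfg)
        report = _predict_patients(
            lambda p: _predict_from_cache(net, p, caches.get(p.patient_id)),
            val_patients)
    else:
        report = evaluate(net, val_patients, aug_cfg)
    return TrainResult(model=net, report=report, loss_history=losses)


def _predict_from_cache(net: DAMNet, record: PatientRecord, cache,
                        window: TimeWindow | None = None) -> Prediction:
    """Inference from the pooled-feature cache (optionally windowed)."""
    bound = window.upper_days if window is not None else float("inf")
    keep = lambda t: t <= bound or t <= 0.0
    cells = markers = None
    if net.fusion_cfg.mode != "tm_only" and cache:
        sel = [(t, f) for t, f in cache if keep(t)]
        if sel:
            cells = net.cell_encoder.encode_stream(sel, pooled=True)
    if net.fusion_cfg.mode != "tci_only" and record.marker_series:
        obs = [o for o in record.marker_series if keep(o.t_days)]
        if obs:
            markers = net.marker_encoder.encode_stream(obs)
    logits = net.forward_streams(cells, markers)
    return prediction_from_logits(logits.data)


# ---------------------------------------------------------------------------
# evaluation

def _predict_patients(predict_fn, patients: list, window: str = "all",
                      ci_seed: int = 0) -> EvalReport:
    per_patient = []
    for p in patients:
        if p.label is ResponseLabel.UNKNOWN:
            continue
        try:
            pred = predict_fn(p)
        except ValueError as e:
            warnings.warn(f"patient {p.patient_id} skipped in window "
                          f"{window}: {e}")
            continue
        per_patient.append((p.patient_id, pred.prob_responder,
                            p.label is ResponseLabel.RESPONDER))
    if not per_patient:
        return EvalReport(auc=float("nan"), ci95=(float("nan"), float("nan")),
                          roc_points=[], per_patient=[], window=window, n=0)
    probs = np.array([q[1] for q in per_patient])
    labels = np.array([q[2] for q in per_patient])
    try:
        a = auc(probs, labels)
        ci = bootstrap_ci(probs, labels, seed=ci_seed)
    except ValueError:  # single-class window → flagged, not fatal
        return EvalReport(auc=float("nan"),
                          ci95=(float("nan"), float("nan")), roc_points=[],
                          per_patient=per_patient, window=window,
                          n=len(per_patient))
    return EvalReport(auc=a, ci95=ci, roc_points=roc_points(probs, labels),
                      per_patient=per_patient, window=window,
                      n=len(per_patient))


def evaluate(net: DAMNet, patients: list,
             aug_cfg: AugmentConfig | None = None,
             window: str = "all") -> EvalReport:
    """Full-sequence, augmentation-free evaluation of one model."""
    return _predict_patients(lambda p: net.predict_record(p, aug_cfg),
                             patients, window=window)


def ensemble_predict(models: list, record: PatientRecord,
                     aug_cfg: AugmentConfig | None = None) -> Prediction:
    """Mean of the member models' softmax probability vectors."""
    cfgs = {(m.fusion_cfg.mode, m.cfg.embed_dim) for m in models}
    if len(cfgs) != 1:
        raise ValueError("ensemble members must share configuration")
    probs = np.mean([m.predict_record(record, aug_cfg).probs
                     for m in models], axis=0)
    logits = np.log(np.maximum(probs, 1e-300))
    return prediction_from_logits(logits)


def evaluate_ensemble(models: list, patients: list,
                      aug_cfg: AugmentConfig | None = None,
                      window: str = "all",
                      caches: dict | None = None,
                      time_window: TimeWindow | None = None) -> EvalReport:
    if caches is not None:
        def predict(p):
            probs = np.mean([_pred_probs(_predict_from_cache(
                m, p, caches.get(p.patient_id), time_window))
                for m in models], axis=0)
            return prediction_from_logits(np.log(np.maximum(probs, 1e-300)))
        return _predict_patients(predict, patients, window=window)
    return _predict_patients(
        lambda p: ensemble_predict(models, p, aug_cfg), patients,
        window=window)


def _pred_probs(pred: Prediction) -> np.ndarray:
    return pred.probs


def windowed_evaluation(models: list, patients: list, windows: list,
                        aug_cfg: AugmentConfig | None = None,
                        caches: dict | None = None) -> list:
    """Early-prediction analysis: restrict inputs to each time window."""
    reports = []
    for win in windows:
        if caches is not None:
            reports.append(evaluate_ensemble(models, patients, aug_cfg,
                                             window=win.name, caches=caches,
                                             time_window=win))
            continue
        restricted = []
        for p in patients:
            try:
                restricted.append(restrict_time_window(p, win))
            except ValueError:
                continue
        reports.append(evaluate_ensemble(models, restricted, aug_cfg,
                                         window=win.name))
    return reports


# ---------------------------------------------------------------------------
# cross-validation driver

def run_cross_validation(cohort: Cohort, model_cfg: ModelConfig,
                         fusion_cfg: FusionConfig, tcfg: TrainConfig,
                         split: SplitPlan | None = None) -> CVResult:
    """Threefold CV + ensemble test evaluation, per the study protocol."""
    if split is None:
        split = split_threefold(cohort, tcfg.seed)
    by_id = {p.patient_id: p for p in cohort}
    aug_cfg = AugmentConfig(out_size=tcfg.image_out_size)

    # All folds share the seeded CNN init, so with a frozen CNN one
    # pooled-feature cache serves training, validation and the ensemble.
    caches: dict | None = None
    if tcfg.freeze_cnn and fusion_cfg.mode != "tm_only":
        proto = DAMNet(model_cfg, fusion_cfg)
        labelled = [p for p in cohort.labelled()
                    if p.patient_id in split.fold_assignment]
        caches = _cache_cohort(proto, labelled, aug_cfg)

    fold_results = []
    for i, fold in enumerate(FOLDS):
        val = [by_id[pid] for pid in split.members(fold)]
        train = [by_id[pid] for f in FOLDS if f != fold
                 for pid in split.members(f)]
        tcfg_i = replace(tcfg, seed=tcfg.seed + 1000 * (i + 1))
        fold_results.append(train_fold(train, val, model_cfg, fusion_cfg,
                                       tcfg_i, caches=caches))
    test = [by_id[pid] for pid in split.members("test")]
    test_report = evaluate_ensemble([fr.model for fr in fold_results],
                                    test, aug_cfg, caches=caches)
    return CVResult(split=split, fold_results=fold_results,
                    test_report=test_report, caches=caches)


# ---------------------------------------------------------------------------
# cell-counting baseline

def _baseline_features(record: PatientRecord):
    if not record.cell_series:
        return None
    first = record.cell_series[0]
    classes = [im.cell_class.value for im in first.images]
    n_ctc = classes.count("CTC")
    n_cec = classes.count("CEC")
    return np.array([n_ctc, n_cec, len(first.images)], dtype=float)


def counting_baseline(cohort: Cohort, split: SplitPlan,
                      seed: int = 0) -> tuple:
    """Gradient-boosted trees on baseline (earliest-draw) cell counts.

    Returns (cv_reports, test_report): per-fold validation reports and
    the mean-probability ensemble on the test holdout — the same
    protocol the dynamic model is evaluated under.
    """
    from xgboost import XGBClassifier

    by_id = {p.patient_id: p for p in cohort}
    feats, labels = {}, {}
    for p in cohort.labelled():
        f = _baseline_features(p)
        if f is None:
            warnings.warn(f"patient {p.patient_id}: no baseline cell counts; "
                          "skipped by counting baseline")
            continue
        feats[p.patient_id] = f
        labels[p.patient_id] = int(p.label is ResponseLabel.RESPONDER)

    def make_clf():
        return XGBClassifier(n_estimators=50, max_depth=3,
                             learning_rate=0.2, random_state=seed,
                             n_jobs=1, eval_metric="logloss")

    def safe_report(ids, probs, ys):
        per_pat = list(zip(ids, probs.tolist(), ys.tolist()))
        try:
            return EvalReport(auc=auc(probs, ys),
                              ci95=bootstrap_ci(probs, ys, seed=seed),
                              roc_points=roc_points(probs, ys),
                              per_patient=per_pat, n=len(ids))
        except ValueError:  # single-class evaluation set
            return EvalReport(auc=float("nan"),
                              ci95=(float("nan"), float("nan")),
                              roc_points=[], per_patient=per_pat,
                              n=len(ids))

    cv_reports, fold_models = [], []
    for fold in FOLDS:
        val_ids = [pid for pid in split.members(fold) if pid in feats]
        train_ids = [pid for f in FOLDS if f != fold
                     for pid in split.members(f) if pid in feats]
        clf = make_clf()
        clf.fit(np.stack([feats[i] for i in train_ids]),
                np.array([labels[i] for i in train_ids]))
        fold_models.append(clf)
        probs = clf.predict_proba(np.stack([feats[i] for i in val_ids]))[:, 1]
        ys = np.array([labels[i] for i in val_ids], dtype=bool)
        cv_reports.append(safe_report(val_ids, probs, ys))

    test_ids = [pid for pid in split.members("test") if pid in feats]
    if test_ids:
        X = np.stack([feats[i] for i in test_ids])
        probs = np.mean([m.predict_proba(X)[:, 1] for m in fold_models],
                        axis=0)
        ys = np.array([labels[i] for i in test_ids], dtype=bool)
        test_report = safe_report(test_ids, probs, ys)
    else:
        test_report = EvalReport(float("nan"), (float("nan"),) * 2, [], [],
                                 n=0)
    return cv_reports, test_report
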