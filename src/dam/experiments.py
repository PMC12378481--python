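"""Canned study protocols on synthetic cohorts.

These bundle the full pipeline — generate a cohort, run threefold CV
with ensembling, evaluate the counting baseline, windowed early
prediction, and truncated-sequence robustness — into single calls used
by the reproduction script and the higher-level checks. Problem sizes
default to a desk-scale analogue of the study (90 patients, 32-px
crops, narrow CNN, 30 epochs): large enough for the dynamics signal
to be recoverable, small enough to run on one CPU in minutes.
"""

from __future__ import annotations

import warnings
from dataclasses import replace

import numpy as np

from .cohort import STANDARD_WINDOWS
from .encoders import ModelConfig
from .fusion import FusionConfig
from .synth import SynthConfig, generate_cohort
from .training import (TrainConfig, _predict_from_cache, _predict_patients,
                       counting_baseline, run_cross_validation,
                       windowed_evaluation)

__all__ = ["small_model_config", "small_train_config",
           "signal_recovery_experiment"]


def small_model_config(seed: int = 0) -> ModelConfig:
    return ModelConfig(embed_dim=32, n_heads=4, cnn_width=8,
                       marker_hidden=32, seed=seed)


def small_train_config(seed: int = 0, image_out_size: int = 32,
                       epochs: int = 30) -> TrainConfig:
    return TrainConfig(epochs=epochs, learning_rate=3e-3, batch_size=8,
                       seed=seed, image_out_size=image_out_size)


def _truncated_eval(cv, patients, frac: float, seed: int):
    """Ensemble AUC with every test sequence thinned to `frac` of its
    timepoints — the robustness the elimination strategy trains for."""
    rng = np.random.default_rng(seed)
    from .training import _keep_indices, prediction_from_logits

    def predict(p):
        cache = cv.caches.get(p.patient_id) if cv.caches else None
        trunc_cache = None
        if cache:
            idx = _keep_indices(len(cache), frac, rng)
            trunc_cache = [cache[i] for i in idx]
        markers = p.marker_series
        if markers:
            idx = _keep_indices(len(markers), frac, rng)
            markers = [markers[i] for i in idx]
        record = replace(p, marker_series=markers)
        probs = np.mean([_predict_from_cache(m, record, trunc_cache).probs
                         for m in cv.models], axis=0)
        return prediction_from_logits(np.log(np.maximum(probs, 1e-300)))

    return _predict_patients(predict, patients, window="truncated")


def signal_recovery_experiment(seed: int, n_patients: int = 90,
                               effect_size: float = 2.0,
                               image_size: int = 32, epochs: int = 30,
                               windows=("d45", "all"),
                               truncate_frac: float | None = 0.5) -> dict:
    """Generate → train → evaluate, returning the headline quantities.

    Returns a dict with CV/test AUCs of the dynamic model, the
    counting baseline's CV/test AUCs, windowed test AUCs, and (when
    `truncate_frac` is set) the ensemble AUC on truncated sequences.
    """
    cohort = generate_cohort(SynthConfig(
        n_patients=n_patients, image_size=image_size,
        effect_size=effect_size, seed=seed))
    mcfg = small_model_config(seed=seed)
    tcfg = small_train_config(seed=seed, image_out_size=image_size,
                              epochs=epochs)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cv = run_cross_validation(cohort, mcfg, FusionConfig(mode="tim"),
                                  tcfg)
        by_id = {p.patient_id: p for p in cohort}
        test = [by_id[pid] for pid in cv.split.members("test")]
        wreports = windowed_evaluation(
            cv.models, test, [STANDARD_WINDOWS[w] for w in windows],
            caches=cv.caches)
        base_cv, base_test = counting_baseline(cohort, cv.split, seed=seed)
        out = {
            "cv_aucs": cv.cv_aucs,
            "cv_auc_mean": float(np.mean(cv.cv_aucs)),
            "test_auc": cv.test_report.auc,
            "baseline_cv_aucs": [r.auc for r in base_cv],
            "baseline_cv_auc_mean": float(np.mean([r.auc for r in base_cv])),
            "baseline_test_auc": base_test.auc,
            "windowed": {r.window: r.auc for r in wreports},
            "n_test": cv.test_report.n,
        }
        if truncate_frac is not None:
            out["truncated_test_auc"] = _truncated_eval(
                cv, test, truncate_frac, seed).auc
        out["_cv"] = cv
    return out
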