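"""Model/Results surface for dynamic-aware response prediction.

``DynamicAwareModel`` is built from a :class:`~dam.cohort.Cohort` and a
configuration; ``fit()`` runs the full study protocol (stratified test
holdout, threefold cross-validation with dynamic longitudinal
elimination, probability-mean ensembling) and returns a
:class:`DAMResults` carrying the per-fold and test reports, windowed
early-prediction AUCs on demand, and a text ``summary()``.

    >>> cohort = generate_cohort(SynthConfig(n_patients=90, seed=7))
    >>> res = DynamicAwareModel(cohort, mode="tim").fit()
    >>> print(res.summary())
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cohort import Cohort, ResponseLabel, STANDARD_WINDOWS
from .encoders import ModelConfig
from .fusion import FusionConfig, Prediction
from .imageprep import AugmentConfig
from .training import (CVResult, SplitPlan, TrainConfig, counting_baseline,
                       ensemble_predict, run_cross_validation,
                       split_threefold, windowed_evaluation)

__all__ = ["DynamicAwareModel", "DAMResults"]


class DynamicAwareModel:
    """Treatment-response model over a longitudinal liquid-biopsy cohort.

    Parameters
    ----------
    cohort : Cohort
        Labelled patients with cell-image and/or marker streams.
    mode : str
        Fusion variant: "tim" (full model), "tci_only", "tm_only",
        "concat" or "sum".
    model_config, train_config : optional
        Architecture and optimisation settings; sensible defaults.
    """

    def __init__(self, cohort: Cohort, mode: str = "tim",
                 model_config: ModelConfig | None = None,
                 train_config: TrainConfig | None = None):
        if not cohort.labelled():
            raise ValueError("cohort has no labelled patients")
        self.cohort = cohort
        self.model_config = model_config or ModelConfig()
        self.fusion_config = FusionConfig(mode=mode)
        self.train_config = train_config or TrainConfig()

    def fit(self, seed: int | None = None,
            split: SplitPlan | None = None) -> "DAMResults":
        tcfg = self.train_config
        if seed is not None:
            from dataclasses import replace
            tcfg = replace(tcfg, seed=seed)
            self.model_config = replace(self.model_config, seed=seed)
        cv = run_cross_validation(self.cohort, self.model_config,
                                  self.fusion_config, tcfg, split=split)
        return DAMResults(model=self, cv=cv)


@dataclass
class DAMResults:
    """Fitted results: fold models, validation and test reports."""

    model: DynamicAwareModel
    cv: CVResult
    _window_cache: dict = field(default_factory=dict)

    # -- estimates -----------------------------------------------------
    @property
    def cv_aucs(self) -> list:
        return self.cv.cv_aucs

    @property
    def cv_auc_mean(self) -> float:
        return float(np.mean(self.cv.cv_aucs))

    @property
    def cv_auc_sd(self) -> float:
        return float(np.std(self.cv.cv_aucs, ddof=0))

    @property
    def test_auc(self) -> float:
        return self.cv.test_report.auc

    def predict(self, record) -> Prediction:
        aug = AugmentConfig(out_size=self.model.train_config.image_out_size)
        return ensemble_predict(self.cv.models, record, aug)

    def windowed(self, window_names=("d45", "m3", "m6", "y1", "all")) -> dict:
        """Early-prediction AUC per time window on the test holdout."""
        key = tuple(window_names)
        if key not in self._window_cache:
            by_id = {p.patient_id: p for p in self.model.cohort}
            test = [by_id[pid] for pid in self.cv.split.members("test")]
            aug = AugmentConfig(
                out_size=self.model.train_config.image_out_size)
            reports = windowed_evaluation(
                self.cv.models, test,
                [STANDARD_WINDOWS[w] for w in window_names], aug,
                caches=self.cv.caches)
            self._window_cache[key] = {r.window: r for r in reports}
        return self._window_cache[key]

    def baseline(self, seed: int = 0):
        """Cell-counting comparator under the identical split."""
        return counting_baseline(self.model.cohort, self.cv.split, seed=seed)

    # -- presentation --------------------------------------------------
    def summary(self) -> str:
        lines = [
            "Dynamic-aware treatment-response model",
            "=" * 54,
            f"mode: {self.model.fusion_config.mode}"
            f"    patients: {len(self.model.cohort)}"
            f"    embed dim: {self.model.model_config.embed_dim}",
            f"folds: " + ", ".join(
                f"{f}: n={len(self.cv.split.members(f))}"
                for f in ("F1", "F2", "F3"))
            + f", test: n={len(self.cv.split.members('test'))}",
            "-" * 54,
        ]
        for f, rep in zip(("F1", "F2", "F3"),
                          [fr.report for fr in self.cv.fold_results]):
            lines.append(f"val AUC {f}: {rep.auc:.3f}  "
                         f"(95% CI {rep.ci95[0]:.3f}-{rep.ci95[1]:.3f})")
        lines.append(f"CV AUC: {self.cv_auc_mean:.3f} ± {self.cv_auc_sd:.3f}")
        t = self.cv.test_report
        lines.append(f"test AUC (ensemble): {t.auc:.3f}  "
                     f"(95% CI {t.ci95[0]:.3f}-{t.ci95[1]:.3f}, n={t.n})")
        return "\n".join(lines)
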