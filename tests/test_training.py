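"""Splits, elimination, training loop, ensembling, baseline."""

import dataclasses
import warnings

import numpy as np
import pytest

from dam.cohort import CellClass, CellImage, CellObservation, Cohort, \
    PatientRecord, ResponseLabel
from dam.encoders import ModelConfig
from dam.fusion import FusionConfig
from dam.synth import SynthConfig, generate_cohort
from dam.training import (TrainConfig, counting_baseline, ensemble_predict,
                          longitudinal_eliminate, run_cross_validation,
                          split_threefold, train_fold)


class TestSplitThreefold:
    def test_91_patients_reproduce_study_fold_sizes(self):
        c = generate_cohort(SynthConfig(n_patients=91, image_size=16,
                                        cells_per_tp_mean=1.0, seed=30))
        plan = split_threefold(c, seed=1)
        sizes = sorted(len(plan.members(f)) for f in ("F1", "F2", "F3"))
        n_test = len(plan.members("test"))
        assert abs(n_test - 17) <= 1
        assert sum(sizes) + n_test == len(c.labelled())
        assert max(sizes) - min(sizes) <= 1

    def test_partition_disjoint_exhaustive(self, small_cohort):
        plan = split_threefold(small_cohort, seed=2)
        all_ids = [pid for g in ("F1", "F2", "F3", "test")
                   for pid in plan.members(g)]
        assert sorted(all_ids) == sorted(
            p.patient_id for p in small_cohort.labelled())

    def test_deterministic_and_seed_sensitive(self, small_cohort):
        p1 = split_threefold(small_cohort, seed=3)
        p2 = split_threefold(small_cohort, seed=3)
        p3 = split_threefold(small_cohort, seed=4)
        assert p1.fold_assignment == p2.fold_assignment
        assert p1.fold_assignment != p3.fold_assignment

    def test_stratification_spreads_classes(self, small_cohort):
        plan = split_threefold(small_cohort, seed=5)
        by_id = {p.patient_id: p for p in small_cohort}
        for f in ("F1", "F2", "F3"):
            labels = {by_id[pid].label for pid in plan.members(f)}
            assert len(labels) == 2

    def test_too_few_patients_rejected(self):
        c = generate_cohort(SynthConfig(n_patients=4, image_size=16, seed=0))
        with pytest.raises(ValueError):
            split_threefold(c, seed=0)


class TestLongitudinalEliminate:
    def _record(self, T):
        img = CellImage(np.zeros((16, 16, 3)), cell_class=CellClass.CTC)
        cells = [CellObservation(float(t), [img]) for t in range(T)]
        return PatientRecord(patient_id="P", cell_series=cells,
                             label=ResponseLabel.RESPONDER)

    def test_eighty_percent_of_five_keeps_four(self):
        r = longitudinal_eliminate(self._record(5), 0.8,
                                   np.random.default_rng(0))
        assert len(r.cell_series) == 4

    def test_single_timepoint_never_dropped(self):
        r = longitudinal_eliminate(self._record(1), 0.5,
                                   np.random.default_rng(0))
        assert len(r.cell_series) == 1

    def test_frac_one_is_identity(self):
        r = longitudinal_eliminate(self._record(4), 1.0,
                                   np.random.default_rng(0))
        assert len(r.cell_series) == 4

    def test_chronology_preserved_and_never_empty(self):
        rng = np.random.default_rng(1)
        for T in range(1, 8):
            for frac in (0.3, 0.5, 0.8):
                r = longitudinal_eliminate(self._record(T), frac, rng)
                times = [o.t_days for o in r.cell_series]
                assert times == sorted(times)
                assert len(times) >= 1

    def test_round_half_to_even(self):
        # 0.5 * 5 = 2.5 -> 2 under banker's rounding
        r = longitudinal_eliminate(self._record(5), 0.5,
                                   np.random.default_rng(2))
        assert len(r.cell_series) == 2

    def test_bad_frac_rejected(self):
        with pytest.raises(ValueError):
            longitudinal_eliminate(self._record(3), 0.0,
                                   np.random.default_rng(0))


SMALL_MCFG = ModelConfig(embed_dim=16, n_heads=2, cnn_width=4,
                         marker_hidden=8, seed=0)


def tiny_train_cfg(**kw):
    base = dict(epochs=2, learning_rate=1e-3, batch_size=4, seed=0,
                image_out_size=16)
    base.update(kw)
    return TrainConfig(**base)


class TestTrainFold:
    def test_epoch_losses_deterministic_under_seed(self, tiny_cohort):
        pats = tiny_cohort.labelled()
        train, val = pats[:4], pats[4:]
        r1 = train_fold(train, val, SMALL_MCFG, FusionConfig(mode="tim"),
                        tiny_train_cfg())
        r2 = train_fold(train, val, SMALL_MCFG, FusionConfig(mode="tim"),
                        tiny_train_cfg())
        assert abs(r1.loss_history[0] - r2.loss_history[0]) < 1e-6
        assert r1.loss_history == pytest.approx(r2.loss_history)

    def test_empty_val_rejected(self, tiny_cohort):
        pats = tiny_cohort.labelled()
        with pytest.raises(ValueError):
            train_fold(pats, [], SMALL_MCFG, FusionConfig(mode="tim"),
                       tiny_train_cfg())

    def test_single_class_train_rejected(self, tiny_cohort):
        pats = [p for p in tiny_cohort.labelled()
                if p.label is ResponseLabel.RESPONDER]
        if len(pats) < 2:
            pytest.skip("fixture lacks two responders")
        with pytest.raises(ValueError, match="both classes"):
            train_fold(pats, pats, SMALL_MCFG, FusionConfig(mode="tim"),
                       tiny_train_cfg())

    def test_finetune_path_trains_cnn(self, tiny_cohort):
        pats = tiny_cohort.labelled()
        tcfg = tiny_train_cfg(epochs=1, freeze_cnn=False)
        res = train_fold(pats[:4], pats[4:], SMALL_MCFG,
                         FusionConfig(mode="tim"), tcfg)
        # CNN weights must have moved away from the seeded init
        from dam.fusion import DAMNet
        ref = DAMNet(SMALL_MCFG, FusionConfig(mode="tim"))
        moved = sum(
            float(np.abs(a.data - b.data).sum())
            for a, b in zip(res.model.cell_encoder.cnn.parameters(),
                            ref.cell_encoder.cnn.parameters()))
        assert moved > 0


class TestEnsemble:
    def test_mean_of_probs_and_convexity(self, tiny_cohort, model_cfg):
        from dam.fusion import DAMNet
        rec = next(p for p in tiny_cohort if p.cell_series
                   and p.marker_series)
        nets = []
        for s in (0, 1, 2):
            net = DAMNet(dataclasses.replace(model_cfg, seed=s),
                         FusionConfig(mode="tim"))
            net.marker_encoder.scaler.fit(
                [o.panel for p in tiny_cohort for o in p.marker_series])
            nets.append(net)
        members = [n.predict_record(rec).prob_responder for n in nets]
        ens = ensemble_predict(nets, rec).prob_responder
        assert ens == pytest.approx(np.mean(members), abs=1e-9)
        assert min(members) - 1e-12 <= ens <= max(members) + 1e-12

    def test_identical_members_equal_single(self, tiny_cohort, model_cfg):
        from dam.fusion import DAMNet
        rec = next(p for p in tiny_cohort if p.cell_series
                   and p.marker_series)
        net = DAMNet(model_cfg, FusionConfig(mode="tim"))
        net.marker_encoder.scaler.fit(
            [o.panel for p in tiny_cohort for o in p.marker_series])
        single = net.predict_record(rec).prob_responder
        ens = ensemble_predict([net, net, net], rec).prob_responder
        assert ens == pytest.approx(single, abs=1e-12)

    def test_mismatched_configs_rejected(self, tiny_cohort, model_cfg):
        from dam.fusion import DAMNet
        rec = tiny_cohort.patients[0]
        a = DAMNet(model_cfg, FusionConfig(mode="tim"))
        b = DAMNet(model_cfg, FusionConfig(mode="tci_only"))
        with pytest.raises(ValueError, match="configuration"):
            ensemble_predict([a, b], rec)


class TestCountingBaseline:
    def test_null_signal_hovers_near_chance(self):
        aucs = []
        for seed in (0, 1, 2):
            c = generate_cohort(SynthConfig(n_patients=60, image_size=16,
                                            effect_size=2.0, seed=seed))
            plan = split_threefold(c, seed=seed)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cv_reports, _ = counting_baseline(c, plan, seed=seed)
            aucs.extend(r.auc for r in cv_reports)
        # dynamics-only signal: baseline counts are uninformative
        assert abs(np.mean(aucs) - 0.5) < 0.2

    def test_counts_ordered_by_label_gives_high_auc(self):
        # construct a cohort whose baseline counts encode the label
        img = lambda: CellImage(np.zeros((16, 16, 3)),
                                cell_class=CellClass.CTC)
        pats = []
        rng = np.random.default_rng(0)
        for i in range(30):
            responder = i % 2 == 0
            n = int(rng.integers(8, 12)) if responder \
                else int(rng.integers(1, 4))
            pats.append(PatientRecord(
                patient_id=f"Q{i}",
                cell_series=[CellObservation(0.0, [img() for _ in range(n)])],
                label=(ResponseLabel.RESPONDER if responder
                       else ResponseLabel.NON_RESPONDER)))
        c = Cohort(patients=pats)
        plan = split_threefold(c, seed=1)
        cv_reports, test_report = counting_baseline(c, plan, seed=1)
        assert np.mean([r.auc for r in cv_reports]) > 0.9

    def test_deterministic_under_seed(self, small_cohort):
        plan = split_threefold(small_cohort, seed=2)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r1, t1 = counting_baseline(small_cohort, plan, seed=3)
            r2, t2 = counting_baseline(small_cohort, plan, seed=3)
        assert [r.auc for r in r1] == [r.auc for r in r2]
        assert t1.auc == t2.auc


class TestCrossValidationDriver:
    def test_smoke_on_small_cohort(self, small_cohort):
        mcfg = ModelConfig(embed_dim=16, n_heads=2, cnn_width=4,
                           marker_hidden=8, seed=0)
        tcfg = TrainConfig(epochs=2, batch_size=4, seed=0,
                           image_out_size=16)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cv = run_cross_validation(small_cohort, mcfg,
                                      FusionConfig(mode="tim"), tcfg)
        assert len(cv.fold_results) == 3
        assert all(len(fr.loss_history) == 2 for fr in cv.fold_results)
        assert cv.test_report.n == len(cv.split.members("test"))
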