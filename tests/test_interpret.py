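"""Grad-CAM, focus-area statistics, importance analyses."""

import warnings

import numpy as np
import pytest
from scipy import ndimage

from dam.cohort import ResponseLabel
from dam.interpret import (AttentionMap, FA_FEATURE_NAMES, FocusMask,
                           cell_importance_scores, dynamic_features,
                           fa_mlp, focus_mask, gradcam, gradcam_from_graph,
                           gradcam_record, patient_focus_features,
                           permutation_importance)
from dam.metrics import mannwhitney_u
from dam.nn.autograd import Tensor
from dam.synth import SynthConfig, generate_cohort
from dam.training import split_threefold


class TestGradCAM:
    def test_analytic_single_channel_model(self):
        """If the scalar output is the mean of channel 0, the map is
        proportional to channel 0's (rectified) activation."""
        rng = np.random.default_rng(0)
        acts = Tensor(rng.normal(size=(1, 3, 4, 4)), requires_grad=True)
        out = acts.mean(axis=(2, 3))[0, 0]
        out.backward()
        amap = gradcam_from_graph(acts, (4, 4))
        expect = np.maximum(acts.data[0, 0] / 16.0, 0.0)
        np.testing.assert_allclose(amap.values, expect, atol=1e-12)

    def test_nonnegative_and_input_sized(self, tim_net, tiny_cohort):
        rec = next(p for p in tiny_cohort if p.cell_series)
        from dam.imageprep import AugmentConfig, preprocess_eval
        img = preprocess_eval(rec.cell_series[0].images[0],
                              AugmentConfig(out_size=32))
        amap = gradcam(tim_net, img)
        assert amap.values.shape == (32, 32)
        assert amap.values.min() >= 0.0

    def test_deterministic(self, tim_net, tiny_cohort):
        rec = next(p for p in tiny_cohort if p.cell_series)
        from dam.imageprep import AugmentConfig, preprocess_eval
        img = preprocess_eval(rec.cell_series[0].images[0],
                              AugmentConfig(out_size=32))
        a = gradcam(tim_net, img).values
        b = gradcam(tim_net, img).values
        np.testing.assert_array_equal(a, b)

    def test_record_level_one_map_per_image(self, tim_net, tiny_cohort):
        rec = next(p for p in tiny_cohort
                   if p.cell_series and p.marker_series)
        maps = gradcam_record(tim_net, rec)
        assert len(maps) == rec.n_images
        assert all(m.values.min() >= 0 for m in maps)


class TestFocusMask:
    def test_constant_map_empty_foreground(self):
        fm = focus_mask(AttentionMap(np.full((8, 8), 3.3)))
        assert fm.F == 0 and fm.D == 0

    def test_hand_computed_percentile_4x4(self):
        fm = focus_mask(AttentionMap(np.arange(1.0, 17.0).reshape(4, 4)))
        # 75th percentile (linear interpolation) of 1..16 is 12.25
        assert fm.F == 4
        assert fm.mask.sum() == 4
        assert fm.mask.ravel().tolist() == [False] * 12 + [True] * 4

    def test_two_blocks_two_components(self):
        m = np.zeros((10, 10))
        m[1:3, 1:3] = 1.0
        m[7:9, 7:9] = 1.0
        fm = focus_mask(AttentionMap(m))
        assert fm.D == 2 and fm.F == 8

    def test_diagonal_counts_as_connected(self):
        m = np.zeros((6, 6))
        m[1, 1] = m[2, 2] = 1.0
        fm = focus_mask(AttentionMap(m))
        assert fm.D == 1  # 8-connectivity joins diagonals

    def test_components_match_reference_floodfill(self):
        rng = np.random.default_rng(1)
        eight = np.ones((3, 3))
        for _ in range(200):
            side = int(rng.integers(4, 33))
            grid = rng.random((side, side)) < 0.35
            amap = AttentionMap(grid.astype(float))
            fm = focus_mask(amap, percentile=50.0)
            _, n_ref = ndimage.label(fm.mask, structure=eight)
            assert fm.D == n_ref
            assert fm.F == fm.mask.sum()


def brute_force_features(Fs, Ds):
    N = len(Fs)
    avg = sum(Fs) / N
    var = sum((f - avg) ** 2 for f in Fs) / (N - 1) if N > 1 else 0.0
    srt = sorted(Fs)
    med = (srt[(N - 1) // 2] + srt[N // 2]) / 2
    return (var, min(Fs), max(Fs), avg, med, sum(Ds))


class TestDynamicFeatures:
    def test_worked_example(self):
        masks = [FocusMask(np.zeros((1, 1), bool), F, D)
                 for F, D in [(4, 1), (9, 3), (2, 0)]]
        f = dynamic_features(masks)
        assert (f.AvgFA, f.VarFA, f.MinFA, f.MaxFA, f.MedFA) == \
            (5.0, 13.0, 2.0, 9.0, 4.0)
        assert f.DisFA == 4  # summed, not averaged

    def test_all_equal(self):
        masks = [FocusMask(np.zeros((1, 1), bool), 7, 1)] * 4
        f = dynamic_features(masks)
        assert f.AvgFA == f.MinFA == f.MaxFA == f.MedFA == 7.0
        assert f.VarFA == 0.0

    def test_single_image_variance_zero(self):
        f = dynamic_features([FocusMask(np.zeros((1, 1), bool), 5, 2)])
        assert f.VarFA == 0.0 and f.N == 1

    def test_matches_bruteforce_on_1000_random_inputs(self):
        rng = np.random.default_rng(2)
        for _ in range(1000):
            N = int(rng.integers(1, 12))
            Fs = rng.integers(0, 500, size=N).tolist()
            Ds = rng.integers(0, 6, size=N).tolist()
            masks = [FocusMask(np.zeros((1, 1), bool), F, D)
                     for F, D in zip(Fs, Ds)]
            f = dynamic_features(masks)
            var, mn, mx, avg, med, dis = brute_force_features(Fs, Ds)
            assert f.VarFA == pytest.approx(var)
            assert (f.MinFA, f.MaxFA) == (mn, mx)
            assert f.AvgFA == pytest.approx(avg)
            assert f.MedFA == pytest.approx(med)
            assert f.DisFA == dis
            assert f.MinFA <= f.MedFA <= f.MaxFA
            assert f.MinFA <= f.AvgFA <= f.MaxFA
            assert f.VarFA >= 0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            dynamic_features([])


class TestCellImportance:
    def test_scores_sum_to_one_per_timepoint(self, tim_net, tiny_cohort):
        rec = next(p for p in tiny_cohort if p.cell_series)
        scores = cell_importance_scores(tim_net, rec)
        assert len(scores) == rec.n_images
        i = 0
        for obs in rec.cell_series:
            tp_scores = [s for _, _, s in scores[i:i + len(obs.images)]]
            assert sum(tp_scores) == pytest.approx(1.0, abs=1e-6)
            i += len(obs.images)

    def test_single_cell_scores_one(self, tim_net, tiny_cohort):
        rec = next(p for p in tiny_cohort
                   if any(len(o.images) == 1 for o in p.cell_series))
        scores = cell_importance_scores(tim_net, rec)
        i = 0
        for obs in rec.cell_series:
            if len(obs.images) == 1:
                assert scores[i][2] == pytest.approx(1.0)
            i += len(obs.images)

    def test_duplicate_cells_split_the_mass(self, tim_net):
        from dam.nn.autograd import Tensor
        rng = np.random.default_rng(3)
        enc = tim_net.cell_encoder
        v = rng.normal(size=(1, tim_net.cfg.embed_dim))
        enc.aggregate_cells(Tensor(np.repeat(v, 3, axis=0)))
        w = enc.cell_importances()
        np.testing.assert_allclose(w, 1 / 3, atol=1e-12)


@pytest.fixture(scope="module")
def fa_dataset():
    """Synthetic focus-area features where AvgFA carries the label."""
    rng = np.random.default_rng(4)
    c = generate_cohort(SynthConfig(n_patients=40, image_size=16,
                                    cells_per_tp_mean=1.0, seed=12))
    feats, labels = {}, {}
    for p in c.labelled():
        y = p.label is ResponseLabel.RESPONDER
        avg = rng.normal(40 if y else 10, 3)
        # only AvgFA (index 3) is informative; the rest is noise
        arr = np.array([rng.normal(5, 1), rng.normal(20, 5),
                        rng.normal(60, 5), avg, rng.normal(30, 5),
                        rng.integers(1, 9)], dtype=float)
        feats[p.patient_id] = arr
        labels[p.patient_id] = y
    split = split_threefold(c, seed=6)
    return feats, labels, split


class TestFaMLP:
    def test_separating_feature_drives_auc_toward_one(self, fa_dataset):
        feats, labels, split = fa_dataset
        cv_reports, test_report, _ = fa_mlp(feats, labels, split, seed=0)
        assert np.mean([r.auc for r in cv_reports]) > 0.9
        assert max(r.auc for r in cv_reports) == 1.0

    def test_deterministic_under_seed(self, fa_dataset):
        feats, labels, split = fa_dataset
        r1, t1, _ = fa_mlp(feats, labels, split, seed=1)
        r2, t2, _ = fa_mlp(feats, labels, split, seed=1)
        assert [r.auc for r in r1] == [r.auc for r in r2]
        assert t1.auc == t2.auc

    def test_shuffled_labels_near_chance(self, fa_dataset):
        feats, labels, split = fa_dataset
        rng = np.random.default_rng(7)
        ids = list(labels)
        vals = rng.permutation([labels[i] for i in ids])
        shuffled = dict(zip(ids, vals.tolist()))
        try:
            cv_reports, _, _ = fa_mlp(feats, shuffled, split, seed=2)
        except ValueError:
            pytest.skip("shuffle produced a single-class fold")
        assert abs(np.mean([r.auc for r in cv_reports]) - 0.5) < 0.25


class TestPermutationImportance:
    def test_informative_feature_dominates_constant_column(self, fa_dataset):
        feats, labels, split = fa_dataset
        # make VarFA constant across patients
        feats = {k: v.copy() for k, v in feats.items()}
        for v in feats.values():
            v[0] = 1.0
        _, _, models = fa_mlp(feats, labels, split, seed=3)
        ids = [i for i in split.members("test") if i in feats]
        imp = permutation_importance(models, feats, labels, ids,
                                     n_reps=10, seed=3)
        assert abs(imp["VarFA"][0]) < 1e-9          # constant column: 0
        assert imp["AvgFA"][0] > 0.2                # the real signal

    def test_deterministic_under_seed(self, fa_dataset):
        feats, labels, split = fa_dataset
        _, _, models = fa_mlp(feats, labels, split, seed=4)
        ids = [i for i in split.members("test") if i in feats]
        a = permutation_importance(models, feats, labels, ids, n_reps=5,
                                   seed=9)
        b = permutation_importance(models, feats, labels, ids, n_reps=5,
                                   seed=9)
        assert a == b

    def test_nreps_validation(self, fa_dataset):
        feats, labels, split = fa_dataset
        _, _, models = fa_mlp(feats, labels, split, seed=5)
        with pytest.raises(ValueError):
            permutation_importance(models, feats, labels,
                                   list(feats)[:4], n_reps=0)


class TestFocusFeatureProperties:
    def test_per_map_threshold_caps_foreground_fraction(self, model_cfg):
        """Strict thresholding at the per-map 75th percentile bounds the
        focus area by a quarter of the pixels — the structural reason
        per-map thresholds measure shape, not overall activation level."""
        from dam.fusion import DAMNet, FusionConfig
        from dam.imageprep import AugmentConfig
        c = generate_cohort(SynthConfig(n_patients=4, image_size=24,
                                        cells_per_tp_mean=1.5, seed=15))
        net = DAMNet(model_cfg, FusionConfig(mode="tim"))
        net.marker_encoder.scaler.fit(
            [o.panel for p in c for o in p.marker_series])
        aug = AugmentConfig(out_size=24)
        rec = next(p for p in c.labelled() if p.cell_series)
        f = patient_focus_features(net, rec, aug)
        assert f.MaxFA <= 0.25 * 24 * 24 + 1

    def test_label_contrast_lives_in_nucleus_area(self):
        """Generator-level analogue of the published size contrast:
        responders' nuclei shrink over treatment, so late-timepoint
        nuclear (blue-channel) areas separate the labels."""
        c = generate_cohort(SynthConfig(n_patients=80, image_size=24,
                                        cells_per_tp_mean=1.0,
                                        effect_size=2.0, seed=15))
        groups = {True: [], False: []}
        for p in c.labelled():
            if not p.cell_series:
                continue
            last = p.cell_series[-1]
            area = np.mean([(im.pixels[:, :, 2] > 0.4).sum()
                            for im in last.images])
            groups[p.label is ResponseLabel.RESPONDER].append(area)
        _, pval = mannwhitney_u(groups[True], groups[False])
        assert pval < 0.05
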