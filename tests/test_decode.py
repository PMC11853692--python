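"""Nested preprocessing, the CV engine, TGM, searchlight, montage tests."""

import warnings

import numpy as np
import pytest

import erpdecode as ed
from erpdecode.decode import _run_cv, stratified_splits

from conftest import balanced_null


class TestZScore:
    def test_hand_arithmetic(self):
        ztr, zte, stats = ed.zscore_train_apply(
            np.array([[1.0], [2.0], [3.0]]), np.array([[4.0]]))
        np.testing.assert_allclose(ztr[:, 0], [-1, 0, 1])  # sample sd = 1
        assert zte[0, 0] == pytest.approx(2.0)

    def test_idempotent_on_standardized_train(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(50, 4))
        x = (x - x.mean(0)) / x.std(0, ddof=1)
        ztr, _, _ = ed.zscore_train_apply(x, x[:5])
        np.testing.assert_allclose(ztr, x, atol=1e-12)

    def test_applying_twice_differs_and_stats_roundtrip(self):
        rng = np.random.default_rng(1)
        tr, te = rng.normal(2, 3, (20, 3)), rng.normal(2, 3, (5, 3))
        ztr, zte, stats = ed.zscore_train_apply(tr, te)
        assert not np.allclose(stats.apply(ztr), ztr)
        back = ed.ZScoreStats.from_dict(stats.to_dict())
        np.testing.assert_allclose(back.apply(te), zte)

    def test_zero_variance_feature_centered_with_warning(self):
        tr = np.array([[1.0, 5.0], [2.0, 5.0], [3.0, 5.0]])
        with pytest.warns(RuntimeWarning, match="zero-variance"):
            ztr, zte, _ = ed.zscore_train_apply(tr, tr[:1])
        np.testing.assert_allclose(ztr[:, 1], 0.0)  # centered, not scaled


class TestAverageSamples:
    def test_group_count_is_floor_n_over_k(self):
        x = np.arange(23)[:, None].astype(float)
        y = np.zeros(23)
        with pytest.raises(ValueError):
            ed.average_samples(x, y, 0)
        xa, ya = ed.average_samples(np.vstack([x, x]),
                                    np.r_[np.zeros(23), np.ones(23)], 5, 0)
        assert (ya == 0).sum() == 4 and (ya == 1).sum() == 4

    def test_k1_is_identity_up_to_order(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(10, 3))
        y = np.r_[np.zeros(5), np.ones(5)]
        xa, ya = ed.average_samples(x, y, 1, 0)
        assert sorted(map(tuple, xa)) == sorted(map(tuple, x))

    def test_pseudo_trial_variance_shrinks_by_k(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(5000, 1))
        y = np.zeros(5000)
        xa, _ = ed.average_samples(x, y, 5, 0)
        ratio = xa.var() / x.var()
        assert ratio == pytest.approx(1 / 5, rel=0.15)

    def test_too_few_trials_raises(self):
        with pytest.raises(ValueError, match="fewer than group size"):
            ed.average_samples(np.zeros((3, 2)), np.zeros(3), 5, 0)


class TestTimeResolved:
    def test_label_flip_symmetry(self, signal_epochs, fast_cfg):
        # evaluation-time flip: scoring a fixed classifier with the class
        # roles swapped mirrors the AUC exactly ...
        rng = np.random.default_rng(0)
        d_dev, d_std = rng.normal(1, 1, 40), rng.normal(0, 1, 40)
        assert ed.auc(d_std, d_dev) == pytest.approx(
            1.0 - ed.auc(d_dev, d_std), abs=1e-15)
        # ... whereas relabeling the *input* retrains the classifier too;
        # the pipeline is then exactly flip-invariant because folds and
        # groupings are assigned label-blind
        curve = ed.decode_time_resolved(signal_epochs, fast_cfg)
        flipped = signal_epochs.copy()
        flipped.labels = np.where(flipped.labels == ed.DEVIANT,
                                  ed.STANDARD, ed.DEVIANT).astype(object)
        curve_f = ed.decode_time_resolved(flipped, fast_cfg)
        np.testing.assert_allclose(curve_f.auc, curve.auc, atol=1e-12)

    def test_auc_bounds_and_dispersion_nonnegative(self, signal_epochs,
                                                   fast_cfg):
        curve = ed.decode_time_resolved(signal_epochs, fast_cfg)
        assert np.all(curve.auc >= 0) and np.all(curve.auc <= 1)
        assert np.all(curve.dispersion >= 0)
        assert len(curve.times) == signal_epochs.n_samples

    def test_strong_signal_peaks_in_component_window(self, signal_epochs,
                                                     fast_cfg):
        curve = ed.decode_time_resolved(signal_epochs, fast_cfg)
        lat, mx = curve.peak()
        assert mx > 0.8
        assert 0.1 <= lat <= 0.4

    def test_unbalanced_input_warns(self, fast_cfg):
        cfg = ed.SimulationConfig(n_blocks=1, trials_per_block=150,
                                  p_deviant=0.4, sfreq=64, seed=44)
        e = ed.generate_epochs(cfg)  # not undersampled
        with pytest.warns(RuntimeWarning, match="unbalanced"):
            ed.decode_time_resolved(e.crop(-0.1, 0.1), fast_cfg)

    def test_too_few_trials_for_grouping_raises(self, fast_cfg):
        e = balanced_null(24, seed=8)
        with pytest.raises(ValueError, match="too few trials"):
            ed.decode_time_resolved(e, fast_cfg.with_(group_size=5))

    def test_fold_hygiene_test_partition_cannot_leak(self, fast_cfg):
        # corrupt trials that only ever appear in test folds of a single
        # split schedule and check the training-side outcome is unchanged
        e = balanced_null(60, seed=12, sfreq=32)
        cfg = fast_cfg.with_(n_repetitions=1, seed=5)
        rng = np.random.default_rng(cfg.seed)
        splits, _ = stratified_splits(e.y(), cfg.n_folds, rng)
        train_idx, test_idx = splits[0]
        probe = e.copy()
        probe.data[test_idx] += 1e4  # absurd artifact confined to test fold 1
        clean_first = _fold_curve(e, cfg, fold=0)
        probe_first = _fold_curve(probe, cfg, fold=0)
        # identical training side: the huge test artifact moves the test
        # scores but cannot change the fitted classifiers; AUC of a
        # constant-shifted test set against the same classifier is invariant
        np.testing.assert_allclose(clean_first, probe_first, atol=1e-12)

    def test_pseudo_trial_averaging_raises_peak_auc(self):
        # SNR gain of k=5 grouping over k=1, stochastic over 20 seeds
        wins = []
        for seed in range(20):
            cfg = ed.SimulationConfig(
                n_blocks=1, trials_per_block=180, p_deviant=0.4, sfreq=32,
                components=(ed.mmn_component(-3.0),),
                noise_white_sd=10.0, noise_pink_scale=0.0, seed=200 + seed)
            e = ed.undersample_balance(ed.generate_epochs(cfg), seed)
            e = e.crop(0.05, 0.35)
            base = ed.DecodingConfig(n_folds=5, n_repetitions=1,
                                     c_grid=(1.0,), seed=seed)
            a1 = ed.decode_time_resolved(e, base.with_(group_size=1)).auc.max()
            a5 = ed.decode_time_resolved(e, base.with_(group_size=5)).auc.max()
            wins.append(a5 - a1)
        assert np.mean(wins) > 0


def _fold_curve(e, cfg, fold):
    stacked, _ = _run_cv(e, cfg, mode="diag")
    return stacked[fold]


class TestTemporalGeneralization:
    def test_diagonal_matches_time_resolved_curve(self, fast_cfg):
        e = balanced_null(80, seed=15, sfreq=32)
        cfg = fast_cfg.with_(c_grid=(0.1, 1.0, 10.0))
        curve = ed.decode_time_resolved(e, cfg)
        tgm = ed.decode_temporal_generalization(e, cfg)
        np.testing.assert_allclose(tgm.diagonal(), curve.auc, atol=1e-12)

    def test_shared_topography_generalizes_off_diagonal(self, fast_cfg):
        # two components with the same spatial pattern at 150 and 450 ms:
        # a classifier trained at one latency transfers to the other
        topo = {"Fz": 1.0, "Cz": 1.0}
        comps = (ed.ComponentSpec("early", 0.150, 0.080, 5.0, topo),
                 ed.ComponentSpec("late", 0.450, 0.080, 5.0, topo))
        cfg = ed.SimulationConfig(
            n_blocks=1, trials_per_block=200, p_deviant=0.4, sfreq=64,
            components=comps, noise_white_sd=5.0, noise_pink_scale=0.0,
            seed=71)
        e = ed.undersample_balance(ed.generate_epochs(cfg), 0)
        tgm = ed.decode_temporal_generalization(e, fast_cfg)
        i = np.argmin(np.abs(tgm.times - 0.150))
        j = np.argmin(np.abs(tgm.times - 0.450))
        assert tgm.auc[i, j] > 0.7 and tgm.auc[j, i] > 0.7

    def test_null_matrix_is_flat_at_chance(self, null_epochs, fast_cfg):
        tgm = ed.decode_temporal_generalization(null_epochs.crop(-0.1, 0.2),
                                                fast_cfg)
        assert abs(tgm.auc.mean() - 0.5) < 0.05
        assert np.all(tgm.auc >= 0) and np.all(tgm.auc <= 1)


class TestSearchlight:
    def test_signal_channels_win_and_silent_channels_stay_at_chance(self):
        topo = {"Fz": 1.0, "Cz": 1.0}
        cfg = ed.SimulationConfig(
            n_blocks=1, trials_per_block=240, p_deviant=0.4, sfreq=64,
            components=(ed.ComponentSpec("MMN", 0.190, 0.080, -6.0, topo),),
            noise_white_sd=5.0, noise_pink_scale=0.0, seed=81)
        e = ed.undersample_balance(ed.generate_epochs(cfg), 0)
        dcfg = ed.DecodingConfig(group_size=2, n_repetitions=2,
                                 c_grid=(1.0,), seed=3)
        windows = ((-0.100, 0.0), (0.150, 0.250))
        sl = ed.searchlight_channels(e, dcfg, windows)
        assert sl.auc.shape == (11, 2)
        assert set(sl.best_channels(1, top=2)) == {"Fz", "Cz"}
        # baseline window: chance for every channel
        assert np.all(np.abs(sl.auc[:, 0] - 0.5) < 0.15)
        # zero-topography channels: chance in the component window too
        silent = [e.channels.index(c) for c in ("T7", "T8", "P3", "P4")]
        assert np.all(np.abs(sl.auc[silent, 1] - 0.5) < 0.15)

    def test_overlapping_windows_rejected(self, signal_epochs, fast_cfg):
        with pytest.raises(ValueError, match="non-overlapping"):
            ed.searchlight_channels(signal_epochs, fast_cfg,
                                    ((0.0, 0.2), (0.1, 0.3)))

    def test_default_windows_span_baseline_plus_50ms_bins(self):
        from erpdecode.decode import DEFAULT_SEARCHLIGHT_WINDOWS as W
        assert W[0] == (-0.100, 0.0)
        assert len(W) == 11
        assert W[1] == (0.050, 0.100) and W[-1] == (0.500, 0.550)


class TestCompareMontages:
    # topography confined to the frontocentral subset: the dropped
    # channels carry pure noise by construction
    _topo = {"Fz": 1.0, "Cz": 1.0, "F3": 0.7, "F4": 0.7, "C3": 0.7, "C4": 0.7}

    def _subjects(self, n, seed0, amp=-5.0):
        out = []
        for s in range(n):
            cfg = ed.SimulationConfig(
                n_blocks=1, trials_per_block=140, p_deviant=0.4, sfreq=32,
                components=(ed.mmn_component(amp, topography=self._topo),),
                noise_white_sd=6.0, noise_pink_scale=0.0, seed=seed0 + s)
            out.append(ed.undersample_balance(ed.generate_epochs(cfg), s))
        return out

    def test_identity_subset_gives_t_zero(self, fast_cfg):
        subs = self._subjects(3, 900)
        res = ed.compare_montages(subs, list(ed.DEFAULT_MONTAGE), fast_cfg)
        np.testing.assert_allclose(res.max_auc_full, res.max_auc_subset)
        assert res.t_statistic == 0.0

    def test_signal_carrying_subset_not_significantly_worse(self, fast_cfg):
        # all component topography lives on the frontocentral subset, so
        # dropping the silent channels must not significantly *reduce*
        # peak AUC (it may slightly improve it by removing noise features)
        subs = self._subjects(6, 950)
        subset = ["F3", "Fz", "F4", "C3", "Cz", "C4"]
        res = ed.compare_montages(subs, subset, fast_cfg)
        worse = res.t_statistic > 0 and res.p_value < 0.05
        assert not worse

    def test_paired_t_matches_closed_form_on_two_pairs(self):
        from scipy import stats as spstats
        full, sub = np.array([0.9, 0.8]), np.array([0.85, 0.7])
        d = full - sub
        expect = d.mean() / (d.std(ddof=1) / np.sqrt(2))
        t, _ = spstats.ttest_rel(full, sub)
        assert t == pytest.approx(expect)

    def test_empty_subset_raises(self, fast_cfg):
        with pytest.raises(ValueError, match="nonempty"):
            ed.compare_montages([], [], fast_cfg)
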