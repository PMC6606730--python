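"""Determinism, labelled structure and statistical contracts of the
synthetic-data generator."""

import numpy as np
import pytest

from emofuse.containers import ValidationError
from emofuse.eeg_features import BANDS, band_average_energy
from emofuse.montage import DEFAULT_MONTAGE, SYMMETRIC_PAIRS
from emofuse.simulate import (
    SimConfig,
    simulate_dataset,
    simulate_eeg_trial,
    simulate_eye_record,
    simulate_rating_table,
)

BROADBAND = type(BANDS[0])("broad", 0.5, 40.0)


class TestEEGTrial:
    def test_fixed_seed_is_bit_identical(self, short_cfg):
        a = simulate_eeg_trial(short_cfg, 3, 4, np.random.default_rng(7))
        b = simulate_eeg_trial(short_cfg, 3, 4, np.random.default_rng(7))
        assert np.array_equal(a.data, b.data)

    def test_level_out_of_range_rejected(self, short_cfg):
        with pytest.raises(ValidationError):
            simulate_eeg_trial(short_cfg, 0, 3, np.random.default_rng(0))
        with pytest.raises(ValidationError):
            simulate_eeg_trial(short_cfg, 3, 6, np.random.default_rng(0))

    def test_zero_asymmetry_balances_hemispheres(self, monkeypatch):
        """With zero valence asymmetry (and the trial-level asymmetry jitter
        silenced) both hemispheres get identical amplitude factors, so the
        expected left-right band-power difference is 0 on every pair."""
        import emofuse.simulate as sim
        from emofuse.simulate import _pair_side_factors

        assert np.allclose(_pair_side_factors(0.0), 1.0)

        monkeypatch.setattr(sim, "ASYM_JITTER_SD", 0.0)
        cfg = SimConfig(
            n_trials_per_level=1,
            trial_duration_s=10.0,
            seed=0,
            valence_asymmetry_per_level=(0.0,) * 5,
        )
        diffs = []
        ss = np.random.SeedSequence(21)
        for child in ss.spawn(30):
            t = sim.simulate_eeg_trial(cfg, 3, 3, np.random.default_rng(child),
                                       noise_sd=0.0)
            power = np.mean(t.data**2, axis=1)
            for left, right in SYMMETRIC_PAIRS:
                diffs.append(
                    power[DEFAULT_MONTAGE.index(left)]
                    - power[DEFAULT_MONTAGE.index(right)]
                )
        diffs = np.array(diffs)
        # independent residuals across 360 pair-trials: the mean is within
        # sampling error of zero
        assert abs(diffs.mean()) < 3 * diffs.std() / np.sqrt(len(diffs))

    def test_broadband_energy_increases_with_arousal_level(self):
        """Monte-Carlo check with the package's own AE operator: the mean
        broadband energy is strictly increasing in the arousal level."""
        cfg = SimConfig(n_trials_per_level=1, trial_duration_s=5.0, seed=0)
        means = []
        ss = np.random.SeedSequence(33)
        children = iter(ss.spawn(5 * 50))
        for level in range(1, 6):
            vals = []
            for _ in range(50):
                t = simulate_eeg_trial(cfg, level, 3,
                                       np.random.default_rng(next(children)))
                vals.append(band_average_energy(t.data[0], cfg.sampling_rate_hz,
                                                BROADBAND))
            means.append(np.mean(vals))
        assert all(means[i] < means[i + 1] for i in range(4))


class TestEyeRecord:
    def test_events_ordered_positive_and_inside_trial(self, short_cfg):
        rec = simulate_eye_record(short_cfg, 3, 3, np.random.default_rng(5))
        onsets = rec.events["onset_s"].to_numpy()
        durs = rec.events["duration_s"].to_numpy()
        assert np.all(np.diff(onsets) > 0)
        assert np.all(durs > 0)
        assert np.all(onsets + durs <= short_cfg.trial_duration_s)

    def test_events_do_not_overlap(self, short_cfg):
        rec = simulate_eye_record(short_cfg, 4, 2, np.random.default_rng(6))
        ends = (rec.events["onset_s"] + rec.events["duration_s"]).to_numpy()
        assert np.all(rec.events["onset_s"].to_numpy()[1:] >= ends[:-1] - 1e-12)

    def test_zero_coupling_leaves_pupil_uncorrelated(self):
        cfg = SimConfig(n_trials_per_level=1, seed=0, illum_coupling=0.0)
        rs = []
        for child in np.random.SeedSequence(9).spawn(30):
            rec = simulate_eye_record(cfg, 3, 3, np.random.default_rng(child))
            rs.append(np.corrcoef(rec.pupil, rec.luminance)[0, 1])
        assert abs(np.mean(rs)) < 0.1

    def test_blink_rate_separates_extreme_levels(self):
        """Level 5 doubles the blink rate of level 1; the blink-frequency
        feature separates the levels with AUC > 0.8 over 100 trials."""
        from emofuse.eye_features import assemble_eye_vector

        cfg = SimConfig(n_trials_per_level=1, seed=0)
        freqs, labels = [], []
        children = iter(np.random.SeedSequence(13).spawn(100))
        for level in (1, 5):
            for _ in range(50):
                rec = simulate_eye_record(cfg, level, 3,
                                          np.random.default_rng(next(children)))
                v = assemble_eye_vector(rec, cfg.trial_duration_s)
                freqs.append(v.values[list(v.names).index("blink_freq")])
                labels.append(level)
        freqs, labels = np.array(freqs), np.array(labels)
        lo, hi = freqs[labels == 1], freqs[labels == 5]
        auc = np.mean(hi[None, :] > lo[:, None]) + 0.5 * np.mean(
            hi[None, :] == lo[:, None]
        )
        assert auc > 0.8


class TestRatingTable:
    def test_row_count_and_positive_dispersion(self, rng):
        table = simulate_rating_table(120, rng)
        scores = table.scores()
        assert len(scores) == 120
        sds = table.ratings.groupby(["clip_id", "dimension"])["rating"].std()
        assert (sds > 0).all()

    def test_fixed_seed_reproducible(self):
        a = simulate_rating_table(50, np.random.default_rng(3)).ratings
        b = simulate_rating_table(50, np.random.default_rng(3)).ratings
        assert a.equals(b)

    def test_arousal_scores_span_anchor_range(self, rng):
        scores = simulate_rating_table(120, rng).scores()
        assert scores["score_arousal"].min() <= -2.5
        assert scores["score_arousal"].max() >= 2.5

    def test_too_few_clips_rejected(self, rng):
        with pytest.raises(ValidationError):
            simulate_rating_table(10, rng)


class TestDataset:
    def test_balanced_labels_on_both_dimensions(self, short_cfg):
        ds = simulate_dataset(short_cfg, eeg=False)
        for col in ("arousal_level", "valence_level"):
            counts = ds.labels[col].value_counts()
            assert sorted(counts.index) == [1, 2, 3, 4, 5]
            assert counts.nunique() == 1

    def test_dataset_determinism(self, short_cfg):
        a = simulate_dataset(short_cfg, eeg=False)
        b = simulate_dataset(short_cfg, eeg=False)
        assert a.labels.equals(b.labels)
        assert np.array_equal(a.eye_records[0].pupil, b.eye_records[0].pupil)

    def test_recoverable_structure_beats_chance(self, full_session):
        """A classifier trained on extracted features of the simulated
        session beats 20% chance on 5-level classification of either
        dimension (40 trials per level, fixed seed)."""
        from sklearn.model_selection import cross_val_score
        from sklearn.svm import SVC

        from emofuse.eeg_features import AbsMinMaxScaler

        ds, feats = full_session
        for dim, modality in (("arousal", "eeg"), ("valence", "eye")):
            X = AbsMinMaxScaler().fit_transform(feats[modality].to_numpy())
            y = ds.labels[f"{dim}_level"].to_numpy()
            acc = cross_val_score(SVC(kernel="rbf", C=1), X, y, cv=5).mean()
            assert acc > 0.2, f"{dim}/{modality} at chance"
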