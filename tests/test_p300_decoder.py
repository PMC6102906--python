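import numpy as np
import pytest

from neurochair.p300_decoder import (bandpass_filter, decode_trial,
                                     extract_epochs_and_featurize,
                                     label_features, score_and_classify,
                                     train_swlda, SWLDAModel)
from neurochair.synth_signals import (EEGRecord, ERPModel,
                                      make_stimulus_schedule,
                                      synth_eeg_session)

from oracles import oracle_swlda


def sine_record(freq, fs=500.0, dur=4.0, amp=1.0):
    t = np.arange(int(dur * fs)) / fs
    return EEGRecord(fs, ("ch",), amp * np.sin(2 * np.pi * freq * t))


class TestBandpass:
    def test_passband_preserves_amplitude(self):
        out = bandpass_filter(sine_record(10.0), 2, 25)
        tail = out.samples[0, 1000:]
        assert np.abs(tail).max() == pytest.approx(1.0, rel=0.05)

    def test_stopband_attenuates_50_hz(self):
        out = bandpass_filter(sine_record(50.0), 2, 25)
        assert np.abs(out.samples[0, 1000:]).max() < 0.1

    def test_dc_rejected(self):
        rec = EEGRecord(500.0, ("ch",), np.full(2000, 3.0))
        out = bandpass_filter(rec, 2, 25)
        assert np.abs(out.samples[0, -500:]).max() < 0.05

    def test_causality(self):
        # an impulse at sample k produces no output before k
        x = np.zeros(1000)
        x[600] = 1.0
        out = bandpass_filter(EEGRecord(500.0, ("ch",), x), 2, 25)
        assert np.all(out.samples[0, :600] == 0)

    def test_band_must_respect_nyquist(self):
        with pytest.raises(ValueError):
            bandpass_filter(sine_record(10.0), 2, 400)


class TestFeaturize:
    def test_one_feature_vector_per_event(self):
        s = make_stimulus_schedule(range(6), 3, seed=0)
        rec = synth_eeg_session(s, 0, ERPModel(), seed=0)
        feats = extract_epochs_and_featurize(rec, s, decim=25)
        assert len(feats) == 18
        assert all(f.values.shape == (12 * 16,) for f in feats)

    def test_constant_record_gives_constant_features(self):
        s = make_stimulus_schedule(range(6), 1, seed=0)
        n = int((s.span + 0.8) * 500)
        rec = EEGRecord(500.0, ("a", "b"), np.full((2, n), 7.5))
        feats = extract_epochs_and_featurize(rec, s, decim=20)
        for f in feats:
            np.testing.assert_allclose(f.values, 7.5)

    def test_identity_decimation_returns_raw_samples(self):
        s = make_stimulus_schedule([0], 1, seed=0)
        rng = np.random.default_rng(0)
        rec = EEGRecord(500.0, ("a",), rng.standard_normal(1000))
        feats = extract_epochs_and_featurize(rec, s, decim=1)
        np.testing.assert_array_equal(feats[0].values, rec.samples[0, :400])

    def test_short_record_error_names_event(self):
        s = make_stimulus_schedule(range(6), 3, seed=0)
        rec = EEGRecord(500.0, ("a",), np.zeros(900))
        with pytest.raises(ValueError, match="stimulus"):
            extract_epochs_and_featurize(rec, s)


class TestSWLDA:
    def test_perfect_feature_selected_noise_ignored(self):
        rng = np.random.default_rng(0)
        y = np.r_[np.ones(20), -np.ones(20)]
        X = np.column_stack([y + 0.01 * rng.standard_normal(40),
                             rng.standard_normal(40)])
        m = train_swlda(X, y)
        assert m.selected == [0]

    def test_matches_bruteforce_oracle_on_random_instances(self):
        rng = np.random.default_rng(2024)
        checked = 0
        while checked < 25:
            n = int(rng.integers(8, 31))
            p = int(rng.integers(2, 11))
            X = rng.standard_normal((n, p))
            beta = rng.standard_normal(p) * (rng.uniform(size=p) < 0.4)
            y = np.sign(X @ beta + 0.8 * rng.standard_normal(n))
            y[y == 0] = 1
            if min((y == 1).sum(), (y == -1).sum()) < 2:
                continue
            m = train_swlda(X, y)
            sel_o, w_o, b_o = oracle_swlda(X, y)
            assert sorted(m.selected) == sorted(sel_o)
            if sel_o:
                order = [m.selected.index(j) for j in sel_o]
                np.testing.assert_allclose(np.asarray(m.weights)[order], w_o,
                                           atol=1e-8)
                assert m.intercept == pytest.approx(b_o, abs=1e-8)
            checked += 1

    def test_shuffled_labels_rarely_admit_features(self):
        # with pure-noise labels the per-shuffle false entry rate ~ p_enter
        rng = np.random.default_rng(7)
        X = rng.standard_normal((40, 5))
        n_selected = []
        for _ in range(100):
            y = rng.permutation(np.r_[np.ones(20), -np.ones(20)])
            m = train_swlda(X, y, p_enter=0.05, p_remove=0.10)
            n_selected.append(len(m.selected))
        assert np.mean(n_selected) < 0.8

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            train_swlda(np.random.default_rng(0).standard_normal((6, 2)),
                        np.ones(6))

    def test_exactly_collinear_candidates_skipped(self):
        rng = np.random.default_rng(1)
        y = np.r_[np.ones(10), -np.ones(10)]
        x0 = y + 0.1 * rng.standard_normal(20)
        X = np.column_stack([x0, 2.0 * x0, rng.standard_normal(20)])
        m = train_swlda(X, y)
        assert 0 in m.selected and 1 not in m.selected

    def test_p_enter_above_p_remove_forbidden(self):
        with pytest.raises(ValueError):
            train_swlda(np.zeros((4, 1)), np.r_[1.0, 1, -1, -1],
                        p_enter=0.2, p_remove=0.1)

    def test_model_json_roundtrip(self):
        m = SWLDAModel([3, 1], np.array([0.5, -0.2]), 0.1)
        m2 = SWLDAModel.from_json(m.to_json())
        assert m2.selected == m.selected
        np.testing.assert_allclose(m2.weights, m.weights)
        assert m2.intercept == m.intercept


class TestClassify:
    def test_zero_weights_tie_breaks_to_lowest_candidate(self):
        s = make_stimulus_schedule(range(6), 1, seed=0)
        rec = synth_eeg_session(s, 0, ERPModel(noise_std=0.0,
                                               p300_amplitude=0.0), seed=0)
        feats = extract_epochs_and_featurize(rec, s)
        m = SWLDAModel([], np.zeros(0), 0.3)
        scores, best = score_and_classify(m, feats, {2, 4, 5})
        assert best == 2
        assert set(scores.scores) == {2, 4, 5}

    def test_forced_single_candidate(self):
        s = make_stimulus_schedule(range(6), 1, seed=0)
        rec = synth_eeg_session(s, 0, ERPModel(), seed=0)
        feats = extract_epochs_and_featurize(rec, s)
        m = SWLDAModel([0], np.array([1.0]), 0.0)
        _, best = score_and_classify(m, feats, {3})
        assert best == 3

    def test_empty_candidate_set_rejected(self, trained_model):
        with pytest.raises(ValueError):
            score_and_classify(trained_model, [], set())

    def test_aggregation_permutation_invariant(self, trained_model):
        s = make_stimulus_schedule(range(6), 3, seed=5)
        rec = synth_eeg_session(s, 2, ERPModel(), seed=5)
        feats = extract_epochs_and_featurize(bandpass_filter(rec, 2, 25), s)
        sc1, _ = score_and_classify(trained_model, feats, range(6))
        rng = np.random.default_rng(0)
        perm = list(feats)
        rng.shuffle(perm)
        sc2, _ = score_and_classify(trained_model, perm, range(6))
        for k in range(6):
            assert sc1.scores[k] == pytest.approx(sc2.scores[k])

    def test_output_always_in_candidate_set(self, trained_model):
        rng = np.random.default_rng(3)
        for _ in range(10):
            s = make_stimulus_schedule(range(6), 2, seed=int(rng.integers(1e6)))
            rec = synth_eeg_session(s, 1, ERPModel(), seed=int(rng.integers(1e6)))
            cands = {1, int(rng.integers(2, 6))}
            _, best = score_and_classify(
                trained_model,
                extract_epochs_and_featurize(bandpass_filter(rec, 2, 25), s),
                cands)
            assert best in cands


class TestDecoderAccuracy:
    def test_above_chance_single_sequence(self, trained_model, default_erp):
        rng = np.random.default_rng(11)
        hits = 0
        n = 60
        for _ in range(n):
            att = int(rng.integers(6))
            s = make_stimulus_schedule(range(6), 1,
                                       seed=int(rng.integers(2**31)))
            rec = synth_eeg_session(s, att, default_erp,
                                    seed=int(rng.integers(2**31)))
            _, best = decode_trial(trained_model, rec, s)
            hits += best == att
        assert hits / n > 1 / 6

    def test_accuracy_monotone_in_amplitude(self, trained_model):
        rng = np.random.default_rng(21)
        accs = []
        for amp in (0.5, 2.0, 6.0):
            erp = ERPModel(p300_amplitude=amp, noise_std=10.0)
            hits = 0
            n = 120
            for _ in range(n):
                att = int(rng.integers(6))
                s = make_stimulus_schedule(range(6), 3,
                                           seed=int(rng.integers(2**31)))
                rec = synth_eeg_session(s, att, erp,
                                        seed=int(rng.integers(2**31)))
                _, best = decode_trial(trained_model, rec, s)
                hits += best == att
            accs.append(hits / n)
        assert accs[0] <= accs[1] + 0.05 and accs[1] <= accs[2] + 0.05

    def test_restriction_never_hurts_on_shared_scores(self, trained_model,
                                                      noisy_erp):
        # restricting the argmax to a candidate subset that contains the
        # attended target can only preserve or fix a correct decision
        rng = np.random.default_rng(31)
        acc_full = acc_two = 0
        n = 80
        for _ in range(n):
            att = int(rng.integers(2))
            s = make_stimulus_schedule(range(6), 3,
                                       seed=int(rng.integers(2**31)))
            rec = synth_eeg_session(s, att, noisy_erp,
                                    seed=int(rng.integers(2**31)))
            filt = bandpass_filter(rec, 2, 25)
            feats = extract_epochs_and_featurize(filt, s)
            _, b6 = score_and_classify(trained_model, feats, range(6))
            _, b2 = score_and_classify(trained_model, feats, range(2))
            acc_full += b6 == att
            acc_two += b2 == att
        assert acc_two >= acc_full
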