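"""Filtering, epoching, rejection, cleanup and matching tests."""

import numpy as np
import pytest

from dyadsync import preprocess, synth
from dyadsync.datatypes import EpochSet, Recording


def sine_recording(freq=5.0, fs=250.0, duration=60.0, amp=50.0, dc=0.0, n_channels=2):
    t = np.arange(int(duration * fs)) / fs
    sig = amp * np.sin(2 * np.pi * freq * t) + dc
    return Recording(
        dyad_id="d0",
        role="infant",
        condition="blank",
        sampling_rate=fs,
        channels=[f"ch{i}" for i in range(n_channels)],
        signal=np.tile(sig, (n_channels, 1)),
    )


class TestBandpass:
    def test_inband_amplitude_preserved(self):
        rec = sine_recording(freq=5.0)
        out = preprocess.bandpass(rec, 1.0, 50.0)
        core = slice(2500, -2500)  # avoid edges
        ratio = np.ptp(out.signal[0, core]) / np.ptp(rec.signal[0, core])
        assert abs(ratio - 1.0) < 0.01

    def test_stopband_suppressed(self):
        rec = sine_recording(freq=60.0)
        out = preprocess.bandpass(rec, 1.0, 50.0)
        core = slice(2500, -2500)
        assert np.ptp(out.signal[0, core]) < 0.01 * np.ptp(rec.signal[0, core])

    def test_dc_removed(self):
        rec = sine_recording(freq=5.0, amp=10.0, dc=100.0)
        out = preprocess.bandpass(rec, 1.0, 50.0)
        assert abs(np.mean(out.signal[0, 2500:-2500])) < 1.0

    def test_length_preserved(self):
        rec = sine_recording()
        out = preprocess.bandpass(rec, 1.0, 50.0)
        assert out.n_samples == rec.n_samples

    def test_band_outside_nyquist(self):
        rec = sine_recording(fs=100.0)
        with pytest.raises(ValueError, match="band"):
            preprocess.bandpass(rec, 1.0, 60.0)

    def test_too_short_recording(self):
        rec = sine_recording(duration=2.0)
        with pytest.raises(ValueError, match="too short"):
            preprocess.bandpass(rec, 1.0, 50.0)

    def test_idempotent_for_inband_content(self):
        rec = sine_recording(freq=6.0)
        once = preprocess.bandpass(rec, 1.0, 50.0)
        twice = preprocess.bandpass(once, 1.0, 50.0)
        core = slice(2500, -2500)
        rel = np.linalg.norm(twice.signal[0, core] - once.signal[0, core]) / np.linalg.norm(
            once.signal[0, core]
        )
        assert rel < 0.02


class TestEpoch:
    def test_default_counts(self):
        rec = sine_recording(duration=180.0)
        eps = preprocess.epoch(rec)
        assert eps.n_epochs == 359  # floor((180-1)/0.5)+1
        assert eps.onsets[1] - eps.onsets[0] == pytest.approx(0.5)

    def test_exactly_one_epoch(self):
        rec = sine_recording(duration=1.0)
        assert preprocess.epoch(rec).n_epochs == 1

    def test_too_short_errors(self):
        # a 0.9 s recording violates the Recording invariant outright ...
        rec = sine_recording(duration=1.0)
        with pytest.raises(ValueError, match="1 s"):
            Recording(
                dyad_id="d0", role="infant", condition="blank", sampling_rate=250.0,
                channels=rec.channels, signal=rec.signal[:, :225],
            )
        # ... and a recording shorter than the epoch length fails in epoch()
        with pytest.raises(ValueError, match="shorter"):
            preprocess.epoch(rec, length=1.5)

    def test_nonpositive_params(self):
        rec = sine_recording()
        with pytest.raises(ValueError):
            preprocess.epoch(rec, length=0.0)
        with pytest.raises(ValueError):
            preprocess.epoch(rec, step=-0.5)

    def test_reconstruction_from_halves(self):
        """First halves of successive epochs re-tile the continuous signal."""
        rec = sine_recording(duration=10.0)
        eps = preprocess.epoch(rec)
        step = int(round(eps.epoch_step * eps.sampling_rate))
        rebuilt = np.concatenate([e[:, :step] for e in eps.data], axis=1)
        np.testing.assert_array_equal(rebuilt, rec.signal[:, : rebuilt.shape[1]])


def clean_fixture(duration=120.0, seed=0, jump_rate=0.0):
    cfg = synth.SimulationConfig(
        n_dyads=1, duration=duration, sampling_rate=100.0, seed=seed, jump_rate=jump_rate
    )
    infant, _ = synth.simulate_dyad(cfg, 0, "blank")
    if jump_rate > 0:
        infant = synth.inject_artifacts(infant, cfg, seed=seed)
    return infant, cfg


class TestRejectEpochs:
    def test_clean_fixture_low_rejection(self):
        infant, _ = clean_fixture()
        out = preprocess.reject_epochs(preprocess.epoch(infant))
        assert out.report["rejection"]["fraction_rejected"] < 0.05

    def test_jump_epochs_rejected(self):
        infant, cfg = clean_fixture(duration=180.0, jump_rate=10 / 3.0)
        eps = preprocess.epoch(infant)
        out = preprocess.reject_epochs(eps)
        # every epoch overlapping an injected jump window must be rejected
        collateral = 0
        for e, onset in enumerate(out.onsets):
            win = (onset, onset + out.epoch_length)
            hit = any(
                j["onset_s"] < win[1] and j["onset_s"] + j["duration_s"] > win[0]
                for j in infant.annotations["jumps"]
            )
            if hit:
                assert not out.good_mask[e], f"jump epoch {e} survived"
            elif not out.good_mask[e]:
                collateral += 1
        n_clean = sum(
            1
            for onset in out.onsets
            if not any(
                j["onset_s"] < onset + out.epoch_length and j["onset_s"] + j["duration_s"] > onset
                for j in infant.annotations["jumps"]
            )
        )
        assert collateral / n_clean < 0.05

    def test_identical_epochs_none_rejected(self):
        data = np.tile(np.linspace(-20, 20, 100), (12, 2, 1))
        eps = EpochSet(
            source={}, sampling_rate=100.0, channels=["a", "b"],
            epoch_length=1.0, epoch_step=0.5,
            onsets=np.arange(12) * 0.5, data=data, good_mask=np.ones(12, bool),
        )
        out = preprocess.reject_epochs(eps)
        assert out.good_mask.all()

    def test_needs_ten_epochs(self):
        infant, _ = clean_fixture(duration=3.0)
        eps = preprocess.epoch(infant)
        with pytest.raises(ValueError, match="at least 10"):
            preprocess.reject_epochs(eps)

    def test_all_rejected_raises(self):
        data = np.tile(np.linspace(-5000, 5000, 100), (12, 2, 1))
        eps = EpochSet(
            source={}, sampling_rate=100.0, channels=["a", "b"],
            epoch_length=1.0, epoch_step=0.5,
            onsets=np.arange(12) * 0.5, data=data, good_mask=np.ones(12, bool),
        )
        with pytest.raises(ValueError, match="every epoch"):
            preprocess.reject_epochs(eps)


class TestRemoveTemplateComponents:
    def ocular_fixture(self, seed=0):
        cfg = synth.SimulationConfig(
            n_dyads=1, duration=60.0, sampling_rate=100.0, seed=seed, ocular_rate=12.0
        )
        clean, _ = synth.simulate_dyad(cfg, 0, "blank")
        dirty = synth.inject_artifacts(clean, cfg, seed=seed)
        return clean, dirty

    def test_ocular_component_removed_and_signal_recovered(self):
        clean, dirty = self.ocular_fixture()
        template = dirty.annotations["ocular_pattern"]
        cleaned, report = preprocess.remove_template_components(dirty, template, seed=0)
        assert len(report["removed"]) >= 1
        c4 = clean.channel_index("C4")
        before = np.corrcoef(dirty.signal[c4], clean.signal[c4])[0, 1]
        after = np.corrcoef(cleaned.signal[c4], clean.signal[c4])[0, 1]
        assert after > before

    def test_recovered_pattern_matches_truth(self):
        _, dirty = self.ocular_fixture()
        template = dirty.annotations["ocular_pattern"]
        _, report = preprocess.remove_template_components(dirty, template, seed=0)
        best_r = max(abs(item["r"]) for item in report["removed"])
        assert best_r > 0.9

    def test_orthogonal_template_identity(self):
        clean, _ = self.ocular_fixture()
        # a template uncorrelated with any mixing pattern: alternating signs
        # on posterior channels only
        template = np.array(
            [0.0] * 7 + [1.0, -1.0, 1.0, -1.0, 1.0, -1.0, 1.0, -1.0, 1.0]
        )
        out, report = preprocess.remove_template_components(
            clean, template, r_threshold=0.999, seed=0
        )
        assert report["removed"] == []
        rel = np.linalg.norm(out.signal - clean.signal) / np.linalg.norm(clean.signal)
        assert rel < 1e-6

    def test_bad_template_length(self):
        clean, _ = self.ocular_fixture()
        with pytest.raises(ValueError, match="template"):
            preprocess.remove_template_components(clean, np.ones(3))

    def test_components_removed_order_of_magnitude(self):
        # stereotyped cleanup should remove on the order of 1-2 components
        _, dirty = self.ocular_fixture()
        template = dirty.annotations["ocular_pattern"]
        _, report = preprocess.remove_template_components(dirty, template, seed=0)
        assert 1 <= len(report["removed"]) <= 4


class TestMatching:
    def test_match_durations(self):
        a = sine_recording(duration=180.0)
        b = sine_recording(duration=150.0)
        ta, tb = preprocess.match_durations(a, b)
        assert ta.duration == tb.duration == 150.0
        np.testing.assert_array_equal(ta.signal, a.signal[:, : tb.n_samples])

    def test_match_durations_identity(self):
        a = sine_recording(duration=60.0)
        b = sine_recording(duration=60.0)
        ta, tb = preprocess.match_durations(a, b)
        assert ta is a and tb is b

    def test_match_durations_fractional(self):
        a = sine_recording(duration=90.3)
        b = sine_recording(duration=90.0)
        ta, tb = preprocess.match_durations(a, b)
        assert ta.duration == pytest.approx(90.0)

    def _eps(self, mask, role="infant"):
        n = len(mask)
        data = np.random.default_rng(0).normal(size=(n, 2, 100))
        return EpochSet(
            source={"dyad_id": "d0", "role": role, "condition": "blank"},
            sampling_rate=100.0, channels=["a", "b"],
            epoch_length=1.0, epoch_step=0.5,
            onsets=np.arange(n) * 0.5, data=data,
            good_mask=np.array(mask, dtype=bool),
        )

    def test_intersection(self):
        m = preprocess.match_epochs(self._eps([1, 1, 0, 0]), self._eps([1, 0, 1, 0], "adult"))
        assert m.n_matched == 1
        assert m.onsets[0] == 0.0

    def test_all_good_identity(self):
        m = preprocess.match_epochs(self._eps([1] * 6), self._eps([1] * 6, "adult"))
        assert m.n_matched == 6

    def test_disjoint_masks(self):
        m = preprocess.match_epochs(self._eps([1, 0, 1, 0]), self._eps([0, 1, 0, 1], "adult"))
        assert m.n_matched == 0

    def test_commutative_and_monotone(self):
        a = [1, 1, 0, 1, 0]
        b = [0, 1, 1, 1, 0]
        m1 = preprocess.match_epochs(self._eps(a), self._eps(b, "adult"))
        m2 = preprocess.match_epochs(self._eps(b), self._eps(a, "adult"))
        np.testing.assert_array_equal(m1.onsets, m2.onsets)
        # adding a good epoch never removes a retained one
        a_more = [1, 1, 1, 1, 0]
        m3 = preprocess.match_epochs(self._eps(a_more), self._eps(b, "adult"))
        assert set(m1.onsets).issubset(set(m3.onsets))

    def test_matched_never_exceeds_member_good_counts(self):
        a = self._eps([1, 0, 1, 1, 0, 1])
        b = self._eps([1, 1, 0, 1, 1, 0], "adult")
        m = preprocess.match_epochs(a, b)
        assert m.n_matched <= min(a.n_good, b.n_good)

    def test_grid_mismatch_raises(self):
        a = self._eps([1, 1, 1])
        b = self._eps([1, 1], "adult")
        with pytest.raises(ValueError, match="grid"):
            preprocess.match_epochs(a, b)


class TestEnforceMinimum:
    def _matched(self, n, step=0.5):
        data = np.zeros((n, 1, 100))
        return preprocess.match_epochs(
            EpochSet(
                source={"dyad_id": "d", "role": "infant", "condition": "c"},
                sampling_rate=100.0, channels=["a"], epoch_length=1.0, epoch_step=step,
                onsets=np.arange(n) * step, data=data, good_mask=np.ones(n, bool),
            ),
            EpochSet(
                source={"dyad_id": "d", "role": "adult", "condition": "c"},
                sampling_rate=100.0, channels=["a"], epoch_length=1.0, epoch_step=step,
                onsets=np.arange(n) * step, data=data, good_mask=np.ones(n, bool),
            ),
        )

    def test_short_dyad_flagged(self):
        m = self._matched(89)  # spans 45 s
        out = preprocess.enforce_minimum(m, min_seconds=60)
        assert out.excluded

    def test_cap_retains_early_epochs(self):
        m = self._matched(359)  # 180 s
        out = preprocess.enforce_minimum(m, min_seconds=60, cap_seconds=90)
        assert not out.excluded
        assert out.onsets.max() < 90.0
        assert out.n_matched == 180  # onsets 0, 0.5, ..., 89.5

    def test_identity_when_disabled(self):
        m = self._matched(100)
        out = preprocess.enforce_minimum(m, min_seconds=0, cap_seconds=None)
        assert not out.excluded
        assert out.n_matched == m.n_matched
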