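"""Filtering, epoching, robust rejection, referencing and HFC."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from megeeg import (
    ChannelInfo,
    EpochSet,
    FilterSpec,
    Modality,
    epoch,
    homogeneous_field_correction,
    preprocess_continuous,
    reject_outliers,
    rereference,
)
from tests.conftest import make_epochs, make_recording


class TestContinuousFiltering:
    def test_all_zero_in_all_zero_out(self):
        rec = make_recording(seed=0, fs=1200.0, n_samples=2400,
                             events=[("x", 100)])
        rec.data[:] = 0.0
        out = preprocess_continuous(rec)
        assert np.allclose(out.data, 0.0)

    def test_mains_attenuated_30db(self):
        fs = 1200.0
        t = np.arange(int(10 * fs)) / fs
        rec = make_recording(n_channels=1, n_samples=t.size, fs=fs,
                             events=[("x", 100)])
        rec.data[0] = np.sin(2 * np.pi * 50.0 * t)
        out = preprocess_continuous(rec)
        mid = slice(int(2 * fs), int(8 * fs))  # avoid filter edges
        atten_db = 20 * np.log10(
            np.sqrt(np.mean(rec.data[0, mid] ** 2))
            / max(np.sqrt(np.mean(out.data[0, mid] ** 2)), 1e-300)
        )
        assert atten_db >= 30.0

    def test_events_and_metadata_untouched(self):
        rec = make_recording(fs=1000.0, n_samples=2000,
                             events=[("a", 10), ("b", 200)])
        out = preprocess_continuous(rec, FilterSpec(band=(1.0, 40.0)))
        assert out.events == rec.events
        assert [c.name for c in out.channels] == [c.name for c in rec.channels]

    def test_band_edge_at_nyquist_rejected(self):
        rec = make_recording(fs=100.0)
        with pytest.raises(ValueError, match="Nyquist"):
            preprocess_continuous(rec, FilterSpec(band=(1.0, 50.0), notches=[]))

    def test_nonfinite_samples_name_channels(self):
        rec = make_recording(n_channels=3, fs=1000.0, n_samples=3000)
        rec.data[1, 5] = np.nan
        with pytest.raises(ValueError, match="CH1"):
            preprocess_continuous(rec)

    def test_detrend_removes_mean_and_slope(self):
        fs = 500.0
        rec = make_recording(n_channels=1, fs=fs, n_samples=5000,
                             events=[("x", 0)])
        t = np.arange(5000) / fs
        rec.data[0] += 5.0 + 0.7 * t
        out = preprocess_continuous(rec, FilterSpec(band=(0.1, 100.0),
                                                    notches=[]))
        assert abs(out.data[0].mean()) < 1e-8
        slope = np.polyfit(t, out.data[0], 1)[0]
        assert abs(slope) < 1e-4

    @settings(max_examples=10, deadline=None, derandomize=True)
    @given(a=st.floats(-3, 3), b=st.floats(-3, 3), seed=st.integers(0, 100))
    def test_linearity(self, a, b, seed):
        """f(a x + b y) = a f(x) + b f(y) for the whole conditioning chain."""
        rng = np.random.default_rng(seed)
        fs = 600.0
        x = rng.standard_normal((2, 3000))
        y = rng.standard_normal((2, 3000))

        def f(d):
            rec = make_recording(n_channels=2, n_samples=3000, fs=fs,
                                 events=[("e", 0)])
            rec.data = d.copy()
            return preprocess_continuous(
                rec, FilterSpec(band=(1.0, 150.0), notches=[50.0, 100.0])
            ).data

        lhs = f(a * x + b * y)
        rhs = a * f(x) + b * f(y)
        scale = max(np.abs(rhs).max(), 1.0)
        assert np.allclose(lhs, rhs, atol=1e-8 * scale)


class TestEpoching:
    def test_motor_window_sample_count(self):
        fs = 1200.0
        n = int(260 * fs)
        events = [("move_offset", int((2 + 5 * k) * fs)) for k in range(50)]
        rec = make_recording(n_channels=2, n_samples=n, fs=fs, events=events)
        ep = epoch(rec, "move_offset", -1.0, 4.0)
        assert ep.data.shape == (50, 2, 6000)
        assert ep.retained.all()

    def test_alpha_window_sample_count(self):
        fs = 1000.0
        rec = make_recording(n_channels=1, n_samples=int(20 * fs), fs=fs,
                             events=[("eyes_closed", int(2 * fs))])
        ep = epoch(rec, "eyes_closed", 1.0, 6.0)
        assert ep.data.shape[2] == 5000

    def test_boundary_trial_flagged_not_kept(self):
        fs = 1200.0
        rec = make_recording(n_channels=1, n_samples=int(30 * fs), fs=fs,
                             events=[("m", 100), ("m", int(10 * fs))])
        ep = epoch(rec, "m", -1.0, 4.0)
        assert ep.n_trials == 2
        assert not ep.retained[0]  # event at sample 100 cannot fit t_min=-1 s
        assert ep.retained[1]

    def test_no_matching_events(self):
        rec = make_recording()
        with pytest.raises(ValueError, match="no events"):
            epoch(rec, "nothing", 0.0, 1.0)

    def test_labels_recorded_per_trial(self):
        fs = 100.0
        rec = make_recording(
            n_channels=1, n_samples=2000, fs=fs,
            events=[("a", 500), ("b", 1000), ("a", 1500)],
        )
        ep = epoch(rec, ["a", "b"], 0.0, 1.0)
        assert ep.labels == ["a", "b", "a"]


class TestRejection:
    def test_identical_trials_nothing_removed(self):
        data = np.tile(np.sin(np.linspace(0, 10, 200)), (6, 3, 1))
        ep = make_epochs(data, fs=100.0, window=(0.0, 2.0))
        out, rep = reject_outliers(ep, 5.0)
        assert rep.removed_trials == []
        assert out.retained.all()

    def test_planted_outlier_trial_removed(self):
        """A 100x-variance trial among clean ones exceeds z = 5; oracle is a
        hand recomputation of the robust z."""
        rng = np.random.default_rng(4)
        data = rng.standard_normal((50, 3, 200))
        data[17] *= 10.0  # 100x variance
        ep = make_epochs(data, fs=100.0, window=(0.0, 2.0))
        out, rep = reject_outliers(ep, 5.0)
        assert rep.removed_trials == [17]
        # independent recomputation
        logvar = np.log(data.var(axis=2))
        stat = np.median(logvar, axis=1)
        med = np.median(stat)
        mad = np.median(np.abs(stat - med))
        z17 = (stat[17] - med) / (1.4826 * mad)
        assert z17 > 5.0
        assert rep.trial_z[17] == pytest.approx(z17)

    def test_infinite_threshold_is_identity(self):
        rng = np.random.default_rng(5)
        ep = make_epochs(rng.standard_normal((8, 2, 100)), fs=50.0,
                         window=(0.0, 2.0))
        out, rep = reject_outliers(ep, np.inf)
        assert out.retained.all()
        assert rep.removed_channels == []

    def test_too_few_trials(self):
        ep = make_epochs(np.random.default_rng(0).standard_normal((3, 2, 50)),
                         fs=50.0, window=(0.0, 1.0))
        with pytest.raises(ValueError, match="4"):
            reject_outliers(ep)

    def test_broken_channel_marked_bad(self):
        rng = np.random.default_rng(6)
        data = rng.standard_normal((20, 5, 200))
        data[:, 3] *= 40.0  # 1600x variance: a broken sensor
        ep = make_epochs(data, fs=100.0, window=(0.0, 2.0))
        out, rep = reject_outliers(ep, 5.0)
        assert rep.removed_channels == ["CH3"]
        assert not out.channels[3].is_good

    def test_retention_high_on_clean_synthetic(self, quiet_motor_eeg):
        rec, _ = quiet_motor_eeg
        rec = preprocess_continuous(rec)
        ep = epoch(rec, "move_offset", -1.0, 4.0)
        out, _ = reject_outliers(ep)
        assert out.retained.sum() >= 0.9 * ep.n_trials


class TestRereference:
    def _eeg_epochs(self, seed=0, n_trials=3, n_ch=5):
        rng = np.random.default_rng(seed)
        return make_epochs(rng.standard_normal((n_trials, n_ch, 100)),
                           fs=100.0, window=(0.0, 1.0))

    def test_average_zeroes_mean_of_good(self):
        ep = self._eeg_epochs()
        out = rereference(ep, "average")
        assert np.abs(out.data.mean(axis=1)).max() < 1e-12

    def test_average_removes_common_signal_exactly(self):
        ep = self._eeg_epochs()
        common = np.sin(np.linspace(0, 20, 100))
        ep2 = ep.copy()
        ep2.data += common
        a = rereference(ep, "average")
        b = rereference(ep2, "average")
        assert np.allclose(a.data, b.data, atol=1e-12)

    def test_average_idempotent(self):
        ep = self._eeg_epochs()
        once = rereference(ep, "average")
        twice = rereference(once, "average")
        assert np.allclose(once.data, twice.data, atol=1e-12)

    def test_crr_is_identity(self):
        ep = self._eeg_epochs()
        out = rereference(ep, "CRR")
        assert np.array_equal(out.data, ep.data)

    def test_average_excluding_reference_set(self):
        ep = self._eeg_epochs(n_ch=4)
        out = rereference(ep, "average_excluding", exclude=["CH2", "CH3"])
        # reference built from CH0, CH1 only but subtracted from all
        ref = ep.data[:, :2, :].mean(axis=1)
        expected = ep.data - ref[:, None, :]
        assert np.allclose(out.data, expected, atol=1e-12)

    def test_meg_rejected(self):
        rng = np.random.default_rng(1)
        data = rng.standard_normal((2, 3, 50))
        channels = [
            ChannelInfo(name=f"M{i}", modality=Modality.MEG,
                        orientation=np.eye(3)[i])
            for i in range(3)
        ]
        ep = EpochSet(data=data, fs=50.0, window=(0.0, 1.0), channels=channels)
        with pytest.raises(ValueError, match="EEG"):
            rereference(ep, "average")

    def test_unknown_excluded_channel(self):
        ep = self._eeg_epochs()
        with pytest.raises(ValueError, match="not present"):
            rereference(ep, "average_excluding", exclude=["Oz"])


class TestHomogeneousFieldCorrection:
    def _meg_epochs(self, n_trials=2, n_samples=120, seed=0):
        from megeeg import meg_layout

        channels = meg_layout(6)  # 12 channels, orientations span 3D
        rng = np.random.default_rng(seed)
        data = rng.standard_normal((n_trials, len(channels), n_samples))
        return EpochSet(data=data, fs=100.0,
                        window=(0.0, n_samples / 100.0), channels=channels)

    def test_uniform_field_removed_exactly(self):
        ep = self._meg_epochs()
        N = np.stack([c.orientation for c in ep.channels])
        b = np.array([0.3, -1.2, 0.8])
        ep.data = np.broadcast_to(
            (N @ b)[None, :, None], ep.data.shape
        ).copy() * np.sin(np.linspace(0, 5, ep.data.shape[2]))
        out = homogeneous_field_correction(ep)
        assert np.abs(out.data).max() < 1e-9

    def test_projector_property_and_oracle(self):
        """N^T (corrected) = 0 and equality with the dense projector."""
        ep = self._meg_epochs(seed=3)
        out = homogeneous_field_correction(ep)
        N = np.stack([c.orientation for c in ep.channels])
        resid = np.einsum("ci,tcs->tis", N, out.data)
        assert np.abs(resid).max() < 1e-9 * np.abs(ep.data).max()
        dense = np.eye(len(ep.channels)) - N @ np.linalg.pinv(N)
        expected = np.einsum("ij,tjs->tis", dense, ep.data)
        assert np.allclose(out.data, expected, atol=1e-12)

    def test_idempotent(self):
        ep = self._meg_epochs(seed=4)
        once = homogeneous_field_correction(ep)
        twice = homogeneous_field_correction(once)
        assert np.allclose(once.data, twice.data, atol=1e-10)

    def test_commutes_with_filtering(self):
        """Projector is time-invariant: HFC then filter == filter then HFC."""
        from scipy import signal as sp

        ep = self._meg_epochs(n_samples=600, seed=5)
        sos = sp.butter(3, (5.0, 20.0), btype="bandpass", fs=100.0,
                        output="sos")

        def filt(e):
            out = e.copy()
            out.data = sp.sosfiltfilt(sos, e.data, axis=2)
            return out

        a = filt(homogeneous_field_correction(ep))
        b = homogeneous_field_correction(filt(ep))
        assert np.allclose(a.data, b.data, atol=1e-10)

    def test_rank_deficient_orientations_rejected(self):
        channels = [
            ChannelInfo(name=f"M{i}", modality=Modality.MEG,
                        orientation=np.array([0.0, 0.0, 1.0]))
            for i in range(5)
        ]
        ep = EpochSet(data=np.zeros((1, 5, 10)), fs=10.0, window=(0.0, 1.0),
                      channels=channels)
        with pytest.raises(ValueError, match="span"):
            homogeneous_field_correction(ep)

    def test_needs_four_channels(self):
        from megeeg import meg_layout

        channels = meg_layout(1)  # 2 channels only
        ep = EpochSet(data=np.zeros((1, 2, 10)), fs=10.0, window=(0.0, 1.0),
                      channels=channels)
        with pytest.raises(ValueError, match="4"):
            homogeneous_field_correction(ep)
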