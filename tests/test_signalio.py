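"""Filtering, resampling, synchronization and session I/O."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import signal as sps

from wristemg.errors import (
    DataError,
    FilterDesignError,
    SchemaError,
    SyncError,
    TrialRejectionError,
)
from wristemg.signalio import (
    ANGLE_LOWPASS,
    EMG_BANDPASS,
    EmgRecording,
    FilterSpec,
    MarkerSession,
    butter_filter,
    design_sos,
    find_sync_edge,
    read_session,
    repair_marker_gaps,
    resample_uniform,
    sync_square_wave,
    synchronize,
    trim_at_sync_edge,
    write_session,
)


def _markers(n=100, fs=256.0, side="right", sync=None):
    base = {
        "MEP": (-10.0, 0.0, 100.0), "LEP": (10.0, 0.0, 100.0),
        "STU": (0.0, -10.0, 0.0), "STR": (0.0, 10.0, 0.0),
        "RMC": (10.0, 0.0, -50.0), "UMC": (-10.0, 0.0, -50.0),
    }
    return MarkerSession(
        {k: np.tile(v, (n, 1)) for k, v in base.items()}, fs, side, sync
    )


class TestButterFilter:
    def test_lowpass_dc_invariance(self):
        x = np.full(2000, 5.0)
        out = butter_filter(x, 256.0, ANGLE_LOWPASS, zero_phase=True)
        assert np.allclose(out, 5.0, rtol=1e-9)

    def test_bandpass_dc_rejection(self):
        x = np.full(8192, 5.0)
        out = butter_filter(x, 2048.0, EMG_BANDPASS, zero_phase=True)
        assert np.abs(out[1000:-1000]).max() < 1e-6

    def test_single_pass_cutoff_gain(self):
        """Steady-state gain at the 10 Hz band edge is -3 dB (1/sqrt(2))."""
        fs = 2048.0
        t = np.arange(int(20 * fs)) / fs
        x = np.sin(2 * np.pi * 10.0 * t)
        y = butter_filter(x, fs, EMG_BANDPASS, zero_phase=False)
        amp = np.abs(y[int(10 * fs):]).max()
        assert amp == pytest.approx(1 / np.sqrt(2), rel=0.02)

    def test_columns_filtered_independently(self, rng):
        x = rng.standard_normal((4096, 3))
        both = butter_filter(x, 2048.0, EMG_BANDPASS)
        one = butter_filter(x[:, 1], 2048.0, EMG_BANDPASS)
        assert np.allclose(both[:, 1], one)

    def test_cutoff_at_nyquist_rejected(self):
        with pytest.raises(FilterDesignError):
            butter_filter(np.zeros(100), 256.0, FilterSpec("lowpass", 2, (128.0,)))

    def test_nonfinite_input_rejected(self):
        x = np.zeros(100)
        x[3] = np.nan
        with pytest.raises(DataError):
            butter_filter(x, 256.0, ANGLE_LOWPASS)


class TestResample:
    @pytest.mark.parametrize(
        "n,fs_in,fs_out,expected",
        [(2048, 2048.0, 1024.0, 1024), (256, 256.0, 1024.0, 1024),
         (1000, 256.0, 1024.0, 4000)],
    )
    def test_output_length(self, n, fs_in, fs_out, expected):
        out = resample_uniform(np.zeros(n), fs_in, fs_out)
        assert out.shape[0] == expected

    def test_upsampled_sinusoid_matches_analytic(self):
        fs_in, fs_out, f = 256.0, 1024.0, 5.0
        t_in = np.arange(1024) / fs_in
        out = resample_uniform(np.sin(2 * np.pi * f * t_in), fs_in, fs_out)
        t_out = np.arange(out.shape[0]) / fs_out
        ref = np.sin(2 * np.pi * f * t_out)
        interior = slice(200, -200)
        assert np.abs(out[interior] - ref[interior]).max() < 0.01

    def test_down_up_round_trip(self, rng):
        """Band-limited signals survive fs -> 2fs -> fs within 1e-3 L2."""
        fs = 256.0
        x = butter_filter(rng.standard_normal(4096), fs, ANGLE_LOWPASS)
        back = resample_uniform(resample_uniform(x, fs, 2 * fs), 2 * fs, fs)
        core = slice(100, -100)
        rel = np.linalg.norm(back[core] - x[core]) / np.linalg.norm(x[core])
        assert rel < 1e-3

    def test_zero_length_rejected(self):
        with pytest.raises(DataError):
            resample_uniform(np.zeros((0, 2)), 256.0, 1024.0)


class TestSync:
    def test_edge_on_clean_square_wave(self):
        fs = 2048.0
        t = np.arange(int(2 * fs)) / fs
        idx = find_sync_edge(sync_square_wave(t), fs)
        # first rising edge after the first low half-cycle: t = 50 ms
        assert idx / fs == pytest.approx(0.050, abs=2 / fs)

    def test_no_edge_raises(self):
        with pytest.raises(SyncError):
            find_sync_edge(np.ones(1000), 256.0)

    def test_zero_offset_alignment(self, small_session):
        pair = synchronize(small_session.emg_right, small_session.markers_right)
        assert abs(pair.offset_applied) < 2 / 256.0
        assert pair.emg.n_samples == pair.kin.n_frames

    def test_known_lag_recovered(self):
        """The sync generator switches on once; a kinematics recorder started
        0.5 s before the EMG recorder sees that onset 0.5 s later in its own
        record, and synchronize reports exactly that offset."""
        fs_e, fs_m = 2048.0, 256.0
        t_e = np.arange(int(5.0 * fs_e)) / fs_e
        t_m = np.arange(int(5.5 * fs_m)) / fs_m

        def gated(t, onset):
            return np.where(t >= onset, sync_square_wave(t - onset), 0.0)

        emg = EmgRecording(
            np.random.default_rng(0).standard_normal((t_e.size, 2)),
            fs_e, ["ch1", "ch2"], sync=gated(t_e, 1.0),
        )
        mk = _markers(t_m.size, fs_m, sync=gated(t_m, 1.5))
        pair = synchronize(emg, mk)
        assert pair.offset_applied == pytest.approx(0.5, abs=2 / fs_m)
        # the common square wave is in phase after alignment
        e_sync, k_sync = pair.emg.sync, pair.kin.sync
        lags = sps.correlation_lags(e_sync.size, k_sync.size)
        corr = sps.correlate(e_sync, k_sync)
        assert abs(lags[np.argmax(corr)]) <= 2

    def test_common_length_truncation(self):
        fs_e, fs_m = 2048.0, 256.0
        t_e = np.arange(int(5.0 * fs_e)) / fs_e
        t_m = np.arange(int(4.0 * fs_m)) / fs_m
        emg = EmgRecording(
            np.zeros((t_e.size, 1)), fs_e, ["ch1"], sync=sync_square_wave(t_e)
        )
        mk = _markers(t_m.size, fs_m, sync=sync_square_wave(t_m))
        pair = synchronize(emg, mk)
        assert pair.emg.n_samples == pair.kin.n_frames
        assert pair.emg.n_samples <= int(4.0 * 1024)

    def test_idempotent_alignment(self, small_session):
        pair = synchronize(small_session.emg_right, small_session.markers_right)
        again = synchronize(pair.emg, pair.kin)
        assert abs(again.offset_applied) <= 1 / 256.0


class TestGapRepair:
    def test_short_gap_interpolated(self):
        mk = _markers(200)
        traj = mk.markers["RMC"].copy()
        traj[50:55] = np.nan
        mk.markers["RMC"] = traj
        fixed = repair_marker_gaps(mk)
        assert np.isfinite(fixed.markers["RMC"]).all()

    def test_long_gap_rejects_trial(self):
        mk = _markers(500)
        traj = mk.markers["RMC"].copy()
        traj[100:200] = np.nan  # ~390 ms at 256 Hz
        mk.markers["RMC"] = traj
        with pytest.raises(TrialRejectionError):
            repair_marker_gaps(mk)


class TestSessionIO:
    def test_hdf5_round_trip_bit_identical(self, tmp_path, rng):
        emg = EmgRecording(
            rng.standard_normal((100, 2)), 2048.0, ["ch1", "ch2"], "left",
            sync=rng.standard_normal(100),
        )
        mk = _markers(50, side="left", sync=np.zeros(50))
        p = write_session(tmp_path / "s.h5", emg, mk, "hdf5")
        emg2, mk2 = read_session(p, "hdf5")
        assert np.array_equal(emg.samples, emg2.samples)
        assert emg2.side == "left" and emg2.fs == 2048.0
        assert set(mk2.markers) >= {"MEP", "LEP", "STU", "STR", "RMC", "UMC"}
        assert np.array_equal(mk.markers["RMC"], mk2.markers["RMC"])

    def test_csv_round_trip_preserves_gaps(self, tmp_path, rng):
        emg = EmgRecording(rng.standard_normal((40, 2)), 2048.0, ["ch1", "ch2"])
        mk = _markers(30)
        traj = mk.markers["UMC"].copy()
        traj[10:12] = np.nan
        mk.markers["UMC"] = traj
        write_session(tmp_path / "sess", emg, mk, "csv")
        assert "NA" in (tmp_path / "sess" / "markers.csv").read_text()
        emg2, mk2 = read_session(tmp_path / "sess", "csv")
        assert np.allclose(emg.samples, emg2.samples, atol=1e-6)
        assert np.isnan(mk2.markers["UMC"][10:12]).all()
        assert np.isfinite(mk2.markers["UMC"][:10]).all()

    def test_missing_marker_is_schema_error(self):
        with pytest.raises(SchemaError):
            MarkerSession({"MEP": np.zeros((5, 3))}, 256.0)


@settings(max_examples=25, derandomize=True, deadline=None)
@given(st.integers(min_value=40, max_value=5000))
def test_trim_then_resample_preserves_duration(n):
    """Trimming at the sync edge keeps durations consistent across rates."""
    fs = 256.0
    t = np.arange(n + 200) / fs
    emg = EmgRecording(np.zeros((t.size, 1)), fs, ["ch1"], sync=sync_square_wave(t))
    trimmed, t_edge = trim_at_sync_edge(emg)
    assert trimmed.n_samples + int(round(t_edge * fs)) == t.size


def test_design_sos_matches_analytic_prototype():
    """Digital design reproduces the Butterworth band edges."""
    sos = design_sos(EMG_BANDPASS, 2048.0)
    w, h = sps.sosfreqz(sos, worN=[10.0, 450.0], fs=2048.0)
    assert np.allclose(20 * np.log10(np.abs(h)), -3.0103, atol=0.2)
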