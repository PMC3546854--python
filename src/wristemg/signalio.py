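"""Domain containers, preprocessing filters, resampling, synchronization and
session file I/O.

The recording model mirrors a bilateral mirrored-contraction experiment:
multi-channel bipolar surface EMG sampled at 2048 Hz and passive-marker
trajectories sampled at 256 Hz, tied together by a shared 20 Hz, +/-5 V
square-wave synchronization signal fed to both acquisition systems.

All offline filtering defaults to zero-phase (forward-backward) application so
that the EMG envelope and the joint-angle traces stay time-locked; single-pass
filtering is available by flag for causal processing studies.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path
from typing import Literal, Sequence

import h5py
import numpy as np
import pandas as pd
from scipy import signal as sps

from .errors import (
    DataError,
    FilterDesignError,
    SchemaError,
    SyncError,
    TrialRejectionError,
)

#: Marker identifiers required by the wrist-angle geometry.  SHO (shoulder)
#: may be present but is not used by the angle equations.
REQUIRED_MARKERS = ("MEP", "LEP", "STU", "STR", "RMC", "UMC")
OPTIONAL_MARKERS = ("SHO",)

#: Square-wave synchronization signal: 20 Hz, +/-5 V.
SYNC_FREQ_HZ = 20.0
SYNC_AMPLITUDE_V = 5.0

#: Gap token used in CSV marker files.
CSV_GAP_TOKEN = "NA"

Side = Literal["left", "right"]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class EmgRecording:
    """Multi-channel surface EMG block.

    Parameters
    ----------
    samples
        ``[n_samples, n_channels]`` array in microvolts.
    fs
        Sampling rate in Hz.
    channel_names
        Ordered channel labels, one per column.
    side
        ``"left"`` or ``"right"`` arm.
    sync
        Optional synchronization trace in volts, one value per sample.
    """

    samples: np.ndarray
    fs: float
    channel_names: Sequence[str]
    side: Side = "right"
    sync: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.samples.ndim != 2 or self.samples.shape[1] < 1:
            raise DataError("EMG samples must be a [n_samples, n_channels] matrix")
        if not np.isfinite(self.samples).all():
            raise DataError("EMG samples contain non-finite values")
        if self.fs <= 0:
            raise DataError("EMG sampling rate must be positive")
        if len(self.channel_names) != self.samples.shape[1]:
            raise DataError("channel_names length must match n_channels")
        if self.side not in ("left", "right"):
            raise DataError(f"invalid side {self.side!r}")
        if self.sync is not None:
            self.sync = np.asarray(self.sync, dtype=float).ravel()
            if self.sync.shape[0] != self.samples.shape[0]:
                raise DataError("sync trace length must equal n_samples")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def n_channels(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    @property
    def t(self) -> np.ndarray:
        """Sample timestamps in seconds (first sample at t = 0)."""
        return np.arange(self.n_samples) / self.fs


@dataclass
class MarkerSession:
    """Per-marker 3-D trajectories in millimetres.

    Missing frames (marker drop-out) are encoded as NaN, never as zeros.
    """

    markers: dict[str, np.ndarray]
    fs: float
    side: Side = "right"
    sync: np.ndarray | None = None

    def __post_init__(self) -> None:
        missing = [m for m in REQUIRED_MARKERS if m not in self.markers]
        if missing:
            raise SchemaError(f"missing required markers: {missing}")
        n = None
        clean: dict[str, np.ndarray] = {}
        for name, traj in self.markers.items():
            arr = np.asarray(traj, dtype=float)
            if arr.ndim != 2 or arr.shape[1] != 3:
                raise SchemaError(f"marker {name} must be [n_frames, 3]")
            if n is None:
                n = arr.shape[0]
            elif arr.shape[0] != n:
                raise SchemaError("all markers must share the same frame count")
            clean[name] = arr
        self.markers = clean
        if self.fs <= 0:
            raise DataError("marker sampling rate must be positive")
        if self.side not in ("left", "right"):
            raise DataError(f"invalid side {self.side!r}")
        if self.sync is not None:
            self.sync = np.asarray(self.sync, dtype=float).ravel()
            if self.sync.shape[0] != n:
                raise DataError("sync trace length must equal n_frames")

    @property
    def n_frames(self) -> int:
        return next(iter(self.markers.values())).shape[0]

    @property
    def t(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.fs


@dataclass(frozen=True)
class FilterSpec:
    """Butterworth filter request.

    ``kind`` is ``"bandpass"`` (two cutoffs) or ``"lowpass"`` (one cutoff);
    ``order`` is the analogue prototype order; cutoffs are in Hz and must lie
    strictly below the Nyquist frequency when the filter is applied.
    """

    kind: Literal["bandpass", "lowpass"]
    order: int
    cutoffs: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.order < 1:
            raise FilterDesignError("filter order must be >= 1")
        cut = tuple(float(c) for c in self.cutoffs)
        object.__setattr__(self, "cutoffs", cut)
        if any(c <= 0 for c in cut):
            raise FilterDesignError("cutoffs must be strictly positive")
        n_expected = 2 if self.kind == "bandpass" else 1
        if len(cut) != n_expected:
            raise FilterDesignError(
                f"{self.kind} filter needs {n_expected} cutoff(s), got {len(cut)}"
            )
        if self.kind == "bandpass" and cut[0] >= cut[1]:
            raise FilterDesignError("bandpass cutoffs must be increasing")


#: EMG band of interest: 10-450 Hz, 2nd-order Butterworth.
EMG_BANDPASS = FilterSpec("bandpass", 2, (10.0, 450.0))
#: Joint-angle smoothing: 6 Hz, 2nd-order Butterworth low-pass.
ANGLE_LOWPASS = FilterSpec("lowpass", 2, (6.0,))

#: Common analysis rate after resampling, Hz.
FS_COMMON = 1024.0


@dataclass
class TimeAlignedPair:
    """EMG and kinematics trimmed to the shared sync edge and resampled to a
    common rate."""

    emg: EmgRecording
    kin: object  # MarkerSession or kinematics.JointAngleSeries
    fs_common: float
    offset_applied: float


# ---------------------------------------------------------------------------
# filtering / resampling
# ---------------------------------------------------------------------------


def design_sos(spec: FilterSpec, fs: float) -> np.ndarray:
    """Design second-order sections for *spec* at sampling rate *fs*."""
    nyq = fs / 2.0
    if max(spec.cutoffs) >= nyq:
        raise FilterDesignError(
            f"cutoff {max(spec.cutoffs)} Hz >= Nyquist {nyq} Hz at fs={fs}"
        )
    wn = spec.cutoffs if spec.kind == "bandpass" else spec.cutoffs[0]
    return sps.butter(spec.order, wn, btype=spec.kind, fs=fs, output="sos")


def butter_filter(
    x: np.ndarray, fs: float, spec: FilterSpec, zero_phase: bool = True
) -> np.ndarray:
    """Apply a Butterworth filter column-wise.

    With ``zero_phase`` the filter is run forward and backward
    (``sosfiltfilt``), doubling the effective order but cancelling group
    delay; otherwise a single causal pass is used.
    """
    x = np.asarray(x, dtype=float)
    if not np.isfinite(x).all():
        raise DataError("cannot filter non-finite input")
    squeeze = x.ndim == 1
    mat = x[:, None] if squeeze else x
    if mat.shape[0] <= 3 * spec.order:
        raise DataError("signal too short for the requested filter order")
    sos = design_sos(spec, fs)
    if zero_phase:
        out = sps.sosfiltfilt(sos, mat, axis=0)
    else:
        out = sps.sosfilt(sos, mat, axis=0)
    return out[:, 0] if squeeze else out


def resample_uniform(x: np.ndarray, fs_in: float, fs_out: float) -> np.ndarray:
    """Resample columns of *x* from *fs_in* to *fs_out*.

    Rational rate ratios (2048 -> 1024, 256 -> 1024) are handled by polyphase
    filtering, which applies the anti-aliasing low-pass implicitly on
    downsampling.  Output length is ``round(n * fs_out / fs_in)``.
    """
    x = np.asarray(x, dtype=float)
    if x.shape[0] == 0:
        raise DataError("cannot resample zero-length input")
    if fs_in <= 0 or fs_out <= 0:
        raise DataError("sampling rates must be positive")
    n_out = int(round(x.shape[0] * fs_out / fs_in))
    if fs_in == fs_out:
        return x.copy()
    ratio = Fraction(fs_out).limit_denominator(10**6) / Fraction(
        fs_in
    ).limit_denominator(10**6)
    up, down = ratio.numerator, ratio.denominator
    # resample about the mean: the polyphase FIR has finite stop-band
    # attenuation, so a large DC component would otherwise leave a small
    # periodic ripple (relevant for angle traces sitting near 90 deg)
    mean = x.mean(axis=0, keepdims=True)
    y = sps.resample_poly(x - mean, up, down, axis=0, padtype="line") + mean
    if y.shape[0] > n_out:
        y = y[:n_out]
    elif y.shape[0] < n_out:  # pad by edge value; off-by-one from ceil vs round
        pad = np.repeat(y[-1:], n_out - y.shape[0], axis=0)
        y = np.concatenate([y, pad], axis=0)
    return y


# ---------------------------------------------------------------------------
# synchronization
# ---------------------------------------------------------------------------


def sync_square_wave(t: np.ndarray) -> np.ndarray:
    """The 20 Hz, +/-5 V synchronization square wave evaluated at times *t*."""
    return SYNC_AMPLITUDE_V * sps.square(2.0 * np.pi * SYNC_FREQ_HZ * np.asarray(t))


def find_sync_edge(sync: np.ndarray, fs: float) -> int:
    """Index of the first usable rising edge of the square wave.

    The detector waits until the trace has first dipped below -SYNC_AMPLITUDE/2
    (rejecting power-on transients) and then returns the first positive-going
    zero crossing.  Raises :class:`SyncError` when no edge exists.
    """
    sync = np.asarray(sync, dtype=float).ravel()
    below = np.flatnonzero(sync < -SYNC_AMPLITUDE_V / 2.0)
    if below.size == 0:
        raise SyncError("sync trace never reaches the low level")
    start = below[0]
    seg = sync[start:]
    rising = np.flatnonzero((seg[:-1] < 0.0) & (seg[1:] >= 0.0))
    if rising.size == 0:
        raise SyncError("no rising edge found in sync trace")
    return int(start + rising[0] + 1)


def _rising_edges(sync: np.ndarray) -> np.ndarray:
    sync = np.asarray(sync, dtype=float).ravel()
    return np.flatnonzero((sync[:-1] < 0.0) & (sync[1:] >= 0.0)) + 1


def check_sync_drift(sync: np.ndarray, fs: float, tol: float = 0.10) -> float:
    """Mean inter-edge period of the sync trace; warns when it deviates from
    the nominal 1/20 s by more than *tol* (relative)."""
    edges = _rising_edges(sync)
    if edges.size < 2:
        raise SyncError("need at least 2 rising edges to estimate drift")
    period = float(np.mean(np.diff(edges))) / fs
    nominal = 1.0 / SYNC_FREQ_HZ
    if abs(period - nominal) / nominal > tol:
        warnings.warn(
            f"sync drift: mean period {period:.4f}s deviates from "
            f"{nominal:.4f}s by more than {tol:.0%}",
            stacklevel=2,
        )
    return period


def trim_at_sync_edge(obj: EmgRecording | MarkerSession):
    """Return (trimmed copy starting at the sync edge, edge time in seconds)."""
    if obj.sync is None:
        raise SyncError("stream carries no sync trace")
    idx = find_sync_edge(obj.sync, obj.fs)
    if isinstance(obj, EmgRecording):
        out = EmgRecording(
            obj.samples[idx:], obj.fs, list(obj.channel_names), obj.side,
            obj.sync[idx:],
        )
    else:
        out = MarkerSession(
            {k: v[idx:] for k, v in obj.markers.items()},
            obj.fs, obj.side, obj.sync[idx:],
        )
    return out, idx / obj.fs


def synchronize(
    emg: EmgRecording, kin, fs_common: float = FS_COMMON
) -> TimeAlignedPair:
    """Align an EMG stream with a kinematics stream via their sync traces.

    Both streams are trimmed to their first detected rising edge of the shared
    square wave, resampled to *fs_common*, and truncated to equal length.
    ``offset_applied`` is the (signed) time by which the kinematics edge
    lagged the EMG edge in the raw records.

    *kin* may be a :class:`MarkerSession` (gaps must have been repaired) or a
    :class:`~wristemg.kinematics.JointAngleSeries`.
    """
    from .kinematics import JointAngleSeries  # local import to avoid a cycle

    emg_trim, t_emg = trim_at_sync_edge(emg)
    check_sync_drift(emg_trim.sync, emg.fs)

    if isinstance(kin, MarkerSession):
        for name, traj in kin.markers.items():
            if np.isnan(traj).any():
                raise DataError(
                    f"marker {name} has unrepaired gaps; call repair_marker_gaps first"
                )
        kin_trim, t_kin = trim_at_sync_edge(kin)
        check_sync_drift(kin_trim.sync, kin.fs)
        kin_rs = MarkerSession(
            {k: resample_uniform(v, kin.fs, fs_common)
             for k, v in kin_trim.markers.items()},
            fs_common, kin.side,
            resample_uniform(kin_trim.sync, kin.fs, fs_common),
        )
        n_kin = kin_rs.n_frames
    elif isinstance(kin, JointAngleSeries):
        if kin.sync is None:
            raise SyncError("angle series carries no sync trace")
        idx = find_sync_edge(kin.sync, kin.fs)
        t_kin = idx / kin.fs
        block = np.column_stack([kin.alpha1, kin.alpha2, kin.alpha3])[idx:]
        rs = resample_uniform(block, kin.fs, fs_common)
        sync_rs = resample_uniform(kin.sync[idx:], kin.fs, fs_common)
        kin_rs = JointAngleSeries(
            alpha1=rs[:, 0], alpha2=rs[:, 1], alpha3=rs[:, 2],
            fs=fs_common, sync=sync_rs,
        )
        n_kin = rs.shape[0]
    else:
        raise TypeError(f"unsupported kinematics type {type(kin).__name__}")

    emg_rs = EmgRecording(
        resample_uniform(emg_trim.samples, emg.fs, fs_common),
        fs_common, list(emg.channel_names), emg.side,
        resample_uniform(emg_trim.sync, emg.fs, fs_common),
    )

    n = min(emg_rs.n_samples, n_kin)
    emg_rs = EmgRecording(
        emg_rs.samples[:n], fs_common, list(emg.channel_names), emg.side,
        emg_rs.sync[:n],
    )
    if isinstance(kin_rs, MarkerSession):
        kin_rs = MarkerSession(
            {k: v[:n] for k, v in kin_rs.markers.items()},
            fs_common, kin_rs.side, kin_rs.sync[:n],
        )
    else:
        kin_rs = JointAngleSeries(
            alpha1=kin_rs.alpha1[:n], alpha2=kin_rs.alpha2[:n],
            alpha3=kin_rs.alpha3[:n], fs=fs_common, sync=kin_rs.sync[:n],
        )
    return TimeAlignedPair(emg_rs, kin_rs, fs_common, t_kin - t_emg)


# ---------------------------------------------------------------------------
# gap repair
# ---------------------------------------------------------------------------


def repair_marker_gaps(
    session: MarkerSession, max_gap: float = 0.25
) -> MarkerSession:
    """Linearly interpolate marker gaps no longer than *max_gap* seconds.

    Longer gaps invalidate the trial (raise :class:`TrialRejectionError`),
    matching the practice of re-recording trials with excessive marker
    drop-out rather than repairing them.  Gaps touching the record edges are
    filled by holding the nearest valid frame.
    """
    max_frames = int(round(max_gap * session.fs))
    repaired: dict[str, np.ndarray] = {}
    for name, traj in session.markers.items():
        bad = np.isnan(traj).any(axis=1)
        if not bad.any():
            repaired[name] = traj.copy()
            continue
        runs = _nan_runs(bad)
        for start, stop in runs:
            interior = start > 0 and stop < traj.shape[0]
            if interior and (stop - start) > max_frames:
                raise TrialRejectionError(
                    f"marker {name}: gap of {(stop - start) / session.fs:.3f}s "
                    f"exceeds {max_gap}s"
                )
        out = traj.copy()
        idx = np.arange(traj.shape[0])
        for col in range(3):
            good = ~np.isnan(traj[:, col])
            out[:, col] = np.interp(idx, idx[good], traj[good, col])
        repaired[name] = out
    return MarkerSession(repaired, session.fs, session.side, session.sync)


def _nan_runs(bad: np.ndarray) -> list[tuple[int, int]]:
    """[start, stop) index pairs of consecutive True runs."""
    runs = []
    in_run = False
    start = 0
    for i, b in enumerate(bad):
        if b and not in_run:
            in_run, start = True, i
        elif not b and in_run:
            in_run = False
            runs.append((start, i))
    if in_run:
        runs.append((start, len(bad)))
    return runs


# ---------------------------------------------------------------------------
# session I/O
# ---------------------------------------------------------------------------
#
# HDF5 layout (one file per arm):
#   /emg/samples  [n, c] float64      /markers/<ID>  [n, 3] float64
#   /emg/fs       scalar              /markers/fs    scalar
#   /emg/sync     [n]                 /markers/sync  [n]
#   /emg/channel_names [c] str        group attribute "side" on both groups
#
# CSV layout (one directory per arm):
#   emg.csv      columns t, <ch>..., sync        (6 decimals)
#   markers.csv  columns t, <ID>_x, <ID>_y, <ID>_z, ..., sync; gaps as "NA"
#   meta.json    {"side": ..., "emg_fs": ..., "markers_fs": ..., "channels": [...]}


def write_session(
    path: str | Path,
    emg: EmgRecording,
    markers: MarkerSession,
    format: Literal["hdf5", "csv"] = "hdf5",
) -> Path:
    """Write one arm's EMG + marker streams; returns the path written."""
    path = Path(path)
    if format == "hdf5":
        with h5py.File(path, "w") as f:
            g = f.create_group("emg")
            g.create_dataset("samples", data=emg.samples)
            g.create_dataset("fs", data=float(emg.fs))
            g.create_dataset(
                "channel_names",
                data=np.array(list(emg.channel_names), dtype="S32"),
            )
            if emg.sync is not None:
                g.create_dataset("sync", data=emg.sync)
            g.attrs["side"] = emg.side
            m = f.create_group("markers")
            for name, traj in markers.markers.items():
                m.create_dataset(name, data=traj)
            m.create_dataset("fs", data=float(markers.fs))
            if markers.sync is not None:
                m.create_dataset("sync", data=markers.sync)
            m.attrs["side"] = markers.side
        return path
    if format == "csv":
        path.mkdir(parents=True, exist_ok=True)
        emg_df = pd.DataFrame(emg.samples, columns=list(emg.channel_names))
        emg_df.insert(0, "t", emg.t)
        if emg.sync is not None:
            emg_df["sync"] = emg.sync
        emg_df.to_csv(path / "emg.csv", index=False, float_format="%.6f")
        cols: dict[str, np.ndarray] = {"t": markers.t}
        for name, traj in markers.markers.items():
            for k, ax in enumerate("xyz"):
                cols[f"{name}_{ax}"] = traj[:, k]
        if markers.sync is not None:
            cols["sync"] = markers.sync
        pd.DataFrame(cols).to_csv(
            path / "markers.csv", index=False, float_format="%.6f",
            na_rep=CSV_GAP_TOKEN,
        )
        meta = {
            "side": emg.side,
            "markers_side": markers.side,
            "emg_fs": float(emg.fs),
            "markers_fs": float(markers.fs),
            "channels": list(emg.channel_names),
        }
        (path / "meta.json").write_text(json.dumps(meta, indent=2, sort_keys=True))
        return path
    raise SchemaError(f"unsupported format {format!r}")


def read_session(
    path: str | Path, format: Literal["hdf5", "csv"] = "hdf5"
) -> tuple[EmgRecording, MarkerSession]:
    """Read one arm's session written by :func:`write_session`."""
    path = Path(path)
    if format == "hdf5":
        with h5py.File(path, "r") as f:
            if "emg" not in f or "markers" not in f:
                raise SchemaError("file lacks /emg or /markers groups")
            g, m = f["emg"], f["markers"]
            emg = EmgRecording(
                g["samples"][()],
                float(g["fs"][()]),
                [c.decode() for c in g["channel_names"][()]],
                g.attrs.get("side", "right"),
                g["sync"][()] if "sync" in g else None,
            )
            marker_data = {
                k: m[k][()]
                for k in m
                if k in REQUIRED_MARKERS + OPTIONAL_MARKERS
            }
            markers = MarkerSession(
                marker_data,
                float(m["fs"][()]),
                m.attrs.get("side", "right"),
                m["sync"][()] if "sync" in m else None,
            )
        return emg, markers
    if format == "csv":
        meta = json.loads((path / "meta.json").read_text())
        emg_df = pd.read_csv(path / "emg.csv")
        chans = meta["channels"]
        if not set(chans) <= set(emg_df.columns):
            raise SchemaError("emg.csv columns do not match channel list")
        emg = EmgRecording(
            emg_df[chans].to_numpy(float),
            float(meta["emg_fs"]),
            chans,
            meta["side"],
            emg_df["sync"].to_numpy(float) if "sync" in emg_df else None,
        )
        mk_df = pd.read_csv(path / "markers.csv", na_values=[CSV_GAP_TOKEN])
        marker_data = {}
        for name in REQUIRED_MARKERS + OPTIONAL_MARKERS:
            cols = [f"{name}_{ax}" for ax in "xyz"]
            if set(cols) <= set(mk_df.columns):
                marker_data[name] = mk_df[cols].to_numpy(float)
        markers = MarkerSession(
            marker_data,
            float(meta["markers_fs"]),
            meta.get("markers_side", meta["side"]),
            mk_df["sync"].to_numpy(float) if "sync" in mk_df else None,
        )
        return emg, markers
    raise SchemaError(f"unsupported format {format!r}")
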