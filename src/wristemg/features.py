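"""Sliding-window segmentation and the TDAR feature set.

TDAR = the four Hudgins time-domain descriptors (mean absolute value,
zero-crossing count, slope-sign-change count, waveform length) plus the six
coefficients of an order-6 autoregressive model, computed per channel per
analysis window.  The default schedule is a 100 ms window advanced by 40 ms
(60 ms overlap), the standard compromise between estimation variance and
controller delay in myoelectric control.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import h5py
import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

from .errors import DataError, ParameterError
from .signalio import EmgRecording

#: Default autoregressive model order.
AR_ORDER = 6
TD_NAMES = ("mav", "zc", "ssc", "wl")


@dataclass(frozen=True)
class WindowSchedule:
    """Sliding-window plan: 100 ms windows every 40 ms by default.

    At 1024 Hz the nominal 100 ms window is 102.4 samples; lengths are rounded
    to the nearest sample (L = 102, S = 41) so window counts are reproducible.
    """

    window_len: float = 0.100
    increment: float = 0.040
    fs: float = 1024.0

    def __post_init__(self) -> None:
        if not 0 < self.increment <= self.window_len:
            raise ParameterError("need 0 < increment <= window_len")
        if self.n_window_samples < 2 * (AR_ORDER + 1):
            raise ParameterError("window too short for the AR model order")

    @property
    def n_window_samples(self) -> int:
        return int(round(self.window_len * self.fs))

    @property
    def n_step_samples(self) -> int:
        return int(round(self.increment * self.fs))

    def n_windows(self, n_samples: int) -> int:
        L, S = self.n_window_samples, self.n_step_samples
        if n_samples < L:
            return 0
        return (n_samples - L) // S + 1

    def window_starts(self, n_samples: int) -> np.ndarray:
        """Start indices of all complete windows (trailing partial discarded)."""
        n = self.n_windows(n_samples)
        return np.arange(n) * self.n_step_samples

    def window_centers(self, n_samples: int) -> np.ndarray:
        """Window midpoints in seconds."""
        L = self.n_window_samples
        return (self.window_starts(n_samples) + (L - 1) / 2.0) / self.fs


@dataclass
class FeatureMatrix:
    """One row per analysis window; columns are channel-major TDAR features."""

    values: np.ndarray
    window_centers: np.ndarray
    feature_names: Sequence[str]
    schedule: WindowSchedule

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.window_centers = np.asarray(self.window_centers, dtype=float)
        if self.values.shape != (self.window_centers.size, len(self.feature_names)):
            raise DataError("FeatureMatrix shape inconsistent with names/centers")
        if not np.isfinite(self.values).all():
            raise DataError("feature values contain non-finite entries")
        if np.any(np.diff(self.window_centers) <= 0):
            raise DataError("window centers must be strictly increasing")

    @property
    def n_windows(self) -> int:
        return self.values.shape[0]

    def to_hdf5(self, path: str | Path) -> None:
        with h5py.File(path, "w") as f:
            g = f.create_group("features")
            g.create_dataset("values", data=self.values)
            g.create_dataset("window_centers", data=self.window_centers)
            g.create_dataset(
                "names", data=np.array(list(self.feature_names), dtype="S64")
            )
            g.attrs["window_len"] = self.schedule.window_len
            g.attrs["increment"] = self.schedule.increment
            g.attrs["fs"] = self.schedule.fs

    @classmethod
    def from_hdf5(cls, path: str | Path) -> "FeatureMatrix":
        with h5py.File(path, "r") as f:
            g = f["features"]
            sched = WindowSchedule(
                float(g.attrs["window_len"]),
                float(g.attrs["increment"]),
                float(g.attrs["fs"]),
            )
            return cls(
                g["values"][()],
                g["window_centers"][()],
                [n.decode() for n in g["names"][()]],
                sched,
            )

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.values, columns=list(self.feature_names))
        df.insert(0, "t", self.window_centers)
        df.to_csv(path, index=False)


def segment_windows(signal: np.ndarray, schedule: WindowSchedule) -> np.ndarray:
    """View of all complete analysis windows.

    Returns ``[n_windows, L]`` for 1-D input or ``[n_windows, L, n_channels]``
    for 2-D input; trailing samples that do not fill a window are discarded.
    """
    signal = np.asarray(signal, dtype=float)
    L, S = schedule.n_window_samples, schedule.n_step_samples
    if signal.shape[0] < L:
        raise DataError(
            f"signal of {signal.shape[0]} samples shorter than one "
            f"{L}-sample window"
        )
    view = sliding_window_view(signal, L, axis=0)[::S]
    # sliding_window_view puts the window axis last; move it next to windows
    return np.moveaxis(view, -1, 1)


def td_features(
    window: np.ndarray, zc_threshold: float = 0.0, ssc_threshold: float = 0.0
) -> np.ndarray:
    """Hudgins time-domain features of one window: (MAV, ZC, SSC, WL).

    ZC counts sign changes between consecutive samples whose amplitude step
    exceeds ``zc_threshold``; SSC counts samples where the slope changes sign
    and at least one adjacent step exceeds ``ssc_threshold``.  Thresholds
    default to 0 (appropriate for noiseless synthetic data) and should be set
    to a few microvolts for recorded EMG.
    """
    w = np.asarray(window, dtype=float)
    if w.ndim != 1 or w.size < 3:
        raise DataError("td_features needs a 1-D window of >= 3 samples")
    return _td_block(w[None, :], zc_threshold, ssc_threshold)[0]


def _td_block(
    wins: np.ndarray, zc_threshold: float, ssc_threshold: float
) -> np.ndarray:
    """Vectorized TD features for a [n_windows, L] block."""
    d = np.diff(wins, axis=1)
    mav = np.mean(np.abs(wins), axis=1)
    wl = np.sum(np.abs(d), axis=1)
    sign_change = (wins[:, :-1] * wins[:, 1:]) < 0.0
    zc = np.sum(sign_change & (np.abs(d) >= zc_threshold), axis=1).astype(float)
    turning = (d[:, :-1] * d[:, 1:]) < 0.0
    big_step = (np.abs(d[:, :-1]) >= ssc_threshold) | (
        np.abs(d[:, 1:]) >= ssc_threshold
    )
    ssc = np.sum(turning & big_step, axis=1).astype(float)
    return np.column_stack([mav, zc, ssc, wl])


def _biased_autocorr(w: np.ndarray, nlags: int) -> np.ndarray:
    """Biased sample autocorrelation r[0..nlags] of a [n_windows, L] block."""
    n = w.shape[1]
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    spec = np.fft.rfft(w, nfft, axis=1)
    acov = np.fft.irfft(spec * np.conj(spec), nfft, axis=1)[:, : nlags + 1]
    return acov / n


def _levinson(r: np.ndarray, order: int) -> np.ndarray:
    """Levinson-Durbin recursion on autocorrelation rows ``r[:, 0..order]``.

    Returns predictor coefficients ``a`` in the convention
    ``x[n] = sum_k a[k] x[n-k] + e[n]`` (so an AR(1) process generated with
    coefficient 0.5 yields a1 ~= 0.5).
    """
    n_rows = r.shape[0]
    a = np.zeros((n_rows, order))
    err = r[:, 0].copy()
    live = err > 0
    for m in range(order):
        acc = r[:, m + 1].copy()
        for k in range(m):
            acc -= a[:, k] * r[:, m - k]
        kappa = np.zeros(n_rows)
        kappa[live] = acc[live] / err[live]
        new_a = a.copy()
        new_a[:, m] = kappa
        for k in range(m):
            new_a[:, k] = a[:, k] - kappa * a[:, m - 1 - k]
        a = new_a
        err = err * (1.0 - kappa**2)
        live = live & (err > 0)
    return a


def _burg(w: np.ndarray, order: int) -> np.ndarray:
    """Burg's method on a [n_windows, L] block; same sign convention as
    :func:`_levinson`."""
    n_rows = w.shape[0]
    f = w.copy()
    b = w.copy()
    a = np.zeros((n_rows, order))
    for m in range(order):
        fm = f[:, 1:]
        bm = b[:, :-1]
        num = 2.0 * np.sum(fm * bm, axis=1)
        den = np.sum(fm**2 + bm**2, axis=1)
        k = np.where(den > 0, num / np.maximum(den, 1e-300), 0.0)
        new_a = a.copy()
        new_a[:, m] = k
        for j in range(m):
            new_a[:, j] = a[:, j] - k * a[:, m - 1 - j]
        a = new_a
        f, b = fm - k[:, None] * bm, bm - k[:, None] * fm
    return a


def ar_coefficients(
    window: np.ndarray,
    order: int = AR_ORDER,
    method: Literal["yule-walker", "burg"] = "yule-walker",
    zeros_on_degenerate: bool = False,
) -> np.ndarray:
    """Order-*order* linear-prediction coefficients of one window.

    The window is mean-removed first.  The default estimator solves the
    Yule-Walker equations on the biased autocorrelation sequence via the
    Levinson-Durbin recursion; Burg's method is available as an alternative.
    Coefficients follow ``x[n] = sum_k a_k x[n-k] + e[n]`` and are invariant
    to amplitude scaling of the window.
    """
    w = np.asarray(window, dtype=float)
    if w.ndim != 1:
        raise DataError("ar_coefficients needs a 1-D window")
    if order < 1 or w.size <= 2 * order:
        raise ParameterError("window length must exceed 2 x AR order")
    w = w - w.mean()
    if np.all(w == 0.0):
        if zeros_on_degenerate:
            return np.zeros(order)
        raise DataError("constant window: AR model undefined")
    if method == "yule-walker":
        r = _biased_autocorr(w[None, :], order)
        return _levinson(r, order)[0]
    if method == "burg":
        return _burg(w[None, :], order)[0]
    raise ParameterError(f"unknown AR method {method!r}")


def extract_tdar(
    emg: EmgRecording,
    schedule: WindowSchedule | None = None,
    zc_threshold: float = 0.0,
    ssc_threshold: float = 0.0,
    ar_order: int = AR_ORDER,
    ar_method: Literal["yule-walker", "burg"] = "yule-walker",
) -> FeatureMatrix:
    """TDAR feature matrix of a (filtered, resampled) EMG recording.

    Columns are channel-major: for each channel, MAV, ZC, SSC, WL followed by
    a1..a6.  Degenerate (constant) windows yield all-zero AR coefficients.
    """
    schedule = schedule or WindowSchedule(fs=emg.fs)
    if schedule.fs != emg.fs:
        raise ParameterError(
            f"schedule rate {schedule.fs} does not match recording rate {emg.fs}"
        )
    wins = segment_windows(emg.samples, schedule)  # [n_win, L, n_ch]
    n_win, L, n_ch = wins.shape
    cols = []
    for c in range(n_ch):
        block = wins[:, :, c]
        td = _td_block(block, zc_threshold, ssc_threshold)
        centered = block - block.mean(axis=1, keepdims=True)
        if ar_method == "yule-walker":
            r = _biased_autocorr(centered, ar_order)
            ar = _levinson(r, ar_order)
        else:
            ar = _burg(centered, ar_order)
        degenerate = np.all(centered == 0.0, axis=1)
        ar[degenerate] = 0.0
        cols.append(np.concatenate([td, ar], axis=1))
    values = np.concatenate(cols, axis=1)
    names = [
        f"{ch}_{feat}"
        for ch in emg.channel_names
        for feat in list(TD_NAMES) + [f"ar{k}" for k in range(1, ar_order + 1)]
    ]
    return FeatureMatrix(
        values, schedule.window_centers(emg.n_samples), names, schedule
    )
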