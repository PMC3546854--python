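"""Marker-based wrist joint angles.

A wrist-centred coordinate frame is built from the six distal markers: the
humeral epicondyles (MEP, LEP), the styloid processes (STU, STR) and the 2nd
and 5th metacarpal heads (RMC, UMC).  The origin O is the midpoint of the
styloids; z points proximally from O to the elbow midpoint E; y is orthogonal
to z and to the styloid line (the dorsopalmar axis); x completes the
right-handed frame (the mediolateral axis).

With H the metacarpal midpoint and (Hx, Hy, Hz) its coordinates in the frame,
the three wrist angles are

    alpha1 = atan2(Hy, -Hz)     flexion (+) / extension (-)
    alpha2 = atan2(Hx, -Hz)     radial (+) / ulnar (-) deviation
    alpha3 = angle(w, l)        with w = LEP - MEP, l = STR - STU;
                                neutral ~ 90 deg, < 90 deg = supination

Because the hand lies distally (Hz < 0 in the frame), atan2 against -Hz keeps
the magnitudes of the arctangent definitions while making flexion and radial
deviation positive.  |alpha1| and |alpha2| cannot exceed 90 deg; frames where
the hand is not distal to the wrist are flagged not-available.

Handedness: a frame that is right-handed on both arms cannot keep y anterior
and x lateral on both — mirroring flips one of them.  The frame keeps y
anterior on either side (the ``side`` field selects the sign of y) and
negates alpha2 on the left arm so that mirrored bilateral movements produce
identical angle traces on both sides, as the mirror-training paradigm
requires.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .errors import DataError, GeometryError, TrialRejectionError
from .signalio import (
    ANGLE_LOWPASS,
    FS_COMMON,
    MarkerSession,
    butter_filter,
    resample_uniform,
)

#: |Hz| below this (relative to |H - O|) flags a frame as out of range.
_HZ_TOL = 1e-9
#: Fraction of invalid frames above which the trial is rejected.
_MAX_INVALID_FRACTION = 0.20


@dataclass
class WristFrame:
    """Wrist-centred orthonormal frame (all vectors in mm / unit length)."""

    origin: np.ndarray
    elbow: np.ndarray
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    side: str = "right"


@dataclass
class JointAngleSeries:
    """Time-indexed wrist angles in degrees.

    ``alpha3`` is stored raw in [0, 180] (neutral ~ 90); the centred form
    ``alpha3 - 90`` (pronation positive) used as the regression target is
    available via :attr:`alpha3_centered`.
    """

    alpha1: np.ndarray
    alpha2: np.ndarray
    alpha3: np.ndarray
    fs: float
    sync: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.alpha1 = np.asarray(self.alpha1, dtype=float).ravel()
        self.alpha2 = np.asarray(self.alpha2, dtype=float).ravel()
        self.alpha3 = np.asarray(self.alpha3, dtype=float).ravel()
        if not (self.alpha1.size == self.alpha2.size == self.alpha3.size):
            raise DataError("angle components must have equal length")
        if self.fs <= 0:
            raise DataError("sampling rate must be positive")
        for arr, lo, hi in (
            (self.alpha1, -90.0, 90.0),
            (self.alpha2, -90.0, 90.0),
            (self.alpha3, 0.0, 180.0),
        ):
            finite = arr[np.isfinite(arr)]
            if finite.size and (finite.min() < lo - 1e-6 or finite.max() > hi + 1e-6):
                raise DataError("angle values outside their admissible range")
        if self.sync is not None:
            self.sync = np.asarray(self.sync, dtype=float).ravel()
            if self.sync.size != self.alpha1.size:
                raise DataError("sync trace length must equal series length")

    @property
    def n_samples(self) -> int:
        return self.alpha1.size

    @property
    def t(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs

    @property
    def alpha3_centered(self) -> np.ndarray:
        """alpha3 - 90 deg: zero at neutral, pronation positive."""
        return self.alpha3 - 90.0

    def as_matrix(self, centered_alpha3: bool = True) -> np.ndarray:
        """``[n, 3]`` matrix of (alpha1, alpha2, alpha3[, centred])."""
        a3 = self.alpha3_centered if centered_alpha3 else self.alpha3
        return np.column_stack([self.alpha1, self.alpha2, a3])

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "t": self.t,
                "alpha1": self.alpha1,
                "alpha2": self.alpha2,
                "alpha3": self.alpha3,
            }
        ).to_csv(path, index=False)

    def to_hdf5(self, path: str | Path) -> None:
        with h5py.File(path, "w") as f:
            g = f.create_group("angles")
            for name in ("alpha1", "alpha2", "alpha3"):
                g.create_dataset(name, data=getattr(self, name))
            g.create_dataset("fs", data=float(self.fs))
            if self.sync is not None:
                g.create_dataset("sync", data=self.sync)

    @classmethod
    def from_hdf5(cls, path: str | Path) -> "JointAngleSeries":
        with h5py.File(path, "r") as f:
            g = f["angles"]
            return cls(
                g["alpha1"][()],
                g["alpha2"][()],
                g["alpha3"][()],
                float(g["fs"][()]),
                g["sync"][()] if "sync" in g else None,
            )


def _unit(v: np.ndarray, axis: int = -1) -> np.ndarray:
    norm = np.linalg.norm(v, axis=axis, keepdims=True)
    if np.any(norm < 1e-12):
        raise GeometryError("degenerate (zero-length) direction vector")
    return v / norm


def build_wrist_frame(
    mep: np.ndarray,
    lep: np.ndarray,
    stu: np.ndarray,
    str_: np.ndarray,
    side: str = "right",
) -> WristFrame:
    """Construct the wrist frame from a single frame's four forearm markers.

    O = (STR + STU)/2, E = (MEP + LEP)/2, z = unit(E - O); y is the unit
    vector orthogonal to z and to the styloid line STR - STU, with the sign
    chosen per arm side (anterior); x = y cross z closes the right-handed
    frame.
    """
    mep, lep, stu, str_ = (np.asarray(p, dtype=float) for p in (mep, lep, stu, str_))
    if not all(np.isfinite(p).all() for p in (mep, lep, stu, str_)):
        raise GeometryError("non-finite marker coordinates")
    origin = (str_ + stu) / 2.0
    elbow = (mep + lep) / 2.0
    z = _unit(elbow - origin)
    styloid = str_ - stu
    y_raw = np.cross(z, styloid)
    if np.linalg.norm(y_raw) < 1e-9:
        raise GeometryError("styloid line collinear with the forearm axis")
    sign = 1.0 if side == "right" else -1.0
    y = sign * _unit(y_raw)
    x = np.cross(y, z)
    return WristFrame(origin, elbow, x, y, z, side)


def wrist_angles(
    frame: WristFrame,
    rmc: np.ndarray,
    umc: np.ndarray,
    mep: np.ndarray,
    lep: np.ndarray,
    stu: np.ndarray,
    str_: np.ndarray,
) -> tuple[float, float, float]:
    """Per-frame wrist angles (degrees) given the frame and the six markers.

    Returns NaN angles when the hand midpoint is not distal to the wrist
    (|Hz| ~ 0 or Hz > 0 would put |alpha| beyond 90 deg).
    """
    rmc, umc = np.asarray(rmc, dtype=float), np.asarray(umc, dtype=float)
    h = (rmc + umc) / 2.0 - frame.origin
    hx, hy, hz = h @ frame.x, h @ frame.y, h @ frame.z
    if -hz <= _HZ_TOL * np.linalg.norm(h):
        return (np.nan, np.nan, np.nan)
    a1 = np.degrees(np.arctan2(hy, -hz))
    sgn = 1.0 if frame.side == "right" else -1.0
    a2 = sgn * np.degrees(np.arctan2(hx, -hz))
    w = np.asarray(lep, dtype=float) - np.asarray(mep, dtype=float)
    l = np.asarray(str_, dtype=float) - np.asarray(stu, dtype=float)
    a3 = np.degrees(
        np.arctan2(np.linalg.norm(np.cross(w, l)), float(w @ l))
    )
    return (float(a1), float(a2), float(a3))


def _angles_raw(session: MarkerSession) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized per-frame angles at the native marker rate (NaN = invalid)."""
    m = session.markers
    mep, lep = m["MEP"], m["LEP"]
    stu, str_ = m["STU"], m["STR"]
    rmc, umc = m["RMC"], m["UMC"]

    origin = (str_ + stu) / 2.0
    elbow = (mep + lep) / 2.0
    zv = elbow - origin
    z_norm = np.linalg.norm(zv, axis=1, keepdims=True)
    styloid = str_ - stu
    y_raw = np.cross(zv / np.where(z_norm > 0, z_norm, np.nan), styloid)
    y_norm = np.linalg.norm(y_raw, axis=1, keepdims=True)
    sign = 1.0 if session.side == "right" else -1.0
    yv = sign * y_raw / np.where(y_norm > 0, y_norm, np.nan)
    zu = zv / np.where(z_norm > 0, z_norm, np.nan)
    xv = np.cross(yv, zu)

    h = (rmc + umc) / 2.0 - origin
    hx = np.einsum("ij,ij->i", h, xv)
    hy = np.einsum("ij,ij->i", h, yv)
    hz = np.einsum("ij,ij->i", h, zu)

    with np.errstate(invalid="ignore"):
        distal = -hz > _HZ_TOL * np.linalg.norm(h, axis=1)
        a1 = np.degrees(np.arctan2(hy, -hz))
        a2 = sign * np.degrees(np.arctan2(hx, -hz))
        w = lep - mep
        l = str_ - stu
        a3 = np.degrees(
            np.arctan2(
                np.linalg.norm(np.cross(w, l), axis=1),
                np.einsum("ij,ij->i", w, l),
            )
        )
    invalid = ~distal | ~np.isfinite(a1) | ~np.isfinite(a2) | ~np.isfinite(a3)
    a1[invalid] = np.nan
    a2[invalid] = np.nan
    a3[invalid] = np.nan
    return a1, a2, a3


def compute_angle_series(
    session: MarkerSession, fs_out: float = FS_COMMON
) -> JointAngleSeries:
    """Full kinematic chain: per-frame angles at the marker rate, 6 Hz
    2nd-order Butterworth zero-phase smoothing, then resampling to *fs_out*.

    Invalid frames (marker gaps or out-of-range geometry) are bridged by
    linear interpolation for filtering and re-flagged NaN in the output; more
    than 20 % invalid frames rejects the trial.
    """
    a1, a2, a3 = _angles_raw(session)
    invalid = np.isnan(a1)
    frac = invalid.mean()
    if frac > _MAX_INVALID_FRACTION:
        raise TrialRejectionError(
            f"{frac:.0%} of frames invalid (limit {_MAX_INVALID_FRACTION:.0%})"
        )
    block = np.column_stack([a1, a2, a3])
    if invalid.any():
        idx = np.arange(block.shape[0])
        good = ~invalid
        if good.sum() < 2:
            raise TrialRejectionError("fewer than 2 valid frames")
        for c in range(3):
            block[:, c] = np.interp(idx, idx[good], block[good, c])
    filt = butter_filter(block, session.fs, ANGLE_LOWPASS, zero_phase=True)
    out = resample_uniform(filt, session.fs, fs_out)
    if invalid.any():
        # re-flag output samples whose nearest source frame was invalid
        src = np.minimum(
            (np.arange(out.shape[0]) * session.fs / fs_out).round().astype(int),
            block.shape[0] - 1,
        )
        out[invalid[src]] = np.nan
    # numerical guard: filtering ringing may leave epsilon excursions
    out[:, 0] = np.clip(out[:, 0], -90.0, 90.0)
    out[:, 1] = np.clip(out[:, 1], -90.0, 90.0)
    out[:, 2] = np.clip(out[:, 2], 0.0, 180.0)
    sync_out = (
        resample_uniform(session.sync, session.fs, fs_out)
        if session.sync is not None
        else None
    )
    return JointAngleSeries(out[:, 0], out[:, 1], out[:, 2], fs_out, sync_out)
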