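"""Synthetic mirrored bilateral sessions.

The generator emulates the recording protocol end to end so the whole
pipeline is testable without any experimental data: prescribed joint-angle
trajectories for the ten contraction types (single-DoF sinusoids, two-DoF
combinations with one DoF held near end range, and cyclic three-DoF
movements), marker trajectories that are the exact geometric inverse of the
angle equations, and surface EMG whose amplitude envelope is a known,
learnable function of the angles.

EMG model: amplitude-modulated band-limited Gaussian noise.  Six
non-negative directional drives (flexion/extension, radial/ulnar,
pronation/supination — half-rectified normalized angles, one per antagonist
of each muscle pair) are mixed into 7 channel envelopes by a non-negative
synergy matrix W; each channel is that envelope times an independent 20-400
Hz Gaussian carrier.  Antagonist pairs make the EMG-to-angle map
non-invertible channel-by-channel, so the estimator must genuinely combine
channels.  The contralateral ("amputated") side uses the mirrored drives
with a per-trial perturbed synergy matrix W' = W * (1 + asymmetry * eps) to
emulate imperfect, trial-to-trial variable mirroring; with asymmetry 0 both
sides have identical envelopes and differ only by carrier realization.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .errors import ParameterError
from .kinematics import JointAngleSeries, MarkerSession
from .signalio import EmgRecording, sync_square_wave

# ---------------------------------------------------------------------------
# contraction taxonomy
# ---------------------------------------------------------------------------

#: Default single-DoF amplitudes, degrees (flexion, deviation, pronation).
DEFAULT_AMPLITUDES = {1: 35.0, 2: 25.0, 3: 45.0}

#: Sinusoid frequency per contraction id, Hz (protocol range 0.5-1 Hz).
DEFAULT_FREQS = {
    1: 0.5, 2: 0.65, 3: 0.8,
    4: 0.5, 5: 0.6, 6: 0.7, 7: 0.8, 8: 0.9, 9: 1.0,
    10: 0.6,
}

#: (sinusoidal DoF, held DoF) for the two-DoF combinations; the first DoF of
#: each pair is articulated sinusoidally, the second held near end range.
COMBINED_PAIRS = {4: (1, 2), 5: (2, 1), 6: (1, 3), 7: (3, 1), 8: (2, 3), 9: (3, 2)}

#: Held DoF level as a fraction of that DoF's amplitude ("close to maximal
#: range of motion").
HELD_LEVEL_FRACTION = 0.8

_RAMP_S = 2.0      # onset ramp of held DoFs and of the trial envelope
_TAPER_S = 1.0     # release taper at the trial end


@dataclass(frozen=True)
class ContractionSpec:
    """One trial of the contraction protocol.

    ``kind`` is ``sinusoid_single`` (ids 1-3: one DoF sinusoidal),
    ``combined_two`` (ids 4-9: one DoF sinusoidal, another held near its end
    range) or ``cyclic_three`` (id 10: three smooth band-limited
    pseudo-random curves).
    """

    id: int
    kind: str
    active_dofs: tuple[int, ...]
    freq: float
    amplitude: dict[int, float]
    held_dof_level: float = 0.0
    duration: float = 65.0

    def __post_init__(self) -> None:
        if not 1 <= self.id <= 10:
            raise ParameterError("contraction id must be in 1..10")
        if any(a > 90.0 for a in self.amplitude.values()):
            raise ParameterError("amplitudes above 90 deg are not reachable")
        if not 0.1 <= self.freq <= 2.0:
            raise ParameterError("sinusoid frequency out of plausible range")


def default_contraction(cid: int, duration: float = 10.0) -> ContractionSpec:
    """The protocol's contraction *cid* with default amplitudes/frequencies."""
    amps = dict(DEFAULT_AMPLITUDES)
    if cid in (1, 2, 3):
        return ContractionSpec(cid, "sinusoid_single", (cid,),
                               DEFAULT_FREQS[cid], amps, duration=duration)
    if cid in COMBINED_PAIRS:
        sin_dof, held_dof = COMBINED_PAIRS[cid]
        level = HELD_LEVEL_FRACTION * amps[held_dof]
        return ContractionSpec(cid, "combined_two", (sin_dof, held_dof),
                               DEFAULT_FREQS[cid], amps, level, duration)
    if cid == 10:
        return ContractionSpec(10, "cyclic_three", (1, 2, 3),
                               DEFAULT_FREQS[10], amps, duration=duration)
    raise ParameterError(f"unknown contraction id {cid}")


def _smoothstep(t: np.ndarray, t0: float, t1: float) -> np.ndarray:
    """Half-cosine ramp from 0 at *t0* to 1 at *t1*."""
    u = np.clip((t - t0) / max(t1 - t0, 1e-9), 0.0, 1.0)
    return 0.5 * (1.0 - np.cos(np.pi * u))


def _trial_envelope(t: np.ndarray, duration: float) -> np.ndarray:
    """Smooth on/off envelope so each trial starts and ends at rest."""
    up = _smoothstep(t, 0.0, _RAMP_S)
    down = 1.0 - _smoothstep(t, duration - _TAPER_S, duration)
    return up * down


def angle_waveform(
    spec: ContractionSpec, seed: int
) -> Callable[[np.ndarray], np.ndarray]:
    """Deterministic prescribed-angle function of time for one trial.

    Returns a callable mapping times (s) to ``[n, 3]`` centred angles
    (alpha1, alpha2, alpha3 - 90) in degrees; evaluable at any rate, which
    makes analytic round-trip checks possible.
    """
    if spec.kind == "cyclic_three":
        rng = np.random.default_rng(seed)
        comps = []
        for dof in (1, 2, 3):
            n_comp = 3
            freqs = rng.uniform(0.15, 1.0, n_comp)
            phases = rng.uniform(0.0, 2.0 * np.pi, n_comp)
            amps = rng.uniform(0.5, 1.0, n_comp)
            # normalize on a dense grid so the curve stays within +/- amplitude
            tg = np.linspace(0.0, spec.duration, 4096)
            raw = sum(a * np.sin(2 * np.pi * f * tg + p)
                      for a, f, p in zip(amps, freqs, phases))
            scale = spec.amplitude[dof] / max(np.max(np.abs(raw)), 1e-9)
            comps.append((freqs, phases, amps, scale))

        def cyclic(t: np.ndarray) -> np.ndarray:
            t = np.asarray(t, dtype=float)
            env = _trial_envelope(t, spec.duration)
            out = np.zeros((t.size, 3))
            for j, (freqs, phases, amps, scale) in enumerate(comps):
                raw = sum(a * np.sin(2 * np.pi * f * t + p)
                          for a, f, p in zip(amps, freqs, phases))
                out[:, j] = env * scale * raw
            return out

        return cyclic

    if spec.kind == "sinusoid_single":
        dof = spec.active_dofs[0]

        def single(t: np.ndarray) -> np.ndarray:
            t = np.asarray(t, dtype=float)
            env = _trial_envelope(t, spec.duration)
            out = np.zeros((t.size, 3))
            out[:, dof - 1] = (
                env * spec.amplitude[dof] * np.sin(2 * np.pi * spec.freq * t)
            )
            return out

        return single

    if spec.kind == "combined_two":
        sin_dof, held_dof = spec.active_dofs

        def combined(t: np.ndarray) -> np.ndarray:
            t = np.asarray(t, dtype=float)
            env = _trial_envelope(t, spec.duration)
            out = np.zeros((t.size, 3))
            out[:, sin_dof - 1] = (
                env * spec.amplitude[sin_dof] * np.sin(2 * np.pi * spec.freq * t)
            )
            out[:, held_dof - 1] = env * spec.held_dof_level
            return out

        return combined

    raise ParameterError(f"unknown contraction kind {spec.kind!r}")


def generate_angle_trajectories(
    spec: ContractionSpec, seed: int, fs: float = 256.0
) -> JointAngleSeries:
    """Sample the prescribed angles of one trial at *fs* (alpha3 stored raw)."""
    n = int(round(spec.duration * fs))
    t = np.arange(n) / fs
    centred = angle_waveform(spec, seed)(t)
    return JointAngleSeries(
        centred[:, 0], centred[:, 1], centred[:, 2] + 90.0, fs,
        sync=sync_square_wave(t),
    )


# ---------------------------------------------------------------------------
# marker synthesis (geometric inverse of the angle equations)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LimbGeometry:
    """Synthetic limb dimensions in millimetres."""

    forearm_length: float = 250.0
    elbow_width: float = 60.0
    wrist_width: float = 50.0
    hand_length: float = 80.0
    hand_width: float = 70.0

    def __post_init__(self) -> None:
        if min(
            self.forearm_length, self.elbow_width, self.wrist_width,
            self.hand_length, self.hand_width,
        ) <= 0:
            raise ParameterError("limb geometry requires positive lengths")


def generate_markers_from_angles(
    angles: JointAngleSeries,
    geometry: LimbGeometry | None = None,
    side: str = "right",
    seed: int = 0,
    noise_mm: float = 0.0,
    gap_rate: float = 0.0,
    max_gap_frames: int = 8,
) -> MarkerSession:
    """Place the seven markers so the angle chain recovers *angles* exactly.

    The right arm lives in a canonical frame: wrist origin at (0,0,0), elbow
    at (0,0,forearm_length), epicondylar axis along +x.  The styloid line is
    rotated in the x-y plane by alpha3 (so the w/l angle equals alpha3) and
    the metacarpal midpoint is placed along the frame direction
    ``(tan(alpha2), tan(alpha1), -1)``, which inverts the arctangent
    definitions of the two hinge angles.  The left arm is the mirror image
    (world x negated).  Optional Gaussian marker noise (mm) and random short
    gaps support robustness tests.
    """
    geometry = geometry or LimbGeometry()
    rng = np.random.default_rng(seed)
    n = angles.n_samples
    a1 = np.radians(angles.alpha1)
    a2 = np.radians(angles.alpha2)
    th3 = np.radians(angles.alpha3)  # raw angle between w and l

    x0 = np.array([1.0, 0.0, 0.0])
    y0 = np.array([0.0, 1.0, 0.0])
    z0 = np.array([0.0, 0.0, 1.0])

    origin = np.zeros((n, 3))
    elbow = np.tile(z0 * geometry.forearm_length, (n, 1))
    mep = elbow - x0 * (geometry.elbow_width / 2.0)
    lep = elbow + x0 * (geometry.elbow_width / 2.0)

    l_hat = np.outer(np.cos(th3), x0) + np.outer(np.sin(th3), y0)
    str_ = origin + l_hat * (geometry.wrist_width / 2.0)
    stu = origin - l_hat * (geometry.wrist_width / 2.0)

    # frame as build_wrist_frame sees it (right side sign)
    y_ax = np.outer(np.cos(th3), y0) - np.outer(np.sin(th3), x0)
    x_ax = np.cross(y_ax, np.tile(z0, (n, 1)))

    v = (
        x_ax * np.tan(a2)[:, None]
        + y_ax * np.tan(a1)[:, None]
        - np.tile(z0, (n, 1))
    )
    v = v / np.linalg.norm(v, axis=1, keepdims=True)
    hand = origin + v * geometry.hand_length
    rmc = hand + x_ax * (geometry.hand_width / 2.0)
    umc = hand - x_ax * (geometry.hand_width / 2.0)
    sho = elbow + np.array([20.0, -30.0, 150.0])

    markers = {
        "MEP": mep, "LEP": lep, "STU": stu, "STR": str_,
        "RMC": rmc, "UMC": umc, "SHO": sho,
    }
    if side == "left":
        markers = {k: v_ * np.array([-1.0, 1.0, 1.0]) for k, v_ in markers.items()}
    elif side != "right":
        raise ParameterError(f"invalid side {side!r}")

    if noise_mm > 0:
        markers = {
            k: v_ + rng.normal(0.0, noise_mm, v_.shape) for k, v_ in markers.items()
        }
    if gap_rate > 0:
        for name in markers:
            traj = markers[name].copy()
            n_gaps = rng.poisson(gap_rate * n / angles.fs)
            for _ in range(n_gaps):
                start = rng.integers(0, max(n - max_gap_frames, 1))
                length = rng.integers(1, max_gap_frames + 1)
                traj[start : start + length] = np.nan
            markers[name] = traj

    sync = angles.sync if angles.sync is not None else sync_square_wave(angles.t)
    return MarkerSession(markers, angles.fs, side, sync)


# ---------------------------------------------------------------------------
# EMG synthesis
# ---------------------------------------------------------------------------


def default_synergy_matrix(n_channels: int = 7) -> np.ndarray:
    """Smooth non-negative mixing of 6 directional drives into channel gains.

    Channels sit equi-spaced on a ring around the forearm; each movement
    direction preferentially drives a sector of the ring with Gaussian
    tuning, so neighbouring channels overlap and every direction excites at
    least one channel.
    """
    chan_angles = 2.0 * np.pi * np.arange(n_channels) / n_channels
    dir_angles = 2.0 * np.pi * np.arange(6) / 6.0
    diff = chan_angles[:, None] - dir_angles[None, :]
    ring_dist = np.angle(np.exp(1j * diff))
    w = np.exp(-(ring_dist**2) / (2.0 * 0.9**2))
    return w


@dataclass
class SynthConfig:
    """Knobs of the synthetic session generator.

    ``noise_floor`` is the resting envelope relative to a unit drive;
    ``channel_asymmetry`` scales the per-trial perturbation of the
    contralateral synergy matrix (0 = perfect mirroring).
    """

    n_channels: int = 7
    fs_emg: float = 2048.0
    fs_markers: float = 256.0
    synergy: np.ndarray | None = None
    noise_floor: float = 0.05
    channel_asymmetry: float = 0.0
    angle_scale: float = 60.0  # degrees mapping to unit drive
    emg_scale_uv: float = 100.0
    geometry: LimbGeometry = field(default_factory=LimbGeometry)
    trial_duration: float = 10.0
    rest_duration: float = 1.0

    def __post_init__(self) -> None:
        if self.synergy is None:
            self.synergy = default_synergy_matrix(self.n_channels)
        self.synergy = np.asarray(self.synergy, dtype=float)
        if self.synergy.shape != (self.n_channels, 6):
            raise ParameterError("synergy matrix must be [n_channels, 6]")
        if (self.synergy < 0).any():
            raise ParameterError("synergy weights must be non-negative")
        if not (self.synergy.max(axis=0) > 0).all():
            raise ParameterError("every direction must drive >= 1 channel")
        if self.noise_floor < 0 or self.channel_asymmetry < 0:
            raise ParameterError("noise_floor and asymmetry must be >= 0")

    @property
    def channel_names(self) -> list[str]:
        return [f"ch{i + 1}" for i in range(self.n_channels)]


def directional_drives(angles: JointAngleSeries, angle_scale: float) -> np.ndarray:
    """Six half-rectified normalized drives from the centred angles.

    Order: flexion, extension, radial, ulnar, pronation, supination.
    """
    a = angles.as_matrix(centered_alpha3=True) / angle_scale
    return np.column_stack(
        [
            np.maximum(a[:, 0], 0.0), np.maximum(-a[:, 0], 0.0),
            np.maximum(a[:, 1], 0.0), np.maximum(-a[:, 1], 0.0),
            np.maximum(a[:, 2], 0.0), np.maximum(-a[:, 2], 0.0),
        ]
    )


def _bandlimited_carrier(
    n: int, n_channels: int, fs: float, rng: np.random.Generator
) -> np.ndarray:
    """Unit-variance Gaussian carriers band-limited to 20-400 Hz."""
    from .signalio import FilterSpec, butter_filter

    white = rng.standard_normal((n, n_channels))
    band = butter_filter(white, fs, FilterSpec("bandpass", 4, (20.0, 400.0)))
    return band / band.std(axis=0, keepdims=True)


def perturbed_synergy(
    config: SynthConfig, rng: np.random.Generator
) -> np.ndarray:
    """W' = W * (1 + asymmetry * eps), clipped non-negative."""
    eps = rng.standard_normal(config.synergy.shape)
    return np.clip(
        config.synergy * (1.0 + config.channel_asymmetry * eps), 0.0, None
    )


def generate_emg_from_angles(
    angles: JointAngleSeries,
    config: SynthConfig,
    side: str = "right",
    seed: int = 0,
    synergy: np.ndarray | None = None,
) -> EmgRecording:
    """Surface EMG consistent with *angles* at the EMG sampling rate.

    The right side uses the reference synergy matrix; the left side (the
    mirrored, "amputated" arm) perturbs it by ``channel_asymmetry`` unless an
    explicit *synergy* override is given.  Deterministic given (config, side,
    seed).
    """
    rng = np.random.default_rng([seed, 0 if side == "right" else 1])
    if synergy is None:
        if side == "left" and config.channel_asymmetry > 0:
            synergy = perturbed_synergy(config, rng)
        else:
            synergy = config.synergy
    drives = directional_drives(angles, config.angle_scale)
    envelope = drives @ synergy.T + config.noise_floor
    n_out = int(round(angles.n_samples * config.fs_emg / angles.fs))
    t_out = np.arange(n_out) / config.fs_emg
    env_up = np.column_stack(
        [np.interp(t_out, angles.t, envelope[:, c])
         for c in range(config.n_channels)]
    )
    carrier = _bandlimited_carrier(n_out, config.n_channels, config.fs_emg, rng)
    samples = config.emg_scale_uv * env_up * carrier
    return EmgRecording(
        samples, config.fs_emg, config.channel_names, side,
        sync=sync_square_wave(t_out),
    )


# ---------------------------------------------------------------------------
# full bilateral sessions
# ---------------------------------------------------------------------------


@dataclass
class LabelledInterval:
    """Contraction id active on [t_start, t_end) of the session timeline."""

    contraction_id: int
    t_start: float
    t_end: float


@dataclass
class Session:
    """A bilateral mirrored recording session plus ground-truth labels."""

    emg_left: EmgRecording
    emg_right: EmgRecording
    markers_left: MarkerSession
    markers_right: MarkerSession
    angles: JointAngleSeries  # prescribed angles (identical on both sides)
    labels: list[LabelledInterval]
    seed: int

    def label_at(self, t: np.ndarray, offset: float = 0.0) -> np.ndarray:
        """Contraction id at times *t* (+*offset* on the raw session clock);
        0 during rest."""
        t = np.asarray(t, dtype=float) + offset
        out = np.zeros(t.shape, dtype=int)
        for iv in self.labels:
            out[(t >= iv.t_start) & (t < iv.t_end)] = iv.contraction_id
        return out


def generate_session(
    config: SynthConfig,
    contraction_ids: Sequence[int] = tuple(range(1, 11)),
    seed: int = 0,
) -> Session:
    """Generate a complete mirrored bilateral session.

    Trials run in protocol order, separated by ``config.rest_duration`` of
    rest; the prescribed angle trajectory is shared by both sides (mirrored
    movement), markers are synthesized per side, and EMG is synthesized per
    side and per trial so that contralateral synergy perturbations vary from
    trial to trial.
    """
    root = np.random.SeedSequence(seed)
    fs_m, fs_e = config.fs_markers, config.fs_emg
    rest_n_m = int(round(config.rest_duration * fs_m))

    angle_chunks: list[np.ndarray] = []
    emg_chunks = {"left": [], "right": []}
    labels: list[LabelledInterval] = []
    t_cursor = 0.0
    for k, cid in enumerate(contraction_ids):
        spec = default_contraction(cid, duration=config.trial_duration)
        trial_seed = int(root.spawn(1)[0].generate_state(1)[0] % 2**31)
        angles = generate_angle_trajectories(spec, trial_seed, fs_m)
        rest = JointAngleSeries(
            np.zeros(rest_n_m), np.zeros(rest_n_m),
            np.full(rest_n_m, 90.0), fs_m,
        )
        seg = JointAngleSeries(
            np.concatenate([angles.alpha1, rest.alpha1]),
            np.concatenate([angles.alpha2, rest.alpha2]),
            np.concatenate([angles.alpha3, rest.alpha3]),
            fs_m,
        )
        angle_chunks.append(seg.as_matrix(centered_alpha3=False))
        for side in ("left", "right"):
            emg_chunks[side].append(
                generate_emg_from_angles(seg, config, side, trial_seed)
            )
        labels.append(
            LabelledInterval(cid, t_cursor, t_cursor + spec.duration)
        )
        t_cursor += spec.duration + config.rest_duration

    full = np.concatenate(angle_chunks, axis=0)
    n_m = full.shape[0]
    t_m = np.arange(n_m) / fs_m
    session_angles = JointAngleSeries(
        full[:, 0], full[:, 1], full[:, 2], fs_m, sync=sync_square_wave(t_m)
    )

    marker_seeds = root.spawn(2)
    markers = {
        side: generate_markers_from_angles(
            session_angles, config.geometry, side,
            int(marker_seeds[i].generate_state(1)[0] % 2**31),
        )
        for i, side in enumerate(("left", "right"))
    }

    emg = {}
    for side in ("left", "right"):
        samples = np.concatenate(
            [rec.samples for rec in emg_chunks[side]], axis=0
        )
        t_e = np.arange(samples.shape[0]) / fs_e
        emg[side] = EmgRecording(
            samples, fs_e, config.channel_names, side,
            sync=sync_square_wave(t_e),
        )

    return Session(
        emg["left"], emg["right"], markers["left"], markers["right"],
        session_angles, labels, seed,
    )
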