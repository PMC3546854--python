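"""End-to-end pipeline: simulate/load -> preprocess -> features + angles ->
assemble -> cross-validated MLP estimation -> report files.

Outputs written to the configured directory:

``report.json``
    Scenario, laterality, per-fold and aggregate R^2 / R_i^2, winner-model
    metadata, the master seed and a hash of the full configuration.  The
    report is deterministic given the configuration (timings live in the
    log, not the report).
``predictions.csv``
    Long-format test-set estimates: t, dof, target, estimate, fold.
``pipeline.log``
    Stage-by-stage timings and seeds.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import PipelineError
from .estimation import (
    CrossValidationResult,
    Dataset,
    ScenarioSpec,
    assemble_dataset,
    run_cross_validation,
)
from .features import WindowSchedule, extract_tdar
from .kinematics import JointAngleSeries, compute_angle_series
from .signalio import (
    EMG_BANDPASS,
    FS_COMMON,
    EmgRecording,
    butter_filter,
    read_session,
    repair_marker_gaps,
    resample_uniform,
    trim_at_sync_edge,
)
from .synthetic import Session, SynthConfig, generate_session


@dataclass
class PipelineConfig:
    """Everything needed to reproduce one pipeline run."""

    scenario: str = "DoF123"
    laterality: str = "contra"
    seed: int = 0
    folds: int = 5
    restarts: int = 30
    simulate: bool = True
    synth: SynthConfig = field(default_factory=SynthConfig)
    contraction_ids: tuple[int, ...] = tuple(range(1, 11))
    input_left: str | None = None   # session file/dir per arm when not simulating
    input_right: str | None = None
    input_format: str = "hdf5"
    labels_file: str | None = None  # CSV: contraction_id,t_start,t_end
    kinematics_side: str = "right"
    window_len: float = 0.100
    increment: float = 0.040
    zero_phase: bool = True
    out_dir: str | None = None

    def config_hash(self) -> str:
        def _default(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            raise TypeError(type(o))

        fields = dataclasses.asdict(self)
        fields.pop("out_dir", None)  # where results land does not change them
        blob = json.dumps(fields, default=_default, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def preprocess_emg(
    emg: EmgRecording, zero_phase: bool = True, fs_out: float = FS_COMMON
) -> tuple[EmgRecording, float]:
    """Trim at the sync edge, band-pass 10-450 Hz, resample to *fs_out*.

    Returns the preprocessed recording and the trimmed edge time (seconds on
    the raw clock).
    """
    trimmed, t_edge = trim_at_sync_edge(emg)
    filt = butter_filter(trimmed.samples, emg.fs, EMG_BANDPASS, zero_phase)
    rs = resample_uniform(filt, emg.fs, fs_out)
    sync_rs = resample_uniform(trimmed.sync, emg.fs, fs_out)
    return (
        EmgRecording(rs, fs_out, list(emg.channel_names), emg.side, sync_rs),
        t_edge,
    )


def _load_session(config: PipelineConfig) -> tuple[Session, object]:
    import pandas as pd

    from .synthetic import LabelledInterval

    if config.simulate:
        return generate_session(
            config.synth, config.contraction_ids, config.seed
        ), None
    if not (config.input_left and config.input_right and config.labels_file):
        raise PipelineError(
            "load stage: input_left, input_right and labels_file are required "
            "when simulate is off"
        )
    try:
        emg_l, mk_l = read_session(config.input_left, config.input_format)
        emg_r, mk_r = read_session(config.input_right, config.input_format)
    except FileNotFoundError as exc:
        raise PipelineError(f"load stage: {exc}") from exc
    ldf = pd.read_csv(config.labels_file)
    labels = [
        LabelledInterval(int(r.contraction_id), float(r.t_start), float(r.t_end))
        for r in ldf.itertuples()
    ]
    session = Session(
        emg_l, emg_r, mk_l, mk_r, angles=None, labels=labels, seed=config.seed
    )
    return session, None


def build_dataset(config: PipelineConfig, session: Session, log) -> Dataset:
    """Stages preprocess/angles/features/assemble on an existing session."""
    schedule = WindowSchedule(config.window_len, config.increment, FS_COMMON)
    scenario = ScenarioSpec.from_name(config.scenario)

    markers = (
        session.markers_right
        if config.kinematics_side == "right"
        else session.markers_left
    )
    t0 = time.perf_counter()
    markers = repair_marker_gaps(markers)
    markers_trim, kin_edge = trim_at_sync_edge(markers)
    angles = compute_angle_series(markers_trim, FS_COMMON)
    log(f"angles: {angles.n_samples} samples @ {FS_COMMON:g} Hz, "
        f"edge {kin_edge:.4f}s [{time.perf_counter() - t0:.1f}s]")

    other = "left" if config.kinematics_side == "right" else "right"
    want_side = config.kinematics_side if config.laterality == "ipsi" else other
    emg = session.emg_left if want_side == "left" else session.emg_right
    t0 = time.perf_counter()
    emg_p, emg_edge = preprocess_emg(emg, config.zero_phase)
    n = min(emg_p.n_samples, angles.n_samples)
    emg_p = EmgRecording(
        emg_p.samples[:n], FS_COMMON, list(emg_p.channel_names), emg_p.side,
        emg_p.sync[:n] if emg_p.sync is not None else None,
    )
    feats = extract_tdar(emg_p, schedule)
    log(f"features[{want_side}]: {feats.n_windows} windows x "
        f"{feats.values.shape[1]} cols, edge {emg_edge:.4f}s "
        f"[{time.perf_counter() - t0:.1f}s]")

    window_labels = session.label_at(feats.window_centers, offset=emg_edge)
    kwargs = {"features_left": None, "features_right": None}
    kwargs[f"features_{want_side}"] = feats
    angles_cut = JointAngleSeries(
        angles.alpha1[:n], angles.alpha2[:n], angles.alpha3[:n], FS_COMMON
    )
    return assemble_dataset(
        angles=angles_cut,
        laterality=config.laterality,
        scenario=scenario,
        contraction_labels=window_labels,
        kinematics_side=config.kinematics_side,
        **kwargs,
    )


def run_pipeline(config: PipelineConfig) -> CrossValidationResult:
    """Execute every stage and (optionally) write the report files."""
    log_lines: list[str] = []

    def log(msg: str) -> None:
        log_lines.append(msg)

    t_start = time.perf_counter()
    log(f"config hash {config.config_hash()}, master seed {config.seed}")

    t0 = time.perf_counter()
    session, _ = _load_session(config)
    log(f"session: {'simulated' if config.simulate else 'loaded'} "
        f"[{time.perf_counter() - t0:.1f}s]")

    dataset = build_dataset(config, session, log)
    log(f"dataset: {dataset.n_rows} rows, scenario {dataset.scenario}, "
        f"laterality {dataset.laterality}")

    t0 = time.perf_counter()
    cv = run_cross_validation(
        dataset,
        n_folds=config.folds,
        restarts=config.restarts,
        master_seed=config.seed,
    )
    log(f"cross-validation: R2 {cv.mean_r2:.4f} +/- {cv.sd_r2:.4f} "
        f"[{time.perf_counter() - t0:.1f}s]")
    log(f"total [{time.perf_counter() - t_start:.1f}s]")

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        report = cv.to_report()
        report["config_hash"] = config.config_hash()
        report["master_seed"] = int(config.seed)
        (out / "report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True)
        )
        cv.predictions_frame().to_csv(out / "predictions.csv", index=False)
        (out / "pipeline.log").write_text("\n".join(log_lines) + "\n")
    return cv
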