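"""Per-DoF multilayer-perceptron regression with the mirror-training
protocol.

One small MLP (n_features -> 3 tanh units -> 1 linear output) is trained per
degree of freedom — the "dedicated MLP" architecture.  Datasets are
assembled contra-laterally (EMG from the arm opposite the measured
kinematics, the only option for unilateral amputees) or ipsi-laterally (same
arm, the control condition).  Evaluation follows a 5-fold cross-validation
over time-contiguous blocks: within each fold, training is restarted 30
times from different random initial weights, the restart with the highest
validation R_i^2 is kept as the fold's "winner", and test-block performance
is summarized by the multivariate R^2 (pooled across DoFs) and the per-DoF
R_i^2.

Blocks are contiguous in time *within each contraction*: adjacent analysis
windows overlap by 60 %, so random row-level splits would leak training
information into the test set.  Winner selection uses the validation block
only; the test block is untouched until final scoring.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from sklearn.neural_network import MLPRegressor

from .errors import DataError, ParameterError, PipelineError
from .features import FeatureMatrix
from .kinematics import JointAngleSeries

# ---------------------------------------------------------------------------
# performance indices
# ---------------------------------------------------------------------------


def global_r2(targets: np.ndarray, estimates: np.ndarray) -> float:
    """Multivariate R^2: share of total target variation captured by the
    estimates, pooled over DoFs.

    ``1 - sum_i sum_t (est_i(t) - tgt_i(t))^2 / sum_i sum_t (tgt_i(t) -
    mean_i)^2`` with ``mean_i`` the temporal mean of target *i*.  Equals 1
    iff the estimates reproduce the targets exactly, 0 for the per-DoF mean
    predictor, and can be negative for estimators worse than the mean.
    """
    tgt = np.atleast_2d(np.asarray(targets, dtype=float))
    est = np.atleast_2d(np.asarray(estimates, dtype=float))
    if tgt.ndim == 2 and tgt.shape[0] == 1:
        tgt, est = tgt.T, est.T
    if tgt.shape != est.shape:
        raise DataError("targets and estimates must have equal shape")
    if tgt.shape[0] < 2:
        raise DataError("need at least 2 samples")
    mean = tgt.mean(axis=0, keepdims=True)
    sst = float(np.sum((tgt - mean) ** 2))
    if sst == 0.0:
        raise DataError("total target variance is zero: R^2 undefined")
    sse = float(np.sum((est - tgt) ** 2))
    return 1.0 - sse / sst


def dof_r2(target: np.ndarray, estimate: np.ndarray) -> float:
    """Single-DoF R_i^2 (the D = 1 case of :func:`global_r2`)."""
    return global_r2(
        np.asarray(target, dtype=float).reshape(-1, 1),
        np.asarray(estimate, dtype=float).reshape(-1, 1),
    )


# ---------------------------------------------------------------------------
# scenarios / laterality
# ---------------------------------------------------------------------------

_SCENARIOS: dict[str, tuple[tuple[int, ...], tuple[int, ...]]] = {
    # name: (contraction ids used, DoFs estimated)
    "DoF12": ((1, 2, 4, 5), (1, 2)),
    "DoF13": ((1, 3, 6, 7), (1, 3)),
    "DoF23": ((2, 3, 8, 9), (2, 3)),
    "DoF123": (tuple(range(1, 11)), (1, 2, 3)),
}


@dataclass(frozen=True)
class ScenarioSpec:
    """Which contractions feed the analysis and which DoFs are estimated."""

    name: str
    contractions: tuple[int, ...]
    target_dofs: tuple[int, ...]

    @classmethod
    def from_name(cls, name: str) -> "ScenarioSpec":
        if name not in _SCENARIOS:
            raise ParameterError(
                f"unknown scenario {name!r}; choose from {sorted(_SCENARIOS)}"
            )
        contractions, dofs = _SCENARIOS[name]
        return cls(name, contractions, dofs)


Laterality = Literal["contra", "ipsi"]


# ---------------------------------------------------------------------------
# dataset assembly
# ---------------------------------------------------------------------------


@dataclass
class Dataset:
    """Assembled regression problem: one row per retained analysis window."""

    X: np.ndarray
    Y: np.ndarray
    t: np.ndarray
    labels: np.ndarray
    target_dofs: tuple[int, ...]
    feature_names: Sequence[str]
    scenario: str
    laterality: str

    @property
    def n_rows(self) -> int:
        return self.X.shape[0]


def _window_mean_angles(
    angles: JointAngleSeries,
    centers: np.ndarray,
    half_window: float,
) -> np.ndarray:
    """Mean centred angle over each window span (columns: DoF 1, 2, 3)."""
    mat = angles.as_matrix(centered_alpha3=True)
    csum = np.cumsum(np.vstack([np.zeros((1, 3)), mat]), axis=0)
    lo = np.searchsorted(angles.t, centers - half_window, side="left")
    hi = np.searchsorted(angles.t, centers + half_window, side="right")
    hi = np.clip(hi, lo + 1, angles.n_samples)
    return (csum[hi] - csum[lo]) / (hi - lo)[:, None]


def assemble_dataset(
    features_left: FeatureMatrix | None,
    features_right: FeatureMatrix | None,
    angles: JointAngleSeries,
    laterality: Laterality,
    scenario: ScenarioSpec,
    contraction_labels: np.ndarray,
    kinematics_side: str = "right",
    target_mode: Literal["window_mean", "midpoint"] = "window_mean",
) -> Dataset:
    """Pair EMG feature rows with per-window target angles.

    *contraction_labels* gives the contraction id of each feature window (0 =
    rest); only windows belonging to the scenario's contractions are kept.
    The per-window target is the mean angle over the window span (or the
    midpoint sample with ``target_mode="midpoint"``).  ``laterality`` selects
    the feature side relative to *kinematics_side*: ``ipsi`` = same side,
    ``contra`` = opposite side.
    """
    if laterality not in ("contra", "ipsi"):
        raise ParameterError(f"invalid laterality {laterality!r}")
    other = "left" if kinematics_side == "right" else "right"
    want_side = kinematics_side if laterality == "ipsi" else other
    feats = features_right if want_side == "right" else features_left
    if feats is None:
        raise ParameterError(f"features for the {want_side} side are required")

    labels = np.asarray(contraction_labels).astype(int).ravel()
    if labels.size != feats.n_windows:
        raise DataError("one contraction label per feature window required")
    centers = feats.window_centers
    if centers[-1] > angles.t[-1] + feats.schedule.increment:
        raise DataError(
            "feature and angle timelines mismatch by more than one increment"
        )

    if target_mode == "window_mean":
        targets = _window_mean_angles(
            angles, centers, feats.schedule.window_len / 2.0
        )
    else:
        idx = np.clip(
            np.round(centers * angles.fs).astype(int), 0, angles.n_samples - 1
        )
        targets = angles.as_matrix(centered_alpha3=True)[idx]

    keep = np.isin(labels, scenario.contractions) & np.isfinite(targets).all(axis=1)
    dof_idx = [d - 1 for d in scenario.target_dofs]
    return Dataset(
        feats.values[keep],
        targets[keep][:, dof_idx],
        centers[keep],
        labels[keep],
        scenario.target_dofs,
        list(feats.feature_names),
        scenario.name,
        laterality,
    )


def make_blocks(dataset: Dataset, n_folds: int = 5) -> list[np.ndarray]:
    """Time-contiguous cross-validation blocks, split within each contraction.

    Each contraction's window sequence is cut into *n_folds* contiguous
    chunks; block *k* is the union of chunk *k* of every contraction, so every
    block samples all contractions but never splits overlapping windows
    across a train/test boundary more than once per contraction.
    """
    blocks: list[list[np.ndarray]] = [[] for _ in range(n_folds)]
    for cid in np.unique(dataset.labels):
        idx = np.flatnonzero(dataset.labels == cid)
        if idx.size < n_folds:
            raise ParameterError(
                f"contraction {cid} has only {idx.size} windows; "
                f"cannot build {n_folds} blocks"
            )
        for k, chunk in enumerate(np.array_split(idx, n_folds)):
            blocks[k].append(chunk)
    return [np.concatenate(b) for b in blocks]


# ---------------------------------------------------------------------------
# MLP training
# ---------------------------------------------------------------------------

HIDDEN_UNITS = 3
MAX_EPOCHS = 500
PATIENCE = 20
_MIN_IMPROVEMENT = 1e-4


@dataclass
class MlpModel:
    """A trained dedicated MLP plus its input/target normalization.

    Features and the target are z-scored with training-partition statistics
    only; predictions are returned in degrees.
    """

    net: MLPRegressor
    x_mean: np.ndarray
    x_std: np.ndarray
    y_mean: float
    y_std: float
    seed: int
    best_epoch: int
    n_epochs: int
    hit_max_epochs: bool
    metadata: dict = field(default_factory=dict)

    def predict(self, X: np.ndarray) -> np.ndarray:
        Xn = (np.asarray(X, dtype=float) - self.x_mean) / self.x_std
        return self.net.predict(Xn) * self.y_std + self.y_mean

    def to_dict(self) -> dict:
        """JSON-serializable dump of weights, normalization and metadata."""
        return {
            "format_version": 1,
            "layer_sizes": [int(self.x_mean.size), HIDDEN_UNITS, 1],
            "activations": ["tanh", "identity"],
            "weights": [w.tolist() for w in self.net.coefs_],
            "biases": [b.tolist() for b in self.net.intercepts_],
            "x_mean": self.x_mean.tolist(),
            "x_std": self.x_std.tolist(),
            "y_mean": self.y_mean,
            "y_std": self.y_std,
            "seed": int(self.seed),
            "best_epoch": int(self.best_epoch),
            "n_epochs": int(self.n_epochs),
            "hit_max_epochs": bool(self.hit_max_epochs),
            "metadata": self.metadata,
        }


def train_mlp(
    X: np.ndarray,
    y: np.ndarray,
    seed: int,
    split: tuple[np.ndarray, np.ndarray],
    max_epochs: int = MAX_EPOCHS,
    patience: int = PATIENCE,
    hidden_units: int = HIDDEN_UNITS,
    learning_rate: float = 0.01,
) -> MlpModel:
    """Train one dedicated MLP with early stopping on a validation partition.

    *split* = (train_idx, val_idx) into the rows of X/y.  The network is
    [n_features -> hidden_units tanh -> 1 linear], optimized by Adam; after
    each epoch the validation R_i^2 is evaluated and the best-so-far weights
    are kept; training stops when no improvement above 1e-4 is seen for
    *patience* epochs.  Deterministic given *seed*.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    train_idx, val_idx = split
    if train_idx.size < 50:
        raise ParameterError("need >= 50 training rows")
    if not np.isfinite(y).all():
        raise DataError("targets must be finite")

    x_mean = X[train_idx].mean(axis=0)
    x_std = np.maximum(X[train_idx].std(axis=0), 1e-12)
    y_mean = float(y[train_idx].mean())
    y_std = float(max(y[train_idx].std(), 1e-12))
    Xtr = (X[train_idx] - x_mean) / x_std
    ytr = (y[train_idx] - y_mean) / y_std
    Xval = (X[val_idx] - x_mean) / x_std
    yval = (y[val_idx] - y_mean) / y_std

    net = MLPRegressor(
        hidden_layer_sizes=(hidden_units,),
        activation="tanh",
        solver="adam",
        learning_rate_init=learning_rate,
        batch_size=min(256, Xtr.shape[0]),
        random_state=int(seed) % (2**31),
        max_iter=1,
        shuffle=True,
        tol=0.0,
        n_iter_no_change=max_epochs + 1,
        warm_start=False,
    )

    best_val = -np.inf
    best_weights = None
    best_epoch = 0
    wait = 0
    epoch = 0
    yval_var = float(np.sum((yval - yval.mean()) ** 2))
    for epoch in range(1, max_epochs + 1):
        import warnings as _warnings

        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")  # sklearn warns on max_iter=1
            net.partial_fit(Xtr, ytr)
        pred = net.predict(Xval)
        if yval_var > 0:
            val_r2 = 1.0 - float(np.sum((pred - yval) ** 2)) / yval_var
        else:
            val_r2 = -float(np.sum((pred - yval) ** 2))
        if val_r2 > best_val + _MIN_IMPROVEMENT:
            best_val = val_r2
            best_weights = (
                [w.copy() for w in net.coefs_],
                [b.copy() for b in net.intercepts_],
            )
            best_epoch = epoch
            wait = 0
        else:
            wait += 1
            if wait >= patience:
                break

    if best_weights is not None:
        net.coefs_, net.intercepts_ = best_weights
    return MlpModel(
        net, x_mean, x_std, y_mean, y_std, int(seed), best_epoch, epoch,
        hit_max_epochs=(epoch == max_epochs),
        metadata={
            "hidden_units": hidden_units,
            "optimizer": "adam",
            "learning_rate_init": learning_rate,
            "max_epochs": max_epochs,
            "patience": patience,
            "normalization": "train-partition z-score (features and target)",
            "val_r2": best_val,
        },
    )


def select_winner(
    models: Sequence[MlpModel], X_val: np.ndarray, y_val: np.ndarray
) -> MlpModel:
    """The restart with the highest validation R_i^2; ties go to the model
    trained first (lowest seed in the restart order)."""
    if len(models) == 0:
        raise PipelineError("select_winner: no candidate models")
    scores = np.array(
        [dof_r2(y_val, m.predict(X_val)) for m in models], dtype=float
    )
    if not np.isfinite(scores).any():
        raise PipelineError("select_winner: all candidates non-finite")
    return models[int(np.nanargmax(scores))]


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------


@dataclass
class FoldResult:
    fold: int
    r2_global: float
    r2_per_dof: dict[int, float]
    winners: dict[int, MlpModel]
    predictions: pd.DataFrame  # columns t, dof, target, estimate


@dataclass
class CrossValidationResult:
    """Per-fold winners, per-fold R^2 indices and their aggregate."""

    folds: list[FoldResult]
    scenario: str
    laterality: str
    master_seed: int

    @property
    def r2_values(self) -> np.ndarray:
        return np.array([f.r2_global for f in self.folds])

    @property
    def mean_r2(self) -> float:
        return float(self.r2_values.mean())

    @property
    def sd_r2(self) -> float:
        return float(self.r2_values.std(ddof=1))

    def mean_dof_r2(self, dof: int) -> float:
        return float(np.mean([f.r2_per_dof[dof] for f in self.folds]))

    def predictions_frame(self) -> pd.DataFrame:
        frames = []
        for f in self.folds:
            df = f.predictions.copy()
            df["fold"] = f.fold
            frames.append(df)
        return pd.concat(frames, ignore_index=True)

    def to_report(self) -> dict:
        dofs = sorted(self.folds[0].r2_per_dof)
        return {
            "scenario": self.scenario,
            "laterality": self.laterality,
            "master_seed": int(self.master_seed),
            "n_folds": len(self.folds),
            "r2_global_mean": self.mean_r2,
            "r2_global_sd": self.sd_r2,
            "r2_global_per_fold": [round(v, 10) for v in self.r2_values],
            "r2_per_dof_mean": {
                str(d): round(self.mean_dof_r2(d), 10) for d in dofs
            },
            "r2_per_dof_per_fold": {
                str(d): [round(f.r2_per_dof[d], 10) for f in self.folds]
                for d in dofs
            },
            "winner_metadata": {
                str(f.fold): {
                    str(d): {
                        "seed": m.seed,
                        "best_epoch": m.best_epoch,
                        "hit_max_epochs": m.hit_max_epochs,
                    }
                    for d, m in f.winners.items()
                }
                for f in self.folds
            },
        }

    def save(self, report_path: str | Path, predictions_path: str | Path | None = None) -> None:
        Path(report_path).write_text(
            json.dumps(self.to_report(), indent=2, sort_keys=True)
        )
        if predictions_path is not None:
            self.predictions_frame().to_csv(predictions_path, index=False)


def _restart_seed(master_seed: int, fold: int, dof: int, restart: int) -> int:
    ss = np.random.SeedSequence(
        entropy=int(master_seed), spawn_key=(fold, dof, restart)
    )
    return int(ss.generate_state(1)[0] % (2**31))


def run_cross_validation(
    dataset: Dataset,
    n_folds: int = 5,
    restarts: int = 30,
    master_seed: int = 0,
    max_epochs: int = MAX_EPOCHS,
    patience: int = PATIENCE,
) -> CrossValidationResult:
    """The full evaluation protocol on an assembled dataset.

    Five time-contiguous blocks; per fold one block is the untouched test
    set, one of the remaining four (rotating with the fold index) is the
    validation set and the other three train the network.  Per DoF,
    *restarts* networks are trained from different seeded initializations and
    the best validation R_i^2 wins; the winners' test-block estimates yield
    the fold's global R^2 and per-DoF R_i^2.
    """
    blocks = make_blocks(dataset, n_folds)
    folds: list[FoldResult] = []
    for f in range(n_folds):
        test_idx = blocks[f]
        rest = [blocks[i] for i in range(n_folds) if i != f]
        val_idx = rest[f % (n_folds - 1)]
        train_idx = np.concatenate(
            [rest[i] for i in range(n_folds - 1) if i != f % (n_folds - 1)]
        )
        winners: dict[int, MlpModel] = {}
        est_cols = []
        for j, dof in enumerate(dataset.target_dofs):
            y = dataset.Y[:, j]
            models = [
                train_mlp(
                    dataset.X, y,
                    _restart_seed(master_seed, f, dof, r),
                    (train_idx, val_idx),
                    max_epochs=max_epochs, patience=patience,
                )
                for r in range(restarts)
            ]
            winner = select_winner(models, dataset.X[val_idx], y[val_idx])
            winners[dof] = winner
            est_cols.append(winner.predict(dataset.X[test_idx]))
        est = np.column_stack(est_cols)
        tgt = dataset.Y[test_idx]
        r2_per_dof = {
            dof: dof_r2(tgt[:, j], est[:, j])
            for j, dof in enumerate(dataset.target_dofs)
        }
        pred = pd.DataFrame(
            {
                "t": np.repeat(dataset.t[test_idx], len(dataset.target_dofs)),
                "dof": np.tile(dataset.target_dofs, test_idx.size),
                "target": tgt.ravel(),
                "estimate": est.ravel(),
            }
        )
        folds.append(
            FoldResult(f, global_r2(tgt, est), r2_per_dof, winners, pred)
        )
    return CrossValidationResult(
        folds, dataset.scenario, dataset.laterality, int(master_seed)
    )
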