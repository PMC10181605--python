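"""The fully convolutional shock-advisory classifier and its training.

The network maps a raw defi-lead ECG window (125 Hz, 1–30 Hz bandwidth)
to the probability pSh that the underlying rhythm is shockable. Three
convolutional blocks (Conv1D → ReLU → MaxPool(2) → Dropout 0.3) with
kernel sizes {10, 20, 20} and filter counts {5, 25, 50} feed a global
average pooling layer (one feature per filter, 50 features) and a dense
unit with sigmoid activation:

    pSh(x) = 1 / (1 + exp(-x)),   x = Σᵢ wᵢ·GAPᵢ + b.

Because global average pooling collapses the time axis, a single weight
set (27,681 parameters) serves any analysis duration D ∈ {5, 10, 15} s
(625, 1250 or 1875 input samples).

Training uses the class-weighted binary cross-entropy (weights summing
to 1, proportional to the opposite class prevalence), Adam (lr 0.001,
β₁ = 0.9, β₂ = 0.999), batch size 128, a patient-wise 70/30
train/validation split of the learning set, early stopping, and five
independent runs of which the one with minimum validation loss is kept.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import nn
from .sliding import SUPPORTED_DURATIONS, analysis_windows, decision_grid, extract_window
from .types import CprShockError, PeriodOfInterest, RhythmLabel

__all__ = [
    "ModelSpec",
    "TrainConfig",
    "OperatingPoint",
    "ShockClassifier",
    "WindowSet",
    "TrainResult",
    "build_model",
    "sigmoid_pSh",
    "weighted_bce",
    "class_weights",
    "expand_training_windows",
    "materialize_windows",
    "train",
    "select_operating_point",
    "predict_sliding",
]


@dataclass(frozen=True)
class ModelSpec:
    """Architecture hyperparameters of the shock-advisory CNN."""

    kernel_sizes: tuple[int, ...] = (10, 20, 20)
    filters: tuple[int, ...] = (5, 25, 50)
    pool_size: int = 2
    dropout: float = 0.3
    init_scale: float = 0.05

    @property
    def n_blocks(self) -> int:
        return len(self.kernel_sizes)

    def parameter_count(self) -> int:
        """Analytic trainable-parameter count (kernels + biases + dense)."""
        total, c = 0, 1
        for k, f in zip(self.kernel_sizes, self.filters):
            total += k * c * f + f
            c = f
        total += c + 1  # dense weights + bias
        return total

    @property
    def receptive_field(self) -> int:
        rf, jump = 1, 1
        for k in self.kernel_sizes:
            rf += (k - 1) * jump
            jump *= self.pool_size
            rf += (self.pool_size - 1) * (jump // self.pool_size)
        return rf


@dataclass(frozen=True)
class TrainConfig:
    """Training protocol settings (defaults are the full clinical-scale protocol)."""

    max_epochs: int = 750
    patience: int = 150
    batch_size: int = 128
    learning_rate: float = 0.001
    beta1: float = 0.9
    beta2: float = 0.999
    val_fraction: float = 0.3
    runs: int = 5
    seed: int = 0
    class_weights: Optional[tuple[float, float]] = None  # (w_Sh, w_NSh)

    def __post_init__(self):
        if not self.patience < self.max_epochs:
            raise CprShockError("early-stopping patience must be < max_epochs")
        if not 0 < self.val_fraction < 1:
            raise CprShockError("val_fraction must lie in (0, 1)")


@dataclass(frozen=True)
class OperatingPoint:
    """Validated decision threshold θ on pSh with its Se/Sp and Se+Sp."""

    threshold: float
    se: float
    sp: float

    @property
    def criterion(self) -> float:
        return self.se + self.sp


def sigmoid_pSh(x):
    """pSh(x) = 1 / (1 + e^(-x)); strictly increasing, range (0, 1)."""
    return nn.sigmoid(x)


def weighted_bce(p, targets, w_sh: float, w_nsh: float, eps: float = 1e-7) -> float:
    """Class-weighted binary cross-entropy on predicted probabilities.

    loss = -1/M Σ_m [δ_m·w_Sh·log P(x_m∈Sh) + (1-δ_m)·w_NSh·log(1-P(x_m∈Sh))]

    Probabilities are clipped to [eps, 1-eps] for numerical safety. With
    w_Sh = w_NSh = 0.5 this equals half the unweighted mean BCE.
    """
    p = np.asarray(p, dtype=float).ravel()
    d = np.asarray(targets, dtype=float).ravel()
    if p.shape != d.shape:
        raise CprShockError(f"length mismatch: {p.shape} probabilities vs {d.shape} targets")
    p = np.clip(p, eps, 1.0 - eps)
    return float(-np.mean(d * w_sh * np.log(p) + (1 - d) * w_nsh * np.log(1 - p)))


def class_weights(n_sh: int, n_nsh: int) -> tuple[float, float]:
    """Loss weights proportional to the opposite class prevalence.

    w_Sh = n_NSh / (n_Sh + n_NSh), w_NSh = n_Sh / (n_Sh + n_NSh); the
    rarer (shockable) class gets the larger weight and the weights sum
    to exactly 1.
    """
    if n_sh <= 0 or n_nsh <= 0:
        raise CprShockError("both class counts must be positive")
    total = n_sh + n_nsh
    return (n_nsh / total, n_sh / total)


class ShockClassifier:
    """The shock-advisory CNN with one weight set for all durations."""

    def __init__(self, duration: int, spec: ModelSpec | None = None, seed=0):
        if duration not in SUPPORTED_DURATIONS:
            raise CprShockError(
                f"analysis duration must be one of {SUPPORTED_DURATIONS}, got {duration}"
            )
        self.duration = int(duration)
        self.spec = spec or ModelSpec()
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        layers = []
        c = 1
        for k, f in zip(self.spec.kernel_sizes, self.spec.filters):
            layers += [
                nn.Conv1D(c, f, k, rng, init_scale=self.spec.init_scale),
                nn.ReLU(),
                nn.MaxPool1D(self.spec.pool_size),
                nn.Dropout(self.spec.dropout),
            ]
            c = f
        layers += [nn.GlobalAveragePooling1D()]
        self.backbone = nn.Sequential(layers)
        self.head = nn.Dense(c, 1, rng, init_scale=self.spec.init_scale)
        self.net = nn.Sequential(self.backbone.layers + [self.head])

    @property
    def n_params(self) -> int:
        return self.net.n_params

    @property
    def gap_features(self) -> int:
        return self.spec.filters[-1]

    #: ECG windows arrive in µV; the network operates on mV so that raw
    #: defi-lead amplitudes (±a few mV) match the weight-init scale.
    INPUT_SCALE = 1e-3

    def _check_input(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=np.float32)
        if X.ndim == 1:
            X = X[None, :]
        if X.ndim != 2:
            raise CprShockError("expected input of shape (n_windows, n_samples)")
        if X.shape[1] < self.spec.receptive_field:
            raise CprShockError(
                f"input length {X.shape[1]} shorter than the receptive field "
                f"({self.spec.receptive_field} samples)"
            )
        return X[:, :, None] * np.float32(self.INPUT_SCALE)  # (B, L, C=1)

    def forward_logits(self, X, train=False, rng=None) -> np.ndarray:
        return self.net.forward(self._check_input(X), train=train, rng=rng)

    def features(self, X) -> np.ndarray:
        """Global-average-pooled feature vector (one value per filter)."""
        return self.backbone.forward(self._check_input(X), train=False)

    def predict_proba(self, X, batch_size: int = 256) -> np.ndarray:
        """pSh for each window; accepts any input length ≥ the receptive field."""
        X = np.asarray(X, dtype=np.float32)
        if X.ndim == 1:
            X = X[None, :]
        out = np.empty(len(X))
        for i in range(0, len(X), batch_size):
            logits = self.forward_logits(X[i : i + batch_size], train=False)
            out[i : i + batch_size] = nn.sigmoid(logits).ravel()
        return out

    def get_weights(self):
        return self.net.get_weights()

    def set_weights(self, weights):
        self.net.set_weights(weights)


def build_model(duration: int, spec: ModelSpec | None = None, seed=0) -> ShockClassifier:
    """Construct the classifier for analysis duration D ∈ {5, 10, 15} s."""
    return ShockClassifier(duration, spec=spec, seed=seed)


def expand_training_windows(manifest: pd.DataFrame, duration: int) -> pd.DataFrame:
    """Expand a period-level manifest 26-fold into the sliding-window set.

    Each period of interest contributes one row per decision time on the
    grid [-15, ..., +10]; the window inherits the period's rhythm label
    and Sh/NSh category. Returns columns (poi_id, patient_id?, label,
    decision_time, shockable).
    """
    grid = decision_grid(duration)
    reps = len(grid)
    out = manifest.loc[manifest.index.repeat(reps)].reset_index(drop=True)
    out["decision_time"] = np.tile(grid, len(manifest))
    out["shockable"] = [RhythmLabel(l).shockable for l in out["label"]]
    return out


@dataclass
class WindowSet:
    """Materialised analysis windows ready for training or scoring."""

    X: np.ndarray  # (n, D*fs) float32, µV
    y: np.ndarray  # (n,) 1 = Sh, 0 = NSh
    groups: np.ndarray  # (n,) patient identifiers
    shot: np.ndarray  # (n,) sHOT seconds
    t: np.ndarray  # (n,) decision times
    poi_id: np.ndarray
    label: np.ndarray  # (n,) rhythm class names
    duration: int

    def __len__(self):
        return len(self.y)


def materialize_windows(pois: Sequence[PeriodOfInterest], duration: int,
                        patient_ids: Optional[Sequence[str]] = None) -> WindowSet:
    """Extract all 26 sliding windows (with sHOT) from each period."""
    if patient_ids is None:
        patient_ids = [p.source.split("-")[0] for p in pois]
    Xs, ys, gs, ss, ts, ids, labs = [], [], [], [], [], [], []
    for poi, pid in zip(pois, patient_ids):
        for w in analysis_windows(poi, duration):
            Xs.append(extract_window(poi, w.decision_time, duration))
            ys.append(1 if poi.label.shockable else 0)
            gs.append(pid)
            ss.append(w.shot)
            ts.append(w.decision_time)
            ids.append(poi.poi_id)
            labs.append(poi.label.value)
    return WindowSet(
        X=np.asarray(Xs, dtype=np.float32), y=np.asarray(ys),
        groups=np.asarray(gs), shot=np.asarray(ss), t=np.asarray(ts),
        poi_id=np.asarray(ids), label=np.asarray(labs), duration=duration,
    )


@dataclass
class TrainResult:
    """Outcome of the multi-run training protocol."""

    classifier: ShockClassifier
    best_run: int
    best_val_loss: float
    run_val_losses: list[float]
    run_seeds: list[int]
    histories: list[pd.DataFrame]  # per run: epoch, train_loss, val_loss
    val_scores: np.ndarray  # pSh of the selected run on the validation set
    val_labels: np.ndarray
    config: TrainConfig


def _patient_split(groups: np.ndarray, val_fraction: float, rng) -> np.ndarray:
    """Boolean validation mask, split patient-wise to prevent leakage."""
    patients = np.unique(groups)
    perm = rng.permutation(len(patients))
    n_val = max(1, int(round(val_fraction * len(patients))))
    val_patients = set(patients[perm[:n_val]].tolist())
    return np.isin(groups, list(val_patients))


def _val_loss(clf, Xva, yva, w_sh, w_nsh, batch_size):
    """Exact mean weighted BCE over the validation set, in chunks."""
    total, n = 0.0, len(yva)
    for i in range(0, n, batch_size):
        logits = clf.forward_logits(Xva[i : i + batch_size], train=False)
        loss, _ = nn.weighted_bce_from_logits(logits, yva[i : i + batch_size],
                                              w_sh, w_nsh)
        total += loss * len(logits)
    return total / n


def _run_one(windows: WindowSet, train_idx, val_idx, config: TrainConfig,
             w_sh, w_nsh, run_seed: int):
    rng = np.random.default_rng(run_seed)
    clf = ShockClassifier(windows.duration, seed=rng)
    opt = nn.Adam(clf.net.params, lr=config.learning_rate,
                  beta1=config.beta1, beta2=config.beta2)
    Xtr, ytr = windows.X[train_idx], windows.y[train_idx]
    Xva, yva = windows.X[val_idx], windows.y[val_idx]
    best_loss, best_weights, best_epoch = np.inf, clf.get_weights(), -1
    history = []
    for epoch in range(config.max_epochs):
        order = rng.permutation(len(ytr))
        tr_losses = []
        for i in range(0, len(order), config.batch_size):
            idx = order[i : i + config.batch_size]
            logits = clf.forward_logits(Xtr[idx], train=True, rng=rng)
            loss, dz = nn.weighted_bce_from_logits(logits, ytr[idx], w_sh, w_nsh)
            clf.net.backward(dz.astype(np.float32))
            opt.step(clf.net.grads)
            tr_losses.append(loss)
        val_loss = _val_loss(clf, Xva, yva, w_sh, w_nsh, config.batch_size)
        history.append({"epoch": epoch, "train_loss": float(np.mean(tr_losses)),
                        "val_loss": val_loss})
        if val_loss < best_loss - 1e-9:
            best_loss, best_weights, best_epoch = val_loss, clf.get_weights(), epoch
        elif epoch - best_epoch >= config.patience:
            break
    clf.set_weights(best_weights)  # restore best-validation-loss weights
    return clf, best_loss, pd.DataFrame(history)


def train(windows: WindowSet, config: TrainConfig | None = None) -> TrainResult:
    """Train with independent runs and keep the minimum-validation-loss run.

    The learning windows are partitioned patient-wise into train and
    validation subsets (default 70/30); class weights default to the
    prevalence-proportional pair computed from the period-level counts.
    Deterministic given ``config.seed``.
    """
    config = config or TrainConfig()
    if len(windows) == 0:
        raise CprShockError("empty training window set")
    split_rng = np.random.default_rng(config.seed)
    val_mask = _patient_split(windows.groups, config.val_fraction, split_rng)
    train_idx = np.flatnonzero(~val_mask)
    val_idx = np.flatnonzero(val_mask)
    if len(train_idx) == 0 or len(val_idx) == 0:
        raise CprShockError("patient-wise split produced an empty subset")
    if config.class_weights is not None:
        w_sh, w_nsh = config.class_weights
    else:
        n_periods_sh = len(set(windows.poi_id[windows.y == 1].tolist()))
        n_periods_nsh = len(set(windows.poi_id[windows.y == 0].tolist()))
        if n_periods_sh == 0 or n_periods_nsh == 0:
            w_sh = w_nsh = 0.5  # degenerate single-class set: plain BCE/2
        else:
            w_sh, w_nsh = class_weights(n_periods_sh, n_periods_nsh)

    run_seeds = [int(s.generate_state(1)[0] % (2**31))
                 for s in np.random.SeedSequence(config.seed).spawn(config.runs)]
    results = []
    for run_seed in run_seeds:
        results.append(_run_one(windows, train_idx, val_idx, config,
                                w_sh, w_nsh, run_seed))
    losses = [r[1] for r in results]
    best = int(np.argmin(losses))
    clf = results[best][0]
    val_scores = clf.predict_proba(windows.X[val_idx])
    return TrainResult(
        classifier=clf, best_run=best, best_val_loss=float(losses[best]),
        run_val_losses=[float(l) for l in losses], run_seeds=run_seeds,
        histories=[r[2] for r in results], val_scores=val_scores,
        val_labels=windows.y[val_idx], config=config,
    )


def select_operating_point(scores, labels) -> OperatingPoint:
    """Threshold on pSh maximising Se + Sp on the validation set.

    Candidates are the observed scores plus {0, 1}; the decision rule is
    Sh iff pSh ≥ θ. Ties in Se + Sp are broken toward higher sensitivity,
    i.e. the smallest maximising threshold.
    """
    scores = np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(labels).ravel().astype(int)
    if scores.shape != labels.shape:
        raise CprShockError("scores and labels must have equal length")
    n_sh = int(labels.sum())
    n_nsh = int(len(labels) - n_sh)
    if n_sh == 0 or n_nsh == 0:
        raise CprShockError("validation set must contain both classes")
    cands = np.unique(np.concatenate([scores, [0.0, 1.0]]))
    decisions = scores[None, :] >= cands[:, None]  # (n_cand, n)
    tp = (decisions & (labels == 1)).sum(axis=1)
    tn = (~decisions & (labels == 0)).sum(axis=1)
    se = tp / n_sh
    sp = tn / n_nsh
    crit = se + sp
    best = crit.max()
    i = int(np.flatnonzero(crit >= best - 1e-12)[0])  # smallest θ → highest Se
    return OperatingPoint(threshold=float(cands[i]), se=float(se[i]), sp=float(sp[i]))


def predict_sliding(classifier: ShockClassifier, poi: PeriodOfInterest,
                    duration: int, threshold: float) -> pd.DataFrame:
    """One shock advice per decision time of the sliding grid.

    Returns a 26-row frame with columns (poi_id, label, decision_time,
    shot, p_sh, decision); decision is "Sh" iff pSh ≥ θ.
    """
    if duration != classifier.duration:
        raise CprShockError(
            f"classifier was trained for D={classifier.duration} s, "
            f"asked to slide at D={duration} s"
        )
    wins = analysis_windows(poi, duration)
    X = np.asarray([extract_window(poi, w.decision_time, duration) for w in wins],
                   dtype=np.float32)
    p = classifier.predict_proba(X)
    return pd.DataFrame({
        "poi_id": poi.poi_id,
        "label": poi.label.value,
        "decision_time": [w.decision_time for w in wins],
        "shot": [w.shot for w in wins],
        "p_sh": p,
        "decision": np.where(p >= threshold, "Sh", "NSh"),
    })
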