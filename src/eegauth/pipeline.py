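"""Training and evaluation protocols for EEG identity authentication.

The authentication unit is a per-subject binary model: *self* trials are
genuine (positive), *familiar* and *stranger* trials are impostor
(negative).  Two protocols are first-class:

* within-subject stratified 5-fold cross-validation, and
* cohort rounds — repeated disjoint random splits of subjects into a
  training group (which fixes architecture, hyperparameters and the blank
  average) and a held-out test group whose subjects are each scored by a
  within-subject holdout.

Class imbalance (default 100 genuine vs 450 impostor trials) is handled by
balanced mini-batch sampling; plain and balanced accuracy are both
reported.  The decision rule is the softmax argmax (0.5 threshold).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict

import numpy as np
from sklearn.model_selection import StratifiedKFold, train_test_split

from . import _nn, model as model_mod
from .core import EpochSet, NAME_CLASSES


@dataclass(frozen=True)
class TrainConfig:
    """Optimization hyperparameters (defaults follow the study protocol)."""

    learning_rate: float = 0.0005
    epochs: int = 5
    batch_size: int = 50
    seed: int = 0
    optimizer: str = "adam"
    balanced_batches: bool = True
    min_iterations: int = 0       # cycle epochs until this many batches ran

    def __post_init__(self):
        if min(self.learning_rate, self.epochs, self.batch_size) <= 0:
            raise ValueError("learning rate, epochs and batch size must be > 0")


@dataclass(frozen=True)
class SplitPlan:
    """Evaluation protocol description."""

    mode: str = "within_subject_cv"      # or "cohort_rounds"
    folds: int = 5
    train_subjects: int = 50
    test_subjects: int = 20
    rounds: int = 10                     # reference protocol uses 100
    holdout_fraction: float = 0.2        # per test subject in cohort mode
    seed: int = 0

    def __post_init__(self):
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.mode not in ("within_subject_cv", "cohort_rounds"):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass
class EvalReport:
    """Per-fold/per-round accuracies with summary statistics."""

    accuracies: list[float]
    balanced_accuracies: list[float]
    loss_traces: list[list[float]]
    config_fingerprint: str
    mode: str = ""

    @property
    def mean(self) -> float:
        return float(np.mean(self.accuracies))

    @property
    def sd(self) -> float:
        return float(np.std(self.accuracies))

    @property
    def balanced_mean(self) -> float:
        return float(np.mean(self.balanced_accuracies))

    def to_dict(self) -> dict:
        return {"mode": self.mode, "accuracies": self.accuracies,
                "balanced_accuracies": self.balanced_accuracies,
                "mean": self.mean, "sd": self.sd,
                "balanced_mean": self.balanced_mean,
                "config_fingerprint": self.config_fingerprint}


def _fingerprint(*objs) -> str:
    blob = json.dumps([_jsonable(o) for o in objs], sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _jsonable(o):
    if hasattr(o, "__dataclass_fields__"):
        return {k: _jsonable(v) for k, v in asdict(o).items()}
    if isinstance(o, (list, tuple)):
        return [_jsonable(v) for v in o]
    if isinstance(o, dict):
        return {str(k): _jsonable(v) for k, v in o.items()}
    if isinstance(o, (np.integer, np.floating)):
        return o.item()
    return o


def make_labels(labels: np.ndarray) -> np.ndarray:
    """Binary authentication labels: self -> 1, familiar/stranger -> 0.

    Blank trials must be excluded upstream; unknown labels raise.
    """
    labels = np.asarray(labels, dtype=object)
    out = np.empty(labels.shape[0], dtype=int)
    for i, lab in enumerate(labels):
        if lab == "self":
            out[i] = 1
        elif lab in NAME_CLASSES:
            out[i] = 0
        else:
            raise ValueError(f"unknown trial label {lab!r}")
    return out


def _batches(y: np.ndarray, batch_size: int, balanced: bool,
             rng: np.random.Generator):
    """One epoch of mini-batch index arrays."""
    n = y.shape[0]
    n_batches = max(1, int(np.ceil(n / batch_size)))
    if not balanced or len(np.unique(y)) < 2:
        order = rng.permutation(n)
        return [order[i * batch_size:(i + 1) * batch_size]
                for i in range(n_batches)]
    pos, neg = np.flatnonzero(y == 1), np.flatnonzero(y == 0)
    half = max(1, batch_size // 2)
    out = []
    for _ in range(n_batches):
        out.append(np.concatenate([rng.choice(pos, half),
                                   rng.choice(neg, batch_size - half)]))
    return out


def _add_channel_axis(x: np.ndarray) -> np.ndarray:
    return np.ascontiguousarray(x[:, None], dtype=np.float32)


def train(network: _nn.Network, x: np.ndarray, y: np.ndarray,
          config: TrainConfig = TrainConfig()) -> tuple[_nn.Network, list[float]]:
    """Train a network in place; returns it with the per-batch loss trace.

    Deterministic given ``config.seed`` (weights, dropout, batch order).
    A NaN loss aborts with diagnostics rather than training on.
    """
    x = _add_channel_axis(np.asarray(x))
    y = np.asarray(y, dtype=int)
    network.initialize(config.seed)
    opt = _nn.make_optimizer(config.optimizer, network.parameters(),
                             config.learning_rate)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    trace: list[float] = []
    epoch = 0
    while epoch < config.epochs or len(trace) < config.min_iterations:
        for idx in _batches(y, config.batch_size, config.balanced_batches, rng):
            logits = network.forward(x[idx], train=True)
            loss, dlogits = _nn.cross_entropy(logits, y[idx])
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite loss {loss} at iteration {len(trace)} "
                    f"(lr={config.learning_rate}, batch={config.batch_size})")
            network.zero_grad()
            network.backward(dlogits)
            opt.step()
            trace.append(loss)
        epoch += 1
        if epoch >= config.epochs and len(trace) >= config.min_iterations:
            break
    return network, trace


def _predict(network: _nn.Network, x: np.ndarray,
             chunk: int = 64) -> np.ndarray:
    x = _add_channel_axis(np.asarray(x))
    out = [np.argmax(network.predict_proba(x[i:i + chunk]), axis=1)
           for i in range(0, x.shape[0], chunk)]
    return np.concatenate(out)


def _balanced_accuracy(y: np.ndarray, pred: np.ndarray) -> float:
    vals = [np.mean(pred[y == c] == c) for c in np.unique(y)]
    return float(np.mean(vals))


class MultiScaleCNNClassifier:
    """sklearn-style estimator wrapping a network spec + training config.

    Parameters
    ----------
    arch : str | NetworkSpec
        Shipped architecture family name (see
        :data:`eegauth.model.ARCHITECTURE_NAMES`) or an explicit spec.
    learning_rate, epochs, batch_size, seed, optimizer, balanced_batches,
    min_iterations
        See :class:`TrainConfig`.
    log_power : bool
        Apply ``log1p`` to the (non-negative) spectrogram power before the
        network; compresses the large dynamic range of ERP power.
    standardize : bool
        Per-feature z-scoring with statistics estimated on the training
        set only (applied identically at predict time).

    Fitted attributes: ``network_``, ``loss_trace_``, ``classes_``,
    ``n_parameters_``, ``feature_mean_``, ``feature_sd_``.
    """

    _PARAM_NAMES = ("arch", "learning_rate", "epochs", "batch_size", "seed",
                    "optimizer", "balanced_batches", "min_iterations",
                    "log_power", "standardize")

    def __init__(self, arch="2d-multi-scale-length", learning_rate=0.0005,
                 epochs=5, batch_size=50, seed=0, optimizer="adam",
                 balanced_batches=True, min_iterations=0, log_power=True,
                 standardize=True):
        self.arch = arch
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.batch_size = batch_size
        self.seed = seed
        self.optimizer = optimizer
        self.balanced_batches = balanced_batches
        self.min_iterations = min_iterations
        self.log_power = log_power
        self.standardize = standardize

    # -- sklearn plumbing -------------------------------------------------
    def get_params(self, deep: bool = True) -> dict:
        return {k: getattr(self, k) for k in self._PARAM_NAMES}

    def set_params(self, **params) -> "MultiScaleCNNClassifier":
        for k, v in params.items():
            if k not in self._PARAM_NAMES:
                raise ValueError(f"invalid parameter {k!r}")
            setattr(self, k, v)
        return self

    # -- core -------------------------------------------------------------
    def _spec(self) -> model_mod.NetworkSpec:
        if isinstance(self.arch, model_mod.NetworkSpec):
            return self.arch
        return model_mod.load_architecture(self.arch)

    def _config(self) -> TrainConfig:
        return TrainConfig(self.learning_rate, self.epochs, self.batch_size,
                           self.seed, self.optimizer, self.balanced_batches,
                           self.min_iterations)

    def _transform(self, X: np.ndarray, fit: bool = False) -> np.ndarray:
        X = np.asarray(X, dtype=np.float32)
        if self.log_power:
            X = np.log1p(np.clip(X, 0, None))
        if self.standardize:
            if fit:
                self.feature_mean_ = X.mean(axis=0)
                self.feature_sd_ = X.std(axis=0) + 1e-6
            X = (X - self.feature_mean_) / self.feature_sd_
        return X

    def fit(self, X: np.ndarray, y: np.ndarray) -> "MultiScaleCNNClassifier":
        X = self._transform(np.asarray(X), fit=True)
        y = np.asarray(y, dtype=int)
        spec = _as_spec(self._spec(), X)
        self.classes_ = np.unique(y)
        net = model_mod.build_network(spec)
        self.network_, self.loss_trace_ = train(net, X, y, self._config())
        self.n_parameters_ = self.network_.n_parameters()
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        return _predict(self.network_, self._transform(np.asarray(X)))

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        x = _add_channel_axis(self._transform(np.asarray(X)))
        out = [self.network_.predict_proba(x[i:i + 64])
               for i in range(0, x.shape[0], 64)]
        return np.concatenate(out)

    def score(self, X: np.ndarray, y: np.ndarray) -> float:
        return float(np.mean(self.predict(X) == np.asarray(y)))


def _fit_classifier(spec, x: np.ndarray, y: np.ndarray,
                    config: TrainConfig) -> MultiScaleCNNClassifier:
    clf = MultiScaleCNNClassifier(
        arch=_as_spec(spec, x), learning_rate=config.learning_rate,
        epochs=config.epochs, batch_size=config.batch_size, seed=config.seed,
        optimizer=config.optimizer, balanced_batches=config.balanced_batches,
        min_iterations=config.min_iterations)
    return clf.fit(x, y)


def evaluate_within_subject(spec, x: np.ndarray, y: np.ndarray,
                            plan: SplitPlan = SplitPlan(),
                            config: TrainConfig = TrainConfig()) -> EvalReport:
    """Stratified k-fold cross-validation on one subject's trials.

    Every trial is tested exactly once; accuracies are per fold.
    Feature standardization uses fold-training statistics only.
    """
    x, y = np.asarray(x), np.asarray(y, dtype=int)
    counts = np.bincount(y, minlength=2)
    if counts.min() < plan.folds:
        raise ValueError(f"need >= {plan.folds} trials per class for "
                         f"stratification, got {counts.tolist()}")
    skf = StratifiedKFold(n_splits=plan.folds, shuffle=True,
                          random_state=plan.seed)
    accs, baccs, traces = [], [], []
    for k, (tr, te) in enumerate(skf.split(x, y)):
        cfg = TrainConfig(**{**asdict(config),
                             "seed": config.seed + 1000 * k})
        clf = _fit_classifier(spec, x[tr], y[tr], cfg)
        pred = clf.predict(x[te])
        accs.append(float(np.mean(pred == y[te])))
        baccs.append(_balanced_accuracy(y[te], pred))
        traces.append(clf.loss_trace_)
    return EvalReport(accs, baccs, traces, _fingerprint(plan, config),
                      mode="within_subject_cv")


def _as_spec(spec, x: np.ndarray) -> model_mod.NetworkSpec:
    if isinstance(spec, str):
        spec = model_mod.load_architecture(spec)
    if x.shape[1:] != spec.resolved_input_shape()[1:]:
        spec = model_mod.NetworkSpec(
            **{**spec.__dict__, "input_shape": (1,) + x.shape[1:]})
    return spec


def evaluate_cohort(spec, subject_data: dict[int, tuple[np.ndarray, np.ndarray]],
                    plan: SplitPlan,
                    config: TrainConfig = TrainConfig()) -> EvalReport:
    """Repeated random disjoint subject splits, averaged over rounds.

    ``subject_data`` maps subject id -> (inputs, binary labels).  Per round,
    ``plan.train_subjects`` + ``plan.test_subjects`` subjects are drawn
    without overlap (asserted); the architecture and hyperparameters are
    fixed, and each test subject is scored by a stratified within-subject
    holdout of ``plan.holdout_fraction``.
    """
    ids = np.array(sorted(subject_data))
    need = plan.train_subjects + plan.test_subjects
    if ids.size < need:
        raise ValueError(f"cohort of {ids.size} subjects cannot supply "
                         f"{need} disjoint train+test subjects")
    rng = np.random.default_rng(plan.seed)
    accs, baccs, traces = [], [], []
    for r in range(plan.rounds):
        perm = rng.permutation(ids)
        train_ids = set(perm[:plan.train_subjects].tolist())
        test_ids = set(perm[plan.train_subjects:need].tolist())
        if train_ids & test_ids:
            raise RuntimeError("train/test subject overlap")
        round_accs, round_baccs = [], []
        for sid in sorted(test_ids):
            x, y = subject_data[sid]
            tr, te = train_test_split(
                np.arange(y.shape[0]), test_size=plan.holdout_fraction,
                stratify=y, random_state=plan.seed + 31 * r + sid)
            cfg = TrainConfig(**{**asdict(config),
                                 "seed": config.seed + 101 * r + sid})
            clf = _fit_classifier(spec, x[tr], y[tr], cfg)
            pred = clf.predict(x[te])
            round_accs.append(float(np.mean(pred == y[te])))
            round_baccs.append(_balanced_accuracy(y[te], pred))
            traces.append(clf.loss_trace_)
        accs.append(float(np.mean(round_accs)))
        baccs.append(float(np.mean(round_baccs)))
    return EvalReport(accs, baccs, traces, _fingerprint(plan, config),
                      mode="cohort_rounds")
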