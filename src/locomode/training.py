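"""Training harness: partitioning, weighted training, grid search.

Data partitioning follows an 80/20 outer split (training vs validation,
stratified by activity label) with a further 20% of the outer training set
held out as an untouched inner test set.  The validation split drives early
stopping on the validation loss; the inner test set is never seen during
training.

Training minimizes class-weighted categorical cross-entropy — balanced
inverse-frequency weights ``w_c = N / (K * n_c)`` penalize errors on the
under-represented transition classes more — with Adam (default) or RMSProp,
a baseline learning rate of 1e-4, up to 400 epochs, and early stopping when
the validation loss fails to improve by at least 0.001 for 10 epochs (best
weights restored).

The hyperparameter grid spans 3 activations x 2 learning rates x
2 optimizers x 2 hidden-unit profiles x 2 dropouts = 48 configurations,
searched with stratified k-fold cross-validation on fold accuracy.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
from sklearn.model_selection import StratifiedKFold, train_test_split

from . import nn
from .labels import CompositeLabel, LabelSchema, enumerate_level2a_classes
from .networks import NetworkSpec, TrainedModel, build_network
from .simulate import DEFAULT_PHASE_CONVENTION, PhaseConvention
from .spectrogram import SpectrogramParams, encode_batch
from .system import MultiLevelSystem
from .windowing import SequenceWindow, build_windows

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TrainConfig:
    """Optimization hyperparameters of one training run."""

    learning_rate: float = 1e-4
    optimizer: str = "adam"
    max_epochs: int = 400
    early_stop_patience: int = 10
    early_stop_min_delta: float = 0.001
    batch_size: int = 64
    grad_clip_norm: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.max_epochs < 1 or self.early_stop_patience < 1:
            raise ValueError("max_epochs and early_stop_patience must be >= 1")
        if self.optimizer not in ("adam", "rmsprop"):
            raise ValueError(f"optimizer must be 'adam' or 'rmsprop', got {self.optimizer!r}")


@dataclass(frozen=True)
class GridSpace:
    """The hyperparameter grid (48 points by default)."""

    activations: tuple[str, ...] = ("relu", "elu", "tanh")
    learning_rates: tuple[float, ...] = (0.001, 0.0001)
    optimizers: tuple[str, ...] = ("adam", "rmsprop")
    hidden_profiles: tuple[tuple[int, ...], ...] = (
        (32, 64, 60, 30, 15),
        (64, 128, 120, 60, 30),
    )
    dropouts: tuple[float, ...] = (0.25, 0.5)

    def __post_init__(self) -> None:
        for name in ("activations", "learning_rates", "optimizers",
                     "hidden_profiles", "dropouts"):
            if not getattr(self, name):
                raise ValueError(f"grid axis {name} must be nonempty")

    def enumerate(self) -> list[dict]:
        """All grid points in fixed (activation-major) enumeration order."""
        return [
            {
                "activation": a,
                "learning_rate": lr,
                "optimizer": opt,
                "hidden_profile": hp,
                "dropout": dr,
            }
            for a, lr, opt, hp, dr in itertools.product(
                self.activations, self.learning_rates, self.optimizers,
                self.hidden_profiles, self.dropouts,
            )
        ]


@dataclass
class EncodedDataset:
    """Encoded windows plus all three label tracks, ready for training.

    ``x`` is (n, channels, 10, 50) float32; ``activity``/``level1`` are
    rendered label strings per window; ``phase`` holds the rendered phase
    label or None.
    """

    x: np.ndarray
    activity: np.ndarray
    level1: np.ndarray
    phase: np.ndarray

    def __post_init__(self) -> None:
        n = self.x.shape[0]
        if not (len(self.activity) == len(self.level1) == len(self.phase) == n):
            raise ValueError("label tracks must match the tensor length")

    @property
    def n(self) -> int:
        return self.x.shape[0]

    def subset(self, idx: np.ndarray) -> "EncodedDataset":
        return EncodedDataset(
            x=self.x[idx],
            activity=self.activity[idx],
            level1=self.level1[idx],
            phase=self.phase[idx],
        )

    def composite_truth(self) -> list[CompositeLabel]:
        out = []
        for act, ph in zip(self.activity, self.phase):
            label = f"{act.split('-')[0]} to {act.split('-')[1]}"
            if ph is not None:
                label += f"-{ph}"
            out.append(CompositeLabel.parse(label))
        return out

    @classmethod
    def from_windows(
        cls,
        windows: list[SequenceWindow],
        params: SpectrogramParams = SpectrogramParams(),
    ) -> "EncodedDataset":
        x = encode_batch(windows, params).astype(np.float32)
        return cls(
            x=x,
            activity=np.array([str(w.activity) for w in windows], dtype=object),
            level1=np.array([w.level1.code for w in windows], dtype=object),
            phase=np.array(
                [None if w.phase is None else str(w.phase) for w in windows],
                dtype=object,
            ),
        )

    @classmethod
    def from_streams(
        cls,
        streams,
        schema: LabelSchema,
        params: SpectrogramParams = SpectrogramParams(),
        phase_convention: PhaseConvention = DEFAULT_PHASE_CONVENTION,
        **window_kwargs,
    ) -> "EncodedDataset":
        """Window and encode a collection of labeled streams."""
        windows: list[SequenceWindow] = []
        for stream in streams:
            windows += build_windows(
                stream, schema, phase_convention=phase_convention, **window_kwargs
            )
        if not windows:
            raise ValueError("no windows could be extracted from the streams")
        return cls.from_windows(windows, params)


def partition(
    dataset: EncodedDataset, seed: int = 0
) -> tuple[EncodedDataset, EncodedDataset, EncodedDataset]:
    """Stratified (train, validation, inner_test) split: 64% / 20% / 16%.

    The outer split holds out 20% for validation; 20% of the remaining
    training data becomes the inner test set.  Stratification is by
    activity label; classes with fewer than 3 windows cannot be stratified
    and stay whole in the training split (with a warning).
    """
    if dataset.n == 0:
        raise ValueError("cannot partition an empty dataset")
    labels = dataset.activity
    classes, counts = np.unique(labels.astype(str), return_counts=True)
    rare = set(classes[counts < 3])
    if rare:
        warnings.warn(
            f"classes with < 3 windows kept whole in the training split: {sorted(rare)}",
            stacklevel=2,
        )
    idx = np.arange(dataset.n)
    rare_mask = np.isin(labels.astype(str), list(rare))
    common = idx[~rare_mask]
    y = labels[~rare_mask].astype(str)
    outer_train, validation = train_test_split(
        common, test_size=0.2, random_state=seed, stratify=y
    )
    y_inner = labels[outer_train].astype(str)
    # a class may have shrunk below 2 in the outer train; keep those whole
    cls2, cnt2 = np.unique(y_inner, return_counts=True)
    rare2 = set(cls2[cnt2 < 2])
    inner_mask = np.isin(y_inner, list(rare2))
    splittable = outer_train[~inner_mask]
    train_idx, inner_test = train_test_split(
        splittable,
        test_size=0.2,
        random_state=seed + 1,
        stratify=y_inner[~inner_mask],
    )
    train_idx = np.concatenate([train_idx, outer_train[inner_mask], idx[rare_mask]])
    return (
        dataset.subset(np.sort(train_idx)),
        dataset.subset(np.sort(validation)),
        dataset.subset(np.sort(inner_test)),
    )


def class_weights(label_counts: dict[str, int]) -> dict[str, float]:
    """Balanced inverse-frequency weights ``w_c = N / (K * n_c)``.

    Equal counts give all-1.0 weights; zero-count classes are excluded with
    a warning (they contribute no gradient anyway).
    """
    zero = [c for c, n in label_counts.items() if n == 0]
    if zero:
        warnings.warn(f"zero-count classes excluded from weighting: {zero}", stacklevel=2)
    counts = {c: n for c, n in label_counts.items() if n > 0}
    total = sum(counts.values())
    k = len(counts)
    return {c: total / (k * n) for c, n in counts.items()}


def _make_optimizer(config: TrainConfig, params) -> nn.Adam | nn.RMSProp:
    if config.optimizer == "adam":
        return nn.Adam(params, lr=config.learning_rate)
    return nn.RMSProp(params, lr=config.learning_rate)


def train_model(
    spec: NetworkSpec,
    config: TrainConfig,
    train: tuple[np.ndarray, np.ndarray],
    validation: tuple[np.ndarray, np.ndarray] | None,
    class_order: list[str],
    weight_per_class: dict[str, float] | None = None,
) -> tuple[TrainedModel, dict]:
    """Train one network; returns the model and its per-epoch history.

    ``train``/``validation`` are ``(x, y)`` with integer targets indexing
    ``class_order``.  The loss is class-weighted categorical cross-entropy;
    the same class weights apply to the monitored validation loss, so that
    early stopping tracks the objective being optimized — under heavy
    imbalance an unweighted validation loss saturates on the majority
    class and stops training before the rare classes are learned.
    Training stops early when the monitored loss has not improved by at
    least ``early_stop_min_delta`` for ``early_stop_patience`` epochs, and
    the best-loss weights are restored.  A NaN loss aborts with a
    diagnostic.
    """
    x_train, y_train = train
    if len(x_train) == 0:
        raise ValueError("empty training set")
    model = build_network(spec, seed=config.seed)
    rng = np.random.default_rng(config.seed + 1)
    optimizer = _make_optimizer(config, model.params)
    if weight_per_class is None:
        sample_w = None
    else:
        w_vec = np.array(
            [weight_per_class.get(class_order[j], 0.0) for j in range(len(class_order))]
        )
        sample_w = w_vec[y_train]

    history: dict = {"train_loss": [], "val_loss": [], "val_accuracy": []}
    best_loss = np.inf          # raw best: tracks the weights to restore
    patience_floor = np.inf     # min-delta improvements reset the counter
    best_weights = model.get_weights()
    best_epoch = -1
    since_improvement = 0
    n = len(x_train)
    for epoch in range(config.max_epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for lo in range(0, n, config.batch_size):
            sel = order[lo:lo + config.batch_size]
            model.zero_grad()
            logits = model.forward(x_train[sel], train=True)
            loss, dlogits = nn.softmax_cross_entropy(
                logits, y_train[sel], None if sample_w is None else sample_w[sel]
            )
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"training diverged (non-finite loss) at epoch {epoch}, "
                    f"batch {lo // config.batch_size}; lower the learning rate"
                )
            model.backward(dlogits)
            if config.grad_clip_norm > 0:
                nn.clip_gradients(model.params, config.grad_clip_norm)
            optimizer.step()
            epoch_loss += loss * len(sel)
        history["train_loss"].append(epoch_loss / n)

        if validation is not None and len(validation[0]) > 0:
            x_val, y_val = validation
            logits = _forward_in_batches(model, x_val, config.batch_size)
            val_w = None if sample_w is None else w_vec[y_val]
            val_loss, _ = nn.softmax_cross_entropy(logits, y_val, val_w)
            val_acc = float(np.mean(np.argmax(logits, axis=1) == y_val))
            monitored = val_loss
        else:
            monitored = history["train_loss"][-1]
            val_loss, val_acc = float("nan"), float("nan")
        history["val_loss"].append(val_loss)
        history["val_accuracy"].append(val_acc)

        if monitored < best_loss:
            best_loss = monitored
            best_weights = model.get_weights()
            best_epoch = epoch
        if epoch == 0 or monitored < patience_floor - config.early_stop_min_delta:
            patience_floor = monitored
            since_improvement = 0
        else:
            since_improvement += 1
            if since_improvement >= config.early_stop_patience:
                break
    model.set_weights(best_weights)
    history["best_epoch"] = best_epoch
    history["stopped_epoch"] = epoch
    return TrainedModel(spec=spec, model=model, class_order=list(class_order)), history


def _forward_in_batches(model: nn.Sequential, x: np.ndarray, batch_size: int) -> np.ndarray:
    outs = [
        model.forward(x[lo:lo + batch_size], train=False)
        for lo in range(0, len(x), batch_size)
    ]
    return np.concatenate(outs, axis=0)


def grid_search(
    variant: str,
    grid: GridSpace,
    x: np.ndarray,
    y: np.ndarray,
    class_order: list[str],
    k: int = 5,
    base_config: TrainConfig = TrainConfig(),
) -> tuple[dict, list[dict]]:
    """Exhaustive grid search with stratified k-fold cross-validation.

    Every grid point is trained and scored (accuracy) on each fold; the
    result list carries mean and standard deviation per point, and the best
    point is the accuracy argmax with deterministic first-in-enumeration
    tie-breaking.  Folds missing a class are skipped with a warning.
    """
    if len(np.unique(y)) < 2:
        raise ValueError("grid search needs at least two classes in the data")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=base_config.seed)
    results = []
    best: dict | None = None
    best_acc = -np.inf
    for point in grid.enumerate():
        spec = NetworkSpec.from_profile(
            variant,
            n_classes=len(class_order),
            profile=tuple(point["hidden_profile"]),
            n_channels=x.shape[1],
            activation=point["activation"],
            dropout=point["dropout"],
        )
        config = replace(
            base_config,
            learning_rate=point["learning_rate"],
            optimizer=point["optimizer"],
        )
        accs = []
        for fold, (tr, te) in enumerate(skf.split(x, y)):
            if len(np.unique(y[tr])) < len(np.unique(y)):
                warnings.warn(f"fold {fold} misses a class; skipped", stacklevel=2)
                continue
            model, _ = train_model(
                spec, config, (x[tr], y[tr]), None, class_order
            )
            logits = _forward_in_batches(model.model, x[te], config.batch_size)
            accs.append(float(np.mean(np.argmax(logits, axis=1) == y[te])))
        entry = {
            **point,
            "cv_accuracy_mean": float(np.mean(accs)) if accs else float("nan"),
            "cv_accuracy_sd": float(np.std(accs)) if accs else float("nan"),
            "n_folds": len(accs),
        }
        results.append(entry)
        if accs and entry["cv_accuracy_mean"] > best_acc:
            best_acc = entry["cv_accuracy_mean"]
            best = entry
    if best is None:
        raise RuntimeError("no grid point could be evaluated on any fold")
    return best, results


def _train_or_stub(
    spec: NetworkSpec,
    config: TrainConfig,
    x_tr: np.ndarray,
    y_tr: np.ndarray,
    val: tuple[np.ndarray, np.ndarray] | None,
    class_order: list[str],
    name: str,
) -> tuple[TrainedModel, dict]:
    if len(x_tr) == 0:
        warnings.warn(
            f"{name}: no training windows; building a majority-class stub",
            stacklevel=2,
        )
        model = build_network(spec, seed=config.seed)
        trained = TrainedModel(spec=spec, model=model, class_order=list(class_order))
        return trained, {"stub": True}
    if len(np.unique(y_tr)) == 1:
        # single observed class: bias the (untrained) softmax toward it
        only = int(y_tr[0])
        warnings.warn(
            f"{name}: only class {class_order[only]!r} observed; "
            "building a majority-class stub",
            stacklevel=2,
        )
        model = build_network(spec, seed=config.seed)
        model.layers[-1].b.value[:] = 0.0
        model.layers[-1].b.value[only] = 10.0
        trained = TrainedModel(spec=spec, model=model, class_order=list(class_order))
        return trained, {"stub": True, "majority_class": class_order[only]}
    weights = class_weights(
        {c: int(np.sum(y_tr == j)) for j, c in enumerate(class_order)}
    )
    return train_model(spec, config, (x_tr, y_tr), val, class_order, weights)


def train_system(
    train_ds: EncodedDataset,
    val_ds: EncodedDataset,
    schema: LabelSchema,
    variant: str = "cnn_lstm",
    config: TrainConfig = TrainConfig(),
    hidden_profile: tuple[int, ...] | None = None,
    activation: str = "relu",
    dropout: float = 0.25,
    config_level1: TrainConfig | None = None,
    config_level2b: TrainConfig | None = None,
) -> tuple[MultiLevelSystem, dict]:
    """Train the full hierarchy: 1 level-1 net + 7 level-2A (+ 5 level-2B).

    The level-2A net of mode *m* trains only on windows whose true level-1
    mode is *m* (likewise 2B, additionally requiring a phase label).  Each
    net is class-weighted against its own label distribution.  The level-1
    net and the gait-phase nets may use their own optimization settings
    (``config_level1`` / ``config_level2b``): the seven-mode
    pre-classifier converges quickly, while phase classification typically
    needs a longer epoch budget than the mode/transition networks.
    Returns the wired system and a per-network training-history dict.
    """
    cfg_1 = config_level1 if config_level1 is not None else config
    cfg_2b = config_level2b if config_level2b is not None else config
    n_ch = train_ds.x.shape[1]

    def make_spec(n_classes: int) -> NetworkSpec:
        if hidden_profile is not None:
            return NetworkSpec.from_profile(
                variant, n_classes, tuple(hidden_profile), n_channels=n_ch,
                activation=activation, dropout=dropout,
            )
        return NetworkSpec(
            variant=variant, n_classes=n_classes, n_channels=n_ch,
            activation=activation, dropout=dropout,
        )

    histories: dict[str, dict] = {}
    mode_codes = [m.code for m in schema.modes]
    code_to_idx = {c: j for j, c in enumerate(mode_codes)}

    y_tr = np.array([code_to_idx[c] for c in train_ds.level1])
    y_va = np.array([code_to_idx[c] for c in val_ds.level1])
    level1, histories["level1"] = _train_or_stub(
        make_spec(len(mode_codes)), cfg_1, train_ds.x, y_tr,
        (val_ds.x, y_va), mode_codes, "level1",
    )

    level2a: dict[str, TrainedModel] = {}
    level2b: dict[str, TrainedModel] = {}
    for mode in schema.modes:
        classes = [str(a) for a in enumerate_level2a_classes(schema, mode)]
        cls_idx = {c: j for j, c in enumerate(classes)}
        tr_sel = np.flatnonzero(train_ds.level1 == mode.code)
        va_sel = np.flatnonzero(val_ds.level1 == mode.code)
        y_tr2 = np.array([cls_idx[c] for c in train_ds.activity[tr_sel]], dtype=int)
        y_va2 = np.array([cls_idx[c] for c in val_ds.activity[va_sel]], dtype=int)
        name = f"level2a_{mode.code}"
        level2a[mode.code], histories[name] = _train_or_stub(
            make_spec(len(classes)), config, train_ds.x[tr_sel], y_tr2,
            (val_ds.x[va_sel], y_va2), classes, name,
        )

        if schema.has_phases and not mode.is_static:
            phases = [str(p) for p in schema.gait_phases(mode)]
            ph_idx = {p: j for j, p in enumerate(phases)}
            tr_ph = np.flatnonzero(
                (train_ds.level1 == mode.code) & (train_ds.phase != None)  # noqa: E711
            )
            va_ph = np.flatnonzero(
                (val_ds.level1 == mode.code) & (val_ds.phase != None)  # noqa: E711
            )
            y_tr3 = np.array([ph_idx[p] for p in train_ds.phase[tr_ph]], dtype=int)
            y_va3 = np.array([ph_idx[p] for p in val_ds.phase[va_ph]], dtype=int)
            name = f"level2b_{mode.code}"
            level2b[mode.code], histories[name] = _train_or_stub(
                make_spec(len(phases)), cfg_2b, train_ds.x[tr_ph], y_tr3,
                (val_ds.x[va_ph], y_va3), phases, name,
            )

    system = MultiLevelSystem(
        schema=schema, level1=level1, level2a=level2a, level2b=level2b
    )
    return system, histories
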