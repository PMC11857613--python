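"""Multi-label fingerprint-prediction models (dense, convolutional, recurrent).

The estimation surface follows the Model/Results convention: a
:class:`FingerprintModel` is constructed from a binned-spectrum matrix ``X``
and a binary fingerprint matrix ``Y`` (plus per-row compound groups so the
validation split is structure-aware), and ``fit()`` returns a
:class:`FingerprintModelResults` carrying the trained parameters, the
training log, validation diagnostics, and prediction/serialization methods.
Thin functional wrappers (:func:`build_model`, :func:`train`,
:func:`predict`) expose the same operations for pipeline code.

Training minimizes one minus a differentiable Tanimoto similarity between
the predicted probability vector and the true fingerprint (binary
cross-entropy is available as an alternative), so the objective matches the
similarity later used to rank annotation candidates.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .fingerprints import CondensedMap

__all__ = [
    "ModelSpec",
    "TrainConfig",
    "FingerprintModel",
    "FingerprintModelResults",
    "TrainedModel",
    "soft_tanimoto_loss",
    "soft_tanimoto_similarity",
    "build_model",
    "train",
    "predict",
    "binarize",
]

_ARCH_ALIASES = {
    "dense": "dense", "dnn": "dense", "mlp": "dense",
    "conv": "conv", "cnn": "conv",
    "recurrent": "recurrent", "rnn": "recurrent", "lstm": "recurrent",
}


def _default_layer_plan(architecture: str) -> dict:
    return {
        "dense": {"hidden": [512, 256]},
        "conv": {"blocks": [[64, 5], [32, 5]], "pool": 2, "dense": 128},
        "recurrent": {"steps": 20, "hidden": 128, "dense": 128},
    }[architecture]


@dataclass
class ModelSpec:
    """Architecture choice plus input/output widths and the init seed."""

    architecture: str
    input_length: int
    output_length: int
    layer_plan: dict | None = None
    seed: int = 0

    def __post_init__(self):
        arch = _ARCH_ALIASES.get(self.architecture.lower())
        if arch is None:
            raise ValueError(f"unknown architecture {self.architecture!r}")
        self.architecture = arch
        if self.input_length <= 0 or self.output_length <= 0:
            raise ValueError("input_length and output_length must be positive")
        if self.layer_plan is None:
            self.layer_plan = _default_layer_plan(arch)


@dataclass
class TrainConfig:
    """Training budget, objective, and augmentation scheme.

    The final objective is the soft-Tanimoto loss (``loss="tanimoto"``; BCE
    available).  At desk-scale training sizes the compound diversity is far
    below what the architectures need to generalize from raw spectra alone,
    so the default scheme bootstraps them with a sparse teacher: a per-bit
    L1-regularized logistic map (which recovers the sparse bin->bit support
    reliably even from few compounds) labels freshly resampled synthetic
    bin vectors each epoch, the network warms up on those under binary
    cross-entropy, and then fine-tunes under the Tanimoto objective.  Set
    ``augmentation="none"`` for plain mini-batch training.

    ``epochs``/``learning_rate``/``batch_size`` of None pick the
    per-architecture defaults (the recurrent model needs a longer, larger-
    step schedule than the dense/convolutional ones).
    """

    loss: str = "tanimoto"  # or "bce"
    augmentation: str = "sparse-teacher"  # or "none"
    augment_factor: int = 8
    teacher_c: float = 10.0
    epochs: int | None = None
    finetune_epochs: int = 25
    batch_size: int | None = None
    learning_rate: float | None = None
    finetune_lr: float = 1e-3
    patience: int = 15
    val_fraction: float = 0.2
    threshold: float = 0.5


# architecture-specific (epochs, learning_rate, batch_size) defaults
_TRAIN_PLAN = {
    "dense": (60, 3e-3, 32),
    "conv": (60, 3e-3, 32),
    "recurrent": (350, 1e-2, 64),
}


def soft_tanimoto_loss(y, p) -> float:
    """1 - soft Tanimoto similarity, averaged over samples.

    ``y`` is binary, ``p`` holds probabilities; 1-D inputs are treated as a
    single sample.  A sample with both vectors all-zero scores loss 0.
    """
    y = np.atleast_2d(np.asarray(y, dtype=float))
    p = np.atleast_2d(np.asarray(p, dtype=float))
    if y.shape != p.shape:
        raise ValueError(f"shape mismatch: {y.shape} vs {p.shape}")
    return nn.SoftTanimotoLoss().value(y, p)


def soft_tanimoto_similarity(y, p) -> float:
    return 1.0 - soft_tanimoto_loss(y, p)


def binarize(p: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Discretize probabilities: bit set iff p >= threshold."""
    return (np.asarray(p) >= threshold).astype(np.uint8)


def _build_network(spec: ModelSpec) -> nn.Network:
    plan = spec.layer_plan
    L, out = spec.input_length, spec.output_length
    layers: list[nn.Layer] = []
    if spec.architecture == "dense":
        prev = L
        for h in plan["hidden"]:
            layers += [nn.Dense(prev, h), nn.ReLU()]
            prev = h
        layers += [nn.Dense(prev, out), nn.Sigmoid()]
    elif spec.architecture == "conv":
        layers.append(nn.Reshape1C())
        length, channels = L, 1
        for filters, width in plan["blocks"]:
            layers += [nn.Conv1D(channels, filters, width), nn.ReLU(),
                       nn.MaxPool1D(plan["pool"])]
            length = (length - width + 1) // plan["pool"]
            channels = filters
            if length < 1:
                raise ValueError("input too short for the convolution plan")
        layers.append(nn.Flatten())
        layers += [nn.Dense(length * channels, plan["dense"]), nn.ReLU(),
                   nn.Dense(plan["dense"], out), nn.Sigmoid()]
    else:  # recurrent
        steps = plan["steps"]
        chunk = -(-L // steps)
        layers += [nn.Chunk(steps), nn.LSTM(chunk, plan["hidden"]),
                   nn.Dense(plan["hidden"], plan["dense"]), nn.ReLU(),
                   nn.Dense(plan["dense"], out), nn.Sigmoid()]
    return nn.Network(layers, seed=spec.seed)


def build_model(spec: ModelSpec) -> nn.Network:
    """Build an untrained network for a spec; same seed, same parameters."""
    return _build_network(spec)


def _group_holdout(groups: np.ndarray, fraction: float, seed: int):
    """Split row indices into (train, val) holding out whole groups."""
    uniq = np.unique(groups)
    rng = np.random.default_rng(seed + 17)
    uniq = rng.permutation(uniq)
    n_val = max(1, int(round(fraction * len(uniq))))
    val_groups = set(uniq[:n_val].tolist())
    mask = np.array([g in val_groups for g in groups])
    return np.flatnonzero(~mask), np.flatnonzero(mask)


class _SparseTeacher:
    """Per-bit L1-regularized logistic map used to bootstrap training.

    For each output bit an L1-penalized logistic regression is fitted on
    the training rows; the L1 penalty recovers the small set of bins that
    actually carry the bit's signal.  ``sample`` then draws synthetic bin
    vectors (independent Bernoulli occupancy at the empirical per-bin rate,
    scaled by the empirical mean nonzero value) and labels them with the
    teacher, giving the downstream network an effectively unlimited
    training stream consistent with the learned bin->bit support.
    """

    def __init__(self, C: float = 10.0):
        self.C = C

    def fit(self, X: np.ndarray, Y: np.ndarray) -> "_SparseTeacher":
        from sklearn.linear_model import LogisticRegression

        self._models: list = []
        for b in range(Y.shape[1]):
            col = Y[:, b]
            if col.min() == col.max():
                self._models.append(float(col[0]))
                continue
            clf = LogisticRegression(
                l1_ratio=1, C=self.C, solver="liblinear", max_iter=2000,
                random_state=0,
            )
            clf.fit(X, col)
            self._models.append(clf)
        occupied = X > 0
        self._p_col = np.clip(occupied.mean(axis=0), 0.02, 0.5)
        sums = X.sum(axis=0)
        counts = occupied.sum(axis=0)
        self._col_value = np.where(counts > 0, sums / np.maximum(counts, 1), 1.0)
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        P = np.empty((len(X), len(self._models)))
        for b, m in enumerate(self._models):
            P[:, b] = m if isinstance(m, float) else m.predict_proba(X)[:, 1]
        return P

    def sample(self, n: int, rng: np.random.Generator):
        Xa = (rng.random((n, len(self._p_col))) < self._p_col) * self._col_value
        Ya = (self.predict_proba(Xa) >= 0.5).astype(float)
        return Xa, Ya


class FingerprintModel:
    """Binned spectra -> condensed fingerprint bits, before fitting.

    Parameters
    ----------
    X : (n_spectra, input_length) array
        Binned intensity vectors restricted to the selected bins.
    Y : (n_spectra, output_length) binary array
        Condensed fingerprint targets.
    spec : ModelSpec
        Architecture, widths, seed.
    groups : array-like, optional
        Per-row compound identifiers (InChIKey first block); the validation
        split holds out whole compounds so replicate spectra never straddle
        the split.  Defaults to one group per row.
    """

    def __init__(self, X, Y, spec: ModelSpec, groups=None, *,
                 selected_bins=None, selected_fps=None,
                 condensed_map: CondensedMap | None = None,
                 mode: str = "positive"):
        self.X = np.asarray(X, dtype=float)
        self.Y = np.asarray(Y, dtype=float)
        if self.X.ndim != 2 or self.Y.ndim != 2 or self.X.shape[0] != self.Y.shape[0]:
            raise ValueError("X and Y must be row-aligned 2-D arrays")
        if self.X.shape[1] != spec.input_length or self.Y.shape[1] != spec.output_length:
            raise ValueError("spec widths do not match the data")
        if not self.Y.any():
            raise ValueError("Y is all zeros: nothing to learn")
        self.spec = spec
        self.groups = (np.arange(self.X.shape[0]) if groups is None
                       else np.asarray(groups))
        self.selected_bins = selected_bins
        self.selected_fps = selected_fps
        self.condensed_map = condensed_map
        self.mode = mode

    def fit(self, config: TrainConfig | None = None) -> "FingerprintModelResults":
        config = config or TrainConfig()
        plan_ep, plan_lr, plan_bs = _TRAIN_PLAN[self.spec.architecture]
        epochs = config.epochs if config.epochs is not None else plan_ep
        lr = config.learning_rate if config.learning_rate is not None else plan_lr
        batch = config.batch_size if config.batch_size is not None else plan_bs

        net = _build_network(self.spec)
        final_loss = nn.BCELoss() if config.loss == "bce" else nn.SoftTanimotoLoss()
        tr, va = _group_holdout(self.groups, config.val_fraction, self.spec.seed)
        input_scale = float(max(np.abs(self.X[tr]).max(), 1e-12))
        Xs = self.X / input_scale
        history: list[dict] = []

        if config.augmentation == "sparse-teacher":
            teacher = _SparseTeacher(config.teacher_c).fit(Xs[tr], self.Y[tr])
            rng = np.random.default_rng(self.spec.seed + 101)
            n_aug = config.augment_factor * len(tr)
            net.loss = nn.BCELoss()
            for epoch in range(epochs):
                Xa, Ya = teacher.sample(n_aug, rng)
                h = net.fit(
                    np.vstack([Xs[tr], Xa]), np.vstack([self.Y[tr], Ya]),
                    epochs=1, batch_size=batch, lr=lr, patience=None,
                )
                history.append({"phase": "warmup", "epoch": epoch, **h[0]})
            net.loss = final_loss
            best = (np.inf, None)
            for epoch in range(config.finetune_epochs):
                Xa, Ya = teacher.sample(n_aug, rng)
                h = net.fit(
                    np.vstack([Xs[tr], Xa]), np.vstack([self.Y[tr], Ya]),
                    epochs=1, batch_size=batch, lr=config.finetune_lr, patience=None,
                )
                val_loss = final_loss.value(self.Y[va], net.forward(Xs[va]))
                history.append(
                    {"phase": "finetune", "epoch": epoch, "val_loss": val_loss, **h[0]}
                )
                if val_loss < best[0]:
                    best = (val_loss, net.get_weights())
            if best[1] is not None:
                net.set_weights(best[1])
        elif config.augmentation == "none":
            net.loss = final_loss
            h = net.fit(
                Xs[tr], self.Y[tr],
                epochs=epochs, batch_size=batch, lr=lr,
                validation=(Xs[va], self.Y[va]), patience=config.patience,
            )
            history.extend({"phase": "train", **rec} for rec in h)
        else:
            raise ValueError(f"unknown augmentation {config.augmentation!r}")

        val_sim = soft_tanimoto_similarity(self.Y[va], net.forward(Xs[va]))
        return FingerprintModelResults(
            model=self, network=net, config=config, training_log=history,
            validation_similarity=float(val_sim),
            n_train=len(tr), n_val=len(va), input_scale=input_scale,
        )


@dataclass
class FingerprintModelResults:
    """A fitted fingerprint predictor plus its training diagnostics.

    Applicable only to vectors built with its own bin selection and scored
    against its own fingerprint selection / condensed map.
    """

    model: FingerprintModel
    network: nn.Network
    config: TrainConfig
    training_log: list = field(default_factory=list)
    validation_similarity: float = float("nan")
    n_train: int = 0
    n_val: int = 0
    input_scale: float = 1.0

    @property
    def spec(self) -> ModelSpec:
        return self.model.spec

    @property
    def selected_bins(self):
        return self.model.selected_bins

    @property
    def selected_fps(self):
        return self.model.selected_fps

    @property
    def condensed_map(self):
        return self.model.condensed_map

    @property
    def mode(self):
        return self.model.mode

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Predict fingerprint probabilities for one vector or a batch."""
        x = np.asarray(x, dtype=float)
        single = x.ndim == 1
        x = np.atleast_2d(x)
        if x.shape[1] != self.spec.input_length:
            raise ValueError(
                f"expected input length {self.spec.input_length}, got {x.shape[1]}"
            )
        p = self.network.forward(x / self.input_scale)
        return p[0] if single else p

    def predict_binary(self, x: np.ndarray, threshold: float | None = None):
        return binarize(self.predict(x), threshold or self.config.threshold)

    def summary(self) -> str:
        n_params = sum(p.size for w in self.network.layers for p in w.params.values())
        lines = [
            "Fingerprint prediction model",
            "=" * 46,
            f"architecture:        {self.spec.architecture}",
            f"input bins:          {self.spec.input_length}",
            f"output fingerprints: {self.spec.output_length}",
            f"mode:                {self.mode}",
            f"parameters:          {n_params}",
            f"loss:                {self.config.loss}",
            f"epochs run:          {len(self.training_log)}",
            f"train/val spectra:   {self.n_train}/{self.n_val}",
            f"final train loss:    {self.training_log[-1]['train_loss']:.4f}"
            if self.training_log else "final train loss:    n/a",
            f"val soft-Tanimoto:   {self.validation_similarity:.4f}",
        ]
        return "\n".join(lines)

    # -- serialization -------------------------------------------------------

    def save(self, directory) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        meta = {
            "spec": asdict(self.spec),
            "config": asdict(self.config),
            "mode": self.mode,
            "selected_bins": None if self.selected_bins is None
            else [int(i) for i in self.selected_bins],
            "selected_fps": None if self.selected_fps is None
            else [int(i) for i in self.selected_fps],
            "validation_similarity": self.validation_similarity,
            "n_train": self.n_train,
            "n_val": self.n_val,
            "input_scale": self.input_scale,
        }
        (d / "model.json").write_text(json.dumps(meta, indent=1))
        (d / "training_log.json").write_text(json.dumps(self.training_log))
        np.savez(d / "weights.npz", **self.network.get_weights())
        if self.condensed_map is not None:
            self.condensed_map.to_json(d / "condensed_map.json")

    @classmethod
    def load(cls, directory) -> "FingerprintModelResults":
        d = Path(directory)
        meta = json.loads((d / "model.json").read_text())
        spec = ModelSpec(**meta["spec"])
        config = TrainConfig(**meta["config"])
        net = _build_network(spec)
        with np.load(d / "weights.npz") as npz:
            net.set_weights({k: npz[k] for k in npz.files})
        cmap = None
        if (d / "condensed_map.json").exists():
            cmap = CondensedMap.from_json(d / "condensed_map.json")
        dummy = FingerprintModel.__new__(FingerprintModel)
        dummy.spec = spec
        dummy.selected_bins = meta["selected_bins"]
        dummy.selected_fps = meta["selected_fps"]
        dummy.condensed_map = cmap
        dummy.mode = meta["mode"]
        res = cls(
            model=dummy, network=net, config=config,
            training_log=json.loads((d / "training_log.json").read_text()),
            validation_similarity=meta["validation_similarity"],
            n_train=meta["n_train"], n_val=meta["n_val"],
            input_scale=meta.get("input_scale", 1.0),
        )
        return res


TrainedModel = FingerprintModelResults


def train(spec: ModelSpec, X, Y, config: TrainConfig | None = None,
          groups=None, **kwargs) -> FingerprintModelResults:
    """Functional wrapper: build a model from data and fit it."""
    return FingerprintModel(X, Y, spec, groups=groups, **kwargs).fit(config)


def predict(results: FingerprintModelResults, x: np.ndarray) -> np.ndarray:
    return results.predict(x)
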