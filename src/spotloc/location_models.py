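"""Supervised location predictor: shared MLP trunk, four task heads.

Tasks
-----
``coord2d``
    two sigmoid outputs; summed squared error against [0,1]-scaled coords.
``ellipse``
    axis-aligned elliptical prediction region (center + strictly positive
    semi-axes) trained with an asymmetric quantile-style loss at coverage
    ``alpha``.
``domain``
    unordered spatial domains; one-vs-rest binary cross-entropy on C scores.
``ordinal``
    ordered layers; one shared score per sample plus L-1 monotone cut
    points (rank-consistent cumulative-logit loss).

All loss functions below are plain-numpy reference implementations of the
exact training objectives (sum reduction, not mean).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._nn import Adam, Linear, Tensor, collect_params
from .augmentation import ReplicateSet
from .io_preprocess import ExpressionError, SpotExpression

__all__ = [
    "LocationModelConfig", "LocationModel", "CoordScaler",
    "coord_loss", "ellipse_loss", "domain_loss", "ordinal_loss",
    "ordinal_probabilities", "scale_coords", "unscale_coords",
    "train_location_model",
]

TASKS = ("coord2d", "ellipse", "domain", "ordinal")


# ---------------------------------------------------------------------------
# Losses (numpy reference forms; training mirrors these in autograd)
# ---------------------------------------------------------------------------

def _sigmoid(x):
    return 0.5 * (1.0 + np.tanh(0.5 * x))


def _log_sigmoid(x):
    return -np.logaddexp(0.0, -x)


def coord_loss(pred_coords: np.ndarray, true_coords: np.ndarray) -> float:
    """Sum over points of squared Euclidean distance in [0,1]^2."""
    pred_coords = np.asarray(pred_coords, dtype=float)
    true_coords = np.asarray(true_coords, dtype=float)
    if pred_coords.shape != true_coords.shape:
        raise ValueError("pred/true length mismatch")
    return float(((true_coords - pred_coords) ** 2).sum())


def ellipse_loss(pred: np.ndarray, true_coords: np.ndarray, alpha: float) -> float:
    """Asymmetric quantile-style region loss.

    ``pred`` columns are (c1, c2, r1, r2).  With
    q_i = ((y1-c1)/r1)^2 + ((y2-c2)/r2)^2 and s_i = I(q_i <= 1), each point
    contributes (alpha*(1-s_i) + (1-alpha)*s_i) * |q_i - 1|.
    """
    pred = np.asarray(pred, dtype=float)
    true_coords = np.asarray(true_coords, dtype=float)
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    c1, c2, r1, r2 = pred.T
    if (r1 <= 0).any() or (r2 <= 0).any():
        raise ValueError("ellipse axes must be strictly positive")
    q = ((true_coords[:, 0] - c1) / r1) ** 2 + ((true_coords[:, 1] - c2) / r2) ** 2
    s = (q <= 1.0).astype(float)
    return float(((alpha * (1 - s) + (1 - alpha) * s) * np.abs(q - 1.0)).sum())


def domain_loss(scores: np.ndarray, labels: np.ndarray, C: int) -> float:
    """One-vs-rest binary cross-entropy over C per-class scores; labels 1..C."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.ndim != 2 or scores.shape[1] != C:
        raise ValueError("scores must be (n, C)")
    if ((labels < 1) | (labels > C)).any():
        raise ValueError(f"labels must lie in 1..{C}")
    onehot = np.zeros_like(scores)
    onehot[np.arange(labels.size), labels - 1] = 1.0
    ll = onehot * _log_sigmoid(scores) + (1 - onehot) * _log_sigmoid(-scores)
    return float(-ll.sum())


def ordinal_loss(a: np.ndarray, b: np.ndarray, labels: np.ndarray, L: int) -> float:
    """Rank-consistent cumulative-logit loss.

    ``a`` are per-sample scores, ``b`` the L-1 cut points; sigma(a_i + b_l)
    models P(y_i > l).  Labels are 1..L.
    """
    a = np.asarray(a, dtype=float).reshape(-1)
    b = np.asarray(b, dtype=float).reshape(-1)
    labels = np.asarray(labels, dtype=int)
    if b.size != L - 1:
        raise ValueError("need L-1 cut points")
    if ((labels < 1) | (labels > L)).any():
        raise ValueError(f"labels must lie in 1..{L}")
    logits = a[:, None] + b[None, :]                       # (n, L-1)
    gt = labels[:, None] > np.arange(1, L)[None, :]        # I(y_i > l)
    ll = np.where(gt, _log_sigmoid(logits), _log_sigmoid(-logits))
    return float(-ll.sum())


def ordinal_probabilities(a: np.ndarray, b: np.ndarray, L: int,
                          strict: bool = True) -> np.ndarray:
    """Per-layer probabilities from cumulative logits; rows sum to 1.

    Requires non-increasing cut points (cumulative P(y>l) then telescopes
    into non-negative layer masses).
    """
    a = np.asarray(a, dtype=float).reshape(-1)
    b = np.asarray(b, dtype=float).reshape(-1)
    if b.size != L - 1:
        raise ValueError("need L-1 cut points")
    if strict and (np.diff(b) > 1e-12).any():
        raise ValueError("cut points must be non-increasing")
    cum = _sigmoid(a[:, None] + b[None, :])                # P(y > l), l=1..L-1
    probs = np.empty((a.size, L))
    probs[:, 0] = 1.0 - cum[:, 0]
    if L > 2:
        probs[:, 1:L - 1] = cum[:, :-1] - cum[:, 1:]
    probs[:, L - 1] = cum[:, -1]
    return probs


# ---------------------------------------------------------------------------
# Coordinate scaling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CoordScaler:
    mins: np.ndarray
    maxs: np.ndarray

    @classmethod
    def fit(cls, coords: np.ndarray) -> "CoordScaler":
        coords = np.asarray(coords, dtype=float)
        mins, maxs = coords.min(axis=0), coords.max(axis=0)
        if np.any(maxs - mins <= 0):
            raise ValueError("degenerate coordinate range (max == min)")
        return cls(mins, maxs)


def scale_coords(coords: np.ndarray, scaler: CoordScaler) -> np.ndarray:
    coords = np.asarray(coords, dtype=float)
    return (coords - scaler.mins) / (scaler.maxs - scaler.mins)


def unscale_coords(coords: np.ndarray, scaler: CoordScaler) -> np.ndarray:
    coords = np.asarray(coords, dtype=float)
    return coords * (scaler.maxs - scaler.mins) + scaler.mins


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------

@dataclass
class LocationModelConfig:
    task: str = "coord2d"
    hidden_sizes: tuple[int, ...] = (50, 10, 5)
    alpha: float = 0.95
    n_classes: int | None = None     # C for domain, L for ordinal
    epochs: int = 500
    lr: float = 1e-3
    batch_size: int | None = None    # None: full batch below 5000 rows, else 1024
    # ellipse only: epochs of center-MSE warm-up before the region loss; the
    # quantile-style region loss has a flat basin in which center gradients
    # vanish, so centers are pre-fit like the plain coordinate task and the
    # region phase runs at a reduced rate to preserve them
    pretrain_epochs: int = 300
    region_lr_scale: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.task not in TASKS:
            raise ValueError(f"task must be one of {TASKS}")
        if not self.hidden_sizes or any(h < 1 for h in self.hidden_sizes):
            raise ValueError("hidden_sizes must be non-empty positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.task in ("domain", "ordinal"):
            if self.n_classes is None or self.n_classes < 2:
                raise ValueError("domain/ordinal tasks need n_classes >= 2")


class LocationModel:
    """Trained predictor; holds trunk + head parameters and the data contract."""

    FORMAT_VERSION = 1

    def __init__(self, config: LocationModelConfig, feature_genes: list[str],
                 scaler: CoordScaler | None, label_order: list[str] | None):
        self.config = config
        self.feature_genes = list(feature_genes)
        self.scaler = scaler
        self.label_order = label_order
        rng = np.random.default_rng(config.seed)
        sizes = [len(feature_genes), *config.hidden_sizes]
        self.trunk = [Linear(a, b, rng) for a, b in zip(sizes[:-1], sizes[1:])]
        out_dim = {"coord2d": 2, "ellipse": 4,
                   "domain": config.n_classes or 0,
                   "ordinal": 1}[config.task]
        self.head = Linear(sizes[-1], out_dim, rng)
        if config.task == "ellipse":
            # start semi-axes near 0.5 so softplus is not saturated at init
            self.head.bias.data[2:] = np.log(np.expm1(0.5))
        if config.task == "ordinal":
            L = config.n_classes
            self.cut_b1 = Tensor(np.array([float(L) / 2.0]), requires_grad=True)
            self.cut_deltas = Tensor(np.zeros(L - 2), requires_grad=True)
        self.training_log: list[tuple[int, float]] = []

    def params(self):
        out = collect_params(*self.trunk, self.head)
        if self.config.task == "ordinal":
            out += [self.cut_b1, self.cut_deltas]
        return out

    # forward pieces -----------------------------------------------------------

    def _trunk_forward(self, x: Tensor) -> Tensor:
        h = x
        for layer in self.trunk:
            h = layer(h).relu()
        return self.head(h)

    def cut_points(self) -> Tensor:
        """Non-increasing cut points: b_1 minus cumulative softplus steps."""
        b1 = self.cut_b1
        L = self.config.n_classes
        if L == 2:
            return b1
        steps = self.cut_deltas.softplus() + 1e-6
        tri = np.tril(np.ones((L - 2, L - 2)))
        from ._nn import concat
        return concat([b1, b1 + (-(Tensor._wrap(tri) @ steps.reshape(L - 2, 1))
                                 .reshape(L - 2))], axis=0)

    def forward(self, x: Tensor):
        raw = self._trunk_forward(x)
        task = self.config.task
        if task == "coord2d":
            return raw.sigmoid()
        if task == "ellipse":
            from ._nn import concat
            c = raw[:, :2].sigmoid()
            r = raw[:, 2:].softplus() + 1e-6
            return concat([c, r], axis=1)
        if task == "domain":
            return raw                    # per-class scores
        return raw.reshape(raw.shape[0])  # ordinal: one score per sample


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def _labels_to_int(labels, label_order: list[str]) -> np.ndarray:
    index = {lab: i + 1 for i, lab in enumerate(label_order)}
    try:
        return np.array([index[str(x)] for x in labels])
    except KeyError as err:
        raise ExpressionError(f"label {err} not in declared order") from err


def _loss_tensor(model: LocationModel, out, y, alpha: float):
    task = model.config.task
    if task == "coord2d":
        return ((Tensor._wrap(y) - out) ** 2.0).sum()
    if task == "ellipse":
        c = out[:, :2]
        r = out[:, 2:]
        q = (((Tensor._wrap(y) - c) * (r ** -1.0)) ** 2.0).sum(axis=1)
        s = (q.data <= 1.0).astype(float)
        w = alpha * (1 - s) + (1 - alpha) * s
        return ((q - 1.0).abs() * w).sum()
    if task == "domain":
        onehot = np.zeros(out.shape)
        onehot[np.arange(y.size), y - 1] = 1.0
        ll = out.logsigmoid() * onehot + (-out).logsigmoid() * (1.0 - onehot)
        return -ll.sum()
    # ordinal
    L = model.config.n_classes
    b = model.cut_points()
    logits = out.reshape(out.shape[0], 1) + b.reshape(1, L - 1)
    gt = (y[:, None] > np.arange(1, L)[None, :]).astype(float)
    ll = logits.logsigmoid() * gt + (-logits).logsigmoid() * (1.0 - gt)
    return -ll.sum()


def train_location_model(reference: SpotExpression,
                         replicates: ReplicateSet | None = None,
                         config: LocationModelConfig | None = None) -> LocationModel:
    """Fit a predictor on the normalized reference (plus optional replicates).

    Replicate rows reuse the source spots' coordinates/labels.  Training is
    Adam on the task's summed loss; with mini-batches the loss is scaled by
    n/batch so gradient magnitudes stay comparable to full batch.
    """
    config = config or LocationModelConfig()
    if not reference.normalized:
        raise ExpressionError("reference must be normalized")

    X = reference.matrix
    label_order = None
    scaler = None
    if config.task in ("coord2d", "ellipse"):
        scaler = CoordScaler.fit(reference.spatial_coords)
        y = scale_coords(reference.spatial_coords, scaler)
    else:
        if reference.labels is None:
            raise ExpressionError(f"task {config.task!r} requires labels")
        label_order = sorted(set(map(str, reference.labels)))
        if config.n_classes != len(label_order):
            raise ExpressionError(
                f"n_classes={config.n_classes} but found {len(label_order)} labels")
        y = _labels_to_int(reference.labels, label_order)

    if replicates is not None:
        X = np.vstack([X] + [r for r in replicates.replicates])
        y = np.concatenate([y] * (1 + len(replicates.replicates)))

    model = LocationModel(config, reference.gene_ids, scaler, label_order)
    opt = Adam(model.params(), lr=config.lr)
    n = X.shape[0]
    batch = config.batch_size or (n if n < 5000 else 1024)
    rng = np.random.default_rng(config.seed + 1)

    if config.task == "ellipse" and config.pretrain_epochs > 0:
        for _ in range(config.pretrain_epochs):
            idx = np.arange(n) if batch >= n else rng.permutation(n)[:batch]
            out = model.forward(Tensor(X[idx]))
            # fit centers only, as in the plain coordinate task
            loss = ((Tensor._wrap(y[idx]) - out[:, :2]) ** 2.0).sum()
            opt.zero_grad()
            loss.backward()
            opt.step()
        # the warm-up can drift the (so far untrained) axis columns into
        # softplus saturation; restart them at r = 0.5 for every sample
        model.head.weight.data[:, 2:] = 0.0
        model.head.bias.data[2:] = np.log(np.expm1(0.5))
        opt = Adam(model.params(), lr=config.lr * config.region_lr_scale)

    for epoch in range(config.epochs):
        if batch >= n:
            out = model.forward(Tensor(X))
            loss = _loss_tensor(model, out, y, config.alpha)
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss = float(loss.data)
        else:
            perm = rng.permutation(n)
            epoch_loss = 0.0
            for lo in range(0, n, batch):
                idx = perm[lo:lo + batch]
                out = model.forward(Tensor(X[idx]))
                loss = _loss_tensor(model, out, y[idx], config.alpha) \
                    * (n / idx.size)
                opt.zero_grad()
                loss.backward()
                opt.step()
                epoch_loss += float(loss.data) * idx.size / n
        model.training_log.append((epoch, epoch_loss))
    return model


# ---------------------------------------------------------------------------
# Persistence
# ---------------------------------------------------------------------------

def _npz_path(path: str | Path) -> str:
    path = str(path)
    return path if path.endswith(".npz") else path + ".npz"


def save_location_model(model: LocationModel, path: str | Path) -> None:
    arrays = {f"param_{i}": p.data for i, p in enumerate(model.params())}
    np.savez(_npz_path(path), **arrays)
    meta = {
        "format_version": LocationModel.FORMAT_VERSION,
        "task": model.config.task,
        "hidden_sizes": list(model.config.hidden_sizes),
        "alpha": model.config.alpha,
        "n_classes": model.config.n_classes,
        "epochs": model.config.epochs, "lr": model.config.lr,
        "seed": model.config.seed,
        "feature_genes": model.feature_genes,
        "label_order": model.label_order,
        "scaler": None if model.scaler is None else
        {"mins": model.scaler.mins.tolist(), "maxs": model.scaler.maxs.tolist()},
    }
    Path(str(path) + ".json").write_text(json.dumps(meta, indent=2))


def load_location_model(path: str | Path) -> LocationModel:
    meta = json.loads(Path(str(path) + ".json").read_text())
    if meta["format_version"] != LocationModel.FORMAT_VERSION:
        raise ValueError("incompatible checkpoint version")
    config = LocationModelConfig(
        task=meta["task"], hidden_sizes=tuple(meta["hidden_sizes"]),
        alpha=meta["alpha"], n_classes=meta["n_classes"],
        epochs=meta["epochs"], lr=meta["lr"], seed=meta["seed"])
    scaler = None
    if meta["scaler"] is not None:
        scaler = CoordScaler(np.array(meta["scaler"]["mins"]),
                             np.array(meta["scaler"]["maxs"]))
    model = LocationModel(config, meta["feature_genes"], scaler,
                          meta["label_order"])
    with np.load(_npz_path(path)) as data:
        for i, p in enumerate(model.params()):
            p.data[...] = data[f"param_{i}"]
    return model
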