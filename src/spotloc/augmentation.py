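"""Replicate generation for grid-layout spatial references.

Pipeline: per-gene rasterization of the spot grid into 2D images,
K-means clustering of genes by spatial pattern, then a cluster-conditioned
variational autoencoder whose sampled decodings become artificial training
"sections" aligned with the original spot list.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.cluster import KMeans

from ._nn import Adam, Conv2d, ConvTranspose2d, Linear, Tensor, collect_params, concat
from .io_preprocess import ExpressionError, SpotExpression

__all__ = [
    "GeneImageStack", "GeneClusterAssignment", "AugmenterConfig",
    "AugmenterModel", "ReplicateSet", "rasterize_genes", "derasterize",
    "cluster_genes", "kl_divergence", "augmenter_loss", "train_augmenter",
    "generate_replicates",
]


@dataclass
class GeneImageStack:
    """Per-gene 2D maps; unoccupied grid cells hold exactly 0."""

    images: np.ndarray          # (p, n1, n2)
    mask: np.ndarray            # (n1, n2) bool occupancy
    rows: np.ndarray            # (n_spots,) grid row per spot, source order
    cols: np.ndarray            # (n_spots,) grid col per spot
    gene_ids: list[str]
    spot_ids: list[str]

    @property
    def n_genes(self) -> int:
        return self.images.shape[0]

    @property
    def grid(self) -> tuple[int, int]:
        return self.images.shape[1:]


@dataclass
class GeneClusterAssignment:
    cluster_of: np.ndarray      # (p,) ints in {0..K-1}
    K: int

    @property
    def one_hot(self) -> np.ndarray:
        out = np.zeros((self.cluster_of.size, self.K))
        out[np.arange(self.cluster_of.size), self.cluster_of] = 1.0
        return out


@dataclass
class AugmenterConfig:
    embedding_dim: int = 512
    beta: float = 1e-5
    channels: tuple[int, int, int] = (16, 8, 4)
    epochs: int = 500
    lr: float = 1e-3
    seed: int = 0


@dataclass
class ReplicateSet:
    replicates: list[np.ndarray]    # each (n_spots, p), source order
    source_fingerprint: str
    seed: int


def rasterize_genes(spots: SpotExpression) -> GeneImageStack:
    """Rearrange each gene's spot vector into a 2D image via array_coords."""
    if not spots.normalized:
        raise ExpressionError("rasterize expects normalized expression")
    if spots.array_coords is None:
        raise ExpressionError("array_coords required for rasterization")
    rows = spots.array_coords[:, 0]
    cols = spots.array_coords[:, 1]
    n1, n2 = int(rows.max()) + 1, int(cols.max()) + 1
    if len(set(zip(rows.tolist(), cols.tolist()))) != rows.size:
        raise ExpressionError("duplicate grid positions")
    images = np.zeros((spots.n_genes, n1, n2))
    images[:, rows, cols] = spots.matrix.T
    mask = np.zeros((n1, n2), dtype=bool)
    mask[rows, cols] = True
    return GeneImageStack(images, mask, rows.copy(), cols.copy(),
                          list(spots.gene_ids), list(spots.spot_ids))


def derasterize(stack: GeneImageStack, images: np.ndarray | None = None) -> np.ndarray:
    """Read occupied positions back into a (n_spots, p) matrix."""
    if images is None:
        images = stack.images
    return images[:, stack.rows, stack.cols].T


def cluster_genes(stack: GeneImageStack, K: int, seed: int = 0) -> GeneClusterAssignment:
    """K-means over flattened gene images restricted to occupied positions."""
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > stack.n_genes:
        raise ValueError(f"K={K} exceeds number of genes {stack.n_genes}")
    feats = stack.images[:, stack.mask]
    if K == 1:
        return GeneClusterAssignment(np.zeros(stack.n_genes, dtype=int), 1)
    km = KMeans(n_clusters=K, random_state=seed, n_init=10)
    return GeneClusterAssignment(km.fit_predict(feats).astype(int), K)


def kl_divergence(mu: np.ndarray, sigma: np.ndarray) -> float:
    """KL( N(mu, diag sigma^2) || N(0, I) ) in closed form."""
    mu = np.asarray(mu, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    if (sigma <= 0).any():
        raise ValueError("sigma must be strictly positive")
    s2 = sigma ** 2
    return float(0.5 * np.sum(s2 + mu ** 2 - 1.0 - np.log(s2)))


def augmenter_loss(X: np.ndarray, X_hat: np.ndarray, mu: np.ndarray,
                   sigma: np.ndarray, beta: float,
                   mask: np.ndarray | None = None) -> tuple[float, float, float]:
    """(total, recon, kl): SSE over occupied positions + beta * summed KL.

    ``mu``/``sigma`` may be one posterior (D,) or per-gene posteriors (p, D);
    the KL term is per gene, summed.
    """
    X = np.asarray(X, dtype=float)
    X_hat = np.asarray(X_hat, dtype=float)
    if X.shape != X_hat.shape:
        raise ValueError(f"shape mismatch {X.shape} vs {X_hat.shape}")
    diff2 = (X - X_hat) ** 2
    if mask is not None:
        diff2 = diff2 * mask
    recon = float(diff2.sum())
    mu = np.atleast_2d(mu)
    sigma = np.atleast_2d(sigma)
    kl = float(sum(kl_divergence(m, s) for m, s in zip(mu, sigma)))
    return recon + beta * kl, recon, kl


# ---------------------------------------------------------------------------
# The cluster-conditioned VAE
# ---------------------------------------------------------------------------

def _padded_grid(n1: int, n2: int) -> tuple[int, int]:
    # three stride-2 convs halve each dim thrice; pad up to a multiple of 8
    return (-(-n1 // 8)) * 8, (-(-n2 // 8)) * 8


class AugmenterModel:
    """Conv encoder -> diagonal Gaussian embedding -> one-hot-conditioned decoder."""

    FORMAT_VERSION = 1

    def __init__(self, grid: tuple[int, int], K: int, config: AugmenterConfig):
        self.config = config
        self.grid = tuple(grid)
        self.K = K
        self.pad_grid = _padded_grid(*grid)
        c1, c2, c3 = config.channels
        h3, w3 = self.pad_grid[0] // 8, self.pad_grid[1] // 8
        self._flat = c3 * h3 * w3
        self._dec_shape = (c3, h3, w3)
        rng = np.random.default_rng(config.seed)
        D = config.embedding_dim
        self.enc_conv = [Conv2d(1, c1, rng), Conv2d(c1, c2, rng), Conv2d(c2, c3, rng)]
        self.enc_fc = Linear(self._flat, 2 * D, rng)
        self.dec_fc = Linear(D + K, self._flat, rng)
        self.dec_conv = [ConvTranspose2d(c3, c2, rng), ConvTranspose2d(c2, c1, rng),
                         ConvTranspose2d(c1, 1, rng)]
        self.posterior_mu: np.ndarray | None = None      # (p, D)
        self.posterior_sigma: np.ndarray | None = None   # (p, D)
        self.training_log: list[tuple[int, float, float, float]] = []
        self.converged: bool | None = None

    # -- network pieces -------------------------------------------------------

    def params(self):
        return collect_params(*self.enc_conv, self.enc_fc, self.dec_fc,
                              *self.dec_conv)

    def encode(self, x: Tensor) -> tuple[Tensor, Tensor]:
        h = x
        for conv in self.enc_conv:
            h = conv(h).relu()
        h = h.reshape(h.shape[0], self._flat)
        out = self.enc_fc(h)
        D = self.config.embedding_dim
        mu = out[:, :D]
        sigma = out[:, D:].exp()        # log-sigma parameterization
        return mu, sigma

    def decode(self, z: Tensor, one_hot: np.ndarray) -> Tensor:
        h = self.dec_fc(concat([z, Tensor(one_hot)], axis=1)).relu()
        h = h.reshape(h.shape[0], *self._dec_shape)
        for i, deconv in enumerate(self.dec_conv):
            h = deconv(h)
            if i < len(self.dec_conv) - 1:
                h = h.relu()
        return h

    def _pad_images(self, images: np.ndarray) -> np.ndarray:
        n1, n2 = self.grid
        p1, p2 = self.pad_grid
        out = np.zeros((images.shape[0], 1, p1, p2))
        out[:, 0, :n1, :n2] = images
        return out

    # -- persistence ----------------------------------------------------------

    @staticmethod
    def _npz_path(path: str | Path) -> str:
        path = str(path)
        return path if path.endswith(".npz") else path + ".npz"

    def save(self, path: str | Path) -> None:
        arrays = {f"param_{i}": p.data for i, p in enumerate(self.params())}
        if self.posterior_mu is not None:
            arrays["posterior_mu"] = self.posterior_mu
            arrays["posterior_sigma"] = self.posterior_sigma
        np.savez(self._npz_path(path), **arrays)
        meta = {
            "format_version": self.FORMAT_VERSION,
            "grid": list(self.grid), "K": self.K,
            "embedding_dim": self.config.embedding_dim,
            "beta": self.config.beta, "channels": list(self.config.channels),
            "epochs": self.config.epochs, "lr": self.config.lr,
            "seed": self.config.seed, "converged": self.converged,
        }
        Path(str(path) + ".json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "AugmenterModel":
        meta = json.loads(Path(str(path) + ".json").read_text())
        if meta["format_version"] != cls.FORMAT_VERSION:
            raise ValueError("incompatible checkpoint version")
        config = AugmenterConfig(
            embedding_dim=meta["embedding_dim"], beta=meta["beta"],
            channels=tuple(meta["channels"]), epochs=meta["epochs"],
            lr=meta["lr"], seed=meta["seed"])
        model = cls(tuple(meta["grid"]), meta["K"], config)
        with np.load(cls._npz_path(path)) as data:
            for i, p in enumerate(model.params()):
                p.data[...] = data[f"param_{i}"]
            if "posterior_mu" in data:
                model.posterior_mu = data["posterior_mu"]
                model.posterior_sigma = data["posterior_sigma"]
        model.converged = meta["converged"]
        return model


def train_augmenter(stack: GeneImageStack, clusters: GeneClusterAssignment,
                    config: AugmenterConfig | None = None,
                    seed: int | None = None) -> AugmenterModel:
    """Fit the VAE on the gene-image stack, minimizing SSE-over-spots + beta*KL.

    The reconstruction error is summed over occupied grid positions only, so
    zero-padding and holes never contribute.  The per-gene posterior is
    stored for replicate sampling.  If the final loss does not improve on the
    initial loss the model is returned with ``converged=False`` and a warning.
    """
    if stack.n_genes != clusters.cluster_of.size:
        raise ValueError("stack and cluster assignment cover different gene sets")
    config = config or AugmenterConfig()
    if seed is not None:
        config = AugmenterConfig(**{**config.__dict__, "seed": seed})
    model = AugmenterModel(stack.grid, clusters.K, config)
    rng = np.random.default_rng(config.seed + 1)

    x_np = model._pad_images(stack.images)
    mask_pad = np.zeros((1, 1) + model.pad_grid)
    mask_pad[0, 0, :stack.grid[0], :stack.grid[1]] = stack.mask
    x = Tensor(x_np)
    one_hot = clusters.one_hot
    opt = Adam(model.params(), lr=config.lr)
    D = config.embedding_dim

    for epoch in range(config.epochs):
        mu, sigma = model.encode(x)
        eps = rng.normal(size=(stack.n_genes, D))
        z = mu + sigma * eps
        xhat = model.decode(z, one_hot)
        diff = (x - xhat) * Tensor(mask_pad)
        recon = (diff ** 2.0).sum()
        s2 = sigma ** 2.0
        kl = ((s2 + mu ** 2.0 - 1.0 - s2.log()) * 0.5).sum()
        total = recon + config.beta * kl
        opt.zero_grad()
        total.backward()
        opt.step()
        model.training_log.append(
            (epoch, float(total.data), float(recon.data), float(kl.data)))

    mu, sigma = model.encode(Tensor(x_np))
    model.posterior_mu = mu.data.copy()
    model.posterior_sigma = sigma.data.copy()
    model.converged = model.training_log[-1][1] < model.training_log[0][1]
    if not model.converged:
        warnings.warn("augmenter did not improve on its initial loss",
                      stacklevel=2)
    return model


def generate_replicates(model: AugmenterModel, stack: GeneImageStack,
                        clusters: GeneClusterAssignment, R: int = 2,
                        seed: int = 0) -> ReplicateSet:
    """Sample R replicate expression matrices from the fitted posteriors."""
    if R < 1:
        raise ValueError("R must be >= 1")
    if model.posterior_mu is None:
        raise ValueError("model has not been trained")
    rng = np.random.default_rng(seed)
    one_hot = clusters.one_hot
    n1, n2 = stack.grid
    reps = []
    for _ in range(R):
        eps = rng.normal(size=model.posterior_mu.shape)
        z = model.posterior_mu + model.posterior_sigma * eps
        decoded = model.decode(Tensor(z), one_hot).data[:, 0, :n1, :n2]
        reps.append(derasterize(stack, decoded))
    fingerprint = f"{stack.n_genes}x{n1}x{n2}:{len(stack.spot_ids)}"
    return ReplicateSet(reps, fingerprint, seed)
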