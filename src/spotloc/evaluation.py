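"""Evaluation statistics: top-k ordered-layer accuracy, pairwise-distance
correlation, per-cell Euclidean error, recovered expression maps and SSIM.

All metrics are pure functions of their inputs.  For very large point sets
the pairwise correlation falls back to a seeded subsample (the subsample
size is reported alongside the value).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import uniform_filter
from scipy.spatial.distance import pdist
from scipy.stats import pearsonr

__all__ = [
    "EvaluationReport", "topk_layer_accuracy", "pairwise_distance_correlation",
    "euclidean_errors", "recovered_expression_map", "ssim",
]

PAIRWISE_SUBSAMPLE = 20_000


@dataclass
class EvaluationReport:
    n_eval: int
    top1: float | None = None
    top2: float | None = None
    pairwise_r: float | None = None
    euclid_median: float | None = None
    euclid_q1: float | None = None
    euclid_q3: float | None = None
    ssim_per_gene: dict = field(default_factory=dict)
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items() if v not in (None, {}, [])}


def topk_layer_accuracy(pred_labels, true_labels, layer_order: list[str],
                        k: int = 1) -> float:
    """k=1: exact match; k=2: match or adjacent in the declared layer order."""
    if k not in (1, 2):
        raise ValueError("k must be 1 or 2")
    index = {lab: i for i, lab in enumerate(layer_order)}
    try:
        p = np.array([index[str(x)] for x in pred_labels])
        t = np.array([index[str(x)] for x in true_labels])
    except KeyError as err:
        raise ValueError(f"label {err} not in layer_order") from err
    if p.size != t.size:
        raise ValueError("length mismatch")
    return float((np.abs(p - t) <= k - 1).mean())


def pairwise_distance_correlation(pred_coords: np.ndarray,
                                  true_coords: np.ndarray,
                                  seed: int = 0) -> float:
    """Pearson r between predicted and true inter-point distances, all pairs."""
    pred_coords = np.asarray(pred_coords, dtype=float)
    true_coords = np.asarray(true_coords, dtype=float)
    if pred_coords.shape != true_coords.shape or pred_coords.ndim != 2:
        raise ValueError("coordinate arrays must share a (n, 2) shape")
    n = pred_coords.shape[0]
    if n < 3:
        raise ValueError("need at least 3 points")
    if n > PAIRWISE_SUBSAMPLE:
        idx = np.random.default_rng(seed).choice(n, PAIRWISE_SUBSAMPLE,
                                                 replace=False)
        pred_coords, true_coords = pred_coords[idx], true_coords[idx]
    dp = pdist(pred_coords)
    dt = pdist(true_coords)
    if dp.std() == 0 or dt.std() == 0:
        raise ValueError("zero variance in a distance vector; r undefined")
    return float(pearsonr(dp, dt).statistic)


def euclidean_errors(pred_coords: np.ndarray, true_coords: np.ndarray):
    """Per-cell l2 distances plus (median, q1, q3)."""
    pred_coords = np.asarray(pred_coords, dtype=float)
    true_coords = np.asarray(true_coords, dtype=float)
    if pred_coords.shape != true_coords.shape:
        raise ValueError("coordinate frames differ in shape")
    d = np.linalg.norm(pred_coords - true_coords, axis=1)
    q1, med, q3 = np.percentile(d, [25, 50, 75])
    return d, {"median": float(med), "q1": float(q1), "q3": float(q3)}


def recovered_expression_map(coords: np.ndarray, gene_values: np.ndarray,
                             grid_shape: tuple[int, int]) -> np.ndarray:
    """Bin cells (coords in [0,1]^2) into a grid of per-bin mean expression.

    Empty bins are NaN.
    """
    n1, n2 = grid_shape
    if n1 < 2 or n2 < 2:
        raise ValueError("grid_shape must be at least 2x2")
    coords = np.asarray(coords, dtype=float)
    gene_values = np.asarray(gene_values, dtype=float)
    r = np.clip((coords[:, 0] * n1).astype(int), 0, n1 - 1)
    c = np.clip((coords[:, 1] * n2).astype(int), 0, n2 - 1)
    total = np.zeros((n1, n2))
    count = np.zeros((n1, n2))
    np.add.at(total, (r, c), gene_values)
    np.add.at(count, (r, c), 1.0)
    with np.errstate(invalid="ignore"):
        out = total / count
    out[count == 0] = np.nan
    return out


def ssim(image_a: np.ndarray, image_b: np.ndarray, *, win_size: int = 7,
         k1: float = 0.01, k2: float = 0.03,
         data_range: float | None = None) -> float:
    """Mean structural similarity with uniform windows.

    Missing (NaN) bins are excluded pairwise by filling them with the mean of
    the jointly observed values before filtering.  Constants follow the
    common defaults; ``data_range`` defaults to the joint observed range.
    """
    a = np.asarray(image_a, dtype=float).copy()
    b = np.asarray(image_b, dtype=float).copy()
    if a.shape != b.shape:
        raise ValueError("shape mismatch")
    bad = ~(np.isfinite(a) & np.isfinite(b))
    if bad.all():
        raise ValueError("no jointly observed bins")
    if bad.any():
        a[bad] = a[~bad].mean()
        b[bad] = b[~bad].mean()
    if data_range is None:
        lo = min(a.min(), b.min())
        hi = max(a.max(), b.max())
        data_range = hi - lo if hi > lo else 1.0
    npix = win_size ** 2
    cov_norm = npix / (npix - 1)
    ua = uniform_filter(a, win_size)
    ub = uniform_filter(b, win_size)
    uaa = uniform_filter(a * a, win_size)
    ubb = uniform_filter(b * b, win_size)
    uab = uniform_filter(a * b, win_size)
    va = cov_norm * (uaa - ua * ua)
    vb = cov_norm * (ubb - ub * ub)
    vab = cov_norm * (uab - ua * ub)
    c1 = (k1 * data_range) ** 2
    c2 = (k2 * data_range) ** 2
    s = ((2 * ua * ub + c1) * (2 * vab + c2)) / \
        ((ua ** 2 + ub ** 2 + c1) * (va + vb + c2))
    pad = (win_size - 1) // 2
    core = s[pad:s.shape[0] - pad, pad:s.shape[1] - pad]
    return float(core.mean())
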