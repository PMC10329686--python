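"""Apply a trained location model to query cells."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._nn import Tensor
from .io_preprocess import CellExpression, ExpressionError
from .location_models import LocationModel, ordinal_probabilities

__all__ = ["PredictionSet", "predict", "certainty_score", "assign_label"]


@dataclass
class PredictionSet:
    cell_ids: list[str]
    task: str
    coords: np.ndarray | None = None        # (n, 2), [0,1]^2, coord2d
    ellipses: np.ndarray | None = None      # (n, 4): c1, c2, r1, r2
    probs: np.ndarray | None = None         # (n, C) or (n, L)
    assigned: np.ndarray | None = None      # 1-based argmax labels
    assigned_names: np.ndarray | None = None
    max_prob: np.ndarray | None = None
    certainty: np.ndarray | None = None     # (n,), ellipse task
    all_zero_features: np.ndarray | None = None   # QC flag per cell

    def to_frame(self) -> pd.DataFrame:
        out = {"cell_id": self.cell_ids}
        if self.task == "coord2d":
            out["pred_y1"], out["pred_y2"] = self.coords[:, 0], self.coords[:, 1]
        elif self.task == "ellipse":
            for i, name in enumerate(("c1", "c2", "r1", "r2")):
                out[name] = self.ellipses[:, i]
            out["certainty"] = self.certainty
        else:
            for c in range(self.probs.shape[1]):
                out[f"prob_{c + 1}"] = self.probs[:, c]
            out["assigned"] = self.assigned
            if self.assigned_names is not None:
                out["assigned_label"] = self.assigned_names
            out["max_prob"] = self.max_prob
        out["all_zero_features"] = self.all_zero_features
        return pd.DataFrame(out)


def certainty_score(r1: float, r2: float,
                    tissue_bounds: tuple[float, float] = (1.0, 1.0)) -> float:
    """1 minus the predicted-ellipse area normalized by the tissue bounding
    box, clipped to [0, 1]; tight regions score near 1."""
    area = tissue_bounds[0] * tissue_bounds[1]
    if area <= 0:
        raise ValueError("zero-area bounding box")
    if r1 <= 0 or r2 <= 0:
        raise ValueError("ellipse axes must be positive")
    return float(1.0 - min(1.0, np.pi * r1 * r2 / area))


def assign_label(probs: np.ndarray) -> tuple[int, float]:
    """Argmax label (1-based, lowest index wins ties) and its probability."""
    probs = np.asarray(probs, dtype=float)
    if abs(probs.sum() - 1.0) > 1e-6 or (probs < -1e-12).any():
        raise ValueError("probs is not a normalized probability vector")
    idx = int(np.argmax(probs))
    return idx + 1, float(probs[idx])


def predict(model: LocationModel, query: CellExpression) -> PredictionSet:
    """Run the model on normalized query cells; pure and deterministic."""
    if not query.normalized:
        raise ExpressionError("query must be normalized")
    missing = [g for g in model.feature_genes if g not in query.gene_ids]
    if missing:
        raise ExpressionError(f"query lacks model features: {missing[:10]}")
    if query.gene_ids != model.feature_genes:
        idx = [query.gene_ids.index(g) for g in model.feature_genes]
        X = query.matrix[:, idx]
    else:
        X = query.matrix
    qc = (X == 0).all(axis=1)

    out = model.forward(Tensor(X)).data
    task = model.config.task
    ps = PredictionSet(list(query.cell_ids), task, all_zero_features=qc)
    if task == "coord2d":
        ps.coords = out
    elif task == "ellipse":
        ps.ellipses = out
        ps.certainty = np.array([certainty_score(r1, r2)
                                 for r1, r2 in out[:, 2:]])
    else:
        if task == "domain":
            # one-vs-rest scores -> per-class sigmoid, normalized to a simplex
            sig = 0.5 * (1.0 + np.tanh(0.5 * out))
            probs = sig / sig.sum(axis=1, keepdims=True)
        else:
            b = model.cut_points().data
            probs = ordinal_probabilities(out, b, model.config.n_classes)
        ps.probs = probs
        pairs = [assign_label(p) for p in probs]
        ps.assigned = np.array([a for a, _ in pairs])
        ps.max_prob = np.array([m for _, m in pairs])
        if model.label_order is not None:
            ps.assigned_names = np.array([model.label_order[a - 1]
                                          for a in ps.assigned])
    return ps
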