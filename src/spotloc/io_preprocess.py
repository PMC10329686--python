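"""Expression-matrix I/O, normalization, gene selection and harmonization.

The two container types, :class:`SpotExpression` (spatial reference) and
:class:`CellExpression` (dissociated query), are thin dataclasses around a
dense ``(n, p)`` float matrix plus identifiers, coordinates and optional
labels.  All preprocessing functions are pure: they return new containers and
never mutate their inputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "SpotExpression",
    "CellExpression",
    "load_expression",
    "save_expression",
    "normalize_expression",
    "select_genes",
    "merge_sections",
    "harmonize_genes",
    "filter_condition_invariant_genes",
]


class ExpressionError(ValueError):
    """Structured error for malformed expression inputs."""


@dataclass
class SpotExpression:
    """Spatial reference: spots x genes with per-spot coordinates."""

    matrix: np.ndarray
    gene_ids: list[str]
    spot_ids: list[str]
    spatial_coords: np.ndarray
    array_coords: np.ndarray | None = None
    section_id: list[str] | None = None
    labels: np.ndarray | None = None
    normalized: bool = False

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        self.spatial_coords = np.asarray(self.spatial_coords, dtype=np.float64)
        if self.array_coords is not None:
            self.array_coords = np.asarray(self.array_coords, dtype=np.int64)
        if self.section_id is None:
            self.section_id = ["S0"] * self.n_spots
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
        self.validate()

    @property
    def n_spots(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_genes(self) -> int:
        return self.matrix.shape[1]

    def validate(self) -> None:
        if self.matrix.ndim != 2:
            raise ExpressionError("matrix must be 2D (spots x genes)")
        if len(self.gene_ids) != self.n_genes:
            raise ExpressionError(
                f"gene list length {len(self.gene_ids)} != matrix columns {self.n_genes}"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ExpressionError("duplicate gene_ids")
        if len(self.spot_ids) != self.n_spots:
            raise ExpressionError("spot_ids length mismatch")
        if self.spatial_coords.shape != (self.n_spots, 2):
            raise ExpressionError("spatial_coords must be (n_spots, 2)")
        if self.array_coords is not None:
            if self.array_coords.shape != (self.n_spots, 2):
                raise ExpressionError("array_coords must be (n_spots, 2)")
            keys = list(zip(self.section_id, map(tuple, self.array_coords)))
            if len(set(keys)) != len(keys):
                raise ExpressionError("duplicate (section_id, array_coords) pairs")
        if self.normalized and not np.isfinite(self.matrix).all():
            raise ExpressionError("normalized matrix contains non-finite entries")


@dataclass
class CellExpression:
    """Dissociated query cells x genes; truth fields are for validation only."""

    matrix: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    true_coords: np.ndarray | None = None
    true_labels: np.ndarray | None = None
    normalized: bool = False

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if len(self.gene_ids) != self.matrix.shape[1]:
            raise ExpressionError(
                f"gene list length {len(self.gene_ids)} != matrix columns "
                f"{self.matrix.shape[1]}"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ExpressionError("duplicate gene_ids")
        if len(self.cell_ids) != self.matrix.shape[0]:
            raise ExpressionError("cell_ids length mismatch")
        if self.normalized and not np.isfinite(self.matrix).all():
            raise ExpressionError("normalized matrix contains non-finite entries")

    @property
    def n_cells(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_genes(self) -> int:
        return self.matrix.shape[1]


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_DEFAULT_COORD_FIELDS = {
    "array_row": "array_row",
    "array_col": "array_col",
    "y1": "y1",
    "y2": "y2",
}
_META_COLUMNS = ("spot_id", "cell_id", "section_id", "label",
                 "true_y1", "true_y2", "true_label", "normalized")


def load_expression(path: str | Path, fmt: str = "csv", *, kind: str = "spot",
                    coord_fields: dict | None = None, obsm_key: str = "spatial"):
    """Read an expression table; ``kind`` selects spot or cell semantics.

    Formats: ``csv`` (one table, meta columns + gene columns), ``mtx``
    (Matrix Market triplets with ``genes.tsv``/``barcodes.tsv``/``coords.tsv``
    sidecars next to it) and ``h5ad``.
    """
    path = Path(path)
    cf = dict(_DEFAULT_COORD_FIELDS, **(coord_fields or {}))
    if fmt == "csv":
        return _load_csv(path, kind, cf)
    if fmt == "mtx":
        return _load_mtx(path, kind, cf)
    if fmt == "h5ad":
        return _load_h5ad(path, kind, obsm_key)
    raise ExpressionError(f"unknown format {fmt!r}")


def _load_csv(path: Path, kind: str, cf: dict):
    df = pd.read_csv(path)
    gene_cols = [c for c in df.columns
                 if c not in _META_COLUMNS and c not in cf.values()]
    matrix = df[gene_cols].to_numpy(dtype=np.float64)
    normalized = bool(df["normalized"].iloc[0]) if "normalized" in df else False
    if kind == "cell":
        ids = (df["cell_id"].astype(str).tolist() if "cell_id" in df
               else [f"cell{i}" for i in range(len(df))])
        tc = None
        if "true_y1" in df and "true_y2" in df:
            tc = df[["true_y1", "true_y2"]].to_numpy(dtype=np.float64)
        tl = df["true_label"].to_numpy() if "true_label" in df else None
        return CellExpression(matrix, gene_cols, ids, true_coords=tc,
                              true_labels=tl, normalized=normalized)
    for key in ("y1", "y2"):
        if cf[key] not in df.columns:
            raise ExpressionError(f"missing coordinate column {cf[key]!r}")
    spatial = df[[cf["y1"], cf["y2"]]].to_numpy(dtype=np.float64)
    array = None
    if cf["array_row"] in df.columns and cf["array_col"] in df.columns:
        array = df[[cf["array_row"], cf["array_col"]]].to_numpy(dtype=np.int64)
    ids = (df["spot_id"].astype(str).tolist() if "spot_id" in df
           else [f"spot{i}" for i in range(len(df))])
    sect = df["section_id"].astype(str).tolist() if "section_id" in df else None
    labels = df["label"].to_numpy() if "label" in df else None
    return SpotExpression(matrix, gene_cols, ids, spatial, array_coords=array,
                          section_id=sect, labels=labels, normalized=normalized)


def _load_mtx(path: Path, kind: str, cf: dict):
    matrix = np.asarray(spio.mmread(path).todense(), dtype=np.float64)
    base = path.parent
    genes = pd.read_csv(base / "genes.tsv", sep="\t", header=None)[0].astype(str).tolist()
    barcodes = pd.read_csv(base / "barcodes.tsv", sep="\t", header=None)[0].astype(str).tolist()
    if matrix.shape == (len(genes), len(barcodes)) and len(genes) != len(barcodes):
        matrix = matrix.T  # genes x cells convention
    if matrix.shape[1] != len(genes):
        raise ExpressionError("gene count mismatch between matrix and gene list")
    if kind == "cell":
        return CellExpression(matrix, genes, barcodes)
    coords_path = base / "coords.tsv"
    if not coords_path.exists():
        raise ExpressionError(f"missing coordinate sidecar {coords_path.name!r}")
    coords = pd.read_csv(coords_path, sep="\t")
    for key in ("y1", "y2"):
        if cf[key] not in coords.columns:
            raise ExpressionError(f"missing coordinate column {cf[key]!r}")
    spatial = coords[[cf["y1"], cf["y2"]]].to_numpy(dtype=np.float64)
    array = None
    if cf["array_row"] in coords.columns and cf["array_col"] in coords.columns:
        array = coords[[cf["array_row"], cf["array_col"]]].to_numpy(dtype=np.int64)
    labels = coords["label"].to_numpy() if "label" in coords.columns else None
    return SpotExpression(matrix, genes, barcodes, spatial, array_coords=array,
                          labels=labels)


def _load_h5ad(path: Path, kind: str, obsm_key: str):
    import anndata

    adata = anndata.read_h5ad(path)
    matrix = adata.X
    if not isinstance(matrix, np.ndarray):
        matrix = np.asarray(matrix.todense())
    genes = adata.var_names.astype(str).tolist()
    ids = adata.obs_names.astype(str).tolist()
    if kind == "cell":
        return CellExpression(np.asarray(matrix, dtype=np.float64), genes, ids)
    if obsm_key not in adata.obsm:
        raise ExpressionError(f"missing coordinates in obsm[{obsm_key!r}]")
    spatial = np.asarray(adata.obsm[obsm_key], dtype=np.float64)
    array = None
    if {"array_row", "array_col"} <= set(adata.obs.columns):
        array = adata.obs[["array_row", "array_col"]].to_numpy(dtype=np.int64)
    labels = adata.obs["label"].to_numpy() if "label" in adata.obs.columns else None
    sect = (adata.obs["section_id"].astype(str).tolist()
            if "section_id" in adata.obs.columns else None)
    return SpotExpression(np.asarray(matrix, dtype=np.float64), genes, ids,
                          spatial, array_coords=array, section_id=sect,
                          labels=labels)


def save_expression(data: SpotExpression | CellExpression, path: str | Path) -> None:
    """Write a container as a single CSV table (inverse of csv loading)."""
    path = Path(path)
    mat = pd.DataFrame(data.matrix, columns=data.gene_ids)
    if isinstance(data, SpotExpression):
        meta = {"spot_id": data.spot_ids,
                "y1": data.spatial_coords[:, 0], "y2": data.spatial_coords[:, 1],
                "section_id": data.section_id}
        if data.array_coords is not None:
            meta["array_row"] = data.array_coords[:, 0]
            meta["array_col"] = data.array_coords[:, 1]
        if data.labels is not None:
            meta["label"] = data.labels
    else:
        meta = {"cell_id": data.cell_ids}
        if data.true_coords is not None:
            meta["true_y1"] = data.true_coords[:, 0]
            meta["true_y2"] = data.true_coords[:, 1]
        if data.true_labels is not None:
            meta["true_label"] = data.true_labels
    meta["normalized"] = data.normalized
    pd.concat([pd.DataFrame(meta), mat], axis=1).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Normalization and gene selection
# ---------------------------------------------------------------------------

def normalize_expression(data: SpotExpression | CellExpression):
    """log(1 + count) per entry, then per-gene z-score across rows.

    Zero-variance genes cannot be standardized and are dropped with a
    warning.  Raises if the input was already normalized or holds negative
    counts.
    """
    if data.normalized:
        raise ExpressionError("data already normalized")
    if (data.matrix < 0).any():
        raise ExpressionError("negative counts")
    logged = np.log1p(data.matrix)
    sd = logged.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.any():
        raise ExpressionError("all genes have zero variance")
    if not keep.all():
        dropped = [g for g, k in zip(data.gene_ids, keep) if not k]
        warnings.warn(f"dropping {len(dropped)} zero-variance gene(s): "
                      f"{dropped[:10]}", stacklevel=2)
    logged = logged[:, keep]
    z = (logged - logged.mean(axis=0)) / logged.std(axis=0, ddof=1)
    genes = [g for g, k in zip(data.gene_ids, keep) if k]
    return replace(data, matrix=z, gene_ids=genes, normalized=True)


def select_genes(reference: SpotExpression, n_top: int, mode: str = "variance") -> list[str]:
    """Rank genes and return up to ``n_top`` ids.

    ``variance`` ranks by cross-spot variance (descending).  ``label_markers``
    runs a per-label Wilcoxon rank-sum (label vs rest, one-sided enrichment)
    and pools the top genes of each label round-robin.
    """
    if not reference.normalized:
        raise ExpressionError("reference must be normalized before gene selection")
    if mode == "variance":
        var = reference.matrix.var(axis=0)
        order = sorted(range(reference.n_genes),
                       key=lambda j: (-var[j], reference.gene_ids[j]))
        return [reference.gene_ids[j] for j in order[:n_top]]
    if mode == "label_markers":
        if reference.labels is None:
            raise ExpressionError("label_markers mode requires labels")
        ranked_per_label = []
        for lab in sorted(set(map(str, reference.labels))):
            in_grp = np.asarray([str(x) == lab for x in reference.labels])
            stat = np.array([
                stats.ranksums(reference.matrix[in_grp, j],
                               reference.matrix[~in_grp, j]).statistic
                for j in range(reference.n_genes)
            ])
            order = sorted(range(reference.n_genes),
                           key=lambda j: (-stat[j], reference.gene_ids[j]))
            ranked_per_label.append([reference.gene_ids[j] for j in order])
        pooled: list[str] = []
        depth = 0
        while len(pooled) < n_top and depth < reference.n_genes:
            for ranked in ranked_per_label:
                g = ranked[depth]
                if g not in pooled:
                    pooled.append(g)
            depth += 1
        return pooled[:n_top]
    raise ExpressionError(f"unknown selection mode {mode!r}")


def merge_sections(sections: list[SpotExpression]) -> SpotExpression:
    """Normalize each section independently, subset common genes, stack rows."""
    if not sections:
        raise ExpressionError("no sections to merge")
    normed = [s if s.normalized else normalize_expression(s) for s in sections]
    if len(normed) == 1:
        return normed[0]
    common = set(normed[0].gene_ids)
    for s in normed[1:]:
        common &= set(s.gene_ids)
    if not common:
        raise ExpressionError("empty gene intersection across sections")
    genes = sorted(common)
    mats, spots, sects, coords, arrays, labels = [], [], [], [], [], []
    have_array = all(s.array_coords is not None for s in normed)
    have_labels = all(s.labels is not None for s in normed)
    for s in normed:
        idx = [s.gene_ids.index(g) for g in genes]
        mats.append(s.matrix[:, idx])
        spots.extend(s.spot_ids)
        sects.extend(s.section_id)
        coords.append(s.spatial_coords)
        if have_array:
            arrays.append(s.array_coords)
        if have_labels:
            labels.append(np.asarray(s.labels))
    return SpotExpression(
        np.vstack(mats), genes, spots, np.vstack(coords),
        array_coords=np.vstack(arrays) if have_array else None,
        section_id=sects,
        labels=np.concatenate(labels) if have_labels else None,
        normalized=True,
    )


def harmonize_genes(reference, query):
    """Restrict both containers to their shared genes, in lexicographic order."""
    common = sorted(set(reference.gene_ids) & set(query.gene_ids))
    if not common:
        raise ExpressionError("no shared genes between reference and query")
    ridx = [reference.gene_ids.index(g) for g in common]
    qidx = [query.gene_ids.index(g) for g in common]
    ref2 = replace(reference, matrix=reference.matrix[:, ridx], gene_ids=list(common))
    qry2 = replace(query, matrix=query.matrix[:, qidx], gene_ids=list(common))
    return ref2, qry2


def filter_condition_invariant_genes(query: CellExpression, condition_labels,
                                     fdr: float = 0.05) -> list[str]:
    """Genes NOT differentially expressed between two conditions.

    Wilcoxon rank-sum per gene with Benjamini-Hochberg adjustment; a gene is
    retained when its adjusted p-value is >= ``fdr``.
    """
    condition_labels = np.asarray(condition_labels)
    levels = sorted(set(map(str, condition_labels)))
    if len(levels) != 2:
        raise ExpressionError(f"need exactly 2 condition levels, got {levels}")
    in_a = np.asarray([str(x) == levels[0] for x in condition_labels])
    if in_a.sum() < 2 or (~in_a).sum() < 2:
        raise ExpressionError("fewer than 2 cells in a condition group")
    pvals = np.array([
        stats.ranksums(query.matrix[in_a, j], query.matrix[~in_a, j]).pvalue
        for j in range(query.n_genes)
    ])
    padj = multipletests(pvals, method="fdr_bh")[1]
    return [g for g, p in zip(query.gene_ids, padj) if p >= fdr]
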