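"""Unsupervised comparison of morphological profiles.

Feature-wise standardization, PCA (SVD with a fixed sign convention),
agglomerative clustering with correlation distance and average (UPGMA)
linkage, and an optional seeded UMAP embedding.  A feature correlation
matrix is reported so multicollinearity among the 12 features stays
visible rather than being pruned away.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .profiling import FEATURE_NAMES, ProfileMatrix

logger = logging.getLogger(__name__)


@dataclass
class Standardization:
    """Column-wise z-scoring with an exact inverse.

    Zero-variance columns are centered but not scaled (scale kept at 1), so
    the round trip is exact for them too.
    """

    mean_: np.ndarray
    scale_: np.ndarray

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.mean_) / self.scale_

    def inverse_transform(self, Z: np.ndarray) -> np.ndarray:
        return np.asarray(Z, dtype=float) * self.scale_ + self.mean_


def standardize(X: np.ndarray | ProfileMatrix) -> tuple[np.ndarray, Standardization]:
    """Center each column to mean 0 and scale to SD 1 (population SD).

    Raises on a single-row input; warns (and leaves centered) on
    zero-variance columns.
    """
    arr = X.values if isinstance(X, ProfileMatrix) else np.asarray(X, dtype=float)
    if arr.ndim != 2:
        raise ValueError("expected a 2-D matrix")
    if arr.shape[0] < 2:
        raise ValueError("standardization requires at least 2 rows")
    if np.isnan(arr).any():
        raise ValueError("matrix contains missing values")
    mean = arr.mean(axis=0)
    sd = arr.std(axis=0)
    zero = sd == 0
    if zero.any():
        logger.warning(
            "zero-variance columns left centered: %s", np.flatnonzero(zero).tolist()
        )
    scale = np.where(zero, 1.0, sd)
    st = Standardization(mean_=mean, scale_=scale)
    return st.transform(arr), st


@dataclass
class PCAResult:
    scores: np.ndarray            # (n, k)
    loadings: np.ndarray          # (k, p) rows = components
    explained_variance_ratio: np.ndarray
    mean_: np.ndarray

    def reconstruct(self) -> np.ndarray:
        return self.scores @ self.loadings + self.mean_


def run_pca(X: np.ndarray | ProfileMatrix) -> PCAResult:
    """Full PCA via SVD with deterministic component signs.

    Loadings are orthonormal; explained-variance ratios are nonincreasing
    and sum to 1 over all retained components (all ``min(n−1, p)`` of them).
    The sign of each component is fixed by making its largest-magnitude
    loading positive.
    """
    arr = X.values if isinstance(X, ProfileMatrix) else np.asarray(X, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2:
        raise ValueError("PCA requires a 2-D matrix with >= 2 rows")
    mean = arr.mean(axis=0)
    U, S, Vt = np.linalg.svd(arr - mean, full_matrices=False)
    k = min(arr.shape[0] - 1, arr.shape[1])
    U, S, Vt = U[:, :k], S[:k], Vt[:k]
    for i in range(k):
        j = int(np.argmax(np.abs(Vt[i])))
        if Vt[i, j] < 0:
            Vt[i] *= -1
            U[:, i] *= -1
    total = float((S**2).sum())
    evr = S**2 / total if total > 0 else np.zeros(k)
    return PCAResult(
        scores=U * S,
        loadings=Vt,
        explained_variance_ratio=evr,
        mean_=mean,
    )


@dataclass
class ClusterResult:
    linkage: np.ndarray           # scipy linkage matrix
    distances: np.ndarray         # condensed correlation distances
    leaf_order: np.ndarray
    flat_labels: np.ndarray | None = None

    def cut(self, k: int) -> np.ndarray:
        return hierarchy.fcluster(self.linkage, t=k, criterion="maxclust")


def correlation_distances(X: np.ndarray) -> np.ndarray:
    """Condensed pairwise 1 − Pearson correlation across each row's features.

    Raises if any row is constant (correlation undefined), naming the row.
    """
    arr = np.asarray(X, dtype=float)
    row_sd = arr.std(axis=1)
    bad = np.flatnonzero(row_sd == 0)
    if bad.size:
        raise ValueError(
            f"correlation distance undefined for constant row(s): {bad.tolist()}"
        )
    d = pdist(arr, metric="correlation")
    # numerical guard: clamp into the theoretical [0, 2] range
    return np.clip(d, 0.0, 2.0)


def cluster_profiles(
    X: np.ndarray | ProfileMatrix, k: int | None = None
) -> ClusterResult:
    """UPGMA (average-linkage) clustering under correlation distance.

    Deterministic: scipy's linkage breaks ties by merge index, which is a
    pure function of row order.
    """
    arr = X.values if isinstance(X, ProfileMatrix) else np.asarray(X, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2:
        raise ValueError("clustering requires at least 2 rows")
    d = correlation_distances(arr)
    Z = hierarchy.linkage(d, method="average")
    order = hierarchy.leaves_list(Z)
    flat = hierarchy.fcluster(Z, t=k, criterion="maxclust") if k else None
    return ClusterResult(
        linkage=Z, distances=d, leaf_order=order, flat_labels=flat
    )


def linkage_to_newick(Z: np.ndarray, leaf_names: list[str]) -> str:
    """Serialize a scipy linkage matrix as a Newick tree with branch lengths."""
    tree = hierarchy.to_tree(Z)

    def walk(node, parent_height: float) -> str:
        length = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{leaf_names[node.id]}:{length:.10g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{length:.10g}"

    return walk(tree, tree.dist) + ";"


def run_umap(
    X: np.ndarray | ProfileMatrix,
    n_neighbors: int = 15,
    min_dist: float = 0.1,
    seed: int = 0,
) -> np.ndarray:
    """Seeded 2-D UMAP embedding (reproducible for a fixed seed)."""
    arr = X.values if isinstance(X, ProfileMatrix) else np.asarray(X, dtype=float)
    if arr.shape[0] < 4:
        raise ValueError("UMAP requires at least 4 rows")
    if arr.shape[0] < n_neighbors:
        raise ValueError(
            f"n_neighbors={n_neighbors} exceeds the {arr.shape[0]} rows available"
        )
    import umap  # deferred: numba-backed import is slow

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        reducer = umap.UMAP(
            n_components=2,
            n_neighbors=n_neighbors,
            min_dist=min_dist,
            random_state=seed,
            transform_seed=seed,
        )
        return np.asarray(reducer.fit_transform(arr), dtype=float)


def feature_correlation(X: np.ndarray | ProfileMatrix) -> pd.DataFrame:
    """12×12 Pearson correlation among profile features (multicollinearity
    report; features are never pruned on its basis)."""
    arr = X.values if isinstance(X, ProfileMatrix) else np.asarray(X, dtype=float)
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(arr, rowvar=False)
    return pd.DataFrame(corr, index=list(FEATURE_NAMES), columns=list(FEATURE_NAMES))


def plot_profile_heatmap(
    matrix: ProfileMatrix,
    result: ClusterResult,
    out_path: str | Path,
    standardized: np.ndarray | None = None,
) -> None:
    """Heatmap of (standardized) profiles reordered by the dendrogram, with
    the tree drawn alongside; publication-style overview figure."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    Xs = standardized if standardized is not None else matrix.values
    order = result.leaf_order
    labels = [matrix.row_labels()[i] for i in order]
    fig, (ax_d, ax_h) = plt.subplots(
        1, 2, figsize=(10, max(4, 0.25 * len(order))),
        gridspec_kw={"width_ratios": [1, 3]},
    )
    hierarchy.dendrogram(
        result.linkage, orientation="left", ax=ax_d, no_labels=True,
        color_threshold=0.0,
    )
    ax_d.set_xlabel("1 - r")
    im = ax_h.imshow(
        Xs[order][::-1], aspect="auto", cmap="coolwarm", interpolation="nearest"
    )
    ax_h.set_yticks(range(len(labels)), labels=labels[::-1], fontsize=6)
    ax_h.set_xticks(range(len(FEATURE_NAMES)), labels=list(FEATURE_NAMES),
                    rotation=90, fontsize=6)
    fig.colorbar(im, ax=ax_h, shrink=0.6, label="z-score")
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)


def write_analysis_outputs(
    matrix: ProfileMatrix,
    out_dir: str | Path,
    standardize_features: bool = True,
    umap_seed: int | None = None,
    umap_n_neighbors: int = 15,
    make_figure: bool = True,
) -> dict[str, str]:
    """Run standardize → PCA → clustering (→ UMAP) and write all outputs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    X = matrix.values
    if standardize_features:
        Xs, _ = standardize(X)
    else:
        Xs = X
    paths: dict[str, str] = {}

    pca = run_pca(Xs)
    k = pca.scores.shape[1]
    comp = [f"PC{i+1}" for i in range(k)]
    scores = pd.concat(
        [
            matrix.meta.reset_index(drop=True),
            pd.DataFrame(pca.scores, columns=comp),
        ],
        axis=1,
    )
    scores.to_csv(out / "pca_scores.csv", index=False)
    pd.DataFrame(pca.loadings, index=comp, columns=list(FEATURE_NAMES)).to_csv(
        out / "pca_loadings.csv"
    )
    pd.DataFrame(
        {"component": comp, "explained_variance_ratio": pca.explained_variance_ratio}
    ).to_csv(out / "pca_explained_variance.csv", index=False)
    paths["pca_scores"] = str(out / "pca_scores.csv")

    n_cond = len(set(map(str, matrix.conditions)))
    res = cluster_profiles(Xs, k=max(n_cond, 2))
    (out / "dendrogram.nwk").write_text(
        linkage_to_newick(res.linkage, matrix.row_labels())
    )
    clusters = matrix.meta.copy()
    clusters["cluster"] = res.flat_labels
    clusters.to_csv(out / "cluster_labels.csv", index=False)
    paths["dendrogram"] = str(out / "dendrogram.nwk")
    paths["clusters"] = str(out / "cluster_labels.csv")

    feature_correlation(X).to_csv(out / "feature_correlation.csv")

    if umap_seed is not None:
        emb = run_umap(
            Xs,
            n_neighbors=min(umap_n_neighbors, len(matrix) - 1),
            seed=umap_seed,
        )
        emb_df = matrix.meta.copy()
        emb_df[["umap1", "umap2"]] = emb
        emb_df.to_csv(out / "umap_embedding.csv", index=False)
        paths["umap"] = str(out / "umap_embedding.csv")

    if make_figure:
        plot_profile_heatmap(matrix, res, out / "profile_heatmap.png", Xs)
        paths["heatmap"] = str(out / "profile_heatmap.png")
    return paths
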