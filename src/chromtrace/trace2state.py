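"""Trace2State: cell-state visualization and classification from scA/B scores.

The single-cell A/B score matrix (cells x regions) is the feature space:
cells with fewer than 10 traces are dropped, missing values are imputed with
0, the matrix is reduced to its first 50 principal components (standardized),
and those components feed 2D embeddings, a cross-validated RBF-kernel SVM
state classifier, and a Leiden clustering that splits the adenoma-to-invasive
continuum into adenoma-like and invasive-like conformation groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import NearestNeighbors
from sklearn.svm import SVC

from .metrics.compartments import ScABMatrix
from .types import CellRecord

__all__ = [
    "StateFeatures",
    "ClassifierReport",
    "build_features",
    "embed",
    "train_classifier",
    "progression_clusters",
]


@dataclass
class StateFeatures:
    """Zero-imputed scA/B matrix and its standardized principal components."""

    matrix: pd.DataFrame       # cells x regions after filtering + imputation
    pcs: pd.DataFrame          # cells x n_pcs, standardized
    labels: pd.Series          # state per retained cell
    sources: pd.Series         # source (mouse/tumor) per retained cell
    n_pcs: int
    seed: int


@dataclass
class ClassifierReport:
    """Cross-validated classification summary."""

    accuracy: float
    confusion: pd.DataFrame          # rows: true state, cols: predicted
    precision: pd.Series             # per predicted state
    auc: pd.Series                   # one-vs-rest AUC per state
    fold_of_cell: pd.Series
    seed: int


def build_features(scab: ScABMatrix, cells: list[CellRecord],
                   min_traces: int = 10, n_pcs: int = 50,
                   seed: int = 0) -> StateFeatures:
    """Filter, impute and reduce the scA/B matrix.

    Only cells with at least ``min_traces`` traces are analyzed; missing
    scA/B values are replaced with 0; PCA retains ``n_pcs`` components (or
    as many as the data allow) with a deterministic sign convention (largest
    absolute loading positive), standardized to zero mean / unit variance.
    """
    info = {c.cell_id: c for c in cells}
    keep = [cid for cid in scab.values.index
            if cid in info and info[cid].n_traces() >= min_traces]
    if len(keep) < 2:
        raise ValueError("fewer than 2 cells pass the trace-count filter")
    mat = scab.values.loc[keep].fillna(0.0)
    k = int(min(n_pcs, len(keep), mat.shape[1]))
    pca = PCA(n_components=k, random_state=seed)
    scores = pca.fit_transform(mat.to_numpy())
    # fix component signs: largest-|loading| coefficient positive
    for j in range(k):
        load = pca.components_[j]
        if load[np.argmax(np.abs(load))] < 0:
            scores[:, j] = -scores[:, j]
    sd = scores.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    scores = (scores - scores.mean(axis=0)) / sd
    pcs = pd.DataFrame(scores, index=keep,
                       columns=[f"PC{j + 1}" for j in range(k)])
    labels = pd.Series({cid: info[cid].state for cid in keep})
    sources = pd.Series({cid: info[cid].source_id for cid in keep})
    return StateFeatures(matrix=mat, pcs=pcs, labels=labels, sources=sources,
                         n_pcs=k, seed=seed)


def embed(features: StateFeatures, method: str = "pca2d",
          seed: int = 0) -> pd.DataFrame:
    """2D embedding of the feature PCs (``pca2d``, ``tsne`` or ``umap``)."""
    x = features.pcs.to_numpy()
    if method == "pca2d":
        coords = x[:, :2].copy()
    elif method == "tsne":
        from sklearn.manifold import TSNE
        perp = min(30.0, max(2.0, (len(x) - 1) / 3.0))
        coords = TSNE(n_components=2, random_state=seed, perplexity=perp,
                      init="pca").fit_transform(x)
    elif method == "umap":
        import umap
        nn = min(15, len(x) - 1)
        coords = umap.UMAP(n_components=2, random_state=seed,
                           n_neighbors=nn, n_jobs=1).fit_transform(x)
    else:
        raise ValueError(
            f"unknown embedding method {method!r}; available: "
            "pca2d, tsne, umap")
    return pd.DataFrame(coords, index=features.pcs.index,
                        columns=["dim1", "dim2"])


def train_classifier(features: StateFeatures, folds: int = 5,
                     model: str = "svm-rbf", seed: int = 0,
                     c: float = 1.0) -> ClassifierReport:
    """Stratified k-fold cross-validated state classifier.

    The default model is an RBF-kernel SVM with unit regularization and
    kernel scale sqrt(n_features) (gamma = 1/n_features on standardized
    PCs).  The confusion matrix and per-class one-vs-rest ROC AUC are built
    from out-of-fold predictions.
    """
    x = features.pcs.to_numpy()
    y = features.labels.to_numpy()
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    counts = pd.Series(y).value_counts()
    if (counts < folds).any():
        small = counts[counts < folds].index.tolist()
        raise ValueError(f"classes smaller than {folds} members: {small}")

    def make_model():
        if model == "svm-rbf":
            return SVC(kernel="rbf", C=c, gamma=1.0 / x.shape[1],
                       decision_function_shape="ovr")
        if model == "svm-linear":
            return SVC(kernel="linear", C=c)
        raise ValueError(f"unknown model {model!r}")

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    pred = np.empty(len(y), dtype=object)
    scores = np.full((len(y), len(classes)), np.nan)
    fold_of = np.zeros(len(y), dtype=int)
    for fold, (tr, te) in enumerate(skf.split(x, y)):
        clf = make_model().fit(x[tr], y[tr])
        pred[te] = clf.predict(x[te])
        df = clf.decision_function(x[te])
        if df.ndim == 1:   # binary: expand to two columns
            df = np.column_stack([-df, df])
        cols = [int(np.where(classes == cl)[0][0]) for cl in clf.classes_]
        scores[np.ix_(te, cols)] = df
        fold_of[te] = fold

    acc = float((pred == y).mean())
    confusion = pd.crosstab(pd.Series(y, name="true"),
                            pd.Series(pred, name="predicted"))
    confusion = confusion.reindex(index=classes, columns=classes,
                                  fill_value=0)
    col_sums = confusion.sum(axis=0)
    precision = pd.Series(np.diag(confusion) / col_sums.replace(0, np.nan),
                          index=classes)
    auc = {}
    for k, cl in enumerate(classes):
        auc[cl] = float(roc_auc_score((y == cl).astype(int), scores[:, k]))
    return ClassifierReport(accuracy=acc, confusion=confusion,
                            precision=precision, auc=pd.Series(auc),
                            fold_of_cell=pd.Series(fold_of,
                                                   index=features.pcs.index),
                            seed=seed)


def progression_clusters(features: StateFeatures, invasive_state: str,
                         resolution: float = 1.0, k_neighbors: int = 15,
                         seed: int = 0) -> dict:
    """Leiden partition of adenoma+invasive cells into conformation groups.

    A k-nearest-neighbor graph on the PCs is partitioned by the Leiden
    algorithm; each cluster is labeled invasive-like or adenoma-like by
    whether its majority member state is ``invasive_state``; per-state
    composition is compared by two-sided Fisher's exact tests
    (state vs others) x (adenoma-like vs invasive-like).
    """
    import igraph
    import leidenalg

    x = features.pcs.to_numpy()
    y = features.labels
    if y.nunique() < 2:
        raise ValueError("need at least 2 states")
    kk = min(k_neighbors, len(x) - 1)
    nn = NearestNeighbors(n_neighbors=kk).fit(x)
    _, idx = nn.kneighbors(x)
    edges = {(min(i, j), max(i, j)) for i in range(len(x))
             for j in idx[i, 1:]}
    graph = igraph.Graph(n=len(x), edges=sorted(edges))
    part = leidenalg.find_partition(
        graph, leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution, seed=seed)
    membership = np.array(part.membership)
    n_clusters = membership.max() + 1

    cluster_kind = {}
    for cl in range(n_clusters):
        states = y.iloc[np.nonzero(membership == cl)[0]]
        top = states.value_counts().idxmax()
        cluster_kind[cl] = ("invasive-like" if top == invasive_state
                            else "adenoma-like")
    kind = pd.Series([cluster_kind[m] for m in membership], index=y.index,
                     name="conformation")

    composition = pd.crosstab(y, kind)
    fisher = {}
    if n_clusters < 2 or kind.nunique() < 2:
        flagged = True
    else:
        flagged = False
        inv = (kind == "invasive-like").to_numpy()
        for state in y.unique():
            in_state = (y == state).to_numpy()
            table = [[int((in_state & inv).sum()),
                      int((in_state & ~inv).sum())],
                     [int((~in_state & inv).sum()),
                      int((~in_state & ~inv).sum())]]
            fisher[state] = float(stats.fisher_exact(table)[1])
    return dict(membership=pd.Series(membership, index=y.index),
                conformation=kind, composition=composition,
                fisher_p=pd.Series(fisher, dtype=float),
                degenerate=flagged, resolution=resolution,
                k_neighbors=kk, seed=seed)
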