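"""Multivariate diagnostics for the solvent-screening step.

Three complementary views of the extraction-replicate × lipid-subclass
abundance matrix:

* PCA — unsupervised projection; components carry a deterministic sign
  convention (the largest-magnitude loading of each component is positive).
* Hierarchical clustering — UPGMA (average linkage) on squared Euclidean
  distances over [0, 1]-range-scaled variables, with a height-based cut and
  Newick export.
* PLS-DA — partial least squares discriminant analysis on a one-hot class
  matrix, validated by a double (nested) cross-validation scheme and by
  out-of-bag bootstrap, reporting per-class RMSECV, Q2, DQ2, accuracy,
  sensitivity and specificity.

Q2 is the cross-validated coefficient of determination, 1 − PRESS/TSS on
held-out predictions.  DQ2 is its discriminant variant: residuals of
predictions that overshoot their class label in the correct direction
(ŷ > 1 for y = 1, ŷ < 0 for y = 0) are zeroed, so DQ2 ≥ Q2 always — a
class prediction "beyond" its label is not an error for discrimination.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist
from sklearn.cross_decomposition import PLSRegression
from sklearn.decomposition import PCA as _SkPCA
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "PCAModel",
    "HCATree",
    "PLSDAReport",
    "pca",
    "hca_average_linkage",
    "cut_tree",
    "compute_q2_dq2",
    "plsda_double_cv",
    "plsda_bootstrap",
]

STAT_ROWS = ("RMSECV", "Q2", "DQ2", "Accuracy", "Sensitivity", "Specificity")


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PCAModel:
    loadings: pd.DataFrame  # variables × components
    scores: pd.DataFrame  # samples × components
    explained_variance_pct: np.ndarray
    center: bool
    scale: bool
    mean_: np.ndarray
    scale_: np.ndarray

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]

    def pretreat(self, X) -> np.ndarray:
        X = np.asarray(X, float)
        return (X - self.mean_) / self.scale_

    def reconstruct(self) -> np.ndarray:
        """Pretreated-scale reconstruction from the retained components."""
        return self.scores.to_numpy() @ self.loadings.to_numpy().T


def pca(data, center: bool = True, scale: bool = True, n_components: int | None = None) -> PCAModel:
    """Principal component analysis with a fixed sign convention.

    ``scale=True`` autoscales (unit variance) after optional mean centering;
    subclass abundance sums span orders of magnitude, so autoscaling is the
    default.  Components are ordered by explained variance; each component
    is flipped so its largest-|loading| entry is positive.
    """
    df = data if isinstance(data, pd.DataFrame) else pd.DataFrame(np.asarray(data, float))
    X = df.to_numpy(float)
    if X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("PCA needs at least 2 samples and 2 variables")
    if not np.isfinite(X).all():
        raise ValueError("PCA input contains missing or non-finite values")

    mean_ = X.mean(axis=0) if center else np.zeros(X.shape[1])
    if scale:
        scale_ = X.std(axis=0, ddof=1)
        if np.any(scale_ == 0):
            bad = [c for c, s in zip(df.columns, scale_) if s == 0]
            raise ValueError(f"cannot autoscale constant columns: {bad}")
    else:
        scale_ = np.ones(X.shape[1])
    Z = (X - mean_) / scale_

    max_comp = min(X.shape[0] - 1 if center else X.shape[0], X.shape[1])
    k = max_comp if n_components is None else min(n_components, max_comp)
    model = _SkPCA(n_components=k)
    scores = model.fit_transform(Z)
    loadings = model.components_.T  # variables × components

    # sign convention: largest-magnitude loading positive per component
    for j in range(k):
        i = np.argmax(np.abs(loadings[:, j]))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1

    total_var = Z.var(axis=0, ddof=1).sum()
    evr_pct = 100.0 * model.explained_variance_ / total_var
    comp_names = [f"PC{j + 1}" for j in range(k)]
    return PCAModel(
        loadings=pd.DataFrame(loadings, index=df.columns, columns=comp_names),
        scores=pd.DataFrame(scores, index=df.index, columns=comp_names),
        explained_variance_pct=np.asarray(evr_pct),
        center=center,
        scale=scale,
        mean_=mean_,
        scale_=scale_,
    )


# ---------------------------------------------------------------------------
# Hierarchical clustering (UPGMA on squared Euclidean distances)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HCATree:
    """UPGMA merge tree; heights are average squared Euclidean distances."""

    linkage_: np.ndarray  # scipy (n−1, 4) linkage matrix
    labels: tuple[str, ...]

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    @property
    def heights(self) -> np.ndarray:
        return self.linkage_[:, 2]

    def cut(self, height: float) -> np.ndarray:
        """Cluster labels from merges with height strictly below ``height``.

        Returns integer labels, renumbered in order of first appearance.
        """
        if height < 0:
            raise ValueError("cut height must be >= 0")
        n = self.n_leaves
        parent = list(range(2 * n - 1))

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for m, (a, b, h, _) in enumerate(self.linkage_):
            if h < height:
                node = n + m
                parent[find(int(a))] = node
                parent[find(int(b))] = node
        roots = [find(i) for i in range(n)]
        seen: dict[int, int] = {}
        out = np.empty(n, dtype=int)
        for i, r in enumerate(roots):
            out[i] = seen.setdefault(r, len(seen))
        return out

    def to_newick(self) -> str:
        """Ultrametric Newick string (leaf-to-node branch = height/2 gaps)."""
        n = self.n_leaves
        node_height = {i: 0.0 for i in range(n)}
        node_str = {i: self.labels[i].replace(" ", "_") for i in range(n)}
        for m, (a, b, h, _) in enumerate(self.linkage_):
            a, b = int(a), int(b)
            ha, hb = h / 2.0, h / 2.0
            sa = f"{node_str[a]}:{ha - node_height[a]:.10g}"
            sb = f"{node_str[b]}:{hb - node_height[b]:.10g}"
            node = n + m
            node_str[node] = f"({sa},{sb})"
            node_height[node] = h / 2.0
        return node_str[2 * n - 2] + ";"


def hca_average_linkage(data, labels=None) -> HCATree:
    """UPGMA clustering on squared Euclidean distances.

    ``data`` is expected on a common scale (typically [0, 1] range-scaled
    columns).  Heights equal the average pairwise squared Euclidean distance
    between the merged groups and are non-decreasing along the merge
    sequence.
    """
    df = data if isinstance(data, pd.DataFrame) else pd.DataFrame(np.asarray(data, float))
    X = df.to_numpy(float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 samples to cluster")
    if not np.isfinite(X).all():
        raise ValueError("clustering input contains non-finite values")
    if labels is None:
        labels = tuple(str(i) for i in df.index)
    Z = linkage(pdist(X, metric="sqeuclidean"), method="average")
    return HCATree(linkage_=Z, labels=tuple(labels))


def cut_tree(tree: HCATree, height: float) -> np.ndarray:
    return tree.cut(height)


# ---------------------------------------------------------------------------
# Q2 / DQ2
# ---------------------------------------------------------------------------


def compute_q2_dq2(y_true, y_pred) -> tuple[float, float]:
    """Cross-validated R² (Q2) and its discriminant variant (DQ2).

    ``y_true`` must be binary 0/1.  DQ2 zeroes the residual of any
    prediction already on the correct side of its label beyond it, so
    DQ2 ≥ Q2.
    """
    y = np.asarray(y_true, float).ravel()
    f = np.asarray(y_pred, float).ravel()
    if y.shape != f.shape:
        raise ValueError("y_true and y_pred must have the same length")
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("y_true must be binary 0/1")
    tss = np.sum((y - y.mean()) ** 2)
    if tss == 0:
        raise ValueError("constant y_true: Q2 undefined")
    resid = y - f
    press = np.sum(resid**2)
    overshoot = ((y == 1) & (f > 1)) | ((y == 0) & (f < 0))
    press_d = np.sum(np.where(overshoot, 0.0, resid) ** 2)
    return float(1 - press / tss), float(1 - press_d / tss)


# ---------------------------------------------------------------------------
# PLS-DA
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PLSDAReport:
    """Per-class diagnostic statistics in the screening-report layout."""

    stats: pd.DataFrame  # rows STAT_ROWS × columns classes
    mode: str  # "double_cv" or "bootstrap"
    classes: tuple[str, ...]
    n_components_chosen: int
    n_replicates_used: int | None = None
    predictions: pd.DataFrame | None = None

    def __getitem__(self, item):
        return self.stats.loc[item]


def _one_hot(y, classes) -> np.ndarray:
    return np.array([[1.0 if yi == c else 0.0 for c in classes] for yi in y])


def _fit_predict(Xtr, Ytr, Xte, n_components: int, scale: bool) -> np.ndarray:
    model = PLSRegression(n_components=n_components, scale=scale)
    model.fit(Xtr, Ytr)
    return model.predict(Xte)


def _class_stats(Y, Yhat, classes) -> pd.DataFrame:
    """Per-class RMSECV/Q2/DQ2 and one-vs-rest confusion statistics."""
    pred_idx = np.argmax(Yhat, axis=1)
    true_idx = np.argmax(Y, axis=1)
    out = {}
    for j, c in enumerate(classes):
        y, f = Y[:, j], Yhat[:, j]
        rmse = float(np.sqrt(np.mean((y - f) ** 2)))
        q2, dq2 = compute_q2_dq2(y, f)
        tp = np.sum((true_idx == j) & (pred_idx == j))
        tn = np.sum((true_idx != j) & (pred_idx != j))
        fp = np.sum((true_idx != j) & (pred_idx == j))
        fn = np.sum((true_idx == j) & (pred_idx != j))
        acc = (tp + tn) / len(y)
        sens = tp / (tp + fn) if tp + fn else np.nan
        spec = tn / (tn + fp) if tn + fp else np.nan
        out[c] = [rmse, q2, dq2, acc, sens, spec]
    return pd.DataFrame(out, index=list(STAT_ROWS))


def _max_ncomp_cap(n_train: int, n_features: int, requested: int) -> int:
    cap = min(requested, n_features, n_train - 1)
    if cap < 1:
        raise ValueError("max_components exceeds the rank supportable by the training data")
    return cap


def plsda_double_cv(
    X,
    y,
    outer_folds: int = 6,
    inner_folds: int = 5,
    max_components: int = 5,
    seed: int = 0,
    scale: bool = True,
) -> PLSDAReport:
    """PLS-DA validated by double (nested) cross-validation.

    The inner CV, run on each outer-training set, picks the number of latent
    variables maximizing the pooled inner Q2; the outer held-out predictions
    — never seen by any fitting or selection step — yield the reported
    statistics.  Folds are stratified and shuffled from ``seed``.
    """
    Xdf = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X, float))
    Xa = Xdf.to_numpy(float)
    y = np.asarray(y)
    classes = tuple(sorted(set(y.tolist())))
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    Y = _one_hot(y, classes)

    outer = StratifiedKFold(n_splits=outer_folds, shuffle=True, random_state=seed)
    Yhat = np.full_like(Y, np.nan, dtype=float)
    chosen: list[int] = []
    for k_out, (tr, te) in enumerate(outer.split(Xa, y)):
        counts = Counter(y[tr])
        if min(counts.values()) < 2:
            raise ValueError("a class has <2 samples in an outer training fold")
        cap = _max_ncomp_cap(len(tr) - max(len(tr) // inner_folds, 1), Xa.shape[1], max_components)
        inner = StratifiedKFold(n_splits=inner_folds, shuffle=True, random_state=seed + 1 + k_out)
        press = np.zeros(cap)
        tss = 0.0
        for itr, ite in inner.split(Xa[tr], y[tr]):
            a, b = tr[itr], tr[ite]
            tss += np.sum((Y[b] - Y[a].mean(axis=0)) ** 2)
            for nc in range(1, cap + 1):
                P = _fit_predict(Xa[a], Y[a], Xa[b], nc, scale)
                press[nc - 1] += np.sum((Y[b] - P) ** 2)
        inner_q2 = 1 - press / tss
        nc_best = int(np.argmax(inner_q2)) + 1
        chosen.append(nc_best)
        Yhat[te] = _fit_predict(Xa[tr], Y[tr], Xa[te], nc_best, scale)

    stats = _class_stats(Y, Yhat, classes)
    preds = pd.DataFrame(Yhat, index=Xdf.index, columns=[f"yhat_{c}" for c in classes])
    preds["true"] = y
    preds["predicted"] = [classes[i] for i in np.argmax(Yhat, axis=1)]
    return PLSDAReport(
        stats=stats,
        mode="double_cv",
        classes=classes,
        n_components_chosen=Counter(chosen).most_common(1)[0][0],
        predictions=preds,
    )


def _select_ncomp_cv(Xa, Y, y, max_components, seed, scale, folds: int = 5) -> int:
    cap = _max_ncomp_cap(len(y) - max(len(y) // folds, 1), Xa.shape[1], max_components)
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    press = np.zeros(cap)
    tss = 0.0
    for tr, te in cv.split(Xa, y):
        tss += np.sum((Y[te] - Y[tr].mean(axis=0)) ** 2)
        for nc in range(1, cap + 1):
            P = _fit_predict(Xa[tr], Y[tr], Xa[te], nc, scale)
            press[nc - 1] += np.sum((Y[te] - P) ** 2)
    return int(np.argmax(1 - press / tss)) + 1


def plsda_bootstrap(
    X,
    y,
    B: int = 1000,
    seed: int = 0,
    max_components: int = 5,
    n_components: int | None = None,
    scale: bool = True,
) -> PLSDAReport:
    """PLS-DA uncertainty via stratified out-of-bag bootstrap.

    Each of the ``B`` replicates resamples every class with replacement,
    fits on the resample, and evaluates on the out-of-bag samples; the
    per-class statistics are averaged over replicates.  Replicates whose
    out-of-bag set misses a class are skipped (counted in
    ``n_replicates_used``).
    """
    if B < 100:
        raise ValueError("B must be >= 100 for stable bootstrap estimates")
    Xdf = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X, float))
    Xa = Xdf.to_numpy(float)
    y = np.asarray(y)
    classes = tuple(sorted(set(y.tolist())))
    Y = _one_hot(y, classes)
    rng = np.random.default_rng(seed)
    if n_components is None:
        n_components = _select_ncomp_cv(Xa, Y, y, max_components, seed, scale)

    class_idx = {c: np.flatnonzero(y == c) for c in classes}
    acc = []
    for _ in range(B):
        boot = np.concatenate(
            [rng.choice(idx, size=len(idx), replace=True) for idx in class_idx.values()]
        )
        oob = np.setdiff1d(np.arange(len(y)), boot)
        if len(oob) == 0 or len(set(y[oob])) < len(classes):
            continue
        P = _fit_predict(Xa[boot], Y[boot], Xa[oob], n_components, scale)
        acc.append(_class_stats(Y[oob], P, classes))
    if not acc:
        raise RuntimeError("every bootstrap replicate had an out-of-bag set missing a class")
    mean_stats = sum(a.to_numpy() for a in acc) / len(acc)
    return PLSDAReport(
        stats=pd.DataFrame(mean_stats, index=list(STAT_ROWS), columns=list(classes)),
        mode="bootstrap",
        classes=classes,
        n_components_chosen=n_components,
        n_replicates_used=len(acc),
    )
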