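"""Signed weighted co-expression network analysis.

Implements the classical WGCNA chain: Pearson similarity, soft-thresholded
(signed or unsigned) adjacency, topological overlap, average-linkage
hierarchical clustering, module extraction with a minimum module size and
eigengene-based rescue of unassigned genes, eigengene computation (first
principal component of the standardized module expression), close-module
merging, and module-trait correlation.

All operations here are deterministic: there is no randomness anywhere in
this module.  Expression matrices are genes x samples DataFrames (the
genes are the objects being clustered).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator, ClusterMixin

__all__ = [
    "MODULE_COLORS",
    "GREY",
    "ModuleAssignment",
    "ModuleEigengenes",
    "ModuleTraitResult",
    "WGCNA",
    "similarity",
    "adjacency",
    "tom",
    "soft_threshold_scan",
    "cluster_genes",
    "cut_modules",
    "module_eigengenes",
    "merge_modules",
    "module_trait_correlation",
    "gene_significance",
]

GREY = "grey"

#: conventional module color palette, assigned in decreasing module size
MODULE_COLORS = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white", "skyblue", "saddlebrown", "steelblue",
    "paleturquoise", "violet", "darkolivegreen", "darkmagenta",
)


def _as_matrix(expr) -> tuple[np.ndarray, list]:
    if isinstance(expr, pd.DataFrame):
        return expr.to_numpy(float), list(expr.index)
    arr = np.asarray(expr, float)
    return arr, list(range(arr.shape[0]))


def similarity(expr) -> pd.DataFrame:
    """Signed Pearson correlation matrix between gene expression rows.

    The matrix is stored signed; unsigned analyses take the absolute
    value inside :func:`adjacency`.  Zero-variance genes make the
    correlation undefined and raise, naming the offending genes.
    """
    X, genes = _as_matrix(expr)
    if X.shape[1] < 3:
        raise ValueError("need at least 3 samples for a meaningful correlation")
    sd = X.std(axis=1, ddof=1)
    dead = [g for g, s in zip(genes, sd) if s == 0 or not np.isfinite(s)]
    if dead:
        raise ValueError(f"zero-variance genes: {dead[:10]}{'...' if len(dead) > 10 else ''}")
    S = np.corrcoef(X)
    S = np.clip((S + S.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(S, 1.0)
    return pd.DataFrame(S, index=genes, columns=genes)


def adjacency(S, beta: int = 3, mode: str = "signed") -> pd.DataFrame:
    """Soft-threshold a similarity matrix into a [0, 1] adjacency.

    ``signed``: ``A = ((1 + S) / 2) ** beta`` -- anti-correlated genes get
    adjacency near 0.  ``unsigned``: ``A = |S| ** beta``.  The diagonal is
    set to 1 by convention and excluded from connectivity sums.
    """
    if beta < 1:
        raise ValueError("beta must be >= 1")
    S_df = S if isinstance(S, pd.DataFrame) else pd.DataFrame(np.asarray(S, float))
    M = S_df.to_numpy(float)
    if mode == "signed":
        A = ((1.0 + M) / 2.0) ** beta
    elif mode == "unsigned":
        A = np.abs(M) ** beta
    else:
        raise ValueError(f"mode must be 'signed' or 'unsigned', got {mode!r}")
    np.fill_diagonal(A, 1.0)
    return pd.DataFrame(A, index=S_df.index, columns=S_df.columns)


def tom(A) -> pd.DataFrame:
    """Topological overlap matrix of an adjacency matrix.

    ``TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij)`` with
    ``l_ij = sum_{u != i,j} a_iu a_uj`` and connectivity
    ``k_i = sum_{j != i} a_ij``; the diagonal is fixed at 1.
    """
    A_df = A if isinstance(A, pd.DataFrame) else pd.DataFrame(np.asarray(A, float))
    M = A_df.to_numpy(float).copy()
    np.fill_diagonal(M, 0.0)  # diagonal excluded from k and l sums
    k = M.sum(axis=1)
    L = M @ M
    denom = np.minimum.outer(k, k) + 1.0 - M
    T = (L + M) / denom
    np.fill_diagonal(T, 1.0)
    T = np.clip((T + T.T) / 2.0, 0.0, 1.0)
    return pd.DataFrame(T, index=A_df.index, columns=A_df.columns)


def soft_threshold_scan(expr, betas=range(1, 13), mode: str = "signed",
                        n_bins: int = 10, r2_target: float = 0.85) -> pd.DataFrame:
    """Scale-free topology fit across candidate soft-threshold powers.

    For each beta the connectivities ``k_i`` are binned on log10 scale
    and log10(frequency) is regressed on log10(mean bin connectivity);
    the table reports the fit R^2, the slope, and the mean connectivity.
    The ``recommended`` column marks the smallest beta whose R^2 reaches
    ``r2_target`` (if any).  The scan is advisory: it never changes the
    configured beta on its own.
    """
    S = similarity(expr)
    rows = []
    for beta in betas:
        A = adjacency(S, beta=int(beta), mode=mode).to_numpy()
        np.fill_diagonal(A, 0.0)
        k = A.sum(axis=1)
        rows.append({"beta": int(beta), "r2": _scale_free_r2(k, n_bins)[0],
                     "slope": _scale_free_r2(k, n_bins)[1], "mean_k": float(k.mean())})
    table = pd.DataFrame(rows)
    table["recommended"] = False
    ok = table.index[table["r2"] >= r2_target]
    if len(ok):
        table.loc[ok[0], "recommended"] = True
    return table


def _scale_free_r2(k: np.ndarray, n_bins: int) -> tuple[float, float]:
    k = k[k > 0]
    if len(k) < 2 or np.ptp(k) == 0:
        warnings.warn("degenerate connectivity distribution; R^2 reported as 0", stacklevel=2)
        return 0.0, 0.0
    logk = np.log10(k)
    edges = np.linspace(logk.min(), logk.max() + 1e-9, n_bins + 1)
    which = np.digitize(logk, edges[1:-1])
    xs, ys = [], []
    for b in range(n_bins):
        mask = which == b
        if mask.sum() == 0:
            continue
        xs.append(np.log10(k[mask].mean()))
        ys.append(np.log10(mask.mean()))
    if len(xs) < 3:
        warnings.warn("too few occupied connectivity bins; R^2 reported as 0", stacklevel=2)
        return 0.0, 0.0
    fit = stats.linregress(xs, ys)
    return float(fit.rvalue ** 2), float(fit.slope)


def cluster_genes(tom_matrix) -> np.ndarray:
    """Average-linkage dendrogram on the TOM dissimilarity ``1 - TOM``.

    Returns a scipy linkage matrix; merge heights are non-decreasing.
    """
    T_df = tom_matrix if isinstance(tom_matrix, pd.DataFrame) else pd.DataFrame(np.asarray(tom_matrix, float))
    if T_df.shape[0] < 2:
        raise ValueError("need at least 2 genes to cluster")
    D = 1.0 - T_df.to_numpy(float)
    D = (D + D.T) / 2.0
    np.fill_diagonal(D, 0.0)
    return linkage(squareform(D, checks=False), method="average")


@dataclass
class ModuleAssignment:
    """Per-gene module colors plus the dendrogram they came from."""

    labels: pd.Series            # gene -> color, "grey" = unassigned
    dendrogram: np.ndarray       # scipy linkage matrix
    min_module_size: int
    cut_height: float

    @property
    def modules(self) -> list:
        sizes = self.labels[self.labels != GREY].value_counts()
        return list(sizes.index)


class ModuleEigengenes(NamedTuple):
    """Module eigengene matrix (modules x samples) and variance explained."""

    values: pd.DataFrame
    variance_explained: pd.Series


class ModuleTraitResult(NamedTuple):
    """Module-trait Pearson correlations and their two-sided p-values."""

    r: pd.DataFrame
    p: pd.DataFrame


def _best_cut(Z: np.ndarray, min_module_size: int) -> float:
    """Deterministic static-cut height: scan the midpoints between
    consecutive merge heights and keep the cut that maximizes the number
    of clusters of at least ``min_module_size`` genes, ties resolved
    toward the highest such cut (the most aggregated tree consistent
    with the maximal module count)."""
    heights = np.unique(Z[:, 2])
    cands = np.concatenate([(heights[:-1] + heights[1:]) / 2.0, [heights[-1] * 1.000001 + 1e-12]])
    best_n, best_c = -1, cands[-1]
    for c in cands:
        flat = fcluster(Z, c, criterion="distance")
        counts = np.bincount(flat)
        n = int((counts >= min_module_size).sum())
        if n >= best_n:
            best_n, best_c = n, float(c)
    return best_c


def cut_modules(dendrogram: np.ndarray, min_module_size: int = 30,
                cut_height: float | None = None, expr=None,
                reassign_threshold: float = 0.3, gene_ids=None) -> ModuleAssignment:
    """Cut a gene dendrogram into color-labeled modules.

    A static cut at ``cut_height`` partitions the tree; clusters smaller
    than ``min_module_size`` are relabeled grey.  When ``cut_height`` is
    None a deterministic scan picks the cut maximizing the number of
    clusters of at least ``min_module_size`` genes (see :func:`_best_cut`).
    If ``expr`` is supplied, grey genes whose absolute correlation with
    some module eigengene reaches ``reassign_threshold`` are rescued
    into the closest module.  Colors follow :data:`MODULE_COLORS` in
    decreasing module size.
    """
    Z = np.asarray(dendrogram, float)
    n = Z.shape[0] + 1
    if gene_ids is None:
        gene_ids = list(expr.index) if isinstance(expr, pd.DataFrame) else list(range(n))
    if len(gene_ids) != n:
        raise ValueError("gene_ids length does not match the dendrogram")
    max_h = float(Z[:, 2].max()) if len(Z) else 0.0
    if cut_height is None:
        cut_height = _best_cut(Z, min_module_size)
    elif not 0 < cut_height <= max_h * 1.000001 + 1e-12:
        raise ValueError(f"cut_height must lie in (0, {max_h}]")
    flat = fcluster(Z, cut_height, criterion="distance")
    labels = _colorize(flat, gene_ids, min_module_size)
    if labels.eq(GREY).all():
        warnings.warn("all genes are grey (no cluster reached min_module_size)", stacklevel=2)
    assignment = ModuleAssignment(labels=labels, dendrogram=Z,
                                  min_module_size=min_module_size, cut_height=float(cut_height))
    if expr is not None and reassign_threshold is not None and assignment.modules:
        _rescue_grey(assignment, expr, reassign_threshold)
    return assignment


def _colorize(flat: np.ndarray, gene_ids, min_module_size: int) -> pd.Series:
    counts = pd.Series(flat).value_counts()
    kept = counts[counts >= min_module_size]
    # deterministic order: size descending, then first-appearance index
    first_pos = {c: int(np.argmax(flat == c)) for c in kept.index}
    ordered = sorted(kept.index, key=lambda c: (-kept[c], first_pos[c]))
    color_of = {}
    for i, c in enumerate(ordered):
        color_of[c] = MODULE_COLORS[i] if i < len(MODULE_COLORS) else f"module{i + 1}"
    labels = pd.Series([color_of.get(c, GREY) for c in flat], index=gene_ids, name="module")
    labels.index.name = "gene"
    return labels


def _rescue_grey(assignment: ModuleAssignment, expr: pd.DataFrame, threshold: float) -> None:
    grey_genes = assignment.labels.index[assignment.labels == GREY]
    if len(grey_genes) == 0:
        return
    mes = module_eigengenes(expr, assignment.labels)
    G = expr.loc[grey_genes].to_numpy(float)
    G = (G - G.mean(axis=1, keepdims=True))
    gsd = G.std(axis=1, ddof=1, keepdims=True)
    ok = gsd[:, 0] > 0
    E = mes.values.to_numpy(float)
    E = E - E.mean(axis=1, keepdims=True)
    C = np.zeros((len(grey_genes), E.shape[0]))
    C[ok] = (G[ok] / gsd[ok]) @ (E / E.std(axis=1, ddof=1, keepdims=True)).T / (expr.shape[1] - 1)
    best = np.abs(C).argmax(axis=1)
    for gi, gene in enumerate(grey_genes):
        if ok[gi] and abs(C[gi, best[gi]]) >= threshold:
            assignment.labels.at[gene] = mes.values.index[best[gi]]


def module_eigengenes(expr: pd.DataFrame, labels: pd.Series) -> ModuleEigengenes:
    """First principal component of each module's standardized expression.

    Gene rows are z-scored across samples; the module eigengene is the
    first right-singular vector over samples, rescaled to unit sample
    variance and sign-oriented so it correlates non-negatively with the
    module's mean standardized expression.  Variance explained is the
    leading singular value's share of total variance.
    """
    me_rows, ve = {}, {}
    sizes = labels[labels != GREY].value_counts()
    for color in sizes.index:
        genes = labels.index[labels == color]
        X = expr.loc[genes].to_numpy(float)
        sd = X.std(axis=1, ddof=1)
        if np.any(sd == 0):
            raise ValueError(f"module {color!r} contains constant gene expression")
        Xs = (X - X.mean(axis=1, keepdims=True)) / sd[:, None]
        U, S, Vt = np.linalg.svd(Xs, full_matrices=False)
        me = Vt[0]
        mean_profile = Xs.mean(axis=0)
        if np.corrcoef(me, mean_profile)[0, 1] < 0:
            me = -me
        me = me / me.std(ddof=1)
        me_rows[color] = me
        ve[color] = float(S[0] ** 2 / np.sum(S ** 2))
    values = pd.DataFrame(me_rows, index=expr.columns).T
    values.index.name = "module"
    return ModuleEigengenes(values=values, variance_explained=pd.Series(ve, name="variance_explained"))


def merge_modules(expr: pd.DataFrame, labels: pd.Series, merge_height: float = 0.25,
                  max_iter: int = 20) -> tuple[pd.Series, ModuleEigengenes]:
    """Merge modules whose eigengenes are closer than ``merge_height``.

    Eigengene dissimilarity is ``1 - cor(ME_a, ME_b)``; average-linkage
    clusters merging below ``merge_height`` are unioned, eigengenes are
    recomputed, and the procedure iterates to a fixed point.  Merging
    never increases the module count.  The merged module keeps the color
    of its largest constituent; colors are then re-assigned by size.
    """
    if not 0 <= merge_height <= 1:
        raise ValueError("merge_height must lie in [0, 1]")
    labels = labels.copy()
    merged_any = False
    for _ in range(max_iter):
        mes = module_eigengenes(expr, labels)
        mods = list(mes.values.index)
        if len(mods) <= 1 or merge_height == 0:
            break
        D = 1.0 - np.corrcoef(mes.values.to_numpy(float))
        D = (D + D.T) / 2.0
        np.fill_diagonal(D, 0.0)
        Z = linkage(squareform(np.clip(D, 0, None), checks=False), method="average")
        flat = fcluster(Z, merge_height, criterion="distance")
        if len(set(flat)) == len(mods):
            break
        merged_any = True
        sizes = labels.value_counts()
        for grp in set(flat):
            members = [m for m, f in zip(mods, flat) if f == grp]
            if len(members) > 1:
                keep = max(members, key=lambda m: (sizes[m], m))
                labels[labels.isin(members)] = keep
    if merged_any:
        # normalize color order by final sizes
        final_sizes = labels[labels != GREY].value_counts()
        order = sorted(final_sizes.index, key=lambda c: (-final_sizes[c], c))
        rename = {c: (MODULE_COLORS[i] if i < len(MODULE_COLORS) else f"module{i + 1}")
                  for i, c in enumerate(order)}
        labels = labels.map(lambda c: rename.get(c, GREY))
    return labels, module_eigengenes(expr, labels)


def module_trait_correlation(mes, traits: pd.DataFrame) -> ModuleTraitResult:
    """Pearson correlation of each module eigengene with each trait column.

    Two-sided p-values come from ``t = r sqrt((n-2)/(1-r^2))`` with
    ``n - 2`` degrees of freedom.  Zero-variance trait columns produce
    NaN correlations (flagged, not fatal).
    """
    values = mes.values if isinstance(mes, ModuleEigengenes) else mes
    if list(values.columns) != list(traits.index):
        if set(values.columns) != set(traits.index):
            raise ValueError("module eigengene samples and trait samples differ")
        traits = traits.loc[values.columns]
    n = values.shape[1]
    if n < 3:
        raise ValueError("need at least 3 samples")
    E = values.to_numpy(float)
    T = traits.to_numpy(float)
    r = np.full((E.shape[0], T.shape[1]), np.nan)
    tsd = T.std(axis=0, ddof=1)
    esd = E.std(axis=1, ddof=1)
    Ec = (E - E.mean(axis=1, keepdims=True))
    Tc = (T - T.mean(axis=0, keepdims=True))
    with np.errstate(invalid="ignore", divide="ignore"):
        raw = (Ec @ Tc) / (n - 1) / np.outer(esd, tsd)
    valid = (tsd > 0)[None, :] & (esd > 0)[:, None]
    r[valid] = np.clip(raw[valid], -1, 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        tstat = r * np.sqrt((n - 2) / (1.0 - r ** 2))
    p = 2.0 * stats.t.sf(np.abs(tstat), df=n - 2)
    p = np.where(np.isclose(np.abs(r), 1.0), 0.0, p)
    idx, cols = values.index, traits.columns
    return ModuleTraitResult(r=pd.DataFrame(r, index=idx, columns=cols),
                             p=pd.DataFrame(p, index=idx, columns=cols))


def gene_significance(expr: pd.DataFrame, trait) -> pd.Series:
    """Absolute Pearson correlation of each gene with a trait vector.

    Zero-variance genes (or a constant trait) yield NaN.
    """
    t = np.asarray(trait, float)
    X = expr.to_numpy(float)
    tsd = t.std(ddof=1)
    gsd = X.std(axis=1, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = ((X - X.mean(axis=1, keepdims=True)) @ (t - t.mean())) / (len(t) - 1) / (gsd * tsd)
    gs = pd.Series(np.abs(np.clip(r, -1, 1)), index=expr.index, name="GS")
    if tsd == 0:
        gs[:] = np.nan
    gs[gsd == 0] = np.nan
    return gs


class WGCNA(ClusterMixin, BaseEstimator):
    """Scikit-learn style estimator for the full co-expression chain.

    ``fit`` expects a genes x samples DataFrame (rows are the objects
    being clustered) and runs similarity -> soft-threshold adjacency ->
    TOM -> average-linkage clustering -> module cut (+ grey rescue) ->
    eigengene merge -> eigengenes.

    Parameters
    ----------
    beta : soft-threshold power (default 3).
    mode : "signed" (default) or "unsigned" adjacency.
    min_module_size : minimum genes per module (default 30).
    cut_height : static dendrogram cut height, or None for the
        deterministic max-module-count scan.
    merge_height : eigengene dissimilarity below which modules merge
        (default 0.25); 0 disables merging.
    reassign_threshold : minimum |cor(gene, ME)| for rescuing a grey
        gene into a module (default 0.3); None disables the rescue.

    Attributes
    ----------
    labels_ : ndarray of module colors per gene.
    assignment_ : :class:`ModuleAssignment`.
    eigengenes_ : :class:`ModuleEigengenes`.
    dendrogram_ : scipy linkage matrix.
    tom_ : TOM DataFrame (kept for downstream edge extraction).
    """

    def __init__(self, beta: int = 3, mode: str = "signed", min_module_size: int = 30,
                 cut_height: float | None = None, merge_height: float = 0.25,
                 reassign_threshold: float | None = 0.3, keep_tom: bool = True):
        self.beta = beta
        self.mode = mode
        self.min_module_size = min_module_size
        self.cut_height = cut_height
        self.merge_height = merge_height
        self.reassign_threshold = reassign_threshold
        self.keep_tom = keep_tom

    def fit(self, X, y=None):
        expr = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X, float))
        S = similarity(expr)
        A = adjacency(S, beta=self.beta, mode=self.mode)
        T = tom(A)
        Z = cluster_genes(T)
        assignment = cut_modules(Z, min_module_size=self.min_module_size,
                                 cut_height=self.cut_height, expr=expr,
                                 reassign_threshold=self.reassign_threshold,
                                 gene_ids=list(expr.index))
        labels = assignment.labels
        if self.merge_height and not labels.eq(GREY).all():
            labels, mes = merge_modules(expr, labels, merge_height=self.merge_height)
        elif not labels.eq(GREY).all():
            mes = module_eigengenes(expr, labels)
        else:
            mes = ModuleEigengenes(values=pd.DataFrame(columns=expr.columns),
                                   variance_explained=pd.Series(dtype=float))
        self.assignment_ = ModuleAssignment(labels=labels, dendrogram=Z,
                                            min_module_size=self.min_module_size,
                                            cut_height=assignment.cut_height)
        self.labels_ = labels.to_numpy()
        self.dendrogram_ = Z
        self.eigengenes_ = mes
        self.tom_ = T if self.keep_tom else None
        self.n_features_in_ = expr.shape[1]
        return self

    def trait_correlation(self, traits: pd.DataFrame) -> ModuleTraitResult:
        """Module-trait correlations of the fitted eigengenes."""
        return module_trait_correlation(self.eigengenes_, traits)
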