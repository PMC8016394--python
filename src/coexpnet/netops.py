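"""Co-expression network extraction, PPI integration, and the per-gene
neighborhood over-representation screen.

The screen asks, for each gene that is both co-expressed (member of the
selected trait-associated modules) and present in a protein-interaction
graph, whether its interaction neighborhood contains more co-expressed
genes than chance: with ``N`` network genes, ``K`` of them co-expressed,
and a gene of degree ``a + b`` of which ``a`` neighbors are co-expressed,
the one-sided p-value is the hypergeometric upper tail
``P(X >= a), X ~ Hypergeom(N, K, a + b)`` (equivalently a one-sided
Fisher exact test on the 2x2 table).  FDR control is Benjamini-Hochberg
across all tested genes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist
from scipy.stats import hypergeom
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from coexpnet.wgcna import GREY

__all__ = [
    "CoexprNetwork",
    "ProfileClusters",
    "NeighborhoodScreen",
    "ProfileClustering",
    "extract_coexpression_edges",
    "read_ppi",
    "network_stats",
    "degree_distribution",
    "fisher_upper_tail",
    "bh_fdr",
    "screen_tumor_specific",
    "cluster_expression_profiles",
    "select_high_abundance_group",
]

log = logging.getLogger(__name__)


@dataclass
class CoexprNetwork:
    """Weighted co-expression network restricted to selected modules."""

    nodes: pd.DataFrame          # columns: gene, module, isolated
    edges: pd.DataFrame          # columns: gene_i, gene_j, weight
    weight_threshold: float

    @property
    def gene_set(self) -> set:
        return set(self.nodes["gene"])


def extract_coexpression_edges(weights: pd.DataFrame, labels: pd.Series,
                               selected_modules, threshold: float = 0.1) -> CoexprNetwork:
    """Edge list of within-selection gene pairs with weight > threshold.

    ``weights`` is a symmetric genes x genes weight matrix (TOM by
    default in the pipeline; adjacency also works).  Genes from the
    selected modules with no surviving edge are retained as isolated
    nodes, flagged.
    """
    if not 0 <= threshold < 1:
        raise ValueError("threshold must lie in [0, 1)")
    selected = list(selected_modules)
    known = set(labels.unique())
    missing = [m for m in selected if m not in known]
    if missing:
        raise ValueError(f"unknown module colors: {missing}")
    genes = [g for g in labels.index if labels[g] in selected and g in weights.index]
    W = weights.loc[genes, genes].to_numpy(float)
    iu = np.triu_indices(len(genes), k=1)
    mask = W[iu] > threshold
    edges = pd.DataFrame({
        "gene_i": np.asarray(genes, object)[iu[0][mask]],
        "gene_j": np.asarray(genes, object)[iu[1][mask]],
        "weight": W[iu][mask],
    })
    connected = set(edges["gene_i"]) | set(edges["gene_j"])
    nodes = pd.DataFrame({
        "gene": genes,
        "module": [labels[g] for g in genes],
        "isolated": [g not in connected for g in genes],
    })
    return CoexprNetwork(nodes=nodes, edges=edges, weight_threshold=float(threshold))


def read_ppi(path, min_confidence: float = 0.0) -> tuple[nx.Graph, dict]:
    """Parse a HIPPIE-style 6-column protein-interaction edge table.

    Columns: symbol_a, entrez_a, symbol_b, entrez_b, confidence,
    annotation.  A header row is auto-detected.  Symbols are uppercased;
    self-loops and duplicate pairs are collapsed; edges below
    ``min_confidence`` are dropped.  Malformed rows are logged and
    skipped; more than 50% malformed is a hard error.

    Returns ``(graph, report)`` with row counts in ``report``.
    """
    graph = nx.Graph()
    report = {"rows_read": 0, "rows_kept": 0, "malformed": 0,
              "self_loops": 0, "duplicates": 0, "low_confidence": 0}
    with open(path) as fh:
        for lineno, line in enumerate(fh):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if lineno == 0 and len(parts) >= 5 and not _is_float(parts[4]):
                continue  # header
            report["rows_read"] += 1
            if len(parts) < 5 or not parts[0].strip() or not parts[2].strip() or not _is_float(parts[4]):
                report["malformed"] += 1
                log.warning("skipping malformed PPI row %d: %r", lineno + 1, line[:80])
                continue
            a, b, conf = parts[0].strip().upper(), parts[2].strip().upper(), float(parts[4])
            if conf < min_confidence:
                report["low_confidence"] += 1
                continue
            if a == b:
                report["self_loops"] += 1
                continue
            if graph.has_edge(a, b):
                report["duplicates"] += 1
                continue
            graph.add_edge(a, b, confidence=conf)
            report["rows_kept"] += 1
    if report["rows_read"] and report["malformed"] > 0.5 * report["rows_read"]:
        raise ValueError(f"more than half of the PPI rows are malformed ({report['malformed']}/{report['rows_read']})")
    return graph, report


def network_stats(graph: nx.Graph, subset=None) -> dict:
    """Node count, mean degree, and subset-internal neighbor statistics."""
    n = graph.number_of_nodes()
    stats = {"n_nodes": n,
             "mean_degree": (2.0 * graph.number_of_edges() / n) if n else 0.0}
    if subset is not None:
        inside = [g for g in subset if g in graph]
        stats["n_subset_in_graph"] = len(inside)
        if inside:
            sset = set(inside)
            internal = [sum(1 for nb in graph.neighbors(g) if nb in sset) for g in inside]
            stats["mean_subset_internal_neighbors"] = float(np.mean(internal))
        else:
            stats["mean_subset_internal_neighbors"] = 0.0
            stats["subset_empty"] = True
    return stats


def degree_distribution(graph: nx.Graph) -> pd.Series:
    """Exact histogram degree -> node count (sums to the node count)."""
    degrees = [d for _, d in graph.degree()]
    counts = pd.Series(degrees, dtype=int).value_counts().sort_index()
    counts.index.name = "degree"
    counts.name = "n_nodes"
    return counts


def fisher_upper_tail(a: int, b: int, K: int, N: int) -> float:
    """One-sided Fisher exact (hypergeometric upper tail) p-value.

    ``P(X >= a)`` for ``X ~ Hypergeom(N, K, a + b)``: the chance of
    drawing at least ``a`` co-expressed genes when sampling the gene's
    ``a + b`` neighbors from a network of ``N`` genes of which ``K``
    are co-expressed.
    """
    a, b, K, N = int(a), int(b), int(K), int(N)
    if a < 0 or b < 0:
        raise ValueError("counts must be non-negative")
    if a > K:
        raise ValueError(f"a={a} exceeds K={K}")
    if a + b > N:
        raise ValueError(f"a+b={a + b} exceeds N={N}")
    if K > N:
        raise ValueError(f"K={K} exceeds N={N}")
    return float(hypergeom.sf(a - 1, N, K, a + b))


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(pvals, float)
    if len(p) == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def screen_tumor_specific(graph: nx.Graph, coexpr, fdr_threshold: float = 0.01,
                          alternative: str = "greater") -> pd.DataFrame:
    """Neighborhood over-representation screen over all co-expressed genes.

    Background ``N`` is the PPI node count and ``K`` the co-expressed
    genes present in the graph.  Every such gene with degree >= 1 is
    tested; rows passing ``fdr < fdr_threshold`` are returned sorted by
    p ascending.  Set ``fdr_threshold=None`` to return all tested rows.

    ``alternative='greater'`` (default) is the enrichment upper tail;
    ``'two-sided'`` is available but changes the published convention.
    """
    screen = NeighborhoodScreen(fdr_threshold=fdr_threshold, alternative=alternative)
    screen.fit(graph, coexpr)
    return screen.significant_ if fdr_threshold is not None else screen.results_


class NeighborhoodScreen(BaseEstimator):
    """Per-gene PPI neighborhood enrichment screen (estimator form).

    Parameters
    ----------
    fdr_threshold : BH-FDR cutoff defining the reported significant set
        (default 0.01).
    alternative : "greater" for the one-sided enrichment test (default)
        or "two-sided".

    Attributes
    ----------
    results_ : DataFrame of all tested genes with columns gene, a, b,
        ratio, K, N, p, fdr (sorted by p).
    significant_ : rows of ``results_`` with fdr < fdr_threshold.
    N_, K_ : background sizes actually used.
    """

    def __init__(self, fdr_threshold: float = 0.01, alternative: str = "greater"):
        self.fdr_threshold = fdr_threshold
        self.alternative = alternative

    def fit(self, graph: nx.Graph, coexpr):
        genes = coexpr.gene_set if isinstance(coexpr, CoexprNetwork) else set(coexpr)
        genes = {str(g).upper() for g in genes}
        nodes = {str(n).upper(): n for n in graph.nodes}
        inter = sorted(g for g in genes if g in nodes)
        if not inter:
            raise ValueError("no co-expressed genes are present in the PPI graph")
        N = graph.number_of_nodes()
        K = len(inter)
        coexpr_nodes = {nodes[g] for g in inter}
        rows = []
        for g in inter:
            node = nodes[g]
            nbrs = list(graph.neighbors(node))
            if not nbrs:
                continue
            a = sum(1 for nb in nbrs if nb in coexpr_nodes)
            b = len(nbrs) - a
            p = fisher_upper_tail(a, b, K, N)
            if self.alternative == "two-sided":
                from scipy.stats import fisher_exact
                p = float(fisher_exact([[a, K - a], [b, N - K - b]], alternative="two-sided")[1])
            elif self.alternative != "greater":
                raise ValueError("alternative must be 'greater' or 'two-sided'")
            rows.append({"gene": g, "a": a, "b": b, "ratio": a / (a + b), "K": K, "N": N, "p": p})
        results = pd.DataFrame(rows)
        results["fdr"] = bh_fdr(results["p"].to_numpy())
        results = results.sort_values(["p", "gene"], kind="mergesort").reset_index(drop=True)
        self.results_ = results
        self.significant_ = results[results["fdr"] < self.fdr_threshold].reset_index(drop=True) \
            if self.fdr_threshold is not None else results
        self.N_, self.K_ = N, K
        return self


@dataclass
class ProfileClusters:
    """Gene and sample classes from expression-profile clustering."""

    gene_class: pd.Series
    sample_class: pd.Series
    high_group: set = field(default_factory=set)


class ProfileClustering(BaseEstimator):
    """Euclidean average-linkage clustering of an expression submatrix.

    Genes are clustered on the Euclidean distance between standardized
    gene profiles into ``n_gene_classes`` classes; samples on the
    Euclidean distance between raw sample columns into
    ``n_sample_classes`` classes.  With exactly two gene classes,
    ``high_group_`` holds the class with the larger mean expression.

    Attributes: ``gene_labels_``, ``sample_labels_``, ``high_group_``,
    ``clusters_`` (a :class:`ProfileClusters`).
    """

    def __init__(self, n_sample_classes: int = 5, n_gene_classes: int = 2):
        self.n_sample_classes = n_sample_classes
        self.n_gene_classes = n_gene_classes

    def fit(self, X, y=None):
        expr = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X, float))
        if expr.empty:
            raise ValueError("empty expression matrix")
        if self.n_gene_classes < 2:
            raise ValueError("n_gene_classes must be >= 2")
        if self.n_gene_classes > expr.shape[0] or self.n_sample_classes > expr.shape[1]:
            raise ValueError("more classes requested than items available")
        G = expr.to_numpy(float)
        sd = G.std(axis=1, ddof=1, keepdims=True)
        sd[sd == 0] = 1.0
        Gs = (G - G.mean(axis=1, keepdims=True)) / sd
        gene_flat = fcluster(linkage(pdist(Gs), method="average"),
                             self.n_gene_classes, criterion="maxclust")
        sample_flat = fcluster(linkage(pdist(G.T), method="average"),
                               self.n_sample_classes, criterion="maxclust")
        self.gene_labels_ = pd.Series(gene_flat, index=expr.index, name="gene_class")
        self.sample_labels_ = pd.Series(sample_flat, index=expr.columns, name="sample_class")
        self.high_group_ = (select_high_abundance_group(expr, self.gene_labels_)
                            if self.n_gene_classes == 2 else set())
        self.clusters_ = ProfileClusters(gene_class=self.gene_labels_,
                                         sample_class=self.sample_labels_,
                                         high_group=self.high_group_)
        return self


def cluster_expression_profiles(expr_subset: pd.DataFrame, n_sample_classes: int = 5,
                                n_gene_classes: int = 2) -> ProfileClusters:
    """Functional wrapper over :class:`ProfileClustering`."""
    return ProfileClustering(n_sample_classes=n_sample_classes,
                             n_gene_classes=n_gene_classes).fit(expr_subset).clusters_


def select_high_abundance_group(expr_subset: pd.DataFrame, gene_class: pd.Series) -> set:
    """Return the gene class with the larger mean expression (of two).

    An exact tie is broken deterministically toward the class containing
    the lexicographically smallest gene id, with a warning.
    """
    classes = sorted(gene_class.unique())
    if len(classes) != 2:
        raise ValueError(f"expected exactly 2 gene classes, got {len(classes)}")
    means = {c: float(expr_subset.loc[gene_class.index[gene_class == c]].to_numpy().mean())
             for c in classes}
    if means[classes[0]] == means[classes[1]]:
        warnings.warn("gene classes tie on mean expression; breaking tie lexicographically",
                      stacklevel=2)
        winner = min(classes, key=lambda c: min(gene_class.index[gene_class == c]))
    else:
        winner = max(classes, key=lambda c: means[c])
    return set(gene_class.index[gene_class == winner])


def _is_float(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False
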