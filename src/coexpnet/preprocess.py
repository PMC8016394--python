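"""Probe collapsing, coefficient-of-variation screening, and trait design matrices."""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd

__all__ = ["STAGES", "collapse_probes", "compute_cv", "filter_by_cv", "build_trait_matrix"]

#: fixed ordinal disease-stage vocabulary, normal tissue through invasive tumor
STAGES = ("normal", "CIN1", "CIN2", "CIN3", "tumor")


def collapse_probes(probe_matrix: pd.DataFrame, probe_map: pd.DataFrame) -> pd.DataFrame:
    """Collapse a probes x samples matrix to genes by per-gene median.

    Probes absent from ``probe_map`` ("idle" probes with no gene
    annotation) are dropped.  For genes measured by several probes the
    per-sample median across those probes is used.  Collapsing an
    already gene-level matrix through an identity map is a no-op.

    Parameters
    ----------
    probe_matrix : DataFrame, probes x samples.
    probe_map : DataFrame with columns ``probe`` and ``gene``.
    """
    if not {"probe", "gene"} <= set(probe_map.columns):
        raise ValueError("probe_map needs 'probe' and 'gene' columns")
    mapped = probe_map[probe_map["probe"].isin(probe_matrix.index)]
    if mapped.empty:
        raise ValueError("no probes in the matrix are covered by the probe map")
    sub = probe_matrix.loc[mapped["probe"]]
    collapsed = sub.groupby(mapped["gene"].to_numpy()).median()
    collapsed.index.name = "gene"
    return collapsed


def compute_cv(expr: pd.DataFrame) -> pd.DataFrame:
    """Per-gene mean, sample SD (n-1), and coefficient of variation sd/mean.

    Genes with non-positive mean get ``flagged=True`` and no rank: a CV
    is not meaningful there, which is a property of the data rather than
    an error.  Ranks are descending in CV, ties broken lexicographically
    by gene id for determinism.
    """
    if expr.shape[1] < 2:
        raise ValueError("need at least 2 samples to compute a CV")
    mean = expr.mean(axis=1)
    sd = expr.std(axis=1, ddof=1)
    cv = sd / mean
    table = pd.DataFrame({"mean": mean, "sd": sd, "cv": cv})
    table["flagged"] = table["mean"] <= 0
    table.loc[table["flagged"], "cv"] = np.nan
    ranked = table.loc[~table["flagged"]]
    order = sorted(ranked.index, key=lambda g: (-ranked.at[g, "cv"], g))
    table["rank"] = pd.Series({g: i + 1 for i, g in enumerate(order)}, dtype="Int64")
    table.index.name = "gene"
    return table


def filter_by_cv(expr: pd.DataFrame, cv_table: pd.DataFrame | None = None,
                 keep_fraction: float = 0.5) -> pd.DataFrame:
    """Keep the top ``keep_fraction`` of ranked genes by CV.

    Retains ``ceil(keep_fraction * n_ranked)`` genes; flagged
    (non-positive-mean) genes are never retained.  Row order of the
    output follows the input matrix.
    """
    if not 0 < keep_fraction <= 1:
        raise ValueError("keep_fraction must lie in (0, 1]")
    if cv_table is None:
        cv_table = compute_cv(expr)
    ranked = cv_table[cv_table["rank"].notna()]
    n_keep = math.ceil(keep_fraction * len(ranked))
    keep = set(ranked[ranked["rank"] <= n_keep].index)
    return expr.loc[[g for g in expr.index if g in keep]]


def build_trait_matrix(stage_of_sample: pd.Series) -> pd.DataFrame:
    """Samples x traits design matrix from ordinal stage labels.

    One binary indicator column per stage plus an ordinal
    ``progression`` column (0 = normal ... 4 = tumor).  A stage with no
    variation across samples is a degenerate trait; it is kept (the
    correlation stage flags it) but a warning is emitted.
    """
    stage_of_sample = pd.Series(stage_of_sample)
    bad = stage_of_sample[~stage_of_sample.isin(STAGES)]
    if not bad.empty:
        sample, label = next(iter(bad.items()))
        raise ValueError(f"unknown stage label {label!r} for sample {sample!r}")
    # copy the index: naming a shared Index in place would leak into the
    # caller's expression matrix columns
    traits = pd.DataFrame(index=stage_of_sample.index.copy())
    for stage in STAGES:
        traits[stage] = (stage_of_sample == stage).astype(int)
    traits["progression"] = stage_of_sample.map({s: i for i, s in enumerate(STAGES)}).astype(int)
    constant = [s for s in STAGES if traits[s].nunique() == 1]
    if constant:
        warnings.warn(f"degenerate (constant) trait columns: {constant}", stacklevel=2)
    traits.index.name = "sample"
    return traits
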