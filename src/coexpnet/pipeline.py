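"""End-to-end orchestration: preprocess -> WGCNA -> module selection ->
network screen -> ORA -> prognosis, from a single validated config.

Every stage writes its artifacts into a per-stage subdirectory of the
output directory, and a machine-readable ``summary.json`` records the
record counts flowing through the pipeline.  Reruns with identical
config and inputs reproduce identical outputs (timestamps aside).
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from importlib.metadata import version as _pkg_version

try:
    _version = _pkg_version("coexpnet")
except Exception:  # editable installs before metadata exists
    _version = "0.1.0"
from coexpnet.netops import NeighborhoodScreen, ProfileClustering, extract_coexpression_edges, read_ppi
from coexpnet.ora import ora_test, read_gmt
from coexpnet.preprocess import build_trait_matrix, collapse_probes, compute_cv, filter_by_cv
from coexpnet.prognosis import CoxScreen, LassoCoxCV, km_logrank, normalize_reference, zscore_genes
from coexpnet.wgcna import GREY, WGCNA, ModuleTraitResult

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "select_modules"]

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """Stage-tagged pipeline failure."""

    def __init__(self, stage: str, cause: str):
        super().__init__(f"[{stage}] {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Input paths and per-stage parameters for a full run."""

    expression: str = ""
    stages: str = ""
    probe_map: str = ""
    ppi: str = ""
    gmt: str = ""
    survival: str = ""

    keep_fraction: float = 0.5
    beta: int = 3
    mode: str = "signed"
    min_module_size: int = 30
    merge_height: float = 0.25
    edge_threshold: float = 0.1
    edge_weight: str = "tom"          # "tom" or "adjacency"
    top_k_modules: int = 3
    fdr_threshold: float = 0.01
    n_sample_classes: int = 5
    reference_gene: str = ""
    alpha: float = 0.05
    n_folds: int = 10
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        flat = {**raw.get("inputs", {}), **raw.get("params", {})}
        unknown = set(flat) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**flat)

    def validate(self) -> None:
        for name in ("expression", "stages", "ppi"):
            p = getattr(self, name)
            if not p:
                raise ValueError(f"required input path {name!r} missing")
            if not Path(p).exists():
                raise ValueError(f"{name} file not found: {p}")
        for name in ("probe_map", "gmt", "survival"):
            p = getattr(self, name)
            if p and not Path(p).exists():
                raise ValueError(f"{name} file not found: {p}")
        if not 0 < self.keep_fraction <= 1:
            raise ValueError("keep_fraction must lie in (0, 1]")
        if not 0 <= self.edge_threshold < 1:
            raise ValueError("edge_threshold must lie in [0, 1)")
        if self.edge_weight not in ("tom", "adjacency"):
            raise ValueError("edge_weight must be 'tom' or 'adjacency'")
        if self.top_k_modules < 1:
            raise ValueError("top_k_modules must be >= 1")


def select_modules(mt: ModuleTraitResult, trait: str, k: int) -> list:
    """Top-k module colors by |r| against the named trait (grey excluded).

    Ties break toward the smaller p-value, then the color name.  If
    fewer than k modules exist, all are returned with a warning.
    """
    if trait not in mt.r.columns:
        raise ValueError(f"trait {trait!r} not in module-trait table")
    if k < 1:
        raise ValueError("k must be >= 1")
    rows = [(abs(mt.r.at[m, trait]), -mt.p.at[m, trait], m)
            for m in mt.r.index if m != GREY]
    rows.sort(key=lambda t: (-t[0], -t[1], t[2]))
    if k > len(rows):
        log.warning("requested top %d modules but only %d exist", k, len(rows))
    return [m for _, _, m in rows[:k]]


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Execute the full analysis; returns the run summary dict."""
    t0 = time.time()
    try:
        config.validate()
    except ValueError as exc:
        raise PipelineError("validate", str(exc)) from exc
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"version": _version, "params": asdict(config), "stages": {}}

    # ---- preprocess -------------------------------------------------------
    stage = "preprocess"
    try:
        expr = pd.read_csv(config.expression, sep="\t", index_col=0)
        stage_labels = pd.read_csv(config.stages, sep="\t", index_col=0)["stage"]
        if config.probe_map:
            probe_map = pd.read_csv(config.probe_map, sep="\t")
            expr = collapse_probes(expr, probe_map)
        n_in = expr.shape[0]
        cv = compute_cv(expr)
        expr = filter_by_cv(expr, cv, keep_fraction=config.keep_fraction)
        traits = build_trait_matrix(stage_labels.loc[expr.columns])
        sdir = out / stage
        sdir.mkdir(exist_ok=True)
        cv.to_csv(sdir / "cv_table.tsv", sep="\t")
        expr.to_csv(sdir / "expression_filtered.tsv", sep="\t")
        traits.to_csv(sdir / "traits.tsv", sep="\t")
        summary["stages"][stage] = {"genes_in": int(n_in), "genes_out": int(expr.shape[0]),
                                    "samples": int(expr.shape[1])}
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # ---- wgcna ------------------------------------------------------------
    stage = "wgcna"
    try:
        model = WGCNA(beta=config.beta, mode=config.mode,
                      min_module_size=config.min_module_size,
                      merge_height=config.merge_height)
        model.fit(expr)
        mt = model.trait_correlation(traits)
        selected = select_modules(mt, "progression", config.top_k_modules)
        sdir = out / stage
        sdir.mkdir(exist_ok=True)
        model.assignment_.labels.to_csv(sdir / "module_assignment.tsv", sep="\t")
        model.eigengenes_.values.to_csv(sdir / "module_eigengenes.tsv", sep="\t")
        mt.r.to_csv(sdir / "module_trait_r.tsv", sep="\t")
        mt.p.to_csv(sdir / "module_trait_p.tsv", sep="\t")
        (sdir / "selected_modules.txt").write_text("\n".join(selected) + "\n")
        labels = model.assignment_.labels
        summary["stages"][stage] = {
            "modules": int(labels[labels != GREY].nunique()),
            "grey_genes": int((labels == GREY).sum()),
            "selected_modules": selected,
        }
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # ---- netops -----------------------------------------------------------
    stage = "netops"
    try:
        weights = model.tom_ if config.edge_weight == "tom" else None
        if weights is None:
            from coexpnet.wgcna import adjacency, similarity
            weights = adjacency(similarity(expr), beta=config.beta, mode=config.mode)
        net = extract_coexpression_edges(weights, labels, selected, threshold=config.edge_threshold)
        graph, ppi_report = read_ppi(config.ppi)
        screen = NeighborhoodScreen(fdr_threshold=config.fdr_threshold)
        screen.fit(graph, net)
        hits = list(screen.significant_["gene"])
        sdir = out / stage
        sdir.mkdir(exist_ok=True)
        net.edges.to_csv(sdir / "coexpression_edges.tsv", sep="\t", index=False)
        net.nodes.to_csv(sdir / "coexpression_nodes.tsv", sep="\t", index=False)
        screen.results_.to_csv(sdir / "neighborhood_screen.tsv", sep="\t", index=False)
        screen.significant_.to_csv(sdir / "tumor_specific_genes.tsv", sep="\t", index=False)
        summary["stages"][stage] = {
            "network_genes": int(net.nodes.shape[0]), "edges": int(net.edges.shape[0]),
            "ppi_nodes": int(graph.number_of_nodes()), "ppi_rows_kept": ppi_report["rows_kept"],
            "genes_tested": int(screen.results_.shape[0]), "genes_significant": len(hits),
        }
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # ---- ora (optional) ---------------------------------------------------
    if config.gmt:
        stage = "ora"
        try:
            collection = read_gmt(config.gmt)
            table = ora_test(hits, collection, universe=set(expr.index)) if hits else pd.DataFrame()
            sdir = out / stage
            sdir.mkdir(exist_ok=True)
            table.to_csv(sdir / "ora.tsv", sep="\t", index=False)
            summary["stages"][stage] = {"sets": len(collection), "rows": int(table.shape[0])}
        except Exception as exc:
            raise PipelineError(stage, str(exc)) from exc

    # ---- profile clustering ----------------------------------------------
    stage = "profiles"
    try:
        high_group: list = []
        if len(hits) >= 2:
            sub = expr.loc[[g for g in expr.index if str(g).upper() in set(hits)]]
            pc = ProfileClustering(n_sample_classes=min(config.n_sample_classes, sub.shape[1]))
            pc.fit(sub)
            high_group = sorted(pc.high_group_)
            sdir = out / stage
            sdir.mkdir(exist_ok=True)
            pc.gene_labels_.to_csv(sdir / "gene_classes.tsv", sep="\t")
            pc.sample_labels_.to_csv(sdir / "sample_classes.tsv", sep="\t")
            (sdir / "high_group.txt").write_text("\n".join(high_group) + "\n")
        summary["stages"][stage] = {"high_group_genes": len(high_group)}
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # ---- prognosis (optional) --------------------------------------------
    if config.survival:
        stage = "prognosis"
        try:
            surv = pd.read_csv(config.survival, sep="\t")
            surv = surv.set_index("sample")
            candidates = high_group if high_group else hits
            sub = expr.loc[[g for g in expr.index if g in set(candidates)]]
            if config.reference_gene:
                sub = normalize_reference(sub, config.reference_gene)
            sub = zscore_genes(sub)
            sdir = out / stage
            sdir.mkdir(exist_ok=True)
            screen_cox = CoxScreen(alpha=config.alpha)
            screen_cox.fit(sub.T.loc[surv.index], surv)
            screen_cox.results_.to_csv(sdir / "univariate_cox.tsv", sep="\t", index=False)
            selected_genes = screen_cox.selected_
            km_rows = []
            for g in selected_genes:
                p, sizes, _ = km_logrank(sub.T[g], surv)
                km_rows.append({"gene": g, "logrank_p": p, **sizes})
            pd.DataFrame(km_rows).to_csv(sdir / "km_logrank.tsv", sep="\t", index=False)
            signature: dict = {}
            if len(selected_genes) >= 2:
                lcv = LassoCoxCV(n_folds=config.n_folds, random_state=config.seed)
                lcv.fit(sub.T.loc[surv.index, selected_genes], surv)
                signature = {g: float(c) for g, c in lcv.coef_.items() if c != 0}
                pd.DataFrame({"lambda": lcv.alphas_, "cv_deviance": lcv.cv_deviance_,
                              "cv_deviance_se": lcv.cv_deviance_se_}).to_csv(
                    sdir / "lasso_path.tsv", sep="\t", index=False)
                (sdir / "signature.json").write_text(json.dumps(
                    {"lambda_opt": lcv.alpha_opt_, "coefficients": signature}, indent=1))
            summary["stages"][stage] = {"candidates": int(sub.shape[0]),
                                        "cox_selected": len(selected_genes),
                                        "signature_genes": len(signature)}
        except Exception as exc:
            raise PipelineError(stage, str(exc)) from exc

    summary["wall_seconds"] = round(time.time() - t0, 3)
    (out / "summary.json").write_text(json.dumps(summary, indent=1, default=str))
    return summary
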