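"""Synthetic data generation for staged co-expression / PPI / survival analyses.

The generator emulates the statistical structure a staged tumor
co-expression study assumes:

* an expression matrix whose genes fall into block-correlated modules,
  each driven by a latent eigengene that trends with an ordinal disease
  stage (normal -> CIN1 -> CIN2 -> CIN3 -> tumor);
* a probe-level view of that matrix (several jittered probes per gene,
  plus unannotated "idle" probes) to exercise probe collapsing;
* a scale-free (preferential-attachment) protein-interaction graph in
  which a planted gene set can be over-represented in the neighborhoods
  of chosen genes;
* proportional-hazards survival times driven by a few genes, with
  independent uniform censoring calibrated to a target censoring rate.

Every generator is deterministic for a fixed :class:`SynthConfig`;
sub-generators draw from independently derived child streams so that,
for example, requesting probe tables never perturbs the expression draw.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from coexpnet.preprocess import STAGES

__all__ = [
    "SynthConfig",
    "SynthTruth",
    "generate_expression",
    "generate_probe_table",
    "generate_ppi",
    "generate_survival",
    "write_expression",
    "write_ppi",
    "write_survival",
]

# fixed sub-stream tags so adding one generator never shifts another
_STREAM = {"expr": 1, "probe": 2, "ppi": 3, "surv": 4}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((int(seed), _STREAM[stream])))


@dataclass
class SynthConfig:
    """Study-design parameters for the synthetic cohort.

    Defaults describe a scaled-down staged cervical-lesion cohort: 100
    samples spread over the five ordinal stages in roughly the
    proportions seen in staged lesion series, three co-expression
    modules of 60 genes plus 60 unstructured background genes, and a
    preferential-attachment interaction graph whose mean degree (~20)
    matches large curated human PPI networks.

    ``stage_effect`` holds one slope per module: the latent module
    eigengene is ``slope * z(stage) + N(0, 1)`` with the ordinal stage
    standardized, so a slope of 1.0 gives an eigengene-stage correlation
    of about 0.7.  Mixed signs (some modules rise with progression, some
    fall) mirror the red/green split of real module-trait heatmaps and
    keep modules mutually distinguishable.
    """

    n_samples: int = 100
    n_genes: int = 240
    n_modules: int = 3
    module_sizes: tuple[int, ...] = (60, 60, 60)
    stage_counts: tuple[int, int, int, int, int] = (19, 11, 17, 31, 22)
    stage_effect: tuple[float, ...] = (1.0, -0.8, 0.6)
    noise_sd: float = 0.3
    loading_range: tuple[float, float] = (0.5, 1.0)
    mixed_sign_loadings: bool = False
    baseline_range: tuple[float, float] = (4.0, 12.0)
    min_probes_per_gene: int = 1
    max_probes_per_gene: int = 3
    probe_jitter_sd: float = 0.1
    n_idle_probes: int = 10
    ppi_n_nodes: int = 2000
    ppi_attach: int = 10
    planted_set_size: int = 40
    planted_enrichment: float = 4.0
    n_enriched_genes: int = 30
    surv_effect_genes: dict = field(default_factory=dict)
    censor_rate: float = 0.2
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples <= 0 or self.n_genes <= 0 or self.n_modules <= 0:
            raise ValueError("counts must be positive")
        if len(self.module_sizes) != self.n_modules:
            raise ValueError(
                f"module_sizes has {len(self.module_sizes)} entries for n_modules={self.n_modules}"
            )
        if any(m <= 0 for m in self.module_sizes):
            raise ValueError("module sizes must be positive")
        if sum(self.module_sizes) > self.n_genes:
            raise ValueError(
                f"sum(module_sizes)={sum(self.module_sizes)} exceeds n_genes={self.n_genes}"
            )
        if len(self.stage_counts) != len(STAGES):
            raise ValueError(f"stage_counts must have {len(STAGES)} entries")
        if sum(self.stage_counts) != self.n_samples:
            raise ValueError(
                f"sum(stage_counts)={sum(self.stage_counts)} != n_samples={self.n_samples}"
            )
        if len(self.stage_effect) != self.n_modules:
            raise ValueError("stage_effect must have one entry per module")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if not 0 <= self.censor_rate < 1:
            raise ValueError("censor_rate must lie in [0, 1)")
        if self.planted_enrichment < 1:
            raise ValueError("planted_enrichment must be >= 1")
        if not 1 <= self.min_probes_per_gene <= self.max_probes_per_gene:
            raise ValueError("need 1 <= min_probes_per_gene <= max_probes_per_gene")

    def replace(self, **kw) -> "SynthConfig":
        return replace(self, **kw)


@dataclass
class SynthTruth:
    """Ground truth emitted alongside the synthetic data."""

    true_module_of_gene: dict[str, int]
    eigengene_profiles: pd.DataFrame  # modules x samples
    planted_ppi_set: set = field(default_factory=set)
    surv_coefficients: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        payload = {
            "true_module_of_gene": self.true_module_of_gene,
            "eigengene_profiles": self.eigengene_profiles.to_dict(),
            "planted_ppi_set": sorted(self.planted_ppi_set),
            "surv_coefficients": self.surv_coefficients,
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def stage_labels(config: SynthConfig) -> pd.Series:
    """Per-sample ordinal stage labels in fixed stage order."""
    samples = [f"S{i + 1:03d}" for i in range(config.n_samples)]
    labels = np.repeat(list(STAGES), config.stage_counts)
    return pd.Series(labels, index=samples, name="stage")


def generate_expression(config: SynthConfig) -> tuple[pd.DataFrame, pd.Series, SynthTruth]:
    """Simulate a modular genes x samples expression matrix.

    Module ``m`` is driven by a latent eigengene
    ``e_m = stage_effect[m] * z(stage) + N(0, 1)``; each member gene is
    ``baseline + loading * e_m + N(0, noise_sd)`` with loadings drawn
    uniform over ``loading_range`` (all positive unless
    ``mixed_sign_loadings``) and a per-gene abundance baseline drawn
    uniform over ``baseline_range``.  Genes beyond the modules are
    baseline plus standard-normal noise.

    Returns ``(expr, stages, truth)`` where ``expr`` is genes x samples.
    """
    config.validate()
    rng = _rng(config.seed, "expr")
    stages = stage_labels(config)
    ordinal = stages.map({s: i for i, s in enumerate(STAGES)}).to_numpy(float)
    z = (ordinal - ordinal.mean()) / ordinal.std(ddof=1)

    blocks, truth_map, eigs = [], {}, []
    gidx = 0
    for m, size in enumerate(config.module_sizes):
        e = config.stage_effect[m] * z + rng.normal(0.0, 1.0, config.n_samples)
        eigs.append(e)
        loadings = rng.uniform(*config.loading_range, size)
        if config.mixed_sign_loadings:
            loadings *= rng.choice([-1.0, 1.0], size)
        blocks.append(loadings[:, None] * e[None, :] + rng.normal(0.0, config.noise_sd, (size, config.n_samples)))
        for _ in range(size):
            truth_map[f"G{gidx + 1:04d}"] = m
            gidx += 1
    n_bg = config.n_genes - sum(config.module_sizes)
    if n_bg:
        blocks.append(rng.normal(0.0, 1.0, (n_bg, config.n_samples)))
        gidx += n_bg

    genes = [f"G{i + 1:04d}" for i in range(config.n_genes)]
    values = np.vstack(blocks)
    # per-gene abundance baseline: log-scale intensities are positive, which
    # keeps the coefficient of variation meaningful downstream
    values = values + rng.uniform(*config.baseline_range, config.n_genes)[:, None]
    expr = pd.DataFrame(values, index=genes, columns=stages.index)
    expr.index.name = "gene"
    eig_df = pd.DataFrame(np.vstack(eigs), index=[f"module{m}" for m in range(config.n_modules)], columns=stages.index)
    return expr, stages, SynthTruth(true_module_of_gene=truth_map, eigengene_profiles=eig_df)


def generate_probe_table(expr: pd.DataFrame, config: SynthConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Expand a gene-level matrix into jittered probe rows plus idle probes.

    Each gene emits between ``min_probes_per_gene`` and
    ``max_probes_per_gene`` probe rows equal to the gene row plus
    ``N(0, probe_jitter_sd)`` jitter.  ``n_idle_probes`` additional rows
    carry no gene annotation (they appear in the matrix but not in the
    probe map), exercising idle-probe removal downstream.

    Returns ``(probe_matrix, probe_map)`` with ``probe_map`` columns
    ``probe`` and ``gene``.
    """
    if expr.empty:
        raise ValueError("expression matrix is empty")
    rng = _rng(config.seed, "probe")
    rows, probe_ids, mapping = [], [], []
    for gene, values in expr.iterrows():
        n_probes = int(rng.integers(config.min_probes_per_gene, config.max_probes_per_gene + 1))
        for p in range(n_probes):
            pid = f"{gene}_p{p + 1}"
            rows.append(values.to_numpy() + rng.normal(0.0, config.probe_jitter_sd, expr.shape[1])
                        if config.probe_jitter_sd > 0 else values.to_numpy())
            probe_ids.append(pid)
            mapping.append((pid, gene))
    for i in range(config.n_idle_probes):
        rows.append(rng.normal(0.0, 1.0, expr.shape[1]))
        probe_ids.append(f"IDLE_p{i + 1}")
    probe_matrix = pd.DataFrame(np.vstack(rows), index=probe_ids, columns=expr.columns)
    probe_matrix.index.name = "probe"
    probe_map = pd.DataFrame(mapping, columns=["probe", "gene"])
    return probe_matrix, probe_map


def generate_ppi(config: SynthConfig, coexpr_set) -> tuple[nx.Graph, set]:
    """Simulate a scale-free PPI graph with optional planted enrichment.

    A Barabasi-Albert graph on ``ppi_n_nodes`` nodes is built with
    ``ppi_attach`` edges per arriving node; a random subset of nodes is
    relabeled with the supplied co-expressed gene ids (the rest become
    anonymous proteins).  A planted subset of the co-expressed genes of
    size ``planted_set_size`` is chosen, and for the
    ``n_enriched_genes`` highest-degree co-expressed genes outside the
    planted set, each incident edge is rewired to a random planted
    member with probability ``1 - 1/planted_enrichment``.  At
    ``planted_enrichment == 1`` no rewiring occurs and the graph is an
    exchangeable null for the neighborhood screen.

    Returns ``(graph, planted_set)``.
    """
    config.validate()
    coexpr = sorted(set(coexpr_set))
    if len(coexpr) > config.ppi_n_nodes:
        raise ValueError("coexpr_set larger than the graph")
    if config.planted_set_size > len(coexpr):
        raise ValueError(
            f"planted_set_size={config.planted_set_size} exceeds |coexpr_set|={len(coexpr)}"
        )
    rng = _rng(config.seed, "ppi")
    g0 = nx.barabasi_albert_graph(config.ppi_n_nodes, config.ppi_attach, seed=int(rng.integers(2**31)))
    # scatter co-expressed genes uniformly over the node set
    slots = rng.choice(config.ppi_n_nodes, size=len(coexpr), replace=False)
    names = {int(s): g for s, g in zip(slots, coexpr)}
    mapping = {n: names.get(n, f"P{n + 1:05d}") for n in g0.nodes}
    graph = nx.relabel_nodes(g0, mapping)

    planted = set(rng.choice(coexpr, size=config.planted_set_size, replace=False).tolist())
    q = 1.0 - 1.0 / config.planted_enrichment
    enriched: list = []
    if q > 0:
        planted_list = sorted(planted)
        candidates = [g for g in coexpr if g not in planted]
        candidates.sort(key=lambda g: (-graph.degree(g), g))
        enriched = candidates[: config.n_enriched_genes]
        for gene in enriched:
            for nbr in sorted(graph.neighbors(gene)):
                if nbr in planted or rng.random() >= q:
                    continue
                new = planted_list[int(rng.integers(len(planted_list)))]
                if new == gene or graph.has_edge(gene, new):
                    continue
                graph.remove_edge(gene, nbr)
                graph.add_edge(gene, new)
    graph.remove_edges_from(nx.selfloop_edges(graph))
    graph.graph["enriched_genes"] = enriched
    return graph, planted


def generate_survival(expr: pd.DataFrame, config: SynthConfig) -> pd.DataFrame:
    """Simulate proportional-hazards survival times from expression.

    The log-hazard of sample ``s`` is ``sum_g beta_g * z(expr_g)[s]``
    over ``surv_effect_genes``; event times are exponential with that
    hazard.  Censoring is independent uniform on ``[0, T_max]`` with
    ``T_max`` calibrated by bisection so the expected censored fraction
    is ``censor_rate`` (+/- 0.02 in expectation).

    Returns a DataFrame with columns ``sample``, ``time``, ``event``.
    """
    config.validate()
    unknown = [g for g in config.surv_effect_genes if g not in expr.index]
    if unknown:
        raise ValueError(f"survival effect genes not in expression matrix: {unknown}")
    rng = _rng(config.seed, "surv")
    n = expr.shape[1]
    eta = np.zeros(n)
    for gene, beta in config.surv_effect_genes.items():
        v = expr.loc[gene].to_numpy(float)
        eta += float(beta) * (v - v.mean()) / v.std(ddof=1)
    times = rng.exponential(1.0 / np.exp(eta))
    if config.censor_rate > 0:
        t_max = _calibrate_censoring(times, config.censor_rate)
        cens = rng.uniform(0.0, t_max, n)
        event = (times <= cens).astype(int)
        obs = np.minimum(times, cens)
    else:
        event = np.ones(n, dtype=int)
        obs = times
    return pd.DataFrame({"sample": expr.columns, "time": obs, "event": event})


def _calibrate_censoring(times: np.ndarray, rate: float) -> float:
    """Bisect T_max so that E[fraction censored] ~= rate for C ~ U(0, T_max)."""
    lo, hi = 1e-12, float(times.max()) * 1e6
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        frac = float(np.minimum(times / mid, 1.0).mean())  # P(C < T) given T
        if frac > rate:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# serialization helpers (TSV carriers shared with the rest of the pipeline)

def write_expression(expr: pd.DataFrame, stages: pd.Series, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    expr.to_csv(out / "expression.tsv", sep="\t")
    stages.rename("stage").to_csv(out / "stages.tsv", sep="\t", index_label="sample")


def write_ppi(graph: nx.Graph, path) -> None:
    """Write a graph as a HIPPIE-style 6-column TSV edge table."""
    with open(path, "w") as fh:
        fh.write("symbol_a\tentrez_a\tsymbol_b\tentrez_b\tconfidence\tannotation\n")
        for i, (u, v) in enumerate(sorted(graph.edges())):
            fh.write(f"{u}\t{i * 2 + 1}\t{v}\t{i * 2 + 2}\t0.9\tsynthetic\n")


def write_survival(surv: pd.DataFrame, path) -> None:
    surv.to_csv(path, sep="\t", index=False)
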