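"""End-to-end orchestration: config, stage functions, and the full pipeline run.

The pipeline runs data loading -> background PPIN -> DEN extraction ->
topology scoring and ego-gene selection -> greedy module growth and
filtering -> permutation significance -> pathway enrichment, writing every
result table plus a structured run summary with before/after counts at each
filter.  Each stage is also exposed as a function operating on the previous
stage's serialized outputs, so runs can be resumed or inspected stage by
stage; because all intermediate files are written at full float precision,
the stage-wise and in-memory paths produce identical results.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import data_io
from .data_io import ExpressionDataset, InteractionNetwork, PathwayCollection
from .enrichment import (
    EnrichmentResult,
    build_background_pathways,
    fisher_enrichment,
)
from .ego_scoring import NodeScoreTable, select_ego_genes, topology_scores
from .errors import ValidationError
from .module_search import (
    CandidateModule,
    EgoModule,
    expand_ego,
    filter_modules,
)
from .network_construction import (
    DifferentialNetwork,
    build_background_ppin,
    edge_statistics,
    extract_den,
)
from .significance import bh_adjust, call_significant, permutation_test
from .synthetic_data import SyntheticConfig, generate_dataset, write_fixture

logger = logging.getLogger(__name__)


@dataclass
class Thresholds:
    """Every filter threshold of the pipeline, with the study defaults."""

    pcc: float = 0.8
    edge_p: float = 0.05
    ego_fraction: float = 0.05
    auc: float = 0.8
    min_module_size: int = 4
    perm_b: int = 1000
    alpha: float = 0.05
    pathway_min: int = 5
    pathway_max: int = 100
    size_cap: int = 30
    drop_tol_pairs: int = 1

    def validate(self) -> None:
        if not (0.0 <= self.pcc <= 1.0):
            raise ValidationError("pcc threshold must be in [0, 1]")
        if not (0.0 < self.edge_p <= 1.0):
            raise ValidationError("edge_p must be in (0, 1]")
        if not (0.0 < self.ego_fraction <= 1.0):
            raise ValidationError("ego_fraction must be in (0, 1]")
        if not (0.0 <= self.auc <= 1.0):
            raise ValidationError("auc threshold must be in [0, 1]")
        if self.min_module_size < 1:
            raise ValidationError("min_module_size must be >= 1")
        if self.perm_b < 1:
            raise ValidationError("perm_b must be >= 1")
        if not (0.0 < self.alpha < 1.0):
            raise ValidationError("alpha must be in (0, 1)")
        if self.pathway_min < 1 or self.pathway_max < self.pathway_min:
            raise ValidationError("invalid pathway size bounds")
        if self.size_cap < 1:
            raise ValidationError("size_cap must be >= 1")
        if self.drop_tol_pairs < 0:
            raise ValidationError("drop_tol_pairs must be >= 0")


@dataclass
class RunConfig:
    """Full run configuration: either file inputs or a synthetic generator block."""

    inputs: dict[str, str] | None = None  # expression, labels, edges, gmt
    synthetic: SyntheticConfig | None = None
    thresholds: Thresholds = field(default_factory=Thresholds)
    seed: int = 0
    out_dir: str = "egonet_results"

    def validate(self) -> None:
        if (self.inputs is None) == (self.synthetic is None):
            raise ValidationError(
                "exactly one of 'inputs' and 'synthetic' must be specified"
            )
        if self.inputs is not None:
            missing = {"expression", "labels", "edges", "gmt"} - set(self.inputs)
            if missing:
                raise ValidationError(f"inputs block missing keys: {sorted(missing)}")
        else:
            self.synthetic.validate()
        self.thresholds.validate()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {"inputs", "synthetic", "thresholds", "seed", "out"}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(
            inputs=raw.get("inputs"),
            synthetic=SyntheticConfig(**raw["synthetic"]) if "synthetic" in raw else None,
            thresholds=Thresholds(**raw.get("thresholds", {})),
            seed=int(raw.get("seed", 0)),
            out_dir=str(raw.get("out", "egonet_results")),
        )
        cfg.validate()
        return cfg


@dataclass
class RunReport:
    """Stage-by-stage counts plus the output manifest of one pipeline run."""

    counts: dict[str, int]
    ego_genes: list[str]
    modules: list[EgoModule]
    enrichment: list[EnrichmentResult]
    out_dir: Path


def stage_seed(seed: int, stage: int, index: int = 0) -> int:
    """Fan a global seed out to independent per-stage (and per-item) child seeds."""
    ss = np.random.SeedSequence((int(seed), int(stage), int(index)))
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


# ---------------------------------------------------------------------------
# Input materialization
# ---------------------------------------------------------------------------


def materialize_inputs(config: RunConfig) -> tuple[ExpressionDataset, InteractionNetwork, PathwayCollection]:
    """Load file inputs, or generate (and persist) the synthetic fixture."""
    if config.synthetic is not None:
        syn = dataclasses.replace(config.synthetic)
        expr, net, pathways, truth = generate_dataset(syn)
        write_fixture(expr, net, pathways, truth, config.out_dir, config=syn)
        return expr, net, pathways
    paths = config.inputs
    expr = data_io.read_expression(paths["expression"], paths["labels"])
    net = data_io.read_edgelist(paths["edges"])
    pathways = data_io.read_gmt(paths["gmt"])
    return expr, net, pathways


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------


def run_network_stage(
    expr: ExpressionDataset, net: InteractionNetwork, config: RunConfig
) -> tuple[InteractionNetwork, DifferentialNetwork]:
    background = build_background_ppin(expr, net)
    stats = edge_statistics(expr, background)
    den = extract_den(stats, config.thresholds.pcc, config.thresholds.edge_p)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    data_io.write_edgelist(den.network, out / "den_edges.tsv")
    (out / "background_nodes.txt").write_text(
        "".join(f"{g}\n" for g in sorted(background.nodes))
    )
    (out / "network_summary.json").write_text(
        json.dumps(
            {
                "background_nodes": background.n_nodes,
                "background_edges": background.n_edges,
                "den_nodes": den.node_count,
                "den_edges": den.edge_count,
            },
            indent=2,
        )
        + "\n"
    )
    return background, den


def run_ego_stage(
    expr: ExpressionDataset, den: DifferentialNetwork, config: RunConfig
) -> tuple[NodeScoreTable, list[str]]:
    scores = topology_scores(den, expr)
    egos = select_ego_genes(scores, config.thresholds.ego_fraction)
    data_io.write_results(config.out_dir, ego_table=scores.table)
    return scores, egos


def run_module_stage(
    expr: ExpressionDataset,
    den: DifferentialNetwork,
    scores: NodeScoreTable,
    egos: list[str],
    config: RunConfig,
) -> tuple[list[CandidateModule], list[EgoModule]]:
    th = config.thresholds
    z = scores.z_of()
    candidates = [
        expand_ego(
            ego, den, expr, z_scores=z, size_cap=th.size_cap,
            module_id=f"M{i + 1}", drop_tol_pairs=th.drop_tol_pairs,
        )
        for i, ego in enumerate(egos)
    ]
    kept = filter_modules(candidates, th.auc, th.min_module_size)
    perms = [
        permutation_test(c, expr, b=th.perm_b, seed=stage_seed(config.seed, 5, i))
        for i, c in enumerate(kept)
    ]
    adj = bh_adjust([p.p_perm for p in perms]) if perms else []
    flags = call_significant(adj, th.alpha) if perms else []
    modules = [
        EgoModule(
            module_id=c.module_id,
            ego_gene=c.ego_gene,
            genes=c.genes,
            auc=c.auc,
            trace=c.trace,
            p_perm=p.p_perm,
            p_adj=float(q),
            significant=bool(s),
        )
        for c, p, q, s in zip(kept, perms, adj, flags)
    ]
    table = pd.DataFrame(
        [
            {
                "module_id": m.module_id,
                "ego_gene": m.ego_gene,
                "genes": ";".join(m.genes),
                "size": m.size,
                "auc": m.auc,
                "p_perm": m.p_perm,
                "p_adj": m.p_adj,
                "is_significant": m.significant,
            }
            for m in modules
        ],
        columns=data_io.MODULE_COLUMNS,
    )
    data_io.write_results(config.out_dir, module_table=table)
    return candidates, modules


def run_enrichment_stage(
    modules: list[EgoModule],
    pathways: PathwayCollection,
    universe: set[str],
    config: RunConfig,
) -> list[EnrichmentResult]:
    th = config.thresholds
    background = build_background_pathways(pathways, universe, th.pathway_min, th.pathway_max)
    results: list[EnrichmentResult] = []
    for m in modules:
        results.extend(
            fisher_enrichment(m.module_id, set(m.genes), background, universe, alpha=th.alpha)
        )
    table = pd.DataFrame(
        [dataclasses.asdict(r) for r in results], columns=data_io.ENRICHMENT_COLUMNS
    )
    data_io.write_results(config.out_dir, enrichment_table=table)
    return results


# ---------------------------------------------------------------------------
# Full run
# ---------------------------------------------------------------------------


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute every stage; on an empty DEN, terminate gracefully with a partial report."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    expr, net, pathways = materialize_inputs(config)

    background, den = run_network_stage(expr, net, config)
    counts = {
        "expression_genes": len(expr.genes),
        "samples": expr.n_samples,
        "network_nodes": net.n_nodes,
        "network_edges": net.n_edges,
        "background_nodes": background.n_nodes,
        "background_edges": background.n_edges,
        "den_nodes": den.node_count,
        "den_edges": den.edge_count,
    }
    if den.is_empty:
        logger.warning("empty differential network; stopping with a partial report")
        counts.update(
            ego_genes=0, candidate_modules=0, ego_modules=0,
            significant_modules=0, background_pathways=0, ego_pathways=0,
        )
        data_io.write_results(out, summary=counts, write_missing=True)
        return RunReport(counts=counts, ego_genes=[], modules=[], enrichment=[], out_dir=out)

    scores, egos = run_ego_stage(expr, den, config)
    candidates, modules = run_module_stage(expr, den, scores, egos, config)
    enrichment = run_enrichment_stage(modules, pathways, background.nodes, config)

    n_bg_pathways = len(
        build_background_pathways(
            pathways, background.nodes, config.thresholds.pathway_min, config.thresholds.pathway_max
        )
    )
    counts.update(
        ego_genes=len(egos),
        candidate_modules=len(candidates),
        ego_modules=len(modules),
        significant_modules=sum(m.significant for m in modules),
        background_pathways=n_bg_pathways,
        ego_pathways=sum(r.is_ego_pathway for r in enrichment),
    )
    data_io.write_results(out, summary=counts)
    logger.info("pipeline complete: %s", counts)
    return RunReport(
        counts=counts, ego_genes=egos, modules=modules, enrichment=enrichment, out_dir=out
    )
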