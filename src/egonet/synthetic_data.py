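"""Synthetic benchmark generator with a planted, group-separating co-expression module.

The generator emulates the statistical structure the pipeline assumes in its
real inputs: a scale-free protein-interaction graph, a two-group expression
matrix in which a hub-centered set of planted genes is both strongly
co-expressed and shifted between groups, and a GMT pathway collection
containing one pathway that overlaps the planted module.  Planted
co-expression uses a single latent factor per module,

    x_g(s) = noise_sd * ( sqrt(rho) * z(s) + sqrt(1 - rho) * eps_g(s) ) + shift * 1[case]

so every planted-gene pair has expected within-group Pearson correlation rho,
and ``shift = effect_size * noise_sd`` gives a standardized between-group mean
difference of ``effect_size`` per planted gene.  Everything is driven by a
single integer seed; equal seeds give bit-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import networkx as nx
import numpy as np

from . import data_io
from .data_io import ExpressionDataset, InteractionNetwork, PathwayCollection
from .errors import ValidationError


@dataclass
class SyntheticConfig:
    """Parameters of one synthetic dataset.

    Defaults mirror a small two-group expression study (19 cases vs 6
    controls) with a 6-gene planted module on a preferential-attachment
    interaction graph.
    """

    n_cases: int = 19
    n_controls: int = 6
    n_genes: int = 150
    graph_model: str = "scale_free"  # or "erdos_renyi"
    planted_module_size: int = 6
    planted_hub: str = "G0001"
    effect_size: float = 3.0  # standardized mean difference per planted gene
    within_module_correlation: float = 0.9  # expected pairwise within-group PCC
    noise_sd: float = 1.0
    pathway_count: int = 40
    planted_pathway_overlap: int = 5
    seed: int = 0

    def validate(self) -> None:
        if self.n_cases < 2:
            raise ValidationError("n_cases must be >= 2")
        if self.n_controls < 2:
            raise ValidationError("n_controls must be >= 2")
        if self.planted_module_size < 4:
            raise ValidationError("planted_module_size must be >= 4")
        if self.n_genes < self.planted_module_size:
            raise ValidationError("n_genes must be >= planted_module_size")
        if self.graph_model not in ("scale_free", "erdos_renyi"):
            raise ValidationError(f"unknown graph_model {self.graph_model!r}")
        if not (0.0 <= self.within_module_correlation < 1.0):
            raise ValidationError("within_module_correlation must be in [0, 1)")
        if self.noise_sd <= 0:
            raise ValidationError("noise_sd must be positive")
        if self.pathway_count < 1:
            raise ValidationError("pathway_count must be >= 1")
        if not (0 <= self.planted_pathway_overlap <= self.planted_module_size):
            raise ValidationError("planted_pathway_overlap must be <= planted_module_size")


@dataclass
class SyntheticTruth:
    """Ground truth of the planted structure, for recovery tests."""

    planted_genes: set[str] = field(default_factory=set)
    planted_hub: str = ""
    planted_pathway: str = ""

    def __post_init__(self) -> None:
        if self.planted_hub and self.planted_hub not in self.planted_genes:
            raise ValidationError("planted_hub must be a planted gene")


def _gene_names(config: SyntheticConfig) -> list[str]:
    names = [f"G{i:04d}" for i in range(1, config.n_genes + 1)]
    # allow a readable hub name, e.g. "IL1B"; it replaces the first symbol
    if config.planted_hub not in names:
        names[0] = config.planted_hub
    return names


def _background_graph(config: SyntheticConfig, rng: np.random.Generator) -> nx.Graph:
    gseed = int(rng.integers(2**31 - 1))
    if config.graph_model == "scale_free":
        m = min(2, config.n_genes - 1)
        return nx.barabasi_albert_graph(config.n_genes, m, seed=gseed)
    p = min(1.0, 4.0 / max(config.n_genes - 1, 1))
    return nx.erdos_renyi_graph(config.n_genes, p, seed=gseed)


def generate_dataset(
    config: SyntheticConfig,
) -> tuple[ExpressionDataset, InteractionNetwork, PathwayCollection, SyntheticTruth]:
    """Generate (expression, network, pathways, truth) from one config.

    The planted module is wired into the graph as a star centred on the hub
    plus chords between consecutive spokes, so it is connected and survives
    intersection with the expression gene set.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    genes = _gene_names(config)
    hub = genes[0] if config.planted_hub == genes[0] else config.planted_hub
    g0 = _background_graph(config, rng)
    graph = nx.relabel_nodes(g0, dict(enumerate(genes)))
    for a, b in graph.edges:
        graph[a][b]["weight"] = round(float(rng.uniform(0.4, 1.0)), 6)

    # spokes drawn away from the earliest preferential-attachment nodes
    # (those are densely interconnected, which would blur the hub's
    # star-centre role in the extracted DEN)
    candidates = [g for g in genes[min(10, max(1, config.n_genes - config.planted_module_size)):] if g != hub]
    if len(candidates) < config.planted_module_size - 1:
        candidates = [g for g in genes if g != hub]
    spokes = [str(s) for s in rng.choice(candidates, size=config.planted_module_size - 1, replace=False)]
    planted = [hub] + spokes
    # star plus chords: hub-spoke edges and a chord between consecutive spokes
    for spoke in planted[1:]:
        graph.add_edge(hub, spoke, weight=round(float(rng.uniform(0.8, 1.0)), 6))
    for a, b in zip(planted[1:], planted[2:]):
        graph.add_edge(a, b, weight=round(float(rng.uniform(0.8, 1.0)), 6))
    network = InteractionNetwork(graph)

    n = config.n_cases + config.n_controls
    samples = [f"S{i:02d}" for i in range(1, n + 1)]
    labels = {
        s: (data_io.CASE if i < config.n_cases else data_io.CONTROL)
        for i, s in enumerate(samples)
    }
    case = np.array([labels[s] == data_io.CASE for s in samples])

    rho = config.within_module_correlation
    values = rng.normal(0.0, config.noise_sd, size=(config.n_genes, n))
    latent = rng.normal(size=n)
    planted_idx = [genes.index(g) for g in planted]
    for i in planted_idx:
        eps = rng.normal(size=n)
        x = np.sqrt(rho) * latent + np.sqrt(1.0 - rho) * eps
        values[i] = config.noise_sd * x + config.effect_size * config.noise_sd * case

    expr = ExpressionDataset(genes=genes, samples=samples, values=values, labels=labels)

    pathways: dict[str, tuple[str, frozenset[str]]] = {}
    planted_pw = "PW0001"
    non_planted = [g for g in genes if g not in planted]
    overlap_genes = planted[: config.planted_pathway_overlap]
    filler_size = max(10 - len(overlap_genes), 0)
    filler = list(rng.choice(non_planted, size=min(filler_size, len(non_planted)), replace=False))
    pathways[planted_pw] = ("planted pathway", frozenset(overlap_genes) | frozenset(filler))
    for k in range(2, config.pathway_count + 1):
        size = int(rng.integers(5, min(41, config.n_genes)))
        members = rng.choice(genes, size=size, replace=False)
        pathways[f"PW{k:04d}"] = ("random gene set", frozenset(str(m) for m in members))
    collection = PathwayCollection(pathways)

    truth = SyntheticTruth(
        planted_genes=set(planted), planted_hub=hub, planted_pathway=planted_pw
    )
    return expr, network, collection, truth


def write_fixture(
    dataset: ExpressionDataset,
    network: InteractionNetwork,
    pathways: PathwayCollection,
    truth: SyntheticTruth,
    directory: str | Path,
    config: SyntheticConfig | None = None,
) -> dict:
    """Write a complete on-disk fixture and return its manifest.

    Emits expression.tsv, labels.tsv, edges.tsv, pathways.gmt and
    manifest.json; the files round-trip losslessly through the paired
    readers in :mod:`egonet.data_io`.
    """
    out = Path(directory)
    out.mkdir(parents=True, exist_ok=True)
    data_io.write_expression(dataset, out / "expression.tsv")
    data_io.write_labels(dataset.labels, out / "labels.tsv")
    data_io.write_edgelist(network, out / "edges.tsv")
    data_io.write_gmt(pathways, out / "pathways.gmt")
    manifest = {
        "files": {
            "expression": "expression.tsv",
            "labels": "labels.tsv",
            "edges": "edges.tsv",
            "gmt": "pathways.gmt",
        },
        "planted_genes": sorted(truth.planted_genes),
        "planted_hub": truth.planted_hub,
        "planted_pathway": truth.planted_pathway,
    }
    if config is not None:
        manifest["config"] = asdict(config)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
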