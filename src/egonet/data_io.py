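"""Core data containers and readers/writers for every on-disk format the pipeline touches.

Formats are deliberately plain: expression matrices and edge lists are
tab-separated text, pathway collections use the Broad GMT dialect, and all
result tables are TSV so they can be inspected with standard shell tools.
Identifier matching is exact-string throughout; no alias resolution is
attempted.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError

logger = logging.getLogger(__name__)

CASE = "case"
CONTROL = "control"


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------


@dataclass
class ExpressionDataset:
    """A normalized, log-scale gene x sample expression matrix with binary group labels.

    Parameters
    ----------
    genes : ordered gene identifiers (rows), unique.
    samples : ordered sample identifiers (columns), unique.
    values : float matrix of shape ``(len(genes), len(samples))`` with no
        missing entries.
    labels : mapping of every sample id to ``"case"`` or ``"control"``;
        each group must contain at least two samples so that per-group
        statistics (correlations, t-statistics) are defined.
    """

    genes: list[str]
    samples: list[str]
    values: np.ndarray
    labels: dict[str, str]

    def __post_init__(self) -> None:
        self.genes = list(self.genes)
        self.samples = list(self.samples)
        # C-contiguous layout keeps floating-point summation order (and thus
        # results) identical whether the matrix was generated or parsed
        self.values = np.ascontiguousarray(self.values, dtype=float)
        if len(set(self.genes)) != len(self.genes):
            dupes = sorted({g for g in self.genes if self.genes.count(g) > 1})
            raise ValidationError(f"duplicate gene ids: {dupes[:5]}")
        if len(set(self.samples)) != len(self.samples):
            raise ValidationError("duplicate sample ids")
        if self.values.shape != (len(self.genes), len(self.samples)):
            raise ValidationError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.genes)} genes x {len(self.samples)} samples"
            )
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ValidationError(
                f"non-finite expression value at gene {self.genes[bad[0]]!r}, "
                f"sample {self.samples[bad[1]]!r}"
            )
        if set(self.labels) != set(self.samples):
            missing = sorted(set(self.samples) - set(self.labels))
            extra = sorted(set(self.labels) - set(self.samples))
            if missing:
                raise ValidationError(f"labels missing for samples: {missing}")
            raise ValidationError(f"labels given for unknown samples: {extra}")
        bad_labels = {v for v in self.labels.values()} - {CASE, CONTROL}
        if bad_labels:
            raise ValidationError(f"unknown group labels: {sorted(bad_labels)}")
        n_case = int(self.case_mask.sum())
        n_control = len(self.samples) - n_case
        if n_case < 2 or n_control < 2:
            raise ValidationError(
                f"need at least 2 samples per group, got {n_case} case / {n_control} control"
            )
        self._gene_index = {g: i for i, g in enumerate(self.genes)}

    @property
    def case_mask(self) -> np.ndarray:
        """Boolean per-sample mask, True for case samples."""
        return np.array([self.labels[s] == CASE for s in self.samples])

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def gene_index(self, gene: str) -> int:
        try:
            return self._gene_index[gene]
        except KeyError:
            raise ValidationError(f"gene {gene!r} not in expression dataset") from None

    def gene_values(self, gene: str) -> np.ndarray:
        return self.values[self.gene_index(gene)]

    def submatrix(self, genes: Sequence[str]) -> np.ndarray:
        """Samples x genes matrix for the requested genes (feature layout)."""
        idx = [self.gene_index(g) for g in genes]
        return self.values[idx].T.copy()

    def equals(self, other: "ExpressionDataset") -> bool:
        return (
            self.genes == other.genes
            and self.samples == other.samples
            and self.labels == other.labels
            and np.allclose(self.values, other.values)
        )


@dataclass
class InteractionNetwork:
    """An undirected weighted gene graph (background PPIN, or the DEN after filtering).

    Backed by a :class:`networkx.Graph`; self-loops are forbidden and each
    unordered pair is stored once with a non-negative ``weight`` attribute.
    """

    graph: nx.Graph = field(default_factory=nx.Graph)

    def __post_init__(self) -> None:
        loops = list(nx.selfloop_edges(self.graph))
        if loops:
            raise ValidationError(f"self-loops are not allowed: {loops[:3]}")

    @classmethod
    def from_edges(
        cls, edges: Iterable[tuple[str, str, float]], nodes: Iterable[str] | None = None
    ) -> "InteractionNetwork":
        g = nx.Graph()
        if nodes is not None:
            g.add_nodes_from(nodes)
        for a, b, w in edges:
            if w < 0:
                raise ValidationError(f"negative edge weight {w} on ({a}, {b})")
            g.add_edge(a, b, weight=float(w))
        return cls(g)

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edges(self) -> list[tuple[str, str, float]]:
        """Edges as (a, b, weight) with a < b, sorted — a canonical ordering."""
        out = [
            (min(a, b), max(a, b), float(d.get("weight", 1.0)))
            for a, b, d in self.graph.edges(data=True)
        ]
        return sorted(out)

    def weight(self, a: str, b: str) -> float:
        return float(self.graph[a][b].get("weight", 1.0))

    def neighbors(self, gene: str) -> set[str]:
        return set(self.graph.neighbors(gene))


@dataclass
class PathwayCollection:
    """Named gene sets (Reactome-style): pathway id -> (description, gene set)."""

    pathways: dict[str, tuple[str, frozenset[str]]]

    def __post_init__(self) -> None:
        for name, (_, genes) in self.pathways.items():
            if not genes:
                raise ValidationError(f"pathway {name!r} has an empty gene set")

    def __len__(self) -> int:
        return len(self.pathways)

    def __contains__(self, name: str) -> bool:
        return name in self.pathways

    def genes_of(self, name: str) -> frozenset[str]:
        return self.pathways[name][1]

    def items(self):
        return self.pathways.items()


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------


def read_labels(path: str | Path) -> dict[str, str]:
    """Read a two-column sample_id TAB {case|control} file."""
    labels: dict[str, str] = {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != 2:
            raise ParseError(f"{path}: line {ln}: expected 2 tab-separated fields")
        sample, group = parts
        if group not in (CASE, CONTROL):
            raise ParseError(
                f"{path}: line {ln}: group must be '{CASE}' or '{CONTROL}', got {group!r}"
            )
        if sample in labels:
            raise ParseError(f"{path}: line {ln}: duplicate sample id {sample!r}")
        labels[sample] = group
    return labels


def read_expression(path: str | Path, labels_path: str | Path) -> ExpressionDataset:
    """Read an expression TSV (gene rows, sample columns) plus its label file.

    Duplicate gene rows are collapsed deterministically by keeping the row
    with the highest mean expression (a stand-in for probe summarization,
    which is upstream of this pipeline).  Missing values are rejected.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    if df.isna().any().any():
        row, col = next(zip(*np.where(df.isna().to_numpy())))
        raise ParseError(
            f"{path}: missing value at gene {df.index[row]!r}, sample {df.columns[col]!r}"
        )
    if df.index.has_duplicates:
        n_before = len(df)
        means = df.mean(axis=1)
        order = np.argsort(-means.to_numpy(), kind="stable")
        df = df.iloc[order]
        df = df[~df.index.duplicated(keep="first")]
        # restore first-occurrence row order of the original file
        seen: dict[str, int] = {}
        original = pd.read_csv(path, sep="\t", index_col=0, usecols=[0])
        for g in original.index:
            if g not in seen:
                seen[g] = len(seen)
        df = df.loc[sorted(df.index, key=seen.__getitem__)]
        logger.info("collapsed %d duplicate gene rows by max mean", n_before - len(df))
    labels = read_labels(labels_path)
    unknown = sorted(set(labels) - set(df.columns))
    if unknown:
        raise ValidationError(f"labels refer to unknown samples: {unknown}")
    return ExpressionDataset(
        genes=[str(g) for g in df.index],
        samples=[str(s) for s in df.columns],
        values=df.to_numpy(dtype=float),
        labels=labels,
    )


def read_edgelist(path: str | Path) -> InteractionNetwork:
    """Read a STRING-style 2- or 3-column edge TSV into an InteractionNetwork.

    A missing third column implies weight 1.0.  Duplicate pairs (in either
    orientation) are merged keeping the maximum weight; self-loops are
    dropped with a logged count; negative weights are rejected.
    """
    best: dict[frozenset[str], float] = {}
    n_loops = 0
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) == 2:
            a, b = parts
            w = 1.0
        elif len(parts) >= 3:
            a, b = parts[0], parts[1]
            try:
                w = float(parts[2])
            except ValueError:
                raise ParseError(f"{path}: line {ln}: unparseable weight {parts[2]!r}") from None
        else:
            raise ParseError(f"{path}: line {ln}: expected at least 2 fields")
        if w < 0:
            raise ValidationError(f"{path}: line {ln}: negative weight {w}")
        if a == b:
            n_loops += 1
            continue
        key = frozenset((a, b))
        if key not in best or w > best[key]:
            best[key] = w
    if n_loops:
        logger.info("dropped %d self-loop edge(s)", n_loops)
    edges = [(min(k), max(k), w) for k, w in best.items()]
    return InteractionNetwork.from_edges(edges)


def read_gmt(path: str | Path) -> PathwayCollection:
    """Read a Broad-dialect GMT file: name TAB description TAB gene TAB gene ..."""
    pathways: dict[str, tuple[str, frozenset[str]]] = {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ParseError(f"{path}: line {ln}: GMT lines need >= 3 tab-separated fields")
        name, desc, *genes = parts
        if name in pathways:
            raise ValidationError(f"{path}: line {ln}: duplicate pathway id {name!r}")
        pathways[name] = (desc, frozenset(g for g in genes if g))
    return PathwayCollection(pathways)


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------


def write_expression(dataset: ExpressionDataset, path: str | Path) -> None:
    df = pd.DataFrame(dataset.values, index=dataset.genes, columns=dataset.samples)
    df.index.name = "gene"
    # default float repr is shortest-round-trip, so the file is lossless
    df.to_csv(path, sep="\t")


def write_labels(labels: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for sample, group in labels.items():
            fh.write(f"{sample}\t{group}\n")


def write_edgelist(net: InteractionNetwork, path: str | Path) -> None:
    with open(path, "w") as fh:
        for a, b, w in net.edges():
            fh.write(f"{a}\t{b}\t{w!r}\n")


def write_gmt(pathways: PathwayCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, (desc, genes) in pathways.items():
            fh.write("\t".join([name, desc, *sorted(genes)]) + "\n")


EGO_GENE_COLUMNS = ["gene", "d", "s", "f", "z", "is_ego"]
MODULE_COLUMNS = [
    "module_id", "ego_gene", "genes", "size", "auc", "p_perm", "p_adj", "is_significant",
]
ENRICHMENT_COLUMNS = [
    "module_id", "pathway_id", "overlap", "module_size", "pathway_size",
    "universe", "p", "p_adj", "is_ego_pathway",
]


def write_results(
    out_dir: str | Path,
    ego_table: pd.DataFrame | None = None,
    module_table: pd.DataFrame | None = None,
    enrichment_table: pd.DataFrame | None = None,
    summary: Mapping | None = None,
    write_missing: bool = False,
) -> dict[str, Path]:
    """Write the pipeline's result tables and run summary; return a file manifest.

    With ``write_missing=True`` absent tables are written header-only, so a
    partial run (e.g. an empty differential network) still leaves a
    complete, machine-readable output directory; otherwise absent tables
    are simply skipped (stage-wise execution writes one table at a time).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Path] = {}

    specs = [
        ("ego_genes.tsv", ego_table, EGO_GENE_COLUMNS),
        ("modules.tsv", module_table, MODULE_COLUMNS),
        ("enrichment.tsv", enrichment_table, ENRICHMENT_COLUMNS),
    ]
    for fname, table, columns in specs:
        path = out / fname
        if table is None:
            if not write_missing:
                continue
            table = pd.DataFrame(columns=columns)
        table = table.reindex(columns=columns)
        table.to_csv(path, sep="\t", index=False)
        manifest[fname] = path
    if summary is not None:
        path = out / "run_summary.json"
        path.write_text(json.dumps(dict(summary), indent=2, sort_keys=True) + "\n")
        manifest["run_summary.json"] = path
    return manifest
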