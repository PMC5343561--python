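"""Topology scoring of DEN genes and ego-gene selection.

Each DEN node is reweighted by how strongly it is connected to
differentially expressed neighbours: with ``W`` the |PCC|-weighted adjacency,
``D = diag(d_i)`` the weighted degree matrix and ``A = D^{-1/2} W D^{-1/2}``
the symmetric normalized adjacency, the topology score of gene ``i`` is

    f_i = sum_{j in N(i)} A_ij * s_j

where ``s_j`` is the node's base importance — by default the absolute Welch
t-statistic of its differential expression between cases and controls.  The
scores are standardized to z-scores over the DEN and the top 5% of nodes
(at least one) are selected as ego genes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data_io import ExpressionDataset
from .errors import ValidationError
from .network_construction import DifferentialNetwork

logger = logging.getLogger(__name__)


@dataclass
class NodeScoreTable:
    """Per-gene topology scores over the DEN, sorted descending by z.

    ``table`` columns: gene, d (weighted degree), s (base importance),
    f (topology score), z (standardized f), is_ego.
    """

    table: pd.DataFrame

    @property
    def genes(self) -> list[str]:
        return list(self.table["gene"])

    def ego_genes(self) -> list[str]:
        return list(self.table.loc[self.table["is_ego"], "gene"])

    def z_of(self) -> dict[str, float]:
        return dict(zip(self.table["gene"], self.table["z"]))


def normalized_adjacency(den: DifferentialNetwork) -> tuple[list[str], np.ndarray]:
    """Return (ordered DEN nodes, symmetric normalized adjacency D^-1/2 W D^-1/2).

    The DEN has no isolated nodes, so every weighted degree is positive and
    the normalization is well defined; entries lie in [0, 1] and the spectrum
    is contained in [-1, 1].
    """
    if den.is_empty:
        raise ValidationError("cannot score an empty differential network")
    nodes = sorted(den.network.nodes)
    import networkx as nx

    w = nx.to_numpy_array(den.network.graph, nodelist=nodes, weight="weight")
    d = w.sum(axis=1)
    if np.any(d <= 0):
        raise ValidationError("DEN contains an isolated node")
    inv_sqrt = 1.0 / np.sqrt(d)
    a = inv_sqrt[:, None] * w * inv_sqrt[None, :]
    return nodes, a


def differential_t_statistics(expr: ExpressionDataset, genes: list[str]) -> np.ndarray:
    """Absolute Welch t-statistic of case-vs-control differential expression per gene."""
    idx = [expr.gene_index(g) for g in genes]
    case = expr.case_mask
    x = expr.values[idx]
    with np.errstate(divide="ignore", invalid="ignore"):
        t, _ = stats.ttest_ind(x[:, case], x[:, ~case], axis=1, equal_var=False)
    t = np.asarray(t, dtype=float)
    bad = ~np.isfinite(t)
    if bad.any():
        logger.warning("%d gene(s) with undefined t-statistic set to 0", int(bad.sum()))
        t[bad] = 0.0
    return np.abs(t)


def topology_scores(
    den: DifferentialNetwork, expr: ExpressionDataset
) -> NodeScoreTable:
    """Compute f and z for every DEN gene and return the sorted score table."""
    nodes, a = normalized_adjacency(den)
    s = differential_t_statistics(expr, nodes)
    f = a @ s
    d = np.array([sum(den.network.weight(g, h) for h in den.network.neighbors(g)) for g in nodes])
    sd = f.std(ddof=1) if len(f) > 1 else 0.0
    if sd == 0:
        logger.warning("all topology scores equal; z-scores set to 0")
        z = np.zeros_like(f)
    else:
        z = (f - f.mean()) / sd
    table = pd.DataFrame({"gene": nodes, "d": d, "s": s, "f": f, "z": z})
    table["is_ego"] = False
    table = table.sort_values(
        by=["z", "d", "gene"], ascending=[False, False, True], kind="mergesort"
    ).reset_index(drop=True)
    return NodeScoreTable(table)


def select_ego_genes(scores: NodeScoreTable, fraction: float = 0.05) -> list[str]:
    """Mark and return the top max(1, floor(fraction * n)) genes by z.

    Ties at the cut are broken by higher weighted degree, then gene id —
    the same ordering the table itself is sorted by, so selection is simply
    the table head.
    """
    if not (0.0 < fraction <= 1.0):
        raise ValidationError("fraction must be in (0, 1]")
    n = len(scores.table)
    if n == 0:
        raise ValidationError("empty score table")
    k = max(1, math.floor(fraction * n))
    scores.table["is_ego"] = False
    scores.table.loc[: k - 1, "is_ego"] = True
    egos = list(scores.table["gene"].iloc[:k])
    logger.info("selected %d ego gene(s) from %d DEN nodes", k, n)
    return egos
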