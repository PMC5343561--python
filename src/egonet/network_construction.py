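"""Background PPIN construction and differential expression network (DEN) extraction.

The background network is the interaction network restricted to genes that
are actually measured.  Each surviving edge is then scored by the pooled
Pearson correlation of its two genes across all samples, and tested for
group-differential co-expression: per sample ``s`` the edge's co-expression
contribution is ``c_s = z_i(s) * z_j(s)`` with ``z`` the gene's expression
standardized over all samples, and a one-sided two-sample t-test compares
the contributions of one group against the other.  Edges with
``|PCC| >= 0.8`` and ``p < 0.05`` form the DEN, whose edge weights are
``|PCC|``.

Under the null the two groups are exchangeable, so their contribution
variances are equal and the pooled-variance Student t-test is exactly sized;
it is the default.  A Welch variant and the Fisher z-test on the difference
of per-group correlations are available via ``method``.

The test direction defaults to ``"minority"``: with pooled standardization,
an edge whose genes separate the groups concentrates its coordinated
deviation from the pooled mean in the smaller group, so aiming the
one-sided alternative at the minority group is the powered choice for
detecting differential edges under an unbalanced design.  ``"cases"`` and
``"controls"`` fix the direction explicitly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .data_io import ExpressionDataset, InteractionNetwork
from .errors import ValidationError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EdgeStatistic:
    """Pooled correlation and one-sided differential co-expression p for one edge."""

    edge: tuple[str, str]
    pcc: float
    p_value: float


@dataclass
class DifferentialNetwork:
    """The DEN: retained edges weighted by |PCC|; nodes are exactly the edge endpoints."""

    network: InteractionNetwork
    pcc_threshold: float
    p_threshold: float

    @property
    def node_count(self) -> int:
        return self.network.n_nodes

    @property
    def edge_count(self) -> int:
        return self.network.n_edges

    @property
    def is_empty(self) -> bool:
        return self.edge_count == 0


def build_background_ppin(
    expr: ExpressionDataset, net: InteractionNetwork
) -> InteractionNetwork:
    """Restrict the interaction network to genes present in the expression data."""
    common = set(expr.genes) & net.nodes
    if not common:
        raise ValidationError(
            "expression genes and interaction-network nodes do not overlap"
        )
    sub = net.graph.subgraph(common).copy()
    logger.info(
        "background PPIN: %d nodes, %d edges (from %d/%d)",
        sub.number_of_nodes(), sub.number_of_edges(), net.n_nodes, net.n_edges,
    )
    return InteractionNetwork(sub)


def _standardize(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-standardize (ddof=1) over samples; zero-variance rows flagged, left at 0."""
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=1, keepdims=True)
    zero = sd[:, 0] == 0
    safe = np.where(sd == 0, 1.0, sd)
    z = (values - mean) / safe
    z[zero] = 0.0
    return z, zero


def _t_greater(a: np.ndarray, b: np.ndarray, equal_var: bool) -> np.ndarray:
    """Vectorized one-sided two-sample t-test (rows = edges), alternative a > b."""
    n1, n0 = a.shape[1], b.shape[1]
    m1, m0 = a.mean(axis=1), b.mean(axis=1)
    v1, v0 = a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        if equal_var:
            sp2 = ((n1 - 1) * v1 + (n0 - 1) * v0) / (n1 + n0 - 2)
            se2 = sp2 * (1 / n1 + 1 / n0)
            df = np.full_like(m1, n1 + n0 - 2)
        else:
            se2 = v1 / n1 + v0 / n0
            df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v0 / n0) ** 2 / (n0 - 1))
        t = (m1 - m0) / np.sqrt(se2)
    p = np.ones_like(t)
    ok = np.isfinite(t) & np.isfinite(df) & (df > 0)
    p[ok] = stats.t.sf(t[ok], df[ok])
    # degenerate zero-variance contributions: decided by the mean difference alone
    degen = ~ok
    p[degen & (m1 > m0)] = 0.0
    return p


def edge_statistics(
    expr: ExpressionDataset,
    net: InteractionNetwork,
    method: str = "student_products",
    direction: str = "minority",
) -> list[EdgeStatistic]:
    """Score every network edge by pooled PCC and a one-sided differential test.

    ``method="student_products"`` (default) tests per-sample standardized
    cross-products between groups with a pooled-variance t-test;
    ``"welch_products"`` is the unequal-variance variant;
    ``method="fisher_z"`` tests the difference of per-group correlations
    with Fisher's z transformation.  ``direction`` names the group the
    one-sided alternative favours: ``"minority"`` (default), ``"cases"`` or
    ``"controls"``.  Edges touching a zero-variance gene get PCC 0 and p 1.
    """
    if expr.n_samples < 3:
        raise ValidationError("need at least 3 samples to compute correlations")
    if method not in ("student_products", "welch_products", "fisher_z"):
        raise ValidationError(f"unknown edge test method {method!r}")
    if direction not in ("minority", "cases", "controls"):
        raise ValidationError(f"unknown test direction {direction!r}")

    edge_list = net.edges()
    if not edge_list:
        return []
    idx = {g: i for i, g in enumerate(expr.genes)}
    for a, b, _ in edge_list:
        if a not in idx or b not in idx:
            raise ValidationError(f"network gene missing from expression data: {a if a not in idx else b}")
    ei = np.array([idx[a] for a, _, _ in edge_list])
    ej = np.array([idx[b] for _, b, _ in edge_list])

    n = expr.n_samples
    z, zero_var = _standardize(expr.values)
    bad_edge = zero_var[ei] | zero_var[ej]
    if bad_edge.any():
        logger.warning(
            "%d edge(s) touch a zero-variance gene; PCC set to 0, p to 1",
            int(bad_edge.sum()),
        )

    products = z[ei] * z[ej]  # edges x samples
    pcc = np.clip(products.sum(axis=1) / (n - 1), -1.0, 1.0)

    case = expr.case_mask
    if direction == "controls" or (
        direction == "minority" and case.sum() > (~case).sum()
    ):
        favoured = ~case
    else:
        favoured = case
    if method == "fisher_z":
        p = _fisher_z_p(expr.values, ei, ej, favoured)
    else:
        p = _t_greater(
            products[:, favoured],
            products[:, ~favoured],
            equal_var=(method == "student_products"),
        )
    pcc = np.where(bad_edge, 0.0, pcc)
    p = np.where(bad_edge, 1.0, p)

    return [
        EdgeStatistic(edge=(a, b), pcc=float(pcc[k]), p_value=float(p[k]))
        for k, (a, b, _) in enumerate(edge_list)
    ]


def _fisher_z_p(
    values: np.ndarray, ei: np.ndarray, ej: np.ndarray, favoured: np.ndarray
) -> np.ndarray:
    """One-sided z-test for r_favoured > r_other via Fisher's transformation."""
    n1, n0 = int(favoured.sum()), int((~favoured).sum())
    if n1 < 4 or n0 < 4:
        raise ValidationError("fisher_z requires at least 4 samples per group")

    def group_r(cols: np.ndarray) -> np.ndarray:
        z, zero = _standardize(values[:, cols])
        r = (z[ei] * z[ej]).sum(axis=1) / (cols.sum() - 1)
        r = np.clip(r, -0.999999, 0.999999)
        r[zero[ei] | zero[ej]] = 0.0
        return r

    r1, r0 = group_r(favoured), group_r(~favoured)
    zdiff = (np.arctanh(r1) - np.arctanh(r0)) / np.sqrt(1 / (n1 - 3) + 1 / (n0 - 3))
    return stats.norm.sf(zdiff)


def extract_den(
    edge_stats: list[EdgeStatistic],
    pcc_threshold: float = 0.8,
    p_threshold: float = 0.05,
) -> DifferentialNetwork:
    """Keep edges with |PCC| >= pcc_threshold (inclusive) and p < p_threshold (strict)."""
    if not (0.0 <= pcc_threshold <= 1.0):
        raise ValidationError("pcc_threshold must be in [0, 1]")
    if not (0.0 < p_threshold <= 1.0):
        raise ValidationError("p_threshold must be in (0, 1]")
    kept = [
        (s.edge[0], s.edge[1], abs(s.pcc))
        for s in edge_stats
        if abs(s.pcc) >= pcc_threshold and s.p_value < p_threshold
    ]
    net = InteractionNetwork.from_edges(kept)
    logger.info("DEN: %d nodes, %d edges from %d scored edges", net.n_nodes, net.n_edges, len(edge_stats))
    return DifferentialNetwork(network=net, pcc_threshold=pcc_threshold, p_threshold=p_threshold)
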