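"""Greedy module growth around ego genes, scored by cross-validated classifier AUC.

A candidate module starts as the ego gene alone and repeatedly adds the DEN
neighbour whose inclusion most improves the module's leave-one-out
cross-validated AUC; a neighbour whose addition leaves the AUC unchanged is
still absorbed (the ego's neighbourhood is part of the module unless it
hurts), and growth stops when the module's accuracy drops — assessed at the
resolution of the AUC estimate itself: with n1 cases and n0 controls the
LOOCV AUC moves in steps of 1/(n1*n0), so a change of a single ranking
inversion is indistinguishable from cross-validation noise and only a
larger decrease counts as a drop (``drop_tol_pairs`` inversions tolerated,
default 1; set 0 for a strict decrease rule).  A safety size cap bounds
pathological growth.  The AUC of a gene set
is computed by training a linear soft-margin SVM (C = 1.0) on the module
genes' expression in each leave-one-out fold — features standardized with
training-fold statistics — pooling the held-out decision values and applying
the rank-sum (Mann-Whitney) formulation against the true labels.  The whole
procedure is deterministic for a fixed input.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata
from sklearn import config_context
from sklearn.svm import SVC

from .data_io import ExpressionDataset
from .errors import ValidationError
from .network_construction import DifferentialNetwork

logger = logging.getLogger(__name__)

DEFAULT_AUC_THRESHOLD = 0.8
DEFAULT_SIZE_THRESHOLD = 4
DEFAULT_SIZE_CAP = 30


@dataclass
class CandidateModule:
    """A grown module: the ego gene, its genes in insertion order, and the LOOCV AUC."""

    module_id: str
    ego_gene: str
    genes: list[str]
    auc: float
    trace: list[tuple[str, float]] = field(default_factory=list)

    @property
    def size(self) -> int:
        return len(self.genes)


@dataclass
class EgoModule(CandidateModule):
    """A candidate that passed the AUC/size filter, with permutation significance."""

    p_perm: float = float("nan")
    p_adj: float = float("nan")
    significant: bool = False


def _rank_auc(scores: np.ndarray, y: np.ndarray) -> float:
    """AUC of decision values against binary labels via the rank-sum identity.

    Equivalent to the fraction of (case, control) pairs in which the case
    score is higher, counting ties as half.
    """
    n1 = int(y.sum())
    n0 = len(y) - n1
    r = rankdata(scores)
    return float((r[y].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def _loocv_decision_values(x: np.ndarray, y: np.ndarray, c: float = 1.0) -> np.ndarray:
    """Held-out linear-SVM decision values from leave-one-out cross-validation.

    ``x`` is samples x features.  Features are standardized with the
    training fold's mean and standard deviation; a zero-variance feature in
    a fold is left centred only.
    """
    n = len(y)
    out = np.empty(n)
    # expression values are validated finite upstream; skip sklearn's
    # per-fit finiteness checks, which dominate runtime at this problem size
    with config_context(assume_finite=True):
        for i in range(n):
            train = np.ones(n, dtype=bool)
            train[i] = False
            xt, yt = x[train], y[train]
            mu = xt.mean(axis=0)
            sd = xt.std(axis=0)
            sd[sd == 0] = 1.0
            clf = SVC(kernel="linear", C=c)
            clf.fit((xt - mu) / sd, yt)
            out[i] = clf.decision_function(((x[i] - mu) / sd)[None, :])[0]
    return out


def module_auc(
    genes: list[str] | set[str],
    expr: ExpressionDataset,
    labels: np.ndarray | None = None,
) -> float:
    """Leave-one-out cross-validated AUC of a gene set as a case/control classifier.

    ``labels`` overrides the dataset's case mask (used by the permutation
    test); both classes must be present.
    """
    genes = list(genes)
    if not genes:
        raise ValidationError("module_auc needs at least one gene")
    y = expr.case_mask if labels is None else np.asarray(labels, dtype=bool)
    if y.all() or not y.any():
        raise ValidationError("AUC undefined: only one class present")
    x = expr.submatrix(genes)
    scores = _loocv_decision_values(x, y.astype(int))
    return _rank_auc(scores, y)


def expand_ego(
    ego: str,
    den: DifferentialNetwork,
    expr: ExpressionDataset,
    z_scores: dict[str, float] | None = None,
    size_cap: int = DEFAULT_SIZE_CAP,
    module_id: str | None = None,
    drop_tol_pairs: int = 1,
) -> CandidateModule:
    """Grow one candidate module from an ego gene by greedy AUC ascent.

    At each step every DEN neighbour of the current module is evaluated and
    the neighbour with the largest AUC change is added (ties broken by
    higher topology z-score, then gene id) unless the module's AUC would
    drop by more than ``drop_tol_pairs`` ranking inversions — one inversion
    being the LOOCV AUC's resolution 1/(n_cases * n_controls).  Stops at
    the first such drop or at the size cap.
    """
    if ego not in den.network.nodes:
        raise ValidationError(f"ego gene {ego!r} is not a DEN node")
    if drop_tol_pairs < 0:
        raise ValidationError("drop_tol_pairs must be >= 0")
    z = z_scores or {}
    y = expr.case_mask
    n1 = int(y.sum())
    tol = drop_tol_pairs / (n1 * (len(y) - n1)) + 1e-12
    module = [ego]
    auc = module_auc(module, expr)
    trace = [(ego, auc)]
    while len(module) < size_cap:
        frontier = set()
        for g in module:
            frontier |= den.network.neighbors(g)
        frontier -= set(module)
        if not frontier:
            break
        # tie-priority order: higher z first, then lexicographic id; with a
        # strict ">" below the first best candidate wins ties
        ordered = sorted(frontier, key=lambda u: (-z.get(u, 0.0), u))
        best_gene, best_auc = None, -np.inf
        for u in ordered:
            a = module_auc(module + [u], expr)
            if a > best_auc:
                best_gene, best_auc = u, a
        if best_gene is None or best_auc - auc < -tol:
            break
        module.append(best_gene)
        auc = best_auc
        trace.append((best_gene, auc))
    return CandidateModule(
        module_id=module_id or f"module_{ego}",
        ego_gene=ego,
        genes=module,
        auc=auc,
        trace=trace,
    )


def filter_modules(
    candidates: list[CandidateModule],
    auc_threshold: float = DEFAULT_AUC_THRESHOLD,
    size_threshold: int = DEFAULT_SIZE_THRESHOLD,
) -> list[CandidateModule]:
    """Keep candidates with auc >= auc_threshold and size >= size_threshold (inclusive)."""
    kept = [c for c in candidates if c.auc >= auc_threshold and c.size >= size_threshold]
    logger.info(
        "module filter (AUC >= %g, size >= %d): %d candidate(s) -> %d",
        auc_threshold, size_threshold, len(candidates), len(kept),
    )
    return kept
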