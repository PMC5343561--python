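"""Permutation testing of ego modules and Benjamini-Hochberg adjustment.

The null model permutes sample labels uniformly at random (module genes
fixed) and recomputes the module's cross-validated AUC each round; the
p-value uses the add-one Monte-Carlo formula

    p = (#{permuted AUC >= observed AUC} + 1) / (B + 1)

which keeps p strictly positive.  Adjusted p-values use the standard BH
step-up procedure and a module is called significant at adjusted p < alpha
(strict).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from statsmodels.stats.multitest import multipletests

from .data_io import ExpressionDataset
from .errors import ValidationError
from .module_search import CandidateModule, module_auc

logger = logging.getLogger(__name__)

DEFAULT_B = 1000
DEFAULT_ALPHA = 0.05


@dataclass
class PermutationResult:
    module_id: str
    observed_auc: float
    permuted_aucs: np.ndarray
    p_perm: float
    seed: int


def permutation_test(
    module: CandidateModule,
    expr: ExpressionDataset,
    b: int = DEFAULT_B,
    seed: int = 0,
) -> PermutationResult:
    """Label-permutation null for one module's AUC; deterministic for a fixed seed."""
    if b < 1:
        raise ValidationError("number of permutations must be >= 1")
    rng = np.random.default_rng(seed)
    y = expr.case_mask
    observed = module_auc(module.genes, expr)
    permuted = np.empty(b)
    for i in range(b):
        perm_y = rng.permutation(y)
        permuted[i] = module_auc(module.genes, expr, labels=perm_y)
    exceed = int(np.sum(permuted >= observed))
    p = (exceed + 1) / (b + 1)
    return PermutationResult(
        module_id=module.module_id,
        observed_auc=observed,
        permuted_aucs=permuted,
        p_perm=p,
        seed=seed,
    )


def bh_adjust(p_values: list[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in the input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_significant(
    adjusted_p: list[float] | np.ndarray, alpha: float = DEFAULT_ALPHA
) -> np.ndarray:
    """Flag adjusted p-values strictly below alpha."""
    return np.asarray(adjusted_p, dtype=float) < alpha
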