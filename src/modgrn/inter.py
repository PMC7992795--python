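"""Inter-module edge inference by closed-form ridge regression.

Pairs whose endpoints share at least one module are handled by the
boosted-tree stage; every remaining ordered pair is scored here.  For each
target gene the expression of all candidate regulators outside the
target's modules enters one L2-penalised linear regression

    min_α ‖E_t − E_r α‖² + λ‖α‖² ,   λ = 1/2 by default,

whose unique stationary point (E_rᵀE_r + λI) α = E_rᵀ E_t is solved in
closed form; |α_i| is the confidence of edge i → t.  Columns and target
are centered when problems are built from expression data so the additive
noise/intercept term is absorbed.

Together the two stages cover exactly the n·(n−1) ordered non-self gene
pairs: unassigned genes act as singleton modules, contributing no intra
pairs and all of their pairs to this stage.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import linalg

from .io import ExpressionMatrix, ModuleSet, ScoredEdgeList

logger = logging.getLogger(__name__)

__all__ = ["RidgeProblem", "ridge_solve", "infer_inter_module", "partition_pairs"]


@dataclass
class RidgeProblem:
    """One per-target regression: centered target vs centered cross-module regulators."""

    E_t: np.ndarray
    E_r: np.ndarray
    regulator_ids: list[str]
    lam: float = 0.5

    def __post_init__(self) -> None:
        if self.E_r.shape != (len(self.E_t), len(self.regulator_ids)):
            raise ValueError("regulator matrix shape mismatch")
        if self.lam < 0:
            raise ValueError("ridge penalty must be non-negative")


def ridge_solve(E_r: np.ndarray, E_t: np.ndarray, lam: float = 0.5) -> np.ndarray:
    """Closed-form minimiser of ‖E_t − E_r α‖² + lam·‖α‖².

    The default lam = 1/2 matches the ½-penalty objective; its stationary
    point is (E_rᵀE_r + lam·I) α = E_rᵀE_t, always invertible for lam > 0.
    With lam = 0 and a rank-deficient design the least-norm solution is
    returned with a warning.
    """
    E_r = np.asarray(E_r, dtype=float)
    E_t = np.asarray(E_t, dtype=float)
    if E_r.ndim != 2 or E_r.shape[0] < 2 or E_r.shape[1] < 1:
        raise ValueError("need at least 2 samples and 1 regulator")
    if lam < 0:
        raise ValueError("ridge penalty must be non-negative")
    if lam == 0:
        alpha, _res, rank, _sv = np.linalg.lstsq(E_r, E_t, rcond=None)
        if rank < E_r.shape[1]:
            warnings.warn(
                "unpenalised rank-deficient system: returning least-norm solution",
                RuntimeWarning,
            )
        return alpha
    p = E_r.shape[1]
    gram = E_r.T @ E_r + lam * np.eye(p)
    return linalg.solve(gram, E_r.T @ E_t, assume_a="pos")


def partition_pairs(
    gene_ids: list[str], modules: ModuleSet
) -> tuple[set[tuple[str, str]], set[tuple[str, str]]]:
    """Split all ordered non-self pairs into intra- and inter-stage candidates.

    A pair is *intra* when its genes share at least one module and *inter*
    otherwise; the two sets are disjoint and their union has n·(n−1)
    elements — the coverage identity behind the two-stage design.
    """
    membership = modules.gene_to_modules()
    intra: set[tuple[str, str]] = set()
    inter: set[tuple[str, str]] = set()
    for i in gene_ids:
        mi = membership.get(i, set())
        for j in gene_ids:
            if i == j:
                continue
            if mi & membership.get(j, set()):
                intra.add((i, j))
            else:
                inter.add((i, j))
    return intra, inter


def infer_inter_module(
    X: ExpressionMatrix,
    modules: ModuleSet,
    tf_set: set[str] | None = None,
    lam: float = 0.5,
) -> ScoredEdgeList:
    """Score every cross-module ordered pair by |ridge coefficient|.

    For each target, candidate regulators are the genes (or supplied TFs)
    sharing no module with it; removing same-module pairs is what keeps
    the regression small.  Targets with no candidates are skipped with a
    log entry.
    """
    membership = modules.gene_to_modules()
    records: list[tuple[str, str, float]] = []
    cols = {g: None for g in X.gene_ids}  # lazy centered columns
    centered = X.values - X.values.mean(axis=0)
    idx = {g: i for i, g in enumerate(X.gene_ids)}
    for target in X.gene_ids:
        mt = membership.get(target, set())
        candidates = [
            g for g in X.gene_ids
            if g != target
            and (tf_set is None or g in tf_set)
            and not (mt & membership.get(g, set()))
        ]
        if not candidates:
            logger.info("target %s has no cross-module candidates; skipped", target)
            continue
        E_r = centered[:, [idx[g] for g in candidates]]
        E_t = centered[:, idx[target]]
        alpha = ridge_solve(E_r, E_t, lam=lam)
        records.extend(
            (g, target, float(abs(a))) for g, a in zip(candidates, alpha)
        )
    return ScoredEdgeList(records=records, provenance="inter")
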