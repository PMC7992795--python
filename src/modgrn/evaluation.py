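"""Evaluation of detected modules and ranked edge predictions.

Module detection is scored with overlap-aware set metrics: every known
module is matched to its best Jaccard partner among the observed modules
(Recovery), every observed module to its best partner among the known ones
(Relevance), and the harmonic mean of the two (F_rr) summarises both.
Unlike partition metrics (Rand index, NMI) these remain well defined when
modules overlap.

Edge rankings are scored against a gold-standard network by sweeping the
cut-off K down the list and computing FPR/TPR (ROC) and recall/precision
(PR) at every distinct score, with trapezoidal areas.  Degree
distributions of binarised networks are summarised by an ordinary
least-squares power-law fit log p_k = −α·log k + c on the log–log plot.

Also provided: the three co-regulation module gold-standard constructions
(minimal / strict / interconnected) derived from an edge list.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import networkx as nx
import numpy as np

from .assembly import RankedNetwork
from .io import GoldStandardNetwork, ModuleSet

logger = logging.getLogger(__name__)

__all__ = [
    "ModuleSimilarityReport",
    "RankingEvaluation",
    "PowerLawFit",
    "jaccard",
    "module_similarity",
    "rank_confusion",
    "auroc_aupr",
    "degree_counts",
    "fit_power_law",
    "derive_module_gold",
]


@dataclass
class ModuleSimilarityReport:
    """Recovery / Relevance / F_rr plus the underlying Jaccard matrix (known × observed)."""

    recovery: float
    relevance: float
    f_rr: float
    jaccard_matrix: np.ndarray


@dataclass
class RankingEvaluation:
    """ROC and PR curves with their trapezoidal areas."""

    roc_points: np.ndarray   # (n, 2) columns FPR, TPR
    pr_points: np.ndarray    # (n, 2) columns recall, precision
    auroc: float
    aupr: float


@dataclass
class PowerLawFit:
    """Least-squares fit of log10 p_k = −alpha·log10 k + c."""

    alpha: float
    c: float
    degrees: list[int]


def jaccard(m1: Iterable[str], m2: Iterable[str]) -> float:
    """|m1 ∩ m2| / |m1 ∪ m2| for two gene sets."""
    s1, s2 = set(m1), set(m2)
    if not s1 and not s2:
        raise ValueError("Jaccard of two empty sets is undefined")
    return len(s1 & s2) / len(s1 | s2)


def module_similarity(known: ModuleSet, observed: ModuleSet) -> ModuleSimilarityReport:
    """Best-match Jaccard averages between known and observed module sets.

    Recovery averages, over known modules, the best Jaccard against any
    observed module; Relevance is the mirror image; F_rr is their harmonic
    mean (0 when both vanish).  Swapping the arguments swaps Recovery and
    Relevance and leaves F_rr unchanged.
    """
    if len(known) == 0:
        raise ValueError("known module set is empty")
    if len(observed) == 0:
        warnings.warn("observed module set is empty; similarity is zero", RuntimeWarning)
        return ModuleSimilarityReport(0.0, 0.0, 0.0, np.zeros((len(known), 0)))
    matrix = np.array(
        [[jaccard(km, om) for om in observed.modules] for km in known.modules]
    )
    recovery = float(matrix.max(axis=1).mean())
    relevance = float(matrix.max(axis=0).mean())
    if recovery + relevance == 0:
        f_rr = 0.0
    else:
        f_rr = 2.0 * recovery * relevance / (recovery + relevance)
    return ModuleSimilarityReport(recovery, relevance, f_rr, matrix)


def _binary_labels(
    ranked: RankedNetwork,
    gold: GoldStandardNetwork,
    negatives: str = "complement",
) -> tuple[np.ndarray, np.ndarray]:
    """Scores and 0/1 labels over the evaluation universe, in ranked order.

    The universe is the set of ranked (scorable) pairs; with
    ``negatives="labelled"`` it is restricted to gold positives plus the
    explicitly labelled negative pairs.
    """
    if negatives not in ("complement", "labelled"):
        raise ValueError(f"unknown negative policy {negatives!r}")
    scores, labels = [], []
    n_gold_seen = 0
    for reg, tgt, score in ranked.records:
        pair = (reg, tgt)
        is_pos = pair in gold.edges
        n_gold_seen += is_pos
        if negatives == "labelled" and not is_pos and pair not in gold.known_negatives:
            continue
        scores.append(score)
        labels.append(1 if is_pos else 0)
    if n_gold_seen < len(gold.edges):
        logger.warning(
            "%d gold edges are outside the ranked universe and cannot be scored",
            len(gold.edges) - n_gold_seen,
        )
    return np.asarray(scores), np.asarray(labels)


def rank_confusion(
    ranked: RankedNetwork,
    gold: GoldStandardNetwork,
    K: int,
    negatives: str = "complement",
) -> tuple[int, int, int, int]:
    """(TP, FP, TN, FN) of the top-K prediction against the gold standard."""
    scores, labels = _binary_labels(ranked, gold, negatives)
    if K > len(scores):
        raise ValueError(f"K={K} exceeds the {len(scores)} pairs in the universe")
    n_pos = int(labels.sum())
    tp = int(labels[:K].sum())
    fp = K - tp
    fn = n_pos - tp
    tn = len(scores) - K - fn
    return tp, fp, tn, fn


def auroc_aupr(
    ranked: RankedNetwork,
    gold: GoldStandardNetwork,
    negatives: str = "complement",
) -> RankingEvaluation:
    """ROC/PR curves and areas for a ranked edge list.

    The threshold sweeps over distinct scores (tied scores form a single
    step), which makes the trapezoidal AUROC equal to the pairwise
    statistic P(s⁺ > s⁻) + ½·P(tie).  The PR curve is anchored at recall 0
    with the precision of the first threshold.
    """
    scores, labels = _binary_labels(ranked, gold, negatives)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("evaluation universe must contain positives and negatives")
    # ranked.records is already sorted descending; find tie-group boundaries
    boundaries = np.flatnonzero(np.diff(scores)) + 1
    ends = np.append(boundaries, len(scores))        # cumulative index after each group
    cum_tp = np.cumsum(labels)[ends - 1]
    cum_fp = ends - cum_tp
    tpr = cum_tp / n_pos
    fpr = cum_fp / n_neg
    recall = tpr
    precision = cum_tp / ends
    roc = np.column_stack((np.concatenate(([0.0], fpr)), np.concatenate(([0.0], tpr))))
    pr = np.column_stack(
        (np.concatenate(([0.0], recall)), np.concatenate(([precision[0]], precision)))
    )
    auroc = float(np.trapezoid(roc[:, 1], roc[:, 0]))
    aupr = float(np.trapezoid(pr[:, 1], pr[:, 0]))
    return RankingEvaluation(roc_points=roc, pr_points=pr, auroc=auroc, aupr=aupr)


def degree_counts(edges: Iterable[tuple[str, str]]) -> dict[int, int]:
    """Histogram of total (in + out) degree over the nodes of an edge set."""
    deg: dict[str, int] = {}
    for reg, tgt in edges:
        deg[reg] = deg.get(reg, 0) + 1
        deg[tgt] = deg.get(tgt, 0) + 1
    counts: dict[int, int] = {}
    for d in deg.values():
        counts[d] = counts.get(d, 0) + 1
    return counts


def fit_power_law(counts: Mapping[int, int]) -> PowerLawFit:
    """OLS power-law fit to a degree histogram.

    Degree frequencies are normalised to probabilities p_k; the regression
    log10 p_k on log10 k uses every degree k ≥ 1 with p_k > 0 and returns
    α with the sign convention slope = −α.
    """
    total = sum(counts.values())
    if total <= 0:
        raise ValueError("degree histogram is empty")
    ks = sorted(k for k, c in counts.items() if k >= 1 and c > 0)
    if len(ks) < 2:
        raise ValueError("need at least 2 distinct positive degrees to fit")
    log_k = np.log10(ks)
    log_p = np.log10([counts[k] / total for k in ks])
    slope, intercept = np.polyfit(log_k, log_p, 1)
    return PowerLawFit(alpha=float(-slope), c=float(intercept), degrees=ks)


def derive_module_gold(gold: GoldStandardNetwork, definition: str) -> ModuleSet:
    """Build a co-regulation module gold standard from an edge list.

    * ``minimal`` — one module per regulator: its target set (overlaps
      allowed, duplicate sets collapsed).
    * ``strict`` — equivalence classes of genes with identical regulator
      sets.
    * ``interconnected`` — connected components of the undirected graph
      joining two genes when they share at least one regulator *and* are
      directly linked by a gold edge, i.e. co-regulated genes that are
      themselves wired together.

    Singleton modules are dropped in all three constructions; an edgeless
    network yields an empty set with a warning.
    """
    if definition not in ("minimal", "strict", "interconnected"):
        raise ValueError(f"unknown module definition {definition!r}")
    if not gold.edges:
        warnings.warn("edgeless gold network: no modules to derive", RuntimeWarning)
        return ModuleSet(modules=[], labels=[])

    regulators_of: dict[str, set[str]] = {}
    targets_of: dict[str, set[str]] = {}
    for reg, tgt in gold.edges:
        regulators_of.setdefault(tgt, set()).add(reg)
        targets_of.setdefault(reg, set()).add(tgt)

    modules: list[set[str]]
    if definition == "minimal":
        unique = {frozenset(ts) for ts in targets_of.values()}
        modules = [set(m) for m in sorted(unique, key=lambda m: sorted(m))]
    elif definition == "strict":
        classes: dict[frozenset[str], set[str]] = {}
        for gene, regs in regulators_of.items():
            classes.setdefault(frozenset(regs), set()).add(gene)
        modules = [m for _, m in sorted(classes.items(), key=lambda kv: sorted(kv[1]))]
    else:
        graph = nx.Graph()
        graph.add_nodes_from(regulators_of)
        for reg, tgt in gold.edges:
            shared = regulators_of.get(reg, set()) & regulators_of.get(tgt, set())
            if shared:
                graph.add_edge(reg, tgt)
        modules = [set(c) for c in nx.connected_components(graph)]
        modules.sort(key=lambda m: sorted(m))
    modules = [m for m in modules if len(m) >= 2]
    return ModuleSet(modules=modules, labels=[f"{definition} {i+1}" for i in range(len(modules))])
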