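"""Data-driven gene module detection by matrix decomposition.

The central method decomposes the expression matrix X (samples × genes) as
X = A·S, where the columns of the mixing matrix A are statistically
independent, non-Gaussian activity signals over samples and the rows of the
source matrix S carry each component's loading on every gene.  Genes are
then assigned to a module per component by converting standardized loadings
to two-sided normal p-values and admitting genes whose
Benjamini–Hochberg-style Q-value falls below a cutoff.

Variants: sign-split FDR assignment (two modules per component), plain
z-score thresholding, PCA loading thresholds, and a k-means partition of
gene profiles as a disjoint-clustering baseline.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .io import ExpressionMatrix, ModuleSet

logger = logging.getLogger(__name__)

__all__ = [
    "Whitener",
    "DecompositionResult",
    "IcaConfig",
    "whiten",
    "fastica",
    "qvalues",
    "fdr_assign",
    "fdr2_assign",
    "zscore_assign",
    "pca_assign",
    "kmeans_assign",
    "decompose",
]


@dataclass
class Whitener:
    """Affine whitening transform: z = K (x - mean) for a gene-space vector x."""

    K: np.ndarray          # (n_comps, n_genes)
    mean: np.ndarray       # (n_genes,)

    def apply(self, values: np.ndarray) -> np.ndarray:
        """Whiten a samples × genes matrix into n_comps × n_samples."""
        return self.K @ (values - self.mean).T


@dataclass
class DecompositionResult:
    """Factorisation X ≈ A·S with the whitener used to obtain it.

    S is n_comps × n_genes (rows unit-variance by convention); A is
    n_samples × n_comps.  ``converged`` records whether the fixed-point
    iteration met its tolerance before ``iterations_used`` hit the cap.
    """

    S: np.ndarray
    A: np.ndarray
    gene_ids: list[str]
    whitener: Whitener | None = None
    converged: bool = True
    iterations_used: int = 0

    @property
    def n_comps(self) -> int:
        return self.S.shape[0]


@dataclass
class IcaConfig:
    """Settings for the fixed-point ICA loop and FDR gene assignment.

    ``contrast`` selects the negentropy contrast non-linearity:
    ``logcosh`` (g(u) = tanh(a1·u), robust default) or ``exp``
    (g(u) = u·exp(−u²/2), suited to very heavy-tailed sources).
    """

    n_comps: int
    max_iter: int = 20_000
    tol: float = 1e-4
    q_cutoff: float = 1e-3
    contrast: Literal["logcosh", "exp"] = "logcosh"
    a1: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_comps < 1:
            raise ValueError("n_comps must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be positive")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if not 1.0 <= self.a1 <= 2.0:
            raise ValueError("a1 must lie in [1, 2]")
        if self.contrast not in ("logcosh", "exp"):
            raise ValueError(f"unknown contrast {self.contrast!r}")


def whiten(X: ExpressionMatrix | np.ndarray, n_comps: int) -> tuple[np.ndarray, Whitener]:
    """Whiten expression data onto its top principal subspace.

    Gene variables are centered, the gene–gene covariance is
    eigendecomposed, and the data are projected onto the leading
    ``n_comps`` eigenvectors scaled to unit variance.  Returns the
    whitened matrix Z (n_comps × n_samples) whose sample covariance is the
    identity, together with the affine transform used.
    """
    values = X.values if isinstance(X, ExpressionMatrix) else np.asarray(X, dtype=float)
    if values.ndim != 2 or values.shape[0] < 2 or values.shape[1] < 1:
        raise ValueError("whitening needs a 2-D matrix with at least 2 samples")
    n_samples = values.shape[0]
    mean = values.mean(axis=0)
    Xc = values - mean
    cov = (Xc.T @ Xc) / n_samples
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    # effective rank: eigenvalues above machine-scale of the largest
    cutoff = max(eigvals[0], 0.0) * 1e-12
    rank = int(np.sum(eigvals > cutoff))
    if n_comps > rank:
        raise ValueError(
            f"requested {n_comps} components but covariance has effective rank {rank}"
        )
    K = (eigvecs[:, :n_comps] / np.sqrt(eigvals[:n_comps])).T
    whitener = Whitener(K=K, mean=mean)
    return whitener.apply(values), whitener


def _contrast_fns(contrast: str, a1: float):
    if contrast == "logcosh":
        def g(u):
            return np.tanh(a1 * u)

        def g_prime(u):
            return a1 * (1.0 - np.tanh(a1 * u) ** 2)
    else:  # exp
        def g(u):
            return u * np.exp(-(u ** 2) / 2.0)

        def g_prime(u):
            return (1.0 - u ** 2) * np.exp(-(u ** 2) / 2.0)
    return g, g_prime


def _sym_decorrelate(W: np.ndarray) -> np.ndarray:
    """Symmetric decorrelation W ← (W Wᵀ)^(−1/2) W (order-independent)."""
    eigvals, eigvecs = np.linalg.eigh(W @ W.T)
    inv_sqrt = eigvecs @ np.diag(1.0 / np.sqrt(eigvals)) @ eigvecs.T
    return inv_sqrt @ W


def fastica(X: ExpressionMatrix, cfg: IcaConfig) -> DecompositionResult:
    """Estimate independent components by fixed-point negentropy maximisation.

    All unmixing vectors are updated in parallel with symmetric
    decorrelation each sweep.  Convergence is declared when every vector's
    direction change |1 − |⟨w_new, w_old⟩|| falls below ``cfg.tol``;
    otherwise the loop runs to ``cfg.max_iter`` and the result is returned
    with ``converged=False`` and a warning (repeat-averaging protocols
    tolerate occasional failed runs).
    """
    n_samples, n_genes = X.values.shape
    if cfg.n_comps > min(n_samples, n_genes):
        raise ValueError("n_comps may not exceed min(n_samples, n_genes)")
    Z, whitener = whiten(X, cfg.n_comps)
    n_obs = Z.shape[1]
    g, g_prime = _contrast_fns(cfg.contrast, cfg.a1)

    rng = np.random.default_rng(cfg.seed)
    W = _sym_decorrelate(rng.standard_normal((cfg.n_comps, cfg.n_comps)))

    converged = False
    iterations = 0
    for iterations in range(1, cfg.max_iter + 1):
        U = W @ Z
        GU = g(U)
        W_new = (GU @ Z.T) / n_obs - np.diag(g_prime(U).mean(axis=1)) @ W
        W_new = _sym_decorrelate(W_new)
        delta = np.max(np.abs(1.0 - np.abs(np.einsum("ij,ij->i", W_new, W))))
        W = W_new
        if delta < cfg.tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"ICA did not converge in {cfg.max_iter} iterations (last delta above tol)",
            RuntimeWarning,
        )

    # Independent activity signals over samples become the mixing columns.
    A = (W @ Z).T                                   # n_samples × n_comps
    Xc = X.values - whitener.mean
    S, *_ = np.linalg.lstsq(A, Xc, rcond=None)      # n_comps × n_genes
    # Normalisation convention: unit-variance S rows, A rescaled to compensate.
    row_sd = S.std(axis=1, ddof=0)
    row_sd[row_sd == 0] = 1.0
    S = S / row_sd[:, None]
    A = A * row_sd[None, :]
    return DecompositionResult(
        S=S, A=A, gene_ids=list(X.gene_ids), whitener=whitener,
        converged=converged, iterations_used=iterations,
    )


def qvalues(pvals: np.ndarray, monotone: bool = True) -> np.ndarray:
    """FDR Q-values q_(i) = p_(i)·n/i for ascending-sorted p-values.

    With ``monotone`` the step-up completion is applied (running minimum
    from the largest rank), which restores rank-consistency of the
    threshold rule when the raw ratios are non-monotone.  Input must be
    sorted ascending; output is aligned with the input order.
    """
    pvals = np.asarray(pvals, dtype=float)
    if np.any(np.diff(pvals) < 0):
        raise ValueError("p-values must be sorted ascending")
    n = len(pvals)
    ranks = np.arange(1, n + 1)
    q = pvals * n / ranks
    if monotone:
        q = np.minimum.accumulate(q[::-1])[::-1]
    return q


def _robust_z_rows(S: np.ndarray) -> np.ndarray:
    """Standardize rows against their Gaussian bulk (median / scaled MAD).

    Source rows are unit-variance overall, but a module's genes can hold a
    sizeable share of that variance: a loading block of gene-fraction f is
    capped at z = sqrt((1−f)/f) under full-row sd scaling, which would
    blind the FDR test to any module above a few percent of the genes.
    The median/MAD estimate is consistent for the N(0, σ²) bulk and
    insensitive to the heavy module tail, so planted loadings keep their
    nominal z-scale.  Degenerate rows (MAD 0) fall back to sd scaling.
    """
    med = np.median(S, axis=1, keepdims=True)
    mad = stats.median_abs_deviation(S, axis=1, scale="normal")[:, None]
    sd = S.std(axis=1, ddof=0, keepdims=True)
    scale = np.where(mad > 0, mad, np.where(sd > 0, sd, 1.0))
    return (S - med) / scale


def _component_module(z: np.ndarray, pvals: np.ndarray, q_cutoff: float) -> np.ndarray:
    """Boolean membership mask from per-gene p-values at an FDR cutoff."""
    order = np.argsort(pvals, kind="stable")
    q_sorted = qvalues(pvals[order])
    mask = np.zeros(len(pvals), dtype=bool)
    mask[order] = q_sorted < q_cutoff
    return mask


def fdr_assign(result: DecompositionResult, q_cutoff: float) -> ModuleSet:
    """Assign genes to one module per component by FDR on |loading|.

    Each source row is standardized; two-sided standard-normal tail
    p-values of the loadings are FDR-corrected per component, and genes
    with Q-value strictly below ``q_cutoff`` form the component's module.
    Empty modules are dropped.
    """
    if not 0 < q_cutoff <= 1:
        raise ValueError("q_cutoff must lie in (0, 1]")
    Z = _robust_z_rows(result.S)
    genes = np.asarray(result.gene_ids)
    modules: list[set[str]] = []
    labels: list[str] = []
    for k in range(result.n_comps):
        pvals = 2.0 * stats.norm.sf(np.abs(Z[k]))
        mask = _component_module(Z[k], pvals, q_cutoff)
        if mask.any():
            modules.append(set(genes[mask]))
            labels.append(f"ic{k + 1}")
    return ModuleSet(modules=modules, labels=labels)


def fdr2_assign(result: DecompositionResult, q_cutoff: float) -> ModuleSet:
    """Sign-split FDR assignment: up to two modules per component.

    The positive- and negative-loading tails are tested separately with
    one-sided p-values over the genes in each tail, so a component whose
    regulatory program has both activated and repressed genes yields two
    disjoint modules.  Empty modules are dropped.
    """
    if not 0 < q_cutoff <= 1:
        raise ValueError("q_cutoff must lie in (0, 1]")
    Z = _robust_z_rows(result.S)
    genes = np.asarray(result.gene_ids)
    modules: list[set[str]] = []
    labels: list[str] = []
    for k in range(result.n_comps):
        for sign, tag in ((1.0, "pos"), (-1.0, "neg")):
            tail = sign * Z[k] > 0
            if not tail.any():
                continue
            pvals = stats.norm.sf(sign * Z[k][tail])
            mask = _component_module(Z[k][tail], pvals, q_cutoff)
            if mask.any():
                modules.append(set(genes[tail][mask]))
                labels.append(f"ic{k + 1}_{tag}")
    return ModuleSet(modules=modules, labels=labels)


def zscore_assign(result: DecompositionResult, z_cutoff: float = 1.5) -> ModuleSet:
    """Threshold standardized |loadings| directly at ``z_cutoff``."""
    if z_cutoff <= 0:
        raise ValueError("z_cutoff must be positive")
    Z = result.S  # rows are unit-variance by convention; thresholded as given
    genes = np.asarray(result.gene_ids)
    modules: list[set[str]] = []
    labels: list[str] = []
    for k in range(result.n_comps):
        mask = np.abs(Z[k]) > z_cutoff
        if mask.any():
            modules.append(set(genes[mask]))
            labels.append(f"ic{k + 1}")
    return ModuleSet(modules=modules, labels=labels)


def pca_assign(X: ExpressionMatrix, n_comps: int, loading_cutoff: float) -> ModuleSet:
    """Modules from principal-axis loadings over genes.

    Gene j joins module k when |loading_kj| ≥ loading_cutoff · max_j
    |loading_kj|, so a cutoff of 1 keeps only the argmax gene(s).
    """
    if not 0 < loading_cutoff <= 1:
        raise ValueError("loading_cutoff must lie in (0, 1]")
    pca = PCA(n_components=n_comps, svd_solver="full")
    pca.fit(X.values)
    genes = np.asarray(X.gene_ids)
    modules: list[set[str]] = []
    labels: list[str] = []
    for k, loadings in enumerate(np.abs(pca.components_)):
        mask = loadings >= loading_cutoff * loadings.max()
        if mask.any():
            modules.append(set(genes[mask]))
            labels.append(f"pc{k + 1}")
    return ModuleSet(modules=modules, labels=labels)


def kmeans_assign(X: ExpressionMatrix, n_comps: int, seed: int = 0) -> ModuleSet:
    """Disjoint baseline: k-means over gene expression profiles."""
    if n_comps > X.n_genes:
        raise ValueError("n_comps may not exceed the number of genes")
    km = KMeans(n_clusters=n_comps, random_state=seed, n_init=10)
    assignment = km.fit_predict(X.values.T)
    genes = np.asarray(X.gene_ids)
    modules = [set(genes[assignment == k]) for k in range(n_comps)]
    modules = [m for m in modules if m]
    return ModuleSet(modules=modules, labels=[f"k{j + 1}" for j in range(len(modules))])


def decompose(
    X: ExpressionMatrix,
    method: str = "ica_fdr",
    n_comps: int = 4,
    q_cutoff: float = 1e-3,
    z_cutoff: float = 1.5,
    loading_cutoff: float = 0.25,
    max_iter: int = 20_000,
    tol: float = 1e-4,
    contrast: str = "logcosh",
    seed: int = 0,
) -> tuple[ModuleSet, DecompositionResult | None]:
    """Dispatch to a module-detection method by name.

    Returns the detected modules and, for ICA-family methods, the
    decomposition they were derived from (None for PCA/k-means).
    """
    if method in ("ica_fdr", "ica_fdr2", "ica_zscore"):
        cfg = IcaConfig(
            n_comps=n_comps, max_iter=max_iter, tol=tol, q_cutoff=q_cutoff,
            contrast=contrast, seed=seed,
        )
        result = fastica(X, cfg)
        if method == "ica_fdr":
            return fdr_assign(result, q_cutoff), result
        if method == "ica_fdr2":
            return fdr2_assign(result, q_cutoff), result
        return zscore_assign(result, z_cutoff), result
    if method == "pca":
        return pca_assign(X, n_comps, loading_cutoff), None
    if method == "kmeans":
        return kmeans_assign(X, n_comps, seed), None
    raise ValueError(f"unknown decomposition method {method!r}")
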