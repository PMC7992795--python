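"""Synthetic modular gene regulatory networks with matched expression data.

The generator plants a hub-regulator community structure: each module has a
few transcription-factor (TF) hubs densely wired to every other member,
plus sparse cross-module TF→gene edges.  Expression follows the linear
mixing view of modular transcription: every module carries an independent
super-Gaussian (Laplace) activity signal over samples; its TFs express
that signal (plus noise), regulated genes express weighted sums of their
regulators' profiles, background genes are pure noise.  Measurement
realism is controlled by additive Gaussian noise and an independent
Bernoulli dropout mask zeroing entries, the main difficulty knob of
single-cell regimes.

Cross-module regulatory weights are drawn weaker than intra-module ones —
the modularity premise — so module membership stays identifiable while
cross edges remain detectable by the inter-module stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import ExpressionMatrix, GoldStandardNetwork, ModuleSet

__all__ = ["SimulationConfig", "generate_modular_grn", "simulate_expression"]

#: intra-module regulatory weight range (uniform draw)
_INTRA_WEIGHT = (0.5, 1.5)
#: cross-module regulatory weight range — weaker, per the modularity premise
_CROSS_WEIGHT = (0.2, 0.5)
#: fraction of samples in which a module's activity signal is "on"; bursty
#: (spike-and-slab) activity is strongly super-Gaussian, mirroring pathway
#: programs active only in a subset of cells
_BURST_FRACTION = 0.3


@dataclass
class SimulationConfig:
    """Study conditions for one simulated dataset.

    Defaults define the "easy" regime used throughout the test-bed:
    4 modules of 25 genes (2 TF hubs each) among 200 genes — the other 100
    are unregulated background — 300 samples, moderate noise, no dropout.
    Raising ``dropout_rate`` (e.g. 0.5 or 0.7) emulates increasingly
    sparse single-cell regimes.
    """

    n_genes: int = 200
    n_modules: int = 4
    module_size_range: tuple[int, int] = (25, 25)
    n_tfs_per_module: int = 2
    cross_module_edge_rate: float = 0.01
    n_samples: int = 300
    noise_sd: float = 0.5
    dropout_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.module_size_range
        if not 2 <= lo <= hi:
            raise ValueError("module sizes must be at least 2 and lo <= hi")
        if self.n_tfs_per_module < 1 or self.n_tfs_per_module > lo:
            raise ValueError("n_tfs_per_module must lie in [1, smallest module size]")
        if self.n_modules * hi > self.n_genes:
            raise ValueError(
                f"{self.n_modules} modules of up to {hi} genes exceed n_genes={self.n_genes}"
            )
        if not 0 <= self.cross_module_edge_rate <= 1:
            raise ValueError("cross_module_edge_rate must lie in [0, 1]")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must lie in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.n_samples < 2:
            raise ValueError("need at least 2 samples")


def _gene_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"G{i + 1:0{width}d}" for i in range(n)]


def generate_modular_grn(cfg: SimulationConfig) -> tuple[GoldStandardNetwork, ModuleSet]:
    """Sample a hub-structured gold network and its planted module set.

    Modules occupy consecutive gene blocks; within each, every TF hub
    regulates every other member (TFs included).  Each TF additionally
    regulates genes outside its module independently with probability
    ``cross_module_edge_rate``.  Genes beyond the module blocks are
    unassigned background.  Deterministic given ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    genes = _gene_ids(cfg.n_genes)
    lo, hi = cfg.module_size_range
    sizes = rng.integers(lo, hi + 1, size=cfg.n_modules)

    modules: list[set[str]] = []
    tf_set: set[str] = set()
    edges: set[tuple[str, str]] = set()
    cursor = 0
    for size in sizes:
        members = genes[cursor : cursor + int(size)]
        cursor += int(size)
        tfs = members[: cfg.n_tfs_per_module]
        tf_set.update(tfs)
        modules.append(set(members))
        for tf in tfs:
            for g in members:
                if g != tf:
                    edges.add((tf, g))
    if cfg.cross_module_edge_rate > 0:
        for k, module in enumerate(modules):
            tfs = sorted(module & tf_set)
            outside = [g for g in genes if g not in module]
            for tf in tfs:
                hits = rng.random(len(outside)) < cfg.cross_module_edge_rate
                for g, hit in zip(outside, hits):
                    if hit:
                        edges.add((tf, g))
    gold = GoldStandardNetwork(
        edges=edges, gene_universe=set(genes), tf_set=tf_set
    )
    labels = [f"planted {k + 1}" for k in range(len(modules))]
    return gold, ModuleSet(modules=modules, labels=labels)


def simulate_expression(
    gold: GoldStandardNetwork, modules: ModuleSet, cfg: SimulationConfig
) -> ExpressionMatrix:
    """Generate samples × genes expression for a planted modular network.

    Every TF hub carries its own bursty super-Gaussian activity signal
    over samples — Laplace(0, 1) amplitudes masked to a random ~30% of
    samples and rescaled to unit variance, mimicking a regulatory program
    active in a cell subset.  Every regulated gene expresses a weighted
    sum of its regulators' profiles (weights uniform in the intra or
    cross range depending on whether regulator and target share a
    module), so module coherence emerges from members mixing their hubs'
    signals; background genes are noise only.  All genes receive additive
    N(0, noise_sd²) noise, then an independent Bernoulli(dropout_rate)
    mask zeroes entries.  Deterministic given ``cfg.seed``.
    """
    rng = np.random.default_rng((cfg.seed, 2**16 + 1))
    genes = sorted(gold.gene_universe)
    n = len(genes)
    idx = {g: i for i, g in enumerate(genes)}
    membership = modules.gene_to_modules()
    tf_set = gold.tf_set or set()

    values = np.zeros((cfg.n_samples, n))
    # TF hub signals first: regulators must exist before their targets'
    # profiles are formed
    tfs_sorted = sorted(tf_set)
    activity = rng.laplace(0.0, 1.0, size=(len(tfs_sorted), cfg.n_samples))
    activity *= rng.random(activity.shape) < _BURST_FRACTION
    sd = activity.std(axis=1, ddof=0, keepdims=True)
    sd[sd == 0] = 1.0
    activity /= sd
    for i, tf in enumerate(tfs_sorted):
        values[:, idx[tf]] = activity[i]
    regulators_of: dict[str, list[str]] = {}
    for reg, tgt in gold.edges:
        regulators_of.setdefault(tgt, []).append(reg)
    for g in genes:
        if g in tf_set:
            continue
        regs = sorted(regulators_of.get(g, []))
        profile = np.zeros(cfg.n_samples)
        for reg in regs:
            shared = membership.get(reg, set()) & membership.get(g, set())
            lo, hi = _INTRA_WEIGHT if shared else _CROSS_WEIGHT
            profile += rng.uniform(lo, hi) * values[:, idx[reg]]
        values[:, idx[g]] = profile
    values += cfg.noise_sd * rng.standard_normal(values.shape)
    if cfg.dropout_rate > 0:
        keep = rng.random(values.shape) >= cfg.dropout_rate
        values = values * keep
    sample_ids = [f"S{i + 1:04d}" for i in range(cfg.n_samples)]
    return ExpressionMatrix(values=values, gene_ids=genes, sample_ids=sample_ids)
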