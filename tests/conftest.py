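"""Shared fixtures: small simulated datasets and text-format examples."""

from __future__ import annotations

import numpy as np
import pytest

from modgrn.synthetic import SimulationConfig, generate_modular_grn, simulate_expression


@pytest.fixture(scope="session")
def easy_dataset():
    """One easy-regime dataset: (gold, planted modules, expression)."""
    cfg = SimulationConfig(seed=0)
    gold, planted = generate_modular_grn(cfg)
    X = simulate_expression(gold, planted, cfg)
    return gold, planted, X


@pytest.fixture(scope="session")
def tiny_dataset():
    """A small, fast dataset for pipeline-level tests."""
    cfg = SimulationConfig(
        n_genes=30, n_modules=2, module_size_range=(8, 8), n_tfs_per_module=2,
        cross_module_edge_rate=0.02, n_samples=120, noise_sd=0.4, seed=11,
    )
    gold, planted = generate_modular_grn(cfg)
    X = simulate_expression(gold, planted, cfg)
    return cfg, gold, planted, X


# Module gold standard for primitive endoderm cells, a published benchmark
# module list used here as a realistic labelled-module text fixture.
PRE_MODULE_LINES = (
    "module 1\tXBP1\tGATA6\tMYBL2\tRHOX6\tJUN\n"
    "module 2\tETS1\tEGR1\tPOU5F1\tELF3\n"
    "module 3\tDNMT3A\tSIX1\tSMAD7\n"
    "module 4\tEPAS1\tBHLHE40\tPOU5F1\n"
)


@pytest.fixture()
def pre_module_file(tmp_path):
    path = tmp_path / "pre_modules.txt"
    path.write_text(PRE_MODULE_LINES)
    return path


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
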