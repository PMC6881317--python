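"""Shared fixtures: small simulated datasets reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from retrosel.branch_models import ModelContext
from retrosel.synthetic_data import (
    SimulationConfig,
    random_tree,
    simulate_alignment,
)


def non_root_internal_branches(tree):
    """Internal branch ids excluding the root-incident ones (whose lengths
    pool under the reversible model)."""
    root_children = {ch.branch_id for ch in tree.root.children}
    return [
        b.branch_id
        for b in tree.branches
        if not b.is_leaf and b.branch_id not in root_children
    ]


@pytest.fixture(scope="session")
def one_ratio_dataset():
    """6-taxon, 300-codon alignment simulated under a single omega = 0.3."""
    rng = np.random.default_rng(2024)
    tree = random_tree(6, rng)
    cfg = SimulationConfig(
        tree=tree,
        n_codons=300,
        kappa=2.0,
        omega_scheme={"type": "one_ratio", "omega": 0.3},
        seed=77,
    )
    aln, truth = simulate_alignment(cfg)
    return aln, tree, truth


@pytest.fixture(scope="session")
def one_ratio_context(one_ratio_dataset):
    aln, tree, _ = one_ratio_dataset
    return ModelContext(aln, tree)


@pytest.fixture(scope="session")
def two_class_dataset():
    """6-taxon, 400-codon data with omega = 3 planted on one internal branch."""
    rng = np.random.default_rng(11)
    tree = random_tree(6, rng)
    target = non_root_internal_branches(tree)[0]
    cfg = SimulationConfig(
        tree=tree,
        n_codons=400,
        kappa=2.0,
        omega_scheme={
            "type": "branch",
            "background": 0.2,
            "omega_of_branch": {target: 3.0},
        },
        seed=13,
    )
    aln, truth = simulate_alignment(cfg)
    truth["target_branch"] = target
    return aln, tree, truth
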