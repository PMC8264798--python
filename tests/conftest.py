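"""Shared fixtures: the seed-pinned default synthetic cohort and its
derived pipeline stages, computed once per session."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from cernet.synthetic import SimulationConfig, simulate_cohort
from cernet.de import run_de
from cernet.network import build_network, filter_ago
from cernet.modules import detect_modules


@pytest.fixture(scope="session")
def default_cohort():
    """Default study-condition cohort (500/200/100 genes, 60 tumor / 20 normal)."""
    return simulate_cohort(SimulationConfig())


@pytest.fixture(scope="session")
def de_by_class(default_cohort):
    bundle, samples, _, _, _ = default_cohort
    return {
        cls: run_de(matrix, samples)
        for cls, matrix in zip(
            ("mRNA", "lncRNA", "miRNA"), (bundle.mrna, bundle.lncrna, bundle.mirna)
        )
    }


@pytest.fixture(scope="session")
def default_network(default_cohort, de_by_class):
    bundle, _, catalog, _, _ = default_cohort
    return build_network(de_by_class, filter_ago(catalog), bundle)


@pytest.fixture(scope="session")
def default_modules(default_network):
    return detect_modules(default_network)


def toy_expression(pairs_r1, pairs_r0, n_samples=12, seed=0):
    """Build a genes x samples frame where listed pairs correlate perfectly
    (r=+1) and everything else is independent noise."""
    rng = np.random.default_rng(seed)
    data = {}
    for a, b in pairs_r1:
        base = rng.normal(size=n_samples)
        data.setdefault(a, base)
        data[b] = 2.0 * data[a] + 1.0
    for g in pairs_r0:
        data[g] = rng.normal(size=n_samples)
    cols = [f"S{i}" for i in range(n_samples)]
    frame = pd.DataFrame({g: v for g, v in data.items()}, index=cols).T
    return np.exp2(frame)  # positive abundances; log2 recovers exact values
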