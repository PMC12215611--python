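"""Shared fixtures: small synthetic datasets built at test time."""

import numpy as np
import pandas as pd
import pytest

from plantfit import synthetic_data as sd
from plantfit.design import make_design


@pytest.fixture(scope="session")
def small_params():
    return sd.SimParams(
        n_genes=60, insertions_per_gene_mean=5.0, read_depth=30_000, seed=42
    )


@pytest.fixture(scope="session")
def small_library(small_params):
    mapping, inoculum = sd.simulate_library(small_params)
    return mapping, inoculum


@pytest.fixture(scope="session")
def small_design():
    return make_design(n_per_habitat=4, n_soil=4, n_flats=4)


@pytest.fixture(scope="session")
def small_effects(small_library):
    mapping, _ = small_library
    genes = sorted(set(mapping["locus_tag"].dropna()))
    rng = np.random.default_rng(7)
    hit = rng.choice(genes, size=6, replace=False)
    return sd.TrueEffects({g: {"At_shoot": -2.0} for g in hit}), set(hit)


@pytest.fixture(scope="session")
def small_counts(small_library, small_design, small_effects, small_params):
    mapping, inoculum = small_library
    effects, _ = small_effects
    return sd.simulate_counts(
        mapping, inoculum, small_design, effects, small_params, seed=43
    )


@pytest.fixture(scope="session")
def protein_family():
    return sd.simulate_protein_family(seed=5)


@pytest.fixture
def toy_mapping():
    """A hand-built mapping table covering the filter edge cases."""
    return pd.DataFrame(
        {
            "barcode": ["A" * 20, "C" * 20, "G" * 20, "T" * 20],
            "scaffold": ["s1"] * 4,
            "position": [150, 500, 1300, 2000],
            "strand": ["+", "-", "+", "-"],
            "locus_tag": ["geneA", "geneA", None, "geneB"],
            "central": [True, True, False, False],
        }
    )
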