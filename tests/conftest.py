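"""Shared fixtures: small synthetic bundles reused across test modules."""

import pytest

from polyprof import pipeline
from polyprof.synthetic_data import SimulationConfig, generate_dataset


@pytest.fixture(scope="session")
def small_bundle():
    """A small but complete dataset: 8 genes, 4 diploids/clade, both polyploids."""
    return generate_dataset(
        SimulationConfig(seed=11, n_genes=8, diploids_per_clade=4, depth=20.0)
    )


@pytest.fixture(scope="session")
def small_panel(small_bundle):
    panel, clade_map = pipeline.build_panel_from_bundle(
        small_bundle, use_true_alleles=True
    )
    return panel


@pytest.fixture(scope="session")
def study_bundle():
    """The full study-scale dataset: 50 genes, 6 focal individuals, depth 20."""
    return generate_dataset(
        SimulationConfig(seed=1, n_genes=50, diploids_per_clade=4, depth=20.0)
    )


@pytest.fixture(scope="session")
def study_panel(study_bundle):
    """Reference panel phased from reads for the study-scale dataset."""
    panel, _ = pipeline.build_panel_from_bundle(study_bundle)
    return panel
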