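"""Shared fixtures: synthetic cores and a trained tumor/stroma classifier.

Image fixtures are session-scoped because rendering and analyzing a core
takes a few seconds; every test consumes them read-only.
"""

import numpy as np
import pytest

from ringquant.pipeline import analyze_core_image, match_to_truth
from ringquant.scoring import train_tumor_stroma_classifier
from ringquant.synth import SyntheticCoreSpec, generate_ihc_core


@pytest.fixture(scope="session")
def training_core():
    """A small annotated core used only to train the tumor/stroma forest."""
    spec = SyntheticCoreSpec(
        n_tumor_cells=80, n_stromal_cells=40, fraction_pn_positive=0.3,
        fraction_diffuse=0.3, seed=424,
    )
    image, truth = generate_ihc_core(spec)
    cells = analyze_core_image(image)
    matched = match_to_truth(cells, truth)
    return matched


@pytest.fixture(scope="session")
def tumor_stroma_classifier(training_core):
    return train_tumor_stroma_classifier(
        training_core, training_core["cell_class_true"], seed=0
    )


@pytest.fixture(scope="session")
def clean_core_40():
    """200 tumor cells, 40% perinuclear-positive, clean staining + stroma."""
    spec = SyntheticCoreSpec(
        n_tumor_cells=200, n_stromal_cells=50, fraction_pn_positive=0.4,
        fraction_diffuse=0.3, noise_sd=0.0, seed=11,
    )
    return spec, *generate_ihc_core(spec)


@pytest.fixture(scope="session")
def clean_core_0():
    """200 tumor cells, no perinuclear positives, clean staining."""
    spec = SyntheticCoreSpec(
        n_tumor_cells=200, n_stromal_cells=50, fraction_pn_positive=0.0,
        fraction_diffuse=0.3, noise_sd=0.0, seed=12,
    )
    return spec, *generate_ihc_core(spec)


@pytest.fixture(scope="session")
def pattern_core():
    """100 perinuclear + 100 strongly-stained diffuse tumor cells."""
    spec = SyntheticCoreSpec(
        n_tumor_cells=200, n_stromal_cells=0, fraction_pn_positive=0.5,
        fraction_diffuse=0.5, seed=13,
    )
    return spec, *generate_ihc_core(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
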