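"""Shared fixtures: seeded synthetic reference bundles and classifiers.

Bundles are session-scoped because building one involves NJ + GTR fitting
and ancestral reconstruction (~seconds).  All randomness is seeded; the
suite is deterministic end to end.
"""

from __future__ import annotations

import numpy as np
import pytest

from vdjplace.classify import Classifier
from vdjplace.synthetic import synthetic_bundle, synthetic_reference


@pytest.fixture(scope="session")
def bundle():
    """Default synthetic reference: 4 V families x 3 genes x 2 alleles."""
    return synthetic_bundle(0)


@pytest.fixture(scope="session")
def small_bundle():
    """Smaller reference for exhaustive-search oracles."""
    return synthetic_bundle(
        1, n_families=3, genes_per_family=2, alleles_per_gene=2,
        n_d_genes=6, n_j_genes=2,
    )


@pytest.fixture(scope="session")
def reference_set():
    return synthetic_reference(0)


@pytest.fixture(scope="session")
def classifier(bundle):
    return Classifier(bundle, seed=11)


@pytest.fixture(scope="session")
def small_classifier(small_bundle):
    return Classifier(small_bundle, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
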