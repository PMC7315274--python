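import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("reproducible", derandomize=True, deadline=None)
settings.load_profile("reproducible")

from epiforest import (
    EpitopeFeaturizer,
    GeneratorConfig,
    NEGATIVE,
    POSITIVE,
    Peptide,
    generate_dataset,
)
from epiforest.peptides import STANDARD_AA


def random_peptides(rng, n, lengths=(8, 9, 10, 11), with_rank=True, labeled=False):
    """Uniform random peptides for oracle checks."""
    peptides = []
    for i in range(n):
        length = int(rng.choice(lengths))
        seq = "".join(rng.choice(list(STANDARD_AA), size=length))
        peptides.append(
            Peptide(
                id=f"r{i:05d}",
                sequence=seq,
                rank_percent=float(np.round(rng.uniform(0.01, 10), 3)) if with_rank else None,
                label=(POSITIVE if i % 2 == 0 else NEGATIVE) if labeled else None,
            )
        )
    return peptides


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260924)


@pytest.fixture(scope="session")
def labeled_peptides(rng):
    """A small labeled random set for frequency-model fitting."""
    return random_peptides(rng, 60, labeled=True)


@pytest.fixture(scope="session")
def frequency_model(labeled_peptides):
    from epiforest import estimate_contact_frequencies

    return estimate_contact_frequencies(labeled_peptides)


@pytest.fixture(scope="session")
def strong_dataset():
    """Strongly separated synthetic corpus (300 records per class)."""
    config = GeneratorConfig(n_pos=300, n_neg=300, effect_size="strong", seed=42)
    return generate_dataset(config)


@pytest.fixture(scope="session")
def strong_features(strong_dataset):
    labels = [p.label for p in strong_dataset]
    X = EpitopeFeaturizer().fit(strong_dataset).transform(strong_dataset)
    return X, labels
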