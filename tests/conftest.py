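import numpy as np
import pytest

from acsarch.motifs import AA_ALPHABET, BackgroundModel, build_motif_model
from acsarch.simulate import FamilySpec, sample_family, family_motif_models


@pytest.fixture(scope="session")
def uniform_bg():
    return BackgroundModel.uniform()


def random_protein(rng, n: int) -> str:
    return "".join(AA_ALPHABET[j] for j in rng.integers(0, 20, size=n))


@pytest.fixture(scope="session")
def benchmark_family():
    """The 50+50 benchmark family at conservation 0.9 with its models."""
    spec = FamilySpec(seed=20211110)
    records, truth = sample_family(spec)
    models = family_motif_models(records, truth, spec.background)
    return spec, records, truth, models


@pytest.fixture(scope="session")
def perfect_family():
    """A small fully-conserved family (c = 1.0) for exact-rule checks."""
    spec = FamilySpec(
        seed=7, conservation=1.0, n_positive=4,
        n_negative_by_class={
            "missing_motif": 3, "scrambled_order": 2, "q98_mutant": 2,
            "n217_mutant": 2, "seven_motif_only": 2, "aat_control": 2,
        },
    )
    records, truth = sample_family(spec)
    models = family_motif_models(records, truth, spec.background)
    return spec, records, truth, models
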