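import numpy as np
import pytest

from genefam import simulate


@pytest.fixture(scope="session")
def models():
    """Default consensus models at a comfortable identity threshold."""
    return simulate.default_domain_models(min_identity=0.8)


@pytest.fixture(scope="session")
def md_model(models):
    return next(m for m in models if m.name == "MD")


@pytest.fixture(scope="session")
def small_proteome(models):
    """Three clades, distinct architectures, mild substitution noise."""
    spec = simulate.FamilySpec(
        architectures=(
            ("SP", "LRR", "MD", "TMD", "PK"),
            ("SP", "MLD", "TMD", "PK"),
            ("MD", "Kin"),
        ),
        genes_per_clade=(4, 3, 3),
        substitution_rate=0.05,
        background_genes=10,
    )
    return spec, simulate.generate_proteome(spec, models, seed=11)
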