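import pytest

from matrisopy import rules, simulate


@pytest.fixture(scope="session")
def default_rules():
    return rules.default_rules()


@pytest.fixture(scope="session")
def proteome_bundle():
    """A synthetic proteome with 10 proteins per class plus duplicates."""
    return simulate.generate_proteome(
        {cls: 10 for cls in simulate.ARCHITECTURES}, seed=42,
        duplicate_pairs=5)


@pytest.fixture(scope="session")
def tmt_bundle():
    return simulate.generate_tmt(
        m_proteins=600, n_per_stage=4, de_fraction=0.05, seed=7)


@pytest.fixture(scope="session")
def atlas_bundle():
    return simulate.generate_atlas(seed=11)
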