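import pytest

from synmend.pipeline import correct_genome, detect_misassemblies
from synmend.synthetic_data import (
    FragmentSpec,
    InversionSpec,
    PanelConfig,
    generate_annotation_fixture,
    generate_pseudogene_ledger,
    generate_scenario,
)

# compact study conditions used by most tests; the full-size defaults are
# exercised in the acceptance suite
SMALL_PANEL = dict(
    n_strains=3, genome_length_bp=150_000, n_genes=140, n_rrna_operons=3, n_trna=8
)
SMALL_FRAG = FragmentSpec(n_cds=4, n_trna=1, displacement_bp=40_000)
SMALL_INV = InversionSpec(n_cds=3, n_trna=1, length_bp=4_000)

TINY_PANEL = dict(
    n_strains=2, genome_length_bp=120_000, n_genes=100, n_rrna_operons=3, n_trna=8
)
TINY_FRAG = FragmentSpec(n_cds=4, n_trna=1, displacement_bp=30_000)
TINY_INV = InversionSpec(n_cds=3, n_trna=1, length_bp=4_000)


@pytest.fixture(scope="session")
def small_scenario():
    return generate_scenario(PanelConfig(seed=7, **SMALL_PANEL), SMALL_FRAG, SMALL_INV)


@pytest.fixture(scope="session")
def small_detection(small_scenario):
    return detect_misassemblies(small_scenario.query, small_scenario.panel)


@pytest.fixture(scope="session")
def small_correction(small_detection):
    return correct_genome(small_detection)


@pytest.fixture(scope="session")
def annotation_fixture_small():
    # (supports_new, supports_original, supports_neither, identical, omitted)
    return generate_annotation_fixture((12, 7, 4, 30, 9), seed=21)


@pytest.fixture(scope="session")
def pseudogene_fixture_small():
    return generate_pseudogene_ledger(5, 3, 4, seed=13)
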