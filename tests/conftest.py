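import logging

import pytest

from motifinc import load_annotation, load_motifs
from motifinc.regulation import classify_catalog
from motifinc.simulate import simulate_fixture, write_fixture

logging.getLogger("motifinc").setLevel(logging.ERROR)

FIXTURE_SEED = 17


@pytest.fixture(scope="session")
def fixture():
    """The default 64-gene synthetic fixture, in memory."""
    return simulate_fixture(seed=FIXTURE_SEED)


@pytest.fixture(scope="session")
def fixture_dir(fixture, tmp_path_factory):
    """The fixture written to disk as GTF/FASTA/TSV files."""
    out = tmp_path_factory.mktemp("fixture")
    paths = write_fixture(fixture, out)
    return paths


@pytest.fixture(scope="session")
def loaded(fixture_dir):
    """(annotation, catalog) round-tripped through the on-disk formats."""
    ann = load_annotation(
        fixture_dir["gtf"],
        genome_fasta=fixture_dir["genome"],
        protein_fasta=fixture_dir["proteins"],
    )
    cat = load_motifs(fixture_dir["motifs"], annotation=ann)
    return ann, cat


@pytest.fixture(scope="session")
def records(loaded):
    ann, cat = loaded
    return classify_catalog(cat, ann)


@pytest.fixture(scope="session")
def truth(fixture):
    return fixture.truth_motifs.set_index("motif_id")
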