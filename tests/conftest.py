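import pytest

from nixlocus.annotate import infer_introns
from nixlocus.synthetic import (
    fixture_primer_panel,
    fragment_genome,
    make_canonical_fixture,
    make_transcript_db,
)
from nixlocus.walker import walk

SESSION_SEED = 0


@pytest.fixture(scope="session")
def locus():
    """The canonical synthetic locus fixture (1580-nt composite)."""
    return make_canonical_fixture(rng_seed=SESSION_SEED)


@pytest.fixture(scope="session")
def genomic_db(locus):
    return fragment_genome(locus, rng_seed=SESSION_SEED)


@pytest.fixture(scope="session")
def transcript_db(locus):
    return make_transcript_db(locus, rng_seed=SESSION_SEED)


@pytest.fixture(scope="session")
def assembly(locus, genomic_db, transcript_db):
    return walk(locus.seed, [("genome", genomic_db), ("transcriptome", transcript_db)])


@pytest.fixture(scope="session")
def gene_model(locus):
    return infer_introns(locus.composite, locus.spliced_transcript)


@pytest.fixture(scope="session")
def panel(locus):
    return fixture_primer_panel(locus)
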