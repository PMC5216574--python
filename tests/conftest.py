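import pytest
from hypothesis import HealthCheck, settings

from intronarch import synthetic_data as synth
from intronarch.gene_models import extract_architecture, read_gene_model

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")

FIXTURE_SEED = 1


@pytest.fixture(scope="session")
def fixture_records():
    return synth.load_fixture_records()


@pytest.fixture(scope="session")
def fixture_set(tmp_path_factory):
    """All 39 recorded genes realised as FASTA + GFF3 files."""
    out = tmp_path_factory.mktemp("fixtures")
    return synth.build_fixture_models(out, seed=FIXTURE_SEED)


@pytest.fixture(scope="session")
def parsed_fixtures(fixture_set):
    """code -> (GeneModel, ArchitectureRecord, FixturePaths) for all records."""
    parsed = {}
    for code, fp in fixture_set.items():
        model = read_gene_model(fp.gff3, fp.fasta, fp.gene_id, code)
        parsed[code] = (model, extract_architecture(model), fp)
    return parsed
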