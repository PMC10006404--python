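from pathlib import Path

import pytest

import sphnkit as sk
from sphnkit import fixtures
from sphnkit.provider_pipeline import (MartConfig, apply_mappings, deidentify,
                                       generate_datamart, pseudonymize,
                                       to_instances)
from sphnkit.terminology_rdf import convert_terminology

DATA = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def mini_dataset():
    return fixtures.mini_dataset()


@pytest.fixture(scope="session")
def snomed_table():
    return fixtures.toy_snomed()


@pytest.fixture(scope="session")
def ucum_table():
    return fixtures.toy_ucum()


@pytest.fixture(scope="session")
def snomed_graph(snomed_table):
    return convert_terminology(snomed_table)


@pytest.fixture(scope="session")
def ucum_graph(ucum_table):
    return convert_terminology(ucum_table)


@pytest.fixture(scope="session")
def schema(mini_dataset, snomed_graph, ucum_graph, snomed_table, ucum_table):
    return sk.compile_schema(mini_dataset, [snomed_graph, ucum_graph],
                             {"SNOMED": snomed_table, "UCUM": ucum_table})


@pytest.fixture(scope="session")
def shapes(schema, snomed_graph, ucum_graph):
    return sk.generate_shapes(schema, [snomed_graph, ucum_graph])


@pytest.fixture(scope="session")
def mapping(mini_dataset):
    return fixtures.default_mapping(mini_dataset.namespace)


def run_pipeline(schema, mapping, *, seed, n_patients, provider="test",
                 config=None):
    """Mart → pseudonymise → deidentify → map → instances, for tests."""
    cfg = config or MartConfig(n_patients=n_patients)
    mart = generate_datamart(cfg, seed=seed)
    mart = deidentify(pseudonymize(mart, f"test-key-{seed}"))
    views, rejections = apply_mappings(mart, mapping)
    data = to_instances(views, schema, provider=provider, seed=seed)
    return data, views, rejections


@pytest.fixture(scope="session")
def instance_graph(schema, mapping):
    data, _, _ = run_pipeline(schema, mapping, seed=11, n_patients=20)
    return data
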