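"""Bundled desk-scale fixture world.

A six-concept dataset definition (Heart Rate, Oxygen Saturation, Allergy
Episode, Quantity, Unit, Subject Pseudo Identifier), toy SNOMED-CT-like and
UCUM-like terminology tables, and the local-to-standard mapping table that
connects the synthetic data mart to the compiled schema.  Everything here
is synthetic: the terminology tables reuse a handful of published code
numbers (e.g. Pulse Vegetable 227313005) purely so worked examples read
naturally, but their content is a hand-made miniature, not an excerpt of
any licensed release.
"""

from __future__ import annotations

from importlib import resources

from .dataset_model import DatasetDefinition, read_dataset
from .provider_pipeline import (LOCAL_REACTIONS, LOCAL_SEVERITIES,
                                LOCAL_SUBSTANCES, MappingRow, MappingTable)
from .schema_compiler import individual_iri
from .terminology_rdf import TerminologyTable, code_iri, read_terminology_csv


def _data_path(name: str):
    return resources.files("sphnkit").joinpath("data", name)


def mini_dataset(**kwargs) -> DatasetDefinition:
    """The six-concept dataset definition used throughout the examples."""
    with resources.as_file(_data_path("mini_sphn.csv")) as p:
        return read_dataset(p, **kwargs)


def toy_snomed() -> TerminologyTable:
    """Tiny SNOMED-CT-like hierarchy (substances, findings; 12 codes)."""
    with resources.as_file(_data_path("toy_snomed.csv")) as p:
        return read_terminology_csv(p, "SNOMED", "2022-02-07")


def toy_ucum() -> TerminologyTable:
    """Tiny flat UCUM-like unit list (5 unit tokens)."""
    with resources.as_file(_data_path("toy_ucum.csv")) as p:
        return read_terminology_csv(p, "UCUM", "2021.1")


#: local substance code → toy SNOMED code
SUBSTANCE_CODES = {
    "ALG-PEANUT": "256349002",
    "ALG-BEAN": "227380006",
    "ALG-LENTIL": "227314004",
    "ALG-EGG": "102263004",
}
REACTION_CODES = {"RASH": "271807003", "ANAPH": "39579001"}

#: root of the edible-substance subtree (allergy substances must descend
#: from it) and of the pulse-vegetable subtree used in the cohort query
EDIBLE_SUBSTANCE = "762766007"
PULSE_VEGETABLE = "227313005"


def default_mapping(namespace: str) -> MappingTable:
    """Local→standard mapping for the synthetic mart against the mini schema.

    Structural rows (``local_value='*'``) declare which concept a mart
    table feeds and which property path each column lands on; value rows
    translate local codes to terminology IRIs and value-set individuals.
    """
    rows = [
        MappingRow("heart_rate", "*", "*", "Heart Rate"),
        MappingRow("heart_rate", "patient_id", "*", "subject pseudo identifier"),
        MappingRow("heart_rate", "hr_bpm", "*", "quantity.value"),
        MappingRow("heart_rate", "unit", "*", "quantity.unit"),
        MappingRow("heart_rate", "measured_at", "*", "datetime"),
        MappingRow("oxygen_saturation", "*", "*", "Oxygen Saturation"),
        MappingRow("oxygen_saturation", "patient_id", "*",
                   "subject pseudo identifier"),
        MappingRow("oxygen_saturation", "spo2", "*", "quantity.value"),
        MappingRow("oxygen_saturation", "unit", "*", "unit"),
        MappingRow("oxygen_saturation", "measured_at", "*", "datetime"),
        MappingRow("allergy", "*", "*", "Allergy Episode"),
        MappingRow("allergy", "patient_id", "*", "subject pseudo identifier"),
        MappingRow("allergy", "substance", "*", "substance"),
        MappingRow("allergy", "reaction", "*", "reaction type"),
        MappingRow("allergy", "severity", "*", "severity"),
        MappingRow("allergy", "note", "*", "comment"),
        MappingRow("heart_rate", "unit", "bpm", str(code_iri("UCUM", "beats/min"))),
        MappingRow("oxygen_saturation", "unit", "pct", str(code_iri("UCUM", "%"))),
    ]
    for local in LOCAL_SUBSTANCES:
        rows.append(MappingRow("allergy", "substance", local,
                               str(code_iri("SNOMED", SUBSTANCE_CODES[local]))))
    for local in LOCAL_REACTIONS:
        rows.append(MappingRow("allergy", "reaction", local,
                               str(code_iri("SNOMED", REACTION_CODES[local]))))
    for local in LOCAL_SEVERITIES:
        rows.append(MappingRow(
            "allergy", "severity", local,
            str(individual_iri("Allergy Severity", local.capitalize(),
                               namespace))))
    table = MappingTable(rows)
    table.check()
    return table
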