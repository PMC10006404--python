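"""Compilation rules: naming conventions, translation, stats, serialisation."""

from pathlib import Path

import pytest

import sphnkit as sk
from sphnkit.dataset_model import (CodeBinding, ConceptDefinition,
                                   DatasetDefinition, PropertyDefinition)
from sphnkit.rdf import (BNode, DCTERMS, Graph, IRI, Literal, OWL, RDF, RDFS,
                         XSD, from_turtle, ground_triples)
from sphnkit.schema_compiler import (CompileError, NamingError, class_iri,
                                     compile_schema, property_iri,
                                     schema_stats, serialize_canonical,
                                     template_ontology, version_iri)
from sphnkit.terminology_rdf import code_iri

NS = "https://biomedit.ch/rdf/sphn-ontology/sphn"
DATA = Path(__file__).parent / "data"


class TestNamingConventions:
    @pytest.mark.parametrize("label,expected", [
        ("Heart Rate", f"{NS}#HeartRate"),
        ("Subject Pseudo Identifier", f"{NS}#SubjectPseudoIdentifier"),
        ("x", f"{NS}#X"),
        ("Oxygen  Saturation", f"{NS}#OxygenSaturation"),
        ("ICD-10 Code", f"{NS}#ICD10Code"),
    ])
    def test_classes_are_pascal_case(self, label, expected):
        assert class_iri(label, NS) == IRI(expected)

    @pytest.mark.parametrize("label,expected", [
        ("quantity", f"{NS}#hasQuantity"),
        ("subject pseudo identifier", f"{NS}#hasSubjectPseudoIdentifier"),
        ("hasUnit", f"{NS}#hasUnit"),      # idempotent on pre-prefixed labels
        ("has unit", f"{NS}#hasUnit"),
        ("reaction type", f"{NS}#hasReactionType"),
    ])
    def test_properties_start_with_has_in_camel_case(self, label, expected):
        assert property_iri(label, NS) == IRI(expected)

    @pytest.mark.parametrize("label", ["", "  ", "!!!"])
    def test_empty_local_names_rejected(self, label):
        with pytest.raises(NamingError):
            class_iri(label, NS)
        with pytest.raises(NamingError):
            property_iri(label, NS)

    def test_leading_digit_rejected(self):
        with pytest.raises(NamingError):
            class_iri("10th Revision", NS)

    def test_version_iri_pattern(self):
        assert version_iri(NS, 2022, 2) == IRI(f"{NS}/2022/2")


class TestCompileSchema:
    def test_refuses_inconsistent_dataset(self):
        ds = DatasetDefinition(concepts=[ConceptDefinition(
            "A", properties=[PropertyDefinition("q", "", "concept",
                                                "Ghost", 1, 1)])])
        with pytest.raises(CompileError) as err:
            compile_schema(ds)
        assert err.value.findings

    def test_empty_dataset_compiles_to_header_only(self):
        g = compile_schema(DatasetDefinition())
        assert g.version_iri == IRI(f"{NS}/2022/2")
        subjects = {s for s, _, _ in g}
        assert subjects == {IRI(NS)}
        st = schema_stats(g)
        assert (st.classes, st.object_properties, st.datatype_properties,
                st.named_individuals, st.restrictions) == (0, 0, 0, 0, 0)

    def test_ontology_header(self, schema, snomed_graph, ucum_graph):
        onto = IRI(NS)
        assert (onto, RDF.type, OWL.Ontology) in schema
        assert (onto, OWL.versionIRI, IRI(f"{NS}/2022/2")) in schema
        assert (onto, DCTERMS.license, Literal("CC BY 4.0")) in schema
        assert (onto, OWL.imports, snomed_graph.version_iri) in schema
        assert (onto, OWL.imports, ucum_graph.version_iri) in schema

    def test_concepts_become_labelled_classes(self, schema, mini_dataset):
        for concept in mini_dataset.concepts:
            cls = class_iri(concept.name, NS)
            assert (cls, RDF.type, OWL.Class) in schema
            assert schema.value(cls, RDFS.label) == Literal(concept.name)

    def test_object_vs_datatype_property_split(self, schema):
        object_props = {"hasSubjectPseudoIdentifier", "hasQuantity", "hasUnit",
                        "hasSubstance", "hasReactionType", "hasSeverity"}
        datatype_props = {"hasValue", "hasDatetime", "hasComment"}
        for local in object_props:
            assert (IRI(f"{NS}#{local}"), RDF.type, OWL.ObjectProperty) in schema
        for local in datatype_props:
            assert (IRI(f"{NS}#{local}"), RDF.type,
                    OWL.DatatypeProperty) in schema

    def test_range_only_for_schema_class_targets(self, schema):
        """hasQuantity gets range Quantity; code-valued hasUnit gets none."""
        assert schema.value(IRI(f"{NS}#hasQuantity"), RDFS.range) \
            == IRI(f"{NS}#Quantity")
        assert schema.value(IRI(f"{NS}#hasUnit"), RDFS.range) is None
        assert schema.value(IRI(f"{NS}#hasValue"), RDFS.range) == XSD.double

    def test_heart_rate_quantity_restriction(self, schema):
        """HeartRate is a subclass of a 1..1 restriction on hasQuantity."""
        hr = IRI(f"{NS}#HeartRate")
        restrictions = [o for o in schema.objects(hr, RDFS.subClassOf)
                        if isinstance(o, BNode)]
        on_quantity = [r for r in restrictions
                       if schema.value(r, OWL.onProperty)
                       == IRI(f"{NS}#hasQuantity")]
        assert len(on_quantity) == 1
        r = on_quantity[0]
        assert schema.value(r, OWL.minCardinality).value == 1
        assert schema.value(r, OWL.maxCardinality).value == 1

    def test_oxygen_saturation_unit_restriction_is_percent_only(self, schema):
        """The only allowed unit code is the UCUM percent IRI (hasValue)."""
        spo2 = IRI(f"{NS}#OxygenSaturation")
        values = []
        for r in schema.objects(spo2, RDFS.subClassOf):
            if isinstance(r, BNode) and schema.value(r, OWL.onProperty) \
                    == IRI(f"{NS}#hasUnit"):
                hv = schema.value(r, OWL.hasValue)
                if hv is not None:
                    values.append(hv)
        assert values == [code_iri("UCUM", "%")]

    def test_descendants_of_binding_stays_symbolic(self, schema):
        """The substance restriction points at the root code class."""
        ae = IRI(f"{NS}#AllergyEpisode")
        targets = [schema.value(r, OWL.allValuesFrom)
                   for r in schema.objects(ae, RDFS.subClassOf)
                   if isinstance(r, BNode)
                   and schema.value(r, OWL.onProperty) == IRI(f"{NS}#hasSubstance")
                   and schema.value(r, OWL.allValuesFrom) is not None]
        assert targets == [code_iri("SNOMED", "762766007")]

    def test_meaning_bindings_become_equivalent_classes(self, schema):
        hr = IRI(f"{NS}#HeartRate")
        assert (hr, OWL.equivalentClass,
                code_iri("SNOMED", "364075005")) in schema
        spo2 = IRI(f"{NS}#OxygenSaturation")
        assert (spo2, OWL.equivalentClass, code_iri("LOINC", "59408-5")) in schema

    def test_value_set_members_become_individuals(self, schema):
        for member in ("Mild", "Moderate", "Severe"):
            ind = IRI(f"{NS}#AllergySeverity-{member}")
            assert (ind, RDF.type, OWL.NamedIndividual) in schema
            assert schema.value(ind, RDFS.label) == Literal(member)

    def test_parent_concept_becomes_subclass_of(self):
        ds = DatasetDefinition(concepts=[
            ConceptDefinition("Measurement", "grouping class"),
            ConceptDefinition("Body Weight", parent="Measurement"),
        ])
        g = compile_schema(ds)
        assert (class_iri("Body Weight", NS), RDFS.subClassOf,
                class_iri("Measurement", NS)) in g

    def test_property_used_as_object_and_datatype_is_an_error(self):
        ds = DatasetDefinition(concepts=[
            ConceptDefinition("A", properties=[
                PropertyDefinition("value", "", "quantitative", None, 0, 1)]),
            ConceptDefinition("B", properties=[
                PropertyDefinition("value", "", "concept", "A", 0, 1)]),
        ])
        with pytest.raises(CompileError, match="object and datatype"):
            compile_schema(ds)

    def test_label_collision_is_an_error(self):
        ds = DatasetDefinition(concepts=[
            ConceptDefinition("A", properties=[
                PropertyDefinition("body weight", "", "string", None, 0, 1),
                PropertyDefinition("body-weight", "", "string", None, 0, 1)])])
        with pytest.raises(CompileError, match="collision"):
            compile_schema(ds)

    def test_compile_is_additive_over_disjoint_union(self, mini_dataset,
                                                     snomed_graph, ucum_graph):
        """Adding concepts only ever adds triples (monotone compile)."""
        import copy
        bigger = copy.deepcopy(mini_dataset)
        bigger.concepts.append(ConceptDefinition(
            "Body Temperature", "new measurement", properties=[
                PropertyDefinition("quantity", "", "concept", "Quantity", 1, 1),
            ]))
        from collections import Counter
        from sphnkit.rdf import signature_ground
        small = compile_schema(mini_dataset, [snomed_graph, ucum_graph])
        large = compile_schema(bigger, [snomed_graph, ucum_graph])
        small_t = Counter(signature_ground(small))
        large_t = Counter(signature_ground(large))
        assert small_t <= large_t
        assert large_t.total() > small_t.total()


class TestRoundTripToDataset:
    def test_decompilation_recovers_structure(self, schema, mini_dataset):
        """Names, kinds and cardinalities survive compilation exactly."""
        for concept in mini_dataset.concepts:
            cls = class_iri(concept.name, NS)
            restrictions = {}
            for r in schema.objects(cls, RDFS.subClassOf):
                if isinstance(r, BNode):
                    prop = schema.value(r, OWL.onProperty)
                    mn = schema.value(r, OWL.minCardinality)
                    mx = schema.value(r, OWL.maxCardinality)
                    if mn is not None or mx is not None:
                        restrictions[prop] = (
                            0 if mn is None else int(mn.value),
                            None if mx is None else int(mx.value))
            for p in concept.properties:
                piri = property_iri(p.name, NS)
                expected_kind = OWL.ObjectProperty \
                    if p.value_kind in ("concept", "code", "valueset") \
                    else OWL.DatatypeProperty
                assert (piri, RDF.type, expected_kind) in schema
                assert schema.value(piri, RDFS.label) == Literal(p.name)
                if p.min_card > 0 or p.max_card is not None:
                    assert restrictions[piri] == (p.min_card, p.max_card)


class TestStatsAndSerialisation:
    def test_mini_fixture_manifest(self, schema):
        """Hand-counted manifest: 6 classes, 6+3 properties, 3 individuals,
        19 restrictions (14 cardinality + 5 allowed-value)."""
        st = schema_stats(schema)
        assert st.classes == 6
        assert st.object_properties == 6
        assert st.datatype_properties == 3
        assert st.object_properties + st.datatype_properties == 9
        assert st.named_individuals == 3
        assert st.restrictions == 19

    def test_stats_ignore_foreign_namespaces(self, schema, snomed_graph):
        merged = schema.copy()
        merged.update(snomed_graph)
        assert schema_stats(merged, str(IRI(NS)) + "#") == schema_stats(schema)

    def test_canonical_turtle_matches_golden_file(self, schema):
        golden = (DATA / "golden_mini_schema.ttl").read_bytes()
        assert serialize_canonical(schema, "turtle") == golden

    def test_owl_xml_round_trip(self, schema):
        data = serialize_canonical(schema, "owl-xml")
        from sphnkit.rdf import from_rdfxml, isomorphic
        assert isomorphic(from_rdfxml(data), schema)

    def test_unsupported_format(self, schema):
        with pytest.raises(ValueError, match="unsupported"):
            serialize_canonical(schema, "n3")

    def test_turtle_parse_serialise_fixpoint(self, schema):
        b1 = serialize_canonical(schema, "turtle")
        g2 = from_turtle(b1)
        assert serialize_canonical(g2, "turtle") == b1


class TestTemplateOntology:
    def test_prefills_imports_and_metadata(self, schema, snomed_graph):
        t = template_ontology("https://example.org/project-x", schema,
                              [snomed_graph])
        onto = IRI("https://example.org/project-x")
        assert (onto, OWL.imports, schema.version_iri) in t
        assert (onto, OWL.imports, snomed_graph.version_iri) in t
        assert (onto, DCTERMS.license, Literal("CC BY 4.0")) in t
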