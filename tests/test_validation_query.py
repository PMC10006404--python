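"""SHACL validation, report rendering, RDFS entailment and queries."""

import numpy as np
import pandas as pd
import pytest

import sphnkit as sk
from conftest import run_pipeline
from sphnkit.provider_pipeline import inject_violations
from sphnkit.rdf import Graph, IRI, Literal, Namespace, RDF, RDFS, XSD
from sphnkit.terminology_rdf import code_iri
from sphnkit.validation_query import (StatsTable, VersionMismatchError,
                                      hierarchy_query, rdfs_closure,
                                      render_report, report_from_json,
                                      run_template_queries, validate)

NS = "https://biomedit.ch/rdf/sphn-ontology/sphn"
EX = Namespace("https://example.org/t#")


def brute_force_rdfs_closure(g):
    """Independent oracle: apply the two RDFS rules until nothing changes."""
    triples = set(g)
    changed = True
    while changed:
        changed = False
        subclass = [(s, o) for s, p, o in triples if p == RDFS.subClassOf]
        types = [(s, o) for s, p, o in triples if p == RDF.type]
        for a, b in subclass:
            for c, d in subclass:
                if b == c and (a, RDFS.subClassOf, d) not in triples \
                        and a != d:
                    triples.add((a, RDFS.subClassOf, d))
                    changed = True
        for x, cls in types:
            for a, b in subclass:
                if cls == a and (x, RDF.type, b) not in triples:
                    triples.add((x, RDF.type, b))
                    changed = True
    out = Graph()
    for t in triples:
        out.add(*t)
    return out


class TestValidate:
    def test_conformant_pipeline_output(self, schema, shapes, mapping,
                                        snomed_graph, ucum_graph):
        data, _, _ = run_pipeline(schema, mapping, seed=21, n_patients=20)
        report = validate(data, shapes, [schema, snomed_graph, ucum_graph])
        assert report.conforms and report.violations == []

    def test_every_injected_violation_is_reported(self, schema, shapes,
                                                  mapping, snomed_graph,
                                                  ucum_graph):
        data, _, _ = run_pipeline(schema, mapping, seed=22, n_patients=30)
        spec = {"missing_required": 4, "extra_beyond_max": 3,
                "wrong_datatype": 3, "code_not_allowed": 3, "wrong_unit": 2}
        mutated, manifest = inject_violations(data, shapes, spec, seed=5)
        report = validate(mutated, shapes, [schema, snomed_graph, ucum_graph])
        assert not report.conforms
        assert len(report.violations) >= len(manifest) == 15
        violation_pairs = {(v.focus, v.path) for v in report.violations}
        manifest_pairs = {(m.instance, m.path) for m in manifest}
        assert manifest_pairs <= violation_pairs

    def test_wrong_oxygen_unit_cites_allowed_value_constraint(
            self, schema, shapes, snomed_graph, ucum_graph):
        """An oxygen-saturation instance annotated beats/min must fail on
        the hasUnit path with the allowed-value (sh:in) constraint."""
        views = {"Oxygen Saturation": pd.DataFrame({
            "subject pseudo identifier": ["p1"],
            "quantity.value": [97.0],
            "unit": [str(code_iri("UCUM", "beats/min"))],
        })}
        data = sk.to_instances(views, schema, provider="x", seed=0)
        report = validate(data, shapes, [schema, snomed_graph, ucum_graph])
        assert not report.conforms
        kinds = {(str(v.path).rsplit("#", 1)[-1], v.kind)
                 for v in report.violations}
        assert ("hasUnit", "InConstraintComponent") in kinds

    def test_violations_sorted_by_focus_then_path(self, schema, shapes,
                                                  mapping, snomed_graph,
                                                  ucum_graph):
        data, _, _ = run_pipeline(schema, mapping, seed=23, n_patients=20)
        mutated, _ = inject_violations(
            data, shapes, {"missing_required": 6, "wrong_datatype": 4}, seed=6)
        report = validate(mutated, shapes, [schema, snomed_graph, ucum_graph])
        keys = [(str(v.focus), str(v.path)) for v in report.violations]
        assert keys == sorted(keys)

    def test_schema_version_mismatch_is_a_hard_error(self, schema, shapes,
                                                     mapping):
        data, _, _ = run_pipeline(schema, mapping, seed=24, n_patients=2)
        from sphnkit.rdf import DCTERMS
        doc = data.ontology_iri
        data.discard(doc, DCTERMS.conformsTo, schema.version_iri)
        data.add(doc, DCTERMS.conformsTo, IRI(f"{NS}/2021/1"))
        with pytest.raises(VersionMismatchError):
            validate(data, shapes, [schema])


class TestRenderReport:
    def test_empty_report_single_line_summary(self):
        from sphnkit.validation_query import ValidationReport
        text = render_report(ValidationReport(True), "text").decode()
        assert text.splitlines()[0] == "Conforms: true"

    def test_header_count_equals_list_length(self, schema, shapes, mapping,
                                             snomed_graph, ucum_graph):
        data, _, _ = run_pipeline(schema, mapping, seed=25, n_patients=20)
        mutated, _ = inject_violations(data, shapes,
                                       {"missing_required": 5}, seed=7)
        report = validate(mutated, shapes, [schema, snomed_graph, ucum_graph])
        text = render_report(report, "text").decode()
        assert f"Violations: {len(report.violations)}" in text
        assert len(report.violations) == 5

    def test_json_round_trip(self, schema, shapes, mapping, snomed_graph,
                             ucum_graph):
        data, _, _ = run_pipeline(schema, mapping, seed=25, n_patients=10)
        mutated, _ = inject_violations(data, shapes, {"wrong_unit": 2}, seed=8)
        report = validate(mutated, shapes, [schema, snomed_graph, ucum_graph])
        assert report_from_json(render_report(report, "json")) == report


class TestRdfsClosure:
    def test_type_propagates_to_ancestors(self):
        g = Graph()
        g.add(EX.Peanut, RDFS.subClassOf, EX.PulseVegetable)
        g.add(EX.x, RDF.type, EX.Peanut)
        closed = rdfs_closure(g)
        assert (EX.x, RDF.type, EX.PulseVegetable) in closed

    def test_no_subclass_triples_means_no_change(self):
        g = Graph()
        g.add(EX.x, RDF.type, EX.Thing)
        g.add(EX.x, RDFS.label, Literal("x"))
        assert rdfs_closure(g) == g

    def test_idempotent_and_monotone(self, instance_graph, schema):
        merged = instance_graph.copy()
        merged.update(schema)
        once = rdfs_closure(merged)
        assert rdfs_closure(once) == once
        assert set(merged) <= set(once)

    def test_matches_brute_force_oracle_on_random_graphs(self):
        """50 random class forests with typed instances, vs the naive
        fixpoint oracle."""
        for trial in range(50):
            rng = np.random.default_rng(1000 + trial)
            n_classes = int(rng.integers(2, 20))
            g = Graph()
            for i in range(1, n_classes):
                if rng.random() < 0.8:
                    g.add(EX.term(f"C{i}"), RDFS.subClassOf,
                          EX.term(f"C{rng.integers(0, i)}"))
            for j in range(int(rng.integers(1, 30))):
                g.add(EX.term(f"x{j}"), RDF.type,
                      EX.term(f"C{rng.integers(0, n_classes)}"))
            assert rdfs_closure(g) == brute_force_rdfs_closure(g)


class TestHierarchyQuery:
    @pytest.fixture()
    def allergy_world(self, schema):
        """10 patients; p1-p4 allergic to pulse vegetables, p5 to eggs,
        p6-p10 without episodes."""
        substances = {"p1": "256349002", "p2": "227380006",
                      "p3": "227314004", "p4": "256349002",
                      "p5": "102263004"}
        views = {
            "Allergy Episode": pd.DataFrame({
                "subject pseudo identifier": list(substances),
                "substance": [str(code_iri("SNOMED", c))
                              for c in substances.values()],
            }),
            "Heart Rate": pd.DataFrame({
                "subject pseudo identifier": [f"p{i}" for i in range(1, 11)],
                "quantity.value": [70.0] * 10,
                "quantity.unit": [str(code_iri("UCUM", "beats/min"))] * 10,
            }),
        }
        return sk.to_instances(views, schema, provider="q", seed=0)

    def patient_node(self, g, pseudo):
        return IRI(f"https://biomedit.ch/rdf/sphn-resource/q/"
                   f"SubjectPseudoIdentifier/{pseudo}")

    def test_pulse_vegetable_cohort(self, allergy_world, snomed_graph):
        got = hierarchy_query(allergy_world, IRI(f"{NS}#AllergyEpisode"),
                              code_iri("SNOMED", "227313005"), [snomed_graph])
        expected = {self.patient_node(allergy_world, p)
                    for p in ("p1", "p2", "p3", "p4")}
        assert got == expected

    def test_leaf_root_matches_exact_code_only(self, allergy_world,
                                               snomed_graph):
        got = hierarchy_query(allergy_world, IRI(f"{NS}#AllergyEpisode"),
                              code_iri("SNOMED", "256349002"), [snomed_graph])
        assert got == {self.patient_node(allergy_world, p)
                       for p in ("p1", "p4")}

    def test_no_episodes_empty_result(self, schema, snomed_graph):
        g = sk.to_instances({}, schema, provider="q", seed=0)
        assert hierarchy_query(g, IRI(f"{NS}#AllergyEpisode"),
                               code_iri("SNOMED", "227313005"),
                               [snomed_graph]) == set()

    def test_monotone_along_the_hierarchy(self, allergy_world, snomed_graph):
        """Querying a parent code returns a superset of any child's cohort."""
        episode = IRI(f"{NS}#AllergyEpisode")
        parent = hierarchy_query(allergy_world, episode,
                                 code_iri("SNOMED", "762766007"),
                                 [snomed_graph])
        for child in ("227313005", "256349002", "102263004"):
            sub = hierarchy_query(allergy_world, episode,
                                  code_iri("SNOMED", child), [snomed_graph])
            assert sub <= parent

    def test_unknown_root_rejected(self, allergy_world, snomed_graph):
        from sphnkit.terminology_rdf import TerminologyError
        with pytest.raises(TerminologyError):
            hierarchy_query(allergy_world, IRI(f"{NS}#AllergyEpisode"),
                            IRI("http://snomed.info/id/0"), [snomed_graph])


class TestTemplateQueries:
    def test_class_counts_match_pipeline(self, schema, mapping):
        from sphnkit.provider_pipeline import MartConfig
        data, _, _ = run_pipeline(schema, mapping, seed=26, n_patients=100,
                                  config=MartConfig(n_patients=100,
                                                    heart_rate_per_patient=3))
        stats = run_template_queries(data, schema)
        assert stats.class_counts[IRI(f"{NS}#HeartRate")] == 300
        assert stats.metadata["schema_version"] == str(schema.version_iri)
        assert stats.metadata["provider"] == "test"

    def test_empty_graph_empty_table(self, schema):
        stats = run_template_queries(Graph(), schema)
        assert stats.class_counts == {} and stats.property_counts == {}

    def test_counts_invariant_under_closure_for_leaf_classes(self, schema,
                                                             mapping):
        data, _, _ = run_pipeline(schema, mapping, seed=27, n_patients=10)
        before = run_template_queries(data, schema).class_counts
        after = run_template_queries(rdfs_closure(data), schema).class_counts
        assert before == after  # mini schema has no class hierarchy
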