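"""Compile a dataset definition into an OWL/RDF schema graph.

Translation rules
-----------------
* concept → ``owl:Class`` with ``rdfs:label`` and a comment annotation;
  Pascal-case IRIs (``Heart Rate`` → ``…#HeartRate``).
* parent concept → ``rdfs:subClassOf``.
* composedOf property → ``owl:ObjectProperty`` for concept-, code- and
  value-set-valued properties, ``owl:DatatypeProperty`` for quantitative,
  temporal and string values; property IRIs start with ``has`` in camel
  case (``quantity`` → ``…#hasQuantity``).
* ``rdfs:range`` is declared only when the target is another class of the
  same schema (codes and value sets are constrained per using class
  instead).
* code / value-set targets → ``owl:Restriction`` on the *using* class:
  ``owl:hasValue`` for a single allowed value, an ``owl:oneOf``
  enumeration for several, and ``owl:allValuesFrom <root>`` for
  descendants-of bindings (the allowed set is then the subclass closure of
  the root in the terminology, resolved downstream).
* cardinalities → ``owl:minCardinality`` / ``owl:maxCardinality`` inside a
  restriction; an unbounded maximum is simply omitted.
* meaning binding → ``owl:equivalentClass`` to the terminology code IRI
  (one axiom per bound code).
* value-set member → ``owl:NamedIndividual`` typed with its set's class,
  IRI ``…#SetName-MemberLabel``.

The ontology header carries the version IRI
``<namespace>/<year>/<index>``, a CC BY 4.0 licence annotation and one
``owl:imports`` per supplied terminology.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Optional

from .dataset_model import (CodeBinding, DatasetDefinition, check_dataset)
from .rdf import (BNode, DCTERMS, Graph, IRI, Literal, Namespace, OWL, RDF,
                  RDFS, XSD, _fresh_bnode, literal, to_rdfxml, to_turtle)
from .terminology_rdf import code_iri

#: value_kind → xsd datatype for datatype properties.
DATATYPE_MAP = {
    "quantitative": XSD.double,
    "temporal": XSD.dateTime,
    "string": XSD.string,
}

OBJECT_KINDS = {"concept", "code", "valueset"}

LICENSE = "CC BY 4.0"


class NamingError(ValueError):
    """A label cannot be turned into a legal IRI local name."""


class CompileError(ValueError):
    def __init__(self, message: str, findings=()):
        super().__init__(message)
        self.findings = list(findings)


_CLEAN = re.compile(r"[^A-Za-z0-9 ]+")


def _tokens(label: str) -> list[str]:
    cleaned = _CLEAN.sub(" ", label)
    return cleaned.split()


def _pascal(label: str) -> str:
    toks = _tokens(label)
    name = "".join(t[0].upper() + t[1:] for t in toks)
    if not name:
        raise NamingError(f"label {label!r} reduces to an empty local name")
    if name[0].isdigit():
        raise NamingError(f"label {label!r} would produce a leading digit")
    return name


def class_iri(label: str, namespace: str) -> IRI:
    """Pascal-case class IRI: ('Heart Rate', ns) → <ns#HeartRate>."""
    return IRI(f"{namespace}#{_pascal(label)}")


def property_iri(label: str, namespace: str) -> IRI:
    """Camel-case property IRI with a 'has' prefix; idempotent on labels
    that already start with it ('hasUnit' stays 'hasUnit')."""
    toks = _tokens(label)
    if not toks:
        raise NamingError(f"label {label!r} reduces to an empty local name")
    if toks[0] == "has" and len(toks) > 1:
        toks = toks[1:]
    elif len(toks) == 1 and re.match(r"\Ahas[A-Z0-9]", toks[0]):
        return IRI(f"{namespace}#{toks[0]}")
    local = "has" + "".join(t[0].upper() + t[1:] for t in toks)
    if local[3].isdigit():
        raise NamingError(f"label {label!r} would produce a leading digit")
    return IRI(f"{namespace}#{local}")


def individual_iri(set_name: str, member: str, namespace: str) -> IRI:
    return IRI(f"{namespace}#{_pascal(set_name)}-{_pascal(member)}")


def version_iri(namespace: str, year: int, index: int) -> IRI:
    return IRI(f"{namespace}/{year}/{index}")


def compile_schema(dataset: DatasetDefinition,
                   terminologies: Iterable[Graph] = (),
                   terminology_tables: Optional[dict] = None) -> Graph:
    """Compile a checked dataset definition into a schema graph.

    ``terminologies`` are converted terminology graphs; they contribute
    ``owl:imports`` statements.  ``terminology_tables`` (id →
    TerminologyTable) additionally lets the consistency check verify that
    bound codes exist.
    """
    findings = check_dataset(dataset, terminology_tables)
    if findings:
        raise CompileError(
            f"dataset definition has {len(findings)} consistency finding(s); "
            "refusing to compile", findings)

    ns = dataset.namespace
    g = Graph()
    g.bind("sphn", ns + "#")
    onto = IRI(ns)
    vers = version_iri(ns, dataset.version_year, dataset.version_index)
    g.ontology_iri, g.version_iri = onto, vers
    g.add(onto, RDF.type, OWL.Ontology)
    g.add(onto, OWL.versionIRI, vers)
    g.add(onto, DCTERMS.license, Literal(LICENSE))
    for tg in terminologies:
        target = tg.version_iri or tg.ontology_iri
        if target is not None:
            g.add(onto, OWL.imports, target)
            g.imports.append(target)

    class_of: dict[str, IRI] = {}
    for concept in dataset.concepts:
        iri = class_iri(concept.name, ns)
        if iri in class_of.values():
            raise CompileError(
                f"IRI collision: two concepts map to {iri}")
        class_of[concept.name] = iri

    # one IRI per distinct property label; object/datatype must not mix
    prop_kind: dict[IRI, str] = {}
    prop_ranges: dict[IRI, set[IRI]] = {}
    prop_label: dict[IRI, str] = {}
    for concept in dataset.concepts:
        for p in concept.properties:
            iri = property_iri(p.name, ns)
            kind = "object" if p.value_kind in OBJECT_KINDS else "datatype"
            if prop_kind.setdefault(iri, kind) != kind:
                raise CompileError(
                    f"property {iri} used both as object and datatype property")
            other = prop_label.setdefault(iri, p.name)
            if other != p.name:
                raise CompileError(
                    f"IRI collision: labels {other!r} and {p.name!r} both "
                    f"map to {iri}")
            if p.value_kind == "concept":
                prop_ranges.setdefault(iri, set()).add(class_of[str(p.target)])
            elif kind == "datatype":
                prop_ranges.setdefault(iri, set()).add(DATATYPE_MAP[p.value_kind])

    for iri, kind in sorted(prop_kind.items()):
        g.add(iri, RDF.type,
              OWL.ObjectProperty if kind == "object" else OWL.DatatypeProperty)
        g.add(iri, RDFS.label, Literal(prop_label[iri]))
        ranges = prop_ranges.get(iri, set())
        if len(ranges) == 1:
            g.add(iri, RDFS.range, next(iter(ranges)))

    # value-set members become named individuals; the set itself stays a
    # naming scope (SetName-Member), not an extra class in the inventory
    for vs in dataset.value_sets:
        for member, description in vs.members:
            ind = individual_iri(vs.name, member, ns)
            g.add(ind, RDF.type, OWL.NamedIndividual)
            g.add(ind, RDFS.label, Literal(member))
            if description:
                g.add(ind, RDFS.comment, Literal(description))

    for concept in dataset.concepts:
        c = class_of[concept.name]
        g.add(c, RDF.type, OWL.Class)
        g.add(c, RDFS.label, Literal(concept.name))
        if concept.description:
            g.add(c, RDFS.comment, Literal(concept.description))
        if concept.parent is not None:
            g.add(c, RDFS.subClassOf, class_of[concept.parent])
        for term, code in concept.meaning_bindings:
            g.add(c, OWL.equivalentClass, code_iri(term, code))
        for p in concept.properties:
            piri = property_iri(p.name, ns)
            _add_cardinality_restriction(g, c, piri, p.min_card, p.max_card)
            _add_value_restriction(g, c, piri, p, dataset, ns)
    return g


def _add_cardinality_restriction(g: Graph, cls: IRI, prop: IRI,
                                 min_card: int, max_card: Optional[int]) -> None:
    if min_card == 0 and max_card is None:
        return  # optional and repeatable: no restriction needed
    r = _fresh_bnode()
    g.add(r, RDF.type, OWL.Restriction)
    g.add(r, OWL.onProperty, prop)
    if min_card > 0:
        g.add(r, OWL.minCardinality,
              Literal(str(min_card), str(XSD.nonNegativeInteger)))
    if max_card is not None:
        g.add(r, OWL.maxCardinality,
              Literal(str(max_card), str(XSD.nonNegativeInteger)))
    g.add(cls, RDFS.subClassOf, r)


def _add_value_restriction(g: Graph, cls: IRI, prop: IRI, p, dataset, ns) -> None:
    if p.value_kind == "code":
        cb: CodeBinding = p.target
        values = [code_iri(cb.terminology, c) for c in cb.codes]
        if cb.mode == "descendants_of":
            _restriction(g, cls, prop, OWL.allValuesFrom, values[0])
        elif len(values) == 1:
            _restriction(g, cls, prop, OWL.hasValue, values[0])
        else:
            _restriction_one_of(g, cls, prop, values)
    elif p.value_kind == "valueset":
        vs = dataset.value_set(str(p.target))
        members = [individual_iri(vs.name, m, ns) for m, _ in vs.members]
        if len(members) == 1:
            _restriction(g, cls, prop, OWL.hasValue, members[0])
        else:
            _restriction_one_of(g, cls, prop, members)


def _restriction(g: Graph, cls: IRI, prop: IRI, constraint: IRI, value) -> None:
    r = _fresh_bnode()
    g.add(r, RDF.type, OWL.Restriction)
    g.add(r, OWL.onProperty, prop)
    g.add(r, constraint, value)
    g.add(cls, RDFS.subClassOf, r)


def _restriction_one_of(g: Graph, cls: IRI, prop: IRI, values: list[IRI]) -> None:
    enum = _fresh_bnode()
    g.add(enum, RDF.type, OWL.Class)
    g.add(enum, OWL.oneOf, g.add_list(sorted(values)))
    _restriction(g, cls, prop, OWL.allValuesFrom, enum)


# ---------------------------------------------------------------------------
# statistics and serialisation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SchemaStats:
    classes: int
    object_properties: int
    datatype_properties: int
    named_individuals: int
    restrictions: int

    @property
    def unique_properties(self) -> int:
        return self.object_properties + self.datatype_properties


def schema_stats(g: Graph, namespace: Optional[str] = None) -> SchemaStats:
    """Count schema elements in the graph's primary namespace.

    ``namespace`` defaults to ``<ontology_iri>#``; restriction nodes are
    counted when their ``owl:onProperty`` lies in that namespace.
    """
    if namespace is None:
        if g.ontology_iri is None:
            raise ValueError("graph has no ontology IRI; pass namespace=")
        namespace = str(g.ontology_iri) + "#"

    def in_ns(node) -> bool:
        return isinstance(node, IRI) and str(node).startswith(namespace)

    classes = {s for s in g.subjects(RDF.type, OWL.Class) if in_ns(s)}
    obj = {s for s in g.subjects(RDF.type, OWL.ObjectProperty) if in_ns(s)}
    dt = {s for s in g.subjects(RDF.type, OWL.DatatypeProperty) if in_ns(s)}
    ind = {s for s in g.subjects(RDF.type, OWL.NamedIndividual) if in_ns(s)}
    restr = {s for s in g.subjects(RDF.type, OWL.Restriction)
             if in_ns(g.value(s, OWL.onProperty))}
    return SchemaStats(len(classes), len(obj), len(dt), len(ind), len(restr))


def serialize_canonical(g: Graph, format: str = "turtle") -> bytes:
    """Deterministic bytes for a graph; 'turtle' or 'owl-xml'."""
    if format == "turtle":
        return to_turtle(g)
    if format == "owl-xml":
        return to_rdfxml(g)
    raise ValueError(f"unsupported serialisation format: {format!r}")


def template_ontology(project_iri: str, schema: Graph,
                      terminologies: Iterable[Graph] = (),
                      title: str = "Project extension ontology") -> Graph:
    """Pre-filled extension ontology: imports + elementary metadata.

    Projects extend the core schema by adding their own classes and
    properties next to these imports, mirroring the published template
    mechanism.
    """
    g = Graph()
    onto = IRI(project_iri)
    g.ontology_iri = onto
    g.bind("sphn", str(schema.ontology_iri) + "#")
    g.add(onto, RDF.type, OWL.Ontology)
    g.add(onto, DCTERMS.title, Literal(title))
    g.add(onto, DCTERMS.license, Literal(LICENSE))
    target = schema.version_iri or schema.ontology_iri
    g.add(onto, OWL.imports, target)
    g.imports.append(target)
    for tg in terminologies:
        t = tg.version_iri or tg.ontology_iri
        if t is not None:
            g.add(onto, OWL.imports, t)
            g.imports.append(t)
    return g
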