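"""Validate instance graphs against generated shapes; entail and query.

The validator implements the SHACL core subset the shape generator emits
(min/max count, class, datatype, allowed-value list) with standard SHACL
semantics over the union of data and background graphs, and renders a
deterministic, human-readable report.  RDFS entailment — subclass
transitivity and type propagation — is materialised into the graph rather
than delegated to a store-side reasoner, so any downstream engine sees the
same triples.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Optional

import networkx as nx

from .rdf import (DCTERMS, Graph, IRI, Literal, Node, RDF, RDFS, XSD)
from .shacl_generator import ShapeSet
from .terminology_rdf import hierarchy_closure


class VersionMismatchError(ValueError):
    """Data and shapes were produced for different schema versions."""


@dataclass(frozen=True)
class Violation:
    focus: IRI
    path: IRI
    kind: str          # SHACL constraint-component name
    message: str
    severity: str = "Violation"
    focus_class: Optional[IRI] = None


@dataclass
class ValidationReport:
    conforms: bool
    violations: list[Violation] = field(default_factory=list)

    def __post_init__(self) -> None:
        assert self.conforms == (not self.violations)


def rdfs_closure(g: Graph) -> Graph:
    """Materialise RDFS subclass entailment.

    Adds (1) the transitive closure of ``rdfs:subClassOf`` and (2) every
    propagated ``rdf:type``: if *x* is typed *C* and *C* is a (transitive)
    subclass of *D*, then *x* is typed *D*.  Idempotent and monotone.
    """
    out = g.copy()
    dg = nx.DiGraph()
    for s, _, o in g.triples(None, RDFS.subClassOf, None):
        if isinstance(s, IRI) and isinstance(o, IRI):
            dg.add_edge(s, o)
    ancestors = {c: nx.descendants(dg, c) for c in dg.nodes}
    for c, ancs in ancestors.items():
        for a in ancs:
            out.add(c, RDFS.subClassOf, a)
    for s, _, cls in list(g.triples(None, RDF.type, None)):
        for a in ancestors.get(cls, ()):
            out.add(s, RDF.type, a)
    return out


def validate(data: Graph, shapes: ShapeSet,
             background: Iterable[Graph] = ()) -> ValidationReport:
    """SHACL-core validation of ``data`` ∪ ``background`` against ``shapes``.

    Raises :class:`VersionMismatchError` when the data graph's
    ``dcterms:conformsTo`` annotation and the shapes' schema version
    disagree.  Violations are ordered by focus node IRI, then path.
    """
    if shapes.schema_version is not None and data.ontology_iri is not None:
        declared = data.value(data.ontology_iri, DCTERMS.conformsTo)
        if declared is not None and declared != shapes.schema_version:
            raise VersionMismatchError(
                f"data declares schema {declared}, shapes were generated "
                f"for {shapes.schema_version}")

    merged = data.copy()
    for bg in background:
        merged.update(bg)
    closed = rdfs_closure(merged)

    violations: list[Violation] = []
    for shape in shapes.shapes:
        for focus in closed.subjects(RDF.type, shape.target_class):
            for c in shape.constraints:
                values = merged.objects(focus, c.path)
                violations.extend(
                    _check(closed, shape.target_class, focus, c, values))
    violations.sort(key=lambda v: (str(v.focus), str(v.path), v.kind))
    return ValidationReport(conforms=not violations, violations=violations)


def _check(closed: Graph, target_class: IRI, focus, c, values):
    out = []

    def emit(kind: str, message: str) -> None:
        out.append(Violation(focus, c.path, kind, message,
                             focus_class=target_class))

    n = len(values)
    if c.min_count is not None and n < c.min_count:
        emit("MinCountConstraintComponent",
             f"expected at least {c.min_count} value(s), found {n}")
    if c.max_count is not None and n > c.max_count:
        emit("MaxCountConstraintComponent",
             f"expected at most {c.max_count} value(s), found {n}")
    for v in values:
        if c.datatype is not None:
            if not isinstance(v, Literal) or v.datatype != str(c.datatype):
                got = v.datatype if isinstance(v, Literal) else "non-literal"
                emit("DatatypeConstraintComponent",
                     f"expected literal of datatype {c.datatype}, got {got}")
        if c.node_class is not None:
            if isinstance(v, Literal) \
                    or (v, RDF.type, c.node_class) not in closed:
                emit("ClassConstraintComponent",
                     f"value is not an instance of {c.node_class}")
        if c.allowed_values is not None and v not in c.allowed_values:
            emit("InConstraintComponent",
                 f"value {v} is not in the list of allowed values "
                 f"({len(c.allowed_values)} allowed)")
    return out


# ---------------------------------------------------------------------------
# report rendering
# ---------------------------------------------------------------------------

def render_report(report: ValidationReport, format: str = "text") -> bytes:
    if format == "json":
        payload = {
            "conforms": report.conforms,
            "violations": [
                {"focus": str(v.focus), "path": str(v.path), "kind": v.kind,
                 "message": v.message, "severity": v.severity,
                 "focus_class": None if v.focus_class is None
                 else str(v.focus_class)}
                for v in report.violations],
        }
        return (json.dumps(payload, indent=2, sort_keys=True) + "\n").encode()
    if format != "text":
        raise ValueError(f"unsupported report format: {format!r}")
    lines = [f"Conforms: {'true' if report.conforms else 'false'}",
             f"Violations: {len(report.violations)}"]
    by_class: dict[str, dict[str, list[Violation]]] = {}
    for v in report.violations:
        cls = str(v.focus_class) if v.focus_class else "(untyped)"
        by_class.setdefault(cls, {}).setdefault(v.kind, []).append(v)
    for cls in sorted(by_class):
        lines.append(f"\nClass {cls}:")
        for kind in sorted(by_class[cls]):
            vs = by_class[cls][kind]
            lines.append(f"  {kind} ({len(vs)}):")
            for v in vs:
                lines.append(f"    {v.focus} {v.path}: {v.message}")
    return ("\n".join(lines) + "\n").encode()


def report_from_json(data: bytes) -> ValidationReport:
    payload = json.loads(data.decode())
    violations = [
        Violation(IRI(v["focus"]), IRI(v["path"]), v["kind"], v["message"],
                  v["severity"],
                  None if v["focus_class"] is None else IRI(v["focus_class"]))
        for v in payload["violations"]]
    return ValidationReport(conforms=payload["conforms"],
                            violations=violations)


# ---------------------------------------------------------------------------
# hierarchy-aware cohort query and template statistics
# ---------------------------------------------------------------------------

def hierarchy_query(data: Graph, episode_class: IRI, substance_root: IRI,
                    background: Iterable[Graph] = ()) -> set[IRI]:
    """Distinct patients with an episode whose substance code is the root
    or any of its descendants.

    The substance hierarchy is taken from ``background`` (the converted
    terminology); patients are recognised as episode-linked objects typed
    ``SubjectPseudoIdentifier``.
    """
    terms = Graph()
    for bg in background:
        terms.update(bg)
    codes = hierarchy_closure(terms, substance_root)

    closed = rdfs_closure(data)
    patients: set[IRI] = set()
    for episode in closed.subjects(RDF.type, episode_class):
        has_code = any(
            o in codes for _, _, o in data.triples(episode, None, None))
        if not has_code:
            continue
        for _, _, o in data.triples(episode, None, None):
            if isinstance(o, IRI) and _is_subject_pseudo_identifier(closed, o):
                patients.add(o)
    return patients


def _is_subject_pseudo_identifier(g: Graph, node: IRI) -> bool:
    for t in g.objects(node, RDF.type):
        if isinstance(t, IRI) and str(t).endswith("#SubjectPseudoIdentifier"):
            return True
    return False


@dataclass
class StatsTable:
    class_counts: dict[IRI, int] = field(default_factory=dict)
    property_counts: dict[IRI, int] = field(default_factory=dict)
    metadata: dict[str, str] = field(default_factory=dict)


def run_template_queries(data: Graph, schema: Graph) -> StatsTable:
    """Per-class instance counts and per-property usage counts.

    Mirrors the statistics queries shipped with the quality-check
    machinery: how many instances of each schema class exist, how often
    each schema property is used, plus the release metadata annotations
    when the data graph carries them.
    """
    ns = str(schema.ontology_iri) + "#"
    stats = StatsTable()
    per_class: dict[IRI, set] = {}
    for s, _, cls in data.triples(None, RDF.type, None):
        if isinstance(cls, IRI) and str(cls).startswith(ns):
            per_class.setdefault(cls, set()).add(s)
    stats.class_counts = {c: len(m) for c, m in sorted(per_class.items())}
    per_prop: dict[IRI, int] = {}
    for _, p, _ in data:
        if str(p).startswith(ns):
            per_prop[p] = per_prop.get(p, 0) + 1
    stats.property_counts = dict(sorted(per_prop.items()))
    if data.ontology_iri is not None:
        version = data.value(data.ontology_iri, DCTERMS.conformsTo)
        creator = data.value(data.ontology_iri, DCTERMS.creator)
        if version is not None:
            stats.metadata["schema_version"] = str(version)
        if isinstance(creator, Literal):
            stats.metadata["provider"] = creator.lexical
    return stats
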