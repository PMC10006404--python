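"""Automatic SHACL shape derivation from a compiled schema graph.

For every schema class a node shape is produced targeting it; every
``owl:Restriction`` on the class becomes (part of) a property shape:

* ``owl:minCardinality`` / ``owl:maxCardinality`` → ``sh:minCount`` /
  ``sh:maxCount``;
* ``rdfs:range`` pointing at a schema class → ``sh:class``;
* the datatype-property range → ``sh:datatype``;
* ``owl:hasValue`` and ``owl:oneOf`` enumerations → an explicit ``sh:in``
  list; ``owl:allValuesFrom <terminology class>`` (a descendants-of
  binding) is expanded into the full subclass closure of that code at
  generation time, so the emitted shapes are plain SHACL and portable to
  any engine.

Shapes are open (``sh:closed`` is not asserted): project-specific
extensions of the data must not be flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

from .rdf import (BNode, DCTERMS, Graph, IRI, Literal, Node, OWL, RDF, RDFS,
                  SH, XSD, _fresh_bnode, from_turtle, to_turtle)
from .terminology_rdf import hierarchy_closure


class ShapeGenerationError(ValueError):
    """A restriction references something the supplied inputs cannot resolve."""


@dataclass(frozen=True)
class PropertyConstraint:
    path: IRI
    min_count: Optional[int] = None
    max_count: Optional[int] = None
    node_class: Optional[IRI] = None
    datatype: Optional[IRI] = None
    allowed_values: Optional[tuple[IRI, ...]] = None


@dataclass
class NodeShape:
    target_class: IRI
    constraints: list[PropertyConstraint] = field(default_factory=list)

    @property
    def iri(self) -> IRI:
        return IRI(str(self.target_class) + "Shape")


@dataclass
class ShapeSet:
    shapes: list[NodeShape] = field(default_factory=list)
    schema_version: Optional[IRI] = None
    namespace: Optional[str] = None

    def shape_for(self, target_class: IRI) -> NodeShape:
        for s in self.shapes:
            if s.target_class == target_class:
                return s
        raise KeyError(target_class)

    def __len__(self) -> int:
        return len(self.shapes)


def generate_shapes(schema: Graph,
                    terminologies: Iterable[Graph] = ()) -> ShapeSet:
    """Derive one node shape per schema class from its restrictions."""
    if schema.ontology_iri is None:
        raise ShapeGenerationError("schema graph has no ontology header")
    ns = str(schema.ontology_iri) + "#"
    terms = Graph()
    for tg in terminologies:
        terms.update(tg)

    shape_set = ShapeSet(schema_version=schema.version_iri, namespace=ns)
    classes = sorted(
        s for s in schema.subjects(RDF.type, OWL.Class)
        if isinstance(s, IRI) and str(s).startswith(ns))
    for cls in classes:
        shape = NodeShape(target_class=cls)
        per_path: dict[IRI, dict] = {}
        for sup in schema.objects(cls, RDFS.subClassOf):
            if not isinstance(sup, BNode):
                continue
            if (sup, RDF.type, OWL.Restriction) not in schema:
                continue
            prop = schema.value(sup, OWL.onProperty)
            if prop is None:
                continue
            acc = per_path.setdefault(prop, {})
            mn = schema.value(sup, OWL.minCardinality)
            mx = schema.value(sup, OWL.maxCardinality)
            if mn is not None:
                acc["min"] = int(mn.value)
            if mx is not None:
                acc["max"] = int(mx.value)
            hv = schema.value(sup, OWL.hasValue)
            if hv is not None:
                acc["in"] = (hv,)
            avf = schema.value(sup, OWL.allValuesFrom)
            if avf is not None:
                acc["in"] = tuple(_expand_all_values(schema, terms, avf))
        for prop in sorted(per_path):
            acc = per_path[prop]
            node_class = datatype = None
            rng = schema.value(prop, RDFS.range)
            if (prop, RDF.type, OWL.DatatypeProperty) in schema:
                datatype = rng
            elif isinstance(rng, IRI) and str(rng).startswith(ns):
                node_class = rng
            shape.constraints.append(PropertyConstraint(
                path=prop,
                min_count=acc.get("min"),
                max_count=acc.get("max"),
                node_class=node_class,
                datatype=datatype,
                allowed_values=acc.get("in"),
            ))
        shape_set.shapes.append(shape)
    return shape_set


def _expand_all_values(schema: Graph, terms: Graph, avf: Node) -> list[IRI]:
    if isinstance(avf, BNode):
        head = schema.value(avf, OWL.oneOf)
        if head is None:
            raise ShapeGenerationError(
                "owl:allValuesFrom on a blank node without owl:oneOf")
        return list(schema.get_list(head))
    # descendants-of binding: allowed set = subclass closure in the
    # supplied terminologies
    try:
        closure = hierarchy_closure(terms, avf)
    except Exception as exc:
        raise ShapeGenerationError(
            f"restriction references code {avf} absent from the supplied "
            f"terminologies") from exc
    return sorted(closure)


# ---------------------------------------------------------------------------
# serialisation
# ---------------------------------------------------------------------------

def shapes_to_graph(shape_set: ShapeSet) -> Graph:
    g = Graph()
    if shape_set.namespace:
        g.bind("sphn", shape_set.namespace)
        doc = IRI(shape_set.namespace.rstrip("#") + "/shapes")
        g.ontology_iri = doc
        g.add(doc, RDF.type, OWL.Ontology)
        if shape_set.schema_version is not None:
            g.add(doc, DCTERMS.conformsTo, shape_set.schema_version)
    for shape in shape_set.shapes:
        s = shape.iri
        g.add(s, RDF.type, SH.NodeShape)
        g.add(s, SH.targetClass, shape.target_class)
        for c in shape.constraints:
            b = _fresh_bnode()
            g.add(s, SH.property, b)
            g.add(b, SH.path, c.path)
            if c.min_count is not None:
                g.add(b, SH.minCount, Literal(str(c.min_count), str(XSD.integer)))
            if c.max_count is not None:
                g.add(b, SH.maxCount, Literal(str(c.max_count), str(XSD.integer)))
            if c.node_class is not None:
                g.add(b, SH["class"], c.node_class)
            if c.datatype is not None:
                g.add(b, SH.datatype, c.datatype)
            if c.allowed_values is not None:
                g.add(b, SH["in"], g.add_list(c.allowed_values))
    return g


def shapes_from_graph(g: Graph) -> ShapeSet:
    shape_set = ShapeSet()
    if g.ontology_iri is not None:
        v = g.value(g.ontology_iri, DCTERMS.conformsTo)
        if isinstance(v, IRI):
            shape_set.schema_version = v
        shape_set.namespace = str(g.ontology_iri).replace("/shapes", "") + "#"
    for s in g.subjects(RDF.type, SH.NodeShape):
        target = g.value(s, SH.targetClass)
        shape = NodeShape(target_class=target)
        props = []
        for b in g.objects(s, SH.property):
            path = g.value(b, SH.path)
            mn = g.value(b, SH.minCount)
            mx = g.value(b, SH.maxCount)
            inlist = g.value(b, SH["in"])
            props.append(PropertyConstraint(
                path=path,
                min_count=None if mn is None else int(mn.value),
                max_count=None if mx is None else int(mx.value),
                node_class=g.value(b, SH["class"]),
                datatype=g.value(b, SH.datatype),
                allowed_values=None if inlist is None
                else tuple(g.get_list(inlist)),
            ))
        shape.constraints = sorted(props, key=lambda c: str(c.path))
        shape_set.shapes.append(shape)
    shape_set.shapes.sort(key=lambda sh: str(sh.target_class))
    return shape_set


def serialize_shapes(shape_set: ShapeSet) -> bytes:
    """Canonical Turtle for the shapes graph (parse → serialise fixpoint)."""
    return to_turtle(shapes_to_graph(shape_set))


def parse_shapes(data: bytes) -> ShapeSet:
    return shapes_from_graph(from_turtle(data))
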