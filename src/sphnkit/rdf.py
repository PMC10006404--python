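"""Minimal RDF core: terms, triple graphs, deterministic serialisation.

This module provides the in-memory triple container shared by every other
layer (compiled schemas, converted terminologies and instance data all live
in the same :class:`Graph`), together with a *canonical* serialiser: for a
given triple set and prefix table the emitted bytes are unique — subjects
are sorted, blank nodes are renumbered from a content-based signature, and
each triple is written on its own line. Canonical output makes golden-file
tests and byte-level reproducibility contracts possible, which off-the-shelf
RDF serialisers do not guarantee.

Two formats are supported: Turtle (primary; the statement-per-line subset is
also what the bundled parser reads back) and an RDF/XML encoding (secondary,
``owl-xml``), both loss-free for the triples this toolkit produces.
"""

from __future__ import annotations

import re
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Union


class IRI(str):
    """An absolute IRI used as subject, predicate or object."""

    __slots__ = ()

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        return f"<{str(self)}>"


class BNode(str):
    """A blank node label (without the ``_:`` prefix)."""

    __slots__ = ()

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        return f"_:{str(self)}"


@dataclass(frozen=True, order=True)
class Literal:
    """An RDF literal with lexical form, datatype IRI and optional language."""

    lexical: str
    datatype: str = "http://www.w3.org/2001/XMLSchema#string"
    lang: Optional[str] = None

    def __post_init__(self) -> None:
        if self.lang is not None:
            object.__setattr__(
                self, "datatype",
                "http://www.w3.org/1999/02/22-rdf-syntax-ns#langString")

    @property
    def value(self) -> object:
        """Python value for the common XSD datatypes, else the lexical form."""
        dt = self.datatype
        if dt == str(XSD.double) or dt == str(XSD.decimal) or dt == str(XSD.float):
            return float(self.lexical)
        if dt in (str(XSD.integer), str(XSD.nonNegativeInteger), str(XSD.int),
                  str(XSD.long)):
            return int(self.lexical)
        if dt == str(XSD.boolean):
            return self.lexical == "true"
        return self.lexical


Node = Union[IRI, BNode, Literal]
Triple = tuple[Union[IRI, BNode], IRI, Node]


class Namespace(str):
    """IRI prefix; attribute access mints terms, e.g. ``RDF.type``."""

    __slots__ = ()

    def __getattr__(self, name: str) -> IRI:
        if name.startswith("__"):
            raise AttributeError(name)
        return IRI(self + name)

    def __getitem__(self, name):
        # allow SH["class"] / SH["in"] for names that are Python keywords
        if isinstance(name, str):
            return IRI(self + name)
        return str.__getitem__(self, name)

    def term(self, name: str) -> IRI:
        return IRI(self + name)


RDF = Namespace("http://www.w3.org/1999/02/22-rdf-syntax-ns#")
RDFS = Namespace("http://www.w3.org/2000/01/rdf-schema#")
OWL = Namespace("http://www.w3.org/2002/07/owl#")
XSD = Namespace("http://www.w3.org/2001/XMLSchema#")
SH = Namespace("http://www.w3.org/ns/shacl#")
DCTERMS = Namespace("http://purl.org/dc/terms/")
SKOS = Namespace("http://www.w3.org/2004/02/skos/core#")

#: Prefixes every serialisation may use; graphs can bind more.
CORE_PREFIXES: dict[str, str] = {
    "rdf": str(RDF),
    "rdfs": str(RDFS),
    "owl": str(OWL),
    "xsd": str(XSD),
    "sh": str(SH),
    "dcterms": str(DCTERMS),
    "skos": str(SKOS),
}


def literal(value: object, datatype: Optional[IRI] = None) -> Literal:
    """Build a Literal from a Python value with the natural XSD datatype."""
    if isinstance(value, Literal):
        return value
    if isinstance(value, bool):
        return Literal("true" if value else "false", str(XSD.boolean))
    if isinstance(value, int):
        return Literal(str(value), str(datatype or XSD.integer))
    if isinstance(value, float):
        lex = repr(value)
        return Literal(lex, str(datatype or XSD.double))
    return Literal(str(value), str(datatype or XSD.string))


@dataclass
class Graph:
    """A set of RDF triples with simple pattern matching.

    ``ontology_iri`` / ``version_iri`` / ``imports`` mirror the OWL ontology
    header when the graph holds a schema or terminology; they are also
    asserted as triples by the producers, so the header survives
    serialisation round trips.
    """

    ontology_iri: Optional[IRI] = None
    version_iri: Optional[IRI] = None
    imports: list[IRI] = field(default_factory=list)
    _spo: dict = field(default_factory=dict, repr=False)
    _size: int = field(default=0, repr=False)
    prefixes: dict[str, str] = field(default_factory=dict, repr=False)

    # -- mutation -------------------------------------------------------
    def add(self, s: Union[IRI, BNode], p: IRI, o: Node) -> "Graph":
        po = self._spo.setdefault(s, {})
        objs = po.setdefault(p, set())
        if o not in objs:
            objs.add(o)
            self._size += 1
        return self

    def discard(self, s: Union[IRI, BNode], p: IRI, o: Node) -> None:
        objs = self._spo.get(s, {}).get(p)
        if objs and o in objs:
            objs.remove(o)
            self._size -= 1
            if not objs:
                del self._spo[s][p]
                if not self._spo[s]:
                    del self._spo[s]

    def update(self, other: "Graph") -> "Graph":
        for t in other:
            self.add(*t)
        return self

    def bind(self, prefix: str, ns: str) -> None:
        self.prefixes[prefix] = str(ns)

    # -- access ---------------------------------------------------------
    def __iter__(self) -> Iterator[Triple]:
        for s, po in self._spo.items():
            for p, objs in po.items():
                for o in objs:
                    yield (s, p, o)

    def __len__(self) -> int:
        return self._size

    def __contains__(self, t: Triple) -> bool:
        return t[2] in self._spo.get(t[0], {}).get(t[1], ())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Graph):
            return NotImplemented
        return set(self) == set(other)

    def triples(self, s=None, p=None, o=None) -> Iterator[Triple]:
        subjects = [s] if s is not None else list(self._spo)
        for subj in subjects:
            po = self._spo.get(subj)
            if po is None:
                continue
            preds = [p] if p is not None else list(po)
            for pred in preds:
                for obj in po.get(pred, ()):
                    if o is None or obj == o:
                        yield (subj, pred, obj)

    def objects(self, s, p) -> list[Node]:
        return sorted(self._spo.get(s, {}).get(p, ()), key=_term_sort_key)

    def value(self, s, p) -> Optional[Node]:
        objs = self._spo.get(s, {}).get(p)
        if not objs:
            return None
        return min(objs, key=_term_sort_key)

    def subjects(self, p=None, o=None) -> list:
        out = set()
        for s, pred, obj in self.triples(None, p, o):
            out.add(s)
        return sorted(out, key=_term_sort_key)

    def copy(self) -> "Graph":
        g = Graph(ontology_iri=self.ontology_iri, version_iri=self.version_iri,
                  imports=list(self.imports))
        g.prefixes = dict(self.prefixes)
        g.update(self)
        return g

    # -- RDF collections ------------------------------------------------
    def add_list(self, items: Iterable[Node]) -> Node:
        """Materialise an RDF collection; returns its head (rdf:nil if empty)."""
        items = list(items)
        if not items:
            return RDF.nil
        head = _fresh_bnode(self)
        node = head
        for i, item in enumerate(items):
            self.add(node, RDF.first, item)
            if i == len(items) - 1:
                self.add(node, RDF.rest, RDF.nil)
            else:
                nxt = _fresh_bnode(self)
                self.add(node, RDF.rest, nxt)
                node = nxt
        return head

    def get_list(self, head: Node) -> list[Node]:
        items: list[Node] = []
        seen = set()
        while head != RDF.nil:
            if head in seen:
                raise ValueError("cyclic RDF collection")
            seen.add(head)
            first = self.value(head, RDF.first)
            if first is None:
                break
            items.append(first)
            head = self.value(head, RDF.rest) or RDF.nil
        return items


_bnode_counter = 0


def _fresh_bnode(g: Optional[Graph] = None) -> BNode:
    global _bnode_counter
    _bnode_counter += 1
    return BNode(f"n{_bnode_counter}")


def _term_sort_key(t: Node):
    if isinstance(t, IRI):
        return (0, str(t), "", "")
    if isinstance(t, BNode):
        return (1, str(t), "", "")
    return (2, t.lexical, t.datatype, t.lang or "")


# ---------------------------------------------------------------------------
# canonical blank-node labelling
# ---------------------------------------------------------------------------

def _bnode_keys(g: Graph) -> dict[BNode, str]:
    """Content-based canonical key per blank node.

    Key = recursive outgoing structure plus the (IRI subject, predicate)
    pairs pointing at the node. Blank nodes in this toolkit form trees
    hanging off IRI subjects (restrictions, RDF lists, shape nodes), for
    which this is a perfect canonical key; nodes with equal keys are
    structurally interchangeable.
    """
    memo: dict[BNode, str] = {}

    def out_sig(node: Node, visiting: frozenset) -> str:
        if isinstance(node, Literal):
            return f'L({node.lexical}|{node.datatype}|{node.lang or ""})'
        if isinstance(node, IRI):
            return f"I({node})"
        if node in visiting:
            return "CYCLE"
        if node in memo:
            return memo[node]
        parts = sorted(
            f"{p}->{out_sig(o, visiting | {node})}"
            for _, p, o in g.triples(node)
        )
        sig = "B[" + ";".join(parts) + "]"
        if not visiting:
            memo[node] = sig
        return sig

    incoming: dict[BNode, list[str]] = {}
    for s, p, o in g:
        if isinstance(o, BNode):
            if isinstance(s, IRI):
                incoming.setdefault(o, []).append(f"{s}|{p}")
            else:
                incoming.setdefault(o, []).append(f"*|{p}")

    bnodes = {t[0] for t in g if isinstance(t[0], BNode)}
    bnodes |= {t[2] for t in g if isinstance(t[2], BNode)}
    return {b: out_sig(b, frozenset()) + "//"
            + ";".join(sorted(incoming.get(b, []))) for b in bnodes}


def _bnode_signatures(g: Graph) -> dict[BNode, str]:
    """Deterministic relabelling map independent of construction order."""
    keys = _bnode_keys(g)
    ordered = sorted(keys, key=lambda b: (keys[b], str(b)))
    return {b: f"b{i}" for i, b in enumerate(ordered)}


def ground_triples(g: Graph) -> list[tuple[str, str, str]]:
    """Sorted triples with blank nodes replaced by canonical labels.

    Two graphs are isomorphic (equal up to blank-node renaming) iff their
    ground triple lists are equal; containment of the lists witnesses
    subgraph relationships for the tree-shaped blank nodes this toolkit
    produces.
    """
    labels = _bnode_signatures(g)

    def ground(t: Node) -> str:
        if isinstance(t, BNode):
            return "_:" + labels[t]
        if isinstance(t, IRI):
            return f"<{t}>"
        return f'"{t.lexical}"^^{t.datatype}@{t.lang or ""}'

    return sorted((ground(s), ground(p), ground(o)) for s, p, o in g)


def isomorphic(a: Graph, b: Graph) -> bool:
    return ground_triples(a) == ground_triples(b)


def signature_ground(g: Graph) -> list[tuple[str, str, str]]:
    """Triples with blank nodes replaced by content-based signature keys.

    Unlike :func:`ground_triples`, the replacement does not depend on which
    other blank nodes exist in the graph, so multiset containment of the
    results witnesses subgraph relationships across graphs of different
    size (used for monotonicity properties)."""
    keys = _bnode_keys(g)

    def ground(t: Node) -> str:
        if isinstance(t, BNode):
            return "_:" + keys[t]
        if isinstance(t, IRI):
            return f"<{t}>"
        return f'"{t.lexical}"^^{t.datatype}@{t.lang or ""}'

    return sorted((ground(s), ground(p), ground(o)) for s, p, o in g)


# ---------------------------------------------------------------------------
# Turtle
# ---------------------------------------------------------------------------

_PN_LOCAL = re.compile(r"\A[A-Za-z_][A-Za-z0-9_.\-]*\Z")

_ESCAPES = {"\\": "\\\\", '"': '\\"', "\n": "\\n", "\r": "\\r", "\t": "\\t"}


def _escape(s: str) -> str:
    return "".join(_ESCAPES.get(c, c) for c in s)


_UNESCAPES = {"\\": "\\", '"': '"', "n": "\n", "r": "\r", "t": "\t"}


def _qname(iri: str, prefixes: dict[str, str], used: set) -> Optional[str]:
    best = None
    for pfx, ns in prefixes.items():
        if iri.startswith(ns) and len(ns) > (len(prefixes.get(best, "")) if best else 0):
            local = iri[len(ns):]
            if _PN_LOCAL.match(local) and not local.endswith("."):
                best = pfx
    if best is None:
        return None
    used.add(best)
    return f"{best}:{iri[len(prefixes[best]):]}"


def _ttl_term(t: Node, prefixes, used, blabels) -> str:
    if isinstance(t, BNode):
        return f"_:{blabels[t]}"
    if isinstance(t, IRI):
        if t == RDF.type:
            used.add("rdf")  # keep prefix table stable whether or not 'a' is used
        q = _qname(str(t), prefixes, used)
        return q if q is not None else f"<{t}>"
    lex = f'"{_escape(t.lexical)}"'
    if t.lang:
        return f"{lex}@{t.lang}"
    if t.datatype == str(XSD.string):
        return lex
    dt = _qname(t.datatype, prefixes, used)
    return f"{lex}^^{dt or '<' + t.datatype + '>'}"


def to_turtle(g: Graph) -> bytes:
    """Canonical Turtle: sorted prefixes, sorted one-triple-per-line body."""
    prefixes = {**CORE_PREFIXES, **g.prefixes}
    blabels = _bnode_signatures(g)
    used: set[str] = set()
    lines = []
    for s, p, o in g:
        st = _ttl_term(s, prefixes, used, blabels)
        pt = "a" if p == RDF.type else _ttl_term(p, prefixes, used, blabels)
        ot = _ttl_term(o, prefixes, used, blabels)
        lines.append(f"{st} {pt} {ot} .")
    lines.sort()
    header = [f"@prefix {pfx}: <{prefixes[pfx]}> ." for pfx in sorted(used)]
    doc = "\n".join(header) + ("\n\n" if header else "") + "\n".join(lines) + "\n"
    return doc.encode("utf-8")


_TOKEN = re.compile(
    r"""(<[^>]*>                              # IRI
        |"(?:[^"\\]|\\.)*"(?:\^\^\S+|@[A-Za-z\-]+)?   # literal
        |_:[A-Za-z0-9]+                       # bnode
        |@prefix
        |[^\s]+)                              # prefixed name / 'a' / '.'
    """,
    re.X,
)


def _parse_term(tok: str, prefixes: dict[str, str]) -> Node:
    if tok.startswith("<"):
        return IRI(tok[1:-1])
    if tok.startswith("_:"):
        return BNode(tok[2:])
    if tok.startswith('"'):
        m = re.match(r'\A"((?:[^"\\]|\\.)*)"(?:\^\^(\S+)|@([A-Za-z\-]+))?\Z', tok)
        if not m:
            raise ValueError(f"bad literal token: {tok}")
        raw, dt_tok, lang = m.groups()
        lex = re.sub(r"\\(.)", lambda mm: _UNESCAPES.get(mm.group(1), mm.group(1)), raw)
        if lang:
            return Literal(lex, lang=lang)
        if dt_tok:
            dt = _parse_term(dt_tok, prefixes)
            return Literal(lex, str(dt))
        return Literal(lex)
    if tok == "a":
        return RDF.type
    if ":" in tok:
        pfx, local = tok.split(":", 1)
        if pfx in prefixes:
            return IRI(prefixes[pfx] + local)
    raise ValueError(f"cannot parse term: {tok}")


def from_turtle(data: Union[bytes, str]) -> Graph:
    """Parse the statement-per-line Turtle subset emitted by this module."""
    if isinstance(data, bytes):
        data = data.decode("utf-8")
    g = Graph()
    prefixes: dict[str, str] = {}
    tokens: list[str] = []
    for line in data.splitlines():
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        tokens.extend(m.group(0) for m in _TOKEN.finditer(stripped))
    i = 0
    while i < len(tokens):
        if tokens[i] == "@prefix":
            pfx = tokens[i + 1].rstrip(":")
            ns = tokens[i + 2]
            if not (ns.startswith("<") and tokens[i + 3] == "."):
                raise ValueError("malformed @prefix directive")
            prefixes[pfx] = ns[1:-1]
            i += 4
            continue
        if i + 3 >= len(tokens) + 0 and len(tokens) - i < 4:
            raise ValueError("truncated statement")
        s = _parse_term(tokens[i], prefixes)
        p = _parse_term(tokens[i + 1], prefixes)
        o = _parse_term(tokens[i + 2], prefixes)
        if tokens[i + 3] != ".":
            raise ValueError(f"expected '.', got {tokens[i + 3]!r}")
        if isinstance(s, Literal) or isinstance(p, (Literal, BNode)):
            raise ValueError("malformed triple")
        g.add(s, p, o)
        i += 4
    g.prefixes = prefixes
    _read_header(g)
    return g


def _read_header(g: Graph) -> None:
    for s in g.subjects(RDF.type, OWL.Ontology):
        if isinstance(s, IRI):
            g.ontology_iri = s
            v = g.value(s, OWL.versionIRI)
            if isinstance(v, IRI):
                g.version_iri = v
            g.imports = [o for o in g.objects(s, OWL.imports) if isinstance(o, IRI)]
            break


# ---------------------------------------------------------------------------
# RDF/XML ("owl-xml" in the toolkit's format enum)
# ---------------------------------------------------------------------------

def _split_iri(iri: str) -> tuple[str, str]:
    m = re.search(r"[#/](?=[^#/]+\Z)", iri)
    if not m:
        raise ValueError(f"cannot derive XML qname for {iri}")
    return iri[: m.end()], iri[m.end():]


def to_rdfxml(g: Graph) -> bytes:
    """Deterministic RDF/XML; loss-free for graphs this toolkit produces."""
    prefixes = {**CORE_PREFIXES, **g.prefixes}
    ns_by_iri = {v: k for k, v in sorted(prefixes.items(), reverse=True)}
    blabels = _bnode_signatures(g)
    extra = 0
    lines = ['<?xml version="1.0" encoding="utf-8"?>']
    body: list[str] = []
    used_ns: dict[str, str] = {"rdf": str(RDF)}

    def qname(iri: str) -> str:
        nonlocal extra
        ns, local = _split_iri(iri)
        if ns not in ns_by_iri:
            extra += 1
            pfx = f"ns{extra}"
            ns_by_iri[ns] = pfx
        pfx = ns_by_iri[ns]
        used_ns[pfx] = ns
        return f"{pfx}:{local}"

    def subj_key(s):
        return (isinstance(s, BNode), blabels.get(s, str(s)) if isinstance(s, BNode) else str(s))

    for s in sorted(g._spo, key=subj_key):
        if isinstance(s, BNode):
            body.append(f'  <rdf:Description rdf:nodeID="{blabels[s]}">')
        else:
            body.append(f'  <rdf:Description rdf:about="{_xml_attr(s)}">')
        rows = []
        for _, p, o in g.triples(s):
            pq = qname(str(p))
            if isinstance(o, IRI):
                rows.append(f'    <{pq} rdf:resource="{_xml_attr(o)}"/>')
            elif isinstance(o, BNode):
                rows.append(f'    <{pq} rdf:nodeID="{blabels[o]}"/>')
            else:
                attrs = ""
                if o.lang:
                    attrs = f' xml:lang="{o.lang}"'
                elif o.datatype != str(XSD.string):
                    attrs = f' rdf:datatype="{_xml_attr(o.datatype)}"'
                rows.append(f"    <{pq}{attrs}>{_xml_text(o.lexical)}</{pq}>")
        body.extend(sorted(rows))
        body.append("  </rdf:Description>")
    decls = " ".join(
        f'xmlns:{pfx}="{_xml_attr(ns)}"' for pfx, ns in sorted(used_ns.items())
    )
    lines.append(f"<rdf:RDF {decls}>")
    lines.extend(body)
    lines.append("</rdf:RDF>")
    return ("\n".join(lines) + "\n").encode("utf-8")


def _xml_attr(s: str) -> str:
    return (s.replace("&", "&amp;").replace("<", "&lt;").replace('"', "&quot;"))


def _xml_text(s: str) -> str:
    return s.replace("&", "&amp;").replace("<", "&lt;")


def from_rdfxml(data: Union[bytes, str]) -> Graph:
    if isinstance(data, str):
        data = data.encode("utf-8")
    root = ET.fromstring(data)
    g = Graph()
    rdfns = "{" + str(RDF) + "}"
    for desc in root:
        about = desc.get(f"{rdfns}about")
        node_id = desc.get(f"{rdfns}nodeID")
        s: Union[IRI, BNode] = IRI(about) if about is not None else BNode(node_id)
        for child in desc:
            tag = child.tag  # '{ns}local'
            p = IRI(tag[1:].replace("}", ""))
            res = child.get(f"{rdfns}resource")
            nid = child.get(f"{rdfns}nodeID")
            if res is not None:
                o: Node = IRI(res)
            elif nid is not None:
                o = BNode(nid)
            else:
                dt = child.get(f"{rdfns}datatype")
                lang = child.get("{http://www.w3.org/XML/1998/namespace}lang")
                text = child.text or ""
                if lang:
                    o = Literal(text, lang=lang)
                else:
                    o = Literal(text, dt or str(XSD.string))
            g.add(s, p, o)
    _read_header(g)
    return g
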