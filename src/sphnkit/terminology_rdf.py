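"""Terminology tables → RDF class hierarchies.

External terminologies (ATC, CHOP, ICD-10-GM, LOINC, SNOMED CT, UCUM) are
distributed as flat code tables; here each code becomes a class carrying an
``rdfs:label``, and each parent link a ``rdfs:subClassOf`` edge from child to
parent.  One RDF file is produced per (terminology, version), with the
version recorded in the ontology header's version IRI.

IRI patterns follow the published conventions: terminologies with
provider-resolvable code IRIs (ATC, LOINC, SNOMED CT) keep the provider's
IRIs; the rest live under ``https://biomedit.ch/rdf/sphn-resource/<id>/``.

UCUM unit tokens contain characters that are hostile inside IRIs ("%",
"/"); a transliteration table maps them to URL-safe local names, applied
consistently wherever a unit code is minted.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Union

import networkx as nx

from .rdf import IRI, Graph, Literal, Namespace, OWL, RDF, RDFS

SPHN_RESOURCE = "https://biomedit.ch/rdf/sphn-resource"


class TerminologyError(ValueError):
    """Invalid terminology table (duplicate codes, dangling parents, cycles)."""


@dataclass(frozen=True)
class IriPattern:
    """Where a terminology's ontology and its individual codes live."""

    ontology_iri: str
    code_prefix: str

    def __post_init__(self) -> None:
        if not self.code_prefix:
            raise ValueError("code_prefix must be non-empty")


def _default_pattern(terminology_id: str) -> IriPattern:
    base = f"{SPHN_RESOURCE}/{terminology_id.lower()}/"
    return IriPattern(base, base)


#: Registered terminologies; ATC, LOINC and SNOMED CT use provider IRIs.
REGISTRY: dict[str, IriPattern] = {
    "ATC": IriPattern(f"{SPHN_RESOURCE}/atc/",
                      "https://www.whocc.no/atc_ddd_index/?code="),
    "CHOP": _default_pattern("CHOP"),
    "ICD-10-GM": _default_pattern("ICD-10-GM"),
    "LOINC": IriPattern(f"{SPHN_RESOURCE}/loinc/", "https://loinc.org/rdf/"),
    "SNOMED": IriPattern("http://snomed.info/sct/900000000000207008",
                         "http://snomed.info/id/"),
    "UCUM": _default_pattern("UCUM"),
}


def register_terminology(terminology_id: str,
                         pattern: Optional[IriPattern] = None) -> IriPattern:
    """Register a terminology id, defaulting to the sphn-resource pattern."""
    p = pattern or _default_pattern(terminology_id)
    REGISTRY[terminology_id] = p
    return p


#: Whole-token UCUM transliterations, checked before the per-character map.
UCUM_TOKEN_MAP = {"%": "percent", "1": "one"}
#: Per-character fallback for composite unit tokens such as "beats/min".
UCUM_CHAR_MAP = {"/": ".", "*": ".", "[": "", "]": "", "{": "", "}": "",
                 " ": "", "'": ""}


def ucum_local_name(token: str) -> str:
    """URL-safe local name for a UCUM unit token ('%' → 'percent')."""
    if token in UCUM_TOKEN_MAP:
        return UCUM_TOKEN_MAP[token]
    return "".join(UCUM_CHAR_MAP.get(c, c) for c in token)


def code_iri(terminology_id: str, code: str) -> IRI:
    """Mint the IRI of a terminology code under the registered pattern."""
    try:
        pattern = REGISTRY[terminology_id]
    except KeyError:
        raise TerminologyError(
            f"unregistered terminology id: {terminology_id!r}") from None
    if terminology_id == "UCUM":
        code = ucum_local_name(code)
    return IRI(pattern.code_prefix + code)


@dataclass
class TerminologyTable:
    """Flat (code, label, parent_code) rows for one terminology release."""

    terminology_id: str
    version_label: str
    rows: list[tuple[str, str, Optional[str]]] = field(default_factory=list)

    def check(self) -> None:
        codes = [r[0] for r in self.rows]
        seen = set()
        for c in codes:
            if c in seen:
                raise TerminologyError(f"duplicate code: {c}")
            seen.add(c)
        for code, _, parent in self.rows:
            if parent is not None and parent not in seen:
                raise TerminologyError(
                    f"parent code {parent!r} of {code!r} not defined")
        dg = nx.DiGraph()
        dg.add_nodes_from(codes)
        dg.add_edges_from((c, p) for c, _, p in self.rows if p is not None)
        try:
            cycle = nx.find_cycle(dg)
        except nx.NetworkXNoCycle:
            return
        chain = " -> ".join(e[0] for e in cycle) + f" -> {cycle[-1][1]}"
        raise TerminologyError(f"cyclic hierarchy: {chain}")

    @property
    def codes(self) -> set[str]:
        return {r[0] for r in self.rows}


def read_terminology_csv(path: Union[str, Path], terminology_id: str,
                         version_label: str) -> TerminologyTable:
    """Read a ``code,label,parent_code`` CSV into a TerminologyTable."""
    table = TerminologyTable(terminology_id, version_label)
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        required = {"code", "label", "parent_code"}
        missing = required - set(reader.fieldnames or [])
        if missing:
            raise TerminologyError(
                f"missing column(s): {', '.join(sorted(missing))}")
        for row in reader:
            parent = (row.get("parent_code") or "").strip() or None
            table.rows.append((row["code"].strip(), row["label"].strip(), parent))
    table.check()
    return table


def convert_terminology(table: TerminologyTable,
                        pattern: Optional[IriPattern] = None) -> Graph:
    """One class per code, one subClassOf edge per parent link.

    The ontology header gets a distinct version IRI per release
    (``<ontology_iri>/<version_label>``), so several versions of the same
    terminology can coexist as separate graphs.
    """
    table.check()
    if pattern is None:
        if table.terminology_id not in REGISTRY:
            register_terminology(table.terminology_id)
        pattern = REGISTRY[table.terminology_id]
    g = Graph()
    onto = IRI(pattern.ontology_iri)
    version = IRI(pattern.ontology_iri.rstrip("/") + "/" + table.version_label)
    g.ontology_iri, g.version_iri = onto, version
    g.add(onto, RDF.type, OWL.Ontology)
    g.add(onto, OWL.versionIRI, version)
    g.bind(table.terminology_id.lower().replace("-", ""), pattern.code_prefix)
    is_ucum = table.terminology_id == "UCUM"
    for code, label, parent in table.rows:
        iri = code_iri(table.terminology_id, code)
        g.add(iri, RDF.type, RDFS.Class)
        g.add(iri, RDFS.label, Literal(label))
        if is_ucum and ucum_local_name(code) != code:
            g.add(iri, RDFS.comment, Literal(f"UCUM notation: {code}"))
        if parent is not None:
            g.add(iri, RDFS.subClassOf, code_iri(table.terminology_id, parent))
    return g


def hierarchy_closure(g: Graph, root: IRI) -> set[IRI]:
    """Reflexive-transitive subclass closure below ``root``.

    Returns ``root`` together with every transitive subclass, i.e. the set
    of codes a query "any descendant of root" must match.
    """
    known = set(g._spo)
    for _, _, o in g.triples(None, RDFS.subClassOf, None):
        known.add(o)
    if root not in known:
        raise TerminologyError(f"root {root} not present in graph")
    closure = {root}
    frontier = [root]
    while frontier:
        node = frontier.pop()
        for child in g.subjects(RDFS.subClassOf, node):
            if child not in closure:
                closure.add(child)
                frontier.append(child)
    return closure
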