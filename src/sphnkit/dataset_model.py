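"""Tabular dataset-definition dialect: parsing and consistency checking.

A dataset definition is the data dictionary of a project: an ordered list of
*concepts* (Heart Rate, Allergy Episode, ...), each composed of typed
properties ("composedOf" in the source vocabulary).  The canonical on-disk
form is a UTF-8 CSV with one row per (concept, property); concept-only rows
(empty ``property_name``) declare concepts without properties.

Columns::

    concept_name, concept_description, parent_concept, meaning_binding,
    property_name, property_description, value_kind, target, min_card, max_card

Cell micro-syntax:

* ``meaning_binding`` — ``TERM:code`` pairs separated by ``;``
  (e.g. ``SNOMED:364075005;LOINC:8867-4``).
* ``target`` for ``value_kind=code`` — ``TERM:exact:c1|c2`` or
  ``TERM:descendants_of:c``.
* ``target`` for ``value_kind=valueset`` — ``SetName:m1|m2|m3`` declares the
  set inline at first use; later rows may write just ``SetName``.
* ``max_card`` — the literal ``n`` means unbounded; empty min/max default to
  ``0`` / ``n`` (optional, repeatable).

An ``.xlsx`` file with identical columns on the first sheet is accepted as a
thin adapter over the same reader.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

from . import terminology_rdf

DIALECT_COLUMNS = [
    "concept_name", "concept_description", "parent_concept", "meaning_binding",
    "property_name", "property_description", "value_kind", "target",
    "min_card", "max_card",
]

VALUE_KINDS = {"concept", "code", "valueset", "quantitative", "temporal",
               "string"}

DEFAULT_NAMESPACE = "https://biomedit.ch/rdf/sphn-ontology/sphn"


class DatasetFormatError(ValueError):
    """The file does not conform to the dialect (bad header, bad cell)."""


@dataclass(frozen=True)
class CodeBinding:
    """A value-set binding to external terminology codes."""

    terminology: str
    mode: str  # "exact_codes" | "descendants_of"
    codes: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.mode not in ("exact_codes", "descendants_of"):
            raise ValueError(f"unknown code-binding mode: {self.mode}")
        if not self.codes:
            raise ValueError("code binding requires at least one code")
        if self.mode == "descendants_of" and len(self.codes) != 1:
            raise ValueError("descendants_of takes exactly one root code")


@dataclass
class PropertyDefinition:
    name: str
    description: str = ""
    value_kind: str = "string"
    #: concept name (kind=concept), CodeBinding (kind=code),
    #: value-set name (kind=valueset), None otherwise.
    target: Union[str, CodeBinding, None] = None
    min_card: int = 0
    max_card: Optional[int] = None  # None = unbounded


@dataclass
class ConceptDefinition:
    name: str
    description: str = ""
    parent: Optional[str] = None
    meaning_bindings: list[tuple[str, str]] = field(default_factory=list)
    properties: list[PropertyDefinition] = field(default_factory=list)


@dataclass
class ValueSetDefinition:
    name: str
    members: list[tuple[str, Optional[str]]] = field(default_factory=list)


@dataclass
class DatasetDefinition:
    concepts: list[ConceptDefinition] = field(default_factory=list)
    value_sets: list[ValueSetDefinition] = field(default_factory=list)
    version_year: int = 2022
    version_index: int = 2
    namespace: str = DEFAULT_NAMESPACE

    def concept(self, name: str) -> ConceptDefinition:
        for c in self.concepts:
            if c.name == name:
                return c
        raise KeyError(name)

    def value_set(self, name: str) -> ValueSetDefinition:
        for v in self.value_sets:
            if v.name == name:
                return v
        raise KeyError(name)


@dataclass(frozen=True)
class Finding:
    """One consistency problem; ``severity`` is 'error' or 'warning'."""

    severity: str
    concept: str
    message: str


def _norm(name: str) -> str:
    return " ".join(name.split()).casefold()


def _parse_card(cell: str, which: str, line_no: int):
    cell = cell.strip()
    if cell == "":
        return 0 if which == "min" else None
    if which == "max" and cell.lower() == "n":
        return None
    try:
        value = int(cell)
    except ValueError:
        raise DatasetFormatError(
            f"line {line_no}: unparseable {which}_card {cell!r}") from None
    if value < 0:
        raise DatasetFormatError(f"line {line_no}: negative {which}_card")
    return value


def _parse_meaning(cell: str, line_no: int) -> list[tuple[str, str]]:
    out = []
    for chunk in filter(None, (c.strip() for c in cell.split(";"))):
        if ":" not in chunk:
            raise DatasetFormatError(
                f"line {line_no}: meaning binding {chunk!r} is not TERM:code")
        term, code = chunk.split(":", 1)
        out.append((term.strip(), code.strip()))
    return out


def _parse_target(kind: str, cell: str, line_no: int, dataset: DatasetDefinition):
    cell = cell.strip()
    if kind == "concept":
        if not cell:
            raise DatasetFormatError(
                f"line {line_no}: concept-valued property needs a target")
        return cell
    if kind == "code":
        parts = cell.split(":", 2)
        if len(parts) != 3:
            raise DatasetFormatError(
                f"line {line_no}: code target must be TERM:mode:codes, got {cell!r}")
        term, mode, codes = parts
        mode = {"exact": "exact_codes", "exact_codes": "exact_codes",
                "descendants_of": "descendants_of"}.get(mode)
        if mode is None:
            raise DatasetFormatError(f"line {line_no}: unknown code mode in {cell!r}")
        return CodeBinding(term, mode, tuple(c for c in codes.split("|") if c))
    if kind == "valueset":
        if ":" in cell:
            set_name, members = cell.split(":", 1)
            labels = [m for m in members.split("|") if m]
            try:
                dataset.value_set(set_name)
            except KeyError:
                dataset.value_sets.append(
                    ValueSetDefinition(set_name, [(m, None) for m in labels]))
            return set_name
        return cell
    if cell:
        raise DatasetFormatError(
            f"line {line_no}: {kind} property takes no target, got {cell!r}")
    return None


def _ingest_rows(rows, dataset: DatasetDefinition) -> DatasetDefinition:
    by_name: dict[str, ConceptDefinition] = {}
    for line_no, row in rows:
        cname = (row.get("concept_name") or "").strip()
        if not cname:
            raise DatasetFormatError(f"line {line_no}: empty concept_name")
        concept = by_name.get(cname)
        if concept is None:
            concept = ConceptDefinition(
                name=cname,
                description=(row.get("concept_description") or "").strip(),
                parent=(row.get("parent_concept") or "").strip() or None,
                meaning_bindings=_parse_meaning(
                    row.get("meaning_binding") or "", line_no),
            )
            by_name[cname] = concept
            dataset.concepts.append(concept)
        pname = (row.get("property_name") or "").strip()
        if not pname:
            continue
        kind = (row.get("value_kind") or "").strip()
        if kind not in VALUE_KINDS:
            raise DatasetFormatError(
                f"line {line_no}: unknown value_kind {kind!r}")
        concept.properties.append(PropertyDefinition(
            name=pname,
            description=(row.get("property_description") or "").strip(),
            value_kind=kind,
            target=_parse_target(kind, row.get("target") or "", line_no, dataset),
            min_card=_parse_card(row.get("min_card") or "", "min", line_no),
            max_card=_parse_card(row.get("max_card") or "", "max", line_no),
        ))
    return dataset


def read_dataset(path: Union[str, Path], *, version_year: int = 2022,
                 version_index: int = 2,
                 namespace: str = DEFAULT_NAMESPACE) -> DatasetDefinition:
    """Read a dataset definition from the CSV dialect (or .xlsx adapter)."""
    path = Path(path)
    dataset = DatasetDefinition(version_year=version_year,
                                version_index=version_index,
                                namespace=namespace)
    if path.suffix.lower() in (".xlsx", ".xlsm"):
        rows = _xlsx_rows(path)
    else:
        rows = _csv_rows(path)
    return _ingest_rows(rows, dataset)


def _check_header(fields) -> None:
    missing = [c for c in DIALECT_COLUMNS if c not in (fields or [])]
    if missing:
        raise DatasetFormatError(
            f"missing mandatory column(s): {', '.join(missing)}")


def _csv_rows(path: Path):
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        _check_header(reader.fieldnames)
        for i, row in enumerate(reader, start=2):
            yield i, row


def _xlsx_rows(path: Path):
    from openpyxl import load_workbook

    wb = load_workbook(path, read_only=True, data_only=True)
    ws = wb.worksheets[0]
    it = ws.iter_rows(values_only=True)
    header = ["" if v is None else str(v).strip() for v in next(it)]
    _check_header(header)
    for i, values in enumerate(it, start=2):
        row = {h: ("" if v is None else str(v))
               for h, v in zip(header, values)}
        yield i, row


def write_dataset(dataset: DatasetDefinition) -> str:
    """Serialise back to the CSV dialect (inverse of :func:`read_dataset`)."""
    buf = io.StringIO()
    writer = csv.DictWriter(buf, fieldnames=DIALECT_COLUMNS, lineterminator="\n")
    writer.writeheader()
    declared: set[str] = set()
    for concept in dataset.concepts:
        base = {
            "concept_name": concept.name,
            "concept_description": concept.description,
            "parent_concept": concept.parent or "",
            "meaning_binding": ";".join(f"{t}:{c}"
                                        for t, c in concept.meaning_bindings),
        }
        if not concept.properties:
            writer.writerow({**base, "property_name": "", "property_description": "",
                             "value_kind": "", "target": "", "min_card": "",
                             "max_card": ""})
        for prop in concept.properties:
            target = ""
            if prop.value_kind == "concept":
                target = str(prop.target)
            elif prop.value_kind == "code":
                cb = prop.target
                mode = "exact" if cb.mode == "exact_codes" else cb.mode
                target = f"{cb.terminology}:{mode}:{'|'.join(cb.codes)}"
            elif prop.value_kind == "valueset":
                set_name = str(prop.target)
                if set_name not in declared:
                    declared.add(set_name)
                    members = "|".join(m for m, _ in dataset.value_set(set_name).members)
                    target = f"{set_name}:{members}"
                else:
                    target = set_name
            writer.writerow({**base, "property_name": prop.name,
                             "property_description": prop.description,
                             "value_kind": prop.value_kind, "target": target,
                             "min_card": str(prop.min_card),
                             "max_card": "n" if prop.max_card is None
                             else str(prop.max_card)})
    return buf.getvalue()


def check_dataset(dataset: DatasetDefinition,
                  terminologies: Optional[dict] = None) -> list[Finding]:
    """Return all invariant violations as findings (empty list = consistent).

    ``terminologies`` optionally maps terminology ids to
    :class:`~sphnkit.terminology_rdf.TerminologyTable`; when supplied, bound
    codes must exist in the referenced table.
    """
    findings: list[Finding] = []

    def err(concept: str, message: str) -> None:
        findings.append(Finding("error", concept, message))

    if dataset.version_year < 2020:
        err("", f"version_year {dataset.version_year} < 2020")
    if dataset.version_index < 1:
        err("", f"version_index {dataset.version_index} < 1")

    seen: dict[str, str] = {}
    names = set()
    for c in dataset.concepts:
        names.add(c.name)
        if not c.name.strip():
            err(c.name, "empty concept name")
            continue
        key = _norm(c.name)
        if key in seen:
            err(c.name, f"duplicate concept name (collides with {seen[key]!r} "
                        "after case-insensitive normalisation)")
        else:
            seen[key] = c.name

    known_terms = set(terminology_rdf.REGISTRY)
    if terminologies:
        known_terms |= set(terminologies)

    for c in dataset.concepts:
        if c.parent is not None:
            if c.parent == c.name:
                err(c.name, "concept is its own parent")
            elif c.parent not in names:
                err(c.name, f"dangling concept reference: parent {c.parent!r} "
                            "is not defined")
        for term, code in c.meaning_bindings:
            if term not in known_terms:
                err(c.name, f"meaning binding to undeclared terminology {term!r}")
            elif terminologies and term in terminologies \
                    and code not in terminologies[term].codes:
                err(c.name, f"meaning-binding code {term}:{code} not found "
                            "in terminology table")
        for p in c.properties:
            if p.max_card is not None and p.min_card > p.max_card:
                err(c.name, f"property {p.name!r}: min_card {p.min_card} > "
                            f"max_card {p.max_card}")
            if p.value_kind == "concept" and p.target not in names:
                err(c.name, f"property {p.name!r}: dangling concept reference "
                            f"{p.target!r}")
            if p.value_kind == "code":
                cb = p.target
                if not isinstance(cb, CodeBinding):
                    err(c.name, f"property {p.name!r}: code kind without binding")
                    continue
                if cb.terminology not in known_terms:
                    err(c.name, f"property {p.name!r}: undeclared terminology "
                                f"{cb.terminology!r}")
                elif terminologies and cb.terminology in terminologies:
                    missing = [x for x in cb.codes
                               if x not in terminologies[cb.terminology].codes]
                    for x in missing:
                        err(c.name, f"property {p.name!r}: code "
                                    f"{cb.terminology}:{x} not in terminology")
            if p.value_kind == "valueset":
                try:
                    vs = dataset.value_set(str(p.target))
                except KeyError:
                    err(c.name, f"property {p.name!r}: unknown value set "
                                f"{p.target!r}")
                    continue
                if not vs.members:
                    err(c.name, f"value set {vs.name!r} has no members")

    for vs in dataset.value_sets:
        labels = [m for m, _ in vs.members]
        if len(set(labels)) != len(labels):
            err("", f"value set {vs.name!r} has duplicate member labels")
    return findings
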