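"""Desk-scale data-provider pipeline.

Re-creates the provider-side steps between a hospital data mart and a
schema-conformant instance graph:

1. synthesize a project data mart (patients, vital-sign measurements,
   allergy episodes) — the stand-in for an EHR extract;
2. pseudonymise direct identifiers (keyed MAC) and generalise
   quasi-identifiers (year truncation, age banding);
3. apply local-to-standard mapping tables;
4. build standardised views with standardised names;
5. convert views to RDF instances following the schema;
6. (for testing the validation stage) inject controlled violations with a
   manifest of every mutation applied.

Instance IRIs are deterministic functions of (provider id, concept, row
key, seed), so re-running the pipeline on the same inputs reproduces the
graph byte for byte.
"""

from __future__ import annotations

import csv
import hashlib
import hmac
import io
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Union

import numpy as np
import pandas as pd

from .rdf import (DCTERMS, Graph, IRI, Literal, OWL, RDF, RDFS, XSD)
from .schema_compiler import class_iri, property_iri
from .terminology_rdf import SPHN_RESOURCE, code_iri

RESOURCE_BASE = SPHN_RESOURCE


class PipelineError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Step 1 — data mart synthesis
# ---------------------------------------------------------------------------

@dataclass
class MartConfig:
    """Synthetic-extract shape: cohort size and per-concept record rates."""

    n_patients: int = 50
    heart_rate_per_patient: int = 3
    oxygen_sat_per_patient: int = 2
    allergy_per_patient: int = 1
    #: resting heart rate ~ N(75, 12), clipped to a plausible ward range
    heart_rate_mean: float = 75.0
    heart_rate_sd: float = 12.0
    #: SpO2 ~ N(97, 1.5) capped at 100
    spo2_mean: float = 97.0
    spo2_sd: float = 1.5

    def __post_init__(self) -> None:
        for name in ("n_patients", "heart_rate_per_patient",
                     "oxygen_sat_per_patient", "allergy_per_patient"):
            if getattr(self, name) < 0:
                raise PipelineError(f"{name} must be non-negative")


@dataclass
class DataMart:
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    id_columns: dict[str, list[str]] = field(default_factory=dict)
    #: table → {column: generalisation rule id}
    quasi_id_columns: dict[str, dict[str, str]] = field(default_factory=dict)

    def check(self) -> None:
        for table, cols in {**self.id_columns,
                            **{t: list(c) for t, c in self.quasi_id_columns.items()}
                            }.items():
            if table not in self.tables:
                raise PipelineError(f"declared table {table!r} does not exist")
            for col in cols:
                if col not in self.tables[table].columns:
                    raise PipelineError(
                        f"declared column {table}.{col} does not exist")

    def copy(self) -> "DataMart":
        return DataMart(
            tables={t: df.copy() for t, df in self.tables.items()},
            id_columns={t: list(c) for t, c in self.id_columns.items()},
            quasi_id_columns={t: dict(c)
                              for t, c in self.quasi_id_columns.items()},
        )

    def dump_csv(self) -> dict[str, str]:
        """Deterministic CSV text per table (sorted table names)."""
        return {name: self.tables[name].to_csv(index=False, lineterminator="\n")
                for name in sorted(self.tables)}


LOCAL_SUBSTANCES = ["ALG-PEANUT", "ALG-BEAN", "ALG-LENTIL", "ALG-EGG"]
LOCAL_REACTIONS = ["RASH", "ANAPH"]
LOCAL_SEVERITIES = ["mild", "moderate", "severe"]


def generate_datamart(config: MartConfig, seed: int) -> DataMart:
    """Synthesize a deterministic project data mart for ``seed``."""
    rng = np.random.default_rng(seed)
    n = config.n_patients
    patient_ids = [f"USZ-PAT-{i:05d}" for i in range(1, n + 1)]
    birth_years = rng.integers(1930, 2005, size=n)
    patients = pd.DataFrame({
        "patient_id": patient_ids,
        "birth_date": [f"{y}-{rng.integers(1, 13):02d}-{rng.integers(1, 29):02d}"
                       for y in birth_years],
        "age": [2022 - int(y) for y in birth_years],
    })

    def timestamps(count: int) -> list[str]:
        days = rng.integers(0, 364, size=count)
        secs = rng.integers(0, 86400, size=count)
        base = pd.Timestamp("2022-01-01", tz="UTC")
        return [(base + pd.Timedelta(days=int(d), seconds=int(s)))
                .strftime("%Y-%m-%dT%H:%M:%SZ") for d, s in zip(days, secs)]

    hr_rows = n * config.heart_rate_per_patient
    heart_rate = pd.DataFrame({
        "patient_id": np.repeat(patient_ids, config.heart_rate_per_patient),
        "hr_bpm": np.clip(
            rng.normal(config.heart_rate_mean, config.heart_rate_sd, hr_rows),
            40, 180).round().astype(int),
        "unit": "bpm",
        "measured_at": timestamps(hr_rows),
    })

    spo2_rows = n * config.oxygen_sat_per_patient
    oxygen_saturation = pd.DataFrame({
        "patient_id": np.repeat(patient_ids, config.oxygen_sat_per_patient),
        "spo2": np.clip(rng.normal(config.spo2_mean, config.spo2_sd, spo2_rows),
                        80, 100).round(1),
        "unit": "pct",
        "measured_at": timestamps(spo2_rows),
    })

    al_rows = n * config.allergy_per_patient
    allergy = pd.DataFrame({
        "patient_id": np.repeat(patient_ids, config.allergy_per_patient),
        "substance": rng.choice(LOCAL_SUBSTANCES, size=al_rows),
        "reaction": rng.choice(LOCAL_REACTIONS, size=al_rows),
        "severity": rng.choice(LOCAL_SEVERITIES, size=al_rows),
        "note": "recorded on admission",
    })

    mart = DataMart(
        tables={"patients": patients, "heart_rate": heart_rate,
                "oxygen_saturation": oxygen_saturation, "allergy": allergy},
        id_columns={t: ["patient_id"] for t in
                    ("patients", "heart_rate", "oxygen_saturation", "allergy")},
        quasi_id_columns={"patients": {"birth_date": "year_only",
                                       "age": "band"}},
    )
    mart.check()
    return mart


# ---------------------------------------------------------------------------
# Step 2 — pseudonymisation and deidentification
# ---------------------------------------------------------------------------

def pseudocode(identifier: str, project_key: str, width: int = 16) -> str:
    """Keyed, deterministic pseudocode (truncated HMAC-SHA256, hex)."""
    mac = hmac.new(project_key.encode("utf-8"), identifier.encode("utf-8"),
                   hashlib.sha256)
    return mac.hexdigest()[:width]


def pseudonymize(mart: DataMart, project_key: str) -> DataMart:
    """Replace every declared direct identifier with a project pseudocode."""
    if not project_key:
        raise PipelineError("a non-empty project key is required")
    mart.check()
    out = mart.copy()
    for table, cols in mart.id_columns.items():
        for col in cols:
            out.tables[table][col] = [
                pseudocode(str(v), project_key)
                for v in mart.tables[table][col]]
    return out


DEFAULT_POLICY: dict[str, dict] = {
    "year_only": {},
    "band": {"width": 5, "cap": 90},
}

_BAND_RE = re.compile(r"\A(\d+-\d+|\d+\+)\Z")
_DATE_RE = re.compile(r"\A(\d{4})(-\d{2}-\d{2}.*)?\Z")


def _apply_rule(rule: str, params: dict, value) -> str:
    v = str(value)
    if rule == "year_only":
        m = _DATE_RE.match(v)
        if not m:
            raise PipelineError(f"year_only rule cannot parse {v!r}")
        return m.group(1)
    if rule == "band":
        if _BAND_RE.match(v):
            return v  # already banded
        age = int(v)
        width, cap = params.get("width", 5), params.get("cap", 90)
        if age >= cap:
            return f"{cap}+"
        lo = (age // width) * width
        return f"{lo}-{lo + width - 1}"
    raise PipelineError(f"unknown generalisation rule {rule!r}")


def deidentify(mart: DataMart, policy: Optional[dict] = None) -> DataMart:
    """Generalise quasi-identifiers; total and idempotent over the policy."""
    policy = DEFAULT_POLICY if policy is None else policy
    mart.check()
    out = mart.copy()
    for table, cols in mart.quasi_id_columns.items():
        for col, rule in cols.items():
            if rule not in policy:
                raise PipelineError(
                    f"quasi-identifier {table}.{col} uses rule {rule!r} "
                    "not covered by the policy")
            params = policy[rule]
            out.tables[table][col] = [
                _apply_rule(rule, params, v) for v in mart.tables[table][col]]
    return out


# ---------------------------------------------------------------------------
# Step 3/4 — mapping tables and standardised views
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MappingRow:
    table: str
    column: str      # "*" declares the table→concept mapping
    local_value: str  # "*" declares a structural (column→property) mapping
    target: str      # concept label, property path, or target IRI


@dataclass
class MappingTable:
    rows: list[MappingRow] = field(default_factory=list)

    def check(self) -> None:
        seen = set()
        for r in self.rows:
            key = (r.table, r.column, r.local_value)
            if key in seen:
                raise PipelineError(f"duplicate mapping row {key}")
            seen.add(key)

    def concept_for(self, table: str) -> Optional[str]:
        for r in self.rows:
            if r.table == table and r.column == "*":
                return r.target
        return None

    def column_target(self, table: str, column: str) -> Optional[str]:
        for r in self.rows:
            if r.table == table and r.column == column and r.local_value == "*":
                return r.target
        return None

    def value_map(self, table: str, column: str) -> dict[str, str]:
        return {r.local_value: r.target for r in self.rows
                if r.table == table and r.column == column
                and r.local_value != "*"}

    def to_csv(self) -> str:
        buf = io.StringIO()
        w = csv.writer(buf, lineterminator="\n")
        w.writerow(["table", "column", "local_value", "target"])
        for r in self.rows:
            w.writerow([r.table, r.column, r.local_value, r.target])
        return buf.getvalue()

    @classmethod
    def from_csv(cls, path: Union[str, Path]) -> "MappingTable":
        table = cls()
        with open(path, newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            required = {"table", "column", "local_value", "target"}
            missing = required - set(reader.fieldnames or [])
            if missing:
                raise PipelineError(
                    f"mapping CSV missing column(s): {', '.join(sorted(missing))}")
            for row in reader:
                table.rows.append(MappingRow(
                    row["table"].strip(), row["column"].strip(),
                    row["local_value"].strip(), row["target"].strip()))
        table.check()
        return table


def apply_mappings(mart: DataMart, mapping: MappingTable
                   ) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Build standardised views; collect unmapped values as rejections.

    Returns ``(views, rejections)``: ``views`` maps concept labels to
    DataFrames whose columns are property paths (``quantity.value``); rows
    containing an unmapped-but-declared local value are excluded from the
    views and reported in ``rejections`` (one row per distinct rejected
    (table, column, value)).
    """
    mapping.check()
    views: dict[str, pd.DataFrame] = {}
    rejected: list[tuple[str, str, str]] = []
    for table in sorted(mart.tables):
        concept = mapping.concept_for(table)
        if concept is None:
            continue
        df = mart.tables[table]
        out = {}
        bad_rows = pd.Series(False, index=df.index)
        for col in df.columns:
            target = mapping.column_target(table, col)
            if target is None:
                continue
            values = df[col]
            vmap = mapping.value_map(table, col)
            if vmap:
                mapped = values.astype(str).map(vmap)
                misses = values[mapped.isna()]
                for v in sorted(set(misses.astype(str))):
                    rejected.append((table, col, v))
                bad_rows |= mapped.isna()
                out[target] = mapped
            else:
                out[target] = values
        view = pd.DataFrame(out)
        if bad_rows.any():
            view = view[~bad_rows].reset_index(drop=True)
        views[concept] = view
    rejections = pd.DataFrame(rejected,
                              columns=["table", "column", "local_value"])
    return views, rejections


# ---------------------------------------------------------------------------
# Step 5 — RDF instance generation
# ---------------------------------------------------------------------------

def _instance_iri(provider: str, concept_local: str, key: str, seed: int) -> IRI:
    digest = hashlib.sha256(
        f"{provider}|{concept_local}|{key}|{seed}".encode()).hexdigest()[:12]
    return IRI(f"{RESOURCE_BASE}/{provider}/{concept_local}/{digest}")


def to_instances(views: dict[str, pd.DataFrame], schema: Graph,
                 provider: str = "demo-provider", seed: int = 0) -> Graph:
    """Transform standardised views into typed RDF instances.

    View columns are property paths over composedOf labels; a dotted path
    (``quantity.value``) materialises the intermediate node (here a
    Quantity) typed with the property's range class.  Cells of
    object-valued properties hold target IRIs from the mapping step; the
    subject-pseudo-identifier column holds the pseudocode, from which a
    patient node is minted (one per patient and provider).
    """
    ns = str(schema.ontology_iri)
    g = Graph()
    g.bind("sphn", ns + "#")
    doc = IRI(f"{RESOURCE_BASE}/{provider}")
    g.ontology_iri = doc
    g.add(doc, RDF.type, OWL.Ontology)
    if schema.version_iri is not None:
        g.add(doc, DCTERMS.conformsTo, schema.version_iri)
    g.add(doc, DCTERMS.creator, Literal(provider))

    minted: dict[tuple[str, str], IRI] = {}

    def keyed_node(range_class: IRI, key: str) -> IRI:
        local = str(range_class).rsplit("#", 1)[-1]
        node = minted.get((local, key))
        if node is None:
            node = IRI(f"{RESOURCE_BASE}/{provider}/{local}/{key}")
            minted[(local, key)] = node
            g.add(node, RDF.type, range_class)
        return node

    for concept_label in sorted(views):
        cls = class_iri(concept_label, ns)
        if (cls, RDF.type, OWL.Class) not in schema:
            raise PipelineError(
                f"view {concept_label!r} does not name a schema concept")
        local = str(cls).rsplit("#", 1)[-1]
        df = views[concept_label]
        for i, row in enumerate(df.itertuples(index=False)):
            inst = _instance_iri(provider, local, f"row{i:06d}", seed)
            g.add(inst, RDF.type, cls)
            children: dict[str, IRI] = {}
            for col, value in zip(df.columns, row):
                if value is None or (isinstance(value, float) and pd.isna(value)):
                    continue
                subject = inst
                parts = col.replace("_", " ").split(".")
                for hop in parts[:-1]:
                    hop_prop = property_iri(hop, ns)
                    rng = schema.value(hop_prop, RDFS.range)
                    if not isinstance(rng, IRI):
                        raise PipelineError(
                            f"path segment {hop!r} has no class range in the "
                            "schema")
                    child = children.get(hop)
                    if child is None:
                        child = _instance_iri(
                            provider, str(rng).rsplit("#", 1)[-1],
                            f"{local}-row{i:06d}-{hop}", seed)
                        g.add(child, RDF.type, rng)
                        g.add(subject, hop_prop, child)
                        children[hop] = child
                    subject = child
                leaf = property_iri(parts[-1], ns)
                if (leaf, RDF.type, OWL.DatatypeProperty) in schema:
                    g.add(subject, leaf, _typed_literal(schema, leaf, value))
                elif (leaf, RDF.type, OWL.ObjectProperty) in schema:
                    sval = str(value)
                    if sval.startswith("http"):
                        g.add(subject, leaf, IRI(sval))
                    else:
                        rng = schema.value(leaf, RDFS.range)
                        if not isinstance(rng, IRI):
                            raise PipelineError(
                                f"column {col!r}: plain value {sval!r} for a "
                                "property without a class range")
                        g.add(subject, leaf, keyed_node(rng, sval))
                else:
                    raise PipelineError(
                        f"column {col!r} does not name a schema property")
    return g


def _typed_literal(schema: Graph, prop: IRI, value) -> Literal:
    rng = schema.value(prop, RDFS.range)
    dt = str(rng) if isinstance(rng, IRI) else str(XSD.string)
    if dt == str(XSD.double):
        return Literal(repr(float(value)), dt)
    return Literal(str(value), dt)


# ---------------------------------------------------------------------------
# Step 6 harness — violation injection
# ---------------------------------------------------------------------------

VIOLATION_KINDS = ("missing_required", "extra_beyond_max", "wrong_datatype",
                   "code_not_allowed", "wrong_unit")


@dataclass(frozen=True)
class ViolationRecord:
    instance: IRI
    kind: str
    path: IRI


def inject_violations(g: Graph, shapes, spec: dict[str, int], seed: int
                      ) -> tuple[Graph, list[ViolationRecord]]:
    """Apply exactly the requested mutations; return graph + manifest.

    Each mutation is designed to trip exactly one constraint of the
    supplied shapes, so a validator with perfect precision/recall reports
    exactly the manifest's (focus, path) pairs.  Mutations prefer distinct
    focus nodes.
    """
    unknown = set(spec) - set(VIOLATION_KINDS)
    if unknown:
        raise PipelineError(f"unsupported violation kind(s): {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    out = g.copy()
    manifest: list[ViolationRecord] = []
    used_focus: set[IRI] = set()

    for kind in VIOLATION_KINDS:
        count = spec.get(kind, 0)
        if count == 0:
            continue
        candidates = _candidates(out, shapes, kind)
        order = list(range(len(candidates)))
        rng.shuffle(order)
        fresh = [i for i in order if candidates[i][0] not in used_focus]
        reused = [i for i in order if candidates[i][0] in used_focus]
        chosen_idx = []
        picked_focus = set()
        for i in fresh + reused:
            if len(chosen_idx) == count:
                break
            focus = candidates[i][0]
            if focus in picked_focus:
                continue  # one mutation per focus within a kind
            picked_focus.add(focus)
            chosen_idx.append(i)
        if len(chosen_idx) < count:
            raise PipelineError(
                f"cannot inject {count} {kind!r} violations: only "
                f"{len(chosen_idx)} eligible instances")
        for i in chosen_idx:
            focus, path, mutate = candidates[i]
            mutate(out)
            used_focus.add(focus)
            manifest.append(ViolationRecord(focus, kind, path))
    return out, manifest


def _candidates(g: Graph, shapes, kind: str):
    """(focus, path, mutation) triples for one violation kind, sorted."""
    out = []
    for shape in shapes.shapes:
        for c in shape.constraints:
            for focus in g.subjects(RDF.type, shape.target_class):
                values = g.objects(focus, c.path)
                if kind == "missing_required":
                    if c.min_count and len(values) == c.min_count:
                        v = values[0]
                        out.append((focus, c.path,
                                    _mk(lambda gg, f=focus, p=c.path, vv=v:
                                        gg.discard(f, p, vv))))
                elif kind == "extra_beyond_max":
                    if c.max_count is not None and len(values) == c.max_count:
                        extra = _extra_value(g, shape, c, focus, values)
                        if extra is not None:
                            out.append((focus, c.path,
                                        _mk(lambda gg, f=focus, p=c.path,
                                            vv=extra: gg.add(f, p, vv))))
                elif kind == "wrong_datatype":
                    if c.datatype is not None and values \
                            and isinstance(values[0], Literal):
                        old = values[0]
                        wrong_dt = (str(XSD.string)
                                    if str(c.datatype) != str(XSD.string)
                                    else str(XSD.double))
                        new = Literal(old.lexical, wrong_dt)

                        def swap(gg, f=focus, p=c.path, o=old, n=new):
                            gg.discard(f, p, o)
                            gg.add(f, p, n)
                        out.append((focus, c.path, swap))
                elif kind == "code_not_allowed":
                    if c.allowed_values and not _is_unit_path(c.path) and values:
                        old = values[0]
                        bad = IRI(f"{RESOURCE_BASE}/not-a-valid-code/0")

                        def swap(gg, f=focus, p=c.path, o=old, n=bad):
                            gg.discard(f, p, o)
                            gg.add(f, p, n)
                        out.append((focus, c.path, swap))
                elif kind == "wrong_unit":
                    if c.allowed_values and _is_unit_path(c.path) and values:
                        old = values[0]
                        bad = _wrong_unit(c.allowed_values)

                        def swap(gg, f=focus, p=c.path, o=old, n=bad):
                            gg.discard(f, p, o)
                            gg.add(f, p, n)
                        out.append((focus, c.path, swap))
    out.sort(key=lambda t: (str(t[0]), str(t[1])))
    return out


def _mk(fn):
    return fn


def _is_unit_path(path: IRI) -> bool:
    return str(path).rsplit("#", 1)[-1] == "hasUnit"


def _wrong_unit(allowed) -> IRI:
    for candidate in (code_iri("UCUM", "beats/min"), code_iri("UCUM", "%"),
                      code_iri("UCUM", "furlong")):
        if candidate not in allowed:
            return candidate
    raise PipelineError("no wrong unit available")  # pragma: no cover


def _extra_value(g: Graph, shape, c, focus, values):
    if c.allowed_values:
        for v in c.allowed_values:
            if v not in values:
                return v
        return None
    if c.node_class is not None:
        for other in g.subjects(RDF.type, c.node_class):
            if other not in values:
                return other
        return None
    if c.datatype is not None:
        base = Literal("999.0", str(c.datatype)) \
            if str(c.datatype) == str(XSD.double) \
            else Literal("duplicate", str(c.datatype))
        return base if base not in values else None
    return IRI(f"{RESOURCE_BASE}/extra/0")
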