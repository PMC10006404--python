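# sphnkit

A toolkit for making hospital data semantically interoperable with Semantic
Web standards, modelled on the Swiss Personalized Health Network (SPHN)
interoperability framework. It is aimed at data engineers at health-data
providers and at researchers who consume RDF health data: it turns a tabular
data dictionary of clinical *concepts* and their *composedOf* properties into
an OWL/RDF schema, converts standard terminologies (SNOMED CT, LOINC, ATC,
ICD-10-GM, CHOP, UCUM) into RDF class hierarchies, derives SHACL validation
shapes automatically from the schema, runs a desk-scale provider ETL
(pseudonymisation, deidentification, local-to-standard mapping, RDF
instantiation), and validates and queries the resulting instance graphs with
RDFS subclass entailment.

## The machinery

**Schema compilation.** Each concept *C* in the dictionary becomes an
`owl:Class` with a Pascal-case IRI (`Heart Rate` → `sphn:HeartRate`); each
composedOf *p* becomes an `owl:ObjectProperty` (concept-, code- or
value-set-valued) or `owl:DatatypeProperty` (quantitative, temporal, string)
named `has` + CamelCase (`quantity` → `sphn:hasQuantity`). `rdfs:range` is
asserted only when the target is another schema class. Allowed codes and
cardinalities are encoded per using class as anonymous restrictions:

```
C  rdfs:subClassOf  [ a owl:Restriction ;
                      owl:onProperty    has_p ;
                      owl:minCardinality m ; owl:maxCardinality n ] ,
                    [ a owl:Restriction ;
                      owl:onProperty    has_p ;
                      owl:hasValue      <code> ]        # single value
```

with an `owl:oneOf` enumeration for several allowed values and
`owl:allValuesFrom <root>` for "any descendant of *root*" bindings. Meaning
bindings to SNOMED CT / LOINC are `owl:equivalentClass` axioms; internally
defined value-set members are `owl:NamedIndividual`s. The ontology header
carries a version IRI `<namespace>/<year>/<index>`.

**Terminologies.** A flat `code,label,parent_code` table becomes one
`rdfs:Class` per code with `rdfs:subClassOf` from child to parent, one graph
per (terminology, version). The reflexive-transitive subclass closure of a
code — the set a "root or any descendant" query must match — is computed by
forward chaining and is the oracle behind both SHACL expansion and cohort
queries.

**SHACL generation.** Every schema class gets an open `sh:NodeShape`; each
restriction becomes a property shape with `sh:minCount`/`sh:maxCount`,
`sh:class` (from schema-class ranges), `sh:datatype`, and `sh:in` lists, with
descendant bindings expanded through the subclass closure at generation time
so the shapes stay engine-portable.

**Provider pipeline.** Direct identifiers are replaced by truncated keyed
HMAC-SHA256 pseudocodes (deterministic per project key, so joins survive);
quasi-identifiers are generalised (year truncation, age banding); mapping
tables translate local codes to terminology IRIs (unmapped values are
rejected, never passed through); standardised views are instantiated as
typed RDF with deterministic instance IRIs. A violation injector mutates a
conformant graph in controlled ways and records a manifest, which the
validator must reproduce exactly — the keystone soundness check.

## Worked example

```python
import sphnkit as sk
from sphnkit import fixtures
from sphnkit.provider_pipeline import (MartConfig, apply_mappings, deidentify,
                                       generate_datamart, pseudonymize,
                                       to_instances, inject_violations)
from sphnkit.terminology_rdf import code_iri, convert_terminology
from sphnkit.validation_query import hierarchy_query, render_report

dataset = fixtures.mini_dataset()            # 6 concepts, 9 properties
snomed = convert_terminology(fixtures.toy_snomed())
ucum = convert_terminology(fixtures.toy_ucum())

schema = sk.compile_schema(dataset, [snomed, ucum])
print("schema:", sk.schema_stats(schema))

shapes = sk.generate_shapes(schema, [snomed, ucum])

mart = generate_datamart(MartConfig(n_patients=50), seed=42)
mart = deidentify(pseudonymize(mart, project_key="my-project-key"))
views, _ = apply_mappings(mart, fixtures.default_mapping(dataset.namespace))
data = to_instances(views, schema, provider="demo-hospital", seed=42)

report = sk.validate(data, shapes, [schema, snomed, ucum])
patients = hierarchy_query(data,
                           sk.class_iri("Allergy Episode", dataset.namespace),
                           code_iri("SNOMED", fixtures.PULSE_VEGETABLE),
                           [snomed])
```

prints

```
schema: SchemaStats(classes=6, object_properties=6, datatype_properties=3,
                    named_individuals=3, restrictions=19)
Conforms: true
patients with a pulse-vegetable allergy: 38
```

The schema stats are the compiled inventory of the bundled six-concept
dictionary (19 restrictions = 14 cardinality + 5 allowed-value). The clean
`Conforms: true` is the keystone property: data produced by the pipeline
from the same schema always validates. The cohort count answers "which
patients had an allergic episode to any pulse vegetable" — patients allergic
to peanut, bean or lentil are found through the SNOMED-style hierarchy
without listing the leaf codes. Injecting a wrong unit makes the validator
name the exact node, path and allowed-value constraint:

```python
bad, manifest = inject_violations(data, shapes, {"wrong_unit": 2}, seed=42)
print(render_report(sk.validate(bad, shapes, [schema, snomed, ucum]), "text"))
```

```
Conforms: false
Violations: 2

Class https://biomedit.ch/rdf/sphn-ontology/sphn#OxygenSaturation:
  InConstraintComponent (1):
    .../OxygenSaturation/80d335cce47c sphn:hasUnit: value .../ucum/beats.min
    is not in the list of allowed values (1 allowed)
...
```

The same pipeline is available from the shell: `sphnkit compile`,
`convert-term`, `shapes`, `simulate`, `etl`, `validate` (exit 1 on
non-conformance), `query` and `stats`.

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
recomputes the full chain from scratch for the given seed — compile the
bundled dictionary, convert the toy terminologies, generate shapes,
synthesize a 100-patient mart, pseudonymise/deidentify/map it, build the
instance graph, validate it, and run the hierarchy and statistics queries —
logging a one-line summary to stderr and writing the JSON result object to
`--out`.
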