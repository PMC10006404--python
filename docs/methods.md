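# Methods

This note records the modelling choices behind sphnkit, what the bundled
synthetic world does and does not exercise, and the numerical/encoding
decisions a maintainer would otherwise have to reverse-engineer.

## The compilation model

The input is a data dictionary: concepts with typed composedOf properties.
The compiler maps it onto OWL with the conventions used by the SPHN
framework:

* **Classes** are Pascal-cased concept labels under a single namespace with
  `#` separator. The schema version lives only in the ontology header's
  version IRI (`<ns>/<year>/<index>`), never in class IRIs, so element IRIs
  stay stable across releases.
* **Properties** are `has`-prefixed camel case, idempotently (a label
  already starting with `has` followed by an upper-case letter is kept).
  Label-to-IRI normalisation strips characters outside `[A-Za-z0-9 ]` and
  rejects empty results and leading digits; two labels mapping to one IRI
  are a compile error, as is one property name used as both an object and a
  datatype property.
* **Ranges.** `rdfs:range` is emitted only when (a) the property is
  concept-valued and all its uses agree on one target class, or (b) it is a
  datatype property (quantitative → `xsd:double`, temporal →
  `xsd:dateTime`, string → `xsd:string` — the minimal set covering numeric
  measurements, timestamps and free text). Code- and value-set-valued
  properties get no range; their constraints are per using class.
  `rdfs:domain` is never emitted: properties are reused across concepts and
  multiple domain triples would mean their intersection under RDFS
  semantics, which is not the intended reading.
* **Restrictions.** One anonymous `owl:Restriction` per property row
  carries `owl:minCardinality` (only when > 0) and `owl:maxCardinality`
  (omitted when unbounded); `min 0, max unbounded` produces no restriction
  at all. Allowed values are a second restriction: `owl:hasValue` for a
  single value, `owl:allValuesFrom [owl:oneOf (…)]` for an explicit list,
  and `owl:allValuesFrom <root>` for descendants-of bindings. The last form
  is deliberately *symbolic*: since terminology codes are classes, "all
  values from the root class" denotes exactly the descendant set, and the
  concrete member list is resolved against whichever terminology release is
  supplied downstream. Expanding at compile time would freeze one
  terminology version into the schema.
* **Meaning bindings** produce one `owl:equivalentClass` axiom per bound
  code. When a concept is bound to several codes the axioms are
  independent (no intersection class); multiple equivalences to distinct
  external codes are taken as multi-axis annotation, not as a logical
  conjunction.
* **Value sets** contribute `owl:NamedIndividual`s with IRIs
  `<ns>#SetName-MemberLabel`. The set itself is a naming scope only; it is
  not declared as a class, so the class inventory counts concepts exactly.

## Shape generation and validation

One open node shape per schema class (`sh:closed` is never asserted —
project extensions must not be flagged). Property shapes merge, per
(class, property), the cardinality and value restrictions plus the
property-level range information: `sh:minCount`/`sh:maxCount`, `sh:class`
for schema-class ranges, `sh:datatype` for datatype ranges, `sh:in` for
allowed values. Descendant bindings are expanded to explicit `sh:in` lists
through the subclass closure at generation time, so validation needs no
SPARQL-based shapes and no reasoning engine. A restriction referencing a
code absent from the supplied terminologies aborts generation, naming the
code.

The validator implements exactly this constraint subset with standard SHACL
semantics over data ∪ background (schema + terminologies). RDFS entailment
(subclass transitivity, type propagation) is materialised before focus-node
selection rather than enabled store-side; materialisation gives identical
results on any engine and makes shapes targeting superclasses work through
inherited `rdf:type`. Inherited properties are therefore handled by
subclass-materialised typing, not by pushing constraints down onto
subclasses — a divergence risk against other SHACL toolchains that is
documented here on purpose. Violations are ordered by (focus IRI, path,
constraint kind) so reports are diffable.

## The synthetic world

The bundled dictionary has six concepts — Heart Rate, Oxygen Saturation,
Allergy Episode, Quantity, Unit, Subject Pseudo Identifier — nine distinct
properties and one three-member value set (allergy severity). Two published
worked examples pin its shape:

* the *instantiation pattern*: a heart-rate instance links a Quantity node
  that carries the numeric value (`hasValue`) and the UCUM unit code
  (`hasUnit`), plus the patient link (`hasSubjectPseudoIdentifier`);
* the *unit restriction*: Oxygen Saturation constrains `hasUnit` to the
  single UCUM "percent" code via `owl:hasValue`.

These two pull in opposite directions (unit on the shared Quantity vs unit
restricted per measurement class). Resolution: code-valued unit properties
attach to the class that declares them. Quantity declares a general unit
binding (beats/min, %), so heart-rate quantities carry their unit as in the
instantiation pattern; Oxygen Saturation declares its own percent-only unit
property, so the restriction and its SHACL rejection live on the
measurement class as in the published restriction example. Consequence: a
heart-rate Quantity annotated "percent" would pass — per-measurement unit
policing exists only where a concept declares its own unit binding. This is
a fixture-modelling limitation, not a validator limitation.

The toy terminologies are hand-made miniatures (12 SNOMED-style codes, 5
UCUM tokens). A few real code numbers (Pulse Vegetable 227313005, peanut
256349002, heart rate 364075005, SpO2 LOINC 59408-5) are reused so examples
read naturally; the hierarchy around them is invented. UCUM tokens are
transliterated to URL-safe local names (`%` → `percent`, `/` → `.`,
brackets dropped), applied identically when minting schema restrictions and
instance data.

The data mart generator emulates a small ward extract: per patient, a fixed
number of records per concept (3 heart rates, 2 oxygen saturations, 1
allergy episode by default), heart rate ~ N(75, 12) clipped to 40–180
beats/min, SpO2 ~ N(97, 1.5) capped at 100 %, substances/reactions/
severities drawn uniformly from the local code lists, timestamps uniform
over 2022. Fixed per-patient counts make record-count assertions exact;
everything is driven by one `numpy` generator per seed, so a (config, seed)
pair reproduces the mart byte for byte. What the generator does **not**
emulate: missing values, free-text noise, coding errors, longitudinal
structure, correlated vitals, or realistic prevalences — a green end-to-end
test therefore establishes pipeline and constraint correctness, not
robustness to messy hospital data (the violation injector covers the
structured error classes only).

## Pipeline encodings

* **Pseudocodes** are `HMAC-SHA256(project_key, identifier)` truncated to
  16 hex characters. Determinism per key preserves cross-table joins;
  distinct keys give disjoint mappings except with negligible collision
  probability (~10⁻¹⁹ per pair at 64 bits); the key is never serialised.
* **Deidentification rules** are a registry keyed by rule id
  (`year_only`: date → 4-digit year; `band`: integer age → width-5 band,
  capped at "90+"), configurable via YAML from the CLI. Both rules detect
  already-generalised values, making re-application a no-op (idempotence is
  tested).
* **Mapping tables** carry both structural rows (`local_value='*'`:
  table → concept, column → property path such as `quantity.value`) and
  value rows (local code → target IRI). Declared-but-unmapped values are
  collected into a rejection report and their rows excluded from the views;
  nothing unmapped ever reaches RDF.
* **Instance IRIs** are
  `<…/sphn-resource>/<provider>/<Concept>/<sha256(provider|concept|rowkey|seed)[:12]>`;
  patient nodes are keyed by pseudocode, one node per patient per provider
  release (chosen over one node per concept instance; the alternative is
  defensible but fragments patient-centric queries). Dotted view columns
  materialise one intermediate node per (row, path head), typed with the
  head property's range class, so `quantity.value` and `quantity.unit`
  land on the same Quantity node.

## Serialisation

Canonical Turtle: sorted `@prefix` lines for the prefixes actually used,
then one triple per line, lexicographically sorted; blank nodes are
renumbered from a content signature (recursive outgoing structure plus
incoming (subject, predicate) context), which is a perfect canonical key
for the tree-shaped blank nodes this toolkit produces (restrictions, RDF
lists, property shapes). Identical triple sets and prefix bindings thus
give identical bytes regardless of construction order. The bundled parser
reads this statement-per-line subset (plus `a` and `@prefix`) — it is a
round-trip parser for the toolkit's own canonical output and hand-written
fixtures, not a general Turtle parser. The secondary `owl-xml` format is a
deterministic RDF/XML encoding with the same round-trip guarantee.

## Known limitations

* SNOMED role relationships (anything beyond is-a) are not modelled; only
  subclass hierarchies are converted, multi-parent DAGs allowed, cycles
  rejected.
* OWL-DL consistency checking and reasoning beyond the two RDFS rules are
  out of scope; `owl:oneOf` lists and `owl:allValuesFrom` roots are read
  structurally, not semantically.
* The validator covers the constraint components its own generator emits;
  it is not a general SHACL engine.
* Desk scale only: graphs of ~10⁴ triples validate in well under a second,
  but nothing here is tuned for billion-triple stores.
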