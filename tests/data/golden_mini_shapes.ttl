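@prefix dcterms: <http://purl.org/dc/terms/> .
@prefix owl: <http://www.w3.org/2002/07/owl#> .
@prefix rdf: <http://www.w3.org/1999/02/22-rdf-syntax-ns#> .
@prefix sh: <http://www.w3.org/ns/shacl#> .
@prefix sphn: <https://biomedit.ch/rdf/sphn-ontology/sphn#> .
@prefix xsd: <http://www.w3.org/2001/XMLSchema#> .

<https://biomedit.ch/rdf/sphn-ontology/sphn/shapes> a owl:Ontology .
<https://biomedit.ch/rdf/sphn-ontology/sphn/shapes> dcterms:conformsTo <https://biomedit.ch/rdf/sphn-ontology/sphn/2022/2> .
_:b0 rdf:first <http://snomed.info/id/102263004> .
_:b0 rdf:rest _:b1 .
_:b1 rdf:first <http://snomed.info/id/227313005> .
_:b1 rdf:rest _:b2 .
_:b10 rdf:first sphn:AllergySeverity-Severe .
_:b10 rdf:rest rdf:nil .
_:b11 rdf:first <https://biomedit.ch/rdf/sphn-resource/ucum/beats.min> .
_:b11 rdf:rest _:b12 .
_:b12 rdf:first <https://biomedit.ch/rdf/sphn-resource/ucum/percent> .
_:b12 rdf:rest rdf:nil .
_:b13 rdf:first <https://biomedit.ch/rdf/sphn-resource/ucum/percent> .
_:b13 rdf:rest rdf:nil .
_:b14 sh:class sphn:Quantity .
_:b14 sh:maxCount "1"^^xsd:integer .
_:b14 sh:minCount "1"^^xsd:integer .
_:b14 sh:path sphn:hasQuantity .
_:b15 sh:class sphn:Quantity .
_:b15 sh:maxCount "1"^^xsd:integer .
_:b15 sh:minCount "1"^^xsd:integer .
_:b15 sh:path sphn:hasQuantity .
_:b16 sh:class sphn:SubjectPseudoIdentifier .
_:b16 sh:maxCount "1"^^xsd:integer .
_:b16 sh:minCount "1"^^xsd:integer .
_:b16 sh:path sphn:hasSubjectPseudoIdentifier .
_:b17 sh:class sphn:SubjectPseudoIdentifier .
_:b17 sh:maxCount "1"^^xsd:integer .
_:b17 sh:minCount "1"^^xsd:integer .
_:b17 sh:path sphn:hasSubjectPseudoIdentifier .
_:b18 sh:class sphn:SubjectPseudoIdentifier .
_:b18 sh:maxCount "1"^^xsd:integer .
_:b18 sh:minCount "1"^^xsd:integer .
_:b18 sh:path sphn:hasSubjectPseudoIdentifier .
_:b19 sh:datatype xsd:dateTime .
_:b19 sh:maxCount "1"^^xsd:integer .
_:b19 sh:path sphn:hasDatetime .
_:b2 rdf:first <http://snomed.info/id/227314004> .
_:b2 rdf:rest _:b3 .
_:b20 sh:datatype xsd:dateTime .
_:b20 sh:maxCount "1"^^xsd:integer .
_:b20 sh:path sphn:hasDatetime .
_:b21 sh:datatype xsd:double .
_:b21 sh:maxCount "1"^^xsd:integer .
_:b21 sh:minCount "1"^^xsd:integer .
_:b21 sh:path sphn:hasValue .
_:b22 sh:datatype xsd:string .
_:b22 sh:maxCount "1"^^xsd:integer .
_:b22 sh:path sphn:hasComment .
_:b23 sh:in _:b0 .
_:b23 sh:maxCount "1"^^xsd:integer .
_:b23 sh:minCount "1"^^xsd:integer .
_:b23 sh:path sphn:hasSubstance .
_:b24 sh:in _:b5 .
_:b24 sh:maxCount "1"^^xsd:integer .
_:b24 sh:path sphn:hasReactionType .
_:b25 sh:in _:b8 .
_:b25 sh:maxCount "1"^^xsd:integer .
_:b25 sh:path sphn:hasSeverity .
_:b26 sh:in _:b11 .
_:b26 sh:maxCount "1"^^xsd:integer .
_:b26 sh:path sphn:hasUnit .
_:b27 sh:in _:b13 .
_:b27 sh:maxCount "1"^^xsd:integer .
_:b27 sh:minCount "1"^^xsd:integer .
_:b27 sh:path sphn:hasUnit .
_:b3 rdf:first <http://snomed.info/id/227380006> .
_:b3 rdf:rest _:b4 .
_:b4 rdf:first <http://snomed.info/id/256349002> .
_:b4 rdf:rest _:b7 .
_:b5 rdf:first <http://snomed.info/id/271807003> .
_:b5 rdf:rest _:b6 .
_:b6 rdf:first <http://snomed.info/id/39579001> .
_:b6 rdf:rest rdf:nil .
_:b7 rdf:first <http://snomed.info/id/762766007> .
_:b7 rdf:rest rdf:nil .
_:b8 rdf:first sphn:AllergySeverity-Mild .
_:b8 rdf:rest _:b9 .
_:b9 rdf:first sphn:AllergySeverity-Moderate .
_:b9 rdf:rest _:b10 .
sphn:AllergyEpisodeShape a sh:NodeShape .
sphn:AllergyEpisodeShape sh:property _:b16 .
sphn:AllergyEpisodeShape sh:property _:b22 .
sphn:AllergyEpisodeShape sh:property _:b23 .
sphn:AllergyEpisodeShape sh:property _:b24 .
sphn:AllergyEpisodeShape sh:property _:b25 .
sphn:AllergyEpisodeShape sh:targetClass sphn:AllergyEpisode .
sphn:HeartRateShape a sh:NodeShape .
sphn:HeartRateShape sh:property _:b14 .
sphn:HeartRateShape sh:property _:b17 .
sphn:HeartRateShape sh:property _:b19 .
sphn:HeartRateShape sh:targetClass sphn:HeartRate .
sphn:OxygenSaturationShape a sh:NodeShape .
sphn:OxygenSaturationShape sh:property _:b15 .
sphn:OxygenSaturationShape sh:property _:b18 .
sphn:OxygenSaturationShape sh:property _:b20 .
sphn:OxygenSaturationShape sh:property _:b27 .
sphn:OxygenSaturationShape sh:targetClass sphn:OxygenSaturation .
sphn:QuantityShape a sh:NodeShape .
sphn:QuantityShape sh:property _:b21 .
sphn:QuantityShape sh:property _:b26 .
sphn:QuantityShape sh:targetClass sphn:Quantity .
sphn:SubjectPseudoIdentifierShape a sh:NodeShape .
sphn:SubjectPseudoIdentifierShape sh:targetClass sphn:SubjectPseudoIdentifier .
sphn:UnitShape a sh:NodeShape .
sphn:UnitShape sh:targetClass sphn:Unit .
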