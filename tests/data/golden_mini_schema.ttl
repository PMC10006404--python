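@prefix dcterms: <http://purl.org/dc/terms/> .
@prefix owl: <http://www.w3.org/2002/07/owl#> .
@prefix rdf: <http://www.w3.org/1999/02/22-rdf-syntax-ns#> .
@prefix rdfs: <http://www.w3.org/2000/01/rdf-schema#> .
@prefix sphn: <https://biomedit.ch/rdf/sphn-ontology/sphn#> .
@prefix xsd: <http://www.w3.org/2001/XMLSchema#> .

<https://biomedit.ch/rdf/sphn-ontology/sphn> a owl:Ontology .
<https://biomedit.ch/rdf/sphn-ontology/sphn> dcterms:license "CC BY 4.0" .
<https://biomedit.ch/rdf/sphn-ontology/sphn> owl:imports <http://snomed.info/sct/900000000000207008/2022-02-07> .
<https://biomedit.ch/rdf/sphn-ontology/sphn> owl:imports <https://biomedit.ch/rdf/sphn-resource/ucum/2021.1> .
<https://biomedit.ch/rdf/sphn-ontology/sphn> owl:versionIRI <https://biomedit.ch/rdf/sphn-ontology/sphn/2022/2> .
_:b0 rdf:first <http://snomed.info/id/271807003> .
_:b0 rdf:rest _:b1 .
_:b1 rdf:first <http://snomed.info/id/39579001> .
_:b1 rdf:rest rdf:nil .
_:b10 a owl:Restriction .
_:b10 owl:allValuesFrom _:b7 .
_:b10 owl:onProperty sphn:hasReactionType .
_:b11 a owl:Restriction .
_:b11 owl:allValuesFrom _:b8 .
_:b11 owl:onProperty sphn:hasSeverity .
_:b12 a owl:Restriction .
_:b12 owl:allValuesFrom _:b9 .
_:b12 owl:onProperty sphn:hasUnit .
_:b13 a owl:Restriction .
_:b13 owl:allValuesFrom <http://snomed.info/id/762766007> .
_:b13 owl:onProperty sphn:hasSubstance .
_:b14 a owl:Restriction .
_:b14 owl:hasValue <https://biomedit.ch/rdf/sphn-resource/ucum/percent> .
_:b14 owl:onProperty sphn:hasUnit .
_:b15 a owl:Restriction .
_:b15 owl:maxCardinality "1"^^xsd:nonNegativeInteger .
_:b15 owl:minCardinality "1"^^xsd:nonNegativeInteger .
_:b15 owl:onProperty sphn:hasQuantity .
_:b16 a owl:Restriction .
_:b16 owl:maxCardinality "1"^^xsd:nonNegativeInteger .
_:b16 owl:minCardinality "1"^^xsd:nonNegativeInteger .
_:b16 owl:onProperty sphn:hasQuantity .
_:b17 a owl:Restriction .
_:b17 owl:maxCardinality "1"^^xsd:nonNegativeInteger .
_:b17 owl:minCardinality "1"^^xsd:nonNegativeInteger .
_:b17 owl:onProperty sphn:hasSubjectPseudoIdentifier .
_:b18 a owl:Restriction .
_:b18 owl:maxCardinality "1"^^xsd:nonNegativeInteger .
_:b18 owl:minCardinality "1"^^xsd:nonNegativeInteger .
_:b18 owl:onProperty sphn:hasSubjectPseudoIdentifier .
_:b19 a owl:Restriction .
_:b19 owl:maxCardinality "1"^^xsd:nonNegativeInteger .
_:b19 owl:minCardinality "1"^^xsd:nonNegativeInteger .
_:b19 owl:onProperty sphn:hasSubjectPseudoIdentifier .
_:b2 rdf:first sphn:AllergySeverity-Mild .
_:b2 rdf:rest _:b3 .
_:b20 a owl:Restriction .
_:b20 owl:maxCardinality "1"^^xsd:nonNegativeInteger .
_:b20 owl:minCardinality "1"^^xsd:nonNegativeInteger .
_:b20 owl:onProperty sphn:hasSubstance .
_:b21 a owl:Restriction .
_:b21 owl:maxCardinality "1"^^xsd:nonNegativeInteger .
_:b21 owl:minCardinality "1"^^xsd:nonNegativeInteger .
_:b21 owl:onProperty sphn:hasUnit .
_:b22 a owl:Restriction .
_:b22 owl:maxCardinality "1"^^xsd:nonNegativeInteger .
_:b22 owl:minCardinality "1"^^xsd:nonNegativeInteger .
_:b22 owl:onProperty sphn:hasValue .
_:b23 a owl:Restriction .
_:b23 owl:maxCardinality "1"^^xsd:nonNegativeInteger .
_:b23 owl:onProperty sphn:hasComment .
_:b24 a owl:Restriction .
_:b24 owl:maxCardinality "1"^^xsd:nonNegativeInteger .
_:b24 owl:onProperty sphn:hasDatetime .
_:b25 a owl:Restriction .
_:b25 owl:maxCardinality "1"^^xsd:nonNegativeInteger .
_:b25 owl:onProperty sphn:hasDatetime .
_:b26 a owl:Restriction .
_:b26 owl:maxCardinality "1"^^xsd:nonNegativeInteger .
_:b26 owl:onProperty sphn:hasReactionType .
_:b27 a owl:Restriction .
_:b27 owl:maxCardinality "1"^^xsd:nonNegativeInteger .
_:b27 owl:onProperty sphn:hasSeverity .
_:b28 a owl:Restriction .
_:b28 owl:maxCardinality "1"^^xsd:nonNegativeInteger .
_:b28 owl:onProperty sphn:hasUnit .
_:b3 rdf:first sphn:AllergySeverity-Moderate .
_:b3 rdf:rest _:b4 .
_:b4 rdf:first sphn:AllergySeverity-Severe .
_:b4 rdf:rest rdf:nil .
_:b5 rdf:first <https://biomedit.ch/rdf/sphn-resource/ucum/beats.min> .
_:b5 rdf:rest _:b6 .
_:b6 rdf:first <https://biomedit.ch/rdf/sphn-resource/ucum/percent> .
_:b6 rdf:rest rdf:nil .
_:b7 a owl:Class .
_:b7 owl:oneOf _:b0 .
_:b8 a owl:Class .
_:b8 owl:oneOf _:b2 .
_:b9 a owl:Class .
_:b9 owl:oneOf _:b5 .
sphn:AllergyEpisode a owl:Class .
sphn:AllergyEpisode owl:equivalentClass <http://snomed.info/id/609328004> .
sphn:AllergyEpisode rdfs:comment "An episode of allergic reaction of a patient to a substance" .
sphn:AllergyEpisode rdfs:label "Allergy Episode" .
sphn:AllergyEpisode rdfs:subClassOf _:b10 .
sphn:AllergyEpisode rdfs:subClassOf _:b11 .
sphn:AllergyEpisode rdfs:subClassOf _:b13 .
sphn:AllergyEpisode rdfs:subClassOf _:b17 .
sphn:AllergyEpisode rdfs:subClassOf _:b20 .
sphn:AllergyEpisode rdfs:subClassOf _:b23 .
sphn:AllergyEpisode rdfs:subClassOf _:b26 .
sphn:AllergyEpisode rdfs:subClassOf _:b27 .
sphn:AllergySeverity-Mild a owl:NamedIndividual .
sphn:AllergySeverity-Mild rdfs:label "Mild" .
sphn:AllergySeverity-Moderate a owl:NamedIndividual .
sphn:AllergySeverity-Moderate rdfs:label "Moderate" .
sphn:AllergySeverity-Severe a owl:NamedIndividual .
sphn:AllergySeverity-Severe rdfs:label "Severe" .
sphn:HeartRate a owl:Class .
sphn:HeartRate owl:equivalentClass <http://snomed.info/id/364075005> .
sphn:HeartRate rdfs:comment "Frequency of heart contractions measured on a patient" .
sphn:HeartRate rdfs:label "Heart Rate" .
sphn:HeartRate rdfs:subClassOf _:b15 .
sphn:HeartRate rdfs:subClassOf _:b18 .
sphn:HeartRate rdfs:subClassOf _:b24 .
sphn:OxygenSaturation a owl:Class .
sphn:OxygenSaturation owl:equivalentClass <https://loinc.org/rdf/59408-5> .
sphn:OxygenSaturation rdfs:comment "Arterial oxygen saturation measured by pulse oximetry" .
sphn:OxygenSaturation rdfs:label "Oxygen Saturation" .
sphn:OxygenSaturation rdfs:subClassOf _:b14 .
sphn:OxygenSaturation rdfs:subClassOf _:b16 .
sphn:OxygenSaturation rdfs:subClassOf _:b19 .
sphn:OxygenSaturation rdfs:subClassOf _:b21 .
sphn:OxygenSaturation rdfs:subClassOf _:b25 .
sphn:Quantity a owl:Class .
sphn:Quantity rdfs:comment "A numerical value together with its unit" .
sphn:Quantity rdfs:label "Quantity" .
sphn:Quantity rdfs:subClassOf _:b12 .
sphn:Quantity rdfs:subClassOf _:b22 .
sphn:Quantity rdfs:subClassOf _:b28 .
sphn:SubjectPseudoIdentifier a owl:Class .
sphn:SubjectPseudoIdentifier rdfs:comment "Project-specific pseudonymised identifier of a patient" .
sphn:SubjectPseudoIdentifier rdfs:label "Subject Pseudo Identifier" .
sphn:Unit a owl:Class .
sphn:Unit rdfs:comment "Unit of measure following the UCUM notation" .
sphn:Unit rdfs:label "Unit" .
sphn:hasComment a owl:DatatypeProperty .
sphn:hasComment rdfs:label "comment" .
sphn:hasComment rdfs:range xsd:string .
sphn:hasDatetime a owl:DatatypeProperty .
sphn:hasDatetime rdfs:label "datetime" .
sphn:hasDatetime rdfs:range xsd:dateTime .
sphn:hasQuantity a owl:ObjectProperty .
sphn:hasQuantity rdfs:label "quantity" .
sphn:hasQuantity rdfs:range sphn:Quantity .
sphn:hasReactionType a owl:ObjectProperty .
sphn:hasReactionType rdfs:label "reaction type" .
sphn:hasSeverity a owl:ObjectProperty .
sphn:hasSeverity rdfs:label "severity" .
sphn:hasSubjectPseudoIdentifier a owl:ObjectProperty .
sphn:hasSubjectPseudoIdentifier rdfs:label "subject pseudo identifier" .
sphn:hasSubjectPseudoIdentifier rdfs:range sphn:SubjectPseudoIdentifier .
sphn:hasSubstance a owl:ObjectProperty .
sphn:hasSubstance rdfs:label "substance" .
sphn:hasUnit a owl:ObjectProperty .
sphn:hasUnit rdfs:label "unit" .
sphn:hasValue a owl:DatatypeProperty .
sphn:hasValue rdfs:label "value" .
sphn:hasValue rdfs:range xsd:double .
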