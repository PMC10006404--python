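concept_name,concept_description,parent_concept,meaning_binding,property_name,property_description,value_kind,target,min_card,max_card
Subject Pseudo Identifier,Project-specific pseudonymised identifier of a patient,,,,,,,,
Unit,Unit of measure following the UCUM notation,,,,,,,,
Quantity,A numerical value together with its unit,,,value,The numerical value,quantitative,,1,1
Quantity,A numerical value together with its unit,,,unit,Unit of the value,code,UCUM:exact:beats/min|%,0,1
Heart Rate,Frequency of heart contractions measured on a patient,,SNOMED:364075005,subject pseudo identifier,Patient the measurement belongs to,concept,Subject Pseudo Identifier,1,1
Heart Rate,Frequency of heart contractions measured on a patient,,SNOMED:364075005,quantity,Measured value and unit,concept,Quantity,1,1
Heart Rate,Frequency of heart contractions measured on a patient,,SNOMED:364075005,datetime,Time of the measurement,temporal,,0,1
Oxygen Saturation,Arterial oxygen saturation measured by pulse oximetry,,LOINC:59408-5,subject pseudo identifier,Patient the measurement belongs to,concept,Subject Pseudo Identifier,1,1
Oxygen Saturation,Arterial oxygen saturation measured by pulse oximetry,,LOINC:59408-5,quantity,Measured value,concept,Quantity,1,1
Oxygen Saturation,Arterial oxygen saturation measured by pulse oximetry,,LOINC:59408-5,unit,Unit code of the measurement,code,UCUM:exact:%,1,1
Oxygen Saturation,Arterial oxygen saturation measured by pulse oximetry,,LOINC:59408-5,datetime,Time of the measurement,temporal,,0,1
Allergy Episode,An episode of allergic reaction of a patient to a substance,,SNOMED:609328004,subject pseudo identifier,Patient who had the reaction,concept,Subject Pseudo Identifier,1,1
Allergy Episode,An episode of allergic reaction of a patient to a substance,,SNOMED:609328004,substance,Substance that caused the reaction,code,SNOMED:descendants_of:762766007,1,1
Allergy Episode,An episode of allergic reaction of a patient to a substance,,SNOMED:609328004,reaction type,Type of allergic reaction observed,code,SNOMED:exact:271807003|39579001,0,1
Allergy Episode,An episode of allergic reaction of a patient to a substance,,SNOMED:609328004,severity,Graded severity of the episode,valueset,Allergy Severity:Mild|Moderate|Severe,0,1
Allergy Episode,An episode of allergic reaction of a patient to a substance,,SNOMED:609328004,comment,Free-text remark,string,,0,1
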