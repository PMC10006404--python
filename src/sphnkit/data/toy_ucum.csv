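code,label,parent_code
beats/min,beats per minute,
%,percent,
mm[Hg],millimetres of mercury,
Cel,degree Celsius,
kg,kilogram,
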