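code,label,parent_code
105590001,Substance,
762766007,Edible substance,105590001
227313005,Pulse Vegetable,762766007
256349002,Peanut,227313005
227380006,Bean,227313005
227314004,Lentil,227313005
102263004,Eggs,762766007
404684003,Clinical finding,
609328004,Allergic disposition,404684003
271807003,Eruption of skin,404684003
39579001,Anaphylaxis,404684003
364075005,Heart rate,404684003
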