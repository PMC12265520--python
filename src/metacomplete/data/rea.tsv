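pattern_type	pattern	canonical_label
tag	race
tag	ethnicity
tag	ancestry
tag	race/ethnicity
tag	race / ethnicity
tag	ethnic group
tag	ethnic background
tag	population
tag	ancestry group
value	^(caucasian|white|european([ -]american)?|non-?hispanic white)$	European
value	^(african([ -]american)?|black|afro-?american)$	African
value	^(asian|east asian|chinese|japanese|korean|han chinese)$	East Asian
value	^(south asian|indian|pakistani|bangladeshi)$	South Asian
value	^(hispanic([ /]?latino)?|latino|latina|latin american)$	Hispanic or Latin American
value	^(native american|american indian|indigenous american)$	Native American
value	^(pacific islander|native hawaiian)$	Oceanian
value	^(middle eastern|arab)$	Greater Middle Eastern
value	^(mixed|admixed|multi-?racial|multi-?ethnic)$	Admixed
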