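pattern_type	pattern	canonical_label
tag	sex
tag	gender
tag	sex/gender
tag	gender/sex
tag	sex (gender)
value	^f(emale)?s?$	female
value	^wom[ae]n$	female
value	^m(ale)?s?$	male
value	^m[ae]n$	male
value	^(mixed|pooled|both|mixed sex(es)?|male and female|female and male)$	mixed
value	^(intersex|hermaphrodite|other)$	other
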