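pattern_type	pattern	canonical_label
tag	strain
tag	strain background
tag	strain/background
tag	genetic background
tag	background
tag	background strain
tag	cultivar
tag	breed
tag	ecotype
tag	line
tag	mouse strain
tag	rat strain
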