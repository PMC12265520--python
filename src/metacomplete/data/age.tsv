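pattern_type	pattern	canonical_label
tag	age
tag	age (yrs)
tag	age (years)
tag	age_years
tag	age in years
tag	age (y)
tag	age (weeks)
tag	age (days)
tag	age at diagnosis
tag	age at collection
tag	age at death
tag	developmental stage
tag	development stage
tag	dev stage
tag	gestational age
tag	embryonic stage
tag	passage
tag	passage number
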