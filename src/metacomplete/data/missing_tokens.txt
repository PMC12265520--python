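# Sentinel strings that denote absent information. Matched case-insensitively
# after stripping surrounding punctuation; they must never count as data.
na
n/a
n.a.
nan
unknown
unkown
unk
not available
not collected
not applicable
not specified
not determined
not provided
not reported
none
missing
no data
null
--
-
?
.
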