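"""Detect and harmonize the six phenotypic attributes for single samples.

Shows how free-text characteristics map to canonical labels, how sentinel
strings ("n/a") are refused, and how species decides which of the two
specific attributes (strain vs race/ethnicity/ancestry) applies.
"""

from metacomplete import annotate_sample
from metacomplete.records import CharacteristicField, Origin, SampleRecord


def sample(organism, chars):
    fields = [CharacteristicField("", organism, Origin.organism_element)]
    fields += [
        CharacteristicField(t, v, Origin.characteristics_element) for t, v in chars
    ]
    return SampleRecord(
        accession="GSM1", organism_raw=organism, characteristics=fields
    )


human = sample(
    "Homo sapiens",
    [("Sex", "F"), ("age", "45-50"), ("tissue", "whole blood"),
     ("ethnicity", "Caucasian"), ("strain", "irrelevant for humans")],
)
mouse = sample(
    "mus musculus",
    [("gender", "Male"), ("age", "6 weeks"), ("strain", "C57BL/6J"),
     ("tissue", "n/a")],
)

for name, s in [("human", human), ("mouse", mouse)]:
    print(f"--- {name} sample ---")
    profile = annotate_sample(s)
    for attr, det in profile.detections.items():
        print(f"  {attr:9s} {det.status.value:15s} {det.normalized_value}")
# The human sample's strain is not_applicable despite the tag being present;
# the mouse's tissue is missing because "n/a" is a sentinel, not data.
# "45-50" parses to an age range; "6 weeks" to a point with unit week.
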