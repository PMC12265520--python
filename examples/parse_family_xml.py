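"""Parse a MINiML family record into the two per-study tables.

Builds a small bundled fixture study, parses it, and prints the series- and
sample-level tables. The `characteristics` column flattens the sample's
tagged free-text entries to `tag=value` pairs.
"""

from metacomplete import parse_miniml
from metacomplete.miniml_io import extract_sample_table, extract_series_table
from metacomplete.synth import make_fixture

doc = parse_miniml(make_fixture("clean_human").encode())

print("series table:")
print(extract_series_table([doc]).to_string(index=False), "\n")
print("sample table:")
print(
    extract_sample_table([doc])[
        ["series_accession", "accession", "organism_raw", "characteristics"]
    ].to_string(index=False)
)
# Each row is one (series, sample) pair; the characteristics column shows the
# raw tagged entries the phenotype detectors will harmonize.
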