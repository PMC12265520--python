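# metacomplete

Audit the completeness of phenotypic metadata accompanying omics studies in
the Gene Expression Omnibus (GEO).

Public omics data is only reusable when the samples are described: without
knowing a sample's organism, tissue, sex, age, strain or ancestry, secondary
analyses cannot stratify, match or de-confound. `metacomplete` measures how
much of that information is actually shared. It parses GEO's machine-readable
MINiML family records, detects and harmonizes six core phenotypic attributes
per sample — organism, tissue/cell type, strain, sex, age, and
race/ethnicity/ancestry (REA) — and scores availability at two levels and
from two sources:

* **sample-level** — a value attributable to each individual sample, either
  stated per sample or implied with certainty by a uniform claim ("all
  samples are female");
* **experiment-level** — summarized information ("12 males and 8 females")
  that cannot be assigned to individual samples;
* **sources** — the repository record itself versus the textual content of
  the publication (ingested as a manually curated table).

Five attributes apply to any given sample: the four common phenotypes
(organism, tissue, sex, age) plus REA for human samples or strain for
non-human samples. The core statistics are:

* **pooled availability** — the fraction of applicable sample × attribute
  cells that carry non-missing information,
  `A = |{cells: level ≠ missing}| / |applicable cells|`;
* **study bracket** — 20% per phenotype a study shares for at least one
  sample, giving a 20/40/60/80/100% completeness class;
* **source categories** — each cell classified as available in `both`
  sources, `repo_only`, `text_only`, or `neither`, plus a per-study
  consistency verdict comparing pooled availability across sources.

Sentinel strings ("n/a", "not collected", "--", …) never count as
information; availability measures presence, not quality, so an age of
"adult" counts even though it is not a number.

A synthetic MINiML generator with ground-truth manifests makes every stage
testable offline, and a mockable fetcher retrieves real family archives from
the NCBI mirror when a network is available.

## Worked example

```sh
python examples/audit_synthetic_corpus.py
```

```text
studies: 60, samples: 478
overall availability (either source): 69.6%
per-attribute availability (repository):
  organism  100.0%
  tissue     88.7%
  strain     71.2%
  sex        46.9%
  age        48.1%
  rea        25.2%
bracket distribution (share of studies):
   40% of phenotypes:   8.3% of studies
   60% of phenotypes:  41.7% of studies
   80% of phenotypes:  40.0% of studies
  100% of phenotypes:  10.0% of studies
```

Reading the output: pooling every applicable sample–attribute cell, 69.6%
carry information in at least one source. Organism is universally present
(every MINiML sample carries an Organism element), ancestry is the rarest
attribute, and only 10% of studies share all five of their applicable
phenotypes. The other scripts in `examples/` show single-sample detection,
table extraction, and the repository-vs-publication comparison.

The same pipeline runs from the shell:

```sh
metacomplete simulate --out corpus --seed 42 --n-studies 60
metacomplete audit corpus/miniml --curation corpus/curation.tsv \
    --claims corpus/claims.tsv --out report
metacomplete report --summary report/summary.json
```

and `metacomplete fetch --accessions list.txt --dest archives/` downloads
real family archives (tranche layout `GSE123nnn/GSE123456/miniml/...`, with
retry and resumable caching) for auditing live GEO content.

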