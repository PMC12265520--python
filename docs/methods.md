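# Methods

## The measurement model

`metacomplete` treats metadata completeness as a presence/absence measurement
over a four-axis grid: study × sample × attribute × source. Six phenotypic
attributes are audited — organism, tissue/cell type, strain, sex, age, and
race/ethnicity/ancestry (REA) — of which five apply to any one sample: the
four common attributes plus REA for human samples or strain for non-human
samples. Applicability depends only on the detected organism ("human" means
the canonical organism label is *Homo sapiens*), never on field content, so
a mouse sample with a `race` tag still has REA marked `not_applicable`.

Each applicable cell carries one availability level:

* `sample_level` — the value is attributable to the individual sample,
  either stated per sample or implied by a uniform claim asserted for all
  samples of the study;
* `experiment_level` — only summarized information exists for the study;
* `missing` — nothing usable.

Both non-missing levels count as "available" in the headline statistics; the
share of availability that is experiment-level only is reported separately,
because experiment-level metadata does not support per-sample reuse.

## Detection and harmonization

Detection is rule-based and auditable. For each attribute, match precedence
is: characteristic *tag* synonym (e.g. `sex`, `gender`) → *value* pattern on
untagged entries (e.g. "Sex: F" inside a value) → for tissue, the Source
element and finally an anatomy-vocabulary scan of remaining free text. The
first match wins; conflicting later matches are flagged but do not change
the verdict, keeping detection deterministic. Every `available` verdict
carries the provenance field that produced it.

Values are harmonized against editable TSV rule tables bundled with the
package — miniature subsets in the spirit of NCBI Taxonomy (organism
binomials), Uberon/Cell Ontology (anatomy terms) and HANCESTRO (broad
ancestry categories). Unmatched organism/tissue/REA values pass through
verbatim with a `non_canonical` flag: an unrecognized term is still
information. A shared missing-token list ("n/a", "unknown", "not
collected", "--", …) is applied case-insensitively after punctuation
stripping; sentinel strings never count as data, because the audit measures
availability, not accuracy.

Age parsing covers points ("45"), ranges ("45-50"), bounds (">60", "65+"),
units in the value or the tag ("6 weeks", tag `age (yrs)`), embryonic days
("E14.5"), and falls back to a stage label for anything else non-missing
("adult") — presence, not parseability, decides availability.

Uniform claims are detected in series summary/design text only for
unambiguous "all samples are/were X" phrasings (sex and simple ages);
anything subtler must enter through explicit claim or curation tables, never
by silent inference.

## Statistics

Pooled availability is computed over applicable sample–attribute cells
(sample-weighted), the package default; an unweighted per-study view is
available through the study scores. A study "shares" a phenotype when it is
non-missing for at least one sample (a configurable coverage threshold
variant exists); its bracket is 20% per shared phenotype. The
publication-text source is compared cell-wise with the repository
(`both` / `repo_only` / `text_only` / `neither` partition the applicable
cells), and per-study consistency compares pooled availabilities as exact
rationals on the backing counts, so 1/3 equals 2/6. Temporal trends use the
series *release* year (public availability) and pool all studies released up
to each year; the final row therefore equals the dataset summary. Weighted
group availabilities (weights = applicable cell counts) reconstruct the
overall availability exactly — an invariant the tests enforce.

SuperSeries (detected via the series type string) are excluded from audits
by default because their samples duplicate those of their sub-series;
multi-channel samples are read from channel 1 only, with the channel count
recorded. A GSM appearing in two series is counted once per series.

## The synthetic generator

The generator emulates the statistical structure of a mixed GEO corpus: a
configurable fraction of human studies (default 0.6) with disease labels,
non-human studies drawn from five model organisms, 3–12 samples per study,
release years 2008–2024. Default per-attribute availability probabilities
are organism 1.0; tissue 0.99 (human) / 0.6 (non-human); sex 0.5; age 0.5;
REA 0.2; strain 0.8 — the prevalence regime the audit is designed around.
Availability is drawn once per (study, attribute); an available pair is
encoded as per-sample tags (weight 0.7), a uniform claim (0.15), or
summary-only text (0.15). Tags are drawn from the vocabulary synonym lists
and values from pools with known canonical forms, so the expected output of
the harmonizer is known by construction without running it.
Publication-text availability is drawn conditionally on the repository
(P(text|repo)=0.85, P(text|¬repo)=0.15, sample-level with probability 0.6
given text availability) and emitted as a curation table, mirroring how a
real text audit is produced by manual reading. A `messy_token_prob` knob
replaces individual values with sentinel strings whose ground truth is
`missing`. Randomness uses one seeded generator with a named substream per
study, so growing a corpus never perturbs existing studies, and generation
is byte-deterministic given the seed.

What the generator does **not** emulate: within-study heterogeneity of
availability (a study either tags all samples or none, apart from messy
tokens), misspelled or multilingual terms beyond the vocabulary, organism
mixtures within a series, supplementary-file-only metadata, and correlated
availability across attributes. Passing round-trip tests therefore
demonstrate that parsing, detection and scoring are exact inverses of the
generative encoding — not that the vocabularies would capture every
idiosyncratic real-world submission.

## Numerical and design choices

* Pooling convention: cell-pooled (sample-weighted) availability is the
  default because the headline statistics concern samples; per-study means
  are derivable from `study_scores`.
* Consistency uses exact rational equality on counts; floats are never
  compared for equality.
* "Mixed"/"pooled" sex counts as available — it is information about the
  sample. A non-missing value under a sex tag that matches no pattern
  (e.g. "2F, 1M") is treated as pooled information rather than discarded.
* The `either` source view takes the cell-wise best level
  (sample > experiment > missing); `not_applicable` is invariant across
  sources by construction and the comparison rejects grids that violate it.
* Empty characteristic tags are kept (some submitters put "Sex: F" in the
  value text); input is decoded as UTF-8 with replacement and normalized to
  NFC before matching.
* Fetching validates cached archives by a non-zero size plus a readable
  gzip header, and re-downloads on failure; transport is injected so tests
  and offline runs never touch the network.
* Problem sizes in the test suite and acceptance script (50-study round
  trips, 200-study binomial checks, 253-study acceptance corpus) keep full
  runs in the tens of seconds while leaving binomial standard errors small
  enough for 3-SE checks to be meaningful.

## Known limitations

The bundled vocabularies are deliberately small; on real GEO content they
will undercount attributes expressed through rare synonyms, and the
missing-token list cannot be exhaustive. Tag-synonym and sentinel lists are
the largest source of divergence from any published estimate of GEO
completeness. The publication-text side is never mined automatically — it
is consumed as a curated table — so text-side statistics are only as good as
the curation. Metadata *quality* (is the stated age correct?) is explicitly
out of scope.
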