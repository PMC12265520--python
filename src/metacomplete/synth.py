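"""Synthetic MINiML corpora with known ground truth.

The generator emulates the statistical structure the audit assumes: a corpus
of GEO-like series, each either human (with a disease label) or non-human
(with a model-organism label), whose per-attribute metadata availability is
drawn from configurable probabilities. Each available (study, attribute)
pair is encoded one of three ways:

* ``per_sample_tag`` — every sample carries a characteristic element whose
  tag is drawn from the vocabulary synonym list (ground truth:
  sample-level);
* ``uniform_claim`` — no per-sample tags; the series summary carries an
  "all samples are X" sentence (sex/age) and a uniform claim row is written
  to the claims table (ground truth: sample-level by inference);
* ``summary_only`` — no per-sample tags; the series summary carries a
  non-uniform sentence and a non-uniform claim row is written (ground
  truth: experiment-level).

``messy_token_prob`` replaces individual per-sample values with sentinel
strings ("n/a", …): those cells are *missing* in the ground truth, because a
sentinel is not information. Publication-text availability is drawn per
(study, attribute) conditionally on repository availability and emitted as a
curation table, mirroring how the text side of a real audit is produced by
manual reading.

Randomness comes from one seeded generator with a named substream per study,
so adding studies never perturbs earlier ones.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .completeness import Level, Source
from .records import ATTRIBUTES
from .source_compare import CURATION_COLUMNS, CurationRecord, write_curation_table

HUMAN = "Homo sapiens"
NONHUMAN_ORGANISMS = [
    "Mus musculus",
    "Parus major",
    "Glycine max",
    "Danio rerio",
    "Gallus gallus",
]
DISEASES = ["AD", "AML", "CVD", "IBD", "MS", "sepsis", "TB"]

MISSING_TOKENS = ["n/a", "NA", "unknown", "not collected", "--", "none", "missing"]

# (raw value, canonical label the harmonizer should produce)
SEX_POOL = [
    ("female", "female"),
    ("Female", "female"),
    ("F", "female"),
    ("male", "male"),
    ("Male", "male"),
    ("M", "male"),
]
TISSUE_POOL = [
    ("whole blood", "blood"),
    ("liver", "liver"),
    ("brain", "brain"),
    ("heart", "heart"),
    ("lung", "lung"),
    ("kidney", "kidney"),
    ("bone marrow", "bone marrow"),
    ("skeletal muscle", "muscle"),
]
AGE_POOL = ["45", "45-50", ">60", "6 weeks", "12 months", "E14.5", "3 days", "adult"]
REA_POOL = [
    ("Caucasian", "European"),
    ("White", "European"),
    ("African American", "African"),
    ("Asian", "East Asian"),
    ("Hispanic", "Hispanic or Latin American"),
]
STRAIN_POOL = [
    ("C57BL/6J", "C57BL/6J"),
    ("BALB/c", "BALB/c"),
    ("DBA/2J", "DBA/2J"),
    ("Sprague-Dawley", "Sprague-Dawley"),
    ("AB", "AB"),
]
SEX_TAGS = ["sex", "gender", "Sex"]
AGE_TAGS = ["age", "age (yrs)", "Age"]
TISSUE_TAGS = ["tissue", "tissue type", "cell type"]
REA_TAGS = ["race", "ethnicity", "ancestry"]
STRAIN_TAGS = ["strain", "genetic background"]

PRESENCE_MODES = ("per_sample_tag", "uniform_claim", "summary_only")

CLAIMS_COLUMNS = ["study_accession", "attribute", "value", "uniform"]
MANIFEST_COLUMNS = ["study", "sample", "attribute", "source", "level", "value"]
STUDIES_COLUMNS = ["study", "year", "is_human", "organism", "disease_label", "n_samples"]


@dataclass
class SyntheticConfig:
    """Generative parameters for a ground-truth-labelled corpus.

    Default availability probabilities emulate the prevalences the audit is
    designed around: organism always present; tissue nearly always present
    for human samples and less often for non-human; sex and age each about
    half the time; ancestry rarely; strain often.
    """

    n_studies: int = 50
    human_fraction: float = 0.6
    samples_min: int = 3
    samples_max: int = 12
    availability_human: dict[str, float] = field(
        default_factory=lambda: {
            "organism": 1.0, "tissue": 0.99, "sex": 0.5, "age": 0.5, "rea": 0.2,
        }
    )
    availability_nonhuman: dict[str, float] = field(
        default_factory=lambda: {
            "organism": 1.0, "tissue": 0.6, "sex": 0.5, "age": 0.5, "strain": 0.8,
        }
    )
    #: relative weights of the three presence encodings plus the forced
    #: 'absent' residual (used only for validation; absence itself is decided
    #: by the availability draw)
    encoding_mode_probs: dict[str, float] = field(
        default_factory=lambda: {
            "per_sample_tag": 0.7,
            "uniform_claim": 0.15,
            "summary_only": 0.15,
            "absent": 0.0,
        }
    )
    messy_token_prob: float = 0.0
    year_range: tuple[int, int] = (2008, 2024)
    #: optional (step_year, factor): availability probabilities of studies
    #: released before step_year are multiplied by factor
    availability_step: Optional[tuple[int, float]] = None
    #: publication-text model: P(text available | repo available),
    #: P(text available | repo missing), P(sample-level | text available)
    text_given_repo: float = 0.85
    text_given_norepo: float = 0.15
    text_sample_level_prob: float = 0.6
    seed: int = 0

    def validate(self) -> None:
        probs = list(self.availability_human.values()) + list(
            self.availability_nonhuman.values()
        ) + [
            self.messy_token_prob,
            self.human_fraction,
            self.text_given_repo,
            self.text_given_norepo,
            self.text_sample_level_prob,
        ]
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.n_studies < 0:
            raise ValueError("n_studies must be non-negative")
        if not (1 <= self.samples_min <= self.samples_max):
            raise ValueError("need 1 <= samples_min <= samples_max")
        mode_sum = sum(self.encoding_mode_probs.get(m, 0.0) for m in PRESENCE_MODES)
        if mode_sum <= 0:
            raise ValueError("at least one presence encoding mode needs weight > 0")
        unknown = set(self.encoding_mode_probs) - set(PRESENCE_MODES) - {"absent"}
        if unknown:
            raise ValueError(f"unknown encoding modes: {sorted(unknown)}")


@dataclass
class SyntheticStudy:
    accession: str
    is_human: bool
    organism: str
    disease_label: str
    year: int
    sample_accessions: list[str]
    xml: str
    #: per (sample, attribute, source) ground truth
    manifest_rows: list[dict]
    curation_records: list[CurationRecord]
    claims_rows: list[dict]


@dataclass
class SyntheticCorpus:
    config: SyntheticConfig
    studies: list[SyntheticStudy]

    @property
    def manifest(self) -> pd.DataFrame:
        rows = [r for s in self.studies for r in s.manifest_rows]
        return pd.DataFrame(rows, columns=MANIFEST_COLUMNS)

    @property
    def curation_records(self) -> list[CurationRecord]:
        return [r for s in self.studies for r in s.curation_records]

    @property
    def claims_table(self) -> pd.DataFrame:
        rows = [r for s in self.studies for r in s.claims_rows]
        return pd.DataFrame(rows, columns=CLAIMS_COLUMNS)

    @property
    def studies_table(self) -> pd.DataFrame:
        rows = [
            {
                "study": s.accession,
                "year": s.year,
                "is_human": s.is_human,
                "organism": s.organism,
                "disease_label": s.disease_label,
                "n_samples": len(s.sample_accessions),
            }
            for s in self.studies
        ]
        return pd.DataFrame(rows, columns=STUDIES_COLUMNS)


def _xml_escape(text: str) -> str:
    return (
        text.replace("&", "&amp;").replace("<", "&lt;").replace(">", "&gt;")
        .replace('"', "&quot;")
    )


def _render_xml(
    accession: str,
    title: str,
    summary: str,
    design: str,
    year: int,
    series_types: Sequence[str],
    samples: list[dict],
) -> str:
    """Minimal but schema-faithful MINiML serialization."""
    sub_date = f"{year}-01-15"
    rel_date = f"{year}-06-15"
    lines = [
        '<?xml version="1.0" encoding="UTF-8"?>',
        '<MINiML xmlns="http://www.ncbi.nlm.nih.gov/geo/info/MINiML">',
        f'  <Series iid="{accession}">',
        f"    <Status database=\"GEO\">",
        f"      <Submission-Date>{sub_date}</Submission-Date>",
        f"      <Release-Date>{rel_date}</Release-Date>",
        "    </Status>",
        f"    <Title>{_xml_escape(title)}</Title>",
        f"    <Accession database=\"GEO\">{accession}</Accession>",
    ]
    for t in series_types:
        lines.append(f"    <Type>{_xml_escape(t)}</Type>")
    lines.append(f"    <Summary>{_xml_escape(summary)}</Summary>")
    lines.append(f"    <Overall-Design>{_xml_escape(design)}</Overall-Design>")
    for s in samples:
        lines.append(f'    <Sample-Ref ref="{s["accession"]}" />')
    lines.append("  </Series>")
    for s in samples:
        lines.append(f'  <Sample iid="{s["accession"]}">')
        lines.append("    <Status database=\"GEO\">")
        lines.append(f"      <Release-Date>{rel_date}</Release-Date>")
        lines.append("    </Status>")
        lines.append(f"    <Title>{_xml_escape(s['title'])}</Title>")
        lines.append(f"    <Accession database=\"GEO\">{s['accession']}</Accession>")
        lines.append(f"    <Channel-Count>{s.get('channel_count', 1)}</Channel-Count>")
        lines.append('    <Channel position="1">')
        if s.get("source"):
            lines.append(f"      <Source>{_xml_escape(s['source'])}</Source>")
        if s.get("organism"):
            lines.append(f"      <Organism>{_xml_escape(s['organism'])}</Organism>")
        for tag, value in s.get("characteristics", []):
            lines.append(
                f'      <Characteristics tag="{_xml_escape(tag)}">{_xml_escape(value)}</Characteristics>'
            )
        lines.append("    </Channel>")
        if s.get("description"):
            lines.append(f"    <Description>{_xml_escape(s['description'])}</Description>")
        lines.append("    <Library-Strategy>RNA-Seq</Library-Strategy>")
        lines.append("  </Sample>")
    lines.append("</MINiML>")
    return "\n".join(lines) + "\n"


def _choice(rng: np.random.Generator, pool: list):
    return pool[int(rng.integers(len(pool)))]


def _generate_study(
    config: SyntheticConfig, index: int
) -> SyntheticStudy:
    rng = np.random.default_rng([config.seed, index])
    accession = f"GSE{100001 + index}"
    is_human = bool(rng.random() < config.human_fraction)
    organism = HUMAN if is_human else _choice(rng, NONHUMAN_ORGANISMS)
    disease = _choice(rng, DISEASES) if is_human else ""
    year = int(rng.integers(config.year_range[0], config.year_range[1] + 1))
    n_samples = int(rng.integers(config.samples_min, config.samples_max + 1))
    gsm_base = 1000001 + index * 1000
    sample_accs = [f"GSM{gsm_base + j}" for j in range(n_samples)]

    avail_probs = dict(
        config.availability_human if is_human else config.availability_nonhuman
    )
    if config.availability_step and year < config.availability_step[0]:
        avail_probs = {a: p * config.availability_step[1] for a, p in avail_probs.items()}
    applicable = list(avail_probs)

    mode_weights = np.array(
        [config.encoding_mode_probs.get(m, 0.0) for m in PRESENCE_MODES], dtype=float
    )
    mode_weights = mode_weights / mode_weights.sum()

    # Per-attribute repo-side decisions
    repo_available: dict[str, bool] = {}
    repo_mode: dict[str, str] = {}
    repo_value: dict[str, tuple[str, str]] = {}  # raw, canonical
    for attr in applicable:
        repo_available[attr] = bool(rng.random() < avail_probs[attr])
        if attr == "organism":
            repo_mode[attr] = "per_sample_tag"  # organism is an XML element
            repo_value[attr] = (organism, organism)
            continue
        mode = PRESENCE_MODES[int(rng.choice(len(PRESENCE_MODES), p=mode_weights))]
        pool = {
            "sex": SEX_POOL,
            "tissue": TISSUE_POOL,
            "rea": REA_POOL,
            "strain": STRAIN_POOL,
        }.get(attr)
        if attr == "age":
            raw = _choice(rng, AGE_POOL)
            repo_value[attr] = (raw, raw)
        else:
            repo_value[attr] = tuple(_choice(rng, pool))
        repo_mode[attr] = mode

    # Uniform claims for sex/age are additionally voiced as a summary
    # sentence so the series-text detection path is exercised.
    summary_bits = [f"Synthetic study of {organism}."]
    claims_rows = []
    for attr in applicable:
        if attr == "organism" or not repo_available[attr]:
            continue
        raw, canonical = repo_value[attr]
        if repo_mode[attr] == "uniform_claim":
            claims_rows.append(
                {
                    "study_accession": accession,
                    "attribute": attr,
                    "value": canonical,
                    "uniform": True,
                }
            )
            if attr == "sex":
                summary_bits.append(f"All samples were {canonical}.")
            elif attr == "age" and raw[0].isdigit():
                summary_bits.append(f"All samples were {raw} old.")
        elif repo_mode[attr] == "summary_only":
            claims_rows.append(
                {
                    "study_accession": accession,
                    "attribute": attr,
                    "value": canonical,
                    "uniform": False,
                }
            )
            summary_bits.append(f"The cohort was heterogeneous in {attr}.")

    # Per-sample XML content and repo-side ground truth
    tag_pools = {
        "sex": SEX_TAGS,
        "age": AGE_TAGS,
        "tissue": TISSUE_TAGS,
        "rea": REA_TAGS,
        "strain": STRAIN_TAGS,
    }
    samples = []
    manifest_rows = []
    for acc in sample_accs:
        characteristics = []
        source = ""
        levels: dict[str, tuple[str, str]] = {}  # attr -> (level, value)
        for attr in ATTRIBUTES:
            if attr not in applicable:
                levels[attr] = (Level.not_applicable.value, "")
                continue
            if not repo_available[attr]:
                levels[attr] = (Level.missing.value, "")
                continue
            raw, canonical = repo_value[attr]
            if attr == "organism":
                levels[attr] = (Level.sample_level.value, canonical)
                continue
            mode = repo_mode[attr]
            if mode == "per_sample_tag":
                messy = rng.random() < config.messy_token_prob
                tag = _choice(rng, tag_pools[attr])
                value = _choice(rng, MISSING_TOKENS) if messy else raw
                characteristics.append((tag, value))
                if attr == "tissue" and not messy and rng.random() < 0.5:
                    source = raw
                levels[attr] = (
                    (Level.missing.value, "")
                    if messy
                    else (Level.sample_level.value, canonical)
                )
            elif mode == "uniform_claim":
                levels[attr] = (Level.sample_level.value, canonical)
            else:  # summary_only
                levels[attr] = (Level.experiment_level.value, canonical)
        rng.shuffle(characteristics)
        samples.append(
            {
                "accession": acc,
                "title": f"{organism} sample {acc}",
                "organism": organism if repo_available.get("organism") else "",
                "source": source,
                "characteristics": characteristics,
            }
        )
        for attr in ATTRIBUTES:
            level, value = levels[attr]
            manifest_rows.append(
                {
                    "study": accession,
                    "sample": acc,
                    "attribute": attr,
                    "source": Source.repository.value,
                    "level": level,
                    "value": value,
                }
            )

    # Publication-text side, encoded as curation records
    curation_records = []
    text_levels: dict[str, str] = {}
    for attr in ATTRIBUTES:
        if attr not in applicable:
            text_levels[attr] = Level.not_applicable.value
            continue
        p = config.text_given_repo if repo_available[attr] else config.text_given_norepo
        if rng.random() < p:
            level = (
                Level.sample_level.value
                if rng.random() < config.text_sample_level_prob
                else Level.experiment_level.value
            )
            text_levels[attr] = level
            curation_records.append(
                CurationRecord(
                    study=accession,
                    scope="study",
                    sample=None,
                    attribute=attr,
                    level=level,
                    value=repo_value.get(attr, ("", ""))[1],
                    disease_label=disease,
                )
            )
        else:
            text_levels[attr] = Level.missing.value
    if disease and not curation_records:
        # carry the disease label even when the text shared nothing
        curation_records.append(
            CurationRecord(
                study=accession,
                scope="study",
                sample=None,
                attribute="organism",
                level=Level.missing.value,
                disease_label=disease,
            )
        )
    for acc in sample_accs:
        for attr in ATTRIBUTES:
            manifest_rows.append(
                {
                    "study": accession,
                    "sample": acc,
                    "attribute": attr,
                    "source": Source.publication_text.value,
                    "level": text_levels[attr],
                    "value": "",
                }
            )

    xml = _render_xml(
        accession,
        title=f"Synthetic {('human ' + disease) if is_human else organism} study {accession}",
        summary=" ".join(summary_bits),
        design=f"{n_samples} samples, RNA-Seq.",
        year=year,
        series_types=["Expression profiling by high throughput sequencing"],
        samples=samples,
    )
    return SyntheticStudy(
        accession=accession,
        is_human=is_human,
        organism=organism,
        disease_label=disease,
        year=year,
        sample_accessions=sample_accs,
        xml=xml,
        manifest_rows=manifest_rows,
        curation_records=curation_records,
        claims_rows=claims_rows,
    )


def generate_corpus(config: SyntheticConfig) -> SyntheticCorpus:
    """Generate an in-memory corpus. Deterministic given ``config.seed``."""
    config.validate()
    studies = [_generate_study(config, i) for i in range(config.n_studies)]
    return SyntheticCorpus(config=config, studies=studies)


def write_corpus(corpus: SyntheticCorpus, out_dir: Union[str, Path]) -> dict[str, object]:
    """Write XML files plus manifest, curation, claims and studies tables.

    Returns a dict with the list of XML paths and the table paths.
    """
    out = Path(out_dir)
    xml_dir = out / "miniml"
    xml_dir.mkdir(parents=True, exist_ok=True)
    xml_paths = []
    for study in corpus.studies:
        p = xml_dir / f"{study.accession}_family.xml"
        p.write_text(study.xml, encoding="utf-8")
        xml_paths.append(p)
    manifest_path = out / "manifest.tsv"
    corpus.manifest.to_csv(manifest_path, sep="\t", index=False)
    curation_path = out / "curation.tsv"
    write_curation_table(corpus.curation_records, curation_path)
    claims_path = out / "claims.tsv"
    corpus.claims_table.to_csv(claims_path, sep="\t", index=False)
    studies_path = out / "studies.tsv"
    corpus.studies_table.to_csv(studies_path, sep="\t", index=False)
    return {
        "xml": xml_paths,
        "manifest": manifest_path,
        "curation": curation_path,
        "claims": claims_path,
        "studies": studies_path,
    }


# ---------------------------------------------------------------------------
# Hand-designed fixtures

FIXTURE_NAMES = (
    "clean_human",
    "mouse_strain",
    "superseries",
    "multichannel",
    "all_missing_tokens",
    "uniform_claim_female",
)


def make_fixture(name: str) -> str:
    """Return the MINiML XML for one named fixture study."""
    if name == "clean_human":
        samples = [
            {
                "accession": f"GSM90000{i}",
                "title": f"patient {i}",
                "organism": "Homo sapiens",
                "source": "whole blood",
                "characteristics": [
                    ("sex", "female" if i % 2 else "male"),
                    ("age", str(40 + i)),
                    ("ethnicity", "Caucasian"),
                    ("tissue", "whole blood"),
                ],
            }
            for i in range(1, 4)
        ]
        return _render_xml(
            "GSE900001", "Clean human cohort", "Blood transcriptomes.",
            "3 patients.", 2020, ["Expression profiling by array"], samples,
        )
    if name == "mouse_strain":
        samples = [
            {
                "accession": f"GSM91000{i}",
                "title": f"mouse {i}",
                "organism": "Mus musculus",
                "source": "liver",
                "characteristics": [
                    ("strain", "C57BL/6J"),
                    ("sex", "M"),
                    ("age", "6 weeks"),
                ],
            }
            for i in range(1, 3)
        ]
        return _render_xml(
            "GSE900002", "Mouse liver study", "Liver expression in B6 mice.",
            "2 mice.", 2019, ["Expression profiling by array"], samples,
        )
    if name == "superseries":
        samples = [
            {
                "accession": "GSM920001",
                "title": "member sample",
                "organism": "Homo sapiens",
                "source": "brain",
                "characteristics": [("sex", "female")],
            }
        ]
        return _render_xml(
            "GSE900003", "Aggregate record",
            "This SuperSeries is composed of the SubSeries listed below.",
            "Refer to individual Series.", 2021,
            ["Expression profiling by array", "This SuperSeries is composed of the SubSeries listed below"],
            samples,
        )
    if name == "multichannel":
        # two-channel sample: only channel 1 is read
        xml = make_fixture("clean_human")
        return xml.replace(
            "<Channel-Count>1</Channel-Count>", "<Channel-Count>2</Channel-Count>", 1
        ).replace("GSE900001", "GSE900004")
    if name == "all_missing_tokens":
        samples = [
            {
                "accession": f"GSM93000{i}",
                "title": f"sample {i}",
                "organism": "Homo sapiens",
                "source": "",
                "characteristics": [
                    ("sex", "N/A"),
                    ("age", "unknown"),
                    ("tissue", "not collected"),
                    ("race", "not available"),
                ],
            }
            for i in range(1, 3)
        ]
        return _render_xml(
            "GSE900005", "Sentinel-token study", "No usable phenotypes.",
            "2 samples.", 2015, ["Expression profiling by array"], samples,
        )
    if name == "uniform_claim_female":
        samples = [
            {
                "accession": f"GSM94000{i}",
                "title": f"donor {i}",
                "organism": "Homo sapiens",
                "source": "liver",
                "characteristics": [("age", str(30 + i))],
            }
            for i in range(1, 4)
        ]
        return _render_xml(
            "GSE900006", "Uniform-sex cohort",
            "Liver biopsies. All samples were female.",
            "3 donors, all female.", 2022, ["Expression profiling by array"], samples,
        )
    raise ValueError(f"unknown fixture {name!r}; known fixtures: {', '.join(FIXTURE_NAMES)}")
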