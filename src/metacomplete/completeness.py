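"""Availability levels and completeness statistics.

The audit distinguishes *sample-level* metadata (a phenotype value
attributable to each individual sample, either stated per sample or implied
by a uniform claim such as "all samples are female") from *experiment-level*
metadata (summarized information that cannot be assigned to individual
samples). Every applicable (study, sample, attribute, source) cell carries
one of the levels ``sample_level``, ``experiment_level``, ``missing`` or
``not_applicable``.

Five attributes apply to any given sample: the four common phenotypes
(organism, tissue, sex, age) plus race/ethnicity/ancestry for human samples
or strain for non-human samples.

Pooled availability is the fraction of applicable sample–attribute cells
that are non-missing (sample-weighted), not an unweighted mean of per-study
scores; an unweighted study mean is available via ``study_scores``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional, Sequence

import pandas as pd

from .phenotype_detect import PhenotypeProfile, Status
from .records import ATTRIBUTES, SeriesRecord

COMMON_ATTRIBUTES = frozenset({"organism", "tissue", "sex", "age"})

MATRIX_COLUMNS = ["study", "sample", "attribute", "source", "level"]


class Level(str, Enum):
    sample_level = "sample_level"
    experiment_level = "experiment_level"
    missing = "missing"
    not_applicable = "not_applicable"


class Source(str, Enum):
    repository = "repository"
    publication_text = "publication_text"


@dataclass(frozen=True)
class Claim:
    """A study-wide assertion about one attribute.

    ``uniform=True`` means the value is asserted for every sample ("all
    samples are female") and upgrades missing cells to sample level;
    ``uniform=False`` is a summary without per-sample assignment ("12 males
    and 8 females") and marks missing cells as experiment level.
    """

    attribute: str
    value: str = ""
    uniform: bool = False

    def __post_init__(self) -> None:
        if self.attribute not in ATTRIBUTES:
            raise ValueError(
                f"unknown attribute {self.attribute!r}; expected one of {ATTRIBUTES}"
            )


# Documented pattern list for uniform claims detected verbatim in series
# summary / overall-design text. Deliberately narrow: only unambiguous
# "all samples are X" phrasings are auto-detected; anything subtler enters
# via curation tables.
_SUBJECT = r"(?:samples|subjects|patients|participants|donors|individuals|animals|mice)"
UNIFORM_TEXT_PATTERNS: list[tuple[str, re.Pattern, str]] = [
    (
        "sex",
        re.compile(rf"\ball {_SUBJECT} (?:are|were) (female|male)s?\b", re.I),
        "",
    ),
    (
        "age",
        re.compile(
            rf"\ball {_SUBJECT} (?:are|were) (\d+(?:\.\d+)?(?:\s*(?:years?|months?|weeks?|days?))?(?:\s*old)?)\b",
            re.I,
        ),
        "",
    ),
]


def detect_uniform_claims(series: SeriesRecord) -> list[Claim]:
    """Scan series summary and overall design for uniform-claim sentences."""
    claims = []
    text = f"{series.summary} {series.overall_design}"
    for attribute, pattern, _ in UNIFORM_TEXT_PATTERNS:
        m = pattern.search(text)
        if m:
            claims.append(Claim(attribute=attribute, value=m.group(1), uniform=True))
    return claims


def applicable_attributes(is_human: bool) -> frozenset:
    """The five attributes applicable to a sample of the given species class."""
    extra = "rea" if is_human else "strain"
    return COMMON_ATTRIBUTES | {extra}


def _detection_level(status: Status) -> Level:
    if status is Status.available:
        return Level.sample_level
    if status is Status.not_applicable:
        return Level.not_applicable
    return Level.missing


def apply_experiment_level(
    profiles: Sequence[PhenotypeProfile],
    series: SeriesRecord,
    claims: Iterable[Claim] = (),
    source: Source = Source.repository,
    scan_series_text: bool = True,
) -> pd.DataFrame:
    """Availability-matrix slice for one study.

    Per-sample detections map to ``sample_level``; uniform claims (supplied,
    or detected in the series text when ``scan_series_text``) upgrade missing
    cells of their attribute to ``sample_level``; non-uniform summary claims
    mark missing cells as ``experiment_level``. Claims never downgrade a
    per-sample detection and never touch inapplicable cells.
    """
    all_claims = list(claims)
    if scan_series_text:
        all_claims.extend(detect_uniform_claims(series))
    upgrade_to: dict[str, Level] = {}
    for claim in all_claims:
        new = Level.sample_level if claim.uniform else Level.experiment_level
        prev = upgrade_to.get(claim.attribute)
        if prev is None or (prev is Level.experiment_level and new is Level.sample_level):
            upgrade_to[claim.attribute] = new

    rows = []
    for profile in profiles:
        for attribute in ATTRIBUTES:
            level = _detection_level(profile.detections[attribute].status)
            if level is Level.missing and attribute in upgrade_to:
                level = upgrade_to[attribute]
            rows.append(
                {
                    "study": series.accession,
                    "sample": profile.accession,
                    "attribute": attribute,
                    "source": source.value,
                    "level": level.value,
                }
            )
    return pd.DataFrame(rows, columns=MATRIX_COLUMNS)


def build_matrix(slices: Iterable[pd.DataFrame]) -> pd.DataFrame:
    """Concatenate per-study slices into one availability matrix."""
    frames = [s for s in slices if len(s)]
    if not frames:
        return pd.DataFrame(columns=MATRIX_COLUMNS)
    out = pd.concat(frames, ignore_index=True)
    dupes = out.duplicated(subset=["study", "sample", "attribute", "source"])
    if dupes.any():
        raise ValueError("duplicate (study, sample, attribute, source) cells")
    return out


def select_source(matrix: pd.DataFrame, selector: str) -> pd.DataFrame:
    """Reduce the matrix to one level per (study, sample, attribute).

    ``selector`` ∈ {"repository", "publication_text", "either"}. "either"
    takes the cell-wise best level across sources (sample beats experiment
    beats missing); ``not_applicable`` is invariant across sources.
    """
    if selector in (Source.repository.value, Source.publication_text.value):
        return matrix[matrix["source"] == selector].drop(columns=["source"])
    if selector != "either":
        raise ValueError(f"unknown source selector: {selector!r}")
    rank = {
        Level.sample_level.value: 3,
        Level.experiment_level.value: 2,
        Level.missing.value: 1,
        Level.not_applicable.value: 0,
    }
    df = matrix.assign(_rank=matrix["level"].map(rank))
    best = (
        df.sort_values("_rank", ascending=False)
        .drop_duplicates(subset=["study", "sample", "attribute"])
        .drop(columns=["source", "_rank"])
        .sort_index()
        .reset_index(drop=True)
    )
    return best


@dataclass
class StudyScore:
    """Completeness of one study under one source view."""

    study: str
    is_human: bool
    n_samples: int
    per_attribute: dict[str, float]
    phenotypes_shared: int
    bracket: int
    pooled_availability: float
    experiment_only_fraction: float
    #: raw counts backing the fractions (available, applicable)
    available_cells: int = 0
    applicable_cells: int = 0


def study_score(study_slice: pd.DataFrame, share_threshold: float = 0.0) -> StudyScore:
    """Score one study from its single-source matrix slice.

    An attribute counts as *shared* when it is non-missing for more than
    ``share_threshold`` fraction of applicable samples (default: at least
    one sample). The bracket is 20 × the number of shared phenotypes.
    """
    if study_slice.empty:
        raise ValueError("cannot score an empty study")
    study = study_slice["study"].iloc[0]
    applicable = study_slice[study_slice["level"] != Level.not_applicable.value]
    available = applicable[applicable["level"] != Level.missing.value]
    n_samples = study_slice["sample"].nunique()

    per_attribute: dict[str, float] = {}
    shared = 0
    for attribute in ATTRIBUTES:
        cells = applicable[applicable["attribute"] == attribute]
        if cells.empty:
            continue
        frac = (cells["level"] != Level.missing.value).mean()
        per_attribute[attribute] = float(frac)
        if frac > share_threshold:
            shared += 1

    # Study species class: human when REA is the applicable extra attribute
    # for the majority of samples.
    rea_applicable = (
        study_slice[study_slice["attribute"] == "rea"]["level"]
        != Level.not_applicable.value
    )
    is_human = bool(rea_applicable.mean() > 0.5) if len(rea_applicable) else False

    n_available = len(available)
    n_applicable = len(applicable)
    n_exp = int((available["level"] == Level.experiment_level.value).sum())
    return StudyScore(
        study=study,
        is_human=is_human,
        n_samples=n_samples,
        per_attribute=per_attribute,
        phenotypes_shared=shared,
        bracket=20 * shared,
        pooled_availability=n_available / n_applicable if n_applicable else 0.0,
        experiment_only_fraction=n_exp / n_available if n_available else 0.0,
        available_cells=n_available,
        applicable_cells=n_applicable,
    )


def study_scores(
    matrix: pd.DataFrame, selector: str = "repository", share_threshold: float = 0.0
) -> list[StudyScore]:
    view = select_source(matrix, selector)
    return [
        study_score(group, share_threshold)
        for _, group in view.groupby("study", sort=True)
    ]


@dataclass
class DatasetSummary:
    """Corpus-wide completeness under one source view."""

    source: str
    n_studies: int
    n_samples: int
    overall_availability: float
    per_attribute: dict[str, float]
    bracket_distribution: dict[int, float]
    experiment_only_share: float
    available_cells: int
    applicable_cells: int
    groups: dict[str, "DatasetSummary"] = field(default_factory=dict)


def _summarize(view: pd.DataFrame, scores: list[StudyScore], source: str) -> DatasetSummary:
    applicable = view[view["level"] != Level.not_applicable.value]
    available = applicable[applicable["level"] != Level.missing.value]
    per_attribute = {}
    for attribute in ATTRIBUTES:
        cells = applicable[applicable["attribute"] == attribute]
        if len(cells):
            per_attribute[attribute] = float(
                (cells["level"] != Level.missing.value).mean()
            )
    brackets: dict[int, float] = {}
    if scores:
        for s in scores:
            brackets[s.bracket] = brackets.get(s.bracket, 0.0) + 1.0
        brackets = {b: c / len(scores) for b, c in sorted(brackets.items())}
    n_exp = int((available["level"] == Level.experiment_level.value).sum())
    return DatasetSummary(
        source=source,
        n_studies=len(scores),
        n_samples=int(view["sample"].nunique()) if len(view) else 0,
        overall_availability=len(available) / len(applicable) if len(applicable) else 0.0,
        per_attribute=per_attribute,
        bracket_distribution=brackets,
        experiment_only_share=n_exp / len(available) if len(available) else 0.0,
        available_cells=len(available),
        applicable_cells=len(applicable),
    )


def dataset_summary(
    matrix: pd.DataFrame,
    selector: str = "repository",
    share_threshold: float = 0.0,
    group_by_species: bool = True,
) -> DatasetSummary:
    """Pooled completeness over all applicable cells, plus the bracket
    distribution over studies and human / non-human sub-summaries."""
    view = select_source(matrix, selector)
    scores = study_scores(matrix, selector, share_threshold)
    summary = _summarize(view, scores, selector)
    if group_by_species and scores:
        human_studies = {s.study for s in scores if s.is_human}
        for name, member in (("human", True), ("non_human", False)):
            studies = {s.study for s in scores if s.is_human == member}
            if not studies:
                continue
            sub_view = view[view["study"].isin(studies)]
            sub_scores = [s for s in scores if s.study in studies]
            summary.groups[name] = _summarize(sub_view, sub_scores, selector)
        del human_studies
    return summary
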