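"""Rule-based detection and harmonization of the six audited phenotypes.

Each detector is a pure function of a :class:`~.records.SampleRecord` and the
vocabulary tables: tag-name matches beat value-pattern matches, which beat
scans of source/title/description text, and the first match wins. Every
``available`` verdict carries the :class:`~.records.CharacteristicField` that
produced it, so detections are auditable.

Availability reflects *presence*, not quality: an age value that cannot be
parsed numerically still counts as available (it is recorded as a stage
label), while sentinel strings like "n/a" or "not collected" never count.

Two attributes are species-specific: race/ethnicity/ancestry (REA) applies
only to human samples, strain only to non-human samples; the inapplicable one
is marked ``not_applicable`` regardless of field content.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Union

from .records import ATTRIBUTES, CharacteristicField, Origin, SampleRecord
from .vocab import AttributeVocabulary, VocabularySet, default_vocabulary

HUMAN_LABEL = "Homo sapiens"


class Status(str, Enum):
    available = "available"
    missing = "missing"
    not_applicable = "not_applicable"


class AgeForm(str, Enum):
    point = "point"
    range = "range"
    bound = "bound"
    stage = "stage"


class AgeUnit(str, Enum):
    year = "year"
    month = "month"
    week = "week"
    day = "day"
    hour = "hour"
    embryonic_day = "embryonic_day"
    unspecified = "unspecified"


@dataclass
class AgeValue:
    """A harmonized age: numeric point/range/bound, or a stage label."""

    form: AgeForm
    unit: AgeUnit = AgeUnit.unspecified
    magnitude: Optional[float] = None
    low: Optional[float] = None
    high: Optional[float] = None
    stage_label: Optional[str] = None

    def __post_init__(self) -> None:
        if self.form is AgeForm.range and (
            self.low is None or self.high is None or self.low > self.high
        ):
            raise ValueError("range requires low <= high")
        if self.form is AgeForm.point and self.magnitude is None:
            raise ValueError("point form requires a magnitude")


@dataclass
class Detection:
    """Outcome of one detector for one sample."""

    status: Status
    normalized_value: Optional[Union[str, AgeValue]] = None
    provenance: Optional[CharacteristicField] = None
    non_canonical: bool = False
    conflict: bool = False

    def __post_init__(self) -> None:
        if self.status is Status.available and self.normalized_value is None:
            raise ValueError("available detection requires a value")


@dataclass
class PhenotypeProfile:
    """Per-sample detection results for all six attributes."""

    accession: str
    detections: dict[str, Detection] = field(default_factory=dict)

    @property
    def is_human(self) -> bool:
        org = self.detections.get("organism")
        return (
            org is not None
            and org.status is Status.available
            and org.normalized_value == HUMAN_LABEL
        )

    def status(self, attribute: str) -> Status:
        return self.detections[attribute].status


_UNIT_PATTERNS: list[tuple[re.Pattern, AgeUnit]] = [
    (re.compile(r"\b(?:years?|yrs?|y\.?o\.?|yo)\b", re.I), AgeUnit.year),
    (re.compile(r"\b(?:months?|mos?)\b", re.I), AgeUnit.month),
    (re.compile(r"\b(?:weeks?|wks?)\b", re.I), AgeUnit.week),
    (re.compile(r"\b(?:days?)\b", re.I), AgeUnit.day),
    (re.compile(r"\b(?:hours?|hrs?)\b", re.I), AgeUnit.hour),
]

_NUM = r"\d+(?:\.\d+)?"
_RANGE_RE = re.compile(rf"^({_NUM})\s*(?:-|–|to)\s*({_NUM})")
_BOUND_RE = re.compile(rf"^(?:([<>]=?)\s*({_NUM})|({_NUM})\s*\+)")
_POINT_RE = re.compile(rf"^({_NUM})")
_EMBRYO_RE = re.compile(rf"^E\s?({_NUM})$", re.I)


def _unit_from_text(*texts: str) -> AgeUnit:
    for text in texts:
        for pattern, unit in _UNIT_PATTERNS:
            if pattern.search(text):
                return unit
    return AgeUnit.unspecified


def parse_age_value(value: str, tag: str = "") -> AgeValue:
    """Parse a free-text age into an :class:`AgeValue`.

    Handles points ("45"), ranges ("45-50"), bounds (">60", "65+"),
    units stated in the value or the tag ("6 weeks", tag "age (yrs)"),
    and embryonic stages ("E14.5"). Anything else becomes a stage label —
    the value is information even when it is not a number.
    """
    text = value.strip()
    m = _EMBRYO_RE.match(text)
    if m:
        return AgeValue(
            form=AgeForm.point,
            unit=AgeUnit.embryonic_day,
            magnitude=float(m.group(1)),
        )
    unit = _unit_from_text(text, tag)
    m = _RANGE_RE.match(text)
    if m:
        low, high = float(m.group(1)), float(m.group(2))
        if low <= high:
            return AgeValue(form=AgeForm.range, unit=unit, low=low, high=high)
    m = _BOUND_RE.match(text)
    if m:
        mag = float(m.group(2) or m.group(3))
        return AgeValue(form=AgeForm.bound, unit=unit, magnitude=mag)
    m = _POINT_RE.match(text)
    if m:
        return AgeValue(form=AgeForm.point, unit=unit, magnitude=float(m.group(1)))
    return AgeValue(form=AgeForm.stage, stage_label=text)


def _tagged_fields(sample: SampleRecord, vocab: AttributeVocabulary):
    for f in sample.characteristics:
        if f.origin is Origin.characteristics_element and f.tag in vocab.tag_synonyms:
            yield f


# Untagged entries like "Sex: F" put the attribute name inside the value.
_INLINE_RE_CACHE: dict[frozenset, re.Pattern] = {}


def _inline_pattern(tag_synonyms: set[str]) -> re.Pattern:
    key = frozenset(tag_synonyms)
    if key not in _INLINE_RE_CACHE:
        alts = "|".join(re.escape(t) for t in sorted(tag_synonyms, key=len, reverse=True))
        _INLINE_RE_CACHE[key] = re.compile(
            rf"(?:^|[;,]\s*)(?:{alts})\s*[:=]\s*([^;,]+)", re.I
        )
    return _INLINE_RE_CACHE[key]


def _scan_untagged(sample: SampleRecord, vocab: AttributeVocabulary):
    """Yield (field, extracted value) for untagged 'tag: value' text."""
    if not vocab.tag_synonyms:
        return
    pattern = _inline_pattern(vocab.tag_synonyms)
    for f in sample.characteristics:
        if f.origin is Origin.organism_element:
            continue
        if f.tag:  # tagged entries are handled by the tag pass
            continue
        m = pattern.search(f.value)
        if m:
            yield f, m.group(1).strip()


def detect_organism(sample: SampleRecord, vocab: VocabularySet) -> Detection:
    """Organism from the channel-1 Organism element, canonicalized against
    the bundled taxonomy table; unmatched names pass through verbatim."""
    table = vocab["organism"]
    raw = sample.organism_raw
    if raw is None or table.is_missing_token(raw):
        return Detection(Status.missing)
    label = table.match_value(raw)
    prov = next(
        (f for f in sample.characteristics if f.origin is Origin.organism_element),
        CharacteristicField("", raw, Origin.organism_element),
    )
    if label is None:
        return Detection(Status.available, raw, prov, non_canonical=True)
    return Detection(Status.available, label, prov)


def detect_sex(sample: SampleRecord, vocab: VocabularySet) -> Detection:
    table = vocab["sex"]
    candidates: list[tuple[CharacteristicField, str]] = [
        (f, f.value) for f in _tagged_fields(sample, table)
    ]
    candidates.extend(_scan_untagged(sample, table))
    detection: Optional[Detection] = None
    for f, value in candidates:
        if table.is_missing_token(value):
            continue
        label = table.match_value(value)
        if label is None:
            # A non-missing value under a sex tag that matches no pattern
            # (e.g. "2F, 1M") is pooled information about the sample.
            label = "mixed"
        if detection is None:
            detection = Detection(Status.available, label, f)
        elif label != detection.normalized_value:
            detection.conflict = True
    return detection or Detection(Status.missing)


def detect_age(sample: SampleRecord, vocab: VocabularySet) -> Detection:
    table = vocab["age"]
    for f in _tagged_fields(sample, table):
        if table.is_missing_token(f.value):
            continue
        return Detection(Status.available, parse_age_value(f.value, f.tag), f)
    for f, value in _scan_untagged(sample, table):
        if table.is_missing_token(value):
            continue
        return Detection(Status.available, parse_age_value(value, "age"), f)
    return Detection(Status.missing)


def detect_tissue(sample: SampleRecord, vocab: VocabularySet) -> Detection:
    """Tissue/cell type. Precedence: tissue-like characteristic tag, then the
    Source element (any non-missing source name counts), then an anatomy
    vocabulary scan of the remaining free text."""
    table = vocab["tissue"]
    for f in _tagged_fields(sample, table):
        if table.is_missing_token(f.value):
            continue
        label = table.match_value(f.value) or f.value
        return Detection(
            Status.available, label, f, non_canonical=table.match_value(f.value) is None
        )
    if sample.source_name and not table.is_missing_token(sample.source_name):
        prov = next(
            (f for f in sample.characteristics if f.origin is Origin.source_element),
            CharacteristicField("", sample.source_name, Origin.source_element),
        )
        label = table.match_value(sample.source_name) or sample.source_name
        return Detection(
            Status.available,
            label,
            prov,
            non_canonical=table.match_value(sample.source_name) is None,
        )
    for f in sample.characteristics:
        if f.origin in (Origin.organism_element, Origin.source_element):
            continue
        if f.tag:  # tagged with a non-tissue tag: skip
            continue
        label = table.match_value(f.value)
        if label is not None and not table.is_missing_token(f.value):
            return Detection(Status.available, label, f)
    return Detection(Status.missing)


def _normalize_label(value: str) -> str:
    return re.sub(r"\s+", " ", value).strip()


def detect_strain(
    sample: SampleRecord, vocab: VocabularySet, is_human: bool
) -> Detection:
    """Strain/genetic background; inapplicable to human samples."""
    if is_human:
        return Detection(Status.not_applicable)
    table = vocab["strain"]
    for f in _tagged_fields(sample, table):
        if table.is_missing_token(f.value):
            continue
        return Detection(Status.available, _normalize_label(f.value), f)
    for f, value in _scan_untagged(sample, table):
        if table.is_missing_token(value):
            continue
        return Detection(Status.available, _normalize_label(value), f)
    return Detection(Status.missing)


def detect_rea(
    sample: SampleRecord, vocab: VocabularySet, is_human: bool
) -> Detection:
    """Race/ethnicity/ancestry, harmonized to broad ancestry categories;
    inapplicable to non-human samples."""
    if not is_human:
        return Detection(Status.not_applicable)
    table = vocab["rea"]
    for f in _tagged_fields(sample, table):
        if table.is_missing_token(f.value):
            continue
        label = table.match_value(f.value)
        if label is None:
            return Detection(
                Status.available, _normalize_label(f.value), f, non_canonical=True
            )
        return Detection(Status.available, label, f)
    for f, value in _scan_untagged(sample, table):
        if table.is_missing_token(value):
            continue
        label = table.match_value(value)
        return Detection(
            Status.available,
            label or _normalize_label(value),
            f,
            non_canonical=label is None,
        )
    return Detection(Status.missing)


def annotate_sample(
    sample: SampleRecord, vocab: Optional[VocabularySet] = None
) -> PhenotypeProfile:
    """Run all six detectors and enforce species applicability.

    A sample is human iff its canonical organism label is "Homo sapiens";
    humans get REA and never strain, non-humans the reverse.
    """
    vocab = vocab or default_vocabulary()
    organism = detect_organism(sample, vocab)
    is_human = (
        organism.status is Status.available
        and organism.normalized_value == HUMAN_LABEL
    )
    profile = PhenotypeProfile(accession=sample.accession)
    profile.detections = {
        "organism": organism,
        "tissue": detect_tissue(sample, vocab),
        "sex": detect_sex(sample, vocab),
        "age": detect_age(sample, vocab),
        "strain": detect_strain(sample, vocab, is_human),
        "rea": detect_rea(sample, vocab, is_human),
    }
    assert set(profile.detections) == set(ATTRIBUTES)
    return profile
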