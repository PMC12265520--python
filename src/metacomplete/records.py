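"""Core record types shared across the audit pipeline.

A parsed MINiML document yields one :class:`SeriesRecord` (the study) and one
:class:`SampleRecord` per GSM. Free-text fields that may carry phenotype
information are kept as :class:`CharacteristicField` entries with explicit
provenance, so every downstream detection can be traced back to the XML
element it came from.
"""

from __future__ import annotations

import re
import unicodedata
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

GSE_RE = re.compile(r"^GSE[0-9]+$")
GSM_RE = re.compile(r"^GSM[0-9]+$")

#: The six audited phenotypic attributes.
ATTRIBUTES = ("organism", "tissue", "strain", "sex", "age", "rea")


class Origin(str, Enum):
    """Where a free-text characteristic entry came from in the XML."""

    characteristics_element = "characteristics_element"
    source_element = "source_element"
    organism_element = "organism_element"
    title = "title"
    description = "description"


def normalize_text(text: str) -> str:
    """NFC-normalize, collapse whitespace and strip. Idempotent."""
    text = unicodedata.normalize("NFC", text)
    return re.sub(r"\s+", " ", text).strip()


@dataclass(frozen=True)
class CharacteristicField:
    """One tagged (or untagged) free-text entry attached to a sample.

    ``tag`` is lowercased and whitespace-collapsed; the empty string means the
    XML attribute was absent (some submitters put ``Sex: F`` inside the value
    text instead).
    """

    tag: str
    value: str
    origin: Origin

    def __post_init__(self) -> None:
        object.__setattr__(self, "tag", normalize_text(self.tag).lower())
        object.__setattr__(self, "value", self.value.strip())


@dataclass
class SampleRecord:
    """A GEO sample (GSM) restricted to the fields the audit consumes."""

    accession: str
    title: str = ""
    organism_raw: Optional[str] = None
    source_name: str = ""
    characteristics: list[CharacteristicField] = field(default_factory=list)
    description: str = ""
    library_strategy: str = ""
    channel_count: int = 1
    release_date: Optional[str] = None

    def __post_init__(self) -> None:
        if not GSM_RE.match(self.accession):
            raise ValueError(f"not a GSM accession: {self.accession!r}")
        if self.channel_count < 1:
            raise ValueError(f"channel_count must be >= 1, got {self.channel_count}")


@dataclass
class SeriesRecord:
    """A GEO series (GSE): study-level descriptive metadata."""

    accession: str
    title: str = ""
    summary: str = ""
    overall_design: str = ""
    submission_date: Optional[str] = None
    release_date: Optional[str] = None
    series_types: list[str] = field(default_factory=list)
    sample_accessions: list[str] = field(default_factory=list)
    is_superseries: bool = False

    def __post_init__(self) -> None:
        if not GSE_RE.match(self.accession):
            raise ValueError(f"not a GSE accession: {self.accession!r}")
        if (
            self.submission_date
            and self.release_date
            and self.release_date < self.submission_date
        ):
            raise ValueError(
                f"{self.accession}: release date {self.release_date} precedes "
                f"submission date {self.submission_date}"
            )


@dataclass
class MinimlDocument:
    """The parsed content of one family archive: a series plus its samples."""

    series: SeriesRecord
    samples: list[SampleRecord] = field(default_factory=list)

    @property
    def accession(self) -> str:
        return self.series.accession
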