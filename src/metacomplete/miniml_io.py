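"""Reading GEO MINiML family archives into structured tables.

A family archive is the per-series bundle GEO publishes as
``GSEnnnnn_family.xml.tgz``; the single ``*_family.xml`` member inside holds
the full series record. :func:`read_family_archive` accepts either the
archive or a bare XML file and returns a :class:`~.records.MinimlDocument`.
:func:`extract_series_table` / :func:`extract_sample_table` flatten parsed
documents into the two per-study tables the audit works from.

Parsing is namespace-agnostic (matches on local element names) because GEO
has shipped MINiML both with and without the schema namespace over the
years. Input is decoded as UTF-8 with replacement of undecodable bytes and
Unicode-normalized to NFC before any downstream matching.
"""

from __future__ import annotations

import io
import tarfile
from pathlib import Path
from typing import Iterable, Sequence, Union

import pandas as pd
from lxml import etree

from .records import (
    CharacteristicField,
    MinimlDocument,
    Origin,
    SampleRecord,
    SeriesRecord,
    normalize_text,
)


class MinimlFormatError(ValueError):
    """Raised for structurally invalid archives or XML."""


#: Delimiter joining flattened ``tag=value`` characteristic pairs in the
#: sample table. Chosen because '|' and '=' are vanishingly rare in GEO
#: characteristic text; values containing them are escaped with backslash.
PAIR_SEP = " | "

SERIES_COLUMNS = [
    "accession",
    "title",
    "summary",
    "overall_design",
    "submission_date",
    "release_date",
    "series_types",
    "sample_accessions",
    "is_superseries",
]

SAMPLE_COLUMNS = [
    "series_accession",
    "accession",
    "title",
    "organism_raw",
    "source_name",
    "characteristics",
    "description",
    "library_strategy",
    "channel_count",
    "release_date",
]


def _local(el: etree._Element) -> str:
    return etree.QName(el).localname


def _text(el) -> str:
    if el is None or el.text is None:
        return ""
    return normalize_text(el.text)


def _children(el: etree._Element, name: str) -> list[etree._Element]:
    return [c for c in el if isinstance(c.tag, str) and _local(c) == name]


def _child(el: etree._Element, name: str):
    found = _children(el, name)
    return found[0] if found else None


def _parse_xml_bytes(data: bytes, source_name: str) -> etree._Element:
    # UTF-8 with replacement, then re-encode so lxml sees clean input.
    text = data.decode("utf-8", errors="replace")
    try:
        return etree.fromstring(text.encode("utf-8"))
    except etree.XMLSyntaxError as exc:
        offset = getattr(exc, "position", (0, 0))
        raise MinimlFormatError(
            f"{source_name}: malformed MINiML XML at line {offset[0]}, "
            f"column {offset[1]}: {exc.msg}"
        ) from exc


def _parse_series(el: etree._Element) -> SeriesRecord:
    accession = _text(_child(el, "Accession")) or el.get("iid", "")
    status = _child(el, "Status")
    submission = _text(_child(status, "Submission-Date")) if status is not None else ""
    release = _text(_child(status, "Release-Date")) if status is not None else ""
    types = [_text(t) for t in _children(el, "Type") if _text(t)]
    sample_refs = [c.get("ref", "") for c in _children(el, "Sample-Ref")]
    return SeriesRecord(
        accession=accession,
        title=_text(_child(el, "Title")),
        summary=_text(_child(el, "Summary")),
        overall_design=_text(_child(el, "Overall-Design")),
        submission_date=submission or None,
        release_date=release or None,
        series_types=types,
        sample_accessions=[r for r in sample_refs if r],
        is_superseries=any("superseries" in t.lower() for t in types),
    )


def _parse_sample(el: etree._Element) -> SampleRecord:
    accession = _text(_child(el, "Accession")) or el.get("iid", "")
    status = _child(el, "Status")
    release = _text(_child(status, "Release-Date")) if status is not None else ""
    channels = _children(el, "Channel")
    count_el = _child(el, "Channel-Count")
    channel_count = int(_text(count_el)) if count_el is not None and _text(count_el) else max(len(channels), 1)

    organism_raw = None
    source_name = ""
    fields: list[CharacteristicField] = []
    if channels:
        # Multi-channel samples: phenotypes are read from channel 1 only;
        # channel_count lets downstream flag these.
        ch = channels[0]
        org = _child(ch, "Organism")
        if org is not None and _text(org):
            organism_raw = _text(org)
            fields.append(
                CharacteristicField("", organism_raw, Origin.organism_element)
            )
        src = _child(ch, "Source")
        if src is not None and _text(src):
            source_name = _text(src)
            fields.append(CharacteristicField("", source_name, Origin.source_element))
        for c in _children(ch, "Characteristics"):
            # Empty tag attributes are kept (tag="") — some submitters put
            # "Sex: F" in the value text.
            fields.append(
                CharacteristicField(
                    c.get("tag", ""), _text(c), Origin.characteristics_element
                )
            )

    title = _text(_child(el, "Title"))
    description = _text(_child(el, "Description"))
    if title:
        fields.append(CharacteristicField("", title, Origin.title))
    if description:
        fields.append(CharacteristicField("", description, Origin.description))

    return SampleRecord(
        accession=accession,
        title=title,
        organism_raw=organism_raw,
        source_name=source_name,
        characteristics=fields,
        description=description,
        library_strategy=_text(_child(el, "Library-Strategy")),
        channel_count=channel_count,
        release_date=release or None,
    )


def parse_miniml(data: bytes, source_name: str = "<bytes>") -> MinimlDocument:
    """Parse MINiML XML bytes into one series plus its samples."""
    root = _parse_xml_bytes(data, source_name)
    series_els = [el for el in root if isinstance(el.tag, str) and _local(el) == "Series"]
    sample_els = [el for el in root if isinstance(el.tag, str) and _local(el) == "Sample"]
    if not series_els:
        raise MinimlFormatError(f"{source_name}: no Series element found")
    if len(series_els) > 1:
        raise MinimlFormatError(
            f"{source_name}: expected one Series element, found {len(series_els)}"
        )
    return MinimlDocument(
        series=_parse_series(series_els[0]),
        samples=[_parse_sample(el) for el in sample_els],
    )


def read_family_archive(path: Union[str, Path]) -> MinimlDocument:
    """Read a family archive (``.tgz``) or a bare ``*_family.xml`` file.

    Decompression is transparent: the ``.tgz`` wrapping and the plain XML
    file yield identical documents.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix in {".tgz", ".gz"} or path.name.endswith(".tar.gz"):
        with tarfile.open(path, "r:gz") as tar:
            members = [
                m for m in tar.getmembers() if m.name.endswith("_family.xml")
            ]
            if not members:
                raise MinimlFormatError(
                    f"{path}: archive contains no *_family.xml member"
                )
            fh = tar.extractfile(members[0])
            assert fh is not None
            data = fh.read()
        return parse_miniml(data, f"{path}::{members[0].name}")
    return parse_miniml(path.read_bytes(), str(path))


def read_corpus(paths: Iterable[Union[str, Path]]) -> list[MinimlDocument]:
    """Read many archives; order of the result follows the input order."""
    return [read_family_archive(p) for p in paths]


def _escape(value: str) -> str:
    return value.replace("\\", "\\\\").replace("|", "\\|").replace("=", "\\=")


def flatten_characteristics(sample: SampleRecord) -> str:
    """Serialize characteristic fields to ``tag=value`` pairs joined by '|'.

    Only entries originating from Characteristics elements are included;
    organism/source/title/description already have dedicated columns.
    """
    pairs = [
        f"{_escape(f.tag)}={_escape(f.value)}"
        for f in sample.characteristics
        if f.origin is Origin.characteristics_element
    ]
    return PAIR_SEP.join(pairs)


def extract_series_table(documents: Sequence[MinimlDocument]) -> pd.DataFrame:
    """One row per series. Duplicate accessions are an error."""
    accs = [d.series.accession for d in documents]
    dupes = sorted({a for a in accs if accs.count(a) > 1})
    if dupes:
        raise ValueError(f"duplicate series accessions: {', '.join(dupes)}")
    rows = []
    for d in documents:
        s = d.series
        rows.append(
            {
                "accession": s.accession,
                "title": s.title,
                "summary": s.summary,
                "overall_design": s.overall_design,
                "submission_date": s.submission_date or "",
                "release_date": s.release_date or "",
                "series_types": "; ".join(s.series_types),
                "sample_accessions": ";".join(s.sample_accessions),
                "is_superseries": s.is_superseries,
            }
        )
    return pd.DataFrame(rows, columns=SERIES_COLUMNS)


def extract_sample_table(documents: Sequence[MinimlDocument]) -> pd.DataFrame:
    """One row per (series, sample) pair.

    A GSM shared by two series yields two rows: accounting is per series.
    """
    rows = []
    for d in documents:
        for s in d.samples:
            rows.append(
                {
                    "series_accession": d.series.accession,
                    "accession": s.accession,
                    "title": s.title,
                    "organism_raw": s.organism_raw or "",
                    "source_name": s.source_name,
                    "characteristics": flatten_characteristics(s),
                    "description": s.description,
                    "library_strategy": s.library_strategy,
                    "channel_count": s.channel_count,
                    "release_date": s.release_date or "",
                }
            )
    return pd.DataFrame(rows, columns=SAMPLE_COLUMNS)


def write_tables(documents: Sequence[MinimlDocument], out_dir: Union[str, Path]) -> tuple[Path, Path]:
    """Write ``series.tsv`` and ``samples.tsv`` (UTF-8, tab-separated)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    series_path = out / "series.tsv"
    samples_path = out / "samples.tsv"
    extract_series_table(documents).to_csv(series_path, sep="\t", index=False)
    extract_sample_table(documents).to_csv(samples_path, sep="\t", index=False)
    return series_path, samples_path
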