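"""Controlled-vocabulary tables driving phenotype detection.

Each audited attribute ships with an editable TSV of rules
(``pattern_type`` ∈ {tag, value}, ``pattern``, ``canonical_label``):

* ``tag`` rows list the characteristic tag names that announce the
  attribute (e.g. ``sex``, ``gender``);
* ``value`` rows are ordered case-insensitive regular expressions mapping
  free-text values to canonical labels (row order is match precedence).

A shared missing-token list holds sentinel strings ("n/a", "not collected",
…) that must never count as information. The bundled tables are miniature
subsets of the vocabularies used for harmonization in the field (NCBI
Taxonomy, Uberon/Cell Ontology, HANCESTRO); they can be extended without
code changes.
"""

from __future__ import annotations

import re
import string
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional, Union

from .records import ATTRIBUTES

_PUNCT_STRIP = string.punctuation + string.whitespace


def _clean_token(value: str) -> str:
    return value.strip(_PUNCT_STRIP).lower()


@dataclass
class AttributeVocabulary:
    """Rule table for one attribute."""

    attribute: str
    tag_synonyms: set[str] = field(default_factory=set)
    value_patterns: list[tuple[re.Pattern, str]] = field(default_factory=list)
    missing_tokens: set[str] = field(default_factory=set)

    def is_missing_token(self, value: str) -> bool:
        """True when the value is a sentinel for absent information."""
        if not value.strip():
            return True
        # check both punctuation-stripped and raw lowercase forms so that
        # bare-punctuation sentinels ('--', '?') are caught
        cleaned = _clean_token(value)
        return (
            cleaned in self.missing_tokens and cleaned != ""
        ) or value.strip().lower() in self.missing_tokens

    def match_value(self, value: str) -> Optional[str]:
        """First value-pattern match wins; returns the canonical label."""
        text = value.strip()
        for pattern, label in self.value_patterns:
            if pattern.search(text):
                return label
        return None


def _load_missing_tokens(path: Optional[Path] = None) -> set[str]:
    if path is None:
        text = (
            resources.files("metacomplete.data")
            .joinpath("missing_tokens.txt")
            .read_text(encoding="utf-8")
        )
    else:
        text = Path(path).read_text(encoding="utf-8")
    tokens = set()
    for line in text.splitlines():
        if line.startswith("#") or not line.strip():
            continue
        tokens.add(_clean_token(line) if _clean_token(line) else line.strip().lower())
    # Bare punctuation sentinels ('-', '--', '?', '.') clean to the empty
    # string; keep their raw lowercase form too.
    for line in text.splitlines():
        if not line.startswith("#") and line.strip():
            tokens.add(line.strip().lower())
    tokens.discard("")
    return tokens


def _load_attribute_table(attribute: str, directory: Optional[Path],
                          missing_tokens: set[str]) -> AttributeVocabulary:
    name = f"{attribute}.tsv"
    if directory is None:
        ref = resources.files("metacomplete.data").joinpath(name)
        text = ref.read_text(encoding="utf-8") if ref.is_file() else ""
    else:
        p = Path(directory) / name
        text = p.read_text(encoding="utf-8") if p.exists() else ""
    vocab = AttributeVocabulary(attribute=attribute, missing_tokens=missing_tokens)
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    for line in lines[1:] if lines else []:  # skip header
        parts = line.split("\t")
        pattern_type = parts[0].strip()
        pattern = parts[1].strip() if len(parts) > 1 else ""
        label = parts[2].strip() if len(parts) > 2 else ""
        if pattern_type == "tag":
            vocab.tag_synonyms.add(pattern.lower())
        elif pattern_type == "value":
            vocab.value_patterns.append(
                (re.compile(pattern, re.IGNORECASE), label or pattern)
            )
        else:
            raise ValueError(
                f"{name}: unknown pattern_type {pattern_type!r} (expected tag|value)"
            )
    return vocab


class VocabularySet:
    """All six attribute vocabularies plus the shared missing-token list."""

    def __init__(self, directory: Optional[Union[str, Path]] = None):
        directory = Path(directory) if directory is not None else None
        missing_path = directory / "missing_tokens.txt" if directory else None
        if missing_path is not None and not missing_path.exists():
            missing_path = None
        self.missing_tokens = _load_missing_tokens(missing_path)
        self.by_attribute: dict[str, AttributeVocabulary] = {
            attr: _load_attribute_table(attr, directory, self.missing_tokens)
            for attr in ATTRIBUTES
        }

    def __getitem__(self, attribute: str) -> AttributeVocabulary:
        return self.by_attribute[attribute]


_default: Optional[VocabularySet] = None


def default_vocabulary() -> VocabularySet:
    """The bundled vocabulary set (cached)."""
    global _default
    if _default is None:
        _default = VocabularySet()
    return _default
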