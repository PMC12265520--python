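"""Comparing repository-derived availability with publication-text curation.

The text of a publication is audited by hand (reading the main text and
supplements); the product of that curation enters the pipeline as a
delimited table of :class:`CurationRecord` rows. Study-scope rows expand to
every sample of the study at the stated level; sample-scope rows address one
sample. The cross-source statistics then classify each applicable
(sample, attribute) cell as available in both sources, only in the
repository, only in the text, or neither.

Experiment-level availability counts as "available" for the comparison;
the experiment-only share is reported separately by the completeness module.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd

from .completeness import MATRIX_COLUMNS, Level, Source, StudyScore
from .records import ATTRIBUTES


class Consistency(str, Enum):
    equal = "equal"
    text_lower = "text_lower"
    text_higher = "text_higher"


class Category(str, Enum):
    both = "both"
    text_only = "text_only"
    repo_only = "repo_only"
    neither = "neither"
    not_applicable = "not_applicable"


@dataclass(frozen=True)
class CurationRecord:
    """One manually curated availability statement."""

    study: str
    scope: str  # "study" | "sample"
    sample: Optional[str]
    attribute: str
    level: str
    value: str = ""
    disease_label: str = ""

    def __post_init__(self) -> None:
        if self.scope not in ("study", "sample"):
            raise ValueError(f"scope must be study|sample, got {self.scope!r}")
        if self.scope == "sample" and not self.sample:
            raise ValueError("sample-scope record requires a sample accession")
        if self.attribute not in ATTRIBUTES:
            raise ValueError(f"unknown attribute {self.attribute!r}")
        valid = {Level.sample_level.value, Level.experiment_level.value, Level.missing.value}
        if self.level not in valid:
            raise ValueError(f"unknown level {self.level!r}; expected one of {sorted(valid)}")


CURATION_COLUMNS = [
    "study_accession",
    "scope",
    "sample_accession",
    "attribute",
    "level",
    "value",
    "disease_label",
]


def load_curation_table(path: Union[str, Path]) -> list[CurationRecord]:
    """Read a curation TSV; validation failures name the offending line."""
    records = []
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        missing_cols = set(CURATION_COLUMNS[:5]) - set(reader.fieldnames or [])
        if missing_cols:
            raise ValueError(f"{path}: missing columns {sorted(missing_cols)}")
        for lineno, row in enumerate(reader, start=2):
            try:
                records.append(
                    CurationRecord(
                        study=row["study_accession"].strip(),
                        scope=row["scope"].strip(),
                        sample=(row.get("sample_accession") or "").strip() or None,
                        attribute=row["attribute"].strip(),
                        level=row["level"].strip(),
                        value=(row.get("value") or "").strip(),
                        disease_label=(row.get("disease_label") or "").strip(),
                    )
                )
            except ValueError as exc:
                raise ValueError(f"{path}, line {lineno}: {exc}") from exc
    return records


def write_curation_table(records: Sequence[CurationRecord], path: Union[str, Path]) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(CURATION_COLUMNS)
        for r in records:
            writer.writerow(
                [r.study, r.scope, r.sample or "", r.attribute, r.level, r.value, r.disease_label]
            )


def curation_to_matrix(
    records: Sequence[CurationRecord], repo_matrix: pd.DataFrame
) -> pd.DataFrame:
    """Expand curation records into a publication-text availability slice.

    The repository matrix supplies the cell universe (which samples exist,
    which attributes are applicable); curation supplies the levels. Cells
    without any curation statement are missing — an empty table means the
    text source contributed nothing.
    """
    repo = repo_matrix[repo_matrix["source"] == Source.repository.value]
    text = repo.copy()
    text["source"] = Source.publication_text.value
    # start from all-missing, preserving not_applicable
    text.loc[text["level"] != Level.not_applicable.value, "level"] = Level.missing.value
    text = text.set_index(["study", "sample", "attribute"])

    for rec in records:
        if rec.scope == "study":
            mask = [
                idx
                for idx in text.index
                if idx[0] == rec.study and idx[2] == rec.attribute
            ]
        else:
            mask = [
                idx
                for idx in text.index
                if idx[0] == rec.study and idx[1] == rec.sample and idx[2] == rec.attribute
            ]
        for idx in mask:
            if text.at[idx, "level"] != Level.not_applicable.value:
                text.at[idx, "level"] = rec.level
    return text.reset_index()[MATRIX_COLUMNS]


def disease_labels(records: Sequence[CurationRecord]) -> dict[str, str]:
    """Study → disease label mapping from curation rows that carry one."""
    labels: dict[str, str] = {}
    for rec in records:
        if rec.disease_label:
            labels[rec.study] = rec.disease_label
    return labels


def categorize_sources(
    repo_matrix: pd.DataFrame, text_matrix: pd.DataFrame
) -> pd.DataFrame:
    """Cell-wise source category grid.

    Availability means level ≠ missing. Output columns: study, sample,
    attribute, category.
    """
    def _one_source(m: pd.DataFrame, name: str) -> pd.DataFrame:
        cols = m.drop(columns=["source"]) if "source" in m.columns else m.copy()
        return cols.rename(columns={"level": name})

    repo = _one_source(repo_matrix, "repo_level")
    text = _one_source(text_matrix, "text_level")
    merged = repo.merge(text, on=["study", "sample", "attribute"], how="outer")
    if merged["repo_level"].isna().any() or merged["text_level"].isna().any():
        raise ValueError("matrices are misaligned on (study, sample, attribute)")

    na = Level.not_applicable.value
    miss = Level.missing.value

    def _cat(row) -> str:
        if row["repo_level"] == na or row["text_level"] == na:
            if row["repo_level"] != row["text_level"]:
                raise ValueError(
                    f"not_applicable differs across sources for "
                    f"{row['study']}/{row['sample']}/{row['attribute']}"
                )
            return Category.not_applicable.value
        in_repo = row["repo_level"] != miss
        in_text = row["text_level"] != miss
        if in_repo and in_text:
            return Category.both.value
        if in_repo:
            return Category.repo_only.value
        if in_text:
            return Category.text_only.value
        return Category.neither.value

    merged["category"] = merged.apply(_cat, axis=1)
    return merged[["study", "sample", "attribute", "category"]]


def category_counts(grid: pd.DataFrame) -> dict[str, int]:
    counts = grid["category"].value_counts().to_dict()
    return {c.value: int(counts.get(c.value, 0)) for c in Category}


def study_consistency(repo_score: StudyScore, text_score: StudyScore) -> Consistency:
    """Compare pooled availability across sources with exact rational
    arithmetic on the backing cell counts (no float equality)."""
    if repo_score.study != text_score.study:
        raise ValueError("scores refer to different studies")
    lhs = text_score.available_cells * repo_score.applicable_cells
    rhs = repo_score.available_cells * text_score.applicable_cells
    if lhs == rhs:
        return Consistency.equal
    return Consistency.text_lower if lhs < rhs else Consistency.text_higher
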