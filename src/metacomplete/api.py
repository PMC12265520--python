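"""End-to-end audit orchestration: parse → detect → score → compare → report.

This is the library face of the pipeline; the command-line interface is a
thin wrapper around :func:`audit_corpus` and :func:`audit_paths`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import pandas as pd

from . import miniml_io, source_compare, stratify_report
from .completeness import (
    Claim,
    DatasetSummary,
    Source,
    StudyScore,
    apply_experiment_level,
    build_matrix,
    dataset_summary,
    study_scores,
)
from .phenotype_detect import PhenotypeProfile, annotate_sample
from .records import MinimlDocument
from .source_compare import Consistency, CurationRecord
from .vocab import VocabularySet, default_vocabulary

logger = logging.getLogger(__name__)


@dataclass
class AuditResult:
    """Everything the audit computes for one corpus."""

    documents: list[MinimlDocument]
    profiles: dict[str, list[PhenotypeProfile]]
    matrix: pd.DataFrame
    summaries: dict[str, DatasetSummary]
    scores: dict[str, list[StudyScore]]
    year_series: list[stratify_report.YearSeries] = field(default_factory=list)
    category_counts: dict[str, int] = field(default_factory=dict)
    consistency_counts: dict[str, int] = field(default_factory=dict)
    disease_summaries: dict[str, DatasetSummary] = field(default_factory=dict)
    excluded_superseries: list[str] = field(default_factory=list)
    excluded_no_date: list[str] = field(default_factory=list)
    log: list[str] = field(default_factory=list)

    @property
    def has_text_source(self) -> bool:
        return Source.publication_text.value in set(self.matrix.get("source", ()))


def load_claims(path: Union[str, Path]) -> dict[str, list[Claim]]:
    """Read a study-claims TSV (study_accession, attribute, value, uniform)."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    claims: dict[str, list[Claim]] = {}
    for _, row in df.iterrows():
        uniform = str(row["uniform"]).strip().lower() in ("true", "1", "yes")
        claims.setdefault(row["study_accession"], []).append(
            Claim(attribute=row["attribute"], value=row["value"], uniform=uniform)
        )
    return claims


def audit_corpus(
    documents: Sequence[MinimlDocument],
    curation: Sequence[CurationRecord] = (),
    claims: Optional[dict[str, list[Claim]]] = None,
    vocab: Optional[VocabularySet] = None,
    include_superseries: bool = False,
    share_threshold: float = 0.0,
    scan_series_text: bool = True,
) -> AuditResult:
    """Run detection and scoring over parsed documents.

    SuperSeries are excluded by default: their samples duplicate those of
    their sub-series and would be double-counted.
    """
    vocab = vocab or default_vocabulary()
    claims = claims or {}
    log: list[str] = []

    kept: list[MinimlDocument] = []
    excluded_super = []
    for doc in documents:
        if doc.series.is_superseries and not include_superseries:
            excluded_super.append(doc.accession)
            log.append(f"excluded SuperSeries {doc.accession}")
        else:
            kept.append(doc)

    profiles: dict[str, list[PhenotypeProfile]] = {}
    slices = []
    for doc in kept:
        study_profiles = [annotate_sample(s, vocab) for s in doc.samples]
        profiles[doc.accession] = study_profiles
        slices.append(
            apply_experiment_level(
                study_profiles,
                doc.series,
                claims.get(doc.accession, ()),
                source=Source.repository,
                scan_series_text=scan_series_text,
            )
        )
    repo_matrix = build_matrix(slices)

    matrix = repo_matrix
    category_counts: dict[str, int] = {}
    consistency_counts: dict[str, int] = {}
    if len(curation) and len(repo_matrix):
        text_matrix = source_compare.curation_to_matrix(curation, repo_matrix)
        matrix = pd.concat([repo_matrix, text_matrix], ignore_index=True)
        grid = source_compare.categorize_sources(repo_matrix, text_matrix)
        category_counts = source_compare.category_counts(grid)
        repo_by_study = {s.study: s for s in study_scores(matrix, "repository", share_threshold)}
        text_by_study = {
            s.study: s for s in study_scores(matrix, "publication_text", share_threshold)
        }
        consistency_counts = {c.value: 0 for c in Consistency}
        for study, rscore in repo_by_study.items():
            verdict = source_compare.study_consistency(rscore, text_by_study[study])
            consistency_counts[verdict.value] += 1
    elif not len(curation):
        log.append("no curation table: source-comparison outputs omitted")
        logger.warning("no curation table supplied; skipping source comparison")

    selectors = ["repository"]
    if len(curation) and len(repo_matrix):
        selectors += ["publication_text", "either"]
    summaries = {
        sel: dataset_summary(matrix, sel, share_threshold) if len(matrix) else
        dataset_summary(matrix.reindex(columns=matrix.columns), "repository")
        for sel in selectors
    } if len(matrix) else {"repository": _empty_summary()}
    scores = {
        sel: study_scores(matrix, sel, share_threshold) if len(matrix) else []
        for sel in selectors
    }

    year_series: list[stratify_report.YearSeries] = []
    excluded_no_date: list[str] = []
    if len(matrix):
        year_series, excluded_no_date = stratify_report.cumulative_by_year(
            matrix, [d.series for d in kept], "repository"
        )
        for acc in excluded_no_date:
            log.append(f"excluded from year series (no release date): {acc}")

    disease_summaries: dict[str, DatasetSummary] = {}
    labels = source_compare.disease_labels(curation)
    if labels and len(matrix):
        disease_summaries = stratify_report.group_summary(matrix, labels, "repository")

    return AuditResult(
        documents=kept,
        profiles=profiles,
        matrix=matrix,
        summaries=summaries,
        scores=scores,
        year_series=year_series,
        category_counts=category_counts,
        consistency_counts=consistency_counts,
        disease_summaries=disease_summaries,
        excluded_superseries=excluded_super,
        excluded_no_date=excluded_no_date,
        log=log,
    )


def _empty_summary() -> DatasetSummary:
    return DatasetSummary(
        source="repository",
        n_studies=0,
        n_samples=0,
        overall_availability=0.0,
        per_attribute={},
        bracket_distribution={},
        experiment_only_share=0.0,
        available_cells=0,
        applicable_cells=0,
    )


def audit_paths(
    paths: Iterable[Union[str, Path]],
    curation_path: Optional[Union[str, Path]] = None,
    claims_path: Optional[Union[str, Path]] = None,
    **kwargs,
) -> AuditResult:
    """Parse family archives / XML files from disk and audit them."""
    documents = miniml_io.read_corpus(paths)
    curation = (
        source_compare.load_curation_table(curation_path) if curation_path else ()
    )
    claims = load_claims(claims_path) if claims_path else None
    return audit_corpus(documents, curation=curation, claims=claims, **kwargs)


def write_audit_report(result: AuditResult, out_dir: Union[str, Path]) -> dict[str, Path]:
    """Serialize an audit result via :mod:`.stratify_report`."""
    primary = result.summaries.get("either") or result.summaries["repository"]
    extra_log = list(result.log)
    if result.category_counts:
        extra_log.append(f"source categories: {result.category_counts}")
    if result.consistency_counts:
        extra_log.append(f"study consistency: {result.consistency_counts}")
    selector = "either" if "either" in result.summaries else "repository"
    return stratify_report.write_report(
        primary,
        out_dir,
        scores=result.scores.get(selector),
        year_series=result.year_series,
        group_summaries=result.disease_summaries or None,
        audit_log=extra_log,
    )
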