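"""Temporal, disease and organism stratification, plus report serialization.

The study year is taken from the series *release* date (public availability,
not submission). Cumulative availability at year *y* pools all applicable
cells of studies released in or before *y*, so the final row of the year
series reproduces the dataset summary.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd

from .completeness import (
    DatasetSummary,
    Level,
    StudyScore,
    _summarize,
    dataset_summary,
    select_source,
    study_scores,
)
from .phenotype_detect import Status
from .records import SeriesRecord

SCHEMA_VERSION = "1.0"


@dataclass
class YearSeries:
    year: int
    cumulative_availability: float
    n_studies: int


def release_years(series_records: Sequence[SeriesRecord]) -> tuple[dict[str, int], list[str]]:
    """Study → release year; studies without a release date are excluded
    and returned separately for the exclusion log."""
    years: dict[str, int] = {}
    excluded: list[str] = []
    for s in series_records:
        if s.release_date:
            years[s.accession] = int(str(s.release_date)[:4])
        else:
            excluded.append(s.accession)
    return years, excluded


def cumulative_by_year(
    matrix: pd.DataFrame,
    series_records: Sequence[SeriesRecord],
    selector: str = "repository",
) -> tuple[list[YearSeries], list[str]]:
    """Cumulative pooled availability over release years.

    Returns the year series plus the accessions excluded for missing dates.
    """
    years, excluded = release_years(series_records)
    view = select_source(matrix, selector)
    view = view[view["study"].isin(years)]
    if view.empty:
        return [], excluded
    view = view.assign(year=view["study"].map(years))
    applicable = view[view["level"] != Level.not_applicable.value]
    out = []
    for year in sorted(applicable["year"].unique()):
        upto = applicable[applicable["year"] <= year]
        avail = (upto["level"] != Level.missing.value).mean()
        n_studies = upto["study"].nunique()
        out.append(YearSeries(int(year), float(avail), int(n_studies)))
    return out, excluded


def group_summary(
    matrix: pd.DataFrame,
    groups: dict[str, str],
    selector: str = "repository",
    min_group_size: int = 1,
) -> dict[str, DatasetSummary]:
    """One DatasetSummary per group (disease label, organism, …).

    ``groups`` maps study accession → group label; studies without a label
    are ignored. Groups below ``min_group_size`` studies are still computed
    but flagged by name suffix in the caller's report.
    """
    view = select_source(matrix, selector)
    scores = {s.study: s for s in study_scores(matrix, selector)}
    out: dict[str, DatasetSummary] = {}
    for label in sorted(set(groups.values())):
        studies = {acc for acc, lab in groups.items() if lab == label}
        sub_view = view[view["study"].isin(studies)]
        if sub_view.empty:
            continue
        sub_scores = [scores[a] for a in studies if a in scores]
        if len(sub_scores) < min_group_size:
            continue
        out[label] = _summarize(sub_view, sub_scores, selector)
    return out


def organism_groups(profiles_by_study: dict[str, Sequence]) -> dict[str, str]:
    """Study → modal detected organism label (for per-organism stratification)."""
    groups = {}
    for study, profiles in profiles_by_study.items():
        counts: dict[str, int] = {}
        for p in profiles:
            det = p.detections.get("organism")
            if det is not None and det.status is Status.available:
                counts[det.normalized_value] = counts.get(det.normalized_value, 0) + 1
        if counts:
            groups[study] = max(sorted(counts), key=counts.get)
    return groups


def _summary_dict(s: DatasetSummary) -> dict:
    d = dataclasses.asdict(s)
    d["bracket_distribution"] = {str(k): v for k, v in s.bracket_distribution.items()}
    d["groups"] = {name: _summary_dict(g) for name, g in s.groups.items()}
    return d


def write_report(
    summary: DatasetSummary,
    out_dir: Union[str, Path],
    scores: Optional[Sequence[StudyScore]] = None,
    year_series: Optional[Sequence[YearSeries]] = None,
    group_summaries: Optional[dict[str, DatasetSummary]] = None,
    audit_log: Sequence[str] = (),
) -> dict[str, Path]:
    """Write ``summary.json`` plus per-study / per-year / per-group TSVs and
    a plain-text audit log. Returns the paths written."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    payload = {"schema_version": SCHEMA_VERSION, "summary": _summary_dict(summary)}
    p = out / "summary.json"
    p.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n", encoding="utf-8")
    written["summary"] = p

    if scores is not None:
        rows = []
        for s in scores:
            row = {
                "study": s.study,
                "is_human": s.is_human,
                "n_samples": s.n_samples,
                "phenotypes_shared": s.phenotypes_shared,
                "bracket": s.bracket,
                "pooled_availability": s.pooled_availability,
                "experiment_only_fraction": s.experiment_only_fraction,
            }
            for attr, frac in s.per_attribute.items():
                row[f"avail_{attr}"] = frac
            rows.append(row)
        p = out / "study_scores.tsv"
        pd.DataFrame(rows).to_csv(p, sep="\t", index=False)
        written["study_scores"] = p

    if year_series is not None:
        p = out / "by_year.tsv"
        pd.DataFrame([dataclasses.asdict(y) for y in year_series]).to_csv(
            p, sep="\t", index=False
        )
        written["by_year"] = p

    if group_summaries is not None:
        rows = []
        for label, g in sorted(group_summaries.items()):
            row = {
                "group": label,
                "n_studies": g.n_studies,
                "n_samples": g.n_samples,
                "overall_availability": g.overall_availability,
                "applicable_cells": g.applicable_cells,
            }
            for attr, frac in g.per_attribute.items():
                row[f"avail_{attr}"] = frac
            rows.append(row)
        p = out / "by_group.tsv"
        pd.DataFrame(rows).to_csv(p, sep="\t", index=False)
        written["by_group"] = p

    p = out / "audit.log"
    p.write_text("\n".join(audit_log) + ("\n" if audit_log else ""), encoding="utf-8")
    written["audit_log"] = p
    return written


def read_report(out_dir: Union[str, Path]) -> dict:
    """Round-trip reader for ``summary.json``."""
    return json.loads((Path(out_dir) / "summary.json").read_text(encoding="utf-8"))
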