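from fractions import Fraction

import pandas as pd
import pytest

from metacomplete.completeness import (
    Claim,
    Level,
    Source,
    applicable_attributes,
    apply_experiment_level,
    build_matrix,
    dataset_summary,
    select_source,
    study_score,
)
from metacomplete.miniml_io import parse_miniml
from metacomplete.phenotype_detect import annotate_sample
from metacomplete.records import ATTRIBUTES
from metacomplete.synth import make_fixture

from .oracle import (
    either_availability,
    per_attribute_availability,
    pooled_availability,
    study_brackets,
)


def profiles_and_series(fixture_name):
    doc = parse_miniml(make_fixture(fixture_name).encode())
    return [annotate_sample(s) for s in doc.samples], doc.series


def matrix_cells(matrix: pd.DataFrame):
    return list(matrix.itertuples(index=False, name=None))


class TestApplicableAttributes:
    def test_human_set(self):
        assert applicable_attributes(True) == {"organism", "tissue", "sex", "age", "rea"}

    def test_nonhuman_set(self):
        assert applicable_attributes(False) == {
            "organism", "tissue", "sex", "age", "strain",
        }

    def test_shared_core(self):
        both = applicable_attributes(True) & applicable_attributes(False)
        assert both == {"organism", "tissue", "sex", "age"}
        assert len(applicable_attributes(True)) == len(applicable_attributes(False)) == 5


class TestExperimentLevel:
    def test_no_claims_is_identity(self):
        profiles, series = profiles_and_series("clean_human")
        m = apply_experiment_level(profiles, series, scan_series_text=False)
        assert set(m["level"]) == {Level.sample_level.value, Level.not_applicable.value}

    def test_uniform_claim_upgrades_missing_to_sample_level(self):
        profiles, series = profiles_and_series("uniform_claim_female")
        # the fixture's summary carries "All samples were female."
        m = apply_experiment_level(profiles, series)
        sex = m[m["attribute"] == "sex"]
        assert (sex["level"] == Level.sample_level.value).all()

    def test_without_text_scan_sex_stays_missing(self):
        profiles, series = profiles_and_series("uniform_claim_female")
        m = apply_experiment_level(profiles, series, scan_series_text=False)
        sex = m[m["attribute"] == "sex"]
        assert (sex["level"] == Level.missing.value).all()

    def test_summary_claim_marks_experiment_level(self):
        profiles, series = profiles_and_series("all_missing_tokens")
        m = apply_experiment_level(
            profiles, series, claims=[Claim("sex", uniform=False)]
        )
        sex = m[m["attribute"] == "sex"]
        assert (sex["level"] == Level.experiment_level.value).all()

    def test_claims_never_downgrade_detections(self):
        profiles, series = profiles_and_series("clean_human")
        m = apply_experiment_level(
            profiles, series, claims=[Claim("sex", uniform=False)]
        )
        sex = m[m["attribute"] == "sex"]
        assert (sex["level"] == Level.sample_level.value).all()

    def test_unknown_attribute_claim_rejected(self):
        with pytest.raises(ValueError, match="weight"):
            Claim("weight", uniform=True)


class TestStudyScore:
    def test_fixture_bracket_three_of_five(self):
        # organism+tissue+sex shared, age+rea missing -> 3 phenotypes, 60%
        profiles, series = profiles_and_series("clean_human")
        m = apply_experiment_level(profiles, series)
        m.loc[m["attribute"].isin(["age", "rea"]), "level"] = Level.missing.value
        score = study_score(select_source(m, "repository"))
        assert score.phenotypes_shared == 3
        assert score.bracket == 60

    def test_full_study_bracket_100(self):
        profiles, series = profiles_and_series("clean_human")
        m = apply_experiment_level(profiles, series)
        score = study_score(select_source(m, "repository"))
        assert score.bracket == 100
        assert score.pooled_availability == 1.0
        assert score.is_human

    def test_pooled_availability_arithmetic(self):
        # 3 samples x 5 applicable attributes, 9 non-missing -> 0.6
        profiles, series = profiles_and_series("clean_human")
        m = apply_experiment_level(profiles, series)
        view = select_source(m, "repository")
        applicable = view[view["level"] != Level.not_applicable.value].copy()
        applicable["level"] = Level.missing.value
        applicable.iloc[:9, applicable.columns.get_loc("level")] = (
            Level.sample_level.value
        )
        score = study_score(applicable)
        assert score.pooled_availability == pytest.approx(0.6)

    def test_empty_study_rejected(self):
        with pytest.raises(ValueError):
            study_score(pd.DataFrame(columns=["study", "sample", "attribute", "level"]))

    def test_share_threshold_variant(self):
        profiles, series = profiles_and_series("clean_human")
        m = apply_experiment_level(profiles, series)
        view = select_source(m, "repository")
        # make sex available for exactly 1 of 3 samples
        sex_idx = view[view["attribute"] == "sex"].index
        view.loc[sex_idx[1:], "level"] = Level.missing.value
        assert study_score(view).phenotypes_shared == 5
        assert study_score(view, share_threshold=0.5).phenotypes_shared == 4


class TestSelectSource:
    def test_either_takes_best_level(self):
        rows = []
        for src, level in [
            ("repository", "missing"),
            ("publication_text", "sample_level"),
        ]:
            rows.append(("GSE1", "GSM1", "sex", src, level))
        m = pd.DataFrame(rows, columns=["study", "sample", "attribute", "source", "level"])
        either = select_source(m, "either")
        assert either["level"].iloc[0] == "sample_level"

    def test_union_monotonicity_on_fixture(self, clean_corpus):
        corpus, docs, claims = clean_corpus
        from metacomplete import audit_corpus

        res = audit_corpus(docs, curation=corpus.curation_records, claims=claims)
        either = res.summaries["either"].overall_availability
        repo = res.summaries["repository"].overall_availability
        text = res.summaries["publication_text"].overall_availability
        assert either >= max(repo, text) >= 0


class TestDatasetSummaryOracle:
    """Brute-force cell-counting oracle equivalence on small matrices."""

    @pytest.mark.parametrize("n_studies,seed", [(1, 0), (2, 1), (3, 2), (4, 3)])
    def test_matches_brute_force(self, n_studies, seed):
        from metacomplete import audit_corpus
        from metacomplete.synth import SyntheticConfig, generate_corpus

        from .conftest import corpus_and_claims

        corpus, docs, claims = corpus_and_claims(
            n_studies=n_studies, seed=seed, samples_min=2, samples_max=5,
            messy_token_prob=0.2,
        )
        res = audit_corpus(docs, curation=corpus.curation_records, claims=claims)
        cells = matrix_cells(res.matrix)

        for selector in ("repository", "publication_text"):
            summary = res.summaries[selector]
            want = pooled_availability(cells, selector)
            assert Fraction(summary.available_cells, summary.applicable_cells) == want
            per_attr = per_attribute_availability(cells, selector)
            for attr, frac in summary.per_attribute.items():
                assert frac == pytest.approx(float(per_attr[attr]))
            brackets = study_brackets(cells, selector)
            got_brackets = {s.study: s.bracket for s in res.scores[selector]}
            assert got_brackets == brackets

        either = res.summaries["either"]
        assert Fraction(either.available_cells, either.applicable_cells) == (
            either_availability(cells)
        )

    def test_bracket_distribution_sums_to_one(self, clean_corpus):
        corpus, docs, claims = clean_corpus
        from metacomplete import audit_corpus

        res = audit_corpus(docs, claims=claims)
        dist = res.summaries["repository"].bracket_distribution
        assert sum(dist.values()) == pytest.approx(1.0)

    def test_organism_always_available_and_bracket_at_least_20(self, clean_corpus):
        corpus, docs, claims = clean_corpus
        from metacomplete import audit_corpus

        res = audit_corpus(docs, claims=claims)
        assert res.summaries["repository"].per_attribute["organism"] == 1.0
        assert all(s.bracket >= 20 for s in res.scores["repository"])

    def test_group_availabilities_reconstruct_overall(self, clean_corpus):
        corpus, docs, claims = clean_corpus
        from metacomplete import audit_corpus

        res = audit_corpus(docs, claims=claims)
        summary = res.summaries["repository"]
        weighted = sum(
            g.overall_availability * g.applicable_cells
            for g in summary.groups.values()
        )
        cells = sum(g.applicable_cells for g in summary.groups.values())
        assert cells == summary.applicable_cells
        assert weighted / cells == pytest.approx(summary.overall_availability)

    def test_single_study_summary_equals_its_score(self):
        from metacomplete import audit_corpus

        profiles, series = profiles_and_series("clean_human")
        m = apply_experiment_level(profiles, series)
        score = study_score(select_source(build_matrix([m]), "repository"))
        summary = dataset_summary(build_matrix([m]), "repository")
        assert summary.overall_availability == pytest.approx(score.pooled_availability)
        assert summary.bracket_distribution == {score.bracket: 1.0}

    def test_duplicate_cells_rejected(self):
        profiles, series = profiles_and_series("clean_human")
        m = apply_experiment_level(profiles, series)
        with pytest.raises(ValueError, match="duplicate"):
            build_matrix([m, m])
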