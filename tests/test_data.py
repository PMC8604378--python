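import math
import textwrap

import pytest

from combimeta import (
    COMORBIDITIES,
    ComorbidityDataset,
    SchemaError,
    StudyEffect,
    TwoByTwo,
    ValidationError,
    read_studies,
    write_studies,
)


def _write(tmp_path, text, name="studies.csv"):
    path = tmp_path / name
    path.write_text(textwrap.dedent(text))
    return path


class TestReadEffects:
    def test_two_row_csv_gives_one_dataset(self, tmp_path):
        path = _write(
            tmp_path,
            """\
            comorbidity,study_label,year,country,sample_size,outcome_type,log_or,se
            diabetes,A,2020,UK,100,mortality,1.2,0.4
            diabetes,B,2021,US,50,hospitalization,0.3,0.9
            """,
        )
        datasets = read_studies(path, schema="effects")
        assert len(datasets) == 1
        ds = datasets[0]
        assert ds.name == "diabetes" and ds.k == 2
        assert ds[0].study_label == "A" and ds[0].y == 1.2 and ds[0].sigma == 0.4
        assert ds[1].outcome_type == "hospitalization"

    def test_missing_column_names_it(self, tmp_path):
        path = _write(tmp_path, "comorbidity,study_label,log_or\nx,A,1.0\n")
        with pytest.raises(SchemaError, match="'se'"):
            read_studies(path, schema="effects")

    def test_nonpositive_sigma_reports_row(self, tmp_path):
        path = _write(
            tmp_path,
            """\
            comorbidity,study_label,log_or,se
            x,A,1.0,0.5
            x,B,1.0,0.0
            """,
        )
        with pytest.raises(ValidationError, match="row 3"):
            read_studies(path, schema="effects")

    def test_optional_metadata_may_be_absent(self, tmp_path):
        path = _write(tmp_path, "comorbidity,study_label,log_or,se\nx,A,1.0,0.5\n")
        (ds,) = read_studies(path)
        assert ds[0].year is None and ds[0].country is None


class TestReadCounts:
    def test_effects_recomputed_from_counts(self, tmp_path):
        path = _write(
            tmp_path,
            """\
            comorbidity,study_label,events_exposed,nonevents_exposed,events_comparator,nonevents_comparator
            x,A,20,80,10,90
            """,
        )
        (ds,) = read_studies(path, schema="counts")
        assert ds[0].y == pytest.approx(math.log(2.25))
        assert ds[0].sigma == pytest.approx(math.sqrt(1 / 20 + 1 / 80 + 1 / 10 + 1 / 90))
        assert ds[0].sample_size == 200  # defaults to the table total
        assert ds[0].counts == TwoByTwo(20, 80, 10, 90)

    def test_missing_count_column(self, tmp_path):
        path = _write(
            tmp_path,
            "comorbidity,study_label,events_exposed,nonevents_exposed,events_comparator\nx,A,1,2,3\n",
        )
        with pytest.raises(SchemaError, match="nonevents_comparator"):
            read_studies(path, schema="counts")


class TestRoundTrip:
    def test_effects_round_trip_is_lossless(self, reference, tmp_path):
        path = tmp_path / "ref.csv"
        write_studies(list(reference.values()), path)
        reread = {ds.name: ds for ds in read_studies(path)}
        assert list(reread) == list(reference)
        for name, ds in reference.items():
            other = reread[name]
            assert other.labels == ds.labels
            for a, b in zip(ds, other):
                assert a.y == b.y and a.sigma == b.sigma
                assert (a.year, a.country, a.sample_size, a.outcome_type) == (
                    b.year,
                    b.country,
                    b.sample_size,
                    b.outcome_type,
                )

    def test_counts_round_trip(self, tmp_path):
        studies = tuple(
            StudyEffect.from_counts(label, counts)
            for label, counts in [("A", TwoByTwo(5, 15, 2, 18)), ("B", TwoByTwo(0, 9, 3, 7))]
        )
        ds = ComorbidityDataset(name="x", studies=studies)
        path = tmp_path / "counts.csv"
        write_studies([ds], path, schema="counts")
        (reread,) = read_studies(path, schema="counts")
        for a, b in zip(ds, reread):
            assert a.counts == b.counts and a.y == b.y and a.sigma == b.sigma

    def test_counts_schema_requires_counts(self, reference, tmp_path):
        with pytest.raises(ValidationError, match="counts"):
            write_studies([reference["diabetes"]], tmp_path / "x.csv", schema="counts")


class TestValidation:
    def test_counts_must_match_stored_effect(self):
        with pytest.raises(ValidationError, match="recomputed"):
            StudyEffect(study_label="A", y=0.0, sigma=1.0, counts=TwoByTwo(20, 80, 10, 90))

    def test_duplicate_labels_rejected(self):
        s = StudyEffect(study_label="A", y=0.0, sigma=1.0)
        with pytest.raises(ValidationError, match="duplicate"):
            ComorbidityDataset(name="x", studies=(s, s))

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValidationError, match="no studies"):
            ComorbidityDataset(name="x", studies=())

    def test_unknown_outcome_type_rejected(self):
        with pytest.raises(ValidationError, match="outcome_type"):
            StudyEffect(study_label="A", y=0.0, sigma=1.0, outcome_type="icu")


class TestEmbeddedDatasets:
    def test_dataset_sizes(self, reference):
        sizes = {name: ds.k for name, ds in reference.items()}
        assert sizes == {
            "diabetes": 9,
            "hypertension": 8,
            "cardiovascular_disease": 6,
            "respiratory_disease": 6,
            "chronic_kidney_disease": 5,
        }
        assert tuple(reference) == COMORBIDITIES

    def test_spot_values(self, reference):
        diabetes = reference["diabetes"]
        assert diabetes[0].study_label == "Bhaskaran"
        assert diabetes[0].y == 3.63
        assert diabetes[0].variance == pytest.approx(0.57)
        assert diabetes[1].variance == pytest.approx(0.04)  # the most precise study
        rd = reference["respiratory_disease"]
        assert rd[1].study_label == "Dandachi"
        assert rd[1].variance == pytest.approx(0.22)
        ckd = reference["chronic_kidney_disease"]
        assert ckd[-1].study_label == "Meyerowitz"
        assert ckd[-1].variance == pytest.approx(1.45)

    def test_all_sigmas_positive_and_labels_unique(self, reference):
        for ds in reference.values():
            assert all(s.sigma > 0 for s in ds)
            assert len(set(ds.labels)) == ds.k

    def test_effects_consistent_with_published_study_intervals(self, reference):
        # transcription check: every stored (y, sigma) reproduces the
        # published per-study 95% CI within rounding of the published values
        from combimeta import published_study_intervals

        intervals = published_study_intervals()
        for name, ds in reference.items():
            for study, (lo, hi) in zip(ds, intervals[name]):
                assert study.y == pytest.approx((lo + hi) / 2, abs=0.011)
                assert 1.96 * study.sigma == pytest.approx((hi - lo) / 2, abs=0.02)
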