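"""Lead-time analysis and cohort summaries on the packaged relapse cohort."""

import statistics

import pytest
from hypothesis import given
from hypothesis import strategies as st

from ctdnakit.clinical_monitoring import (
    LongitudinalSample,
    PatientSeries,
    accumulation_rate,
    cohort_summary,
    first_positive_day,
    lead_time,
    load_retrospective_cohort,
    read_patient_table,
)
from ctdnakit.core_model import MarkerSpec, ReadCounts
from ctdnakit.synthetic_data import SimConfig, simulate_patient_series


def vaf_sample(day, vaf_pct, marker_id="m", total=100_000):
    alt = round(vaf_pct / 100 * total)
    return LongitudinalSample(day=day, counts={marker_id: [ReadCounts(marker_id, 0, alt, total)]})


def series_from_vafs(pairs, imaging_day=None, marker_id="m"):
    marker = MarkerSpec.from_hgvs(marker_id, "KRAS", "c.35G>A")
    return PatientSeries(
        patient_id="P",
        markers=[marker],
        samples=[vaf_sample(d, v, marker_id) for d, v in pairs],
        imaging_relapse_day=imaging_day,
    )


class TestFixture:
    def test_cohort_size_and_sex(self):
        cohort, leads = load_retrospective_cohort()
        assert len(cohort) == 14
        sexes = [p.sex for p in cohort]
        assert sexes.count("male") == 10 and sexes.count("female") == 4

    def test_one_patient_never_detected(self):
        cohort, leads = load_retrospective_cohort()
        not_detected = [lt for lt in leads if lt.ctdna_day is None]
        assert len(not_detected) == 1
        assert not_detected[0].patient_id == "Pat#5"

    def test_marker_classes_parsed(self):
        cohort, _ = load_retrospective_cohort()
        by_id = {p.patient_id: p for p in cohort}
        assert by_id["Pat#1"].markers[0].mutation_class == "transition"
        assert by_id["Pat#5"].markers[0].mutation_class == "transversion"


class TestLeadTime:
    @pytest.mark.parametrize(
        "imaging, ctdna, delta", [(764, 647, 117), (962, 962, 0), (268, 42, 226)]
    )
    def test_published_examples(self, imaging, ctdna, delta):
        assert lead_time("p", imaging, ctdna).delta_days == delta

    def test_not_detected_has_no_delta(self):
        lt = lead_time("p", 305, None)
        assert lt.ctdna_day is None and lt.delta_days is None

    def test_negative_lead_warned_not_rejected(self):
        with pytest.warns(UserWarning, match="negative lead"):
            lt = lead_time("p", 100, 150)
        assert lt.delta_days == -50


class TestCohortSummary:
    def test_reproduces_published_cohort_statistics(self):
        cohort, leads = load_retrospective_cohort()
        s = cohort_summary(cohort, leads)
        assert s["age_years"]["median"] == 68
        assert (s["age_years"]["min"], s["age_years"]["max"]) == (50, 81)
        assert s["lead_time_days"]["median"] == 112
        assert (s["lead_time_days"]["min"], s["lead_time_days"]["max"]) == (0, 226)
        assert s["gene_marker_counts"] == {"KRAS": 9, "NRAS": 2, "TP53": 3}
        assert s["n_ctdna_detected"] == 13
        assert s["detected_fraction_pct"] == pytest.approx(92.857, abs=0.01)
        # follow-up over delta-contributing patients matches the printed range
        assert s["followup_days"]["median"] == 381
        assert (s["followup_days"]["min"], s["followup_days"]["max"]) == (163, 962)

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            cohort_summary([], [])

    @given(st.lists(st.integers(0, 1000), min_size=1, max_size=15))
    def test_median_matches_sort_based_oracle(self, values):
        s = sorted(values)
        n = len(s)
        brute = s[n // 2] if n % 2 else (s[n // 2 - 1] + s[n // 2]) / 2
        assert statistics.median(values) == brute


class TestFirstPositiveDay:
    def test_first_crossing_day(self):
        series = series_from_vafs([(14, 0.0), (60, 0.005), (120, 0.02), (200, 0.4)])
        assert first_positive_day(series) == 120

    def test_all_wild_type_is_none(self):
        series = series_from_vafs([(14, 0.0), (60, 0.002)])
        assert first_positive_day(series) is None

    def test_positive_at_first_sample(self):
        series = series_from_vafs([(14, 0.5), (60, 1.0)])
        assert first_positive_day(series) == 14

    def test_empty_series_rejected(self):
        series = series_from_vafs([])
        with pytest.raises(ValueError):
            first_positive_day(series)


class TestAccumulationRate:
    @pytest.mark.parametrize(
        "pairs, rate",
        [
            ([(0, 0.01), (100, 1.21)], 0.012),
            ([(0, 0.01), (100, 0.31)], 0.003),
        ],
    )
    def test_rise_over_run(self, pairs, rate):
        series = series_from_vafs(pairs, imaging_day=100)
        assert accumulation_rate(series) == pytest.approx(rate, rel=1e-6)

    def test_single_positive_sample_undefined(self):
        series = series_from_vafs([(0, 0.005), (100, 1.0)], imaging_day=100)
        assert accumulation_rate(series) is None

    def test_samples_after_imaging_excluded(self):
        series = series_from_vafs(
            [(0, 0.01), (100, 1.21), (150, 50.0)], imaging_day=100
        )
        assert accumulation_rate(series) == pytest.approx(0.012, rel=1e-6)


class TestPatientTableIO:
    def test_empty_file_rejected(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("patient_id\tsex\tage\tuicc\tpt\tpn\tm\tgene\thgvs_c\thgvs_p\timaging_day\tctdna_day\tdelta\n")
        with pytest.raises(ValueError, match="no rows"):
            read_patient_table(path)

    def test_inconsistent_delta_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text(
            "patient_id\tsex\tage\tuicc\tpt\tpn\tm\tgene\thgvs_c\thgvs_p\timaging_day\tctdna_day\tdelta\n"
            "P1\tmale\t60\tIV\t3\t1\t1\tKRAS\tc.35G>A\tp.Gly12Asp\t100\t50\t40\n"
        )
        with pytest.raises(ValueError, match="delta"):
            read_patient_table(path)

    def test_missing_column_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("patient_id\tsex\n")
        with pytest.raises(ValueError, match="missing columns"):
            read_patient_table(path)

    def test_multi_marker_patient_grouped(self, tmp_path):
        header = "patient_id\tsex\tage\tuicc\tpt\tpn\tm\tgene\thgvs_c\thgvs_p\timaging_day\tctdna_day\tdelta\n"
        path = tmp_path / "two.tsv"
        path.write_text(
            header
            + "P1\tmale\t60\tIV\t3\t1\t1\tKRAS\tc.35G>A\tp.Gly12Asp\t100\t50\t50\n"
            + "P1\tmale\t60\tIV\t3\t1\t1\tTP53\tc.742C>T\tp.Arg248Trp\t100\t50\t50\n"
        )
        cohort, leads = read_patient_table(path)
        assert len(cohort) == 1 and len(cohort[0].markers) == 2
        assert len(leads) == 1


class TestEndToEndRecovery:
    def test_simulated_relapse_recovered(self, kras_marker):
        # triplicate 20 ng PCRs every 30 days; ctDNA grows at 0.012%/day from day 30
        cfg = SimConfig(seed=21, replicates=3, input_mass_ng=20.0, coverage_target=150_000)
        days = list(range(14, 201, 30)) + [200]
        series = simulate_patient_series(kras_marker, 200, 0.012, days, cfg)
        day = first_positive_day(series)
        assert day is not None and day < 200
        rate = accumulation_rate(series)
        assert rate == pytest.approx(0.012, rel=0.20)
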