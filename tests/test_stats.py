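"""Agreement statistics: fixture integrity, summaries, Wilcoxon against
brute-force enumeration, ICC against an independent implementation and
analytic variance components, diagnostic metrics, sample size."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import rankdata

from roboct.stats import (
    RAOCT_GRADING,
    SPECTRALIS_GRADING,
    CohortTable,
    ConfusionMatrix,
    bland_altman,
    cohort_aggregates,
    diagnostic_metrics,
    eye_summary,
    icc,
    implied_sd_diff,
    load_table1_fixture,
    paired_differences,
    required_sample_size,
    subgroup_report,
    wilcoxon_signed_rank,
)


@pytest.fixture(scope="module")
def fixture():
    return load_table1_fixture()


class TestFixture:
    def test_eye_counts(self, fixture):
        assert len(fixture.select(device="RAOCT", health="healthy")) == 20
        assert len(fixture.select(device="RAOCT", health="diseased")) == 22
        assert fixture.frame["patient_id"].nunique() == 25

    def test_patient1_od_raoct(self, fixture):
        row = fixture.select(device="RAOCT", patient_id=1, eye="OD")
        assert float(row["mean_um"].iloc[0]) == 297
        assert float(row["sd_um"].iloc[0]) == 0.6

    def test_single_eyed_patients_have_one_eye(self, fixture):
        for pid in (11, 13, 15, 18, 23):
            assert fixture.select(device="RAOCT", patient_id=pid)["eye"].tolist() == ["OD"] or \
                fixture.select(device="RAOCT", patient_id=pid)["eye"].tolist() == ["OS"]

    def test_pairing_yields_42_eyes(self, fixture):
        assert len(paired_differences(fixture)) == 42

    def test_schema_validation(self):
        with pytest.raises(ValueError, match="missing columns"):
            CohortTable(pd.DataFrame({"patient_id": [1]}))


class TestEyeSummary:
    def test_triplicate_mean_and_sample_sd(self):
        m, s = eye_summary([250, 250, 251])
        assert m == pytest.approx(250.333, abs=1e-3)
        assert s == pytest.approx(0.577, abs=1e-3)

    def test_identical_values_zero_sd(self):
        assert eye_summary([300, 300, 300]) == (300.0, 0.0)

    def test_hand_arithmetic(self):
        m, s = eye_summary([280, 290, 300])
        assert (m, s) == (290.0, 10.0)

    def test_wrong_count_rejected(self):
        with pytest.raises(ValueError):
            eye_summary([1.0, 2.0])


class TestCohortAggregates:
    @pytest.mark.parametrize(
        "device,health,mean,intra,pop",
        [
            ("RAOCT", "healthy", 282.9, 0.8, 21.7),
            ("Spectralis", "healthy", 283.7, 2.2, 19.8),
            ("RAOCT", "diseased", None, 2.0, None),
            ("Spectralis", "diseased", 310.8, 11.4, 78.3),
        ],
    )
    def test_printed_cohort_statistics(self, fixture, device, health, mean, intra, pop):
        agg = cohort_aggregates(fixture, device, health)
        if mean is not None:
            assert agg.mean_of_eye_means == pytest.approx(mean, abs=0.15)
        if intra is not None:
            assert agg.mean_intrasession_sd == pytest.approx(intra, abs=0.15)
        if pop is not None:
            assert agg.population_sd == pytest.approx(pop, abs=0.15)

    def test_duplicated_single_record_zero_population_sd(self):
        rows = []
        for eye in ("OD", "OS"):
            rows.append(dict(patient_id=1, gender="Female", race="White", age=40,
                             eye=eye, health="healthy", device="RAOCT",
                             mean_um=300.0, sd_um=1.0))
        agg = cohort_aggregates(CohortTable(pd.DataFrame(rows)), "RAOCT")
        assert agg.population_sd == 0.0

    def test_empty_selection_rejected(self, fixture):
        with pytest.raises(ValueError):
            cohort_aggregates(fixture, "RAOCT", health="healthy", race="Martian")


class TestPairedAndBlandAltman:
    def test_identical_tables_all_zero(self, fixture):
        df = fixture.frame.copy()
        df.loc[df.device == "Spectralis", "mean_um"] = (
            df[df.device == "RAOCT"].set_index(["patient_id", "eye"])["mean_um"]
            .reindex(pd.MultiIndex.from_frame(
                df[df.device == "Spectralis"][["patient_id", "eye"]]))
            .to_numpy()
        )
        d = paired_differences(CohortTable(df))
        assert np.allclose(d, 0.0)

    def test_patient2_od_difference(self, fixture):
        pairs = fixture.pairs()
        row = pairs[(pairs.patient_id == 2) & (pairs.eye == "OD")]
        assert float(row["RAOCT"].iloc[0] - row["Spectralis"].iloc[0]) == -5.0

    def test_all_eyes_mean_difference_minus_one(self, fixture):
        ba = bland_altman(paired_differences(fixture))
        assert -1.5 <= ba.mean_difference <= -0.5

    def test_two_point_loa(self):
        ba = bland_altman([-2.0, 2.0])
        assert ba.mean_difference == 0.0
        assert ba.loa_high == pytest.approx(1.96 * np.std([-2, 2], ddof=1), abs=1e-9)
        assert ba.loa_high == pytest.approx(5.54, abs=0.01)

    def test_all_zero_diffs(self):
        ba = bland_altman(np.zeros(5))
        assert (ba.mean_difference, ba.loa_low, ba.loa_high) == (0.0, 0.0, 0.0)


def _brute_force_wilcoxon(d):
    d = np.asarray(d, float)
    d = d[d != 0]
    ranks = rankdata(np.abs(d))
    w = ranks[d > 0].sum()
    ws = [
        sum(r for s, r in zip(signs, ranks) if s > 0)
        for signs in itertools.product([1, -1], repeat=len(d))
    ]
    ws = np.array(ws)
    return min(1.0, 2.0 * min((ws <= w).mean(), (ws >= w).mean()))


class TestWilcoxon:
    def test_one_to_five_exact(self):
        assert wilcoxon_signed_rank([1, 2, 3, 4, 5]) == pytest.approx(2 / 32)

    def test_perfectly_symmetric_p_one(self):
        assert wilcoxon_signed_rank([-3, -1, 1, 3, -2, 2]) == 1.0

    def test_all_zero_p_one(self):
        assert wilcoxon_signed_rank([0.0, 0.0, 0.0]) == 1.0

    def test_fixture_healthy_non_significant(self, fixture):
        assert wilcoxon_signed_rank(paired_differences(fixture, health="healthy")) > 0.05

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.lists(st.integers(min_value=-9, max_value=9), min_size=3, max_size=12))
    def test_matches_brute_force_enumeration(self, diffs):
        """Exact enumeration oracle: every sign assignment of |d| ranks."""
        d = np.asarray(diffs, float)
        if np.all(d == 0):
            assert wilcoxon_signed_rank(d) == 1.0
        else:
            assert wilcoxon_signed_rank(d) == pytest.approx(_brute_force_wilcoxon(d))

    def test_matches_scipy_exact_without_ties(self):
        from scipy.stats import wilcoxon as scipy_wilcoxon

        rng = np.random.default_rng(0)
        for _ in range(5):
            d = rng.permutation(np.arange(1, 13)) * rng.choice([-1, 1], 12) + 0.0
            assert wilcoxon_signed_rank(d) == pytest.approx(
                scipy_wilcoxon(d, method="exact").pvalue
            )

    def test_large_n_normal_approximation_close_to_scipy(self):
        from scipy.stats import wilcoxon as scipy_wilcoxon

        rng = np.random.default_rng(1)
        d = rng.normal(0.3, 1.0, 60)
        p = wilcoxon_signed_rank(d)
        ref = scipy_wilcoxon(d, method="approx", correction=True).pvalue
        assert p == pytest.approx(ref, rel=0.05)


class TestICC:
    def test_identical_pairs_icc_one(self):
        x = np.column_stack([np.arange(10.0), np.arange(10.0)])
        r = icc(x)
        assert r.icc == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "health,expected,ci",
        [("healthy", 0.956, (0.894, 0.982)), ("diseased", 0.994, (0.986, 0.998))],
    )
    def test_fixture_icc_matches_printed(self, fixture, health, expected, ci):
        pairs = fixture.pairs(health=health)[["RAOCT", "Spectralis"]].to_numpy(float)
        r = icc(pairs)
        assert r.icc == pytest.approx(expected, abs=0.01)
        assert r.ci_low == pytest.approx(ci[0], abs=0.02)
        assert r.ci_high == pytest.approx(ci[1], abs=0.02)

    def test_matches_pingouin(self, fixture):
        pg = pytest.importorskip("pingouin")
        pairs = fixture.pairs(health="healthy")
        long = pairs.melt(id_vars=["patient_id", "eye"],
                          value_vars=["RAOCT", "Spectralis"],
                          var_name="rater", value_name="y")
        long["target"] = long.patient_id.astype(str) + long.eye
        ref = pg.intraclass_corr(long, targets="target", raters="rater", ratings="y")
        # two-way random absolute agreement, single measure
        ref_icc = float(ref.loc[ref.Type.str.contains("A,1"), "ICC"].iloc[0])
        mine = icc(pairs[["RAOCT", "Spectralis"]].to_numpy(float))
        assert mine.icc == pytest.approx(ref_icc, abs=1e-9)

    def test_recovers_analytic_icc_from_variance_components(self, rng):
        """Simulated two-device data with known between-subject and error
        variances: ICC -> sigma_b^2 / (sigma_b^2 + sigma_e^2)."""
        sigma_b, sigma_e = 20.0, 5.0
        n = 400
        subj = rng.normal(300, sigma_b, n)
        x = np.column_stack([subj + rng.normal(0, sigma_e, n),
                             subj + rng.normal(0, sigma_e, n)])
        target = sigma_b**2 / (sigma_b**2 + sigma_e**2)
        assert icc(x).icc == pytest.approx(target, abs=0.03)

    def test_independent_pairs_icc_near_zero(self, rng):
        x = rng.normal(0, 1, (500, 2))
        r = icc(x)
        assert r.ci_low < 0.0 < r.ci_high or abs(r.icc) < 0.1

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError):
            icc(np.full((10, 2), 5.0))


class TestDiagnosticMetrics:
    def test_raoct_grading(self):
        assert diagnostic_metrics(RAOCT_GRADING) == (93, 90, 93, 90)

    def test_spectralis_grading(self):
        assert diagnostic_metrics(SPECTRALIS_GRADING) == (87, 60, 76, 75)

    def test_perfect_grading(self):
        assert diagnostic_metrics(ConfusionMatrix(15, 0, 0, 10)) == (100, 100, 100, 100)

    def test_grading_totals(self):
        for cm in (RAOCT_GRADING, SPECTRALIS_GRADING):
            assert cm.tp + cm.fn == 15   # abnormal volumes
            assert cm.fp + cm.tn == 10   # normal volumes

    def test_zero_denominator_flagged(self):
        with pytest.raises(ZeroDivisionError):
            diagnostic_metrics(ConfusionMatrix(0, 0, 3, 5))


class TestSampleSize:
    def test_implied_sd_for_18_eyes(self):
        assert implied_sd_diff(18, 15.0) == pytest.approx(19.6, abs=0.1)
        assert required_sample_size(15.0, implied_sd_diff(18, 15.0)) == 18

    def test_huge_delta_floors_at_one(self):
        assert required_sample_size(1e9, 10.0) == 1

    def test_doubling_sd_quadruples_n(self):
        n1 = required_sample_size(15.0, 40.0)
        n2 = required_sample_size(15.0, 80.0)
        assert 4 * n1 - 3 <= n2 <= 4 * n1   # ceiling slack

    def test_invalid_power_rejected(self):
        with pytest.raises(ValueError):
            required_sample_size(15.0, 20.0, power=1.5)


class TestSubgroups:
    def test_black_race_pair_count(self, fixture):
        rep = subgroup_report(fixture)
        row = rep[(rep.subgroup == "race") & (rep.level == "Black")]
        assert int(row["n_pairs"].iloc[0]) == 8

    def test_asian_patient_excluded_from_race_only(self, fixture):
        rep = subgroup_report(fixture)
        race_n = rep[rep.subgroup == "race"]["n_pairs"].sum()
        gender_n = rep[rep.subgroup == "gender"]["n_pairs"].sum()
        assert gender_n == 42
        assert race_n == 40   # patient 8's two eyes excluded

    def test_age_bins_partition_pairs(self, fixture):
        rep = subgroup_report(fixture)
        assert rep[rep.subgroup == "age"]["n_pairs"].sum() == 42

    def test_all_subgroup_iccs_above_09(self, fixture):
        rep = subgroup_report(fixture)
        ok = rep[rep.sufficient]
        assert (ok["icc"] > 0.9).all()
        assert (ok["wilcoxon_p"] > 0.05).all()
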