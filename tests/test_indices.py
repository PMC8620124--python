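"""Use-value and informant-agreement indices."""

import math

import pytest
from hypothesis import given, strategies as st

from _oracles import spearman_rho
from conftest import make_report, make_respondent
from ethnosurvey.indices import (
    compare_correlations_fisher_z,
    iar_table,
    informant_agreement_ratio,
    respondent_use_value,
    total_use_value,
    use_value_by,
    uv_trees_correlation,
)
from ethnosurvey.survey_data import SurveyDataset


class TestRespondentUseValue:
    def test_no_reports_gives_zero(self, tiny_dataset):
        tiny_dataset.use_reports = [u for u in tiny_dataset.use_reports
                                    if u.respondent_id != "R2"]
        assert respondent_use_value(tiny_dataset, "R2") == 0

    def test_three_distinct_citations(self):
        ds = SurveyDataset([make_respondent("R1")], [
            make_report("R1"),
            make_report("R1", use_label="malaria", category="medicinal",
                        body_system="general_health", plant_part="leaf"),
            make_report("R1", use_label="lucky_charm",
                        category="magico_spiritual", plant_part="root"),
        ])
        assert respondent_use_value(ds, "R1") == 3

    def test_duplicate_rows_counted_once(self):
        ds = SurveyDataset([make_respondent("R1")],
                           [make_report("R1"), make_report("R1")])
        assert respondent_use_value(ds, "R1") == 1

    def test_unknown_id_raises(self, tiny_dataset):
        with pytest.raises(KeyError):
            respondent_use_value(tiny_dataset, "R99")


class TestTotalUseValue:
    def test_closed_form_two_respondents(self):
        ds = SurveyDataset([make_respondent("R1"), make_respondent("R2")], [])
        ds.use_reports = (
            [make_report("R1"),
             make_report("R1", use_label="malaria", category="medicinal",
                         body_system="general_health", plant_part="leaf")]
            + [make_report("R2"),
               make_report("R2", use_label="malaria", category="medicinal",
                           body_system="general_health", plant_part="leaf"),
               make_report("R2", use_label="lucky_charm",
                           category="magico_spiritual", plant_part="root"),
               make_report("R2", use_label="commercialization",
                           category="sales", plant_part="fruit")])
        rec = total_use_value(ds)
        # UV_j = {2, 4}: mean 3, sample SD sqrt(2), SEM 1
        assert rec.uv == pytest.approx(3.0)
        assert rec.sem == pytest.approx(1.0)

    def test_single_citation_each(self):
        ds = SurveyDataset([make_respondent(f"R{i}") for i in range(5)],
                           [make_report(f"R{i}") for i in range(5)])
        rec = total_use_value(ds)
        assert rec.uv == pytest.approx(1.0)
        assert rec.sem == 0.0

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            total_use_value(SurveyDataset([], []))

    def test_synthetic_uv_near_study_value(self, default_dataset):
        # the generator is calibrated so the overall UV lands near 2.45
        rec = total_use_value(default_dataset)
        assert rec.uv == pytest.approx(2.45, abs=0.25)


class TestUseValueBy:
    def test_single_category_concentrates_uv(self):
        ds = SurveyDataset([make_respondent("R1"), make_respondent("R2")],
                           [make_report("R1"), make_report("R2")])
        recs = {r.scope: r for r in use_value_by(ds, "category")}
        assert recs["food"].uv == pytest.approx(total_use_value(ds).uv)
        assert all(recs[c].uv == 0 for c in recs if c != "food")

    def test_category_additivity(self, default_dataset):
        total = total_use_value(default_dataset).uv
        parts = sum(r.uv for r in use_value_by(default_dataset, "category"))
        assert parts == pytest.approx(total, rel=1e-12)

    def test_gender_partition_hand_counts(self):
        rs = [make_respondent("R1"), make_respondent("R2"),
              make_respondent("R3", gender="woman"),
              make_respondent("R4", gender="woman")]
        reports = [make_report("R1"),
                   make_report("R1", use_label="malaria", category="medicinal",
                               body_system="general_health", plant_part="leaf"),
                   make_report("R3")]
        recs = {r.scope: r for r in use_value_by(SurveyDataset(rs, reports),
                                                 "gender")}
        assert recs["man"].uv == pytest.approx(1.0)    # (2 + 0) / 2
        assert recs["woman"].uv == pytest.approx(0.5)  # (1 + 0) / 2

    def test_unknown_axis_rejected(self, tiny_dataset):
        with pytest.raises(ValueError, match="axis"):
            use_value_by(tiny_dataset, "shoe_size")


class TestInformantAgreementRatio:
    @pytest.mark.parametrize("nr,na,expected", [
        (112, 5, 0.96),   # commercialization
        (21, 4, 0.85),    # woe induction
        (8, 4, 0.57),     # wealth attraction
        (9, 2, 0.875),    # female genital system
        (26, 2, 0.96),    # urinary system
        (2, 2, 0.00),     # eye: every citation a different part
        (497, 1, 1.00),   # sweetener: full consensus
        (35, 6, 0.85),    # male genital system
        (117, 1, 1.00),   # chewing stick
        (90, 6, 0.94),    # digestive system
    ])
    def test_documented_cells(self, nr, na, expected):
        assert informant_agreement_ratio(nr, na) == pytest.approx(expected,
                                                                  abs=0.005)

    def test_single_report_undefined(self):
        assert informant_agreement_ratio(1, 1) is None

    @pytest.mark.parametrize("k", [2, 5, 100])
    def test_single_part_full_agreement(self, k):
        assert informant_agreement_ratio(k, 1) == 1.0

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            informant_agreement_ratio(3, 4)
        with pytest.raises(ValueError):
            informant_agreement_ratio(3, 0)

    @given(nr=st.integers(2, 500), frac=st.floats(0, 1))
    def test_bounds_and_extremes(self, nr, frac):
        na = 1 + round(frac * (min(nr, 7) - 1))
        iar = informant_agreement_ratio(nr, na)
        assert 0.0 <= iar <= 1.0
        assert (iar == 1.0) == (na == 1)
        assert (iar == 0.0) == (na == nr)


class TestIARTable:
    def test_female_genital_fixture(self):
        rs = [make_respondent(f"R{i}") for i in range(9)]
        parts = ["leaf"] * 5 + ["root"] * 4
        reports = [make_report(f"R{i}", use_label="cyst", category="medicinal",
                               body_system="female_genital", plant_part=p)
                   for i, p in enumerate(parts)]
        recs = {r.scope: r for r in iar_table(SurveyDataset(rs, reports),
                                              "body_system")}
        rec = recs["female_genital"]
        assert (rec.nr, rec.na) == (9, 2)
        assert rec.iar == pytest.approx(0.875)

    def test_single_report_scope_is_na(self):
        ds = SurveyDataset([make_respondent("R1")], [
            make_report("R1", use_label="firewood", category="firewood",
                        plant_part="twig")])
        recs = {r.scope: r for r in iar_table(ds, "category")}
        assert recs["firewood"].iar is None
        assert recs["firewood"].iar_display() == "NA"

    def test_empty_scopes_omitted(self, tiny_dataset):
        scopes = {r.scope for r in iar_table(tiny_dataset, "category")}
        assert "firewood" not in scopes

    def test_synthetic_na_bounded_by_part_lists(self, default_dataset):
        from ethnosurvey.catalog import USE_CATALOG
        allowed = {}
        for e in USE_CATALOG:
            if e.category == "medicinal":
                allowed.setdefault(e.body_system, set()).update(e.parts)
        for rec in iar_table(default_dataset, "body_system"):
            assert rec.na <= len(allowed[rec.scope])


class TestCorrelations:
    def _ds(self, uv_counts, n_trees):
        labels = ["sweetener", "malaria", "lucky_charm", "commercialization",
                  "chewing_stick", "protection", "woe_induction"]
        cats = ["food", "medicinal", "magico_spiritual", "sales", "social",
                "magico_spiritual", "magico_spiritual"]
        systems = ["non_medicinal", "general_health"] + ["non_medicinal"] * 5
        rs, reports = [], []
        for i, (k, t) in enumerate(zip(uv_counts, n_trees)):
            rid = f"R{i}"
            rs.append(make_respondent(rid, n_trees=t, owns_trees=t > 0,
                                      ownership_mode="legacy" if t else None,
                                      habitat="farm" if t else None))
            for j in range(k):
                reports.append(make_report(
                    rid, use_label=labels[j], category=cats[j],
                    body_system=systems[j],
                    plant_part="leaf" if cats[j] == "medicinal" else "fruit"))
        return SurveyDataset(rs, reports)

    def test_identity_gives_unit_correlation(self):
        ds = self._ds([1, 2, 3, 4], [1, 2, 3, 4])
        r, p, n = uv_trees_correlation(ds, method="spearman")
        assert r == pytest.approx(1.0)
        assert n == 4

    def test_antimonotone_gives_minus_one(self):
        ds = self._ds([1, 2, 3, 4], [9, 7, 5, 2])
        r, _, _ = uv_trees_correlation(ds, method="spearman")
        assert r == pytest.approx(-1.0)

    def test_matches_rank_formula_oracle(self):
        uv = [1, 3, 2, 5, 4, 6]
        trees = [2, 1, 4, 3, 6, 5]
        ds = self._ds(uv, trees)
        r, p, n = uv_trees_correlation(ds, method="spearman")
        assert r == pytest.approx(spearman_rho(uv, trees))
        assert 0.0 <= p <= 1.0

    def test_constant_vector_flagged(self):
        ds = self._ds([2, 2, 2, 2], [1, 2, 3, 4])
        with pytest.raises(ValueError, match="constant"):
            uv_trees_correlation(ds)

    def test_small_subset_rejected(self):
        ds = self._ds([1, 2, 3], [1, 2, 3])
        with pytest.raises(ValueError, match="4"):
            uv_trees_correlation(ds)


class TestFisherZ:
    def test_equal_correlations_give_null(self):
        z, p = compare_correlations_fisher_z(0.3, 40, 0.3, 60)
        assert z == 0.0
        assert p == pytest.approx(1.0)

    def test_closed_form_value(self):
        # atanh(0.5) / sqrt(2/47) evaluated independently
        z, p = compare_correlations_fisher_z(0.5, 50, 0.0, 50)
        expected = math.atanh(0.5) / math.sqrt(2.0 / 47.0)
        assert z == pytest.approx(expected)
        assert p == pytest.approx(2 * (1 - 0.5 * (1 + math.erf(
            expected / math.sqrt(2)))), abs=1e-12)

    def test_antisymmetry(self):
        z1, p1 = compare_correlations_fisher_z(0.6, 30, 0.1, 45)
        z2, p2 = compare_correlations_fisher_z(0.1, 45, 0.6, 30)
        assert z1 == pytest.approx(-z2)
        assert p1 == pytest.approx(p2)

    def test_small_samples_rejected(self):
        with pytest.raises(ValueError):
            compare_correlations_fisher_z(0.5, 3, 0.2, 50)
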