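import math

import pandas as pd
import pytest

from conftest import diagnoses_frame, purchases_frame
from hcepi.risk import (
    DEFAULT_CONDITION_FACTORS,
    FIXED_FACTORS,
    RiskProfile,
    assess_risk_factors,
    carrier_status,
    carrier_thrombosis_association,
    factor_prevalence_comparison,
    family_history_vs_carrier,
    index_year_groups,
)
from hcepi.stats import FourfoldTable


class TestCarrierStatus:
    @pytest.mark.parametrize(
        "fvl,ptm,expected",
        [(0, 0, False), (1, 0, True), (0, 2, True), (0.4, 0.4, False), (0.5, 0, True)],
    )
    def test_thresholding(self, fvl, ptm, expected):
        assert carrier_status(fvl, ptm).any_carrier is expected

    def test_missing_genotype_stays_missing(self):
        assert carrier_status(math.nan, math.nan).any_carrier is None
        assert carrier_status(math.nan, 1).any_carrier is True


class TestVcfReader:
    HEADER = (
        "##fileformat=VCFv4.2\n"
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        '##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage">\n'
        "##contig=<ID=1>\n##contig=<ID=11>\n"
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tP1\tP2\tP3\n"
    )

    def test_imputed_dosages_preferred(self, tmp_path):
        from hcepi.risk import read_genotypes_vcf

        body = (
            "1\t169519049\trs6025\tT\tC\t.\tPASS\t.\tGT:DS\t0/0:0.02\t0/1:0.97\t1/1:1.98\n"
            "11\t46761055\trs1799963\tG\tA\t.\tPASS\t.\tGT:DS\t0/0:0.01\t0/0:0.10\t0/1:1.02\n"
        )
        path = tmp_path / "geno.vcf"
        path.write_text(self.HEADER + body)
        df = read_genotypes_vcf(path)
        assert df["participant_id"].tolist() == ["P1", "P2", "P3"]
        assert df["fvl_copies"].tolist() == pytest.approx([0.02, 0.97, 1.98])
        carriers = [
            carrier_status(f, p).any_carrier
            for f, p in zip(df["fvl_copies"], df["ptm_copies"])
        ]
        assert carriers == [False, True, True]

    def test_hard_calls_fallback_and_missing_variant(self, tmp_path):
        from hcepi.risk import read_genotypes_vcf

        body = "1\t169519049\trs6025\tT\tC\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1\n"
        path = tmp_path / "geno.vcf"
        path.write_text(self.HEADER.replace(":DS", "") + body)
        df = read_genotypes_vcf(path)
        assert df["fvl_copies"].tolist() == [0.0, 1.0, 2.0]
        assert df["ptm_copies"].isna().all()  # variant absent from the file


class TestIndexYearGroups:
    def test_first_purchase_of_year_governs(self):
        purchases = purchases_frame(
            [
                ("P1", "2022-02-01", "G03AA12", 3),   # CHC first
                ("P1", "2022-08-01", "G03AC09", 3),   # POP later
                ("P2", "2022-05-01", "G03AC09", 3),   # POC only
                ("P3", "2021-05-01", "G03AA12", 3),   # outside the index year
            ]
        )
        profiles = {p.participant_id: p for p in index_year_groups(purchases, 2022)}
        assert profiles["P1"].group == "CHC"
        assert profiles["P1"].index_date == pd.Timestamp("2022-02-01")
        assert profiles["P2"].group == "POC"
        assert "P3" not in profiles


class TestAssessRiskFactors:
    def _assess(self, birth_year=1986, dx=None, purchases=None, rel_dx=None, bmi=None,
                fvl=0.0, ptm=0.0):
        profile = RiskProfile("P1", "CHC", pd.Timestamp("2022-03-01"))
        return assess_risk_factors(
            profile,
            dx if dx is not None else diagnoses_frame([]),
            purchases if purchases is not None else purchases_frame([]),
            {"birth_year": birth_year, "fvl_copies": fvl, "ptm_copies": ptm},
            relative_diagnoses=rel_dx,
            bmi_records=bmi,
        ).factors

    def test_fifteen_factors_populated(self):
        factors = self._assess()
        assert len(factors) == 15
        assert set(factors) == set(FIXED_FACTORS) | set(DEFAULT_CONDITION_FACTORS)

    def test_age_year_arithmetic(self):
        assert self._assess(birth_year=1986)["age_over_35"] is True    # 36
        assert self._assess(birth_year=1987)["age_over_35"] is False   # 35

    def test_lookback_window_boundary(self):
        # index 2022-03-01; window starts 2020-03-01 (730 days before)
        inside = purchases_frame([("P1", "2020-03-01", "N05AH04", 1)])
        outside = purchases_frame([("P1", "2020-02-29", "N05AH04", 1)])
        assert self._assess(purchases=inside)["risk_medication"] is True
        assert self._assess(purchases=outside)["risk_medication"] is False

    def test_condition_factor_from_window_codes(self):
        dx = diagnoses_frame([("P1", "2021-06-01", "I10"), ("P1", "2021-07-01", "E11.9")])
        factors = self._assess(dx=dx)
        assert factors["hypertension"] and factors["diabetes"]
        assert not factors["pneumonia"]

    def test_personal_history_is_whole_history(self):
        dx = diagnoses_frame([("P1", "2008-01-01", "I80.2")])  # long before the window
        assert self._assess(dx=dx)["personal_vte_ate_history"] is True

    def test_family_history_before_index_only(self):
        before = diagnoses_frame([("R1", "2021-01-01", "I26.9")])
        after = diagnoses_frame([("R1", "2022-06-01", "I26.9")])
        assert self._assess(rel_dx=before)["family_vte_ate_history"] is True
        assert self._assess(rel_dx=after)["family_vte_ate_history"] is False

    def test_obesity_via_closest_bmi(self):
        bmi = pd.DataFrame(
            {"participant_id": ["P1"], "date": pd.to_datetime(["2022-01-01"]), "bmi": [31.0]}
        )
        assert self._assess(bmi=bmi)["obesity"] is True

    def test_missing_genotype_marks_carrier_missing(self):
        assert self._assess(fvl=math.nan, ptm=math.nan)["carrier"] is None

    def test_translation_invariance(self):
        dx = diagnoses_frame([("P1", "2021-06-01", "I10")])
        base = self._assess(dx=dx)
        shifted_profile = RiskProfile("P1", "CHC", pd.Timestamp("2022-03-01") + pd.Timedelta(days=55))
        shifted_dx = dx.copy()
        shifted_dx["date"] += pd.Timedelta(days=55)
        shifted = assess_risk_factors(
            shifted_profile, shifted_dx, purchases_frame([]),
            {"birth_year": 1986, "fvl_copies": 0.0, "ptm_copies": 0.0},
        ).factors
        assert shifted == base


class TestFactorComparison:
    def _profiles(self, n_chc, n_poc, p_chc, p_poc, factor="age_over_35"):
        profiles = []
        for i in range(n_chc):
            profiles.append(RiskProfile(f"C{i}", "CHC", pd.Timestamp("2022-01-01"),))
            profiles[-1].factors = {factor: i < round(p_chc * n_chc)}
        for i in range(n_poc):
            profiles.append(RiskProfile(f"Q{i}", "POC", pd.Timestamp("2022-01-01"),))
            profiles[-1].factors = {factor: i < round(p_poc * n_poc)}
        return profiles

    def test_reference_prevalence_ratios(self):
        # printed group sizes with printed within-group percentages
        for p_poc, p_chc, expected in [
            (0.551, 0.406, 0.74),
            (0.148, 0.172, 1.16),
            (0.082, 0.056, 0.68),
            (0.034, 0.017, 0.50),
        ]:
            table = factor_prevalence_comparison(self._profiles(8840, 4770, p_chc, p_poc), m=15)
            assert round(table.iloc[0]["pr"], 2) == expected

    def test_equal_prevalence_gives_unity(self):
        table = factor_prevalence_comparison(self._profiles(100, 200, 0.3, 0.3))
        assert table.iloc[0]["pr"] == pytest.approx(1.0)

    def test_bonferroni_applied(self):
        table = factor_prevalence_comparison(self._profiles(50, 50, 0.9, 0.1), m=15)
        assert table.iloc[0]["p_bonferroni"] == pytest.approx(
            min(1.0, 15 * table.iloc[0]["p_raw"])
        )

    def test_empty_group_errors(self):
        with pytest.raises(ValueError):
            factor_prevalence_comparison(self._profiles(10, 0, 0.5, 0.0))


class TestFamilyHistoryVsCarrier:
    def _profiles_from_counts(self, a, b, c, d):
        profiles = []
        spec = [(True, True, a), (True, False, b), (False, True, c), (False, False, d)]
        i = 0
        for fh, carrier, count in spec:
            for _ in range(count):
                p = RiskProfile(f"P{i}", "CHC", pd.Timestamp("2022-01-01"))
                p.factors = {"family_vte_ate_history": fh, "carrier": carrier}
                profiles.append(p)
                i += 1
        return profiles

    def test_printed_counts_reproduce_or_and_sens_spec(self):
        res = family_history_vs_carrier(self._profiles_from_counts(76, 946, 327, 7048))
        assert round(res["odds_ratio"].estimate, 2) == 1.73
        assert round(100 * res["sensitivity"].estimate, 1) == 18.9
        assert round(100 * res["specificity"].estimate, 1) == 88.2

    def test_sensitivity_specificity_identities(self):
        res = family_history_vs_carrier(self._profiles_from_counts(20, 30, 10, 40))
        t = res["table"]
        assert res["sensitivity"].estimate * (t.a + t.c) == pytest.approx(t.a)
        assert res["specificity"].estimate * (t.b + t.d) == pytest.approx(t.d)

    def test_perfect_concordance(self):
        res = family_history_vs_carrier(self._profiles_from_counts(5, 0, 0, 5))
        assert res["sensitivity"].estimate == 1.0
        assert res["specificity"].estimate == 1.0

    def test_zero_carriers_sensitivity_missing(self):
        res = family_history_vs_carrier(self._profiles_from_counts(0, 10, 0, 10))
        assert res["sensitivity"] is None


class TestCarrierThrombosis:
    def test_carrier_breakdown_percentage(self):
        # counts shaped like the reference cohort: 2,556 FVL-only,
        # 1,276 PTM-only, 54 both among 73,071 genotyped users
        n = 73071
        fvl = [1.0] * 2556 + [0.0] * 1276 + [1.0] * 54
        ptm = [0.0] * 2556 + [1.0] * 1276 + [1.0] * 54
        rest = n - len(fvl)
        participants = pd.DataFrame(
            {
                "participant_id": [f"P{i}" for i in range(n)],
                "fvl_copies": fvl + [0.0] * rest,
                "ptm_copies": ptm + [0.0] * rest,
            }
        )
        res = carrier_thrombosis_association(participants, diagnoses_frame([]))
        bd = res["carrier_breakdown"]
        assert (bd["fvl_only"], bd["ptm_only"], bd["both"]) == (2556, 1276, 54)
        assert round(bd["any_pct"], 1) == 5.3

    def test_zero_carriers_or_missing(self):
        participants = pd.DataFrame(
            {"participant_id": ["P0", "P1"], "fvl_copies": [0.0, 0.0], "ptm_copies": [0.0, 0.0]}
        )
        res = carrier_thrombosis_association(participants, diagnoses_frame([("P0", "2010-01-01", "I80")]))
        assert res["odds_ratio"] is None

    def test_or_direction(self):
        participants = pd.DataFrame(
            {
                "participant_id": [f"P{i}" for i in range(100)],
                "fvl_copies": [1.0] * 50 + [0.0] * 50,
                "ptm_copies": [0.0] * 100,
            }
        )
        dx = diagnoses_frame([(f"P{i}", "2010-01-01", "I80") for i in range(20)])
        res = carrier_thrombosis_association(participants, dx)
        # 20/50 carriers vs 0/50 non-carriers -> OR far above 1
        assert res["odds_ratio"].estimate > 1
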