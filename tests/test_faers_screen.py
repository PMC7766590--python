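"""Unit and property tests for the adverse-event disproportionality screen."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cinscreen.faers_screen import (
    CaseReport,
    ContingencyTable,
    Z_95,
    build_cohort,
    collate_to_atc,
    compute_ror,
    contingency_for,
    deduplicate_cases,
    read_faers_tables,
    screen_comedications,
)

AKI = "ACUTE KIDNEY INJURY"


def write_tables(tmp_path, demo_rows, drug_rows, reac_rows):
    paths = []
    for name, header, rows in [
        ("DEMO.txt", "primaryid$caseid$caseversion", demo_rows),
        ("DRUG.txt", "primaryid$drugname", drug_rows),
        ("REAC.txt", "primaryid$pt", reac_rows),
    ]:
        p = tmp_path / name
        p.write_text("\n".join([header] + rows) + "\n")
        paths.append(p)
    return paths


class TestReadFaersTables:
    def test_one_case_fixture(self, tmp_path):
        demo, drug, reac = write_tables(
            tmp_path, ["101$1$1"], ["101$CISPLATIN", "101$Palonosetron HCl"], [f"101${AKI}"]
        )
        cases, skipped = read_faers_tables(demo, drug, reac)
        assert len(cases) == 1
        assert len(cases[0].drugs) == 2 and cases[0].reactions == [AKI]
        assert not any(skipped.values())

    def test_empty_reac_file_keeps_cases(self, tmp_path):
        demo, drug, reac = write_tables(tmp_path, ["101$1$1"], ["101$CISPLATIN"], [])
        cases, _ = read_faers_tables(demo, drug, reac)
        assert len(cases) == 1 and cases[0].reactions == []

    def test_unknown_primaryid_skipped_and_counted(self, tmp_path):
        demo, drug, reac = write_tables(tmp_path, ["101$1$1"], ["999$MYSTERY"], [f"101${AKI}"])
        cases, skipped = read_faers_tables(demo, drug, reac)
        assert len(cases) == 1 and cases[0].drugs == []
        assert skipped["drug_rows_unknown_primaryid"] == 1

    def test_malformed_row_reports_line_number(self, tmp_path):
        demo, drug, reac = write_tables(tmp_path, ["101$1$1", "102$2"], ["101$CISPLATIN"], [])
        with pytest.raises(ValueError, match=r"DEMO\.txt:3"):
            read_faers_tables(demo, drug, reac)

    def test_bad_header_rejected(self, tmp_path):
        demo, drug, reac = write_tables(tmp_path, ["101$1$1"], ["101$CISPLATIN"], [])
        drug.write_text("wrong$header\n101$CISPLATIN\n")
        with pytest.raises(ValueError, match="DRUG"):
            read_faers_tables(demo, drug, reac)


class TestDeduplicateCases:
    def test_highest_version_kept(self):
        reports = [
            CaseReport("7", 1, ["A"], [], primary_id="701"),
            CaseReport("7", 2, ["B"], [], primary_id="702"),
        ]
        kept = deduplicate_cases(reports)
        assert len(kept) == 1 and kept[0].version == 2 and kept[0].drugs == ["B"]

    def test_version_tie_broken_by_primary_id(self):
        reports = [
            CaseReport("7", 1, ["A"], [], primary_id="9"),
            CaseReport("7", 1, ["B"], [], primary_id="10"),
        ]
        kept = deduplicate_cases(reports)
        assert kept[0].drugs == ["B"]

    def test_unique_cases_pass_through(self):
        reports = [CaseReport(str(i), 1, [], [], primary_id=str(i)) for i in (3, 1, 2)]
        kept = deduplicate_cases(reports)
        assert [r.case_id for r in kept] == ["1", "2", "3"]

    def test_idempotent(self):
        reports = [
            CaseReport("1", 2, ["A"], [], primary_id="102"),
            CaseReport("1", 1, ["B"], [], primary_id="101"),
            CaseReport("2", 1, ["C"], [], primary_id="201"),
        ]
        once = deduplicate_cases(reports)
        assert deduplicate_cases(once) == once


class TestCollateToAtc:
    SYN = {"PALONOSETRON HCL": "A04AA05", "PALONOSETRON": "A04AA05", "CISPLATIN": "L01XA01"}

    def test_variants_collapse_to_one_code(self):
        r = CaseReport("1", 1, ["Palonosetron HCl", "PALONOSETRON", "CISPLATIN"], [])
        out, unmapped = collate_to_atc([r], self.SYN)
        assert out[0].drugs == ["A04AA05", "L01XA01"] and not unmapped

    def test_unmapped_dropped_and_counted(self):
        r = CaseReport("1", 1, ["HERBAL BLEND"], [])
        out, unmapped = collate_to_atc([r], self.SYN)
        assert out[0].drugs == [] and unmapped["HERBAL BLEND"] == 1

    def test_whitespace_normalization(self):
        r = CaseReport("1", 1, ["  palonosetron   hcl "], [])
        out, _ = collate_to_atc([r], self.SYN)
        assert out[0].drugs == ["A04AA05"]

    def test_invalid_atc_code_rejected(self):
        with pytest.raises(ValueError, match="XYZ"):
            collate_to_atc([], {"DRUG": "XYZ"})


class TestBuildCohort:
    CASES = [
        CaseReport("1", 1, ["L01XA01", "A04AA05"], []),
        CaseReport("2", 1, ["A04AA05"], []),
        CaseReport("3", 1, ["L01XA01"], []),
    ]

    def test_subset_with_drug_a(self):
        cohort = build_cohort(self.CASES, "L01XA01")
        assert [r.case_id for r in cohort] == ["1", "3"]

    def test_absent_drug_a_errors(self):
        with pytest.raises(ValueError):
            build_cohort(self.CASES, "Z99ZZ99")

    def test_all_cases_match(self):
        cohort = build_cohort(self.CASES[:1] * 3, "L01XA01")
        assert len(cohort) == 3


class TestContingency:
    COHORT = [
        CaseReport("1", 1, ["L01XA01", "D"], [AKI]),
        CaseReport("2", 1, ["L01XA01", "D"], ["NAUSEA"]),
        CaseReport("3", 1, ["L01XA01"], [AKI]),
        CaseReport("4", 1, ["L01XA01"], []),
    ]

    def test_one_case_per_cell(self):
        t = contingency_for(self.COHORT, "D", AKI)
        assert (t.d1r1, t.d1r0, t.d0r1, t.d0r0) == (1, 1, 1, 1)

    def test_absent_co_drug_empty_exposed_row(self):
        t = contingency_for(self.COHORT, "E", AKI)
        assert t.d1r1 == 0 and t.d1r0 == 0 and t.total == 4

    def test_co_drug_equal_to_drug_a_rejected(self):
        with pytest.raises(ValueError):
            contingency_for(self.COHORT, "L01XA01", AKI, drug_a="L01XA01")

    def test_matches_bruteforce_recount(self):
        rng = np.random.default_rng(21)
        cohort = [
            CaseReport(
                str(i), 1,
                ["L01XA01"] + (["D"] if rng.random() < 0.4 else []),
                [AKI] if rng.random() < 0.3 else ["OTHER"],
            )
            for i in range(300)
        ]
        t = contingency_for(cohort, "D", AKI)
        brute = [0, 0, 0, 0]
        for r in cohort:
            d, e = "D" in r.drugs, AKI in r.reactions
            brute[(0 if d else 2) + (0 if e else 1)] += 1
        assert (t.d1r1, t.d1r0, t.d0r1, t.d0r0) == tuple(brute)


def oracle_ror(a, b, c, d):
    """Independent log-space evaluation of the odds ratio and Woolf interval."""
    log_ror = math.log(a) + math.log(d) - math.log(b) - math.log(c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return (
        math.exp(log_ror),
        math.exp(log_ror - Z_95 * se),
        math.exp(log_ror + Z_95 * se),
    )


class TestComputeRor:
    def test_balanced_table_is_null(self):
        r = compute_ror(ContingencyTable(10, 10, 10, 10))
        assert r.ror == pytest.approx(1.0)
        assert r.ci_low < 1 < r.ci_high and not r.protective

    def test_protective_worked_example(self):
        r = compute_ror(ContingencyTable(10, 90, 200, 700))
        assert r.ror == pytest.approx(0.3889, abs=1e-4)
        assert r.ci_low == pytest.approx(0.199, abs=1e-3)
        assert r.ci_high == pytest.approx(0.762, abs=1e-3)
        assert r.protective and not r.corrected

    def test_zero_cell_continuity_correction(self):
        r = compute_ror(ContingencyTable(0, 50, 100, 400))
        expected = (0.5 / 50.5) / (100.5 / 400.5)
        assert r.corrected and r.ror == pytest.approx(expected, rel=1e-12)
        assert r.ror == pytest.approx(0.0395, abs=1e-4)

    def test_empty_margin_undefined(self):
        r = compute_ror(ContingencyTable(0, 0, 10, 10))
        assert r.undefined and not r.protective

    @settings(max_examples=300, derandomize=True, deadline=None)
    @given(st.tuples(*[st.integers(min_value=1, max_value=5000)] * 4))
    def test_matches_log_space_oracle(self, cells):
        a, b, c, d = cells
        r = compute_ror(ContingencyTable(a, b, c, d))
        ror, lo, hi = oracle_ror(a, b, c, d)
        assert r.ror == pytest.approx(ror, rel=1e-10)
        assert r.ci_low == pytest.approx(lo, rel=1e-10)
        assert r.ci_high == pytest.approx(hi, rel=1e-10)

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(st.tuples(*[st.integers(min_value=1, max_value=1000)] * 4))
    def test_reaction_swap_reciprocates(self, cells):
        a, b, c, d = cells
        r1 = compute_ror(ContingencyTable(a, b, c, d))
        r2 = compute_ror(ContingencyTable(b, a, d, c))
        assert r1.ror == pytest.approx(1 / r2.ror, rel=1e-10)
        assert r1.ci_low == pytest.approx(1 / r2.ci_high, rel=1e-10)
        assert r1.ci_high == pytest.approx(1 / r2.ci_low, rel=1e-10)


class TestScreen:
    def test_min_exposed_floor(self):
        cohort = [
            CaseReport("1", 1, ["L01XA01", "D"], [AKI]),
            CaseReport("2", 1, ["L01XA01"], []),
            CaseReport("3", 1, ["L01XA01"], []),
        ]
        assert screen_comedications(cohort, AKI, min_exposed=3, drug_a="L01XA01") == []

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            screen_comedications([], AKI)

    def test_sorted_by_ci_high(self):
        rng = np.random.default_rng(31)
        cohort = []
        for i in range(500):
            drugs = ["L01XA01"]
            if rng.random() < 0.4:
                drugs.append("GOOD")
            if rng.random() < 0.4:
                drugs.append("BAD")
            evt = rng.random() < (0.1 if "GOOD" in drugs else 0.5)
            cohort.append(CaseReport(str(i), 1, drugs, [AKI] if evt else []))
        results = screen_comedications(cohort, AKI, drug_a="L01XA01")
        his = [r.ci_high for r in results]
        assert his == sorted(his)

    def test_row_order_invariance(self, tmp_path):
        demo_rows = ["101$1$1", "202$2$1", "303$3$1", "404$4$1", "505$5$1", "606$6$1"]
        drug_rows = [f"{p}$CISPLATIN" for p in (101, 202, 303, 404, 505, 606)] + [
            "101$PALONOSETRON", "202$PALONOSETRON", "303$PALONOSETRON"
        ]
        reac_rows = [f"404${AKI}", f"505${AKI}"]
        syn = {"CISPLATIN": "L01XA01", "PALONOSETRON": "A04AA05"}

        def run(dr, gr, rr):
            demo, drug, reac = write_tables(tmp_path, dr, gr, rr)
            cases, _ = read_faers_tables(demo, drug, reac)
            collated, _ = collate_to_atc(deduplicate_cases(cases), syn)
            cohort = build_cohort(collated, "L01XA01")
            return [
                (r.drug, r.ror, r.ci_low, r.ci_high)
                for r in screen_comedications(cohort, AKI, min_exposed=1, drug_a="L01XA01")
            ]

        base = run(demo_rows, drug_rows, reac_rows)
        shuffled = run(demo_rows[::-1], drug_rows[::-1], reac_rows[::-1])
        assert base == shuffled
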