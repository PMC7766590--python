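"""Pharmacovigilance screen for protective co-medications.

Reimplements a spontaneous-report disproportionality calculator: parse
DEMO/DRUG/REAC report tables, deduplicate each case to its most recent
version, collate verbatim drug strings to ATC level-5 codes, restrict to
the cohort exposed to a causative drug A (e.g. cisplatin, L01XA01), and
for every co-administered drug d build the 2x2 table of the cohort

====== =========== ===========
 .      reaction r  no reaction
 d      d1r1        d1r0
 no d   d0r1        d0r0
====== =========== ===========

The reporting odds ratio is ROR = (d1r1/d1r0)/(d0r1/d0r0) with the Woolf
log-normal 95% interval ``exp(ln ROR +/- 1.96*sqrt(sum of reciprocal
cells))``.  Tables with a zero cell receive the Haldane-Anscombe +0.5
correction.  A co-medication is flagged protective when the interval's
upper bound lies below 1 — i.e. the drug is reported with the reaction
significantly less often than the rest of the cohort.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import io as _io
from .signature import bh_adjust

__all__ = [
    "CaseReport",
    "ContingencyTable",
    "RorResult",
    "Z_95",
    "read_faers_tables",
    "cases_from_tables",
    "deduplicate_cases",
    "collate_to_atc",
    "build_cohort",
    "contingency_for",
    "compute_ror",
    "screen_comedications",
    "normalize_drug_string",
]

#: two-sided 95% normal quantile used for the Woolf interval
Z_95 = 1.959964

ATC_PATTERN = re.compile(r"^[A-Z]\d{2}[A-Z]{2}\d{2}$")


@dataclass
class CaseReport:
    """One version of one adverse-event case."""

    case_id: str
    version: int
    drugs: list[str]
    reactions: list[str]
    primary_id: str = ""

    def __post_init__(self) -> None:
        if self.version < 1:
            raise ValueError("version must be >= 1")
        # dedupe within the case, preserving first-seen order
        self.drugs = list(dict.fromkeys(self.drugs))
        self.reactions = list(dict.fromkeys(self.reactions))


@dataclass
class ContingencyTable:
    d1r1: float
    d1r0: float
    d0r1: float
    d0r0: float

    def __post_init__(self) -> None:
        if min(self.d1r1, self.d1r0, self.d0r1, self.d0r0) < 0:
            raise ValueError("contingency cells must be non-negative")

    @property
    def total(self) -> float:
        return self.d1r1 + self.d1r0 + self.d0r1 + self.d0r0

    def corrected(self) -> "ContingencyTable":
        return ContingencyTable(self.d1r1 + 0.5, self.d1r0 + 0.5, self.d0r1 + 0.5, self.d0r0 + 0.5)


@dataclass
class RorResult:
    drug: str
    table: ContingencyTable
    ror: float
    ci_low: float
    ci_high: float
    protective: bool
    corrected: bool
    undefined: bool = False


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------


def read_faers_tables(
    demo_path: str | Path,
    drug_path: str | Path,
    reac_path: str | Path,
) -> tuple[list[CaseReport], dict[str, int]]:
    """Read the ``$``-delimited DEMO/DRUG/REAC tables into case reports.

    Returns the cases and a report counting DRUG/REAC rows that referenced
    an unknown primary id (those rows are skipped).
    """
    demo = _io.read_delim_table(demo_path, ["primaryid", "caseid", "caseversion"])
    drug = _io.read_delim_table(drug_path, ["primaryid", "drugname"])
    reac = _io.read_delim_table(reac_path, ["primaryid", "pt"])
    return cases_from_tables(demo, drug, reac)


def cases_from_tables(
    demo: pd.DataFrame,
    drug: pd.DataFrame,
    reac: pd.DataFrame,
) -> tuple[list[CaseReport], dict[str, int]]:
    """Join DEMO/DRUG/REAC rows by primary id into one CaseReport per row of DEMO."""
    known = set(demo["primaryid"])
    skipped = {
        "drug_rows_unknown_primaryid": int((~drug["primaryid"].isin(known)).sum()),
        "reac_rows_unknown_primaryid": int((~reac["primaryid"].isin(known)).sum()),
    }
    drugs_by_pid: dict[str, list[str]] = {}
    for pid, name in zip(drug["primaryid"], drug["drugname"]):
        if pid in known:
            drugs_by_pid.setdefault(pid, []).append(name)
    reacs_by_pid: dict[str, list[str]] = {}
    for pid, pt in zip(reac["primaryid"], reac["pt"]):
        if pid in known:
            reacs_by_pid.setdefault(pid, []).append(pt)
    cases = [
        CaseReport(
            case_id=str(cid),
            version=int(ver),
            drugs=drugs_by_pid.get(pid, []),
            reactions=reacs_by_pid.get(pid, []),
            primary_id=str(pid),
        )
        for pid, cid, ver in zip(demo["primaryid"], demo["caseid"], demo["caseversion"])
    ]
    return cases, skipped


# ---------------------------------------------------------------------------
# curation
# ---------------------------------------------------------------------------


def deduplicate_cases(reports: Iterable[CaseReport]) -> list[CaseReport]:
    """Keep the most recent report per case: highest version, ties by primary id."""

    def recency(r: CaseReport) -> tuple[int, tuple[int, str]]:
        pid = r.primary_id
        pid_key = (1, "") if not pid else ((0, pid) if not pid.isdigit() else (1, f"{int(pid):020d}"))
        return (r.version, pid_key)

    best: dict[str, CaseReport] = {}
    for r in reports:
        cur = best.get(r.case_id)
        if cur is None or recency(r) > recency(cur):
            best[r.case_id] = r

    def case_key(cid: str):
        return (0, int(cid), "") if cid.isdigit() else (1, 0, cid)

    return [best[cid] for cid in sorted(best, key=case_key)]


def normalize_drug_string(verbatim: str) -> str:
    """Trim, uppercase and collapse internal whitespace."""
    return " ".join(verbatim.strip().upper().split())


def collate_to_atc(
    reports: Sequence[CaseReport],
    synonym_table: Mapping[str, str],
) -> tuple[list[CaseReport], Counter]:
    """Map verbatim drug strings to ATC level-5 codes.

    Two strings mapping to one code collapse to a single drug per case;
    unmapped strings are dropped and tallied in the returned counter.
    """
    normalized = {}
    for verbatim, atc in synonym_table.items():
        if not ATC_PATTERN.match(atc):
            raise ValueError(f"invalid ATC level-5 code {atc!r} for {verbatim!r}")
        normalized[normalize_drug_string(verbatim)] = atc
    unmapped: Counter = Counter()
    out: list[CaseReport] = []
    for r in reports:
        codes: list[str] = []
        for d in r.drugs:
            key = normalize_drug_string(d)
            atc = normalized.get(key)
            if atc is None:
                unmapped[key] += 1
            elif atc not in codes:
                codes.append(atc)
        out.append(CaseReport(r.case_id, r.version, codes, list(r.reactions), r.primary_id))
    return out, unmapped


def build_cohort(reports: Sequence[CaseReport], drug_a: str | set[str]) -> list[CaseReport]:
    """Cases whose (collated) drug set intersects the causative drug(s)."""
    drug_a_set = {drug_a} if isinstance(drug_a, str) else set(drug_a)
    cohort = [r for r in reports if drug_a_set & set(r.drugs)]
    if not cohort:
        raise ValueError(f"no case contains causative drug {sorted(drug_a_set)}; screen undefined")
    return cohort


# ---------------------------------------------------------------------------
# disproportionality
# ---------------------------------------------------------------------------


def contingency_for(
    cohort: Sequence[CaseReport],
    co_drug: str,
    reaction: str,
    drug_a: str | set[str] | None = None,
) -> ContingencyTable:
    """2x2 table of the cohort cross-classified by co-drug and reaction."""
    if drug_a is not None:
        drug_a_set = {drug_a} if isinstance(drug_a, str) else set(drug_a)
        if co_drug in drug_a_set:
            raise ValueError(f"co-drug {co_drug!r} equals causative drug A")
    term = normalize_drug_string(reaction)
    cells = [0, 0, 0, 0]  # d1r1, d1r0, d0r1, d0r0
    for r in cohort:
        has_d = co_drug in r.drugs
        has_r = any(normalize_drug_string(x) == term for x in r.reactions)
        cells[(0 if has_d else 2) + (0 if has_r else 1)] += 1
    return ContingencyTable(*cells)


def compute_ror(table: ContingencyTable, drug: str = "") -> RorResult:
    """Reporting odds ratio with the Woolf log-normal 95% interval.

    Zero cells trigger the Haldane-Anscombe +0.5 correction (flagged).  A
    table whose d1 or d0 margin is empty yields an undefined result that
    the screen excludes.
    """
    if table.d1r1 + table.d1r0 == 0 or table.d0r1 + table.d0r0 == 0:
        nan = float("nan")
        return RorResult(drug, table, nan, nan, nan, protective=False, corrected=False, undefined=True)
    corrected = min(table.d1r1, table.d1r0, table.d0r1, table.d0r0) == 0
    t = table.corrected() if corrected else table
    ror = (t.d1r1 / t.d1r0) / (t.d0r1 / t.d0r0)
    se = np.sqrt(1.0 / t.d1r1 + 1.0 / t.d1r0 + 1.0 / t.d0r1 + 1.0 / t.d0r0)
    ci_low = float(ror * np.exp(-Z_95 * se))
    ci_high = float(ror * np.exp(Z_95 * se))
    return RorResult(drug, table, float(ror), ci_low, ci_high, protective=ci_high < 1.0, corrected=corrected)


def screen_comedications(
    cohort: Sequence[CaseReport],
    reaction: str,
    min_exposed: int = 3,
    drug_a: str | set[str] | None = None,
    bh_correct: bool = False,
) -> list[RorResult]:
    """ROR screen of every co-medication seen in >= ``min_exposed`` cohort cases.

    Results are sorted by CI upper bound ascending; ``protective`` marks
    drugs whose whole 95% interval lies below 1.  ``bh_correct=True``
    additionally requires a BH-adjusted two-sided Wald p < 0.05 (off by
    default, mirroring the CI-only convention).
    """
    if not cohort:
        raise ValueError("empty cohort")
    drug_a_set = ({drug_a} if isinstance(drug_a, str) else set(drug_a)) if drug_a is not None else set()
    term = normalize_drug_string(reaction)

    exposure: Counter = Counter()
    with_r: Counter = Counter()
    n_r = 0
    for r in cohort:
        has_r = any(normalize_drug_string(x) == term for x in r.reactions)
        n_r += has_r
        for d in r.drugs:
            if d in drug_a_set:
                continue
            exposure[d] += 1
            if has_r:
                with_r[d] += 1
    n = len(cohort)

    results: list[RorResult] = []
    for d, n_exposed in exposure.items():
        if n_exposed < min_exposed:
            continue
        d1r1 = with_r[d]
        table = ContingencyTable(d1r1, n_exposed - d1r1, n_r - d1r1, n - n_exposed - (n_r - d1r1))
        results.append(compute_ror(table, drug=d))

    results = [r for r in results if not r.undefined]
    if bh_correct and results:
        z = np.array([abs(np.log(r.ror)) / (np.log(r.ci_high / r.ror) / Z_95) for r in results])
        q = bh_adjust(2.0 * stats.norm.sf(z))
        for r, qv in zip(results, q):
            r.protective = bool(r.protective and qv < 0.05 and r.ror < 1.0)
    results.sort(key=lambda r: (r.ci_high, r.drug))
    return results


def results_to_frame(results: Sequence[RorResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "drug": [r.drug for r in results],
            "d1r1": [r.table.d1r1 for r in results],
            "d1r0": [r.table.d1r0 for r in results],
            "d0r1": [r.table.d0r1 for r in results],
            "d0r0": [r.table.d0r0 for r in results],
            "ror": [r.ror for r in results],
            "ci_low": [r.ci_low for r in results],
            "ci_high": [r.ci_high for r in results],
            "protective": [r.protective for r in results],
            "corrected": [r.corrected for r in results],
        }
    )
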