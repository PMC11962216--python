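"""Spontaneous-report disproportionality analysis.

Case reports from a FAERS-style adverse-event database are reduced to one
record per case (keeping the latest version), cross-tabulated against a
target drug class and a target set of MedDRA preferred terms (PTs), and
screened for a reporting signal with the reporting odds ratio (ROR)

    ROR = (a/c) / (b/d),    95% CI = exp( ln ROR ± z * sqrt(1/a+1/b+1/c+1/d) )

where ``a`` counts reports with both the target drug (as primary suspect)
and the target event, and ``b``, ``c``, ``d`` fill the remaining cells of
the drug x event 2x2 table.  A signal requires at least ``min_reports``
target reports and a CI lower bound strictly above 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "CaseReport",
    "TwoByTwo",
    "SignalResult",
    "deduplicate_reports",
    "build_two_by_two",
    "ror_signal",
    "summarize_characteristics",
    "read_reports_csv",
    "write_reports_csv",
]

SEXES = frozenset({"F", "M"})
ROLES = frozenset({"suspect", "concomitant"})
REPORTERS = frozenset({"CN", "HP", "LW", "MD", "OT", "PH", "RN"})

def _weight_band(v: float) -> str:
    if v < 50:
        return "< 50 kg"
    if v <= 100:
        return "50-100 kg"
    return "> 100 kg"


def _age_band(v: float) -> str:
    if v < 18:
        return "< 18"
    if v < 65:
        return "18-64.9"
    if v <= 85:
        return "65-85"
    return "> 85"


@dataclass(frozen=True)
class CaseReport:
    """A single adverse-event case report (one row of a FAERS-style extract)."""

    case_id: str
    version: int
    drug: str
    role: str  # 'suspect' or 'concomitant'
    pt: str  # MedDRA preferred term
    sex: str | None = None  # 'F', 'M' or None
    age_years: float | None = None
    weight_kg: float | None = None
    reporter: str | None = None
    country: str | None = None
    year: int = 2004

    def __post_init__(self) -> None:
        if self.version < 1:
            raise ValueError(f"case {self.case_id}: version must be >= 1, got {self.version}")
        if self.role not in ROLES:
            raise ValueError(f"case {self.case_id}: invalid role {self.role!r}")
        if self.sex is not None and self.sex not in SEXES:
            raise ValueError(f"case {self.case_id}: invalid sex {self.sex!r}")
        if self.reporter is not None and self.reporter not in REPORTERS:
            raise ValueError(f"case {self.case_id}: invalid reporter {self.reporter!r}")


@dataclass(frozen=True)
class TwoByTwo:
    """Drug x event contingency table.

    a = target drug & target event, b = target drug & other events,
    c = other drugs & target event, d = other drugs & other events.
    ``corrected`` marks the Haldane-Anscombe 0.5 continuity correction.
    """

    a: float
    b: float
    c: float
    d: float
    corrected: bool = False

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be nonnegative")

    @property
    def total(self) -> float:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class SignalResult:
    """ROR disproportionality verdict for one drug/event pairing."""

    label: str
    n_target: int
    ror: float
    ci_low: float
    ci_high: float
    is_signal: bool


def _require_consistent(reports: Sequence[CaseReport]) -> None:
    seen: dict[tuple[str, int], CaseReport] = {}
    for r in reports:
        key = (r.case_id, r.version)
        prev = seen.get(key)
        if prev is not None and prev != r:
            raise ValueError(f"conflicting duplicate records for case {r.case_id!r} version {r.version}")
        seen[key] = r


def deduplicate_reports(reports: Sequence[CaseReport]) -> list[CaseReport]:
    """Keep one report per case: highest version, ties by latest year then input order.

    Returns reports sorted by ``case_id`` (stable).  Identical duplicate
    (case_id, version) rows collapse silently; conflicting ones raise.
    """
    _require_consistent(reports)
    best: dict[str, tuple[int, int, int, CaseReport]] = {}
    for idx, r in enumerate(reports):
        cur = best.get(r.case_id)
        key = (r.version, r.year, -idx)  # -idx: earlier input wins at full ties
        if cur is None or key > (cur[0], cur[1], cur[2]):
            best[r.case_id] = (r.version, r.year, -idx, r)
    return [best[cid][3] for cid in sorted(best)]


def build_two_by_two(
    reports: Sequence[CaseReport],
    target_drugs: Iterable[str],
    target_pts: Iterable[str],
    suspect_only: bool = True,
) -> TwoByTwo:
    """Cross-tabulate deduplicated reports into the drug x event 2x2 table.

    With ``suspect_only`` (the default) a report counts as drug-exposed only
    when the target drug is the primary suspect; concomitant target-drug
    reports fall into the comparator row so the four cells always sum to the
    number of reports.
    """
    drugs = set(target_drugs)
    pts = set(target_pts)
    if not drugs:
        raise ValueError("target_drugs must be nonempty")
    if not pts:
        raise ValueError("target_pts must be nonempty")
    a = b = c = d = 0
    for r in reports:
        exposed = r.drug in drugs and (r.role == "suspect" or not suspect_only)
        event = r.pt in pts
        if exposed and event:
            a += 1
        elif exposed:
            b += 1
        elif event:
            c += 1
        else:
            d += 1
    return TwoByTwo(a, b, c, d)


def ror_signal(t: TwoByTwo, label: str = "target", min_reports: int = 3, z: float = 1.96) -> SignalResult:
    """Reporting odds ratio with normal-approximation CI and the signal rule.

    Zero cells trigger the Haldane-Anscombe correction (0.5 added to every
    cell) before the ratio is formed; ``n_target`` reports the uncorrected
    ``a``.  A signal needs n_target >= min_reports and ci_low > 1.
    """
    if t.total == 0:
        raise ValueError("all-zero contingency table")
    n_target = int(t.a)
    if min(t.a, t.b, t.c, t.d) == 0 and not t.corrected:
        t = TwoByTwo(t.a + 0.5, t.b + 0.5, t.c + 0.5, t.d + 0.5, corrected=True)
    ror = (t.a * t.d) / (t.b * t.c)
    se_log = math.sqrt(1 / t.a + 1 / t.b + 1 / t.c + 1 / t.d)
    ci_low = math.exp(math.log(ror) - z * se_log)
    ci_high = math.exp(math.log(ror) + z * se_log)
    return SignalResult(
        label=label,
        n_target=n_target,
        ror=ror,
        ci_low=ci_low,
        ci_high=ci_high,
        is_signal=n_target >= min_reports and ci_low > 1.0,
    )


def round_pct(count: int, total: int) -> float:
    """Percentage 100*count/total, rounded half-up to one decimal (0.0 if total=0)."""
    if total == 0:
        return 0.0
    pct = Decimal(100 * count) / Decimal(total)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def _level(r: CaseReport, variable: str) -> str:
    if variable == "sex":
        return r.sex if r.sex is not None else "Missing"
    if variable == "weight":
        return "Missing" if r.weight_kg is None else _weight_band(r.weight_kg)
    if variable == "age":
        return "Missing" if r.age_years is None else _age_band(r.age_years)
    if variable == "reporter":
        return r.reporter if r.reporter is not None else "Missing"
    if variable == "year":
        return str(r.year)
    if variable == "country":
        return r.country if r.country is not None else "Missing"
    raise KeyError(variable)


def summarize_characteristics(
    reports: Sequence[CaseReport], target_pts: Iterable[str]
) -> pd.DataFrame:
    """Stratified report characteristics split by target-event status.

    One row per (variable, level) with counts and one-decimal percentages in
    the no-target-PT, target-PT and overall columns; an explicit ``Missing``
    level is always present.  Percentages are taken against each column's
    total report count, so levels within a variable sum to the column total.
    """
    pts = set(target_pts)
    variables = ("sex", "weight", "age", "reporter", "year", "country")
    is_target = [r.pt in pts for r in reports]
    n_target = sum(is_target)
    n_other = len(reports) - n_target
    n_all = len(reports)

    rows = []
    for var in variables:
        counts: dict[str, list[int]] = {}
        for r, tgt in zip(reports, is_target):
            lev = _level(r, var)
            cell = counts.setdefault(lev, [0, 0])
            cell[1 if tgt else 0] += 1
        levels = sorted(counts)
        if "Missing" not in counts:
            levels.append("Missing")
            counts["Missing"] = [0, 0]
        else:  # Missing reported last, matching the conventional table layout
            levels.remove("Missing")
            levels.append("Missing")
        for lev in levels:
            c0, c1 = counts[lev]
            rows.append(
                {
                    "variable": var,
                    "level": lev,
                    "count_no_target": c0,
                    "pct_no_target": round_pct(c0, n_other),
                    "count_target": c1,
                    "pct_target": round_pct(c1, n_target),
                    "count_overall": c0 + c1,
                    "pct_overall": round_pct(c0 + c1, n_all),
                }
            )
    df = pd.DataFrame(
        rows,
        columns=[
            "variable",
            "level",
            "count_no_target",
            "pct_no_target",
            "count_target",
            "pct_target",
            "count_overall",
            "pct_overall",
        ],
    )
    df.attrs["n_no_target"] = n_other
    df.attrs["n_target"] = n_target
    df.attrs["n_overall"] = n_all
    return df


# ---------------------------------------------------------------------------
# I/O: CSV with header case_id,version,drug,role,pt,sex,age_years,weight_kg,
# reporter,country,year; missing values are empty fields.

_REPORT_COLUMNS = [
    "case_id",
    "version",
    "drug",
    "role",
    "pt",
    "sex",
    "age_years",
    "weight_kg",
    "reporter",
    "country",
    "year",
]


def read_reports_csv(path) -> list[CaseReport]:
    df = pd.read_csv(path, dtype={"case_id": str}, keep_default_na=True)
    missing = [c for c in _REPORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"reports file lacks columns: {missing}")
    out = []
    for row in df.itertuples(index=False):
        out.append(
            CaseReport(
                case_id=str(row.case_id),
                version=int(row.version),
                drug=str(row.drug),
                role=str(row.role),
                pt=str(row.pt),
                sex=None if pd.isna(row.sex) else str(row.sex),
                age_years=None if pd.isna(row.age_years) else float(row.age_years),
                weight_kg=None if pd.isna(row.weight_kg) else float(row.weight_kg),
                reporter=None if pd.isna(row.reporter) else str(row.reporter),
                country=None if pd.isna(row.country) else str(row.country),
                year=int(row.year),
            )
        )
    return out


def write_reports_csv(reports: Sequence[CaseReport], path) -> None:
    df = pd.DataFrame([vars(r) for r in reports], columns=_REPORT_COLUMNS)
    df.to_csv(path, index=False)
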