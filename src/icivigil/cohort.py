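"""Descriptive and comparative cohort analyses of selected cases.

Reproduces the standard pharmacovigilance cohort outputs: a characteristics
table (counts and percentages per stratum), fatal vs non-fatal contrasts
(chi-square for categorical strata, rank-based tests for age and time to
onset), per-regimen time-to-onset distributions with an omnibus
Kruskal–Wallis test, and case-fatality proportions by regimen or event group.

Percentages are rounded half-up to two decimals, the convention of published
characteristic tables.  Quantiles use linear interpolation between order
statistics, so interquartile bounds like 73.75 or 88.5 are representable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .ingest import PTCatalog, RegimenLabel, SafetyReport, classify_regimen, compute_tto

AGE_BANDS = ("<18", "18-64", ">=65", "unknown")
TTO_BANDS = ("0-30", "31-60", "61-90", "91-180", ">180", "unknown")
OUTCOME_LEVELS = ("DE", "LT", "DS", "HO", "OT", "RI", "CA", "NS")

CHARACTERISTICS = (
    "sex",
    "age_band",
    "year",
    "continent",
    "indication",
    "outcome",
    "tto_band",
    "regimen",
)


def round_half_up(x: float, ndigits: int = 2) -> float:
    scale = 10 ** ndigits
    return math.floor(x * scale + 0.5) / scale


def age_band(age_years: Optional[float]) -> str:
    if age_years is None:
        return "unknown"
    if age_years < 18:
        return "<18"
    if age_years < 65:
        return "18-64"
    return ">=65"


def tto_band(tto_days: Optional[int]) -> str:
    if tto_days is None:
        return "unknown"
    if tto_days <= 30:
        return "0-30"
    if tto_days <= 60:
        return "31-60"
    if tto_days <= 90:
        return "61-90"
    if tto_days <= 180:
        return "91-180"
    return ">180"


def report_year(report: SafetyReport) -> str:
    if report.report_date and len(report.report_date) >= 4:
        return report.report_date[:4]
    return "unknown"


def case_frame(reports: Sequence[SafetyReport]) -> pd.DataFrame:
    """One row per case with the derived analysis variables."""
    rows = []
    for r in reports:
        tto = compute_tto(r)
        try:
            regimen = classify_regimen(r).label
        except ValueError:
            regimen = "unclassified"
        rows.append(
            {
                "case_id": r.case_id,
                "sex": r.sex,
                "age_years": r.age_years,
                "age_band": age_band(r.age_years),
                "year": report_year(r),
                "continent": r.continent,
                "indication": r.indication,
                "outcome": r.primary_outcome(),
                "tto": tto,
                "tto_band": tto_band(tto),
                "regimen": regimen,
                "died": r.died,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class CohortSummary:
    n_cases: int
    strata: pd.DataFrame  # characteristic, level, count, percent
    medians: dict[str, tuple[float, float, float]]  # var -> (median, q1, q3)
    n_known_tto: int = 0

    def count(self, characteristic: str, level: str) -> int:
        df = self.strata
        m = (df["characteristic"] == characteristic) & (df["level"] == level)
        return int(df.loc[m, "count"].sum())

    def percent(self, characteristic: str, level: str) -> float:
        df = self.strata
        m = (df["characteristic"] == characteristic) & (df["level"] == level)
        vals = df.loc[m, "percent"]
        return float(vals.iloc[0]) if len(vals) else 0.0

    def percent_of_known_tto(self, band: str) -> float:
        """Share of a TTO band among cases with a known onset interval."""
        if self.n_known_tto == 0:
            return 0.0
        return round_half_up(100.0 * self.count("tto_band", band) / self.n_known_tto)


def _quantiles(values: Iterable[float]) -> Optional[tuple[float, float, float]]:
    arr = np.asarray([v for v in values if v is not None and not pd.isna(v)], dtype=float)
    if arr.size == 0:
        return None
    q1, med, q3 = np.quantile(arr, [0.25, 0.5, 0.75])  # linear interpolation
    return float(med), float(q1), float(q3)


def summarize(reports: Sequence[SafetyReport]) -> CohortSummary:
    """Characteristics table: count and percent-of-cohort per stratum level."""
    df = case_frame(reports)
    n = len(df)
    if n == 0:
        return CohortSummary(0, pd.DataFrame(
            columns=["characteristic", "level", "count", "percent"]), {})

    rows = []
    for char in CHARACTERISTICS:
        counts = df[char].value_counts()
        for level, cnt in counts.items():
            rows.append(
                {
                    "characteristic": char,
                    "level": str(level),
                    "count": int(cnt),
                    "percent": round_half_up(100.0 * cnt / n),
                }
            )
    strata = pd.DataFrame(rows).sort_values(
        ["characteristic", "level"], kind="mergesort"
    ).reset_index(drop=True)

    medians = {}
    for var in ("age_years", "tto"):
        q = _quantiles(df[var])
        if q is not None:
            medians[var] = q
    return CohortSummary(
        n_cases=n,
        strata=strata,
        medians=medians,
        n_known_tto=int((df["tto_band"] != "unknown").sum()),
    )


# ---------------------------------------------------------------------------
# fatal vs non-fatal comparison
# ---------------------------------------------------------------------------

_TESTABLE_CATEGORICAL = ("sex", "age_band", "year", "continent", "indication", "regimen")


def compare_fatal_nonfatal(reports: Sequence[SafetyReport]) -> pd.DataFrame:
    """Fatal vs non-fatal contrasts per characteristic.

    Categorical characteristics are tested with a chi-square on the
    level x {fatal, non-fatal} contingency, excluding 'unknown' levels;
    age and TTO with a two-sided Wilcoxon rank-sum test.  Characteristics
    with a single observed level are skipped (recorded with test 'skipped').
    """
    df = case_frame(reports)
    if df.empty or df["died"].nunique() < 2:
        raise ValueError("cohort must contain both fatal and non-fatal cases")

    out = []
    for char in _TESTABLE_CATEGORICAL:
        sub = df[~df[char].isin(["unknown", "Unknown"])]
        tab = pd.crosstab(sub[char], sub["died"])
        if tab.shape[0] < 2 or tab.shape[1] < 2:
            out.append({"characteristic": char, "test": "skipped",
                        "statistic": float("nan"), "p_value": float("nan")})
            continue
        res = stats.chi2_contingency(tab.values, correction=False)
        out.append({"characteristic": char, "test": "chi-square",
                    "statistic": float(res.statistic), "p_value": float(res.pvalue)})

    for var in ("age_years", "tto"):
        fatal = df.loc[df["died"], var].dropna().to_numpy(dtype=float)
        nonfatal = df.loc[~df["died"], var].dropna().to_numpy(dtype=float)
        if len(fatal) == 0 or len(nonfatal) == 0:
            out.append({"characteristic": var, "test": "skipped",
                        "statistic": float("nan"), "p_value": float("nan")})
            continue
        res = stats.mannwhitneyu(fatal, nonfatal, alternative="two-sided")
        out.append({"characteristic": var, "test": "rank-sum",
                    "statistic": float(res.statistic), "p_value": float(res.pvalue)})
    return pd.DataFrame(out, columns=["characteristic", "test", "statistic", "p_value"])


# ---------------------------------------------------------------------------
# time to onset by regimen
# ---------------------------------------------------------------------------


@dataclass
class TTOByRegimen:
    per_regimen: pd.DataFrame  # regimen, n_known, median, q1, q3
    test_name: str
    statistic: float
    p_value: float


def tto_by_regimen(reports: Sequence[SafetyReport], min_group_size: int = 5) -> TTOByRegimen:
    """Per-regimen TTO median/IQR plus an omnibus Kruskal–Wallis test.

    The omnibus test uses regimens with at least ``min_group_size`` known
    onset intervals; the summary table includes all regimens with >= 1.
    """
    df = case_frame(reports).dropna(subset=["tto"])
    if df.empty:
        raise ValueError("no cases with a known time to onset")

    rows = []
    groups = []
    for regimen, sub in df.groupby("regimen", sort=True):
        vals = sub["tto"].to_numpy(dtype=float)
        med, q1, q3 = _quantiles(vals)
        rows.append({"regimen": regimen, "n_known": len(vals),
                     "median": med, "q1": q1, "q3": q3})
        if len(vals) >= min_group_size:
            groups.append(vals)

    if len(groups) >= 2:
        res = stats.kruskal(*groups)
        stat, p = float(res.statistic), float(res.pvalue)
        name = "Kruskal-Wallis"
    else:
        stat, p, name = float("nan"), float("nan"), "skipped"
    return TTOByRegimen(pd.DataFrame(rows), name, stat, p)


def pairwise_tto(reports: Sequence[SafetyReport], regimen_a: str, regimen_b: str) -> tuple[float, float]:
    """Two-sided rank-sum test between two regimens' TTO distributions."""
    df = case_frame(reports).dropna(subset=["tto"])
    a = df.loc[df["regimen"] == regimen_a, "tto"].to_numpy(dtype=float)
    b = df.loc[df["regimen"] == regimen_b, "tto"].to_numpy(dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both regimens need at least one known TTO")
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def table1_frame(reports: Sequence[SafetyReport]) -> pd.DataFrame:
    """Characteristics table split by outcome, one row per stratum level.

    Columns: characteristic, level, total_n, total_pct, fatal_n, fatal_pct,
    nonfatal_n, nonfatal_pct, p_value (the fatal vs non-fatal test for that
    characteristic, repeated across its levels).
    """
    total = summarize(reports)
    fatal = summarize([r for r in reports if r.died])
    nonfatal = summarize([r for r in reports if not r.died])
    try:
        tests = compare_fatal_nonfatal(reports).set_index("characteristic")["p_value"]
    except ValueError:
        tests = pd.Series(dtype=float)

    rows = []
    for char in CHARACTERISTICS:
        sub = total.strata[total.strata["characteristic"] == char]
        for rec in sub.itertuples(index=False):
            rows.append(
                {
                    "characteristic": char,
                    "level": rec.level,
                    "total_n": rec.count,
                    "total_pct": rec.percent,
                    "fatal_n": fatal.count(char, rec.level),
                    "fatal_pct": fatal.percent(char, rec.level),
                    "nonfatal_n": nonfatal.count(char, rec.level),
                    "nonfatal_pct": nonfatal.percent(char, rec.level),
                    "p_value": float(tests.get(char, float("nan"))),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# case-fatality proportions
# ---------------------------------------------------------------------------


def fatality_rates(
    reports: Sequence[SafetyReport],
    by: str = "regimen",
    catalog: Optional[PTCatalog] = None,
) -> pd.DataFrame:
    """Case-fatality proportion per stratum: deaths / reports, as a percent.

    ``by='regimen'`` strata are the classified regimen labels.
    ``by='event_group'`` attributes each case to *every* event group among its
    qualifying reaction PTs (a case with both an atrial and a ventricular PT
    counts once in each group), so group Ns can exceed the case total.
    Strata with zero reports are omitted.
    """
    if by not in ("regimen", "event_group"):
        raise ValueError("by must be 'regimen' or 'event_group'")

    counts: dict[str, list[int]] = {}
    if by == "regimen":
        for r in reports:
            try:
                label = classify_regimen(r).label
            except ValueError:
                label = "unclassified"
            n, dth = counts.get(label, (0, 0))
            counts[label] = [n + 1, dth + r.died]
    else:
        catalog = catalog or PTCatalog.default()
        for r in reports:
            groups = {g for g in (catalog.group_of(pt) for pt in r.reactions) if g}
            for g in groups:
                n, dth = counts.get(g, (0, 0))
                counts[g] = [n + 1, dth + r.died]

    rows = [
        {
            "stratum": k,
            "n_reports": n,
            "n_deaths": dth,
            "fatality_percent": round_half_up(100.0 * dth / n),
        }
        for k, (n, dth) in sorted(counts.items())
        if n > 0
    ]
    return pd.DataFrame(rows, columns=["stratum", "n_reports", "n_deaths", "fatality_percent"])
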