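"""Ingestion of FAERS-style quarterly ASCII extracts.

FAERS distributes spontaneous adverse-event reports as ``$``-delimited text
tables (DEMO, DRUG, REAC, OUTC, THER, INDI) keyed by a version-bearing
``primaryid`` and a stable ``caseid``.  This module parses those tables,
deduplicates case revisions, normalises drug names against a dictionary of
brand and generic names, and assembles one :class:`SafetyReport` per case.

Case selection follows the usual pharmacovigilance convention: a case enters
the study cohort when the drug of interest is the *primary suspect* (role code
``PS``) and at least one reaction preferred term (PT) belongs to the event
catalog.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from datetime import date, datetime
from pathlib import Path
from typing import Callable, Iterable, Mapping, Optional, Sequence

import pandas as pd

from ._resources import (
    country_continent_map,
    drug_dictionary_frame,
    indication_keyword_map,
    pt_catalog_frame,
)

ROLE_CODES = ("PS", "SS", "C", "I")
OUTCOME_CODES = ("DE", "LT", "HO", "DS", "CA", "RI", "OT")
# display order for the "most serious outcome" of a case
OUTCOME_SEVERITY = ("DE", "LT", "DS", "HO", "RI", "CA", "OT")

ANTI_PD1 = frozenset({"nivolumab", "pembrolizumab", "cemiplimab"})
ANTI_PDL1 = frozenset({"atezolizumab", "avelumab", "durvalumab"})
ANTI_CTLA4 = frozenset({"ipilimumab", "tremelimumab"})
ICI_SUBSTANCES = ANTI_PD1 | ANTI_PDL1 | ANTI_CTLA4

NAMED_COMBINATIONS = {
    frozenset({"ipilimumab", "nivolumab"}): "Ipilimumab + nivolumab",
    frozenset({"ipilimumab", "pembrolizumab"}): "Ipilimumab + pembrolizumab",
    frozenset({"tremelimumab", "durvalumab"}): "Tremelimumab + durvalumab",
    frozenset({"pembrolizumab", "atezolizumab"}): "Pembrolizumab + atezolizumab",
}

_AGE_UNIT_FACTORS = {
    "DEC": 10.0,
    "YR": 1.0,
    "MON": 1.0 / 12.0,
    "WK": 1.0 / 52.0,
    "DY": 1.0 / 365.25,
}


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DrugExposure:
    """One drug row attached to a case.

    ``start_date``/``end_date`` keep the raw FAERS digit strings (``YYYY``,
    ``YYYYMM`` or ``YYYYMMDD``); partial dates are preserved, not imputed.
    """

    verbatim_name: str
    substance: str  # canonical active substance, or "other"
    role: str  # PS / SS / C / I
    start_date: Optional[str] = None
    end_date: Optional[str] = None


@dataclass
class SafetyReport:
    """One deduplicated spontaneous report."""

    case_id: str
    primary_id: str
    sex: str  # male / female / unknown
    age_years: Optional[float]
    country: Optional[str]
    continent: str
    report_date: Optional[str]  # FDA receipt date, YYYYMMDD
    event_date: Optional[str]  # onset date, possibly partial
    indication: str  # indication group label
    drugs: list[DrugExposure] = field(default_factory=list)
    reactions: list[str] = field(default_factory=list)
    outcome_codes: tuple[str, ...] = ()

    @property
    def died(self) -> bool:
        return "DE" in self.outcome_codes

    def primary_outcome(self) -> str:
        """Most serious outcome code, or 'NS' (non-serious) when none."""
        for code in OUTCOME_SEVERITY:
            if code in self.outcome_codes:
                return code
        return "NS"

    def ici_substances(self, roles: Sequence[str] = ("PS", "SS")) -> frozenset[str]:
        return frozenset(
            d.substance
            for d in self.drugs
            if d.substance in ICI_SUBSTANCES and d.role in roles
        )


@dataclass(frozen=True)
class RegimenLabel:
    kind: str  # "monotherapy" | "combination"
    substances: tuple[str, ...]
    drug_class: str  # anti-PD-1 / anti-PD-L1 / anti-CTLA-4 / combination
    label: str


@dataclass
class RawRecordSet:
    """Parsed quarterly tables, referential integrity enforced against DEMO."""

    demo: pd.DataFrame
    drug: pd.DataFrame
    reac: pd.DataFrame
    outc: pd.DataFrame
    ther: pd.DataFrame
    indi: pd.DataFrame
    quarter: str
    counters: dict[str, int] = field(default_factory=dict)

    def n_cases(self) -> int:
        return self.demo["primaryid"].nunique()


class DrugDictionary:
    """Case-insensitive name-variant -> canonical substance lookup.

    FAERS ``drugname`` strings routinely carry dose and formulation suffixes
    ("OPDIVO 240MG"), so matching is by containment of a dictionary variant
    in the verbatim name, longest variant first.
    """

    def __init__(self, entries: Mapping[str, str]):
        self.entries = {k.strip().upper(): v for k, v in entries.items()}
        self._variants = sorted(self.entries, key=len, reverse=True)
        self.substances = frozenset(self.entries.values())

    @classmethod
    def default(cls) -> "DrugDictionary":
        df = drug_dictionary_frame()
        return cls(dict(zip(df["variant"], df["substance"])))

    @classmethod
    def from_csv(cls, path: str | Path) -> "DrugDictionary":
        df = pd.read_csv(path, dtype=str)
        return cls(dict(zip(df["variant"], df["substance"])))

    def match(self, verbatim_name: str) -> Optional[str]:
        name = verbatim_name.strip().upper()
        if name in self.entries:
            return self.entries[name]
        for variant in self._variants:
            if variant in name:
                return self.entries[variant]
        return None


class PTCatalog:
    """Flat list of event preferred terms, each mapped to one event group."""

    def __init__(self, groups: Mapping[str, str]):
        self.groups = dict(groups)
        self.pts = tuple(self.groups)
        self._lower = {pt.lower(): pt for pt in self.pts}

    @classmethod
    def default(cls) -> "PTCatalog":
        df = pt_catalog_frame()
        return cls(dict(zip(df["pt"], df["group"])))

    @classmethod
    def from_csv(cls, path: str | Path) -> "PTCatalog":
        df = pd.read_csv(path, dtype=str)
        return cls(dict(zip(df["pt"], df["group"])))

    def __contains__(self, pt: str) -> bool:
        return pt.strip().lower() in self._lower

    def canonical(self, pt: str) -> Optional[str]:
        return self._lower.get(pt.strip().lower())

    def group_of(self, pt: str) -> Optional[str]:
        canon = self.canonical(pt)
        return self.groups.get(canon) if canon else None


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------

_TABLE_MANDATORY = {
    "demo": ("primaryid", "caseid"),
    "drug": ("primaryid", "drugname", "role_cod"),
    "reac": ("primaryid", "pt"),
    "outc": ("primaryid", "outc_cod"),
    "ther": ("primaryid", "start_dt"),
    "indi": ("primaryid", "indi_pt"),
}

# legacy (pre-2012Q3) extracts are keyed by ISR / CASE
_HEADER_ALIASES = {
    "isr": "primaryid",
    "case": "caseid",
    "gndr_cod": "sex",
    "outc_code": "outc_cod",
}


def _read_dollar_table(path: str | Path, counters: dict[str, int], label: str) -> pd.DataFrame:
    def _on_bad(line):  # malformed lines are counted, never fatal
        counters[f"malformed_{label}"] = counters.get(f"malformed_{label}", 0) + 1
        return None

    df = pd.read_csv(
        path,
        sep="$",
        dtype=str,
        engine="python",
        on_bad_lines=_on_bad,
        keep_default_na=False,
    )
    df.columns = [_HEADER_ALIASES.get(c.strip().lower(), c.strip().lower()) for c in df.columns]
    return df


def parse_quarter(paths: Mapping[str, str | Path], quarter: str) -> RawRecordSet:
    """Parse one quarter's table files into a :class:`RawRecordSet`.

    ``paths`` maps lowercase table names (``demo``, ``drug``, ``reac``,
    ``outc``, ``ther``, ``indi``) to file paths; ``indi``/``ther``/``outc``
    may be omitted.  Rows in satellite tables whose ``primaryid`` does not
    appear in DEMO are dropped and counted under ``orphan_rows``.
    """
    import re

    if not re.fullmatch(r"\d{4}Q[1-4]", quarter):
        raise ValueError(f"quarter label {quarter!r} does not match YYYYQ[1-4]")

    counters: dict[str, int] = {}
    tables: dict[str, pd.DataFrame] = {}
    for name in ("demo", "drug", "reac", "outc", "ther", "indi"):
        if name in paths:
            tables[name] = _read_dollar_table(paths[name], counters, name)
        else:
            tables[name] = pd.DataFrame(columns=list(_TABLE_MANDATORY[name]))

    for name in ("demo", "drug", "reac"):
        for col in _TABLE_MANDATORY[name]:
            if col not in tables[name].columns:
                raise ValueError(
                    f"{name.upper()} file {paths.get(name)!s} lacks mandatory column {col!r}"
                )

    if "caseid" not in tables["demo"].columns:
        raise ValueError(f"DEMO file {paths.get('demo')!s} lacks mandatory column 'caseid'")

    known = set(tables["demo"]["primaryid"])
    for name in ("drug", "reac", "outc", "ther", "indi"):
        df = tables[name]
        if len(df) and "primaryid" in df.columns:
            keep = df["primaryid"].isin(known)
            dropped = int((~keep).sum())
            if dropped:
                counters["orphan_rows"] = counters.get("orphan_rows", 0) + dropped
                tables[name] = df[keep].reset_index(drop=True)

    return RawRecordSet(
        demo=tables["demo"],
        drug=tables["drug"],
        reac=tables["reac"],
        outc=tables["outc"],
        ther=tables["ther"],
        indi=tables["indi"],
        quarter=quarter,
        counters=counters,
    )


def concat_quarters(record_sets: Sequence[RawRecordSet]) -> RawRecordSet:
    """Stack several quarters into one record set (before deduplication)."""
    if not record_sets:
        raise ValueError("no record sets to concatenate")
    counters: dict[str, int] = {}
    for rs in record_sets:
        for k, v in rs.counters.items():
            counters[k] = counters.get(k, 0) + v
    cat = lambda name: pd.concat(
        [getattr(rs, name) for rs in record_sets], ignore_index=True
    )
    return RawRecordSet(
        demo=cat("demo"),
        drug=cat("drug"),
        reac=cat("reac"),
        outc=cat("outc"),
        ther=cat("ther"),
        indi=cat("indi"),
        quarter=record_sets[0].quarter if len(record_sets) == 1 else "multi",
        counters=counters,
    )


# ---------------------------------------------------------------------------
# deduplication
# ---------------------------------------------------------------------------


def deduplicate(records: RawRecordSet) -> RawRecordSet:
    """Keep one version per case: highest FDA receipt date, then highest primaryid.

    FAERS ships revised versions of the same case under new ``primaryid``s;
    counting them all would inflate disproportionality numerators.
    """
    demo = records.demo.copy()
    if "fda_dt" not in demo.columns:
        demo["fda_dt"] = ""
    demo["_fda"] = pd.to_numeric(demo["fda_dt"], errors="coerce").fillna(0)
    demo["_pid"] = pd.to_numeric(demo["primaryid"], errors="coerce")
    # lexicographic fallback when primaryid is not numeric
    demo["_pid_str"] = demo["primaryid"].astype(str)

    demo = demo.sort_values(
        ["caseid", "_fda", "_pid", "_pid_str"], kind="mergesort"
    )
    keep = demo.drop_duplicates("caseid", keep="last")
    retained = set(keep["primaryid"])

    counters = dict(records.counters)
    counters["cases_in"] = int(demo["caseid"].nunique())
    counters["versions_dropped"] = int(len(demo) - len(keep))
    counters["cases_out"] = int(len(keep))

    def _filter(df: pd.DataFrame) -> pd.DataFrame:
        if not len(df):
            return df
        return df[df["primaryid"].isin(retained)].reset_index(drop=True)

    return RawRecordSet(
        demo=keep.drop(columns=["_fda", "_pid", "_pid_str"]).reset_index(drop=True),
        drug=_filter(records.drug),
        reac=_filter(records.reac),
        outc=_filter(records.outc),
        ther=_filter(records.ther),
        indi=_filter(records.indi),
        quarter=records.quarter,
        counters=counters,
    )


# ---------------------------------------------------------------------------
# report assembly
# ---------------------------------------------------------------------------


def convert_age(value: str | None, unit: str | None, counters: dict[str, int]) -> Optional[float]:
    """Age in years from FAERS (age, age_cod); None when missing or unmappable."""
    if value in (None, "") or pd.isna(value):
        return None
    try:
        v = float(value)
    except (TypeError, ValueError):
        counters["age_unparseable"] = counters.get("age_unparseable", 0) + 1
        return None
    unit = (unit or "YR").strip().upper()
    factor = _AGE_UNIT_FACTORS.get(unit)
    if factor is None:
        counters["age_unit_unknown"] = counters.get("age_unit_unknown", 0) + 1
        return None
    years = v * factor
    if not (0 <= years <= 120):
        counters["age_out_of_range"] = counters.get("age_out_of_range", 0) + 1
        return None
    return years


def map_indication(free_text: str | None) -> str:
    if not free_text:
        return "Unknown"
    text = free_text.upper()
    for keyword, group in indication_keyword_map():
        if keyword in text:
            return group
    return "Other"


def _sex_label(raw: str | None) -> str:
    raw = (raw or "").strip().upper()
    return {"M": "male", "F": "female"}.get(raw, "unknown")


def build_reports(records: RawRecordSet, dictionary: DrugDictionary) -> list[SafetyReport]:
    """Assemble one SafetyReport per deduplicated case.

    Reports without any reaction row are dropped (counted under
    ``no_reaction``): a spontaneous report with no coded event carries no
    information for either the signal or the cohort analyses.
    """
    counters = records.counters
    continents = country_continent_map()

    reac_by_pid: dict[str, list[str]] = {}
    for pid, pt in zip(records.reac["primaryid"], records.reac["pt"]):
        if pt:
            reac_by_pid.setdefault(pid, []).append(pt)

    outc_by_pid: dict[str, list[str]] = {}
    if len(records.outc) and "outc_cod" in records.outc.columns:
        for pid, code in zip(records.outc["primaryid"], records.outc["outc_cod"]):
            code = (code or "").strip().upper()
            if code:
                outc_by_pid.setdefault(pid, []).append(code)

    ther = records.ther
    ther_key = None
    for cand in ("dsg_drug_seq", "drug_seq"):
        if cand in ther.columns:
            ther_key = cand
            break
    ther_by_pid_seq: dict[tuple[str, str], tuple[str, str]] = {}
    if len(ther) and ther_key:
        for pid, seq, s, e in zip(
            ther["primaryid"],
            ther[ther_key],
            ther.get("start_dt", [""] * len(ther)),
            ther.get("end_dt", [""] * len(ther)),
        ):
            ther_by_pid_seq[(pid, seq)] = (s or "", e or "")

    drug_rows: dict[str, list[DrugExposure]] = {}
    drug = records.drug
    seq_col = "drug_seq" if "drug_seq" in drug.columns else None
    for i in range(len(drug)):
        pid = drug["primaryid"].iat[i]
        name = drug["drugname"].iat[i] or ""
        role = (drug["role_cod"].iat[i] or "").strip().upper()
        if role not in ROLE_CODES:
            role = "C"
        seq = drug[seq_col].iat[i] if seq_col else ""
        start, end = ther_by_pid_seq.get((pid, seq), ("", ""))
        substance = dictionary.match(name) or "other"
        drug_rows.setdefault(pid, []).append(
            DrugExposure(
                verbatim_name=name,
                substance=substance,
                role=role,
                start_date=start or None,
                end_date=end or None,
            )
        )

    indi_by_pid: dict[str, str] = {}
    if len(records.indi) and "indi_pt" in records.indi.columns:
        for pid, text in zip(records.indi["primaryid"], records.indi["indi_pt"]):
            if pid not in indi_by_pid and text:
                indi_by_pid[pid] = text

    demo = records.demo
    col = lambda name: demo[name] if name in demo.columns else pd.Series([""] * len(demo))
    reports: list[SafetyReport] = []
    for pid, cid, age, age_cod, sex, country, fda_dt, event_dt in zip(
        demo["primaryid"],
        demo["caseid"],
        col("age"),
        col("age_cod"),
        col("sex"),
        col("occr_country"),
        col("fda_dt"),
        col("event_dt"),
    ):
        reactions = reac_by_pid.get(pid, [])
        if not reactions:
            counters["no_reaction"] = counters.get("no_reaction", 0) + 1
            continue
        country = (country or "").strip().upper() or None
        reports.append(
            SafetyReport(
                case_id=str(cid),
                primary_id=str(pid),
                sex=_sex_label(sex),
                age_years=convert_age(age, age_cod, counters),
                country=country,
                continent=continents.get(country, "Unknown") if country else "Unknown",
                report_date=(fda_dt or None),
                event_date=(event_dt or None),
                indication=map_indication(indi_by_pid.get(pid)),
                drugs=drug_rows.get(pid, []),
                reactions=reactions,
                outcome_codes=tuple(sorted(set(outc_by_pid.get(pid, [])))),
            )
        )
    return reports


# ---------------------------------------------------------------------------
# case selection / regimen classification / time to onset
# ---------------------------------------------------------------------------


def select_cases(
    reports: Iterable[SafetyReport],
    dictionary: DrugDictionary,
    catalog: PTCatalog,
) -> list[SafetyReport]:
    """Retain cases with a primary-suspect study drug and a catalog reaction."""
    selected = []
    for r in reports:
        has_ps = any(
            d.role == "PS" and d.substance in dictionary.substances for d in r.drugs
        )
        if has_ps and any(pt in catalog for pt in r.reactions):
            selected.append(r)
    return selected


def classify_regimen(report: SafetyReport) -> RegimenLabel:
    """Monotherapy agent + class, or a (possibly named) combination.

    Classification uses the distinct study substances among suspect-role
    (PS/SS) drugs of the case — the only combination evidence a spontaneous
    report carries.
    """
    subs = report.ici_substances()
    if not subs:
        raise ValueError(
            f"case {report.case_id}: no study substance among suspect drugs; "
            "run select_cases first"
        )
    if len(subs) == 1:
        (agent,) = subs
        drug_class = (
            "anti-PD-1" if agent in ANTI_PD1
            else "anti-PD-L1" if agent in ANTI_PDL1
            else "anti-CTLA-4"
        )
        return RegimenLabel("monotherapy", (agent,), drug_class, agent.capitalize())
    key = frozenset(subs)
    label = NAMED_COMBINATIONS.get(key, "Other combination")
    return RegimenLabel("combination", tuple(sorted(subs)), "combination", label)


def _full_date(raw: str | None) -> Optional[date]:
    if raw is None:
        return None
    raw = raw.strip()
    if len(raw) != 8 or not raw.isdigit():
        return None
    try:
        return datetime.strptime(raw, "%Y%m%d").date()
    except ValueError:
        return None


def compute_tto(
    report: SafetyReport, counters: Optional[dict[str, int]] = None
) -> Optional[int]:
    """Days from earliest full study-drug start date to event onset.

    Partial dates (year or year-month only) yield missing rather than an
    imputed onset; negative intervals are treated as data-entry errors,
    excluded and counted under ``tto_negative``.
    """
    event = _full_date(report.event_date)
    if event is None:
        return None
    starts = [
        d
        for d in (
            _full_date(x.start_date)
            for x in report.drugs
            if x.substance in ICI_SUBSTANCES and x.role in ("PS", "SS")
        )
        if d is not None
    ]
    if not starts:
        return None
    tto = (event - min(starts)).days
    if tto < 0:
        if counters is not None:
            counters["tto_negative"] = counters.get("tto_negative", 0) + 1
        return None
    return tto


# ---------------------------------------------------------------------------
# interchange format (one row per case)
# ---------------------------------------------------------------------------

_CASE_COLUMNS = [
    "case_id",
    "primary_id",
    "sex",
    "age_years",
    "country",
    "continent",
    "report_date",
    "event_date",
    "indication",
    "reactions",
    "outcome_codes",
    "died",
    "drugs_json",
]


def reports_to_frame(reports: Iterable[SafetyReport]) -> pd.DataFrame:
    rows = []
    for r in reports:
        rows.append(
            {
                "case_id": r.case_id,
                "primary_id": r.primary_id,
                "sex": r.sex,
                "age_years": "" if r.age_years is None else repr(float(r.age_years)),
                "country": r.country or "",
                "continent": r.continent,
                "report_date": r.report_date or "",
                "event_date": r.event_date or "",
                "indication": r.indication,
                "reactions": ";".join(r.reactions),
                "outcome_codes": ";".join(r.outcome_codes),
                "died": str(r.died),
                "drugs_json": json.dumps(
                    [asdict(d) for d in r.drugs], separators=(",", ":")
                ),
            }
        )
    return pd.DataFrame(rows, columns=_CASE_COLUMNS, dtype=str)


def frame_to_reports(df: pd.DataFrame) -> list[SafetyReport]:
    reports = []
    for row in df.itertuples(index=False):
        drugs = [
            DrugExposure(
                verbatim_name=d["verbatim_name"],
                substance=d["substance"],
                role=d["role"],
                start_date=d["start_date"],
                end_date=d["end_date"],
            )
            for d in json.loads(row.drugs_json)
        ]
        reports.append(
            SafetyReport(
                case_id=row.case_id,
                primary_id=row.primary_id,
                sex=row.sex,
                age_years=float(row.age_years) if row.age_years else None,
                country=row.country or None,
                continent=row.continent,
                report_date=row.report_date or None,
                event_date=row.event_date or None,
                indication=row.indication,
                drugs=drugs,
                reactions=row.reactions.split(";") if row.reactions else [],
                outcome_codes=tuple(
                    row.outcome_codes.split(";") if row.outcome_codes else ()
                ),
            )
        )
    return reports


def write_cases(reports: Iterable[SafetyReport], path: str | Path) -> pd.DataFrame:
    """Write the one-row-per-case interchange CSV plus a parquet mirror."""
    df = reports_to_frame(reports)
    path = Path(path)
    df.to_csv(path, index=False)
    try:
        df.to_parquet(path.with_suffix(".parquet"), index=False)
    except ImportError:  # pragma: no cover - pyarrow is a hard dependency
        pass
    return df


def read_cases(path: str | Path) -> list[SafetyReport]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    return frame_to_reports(df)
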