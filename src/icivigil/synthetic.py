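"""Synthetic FAERS-format databases with known ground truth.

The generator emulates the statistical structure a disproportionality analysis
assumes: each case is assigned one drug regimen (possibly a two-agent
combination, possibly a background non-study drug), then reaction preferred
terms are drawn independently per PT with probability
``background x multiplier``, so a multiplier above 1 plants a drug-event
association of known strength.  Demographics, partial therapy dates, case
revisions (superseded report versions) and fatal outcomes with their own
time-to-onset law are all generated so that every pipeline stage — parsing,
deduplication, selection, signal detection, cohort analysis — can be tested
end to end without any external download.

Everything is driven by a single integer seed: identical config + seed gives
byte-identical output files.

A separate deterministic fixture, :func:`table1_fixture`, realises a cohort of
exactly 1945 cases whose fatal and non-fatal margins match a published
characteristics table for checkpoint-inhibitor-associated arrhythmias; it is
used to verify that summary percentages reproduce printed values exactly.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from datetime import date, timedelta
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from ._resources import table1_margins
from .ingest import DrugExposure, SafetyReport, map_indication

_CONTINENT_COUNTRY = {
    "America": "US",
    "Europe": "FR",
    "Asia": "JP",
    "Oceania": "AU",
    "Africa": "ZA",
    "Unknown": "",
}

_EPOCH = date(2015, 1, 1)


@dataclass(frozen=True)
class DrugProfile:
    """One regimen arm of the generator.

    ``substances`` holds one active substance for monotherapy or two for a
    combination; ``prob`` is the marginal probability that a case is assigned
    this regimen; ``fatality`` the death probability of its cases;
    ``role_probs`` the distribution of the FAERS role code given to the study
    drug rows (overwhelmingly primary suspect by default).
    """

    substances: tuple[str, ...]
    prob: float
    fatality: float = 0.15
    role_probs: tuple[float, float, float, float] = (0.9, 0.06, 0.03, 0.01)  # PS,SS,C,I

    @property
    def label(self) -> str:
        return " + ".join(self.substances)


@dataclass(frozen=True)
class EventProfile:
    pt: str
    prob: float  # background per-case inclusion probability


@dataclass
class SyntheticConfig:
    n_reports: int = 10_000
    drugs: tuple[DrugProfile, ...] = ()
    events: tuple[EventProfile, ...] = ()
    multipliers: dict[tuple[str, str], float] = field(default_factory=dict)
    sex_probs: tuple[float, float, float] = (0.58, 0.36, 0.06)  # male, female, unknown
    age_mean: float = 66.0
    age_sd: float = 12.0
    continent_probs: dict[str, float] = field(
        default_factory=lambda: {
            "America": 0.43, "Europe": 0.33, "Asia": 0.21,
            "Oceania": 0.027, "Africa": 0.002, "Unknown": 0.001,
        }
    )
    # log-normal time-to-onset, log-days; fatal cases onset earlier
    tto_mu_fatal: float = 3.20
    tto_sigma_fatal: float = 1.15
    tto_mu_nonfatal: float = 3.50
    tto_sigma_nonfatal: float = 1.25
    revision_rate: float = 0.0
    partial_date_rate: float = 0.35
    fallback_pt: str = "Drug ineffective"
    indications: tuple[str, ...] = (
        "LUNG CANCER", "MALIGNANT MELANOMA", "RENAL CELL CARCINOMA",
        "BLADDER CANCER", "HEAD AND NECK CANCER", "HODGKIN LYMPHOMA",
        "OVARIAN CANCER", "GASTRIC CANCER", "BREAST CANCER",
        "MESOTHELIOMA", "HEPATOCELLULAR CARCINOMA", "PROSTATE CANCER",
    )

    def __post_init__(self):
        total = sum(p.prob for p in self.drugs)
        if self.drugs and not np.isclose(total, 1.0):
            raise ValueError(f"drug marginal probabilities sum to {total}, expected 1")
        for e in self.events:
            if not 0 <= e.prob <= 1:
                raise ValueError(f"event probability out of [0,1] for {e.pt}")

    def multiplier(self, substances: Sequence[str], pt: str) -> float:
        """Planted multiplier for a regimen: max over its substances."""
        return max((self.multipliers.get((s, pt), 1.0) for s in substances), default=1.0)


def default_config(n_reports: int = 10_000, **overrides) -> SyntheticConfig:
    """Study conditions: a small oncology-flavoured database.

    Eight study substances (one combination arm) against a large background of
    common oncology/comedication drugs; arrhythmia PTs at sub-percent
    background rates next to frequent non-cardiac PTs; a handful of planted
    drug-event multipliers of known strength.
    """
    drugs = (
        DrugProfile(("nivolumab",), 0.050, fatality=0.26),
        DrugProfile(("pembrolizumab",), 0.040, fatality=0.28),
        DrugProfile(("atezolizumab",), 0.020, fatality=0.24),
        DrugProfile(("ipilimumab",), 0.015, fatality=0.26),
        DrugProfile(("durvalumab",), 0.006, fatality=0.34),
        DrugProfile(("avelumab",), 0.004, fatality=0.24),
        DrugProfile(("cemiplimab",), 0.002, fatality=0.25),
        DrugProfile(("ipilimumab", "nivolumab"), 0.012, fatality=0.24),
        DrugProfile(("carboplatin",), 0.250, fatality=0.10),
        DrugProfile(("paclitaxel",), 0.200, fatality=0.10),
        DrugProfile(("pemetrexed",), 0.150, fatality=0.10),
        DrugProfile(("docetaxel",), 0.100, fatality=0.10),
        DrugProfile(("osimertinib",), 0.100, fatality=0.12),
        DrugProfile(("aspirin",), 0.051, fatality=0.05),
    )
    events = (
        EventProfile("Atrial fibrillation", 0.020),
        EventProfile("Cardiac arrest", 0.012),
        EventProfile("Tachycardia", 0.010),
        EventProfile("Bradycardia", 0.008),
        EventProfile("Ventricular tachycardia", 0.005),
        EventProfile("Sudden death", 0.004),
        EventProfile("Supraventricular tachycardia", 0.004),
        EventProfile("Electrocardiogram QT prolonged", 0.004),
        EventProfile("Atrioventricular block complete", 0.003),
        EventProfile("Nausea", 0.120),
        EventProfile("Fatigue", 0.100),
        EventProfile("Diarrhoea", 0.080),
        EventProfile("Pyrexia", 0.060),
        EventProfile("Anaemia", 0.050),
        EventProfile("Dyspnoea", 0.050),
    )
    multipliers = {
        ("nivolumab", "Atrial fibrillation"): 2.0,
        ("nivolumab", "Cardiac arrest"): 2.0,
        ("avelumab", "Atrial fibrillation"): 3.0,
    }
    params = dict(
        n_reports=n_reports, drugs=drugs, events=events, multipliers=multipliers
    )
    params.update(overrides)
    return SyntheticConfig(**params)


def null_config(n_reports: int = 4_000, **overrides) -> SyntheticConfig:
    """Default conditions with every planted multiplier removed."""
    return default_config(n_reports=n_reports, multipliers={}, **overrides)


@dataclass
class GroundTruth:
    """What the generator actually planted, for assertions in tests."""

    expected_counts: dict[tuple[str, str], float]  # (regimen label, pt) -> E[a]
    multipliers: dict[tuple[str, str], float]
    regimen: list[str]  # per case
    died: list[bool]
    tto_days: list[int]
    n_revised: int

    def to_json(self) -> str:
        payload = {
            "expected_counts": {f"{k[0]}|{k[1]}": v for k, v in self.expected_counts.items()},
            "multipliers": {f"{k[0]}|{k[1]}": v for k, v in self.multipliers.items()},
            "regimen": self.regimen,
            "died": self.died,
            "tto_days": self.tto_days,
            "n_revised": self.n_revised,
        }
        return json.dumps(payload, indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# core sampling
# ---------------------------------------------------------------------------


def _sample(config: SyntheticConfig, seed: int):
    """Draw every per-case variable as numpy arrays (one pass, vectorised)."""
    rng = np.random.default_rng(seed)
    n = config.n_reports
    profiles = config.drugs
    n_drugs = len(profiles)
    n_events = len(config.events)

    drug_idx = rng.choice(n_drugs, size=n, p=[p.prob for p in profiles])

    # per-profile x per-event inclusion probabilities (background x multiplier)
    pmat = np.empty((n_drugs, n_events))
    capped = []
    for i, prof in enumerate(profiles):
        for j, ev in enumerate(config.events):
            p = ev.prob * config.multiplier(prof.substances, ev.pt)
            if p > 1.0:
                capped.append((prof.label, ev.pt))
                p = 1.0
            pmat[i, j] = p
    if capped:
        warnings.warn(
            f"event probabilities capped at 1 after multiplication: {capped}",
            stacklevel=3,
        )
    event_hits = rng.random((n, n_events)) < pmat[drug_idx]

    fatality = np.array([p.fatality for p in profiles])
    died = rng.random(n) < fatality[drug_idx]

    mu = np.where(died, config.tto_mu_fatal, config.tto_mu_nonfatal)
    sigma = np.where(died, config.tto_sigma_fatal, config.tto_sigma_nonfatal)
    tto = np.rint(rng.lognormal(mu, sigma)).astype(np.int64)

    sex = rng.choice(np.array(["M", "F", ""]), size=n, p=config.sex_probs)
    age = np.clip(np.rint(rng.normal(config.age_mean, config.age_sd, size=n)), 0, 120)
    conts = list(config.continent_probs)
    continent = rng.choice(np.array(conts), size=n, p=list(config.continent_probs.values()))

    roles = np.empty(n, dtype="<U2")
    role_codes = np.array(["PS", "SS", "C", "I"])
    for i, prof in enumerate(profiles):
        mask = drug_idx == i
        roles[mask] = rng.choice(role_codes, size=int(mask.sum()), p=prof.role_probs)

    start_offset = rng.integers(0, 6 * 365, size=n)  # within a six-year window
    report_lag = rng.integers(5, 60, size=n)
    partial = rng.random(n) < config.partial_date_rate
    revised = rng.random(n) < config.revision_rate

    indication = rng.choice(np.array(config.indications), size=n)
    outcome_choice = rng.choice(
        np.array(["HO", "LT", "OT", ""]), size=n, p=[0.55, 0.10, 0.30, 0.05]
    )

    return {
        "rng": rng,
        "drug_idx": drug_idx,
        "event_hits": event_hits,
        "died": died,
        "tto": tto,
        "sex": sex,
        "age": age,
        "continent": continent,
        "roles": roles,
        "start_offset": start_offset,
        "report_lag": report_lag,
        "partial": partial,
        "revised": revised,
        "indication": indication,
        "outcome_choice": outcome_choice,
        "pmat": pmat,
    }


def _ground_truth(config: SyntheticConfig, s: dict) -> GroundTruth:
    profiles = config.drugs
    expected = {}
    for i, prof in enumerate(profiles):
        n_prof = config.n_reports * prof.prob
        for j, ev in enumerate(config.events):
            expected[(prof.label, ev.pt)] = n_prof * s["pmat"][i, j]
    return GroundTruth(
        expected_counts=expected,
        multipliers=dict(config.multipliers),
        regimen=[profiles[i].label for i in s["drug_idx"]],
        died=[bool(x) for x in s["died"]],
        tto_days=[int(x) for x in s["tto"]],
        n_revised=int(s["revised"].sum()),
    )


def _dates(i: int, s: dict) -> tuple[str, str, str, str]:
    """(start_dt, event_dt, fda_dt, start_dt_emitted) for case i."""
    start = _EPOCH + timedelta(days=int(s["start_offset"][i]))
    event = start + timedelta(days=int(s["tto"][i]))
    fda = event + timedelta(days=int(s["report_lag"][i]))
    start_full = start.strftime("%Y%m%d")
    emitted = start.strftime("%Y%m") if s["partial"][i] else start_full
    return start_full, event.strftime("%Y%m%d"), fda.strftime("%Y%m%d"), emitted


def _case_reactions(config: SyntheticConfig, s: dict, i: int) -> list[str]:
    pts = [ev.pt for j, ev in enumerate(config.events) if s["event_hits"][i, j]]
    return pts if pts else [config.fallback_pt]


def generate_reports(
    config: SyntheticConfig, seed: int = 0
) -> tuple[list[SafetyReport], GroundTruth]:
    """In-memory fast path: the deduplicated reports the file set would yield.

    Statistically identical to writing files with :func:`generate` and running
    them through the ingest pipeline (revision copies excluded, since
    deduplication removes them).
    """
    s = _sample(config, seed)
    profiles = config.drugs
    reports = []
    for i in range(config.n_reports):
        prof = profiles[s["drug_idx"][i]]
        _, event_dt, fda_dt, start_emitted = _dates(i, s)
        drugs = [
            DrugExposure(
                verbatim_name=sub.upper(),
                substance=sub,
                role=s["roles"][i],
                start_date=start_emitted,
            )
            for sub in prof.substances
        ]
        codes = ("DE",) if s["died"][i] else (
            (s["outcome_choice"][i],) if s["outcome_choice"][i] else ()
        )
        caseid = str(1_000_000 + i)
        reports.append(
            SafetyReport(
                case_id=caseid,
                primary_id=caseid + ("2" if s["revised"][i] else "1"),
                sex={"M": "male", "F": "female"}.get(s["sex"][i], "unknown"),
                age_years=float(s["age"][i]),
                country=_CONTINENT_COUNTRY[s["continent"][i]] or None,
                continent=s["continent"][i],
                report_date=fda_dt,
                event_date=event_dt,
                indication=map_indication(s["indication"][i]),
                drugs=drugs,
                reactions=_case_reactions(config, s, i),
                outcome_codes=codes,
            )
        )
    return reports, _ground_truth(config, s)


def generate(
    config: SyntheticConfig, outdir: str | Path, seed: int = 0, quarter: str = "2020Q1"
) -> GroundTruth:
    """Emit a $-delimited FAERS-style file set plus ground-truth JSON.

    Cases drawn as revised get an additional superseded earlier version (lower
    primaryid, earlier FDA receipt date) in every table, exactly what the
    deduplication stage must strip.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    s = _sample(config, seed)
    profiles = config.drugs

    demo_rows, drug_rows, reac_rows, outc_rows, ther_rows, indi_rows = [], [], [], [], [], []

    for i in range(config.n_reports):
        prof = profiles[s["drug_idx"][i]]
        caseid = str(1_000_000 + i)
        _, event_dt, fda_dt, start_emitted = _dates(i, s)
        versions = [(caseid + "1", fda_dt)]
        if s["revised"][i]:
            # superseded earlier version: shift receipt back, bump final pid
            earlier = (
                date(int(fda_dt[:4]), int(fda_dt[4:6]), int(fda_dt[6:])) - timedelta(days=90)
            ).strftime("%Y%m%d")
            versions = [(caseid + "1", earlier), (caseid + "2", fda_dt)]

        for pid, fda in versions:
            demo_rows.append(
                {
                    "primaryid": pid,
                    "caseid": caseid,
                    "fda_dt": fda,
                    "event_dt": event_dt,
                    "age": str(int(s["age"][i])),
                    "age_cod": "YR",
                    "sex": s["sex"][i],
                    "occr_country": _CONTINENT_COUNTRY[s["continent"][i]],
                }
            )
            for seq, sub in enumerate(prof.substances, start=1):
                drug_rows.append(
                    {
                        "primaryid": pid,
                        "caseid": caseid,
                        "drug_seq": str(seq),
                        "role_cod": s["roles"][i],
                        "drugname": sub.upper(),
                    }
                )
                ther_rows.append(
                    {
                        "primaryid": pid,
                        "caseid": caseid,
                        "dsg_drug_seq": str(seq),
                        "start_dt": start_emitted,
                        "end_dt": "",
                    }
                )
                indi_rows.append(
                    {
                        "primaryid": pid,
                        "caseid": caseid,
                        "indi_drug_seq": str(seq),
                        "indi_pt": s["indication"][i],
                    }
                )
            for pt in _case_reactions(config, s, i):
                reac_rows.append({"primaryid": pid, "caseid": caseid, "pt": pt})
            code = "DE" if s["died"][i] else s["outcome_choice"][i]
            if code:
                outc_rows.append({"primaryid": pid, "caseid": caseid, "outc_cod": code})

    q = quarter.lower()
    for name, rows in (
        ("demo", demo_rows), ("drug", drug_rows), ("reac", reac_rows),
        ("outc", outc_rows), ("ther", ther_rows), ("indi", indi_rows),
    ):
        pd.DataFrame(rows).to_csv(outdir / f"{name}{q}.txt", sep="$", index=False)

    truth = _ground_truth(config, s)
    (outdir / "ground_truth.json").write_text(truth.to_json())
    return truth


# ---------------------------------------------------------------------------
# deterministic published-margins fixture
# ---------------------------------------------------------------------------

_AGE_VALUE = {"<18": 10.0, "18-64": 55.0, ">=65": 72.0, "unknown": None}
_TTO_VALUE = {"0-30": 15, "31-60": 45, "61-90": 75, "91-180": 135, ">180": 200, "unknown": None}

_FIXTURE_PTS = (
    "Atrial fibrillation", "Cardiac arrest", "Tachycardia", "Bradycardia",
    "Ventricular tachycardia", "Atrioventricular block complete",
    "Supraventricular tachycardia", "Electrocardiogram QT prolonged",
    "Sudden death", "Conduction disorder",
)


def _expand(levels: Sequence[str], counts: Sequence[int]) -> list[str]:
    out: list[str] = []
    for lev, cnt in zip(levels, counts):
        out.extend([lev] * cnt)
    return out


def table1_fixture() -> list[SafetyReport]:
    """A deterministic 1945-case cohort matching published fatal/non-fatal margins.

    Within each arm (507 fatal, 1438 non-fatal) every characteristic is
    assigned independently by position — margins are exact, joint structure
    beyond arm x characteristic is arbitrary but deterministic.
    """
    margins = table1_margins()
    reports: list[SafetyReport] = []
    case_no = 0

    for arm in ("fatal", "nonfatal"):
        per_char = {}
        for char, sub in margins.groupby("characteristic", sort=False):
            per_char[char] = _expand(list(sub["level"]), list(sub[arm]))
        n_arm = len(per_char["sex"])

        for i in range(n_arm):
            sex = per_char["sex"][i]
            age = _AGE_VALUE[per_char["age_band"][i]]
            year = per_char["year"][i]
            continent = per_char["continent"][i]
            indication = per_char["indication"][i]
            outcome = per_char["outcome"][i]
            tto = _TTO_VALUE[per_char["tto_band"][i]]
            regimen = per_char["regimen"][i]

            start = date(int(year), 1, 10)
            event_date = (
                (start + timedelta(days=tto)).strftime("%Y%m%d") if tto is not None else None
            )
            substances = [p.strip().lower() for p in regimen.split("+")]
            drugs = [
                DrugExposure(
                    verbatim_name=sub.upper(),
                    substance=sub,
                    role="PS",
                    start_date=start.strftime("%Y%m%d") if tto is not None else None,
                )
                for sub in substances
            ]
            reports.append(
                SafetyReport(
                    case_id=f"T{case_no:05d}",
                    primary_id=f"T{case_no:05d}1",
                    sex=sex,
                    age_years=age,
                    country=_CONTINENT_COUNTRY.get(continent) or None,
                    continent=continent,
                    report_date=f"{year}0615",
                    event_date=event_date,
                    indication=indication,
                    drugs=drugs,
                    reactions=[_FIXTURE_PTS[case_no % len(_FIXTURE_PTS)]],
                    outcome_codes=() if outcome == "NS" else (outcome,),
                )
            )
            case_no += 1
    return reports
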