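"""End-to-end pipeline: parse -> deduplicate -> select -> analyse -> render.

``run_pipeline`` orchestrates the full analysis over a directory of quarterly
FAERS-style files and writes a fixed set of artifacts with deterministic
formatting, so two runs over identical inputs are byte-identical:

* ``cases.csv`` / ``cases.parquet`` — one row per selected case (interchange)
* ``signals.csv`` — disproportionality statistics per regimen/class
* ``spectrum.json`` — the regimen x PT signal matrix
* ``table1.csv`` — cohort characteristics split by outcome
* ``fatality.csv`` — case-fatality proportions by regimen and event group
* ``tto.csv`` — time-to-onset by regimen with the omnibus test
* ``run_log.jsonl`` — stage-by-stage row counts and exclusion counters
* ``manifest.json`` — list of artifacts written
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional

import pandas as pd

from . import cohort as _cohort
from .disproportionality import (
    SignalCriteria,
    build_contingency,
    comparative_ror,
    compute_signal,
    signal_spectrum,
)
from .ingest import (
    ANTI_CTLA4,
    ANTI_PD1,
    ANTI_PDL1,
    DrugDictionary,
    PTCatalog,
    SafetyReport,
    classify_regimen,
    concat_quarters,
    deduplicate,
    parse_quarter,
    select_cases,
    build_reports,
    write_cases,
)

_TABLES = ("demo", "drug", "reac", "outc", "ther", "indi")

ARTIFACTS = (
    "cases.csv",
    "signals.csv",
    "spectrum.json",
    "table1.csv",
    "fatality.csv",
    "tto.csv",
)


@dataclass
class PipelineConfig:
    input_dir: str | Path
    output_dir: str | Path
    quarters: Optional[list[str]] = None  # default: every quarter found
    drug_dictionary: Optional[str | Path] = None
    pt_catalog: Optional[str | Path] = None
    criteria: SignalCriteria = field(default_factory=SignalCriteria)
    unit: str = "record"
    seed: int = 0


def discover_quarters(input_dir: Path) -> dict[str, dict[str, Path]]:
    """Map quarter label -> table-name -> path from files like ``demo2020q1.txt``."""
    found: dict[str, dict[str, Path]] = {}
    for path in sorted(input_dir.glob("*.txt")):
        m = re.fullmatch(r"(demo|drug|reac|outc|ther|indi)(\d{4}q[1-4])\.txt", path.name.lower())
        if m:
            found.setdefault(m.group(2).upper(), {})[m.group(1)] = path
    return found


def _regimen_or_none(report: SafetyReport) -> Optional[str]:
    try:
        return classify_regimen(report).label
    except ValueError:
        return None


def _class_selector(substances: frozenset[str], kind: str) -> Callable[[SafetyReport], bool]:
    def sel(r: SafetyReport) -> bool:
        subs = r.ici_substances()
        if not subs:
            return False
        if kind == "monotherapy":
            return len(subs) == 1 and next(iter(subs)) in substances
        if kind == "combination":
            return len(subs) >= 2
        return bool(subs & substances)  # any exposure

    return sel


def signal_table(
    reports: list[SafetyReport],
    catalog: PTCatalog,
    criteria: SignalCriteria = SignalCriteria(),
    unit: str = "record",
) -> pd.DataFrame:
    """Regimen/class-level disproportionality against the full database."""
    all_ici = ANTI_PD1 | ANTI_PDL1 | ANTI_CTLA4
    rows: list[tuple[str, Callable]] = [
        ("Total ICIs", _class_selector(frozenset(all_ici), "any")),
        ("Anti-PD-1 monotherapy", _class_selector(ANTI_PD1, "monotherapy")),
        ("Anti-PD-L1 monotherapy", _class_selector(ANTI_PDL1, "monotherapy")),
        ("Anti-CTLA-4 monotherapy", _class_selector(ANTI_CTLA4, "monotherapy")),
        ("Combination therapy", _class_selector(frozenset(all_ici), "combination")),
    ]
    for agent in sorted(all_ici):
        rows.append(
            (agent.capitalize(), _class_selector(frozenset({agent}), "monotherapy"))
        )

    out = []
    for label, selector in rows:
        try:
            table = build_contingency(reports, selector, catalog, unit=unit)
        except ValueError:
            continue
        if table.a == 0:
            continue
        res = compute_signal(table, criteria, drug=label)
        out.append(
            {
                "strategy": label,
                "n": res.n_reports,
                "ror": res.ror, "ror025": res.ror_low, "ror975": res.ror_high,
                "prr": res.prr, "chi2": res.chi2,
                "ic": res.ic, "ic025": res.ic_low, "ic975": res.ic_high,
                "any_signal": res.any_signal,
            }
        )
    return pd.DataFrame(out)


def comparative_table(
    reports: list[SafetyReport],
    catalog: PTCatalog,
    z: float = 1.96,
) -> pd.DataFrame:
    """Class-vs-class comparative RORs (group A odds over group B odds)."""
    contrasts = [
        ("Anti-PD-1 vs anti-PD-L1",
         _class_selector(ANTI_PD1, "monotherapy"), _class_selector(ANTI_PDL1, "monotherapy")),
        ("Anti-PD-1 vs anti-CTLA-4",
         _class_selector(ANTI_PD1, "monotherapy"), _class_selector(ANTI_CTLA4, "monotherapy")),
        ("Anti-PD-L1 vs anti-CTLA-4",
         _class_selector(ANTI_PDL1, "monotherapy"), _class_selector(ANTI_CTLA4, "monotherapy")),
        ("Combination vs monotherapy",
         _class_selector(frozenset(ANTI_PD1 | ANTI_PDL1 | ANTI_CTLA4), "combination"),
         _class_selector(frozenset(ANTI_PD1 | ANTI_PDL1 | ANTI_CTLA4), "monotherapy")),
    ]
    out = []
    for label, sel_a, sel_b in contrasts:
        try:
            est, lo, hi, table = comparative_ror(reports, sel_a, sel_b, catalog, z=z)
        except ValueError:
            continue
        out.append({"contrast": label, "ror": est, "ror025": lo, "ror975": hi,
                    "a": table.a, "b": table.b, "c": table.c, "d": table.d})
    return pd.DataFrame(out)


def _fmt(df: pd.DataFrame, two_dp: tuple[str, ...]) -> pd.DataFrame:
    df = df.copy()
    for col in two_dp:
        if col in df.columns:
            df[col] = df[col].map(lambda x: f"{x:.2f}")
    return df


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured pipeline; returns the artifact manifest.

    Any stage failure removes partial outputs and re-raises.
    """
    input_dir = Path(config.input_dir)
    output_dir = Path(config.output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)

    dictionary = (
        DrugDictionary.from_csv(config.drug_dictionary)
        if config.drug_dictionary
        else DrugDictionary.default()
    )
    catalog = (
        PTCatalog.from_csv(config.pt_catalog) if config.pt_catalog else PTCatalog.default()
    )

    written: list[Path] = []
    log: list[dict] = []

    def emit(stage: str, **fields):
        log.append({"stage": stage, **fields})

    try:
        by_quarter = discover_quarters(input_dir)
        if config.quarters:
            by_quarter = {q: by_quarter[q] for q in config.quarters}
        if not by_quarter:
            raise FileNotFoundError(f"no quarterly table files under {input_dir}")

        record_sets = [parse_quarter(paths, q) for q, paths in sorted(by_quarter.items())]
        records = concat_quarters(record_sets)
        emit("parsed", n_rows_demo=int(len(records.demo)), counters=records.counters)

        records = deduplicate(records)
        emit("deduplicated", n_cases=records.n_cases(), counters=records.counters)

        reports = build_reports(records, dictionary)
        emit("reports_built", n_reports=len(reports))

        selected = select_cases(reports, dictionary, catalog)
        emit("selected", n_selected=len(selected))

        tto_counters: dict[str, int] = {}
        from .ingest import compute_tto

        for r in selected:
            compute_tto(r, tto_counters)
        emit("tto", counters=tto_counters)

        # --- artifacts -----------------------------------------------------
        write_cases(selected, output_dir / "cases.csv")
        written += [output_dir / "cases.csv", output_dir / "cases.parquet"]

        sig = signal_table(reports, catalog, config.criteria, unit=config.unit)
        comp = comparative_table(reports, catalog, z=config.criteria.z)
        ratio_cols = ("ror", "ror025", "ror975", "prr", "chi2", "ic", "ic025", "ic975")
        with open(output_dir / "signals.csv", "w") as fh:
            _fmt(sig, ratio_cols).to_csv(fh, index=False)
            fh.write("# comparative\n")
            _fmt(comp, ratio_cols).to_csv(fh, index=False)
        written.append(output_dir / "signals.csv")

        regimens = sorted({lab for lab in map(_regimen_or_none, selected) if lab})
        spec = signal_spectrum(reports, regimens, catalog, config.criteria, unit=config.unit)
        spectrum_doc = {
            "unit": config.unit,
            "regimens": regimens,
            "pts": list(catalog.pts),
            "cells": [
                {k: (round(v, 4) if isinstance(v, float) else (bool(v) if isinstance(v, (bool,)) else v))
                 for k, v in row.items()}
                for row in spec.to_dict(orient="records")
            ],
        }
        (output_dir / "spectrum.json").write_text(json.dumps(spectrum_doc, indent=1, default=str))
        written.append(output_dir / "spectrum.json")

        _cohort.table1_frame(selected).to_csv(
            output_dir / "table1.csv", index=False, float_format="%.4f"
        )
        written.append(output_dir / "table1.csv")

        fat_reg = _cohort.fatality_rates(selected, by="regimen")
        fat_reg.insert(0, "by", "regimen")
        fat_grp = _cohort.fatality_rates(selected, by="event_group", catalog=catalog)
        fat_grp.insert(0, "by", "event_group")
        pd.concat([fat_reg, fat_grp], ignore_index=True).to_csv(
            output_dir / "fatality.csv", index=False, float_format="%.2f"
        )
        written.append(output_dir / "fatality.csv")

        try:
            tto = _cohort.tto_by_regimen(selected)
            tto_df = tto.per_regimen.copy()
            tto_df["omnibus_test"] = tto.test_name
            tto_df["omnibus_statistic"] = tto.statistic
            tto_df["omnibus_p"] = tto.p_value
        except ValueError:
            tto_df = pd.DataFrame(
                columns=["regimen", "n_known", "median", "q1", "q3",
                         "omnibus_test", "omnibus_statistic", "omnibus_p"]
            )
        tto_df.to_csv(output_dir / "tto.csv", index=False, float_format="%.4f")
        written.append(output_dir / "tto.csv")

        funnel = {
            "parsed_cases": int(concat_quarters(record_sets).demo["caseid"].nunique()),
            "deduplicated": records.n_cases(),
            "reports_built": len(reports),
            "selected": len(selected),
        }
        emit("funnel", **funnel)

        with open(output_dir / "run_log.jsonl", "w") as fh:
            for entry in log:
                fh.write(json.dumps(entry, sort_keys=True) + "\n")
        written.append(output_dir / "run_log.jsonl")

        manifest = {
            "artifacts": sorted(p.name for p in written if p.exists()),
            "funnel": funnel,
        }
        (output_dir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
        return manifest
    except Exception:
        for p in written:
            if p.exists():
                p.unlink()
        raise
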