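"""Bundled reference tables (drug dictionary, PT catalog, lookup maps).

All tables ship as editable CSVs under ``icivigil/resources`` so that users can
swap in their own drug dictionaries or event catalogs without touching code.
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources

import pandas as pd


def _resource_path(name: str):
    return resources.files("icivigil") / "resources" / name


@lru_cache(maxsize=None)
def load_table(name: str) -> pd.DataFrame:
    with resources.as_file(_resource_path(name)) as p:
        return pd.read_csv(p, dtype=str)


def drug_dictionary_frame() -> pd.DataFrame:
    return load_table("drug_dictionary.csv")


def pt_catalog_frame() -> pd.DataFrame:
    return load_table("pt_catalog.csv")


@lru_cache(maxsize=None)
def country_continent_map() -> dict[str, str]:
    df = load_table("country_continent.csv")
    return dict(zip(df["country"].str.upper(), df["continent"]))


@lru_cache(maxsize=None)
def indication_keyword_map() -> list[tuple[str, str]]:
    """Ordered (keyword, group) pairs; first match wins."""
    df = load_table("indication_groups.csv")
    return list(zip(df["keyword"].str.upper(), df["group"]))


def table1_margins() -> pd.DataFrame:
    df = load_table("table1_margins.csv").copy()
    df["fatal"] = df["fatal"].astype(int)
    df["nonfatal"] = df["nonfatal"].astype(int)
    return df
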