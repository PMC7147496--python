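"""Packaged report fixtures and their arithmetic replay.

The package ships two TSV fixtures transcribed from a published
EST-based miRNA survey of an orchid: the 14-candidate hairpin table
(accession, mature
sequence, precursor length, GC%, MFE, AMFE, MFEI) and the 134-row
predicted-target table.  ``replay_table1`` recomputes AMFE and MFEI
from each row's own inputs under the 2-decimal truncation convention
and flags rows whose printed values are not internally consistent
(the two zma-miR528 rows print an AMFE that does not follow from
their printed MFE and length).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .hairpin import amfe, mfei
from .io import parse_mirna_family

__all__ = [
    "load_table1",
    "load_table2",
    "replay_table1",
    "replay_table2",
    "summarize_table1",
]

_T1_COLUMNS = [
    "accession",
    "mirna_id",
    "mature_seq",
    "precursor_length",
    "gc_percent",
    "mfe",
    "amfe",
    "mfei",
]
_T2_COLUMNS = [
    "mirna_id",
    "target_accession",
    "expectation",
    "description",
    "inhibition",
]


def _data_path(name: str):
    return resources.files("estmir.data").joinpath(name)


def load_table1() -> pd.DataFrame:
    df = pd.read_csv(_data_path("table1.tsv"), sep="\t")
    missing = set(_T1_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"table1 fixture missing columns {sorted(missing)}")
    return df


def load_table2() -> pd.DataFrame:
    df = pd.read_csv(_data_path("table2.tsv"), sep="\t")
    missing = set(_T2_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"table2 fixture missing columns {sorted(missing)}")
    return df


def replay_table1(df: pd.DataFrame | None = None) -> pd.DataFrame:
    """Recompute AMFE from (MFE, length) and MFEI from (AMFE, GC%) per row.

    Adds ``amfe_recomputed`` / ``mfei_recomputed`` and boolean
    ``amfe_consistent`` / ``mfei_consistent`` columns; a row is flagged
    inconsistent when the printed value differs from the recomputation
    at 2-decimal truncation.
    """
    if df is None:
        df = load_table1()
    out = df.copy()
    out["amfe_recomputed"] = [
        amfe(row.mfe, int(row.precursor_length)) for row in out.itertuples()
    ]
    out["mfei_recomputed"] = [
        mfei(row.amfe, row.gc_percent) for row in out.itertuples()
    ]
    out["amfe_consistent"] = (out["amfe_recomputed"] - out["amfe"]).abs() < 5e-3
    out["mfei_consistent"] = (out["mfei_recomputed"] - out["mfei"]).abs() < 5e-3
    return out


def replay_table2(df: pd.DataFrame | None = None) -> dict:
    """Totals, inhibition-mode counts, expectation range, per-miRNA counts."""
    if df is None:
        df = load_table2()
    known = {"Cleavage", "Translation"}
    bad = set(df["inhibition"]) - known
    if bad:
        raise ValueError(f"unknown inhibition token(s) {sorted(bad)}")
    if len(df) == 0:
        return {
            "total": 0,
            "by_inhibition": {},
            "expectation_range": None,
            "per_mirna": {},
        }
    return {
        "total": int(len(df)),
        "by_inhibition": df["inhibition"].value_counts().to_dict(),
        "expectation_range": (
            float(df["expectation"].min()),
            float(df["expectation"].max()),
        ),
        "per_mirna": df["mirna_id"].value_counts().to_dict(),
    }


def summarize_table1(df: pd.DataFrame | None = None) -> dict:
    """Family counts and the length / energy ranges of the hairpin table."""
    if df is None:
        df = load_table1()
    families: dict[str, int] = {}
    for mid in df["mirna_id"]:
        fam = parse_mirna_family(mid)[1]
        families[fam] = families.get(fam, 0) + 1
    return {
        "n_candidates": int(len(df)),
        "families": families,
        "mature_length_range": (
            int(df["mature_seq"].str.len().min()),
            int(df["mature_seq"].str.len().max()),
        ),
        "precursor_length_range": (
            int(df["precursor_length"].min()),
            int(df["precursor_length"].max()),
        ),
        # MFE is the -dG magnitude, so dG spans (-max, -min)
        "delta_g_range_kcal_mol": (
            -float(df["mfe"].max()),
            -float(df["mfe"].min()),
        ),
    }
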