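"""Parse, deduplicate and filter FAERS-dialect quarterly tables.

The cleaning rules follow standard FDA practice for spontaneous-report
analysis:

1. **Deduplication** — one report per CASEID: keep the version with the most
   recent FDA_DT; on an FDA_DT tie keep the higher PRIMARYID.  Child-table
   rows of discarded versions are dropped.
2. **Suspect-role selection** — a report belongs to the target drug iff at
   least one of its drug rows names the drug (exact match on uppercased,
   trimmed DRUGNAME or PROD_AI against a synonym list) with role code PS
   (primary suspect, by default).
3. **Indication-term removal** — preferred terms that are also recorded as
   the target drug's indication (e.g. the treated disease itself) are removed
   from the target reports' event rows before PT-level disproportionality, to
   avoid counting the indication as an adverse event.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from ._util import date_sort_key
from .synthetic import DELIM, TABLE_COLUMNS

UNKNOWN_INDICATION = "PRODUCT USED FOR UNKNOWN INDICATION"

#: AGE_COD unit -> years multiplier
AGE_UNIT_TO_YEARS = {
    "DEC": 10.0, "YR": 1.0, "MON": 1 / 12, "WK": 7 / 365.25,
    "DY": 1 / 365.25, "HR": 1 / (24 * 365.25),
}
LB_TO_KG = 0.453592

#: OCCP_COD -> reporter category (FAERS codebook occupations)
REPORTER_MAP = {
    "MD": "health professional", "PH": "health professional",
    "HP": "health professional", "OT": "health professional",
    "CN": "consumer", "LW": "consumer",
}

SERIOUS_OUTCOME_CODES = ("DE", "LT", "HO", "DS", "CA", "RI", "OT")

#: mandatory columns per table for format validation
_MANDATORY = {
    "DEMO": ["PRIMARYID", "CASEID", "FDA_DT"],
    "DRUG": ["PRIMARYID", "DRUG_SEQ", "ROLE_COD", "DRUGNAME"],
    "REAC": ["PRIMARYID", "PT"],
    "THER": ["PRIMARYID", "DSG_DRUG_SEQ", "START_DT"],
    "INDI": ["PRIMARYID", "INDI_PT"],
    "OUTC": ["PRIMARYID", "OUTC_COD"],
}


class FormatError(ValueError):
    """Raised for malformed input tables (bad delimiter, ragged rows, ...)."""


@dataclass
class CleanDataset:
    """Deduplicated report set with its child tables and target selection."""

    reports: pd.DataFrame     # one row per surviving report
    drugs: pd.DataFrame
    events: pd.DataFrame      # unique (primaryid, pt)
    therapies: pd.DataFrame
    indications: pd.DataFrame
    outcomes: pd.DataFrame
    target_ids: frozenset[str]
    synonyms: tuple[str, ...]
    log: dict = field(default_factory=dict)

    @property
    def target_reports(self) -> pd.DataFrame:
        return self.reports[self.reports["primaryid"].isin(self.target_ids)]


def _read_table(path: Path, name: str) -> pd.DataFrame:
    """Read one dollar-delimited table with strict structural validation."""
    with open(path, "r", encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise FormatError(f"{name}: file {path} is empty (no header row)")
    header = lines[0].split(DELIM)
    if len(header) == 1 and ("," in lines[0] or "\t" in lines[0]):
        raise FormatError(
            f"{name}: expected '{DELIM}'-delimited input, header looks "
            f"comma/tab-delimited: {lines[0][:80]!r}")
    missing = [c for c in _MANDATORY.get(name, []) if c not in header]
    if missing:
        raise FormatError(f"{name}: missing mandatory column(s) {missing}")
    rows = []
    for lineno, line in enumerate(lines[1:], start=2):
        if line == "":
            continue
        parts = line.split(DELIM)
        if len(parts) != len(header):
            raise FormatError(
                f"{name}: line {lineno} has {len(parts)} fields, "
                f"header has {len(header)}")
        rows.append(parts)
    df = pd.DataFrame(rows, columns=header, dtype=str)
    if df.empty:
        df = pd.DataFrame(columns=header, dtype=str)
    return df


def read_bundle(paths: Mapping[str, str | Path] | str | Path) -> dict[str, pd.DataFrame]:
    """Read a bundle given a directory or an explicit table->path mapping.

    All fields are read as text; row counts are recorded under the ``_log``
    key so the cleaning funnel can be reported.
    """
    if isinstance(paths, (str, Path)):
        d = Path(paths)
        paths = {t: d / f"{t}.txt" for t in TABLE_COLUMNS}
    tables: dict[str, pd.DataFrame] = {}
    log = {}
    for name in TABLE_COLUMNS:
        p = Path(paths[name])
        if not p.exists():
            raise FileNotFoundError(f"{name} table not found at {p}")
        tables[name] = _read_table(p, name)
        log[f"rows_{name}"] = len(tables[name])
    tables["_log"] = log  # type: ignore[assignment]
    return tables


def deduplicate(demo: pd.DataFrame) -> pd.DataFrame:
    """One row per CASEID: argmax of (FDA_DT, then numeric PRIMARYID).

    Unparseable FDA_DT ranks lowest (kept only if the case has no parseable
    sibling); PRIMARYID falls back to a string comparison when non-numeric.
    The operation is idempotent and total.
    """
    if demo.empty:
        return demo.copy()
    work = demo.copy()
    work["_fda"] = work["FDA_DT"].map(date_sort_key)
    pid_num = pd.to_numeric(work["PRIMARYID"], errors="coerce")
    work["_pid"] = pid_num.fillna(-1.0)
    work = work.sort_values(["CASEID", "_fda", "_pid", "PRIMARYID"],
                            kind="mergesort")
    out = work.groupby("CASEID", sort=False).tail(1)
    return out.drop(columns=["_fda", "_pid"]).reset_index(drop=True)


def filter_children(tables: Mapping[str, pd.DataFrame],
                    keep: Iterable[str]) -> dict[str, pd.DataFrame]:
    """Restrict child tables to the surviving PRIMARYIDs."""
    keep = set(keep)
    return {name: df[df["PRIMARYID"].isin(keep)].reset_index(drop=True)
            for name, df in tables.items()
            if name in ("DRUG", "REAC", "THER", "INDI", "OUTC")}


def select_target_reports(drugs: pd.DataFrame, synonyms: Iterable[str],
                          roles: Iterable[str] = ("PS",)) -> frozenset[str]:
    """Report ids with >=1 drug row exactly matching a synonym in a kept role.

    Matching is exact on uppercased, whitespace-trimmed DRUGNAME or PROD_AI;
    no substring matching ("DRUG 100MG" does not match "DRUG").
    """
    synonyms = [s.strip().upper() for s in synonyms if s and s.strip()]
    if not synonyms:
        raise ValueError("synonym list must be non-empty")
    roles = set(roles)
    if drugs.empty:
        return frozenset()
    name = drugs["DRUGNAME"].fillna("").str.strip().str.upper()
    ai = drugs.get("PROD_AI", pd.Series("", index=drugs.index)).fillna("")
    ai = ai.str.strip().str.upper()
    hit = (name.isin(synonyms) | ai.isin(synonyms)) & drugs["ROLE_COD"].isin(roles)
    return frozenset(drugs.loc[hit, "PRIMARYID"])


def target_indication_set(indications: pd.DataFrame, drugs: pd.DataFrame,
                          target_ids: frozenset[str],
                          synonyms: Iterable[str]) -> set[str]:
    """Uppercased indication terms recorded for the target drug itself.

    INDI rows are joined to the target drug's DRUG_SEQ within target reports
    when the sequence column is present; the placeholder term for an unknown
    indication is never treated as an indication.
    """
    if indications.empty:
        return set()
    syn = {s.strip().upper() for s in synonyms}
    tgt_drugs = drugs[
        drugs["PRIMARYID"].isin(target_ids)
        & (drugs["DRUGNAME"].str.strip().str.upper().isin(syn)
           | drugs.get("PROD_AI", pd.Series("", index=drugs.index))
           .fillna("").str.strip().str.upper().isin(syn))
    ]
    ind = indications[indications["PRIMARYID"].isin(target_ids)]
    if "INDI_DRUG_SEQ" in ind.columns and "DRUG_SEQ" in tgt_drugs.columns:
        keys = set(zip(tgt_drugs["PRIMARYID"], tgt_drugs["DRUG_SEQ"]))
        ind = ind[[(p, s) in keys for p, s in
                   zip(ind["PRIMARYID"], ind["INDI_DRUG_SEQ"])]]
    terms = {t.strip().upper() for t in ind["INDI_PT"] if t and t.strip()}
    terms.discard(UNKNOWN_INDICATION)
    return terms


def exclude_indication_pts(events: pd.DataFrame, indication_terms: set[str],
                           target_ids: frozenset[str]) -> tuple[pd.DataFrame, int]:
    """Drop target-report event rows whose PT is an indication term.

    Case-insensitive membership; comparator reports are untouched.  Returns
    the filtered events and the number of removed rows.
    """
    if events.empty or not indication_terms:
        return events.copy(), 0
    is_tgt = events["PRIMARYID"].isin(target_ids)
    is_ind = events["PT"].str.strip().str.upper().isin(indication_terms)
    drop = is_tgt & is_ind
    return events[~drop].reset_index(drop=True), int(drop.sum())


def convert_age_years(age: str, cod: str) -> float:
    """AGE plus AGE_COD unit to years; NaN when absent/unparseable."""
    try:
        v = float(age)
    except (TypeError, ValueError):
        return np.nan
    mult = AGE_UNIT_TO_YEARS.get((cod or "").strip().upper(), 1.0)
    return v * mult


def convert_weight_kg(wt: str, cod: str) -> float:
    """WT plus WT_COD unit to kilograms; NaN when absent or non-positive."""
    try:
        v = float(wt)
    except (TypeError, ValueError):
        return np.nan
    if (cod or "").strip().upper() == "LBS":
        v *= LB_TO_KG
    return v if v > 0 else np.nan


def _col(df: pd.DataFrame, name: str) -> pd.Series:
    return df[name] if name in df.columns else pd.Series("", index=df.index, dtype=str)


def build_reports(demo: pd.DataFrame) -> pd.DataFrame:
    """Normalize a deduplicated DEMO table to typed report records."""
    sex = _col(demo, "SEX").str.strip().str.upper()
    rep = pd.DataFrame({
        "primaryid": demo["PRIMARYID"],
        "caseid": demo["CASEID"],
        "fda_dt": demo["FDA_DT"],
        "event_dt": _col(demo, "EVENT_DT"),
        "sex": sex.where(sex.isin(["F", "M"]), "UNK"),
        "country": _col(demo, "OCCR_COUNTRY"),
    })
    rep["age_years"] = [
        convert_age_years(a, c)
        for a, c in zip(_col(demo, "AGE"), _col(demo, "AGE_COD"))
    ]
    rep["weight_kg"] = [
        convert_weight_kg(w, c)
        for w, c in zip(_col(demo, "WT"), _col(demo, "WT_COD"))
    ]
    occ = _col(demo, "OCCP_COD").str.strip().str.upper()
    rep["reporter"] = occ.map(REPORTER_MAP).fillna("unknown")
    return rep.reset_index(drop=True)


def assign_strata(reports: pd.DataFrame) -> pd.DataFrame:
    """Add age/weight stratum labels.

    Boundary convention: the middle stratum is closed on both sides —
    age 18 and 64 both fall in "18-64", weight 80 and 100 both in "80-100".
    """
    out = reports.copy()
    age = out["age_years"]
    out["age_group"] = np.select(
        [age < 18, (age >= 18) & (age <= 64), age > 64],
        ["<18", "18-64", ">64"], default="unknown")
    wt = out["weight_kg"]
    out["weight_group"] = np.select(
        [wt < 80, (wt >= 80) & (wt <= 100), wt > 100],
        ["<80", "80-100", ">100"], default="unknown")
    return out


def clean_bundle(tables: Mapping[str, pd.DataFrame], synonyms: Iterable[str],
                 roles: Iterable[str] = ("PS",)) -> CleanDataset:
    """Run the full cleaning funnel on raw tables.

    dedup -> child filtering -> record normalization -> target selection ->
    event pair dedup -> indication-term removal, with before/after counts in
    ``dataset.log``.
    """
    synonyms = tuple(s.strip().upper() for s in synonyms if s and s.strip())
    log: dict = dict(tables.get("_log", {}))
    demo = tables["DEMO"]
    log["demo_rows_raw"] = len(demo)
    # mandatory-field presence: primaryid and caseid must be non-empty
    demo = demo[(demo["PRIMARYID"].str.strip() != "")
                & (demo["CASEID"].str.strip() != "")]
    dedup = deduplicate(demo)
    log["reports_after_dedup"] = len(dedup)
    children = filter_children(tables, dedup["PRIMARYID"])
    reports = assign_strata(build_reports(dedup))

    target_ids = select_target_reports(children["DRUG"], synonyms, roles)
    log["target_reports"] = len(target_ids)

    events = children["REAC"][["PRIMARYID", "PT"]].copy()
    events["PT"] = events["PT"].str.strip()
    events = events[events["PT"] != ""]
    before = len(events)
    events = events.drop_duplicates(["PRIMARYID", "PT"]).reset_index(drop=True)
    log["event_rows_deduped"] = before - len(events)

    ind_terms = target_indication_set(children["INDI"], children["DRUG"],
                                      target_ids, synonyms)
    events, removed = exclude_indication_pts(events, ind_terms, target_ids)
    log["indication_terms"] = sorted(ind_terms)
    log["indication_event_rows_removed"] = removed
    log["event_rows_final"] = len(events)

    return CleanDataset(
        reports=reports, drugs=children["DRUG"], events=events,
        therapies=children["THER"], indications=children["INDI"],
        outcomes=children["OUTC"], target_ids=target_ids,
        synonyms=synonyms, log=log,
    )


def load_clean_bundle(bundle_dir: str | Path, synonyms: Iterable[str],
                      roles: Iterable[str] = ("PS",)) -> CleanDataset:
    """Convenience: :func:`read_bundle` + :func:`clean_bundle`."""
    return clean_bundle(read_bundle(bundle_dir), synonyms, roles)


def read_soc_map(path: str | Path) -> pd.Series:
    """Two-column delimited PT->SOC map, uppercased PT index."""
    df = pd.read_csv(path, sep=DELIM, dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        df = pd.read_csv(path, sep=None, engine="python", dtype=str,
                         keep_default_na=False)
    pts = df.iloc[:, 0].str.strip().str.upper()
    if pts.duplicated().any():
        dup = sorted(pts[pts.duplicated()].unique())
        raise FormatError(f"PT->SOC map has duplicate PT entries: {dup[:5]}")
    return pd.Series(df.iloc[:, 1].values, index=pts)
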