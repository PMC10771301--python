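"""Subgroup signal tables and the gender-difference volcano analysis.

Two stratified views are provided:

- **Subgroup signals** — the full disproportionality screen rerun within one
  stratum of a demographic field (age group, weight group, reporter, sex),
  with both target and comparator reports restricted to that stratum.
- **Gender contrast** — within target-drug reports only, a per-PT 2x2 table
  of sex (F/M) against event presence, summarised by the female-vs-male odds
  ratio with a Woolf CI, a two-sided Fisher exact p-value and a
  Benjamini-Hochberg adjusted p-value.  This "ROR" is a case/non-case odds
  ratio between sexes within one drug, not a between-drug reporting odds
  ratio.  Reports of unknown sex are excluded here but retained everywhere
  else.

The volcano view maps each PT to (log2 OR, -log10 adjusted p) and labels it
female-enriched / male-enriched / null at a configurable significance level.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

from .ingest import CleanDataset
from .signals import signal_table, rank_table


@dataclass(frozen=True)
class StratumSignal:
    pt: str
    stratum_a: str
    stratum_b: str
    n_a: int
    n_b: int
    other_a: int
    other_b: int
    or_value: float
    or_ci95: tuple[float, float]
    log2_or: float
    p_raw: float


STRATUM_FIELDS = {"age": "age_group", "weight": "weight_group",
                  "reporter": "reporter", "sex": "sex"}


def subset_dataset(dataset: CleanDataset, report_ids) -> CleanDataset:
    """Restrict a dataset to a report subset, preserving referential integrity."""
    keep = set(report_ids)
    return CleanDataset(
        reports=dataset.reports[dataset.reports["primaryid"].isin(keep)]
        .reset_index(drop=True),
        drugs=dataset.drugs[dataset.drugs["PRIMARYID"].isin(keep)]
        .reset_index(drop=True),
        events=dataset.events[dataset.events["PRIMARYID"].isin(keep)]
        .reset_index(drop=True),
        therapies=dataset.therapies[dataset.therapies["PRIMARYID"].isin(keep)]
        .reset_index(drop=True),
        indications=dataset.indications[dataset.indications["PRIMARYID"].isin(keep)]
        .reset_index(drop=True),
        outcomes=dataset.outcomes[dataset.outcomes["PRIMARYID"].isin(keep)]
        .reset_index(drop=True),
        target_ids=frozenset(dataset.target_ids & keep),
        synonyms=dataset.synonyms,
        log={"parent_log": dataset.log, "subset_n": len(keep)},
    )


def subgroup_signals(dataset: CleanDataset, stratum_field: str,
                     min_cases: int = 3, soc_map: pd.Series | None = None,
                     level: str = "PT",
                     top_k: int | None = None) -> dict[str, pd.DataFrame]:
    """Per-stratum signal tables for one demographic field.

    Strata partition the reports (an "unknown" stratum included), so the
    per-stratum ``a`` cells sum to the unstratified ``a`` for every event.
    """
    if stratum_field not in STRATUM_FIELDS:
        raise ValueError(f"stratum_field must be one of {sorted(STRATUM_FIELDS)}")
    col = STRATUM_FIELDS[stratum_field]
    out: dict[str, pd.DataFrame] = {}
    for stratum, grp in dataset.reports.groupby(col, sort=True):
        sub = subset_dataset(dataset, grp["primaryid"])
        if not sub.target_ids:
            out[str(stratum)] = pd.DataFrame()
            continue
        tbl = signal_table(sub, level=level, soc_map=soc_map,
                           min_cases=min_cases)
        tbl = rank_table(tbl, sort_key="a", min_cases=min_cases)
        out[str(stratum)] = tbl.head(top_k) if top_k else tbl
    return out


def gender_contrast(dataset: CleanDataset, pt: str) -> StratumSignal:
    """Female-vs-male 2x2 contrast for one PT within target reports.

    OR = (n_F * other_M) / (other_F * n_M); NaN when any cell is zero (no
    continuity correction).  The Fisher exact p-value is defined regardless.
    """
    rep = dataset.target_reports
    known = rep[rep["sex"].isin(["F", "M"])]
    with_pt = set(dataset.events.loc[dataset.events["PT"] == pt, "PRIMARYID"])
    is_case = known["primaryid"].isin(with_pt)
    is_f = known["sex"] == "F"
    n_f = int((is_case & is_f).sum())
    n_m = int((is_case & ~is_f).sum())
    other_f = int((~is_case & is_f).sum())
    other_m = int((~is_case & ~is_f).sum())
    return _contrast_from_cells(pt, n_f, n_m, other_f, other_m)


def _contrast_from_cells(pt: str, n_f: int, n_m: int, other_f: int,
                         other_m: int) -> StratumSignal:
    if min(n_f, n_m, other_f, other_m) > 0:
        or_v = (n_f * other_m) / (other_f * n_m)
        se = math.sqrt(1 / n_f + 1 / n_m + 1 / other_f + 1 / other_m)
        ci = (math.exp(math.log(or_v) - 1.96 * se),
              math.exp(math.log(or_v) + 1.96 * se))
        l2 = math.log2(or_v)
    else:
        or_v, ci, l2 = float("nan"), (float("nan"), float("nan")), float("nan")
    _, p = fisher_exact([[n_f, other_f], [n_m, other_m]], alternative="two-sided")
    return StratumSignal(pt=pt, stratum_a="F", stratum_b="M", n_a=n_f,
                         n_b=n_m, other_a=other_f, other_b=other_m,
                         or_value=or_v, or_ci95=ci, log2_or=l2,
                         p_raw=float(p))


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def gender_volcano(dataset: CleanDataset, min_cases: int = 3,
                   significance: float = 0.05,
                   effect_floor: float = 0.0) -> pd.DataFrame:
    """Volcano table over all PTs with >= min_cases known-sex target cases.

    One row per PT: the 2x2 cells, OR and CI, log2 OR, raw and BH-adjusted p,
    -log10(p_adj) and the direction label.
    """
    rep = dataset.target_reports
    known = rep[rep["sex"].isin(["F", "M"])]
    ev = dataset.events[dataset.events["PRIMARYID"].isin(known["primaryid"])]
    counts = ev.groupby("PT")["PRIMARYID"].nunique()
    pts = counts[counts >= min_cases].index
    sex = known.set_index("primaryid")["sex"]
    n_f_total = int((sex == "F").sum())
    n_m_total = int((sex == "M").sum())
    rows = []
    for pt in pts:
        pids = ev.loc[ev["PT"] == pt, "PRIMARYID"].unique()
        s = sex.loc[sex.index.intersection(pids)]
        n_f = int((s == "F").sum())
        n_m = len(s) - n_f
        sig = _contrast_from_cells(pt, n_f, n_m, n_f_total - n_f,
                                   n_m_total - n_m)
        rows.append({
            "pt": pt, "n_f": sig.n_a, "n_m": sig.n_b,
            "other_f": sig.other_a, "other_m": sig.other_b,
            "or_value": sig.or_value, "or_lo": sig.or_ci95[0],
            "or_hi": sig.or_ci95[1], "log2_or": sig.log2_or,
            "p_raw": sig.p_raw,
        })
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    df["p_adj"] = fdr_adjust(df["p_raw"].to_numpy())
    return volcano_table(df, significance=significance,
                         effect_floor=effect_floor)


def volcano_table(signals: pd.DataFrame, significance: float = 0.05,
                  effect_floor: float = 0.0) -> pd.DataFrame:
    """Attach volcano coordinates and direction labels to contrast rows."""
    df = signals.copy()
    df["neg_log10_p_adj"] = -np.log10(df["p_adj"])
    sig = df["p_adj"] < significance
    l2 = df["log2_or"]
    df["direction"] = np.select(
        [sig & (l2 > effect_floor), sig & (l2 < -effect_floor)],
        ["female-enriched", "male-enriched"], default="null")
    df.loc[l2.isna(), "direction"] = "null"
    return df
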