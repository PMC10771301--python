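"""Drug-event 2x2 contingency tables and disproportionality statistics.

For a drug-event pair the database collapses to the 2x2 table

====================  ============  ============
                      target event  other events
target drug           a             b
all other drugs       c             d
====================  ============  ============

counted in unique (report, event-label) pairs, so one report contributes at
most 1 to any ``a`` cell (and at most once per SOC even when several of its
PTs map to that SOC).  Four classic statistics are computed:

- **ROR** ``ad/bc`` with a Woolf (log-normal) 95% CI;
- **PRR** ``a(c+d)/(c(a+b))`` with the (uncorrected) Pearson chi-squared;
- **BCPNN information component** ``IC = log2(a*n/((a+c)(a+b)))`` with the
  Bate-style closed-form posterior mean/variance and the two-sigma lower
  credibility bound IC025;
- **EBGM** — the relative reporting ratio ``a*n/((a+c)(a+b))`` with a
  log-normal interval whose lower bound is reported as EBGM05.  (This is the
  simplified closed form; no gamma-Poisson mixture prior is fitted.)

Signal criteria (per-algorithm) are the conventional ones: ROR CI lower
bound > 1 with N >= 3; PRR >= 2 with chi2 >= 4 and N >= 3; IC025 > 0;
EBGM05 > 2.  The combined signal is the conjunction of all four; an
any-of-four flag is also emitted for SOC-level reporting.

Zero cells: no continuity correction is applied — a statistic whose formula
requires a zero cell in a denominator is reported not-evaluable (NaN) and
fails its criterion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from ._util import round_half_up
from .ingest import CleanDataset

LOG2 = math.log(2.0)

#: Bate-style BCPNN prior: margin Beta priors all 1, joint prior mass
#: gamma11 tied to the margins so that the prior IC expectation is 0.
DEFAULT_BCPNN_PRIOR = {"alpha1": 1.0, "beta1": 1.0, "alpha": 2.0, "beta": 2.0,
                       "gamma11": 1.0}


@dataclass(frozen=True)
class ContingencyTable:
    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class SignalMetrics:
    a: int
    ror: float
    ror_ci95: tuple[float, float]
    prr: float
    chi2: float
    ic: float
    e_ic: float
    v_ic: float
    ic025: float
    ebgm: float
    ebgm05: float
    ror_pos: bool
    prr_pos: bool
    bcpnn_pos: bool
    mgps_pos: bool
    combined_signal: bool
    any_signal: bool


# ---------------------------------------------------------------------------
# vectorised kernels (scalar API wraps these)
# ---------------------------------------------------------------------------

def _as_float(*cells):
    return [np.asarray(x, dtype=float) for x in cells]


def ror_arrays(a, b, c, d):
    """ROR and Woolf 95% CI; NaN where any cell is zero."""
    a, b, c, d = _as_float(a, b, c, d)
    with np.errstate(divide="ignore", invalid="ignore"):
        ok = (a > 0) & (b > 0) & (c > 0) & (d > 0)
        ror = np.where(ok, (a * d) / (b * c), np.nan)
        se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
        lo = np.where(ok, np.exp(np.log(ror) - 1.96 * se), np.nan)
        hi = np.where(ok, np.exp(np.log(ror) + 1.96 * se), np.nan)
    return ror, lo, hi


def prr_arrays(a, b, c, d):
    """PRR and uncorrected chi-squared; NaN where a denominator is zero."""
    a, b, c, d = _as_float(a, b, c, d)
    n = a + b + c + d
    with np.errstate(divide="ignore", invalid="ignore"):
        prr_ok = (c > 0) & (a + b > 0) & (c + d > 0)
        prr = np.where(prr_ok, (a * (c + d)) / (c * (a + b)), np.nan)
        denom = (a + b) * (c + d) * (a + c) * (b + d)
        chi_ok = denom > 0
        chi2 = np.where(chi_ok, (a * d - b * c) ** 2 * n / np.where(chi_ok, denom, 1.0),
                        np.nan)
    return prr, chi2


def bcpnn_arrays(a, b, c, d, prior: Mapping[str, float] | None = None):
    """Observed IC plus Bate closed-form posterior moments and IC025.

    The observed IC is -inf when a = 0 (log of zero); the Bayesian moments
    remain finite there, which is the point of the prior.
    """
    a, b, c, d = _as_float(a, b, c, d)
    pr = dict(DEFAULT_BCPNN_PRIOR)
    if prior:
        pr.update(prior)
    a1, b1 = pr["alpha1"], pr["beta1"]
    al, be, g11 = pr["alpha"], pr["beta"], pr["gamma11"]
    n = a + b + c + d
    ab, ac = a + b, a + c
    with np.errstate(divide="ignore", invalid="ignore"):
        margins_ok = (ab > 0) & (ac > 0) & (n > 0)
        ic = np.where(margins_ok,
                      np.log2(a * n / np.where(margins_ok, ac * ab, 1.0)),
                      np.nan)
        ic = np.where(margins_ok & (a == 0), -np.inf, ic)
        gamma = g11 * (n + al) * (n + be) / ((ab + a1) * (ac + b1))
        e_ic = (np.log((a + g11) / (n + gamma))
                - np.log((ab + a1) / (n + al))
                - np.log((ac + b1) / (n + be))) / LOG2
        v_ic = ((n - a + gamma - g11) / ((a + g11) * (1 + n + gamma))
                + (n - ab + al - a1) / ((ab + a1) * (1 + n + al))
                + (n - ac + be - b1) / ((ac + b1) * (1 + n + be))) / LOG2 ** 2
        ic025 = e_ic - 2.0 * np.sqrt(v_ic)
    return ic, e_ic, v_ic, ic025


def mgps_arrays(a, b, c, d):
    """EBGM (relative reporting ratio) and the log-normal EBGM05."""
    a, b, c, d = _as_float(a, b, c, d)
    n = a + b + c + d
    ab, ac = a + b, a + c
    with np.errstate(divide="ignore", invalid="ignore"):
        point_ok = (ab > 0) & (ac > 0)
        ebgm = np.where(point_ok, a * n / np.where(point_ok, ac * ab, 1.0), np.nan)
        ci_ok = (a > 0) & (b > 0) & (c > 0) & (d > 0)
        se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
        ebgm05 = np.where(ci_ok, np.exp(np.log(ebgm) - 1.96 * se), np.nan)
    return ebgm, ebgm05


# ---------------------------------------------------------------------------
# scalar API
# ---------------------------------------------------------------------------

def compute_ror(t: ContingencyTable) -> tuple[float, tuple[float, float]]:
    ror, lo, hi = ror_arrays(t.a, t.b, t.c, t.d)
    return float(ror), (float(lo), float(hi))


def compute_prr(t: ContingencyTable) -> tuple[float, float]:
    prr, chi2 = prr_arrays(t.a, t.b, t.c, t.d)
    return float(prr), float(chi2)


def compute_bcpnn(t: ContingencyTable,
                  prior: Mapping[str, float] | None = None
                  ) -> tuple[float, float, float, float]:
    ic, e_ic, v_ic, ic025 = bcpnn_arrays(t.a, t.b, t.c, t.d, prior)
    return float(ic), float(e_ic), float(v_ic), float(ic025)


def compute_mgps(t: ContingencyTable) -> tuple[float, float]:
    ebgm, ebgm05 = mgps_arrays(t.a, t.b, t.c, t.d)
    return float(ebgm), float(ebgm05)


def classify_signal(ror_lo: float, prr: float, chi2: float, ic025: float,
                    ebgm05: float, n_cases: int) -> dict[str, bool]:
    """Apply the per-algorithm criteria; not-evaluable (NaN) never fires."""
    def _ok(x):
        return x is not None and not (isinstance(x, float) and math.isnan(x))

    ror_pos = _ok(ror_lo) and ror_lo > 1 and n_cases >= 3
    prr_pos = (_ok(prr) and _ok(chi2) and prr >= 2 and chi2 >= 4
               and n_cases >= 3)
    bcpnn_pos = _ok(ic025) and ic025 > 0
    mgps_pos = _ok(ebgm05) and ebgm05 > 2
    flags = {"ror_pos": bool(ror_pos), "prr_pos": bool(prr_pos),
             "bcpnn_pos": bool(bcpnn_pos), "mgps_pos": bool(mgps_pos)}
    flags["combined_signal"] = all(flags.values())
    flags["any_signal"] = any([ror_pos, prr_pos, bcpnn_pos, mgps_pos])
    return flags


def signal_metrics(t: ContingencyTable,
                   prior: Mapping[str, float] | None = None) -> SignalMetrics:
    """All four statistics plus flags for one 2x2 table."""
    ror, (lo, hi) = compute_ror(t)
    prr, chi2 = compute_prr(t)
    ic, e_ic, v_ic, ic025 = compute_bcpnn(t, prior)
    ebgm, ebgm05 = compute_mgps(t)
    flags = classify_signal(lo, prr, chi2, ic025, ebgm05, t.a)
    return SignalMetrics(a=t.a, ror=ror, ror_ci95=(lo, hi), prr=prr,
                         chi2=chi2, ic=ic, e_ic=e_ic, v_ic=v_ic, ic025=ic025,
                         ebgm=ebgm, ebgm05=ebgm05, **flags)


# ---------------------------------------------------------------------------
# dataset-level construction
# ---------------------------------------------------------------------------

def event_pairs(dataset: CleanDataset, level: str = "PT",
                soc_map: pd.Series | None = None) -> pd.DataFrame:
    """Unique (primaryid, label, is_target) pairs at PT or SOC level."""
    level = level.upper()
    if level not in ("PT", "SOC"):
        raise ValueError(f"unknown level {level!r}")
    ev = dataset.events[["PRIMARYID", "PT"]].copy()
    if level == "SOC":
        if soc_map is None:
            raise ValueError("SOC level requires a PT->SOC map")
        key = ev["PT"].str.strip().str.upper()
        unmapped = sorted(set(key) - set(soc_map.index))
        if unmapped:
            raise ValueError(f"PTs missing from the SOC map: {unmapped[:10]}"
                             + ("..." if len(unmapped) > 10 else ""))
        ev["label"] = key.map(soc_map)
    else:
        ev["label"] = ev["PT"]
    ev = ev[["PRIMARYID", "label"]].drop_duplicates()
    ev["is_target"] = ev["PRIMARYID"].isin(dataset.target_ids)
    return ev.reset_index(drop=True)


def contingency_counts(dataset: CleanDataset, level: str = "PT",
                       soc_map: pd.Series | None = None) -> pd.DataFrame:
    """Per-label a, b, c, d over the whole dataset (pair counting unit)."""
    pairs = event_pairs(dataset, level, soc_map)
    total_target = int(pairs["is_target"].sum())
    total_other = int(len(pairs) - total_target)
    grp = pairs.groupby("label")["is_target"]
    a = grp.sum().astype(int)
    ac = grp.count().astype(int)
    out = pd.DataFrame({"a": a, "c": ac - a})
    out["b"] = total_target - out["a"]
    out["d"] = total_other - out["c"]
    return out[["a", "b", "c", "d"]].sort_index()


def build_contingency(dataset: CleanDataset, event: str, level: str = "PT",
                      soc_map: pd.Series | None = None) -> ContingencyTable:
    """The 2x2 table for one PT or SOC label."""
    counts = contingency_counts(dataset, level, soc_map)
    if event in counts.index:
        row = counts.loc[event]
        return ContingencyTable(int(row["a"]), int(row["b"]),
                                int(row["c"]), int(row["d"]))
    pairs = event_pairs(dataset, level, soc_map)
    nt = int(pairs["is_target"].sum())
    return ContingencyTable(0, nt, 0, len(pairs) - nt)


def signal_table(dataset: CleanDataset, level: str = "PT",
                 soc_map: pd.Series | None = None, min_cases: int = 3,
                 prior: Mapping[str, float] | None = None) -> pd.DataFrame:
    """Full signal screen: one row per label with a >= min_cases.

    Columns: the 2x2 cells, all statistics/CIs and the per-algorithm,
    combined (all-four) and any-of-four flags.  Values are full precision;
    use :func:`rank_table` for display formatting.
    """
    counts = contingency_counts(dataset, level, soc_map)
    counts = counts[counts["a"] >= max(min_cases, 0)]
    if counts.empty:
        return pd.DataFrame(columns=[
            "a", "b", "c", "d", "ror", "ror_lo", "ror_hi", "prr", "chi2",
            "ic", "e_ic", "v_ic", "ic025", "ebgm", "ebgm05", "ror_pos",
            "prr_pos", "bcpnn_pos", "mgps_pos", "combined_signal",
            "any_signal"])
    a, b, c, d = (counts[k].to_numpy() for k in ("a", "b", "c", "d"))
    ror, lo, hi = ror_arrays(a, b, c, d)
    prr, chi2 = prr_arrays(a, b, c, d)
    ic, e_ic, v_ic, ic025 = bcpnn_arrays(a, b, c, d, prior)
    ebgm, ebgm05 = mgps_arrays(a, b, c, d)
    out = counts.copy()
    out["ror"], out["ror_lo"], out["ror_hi"] = ror, lo, hi
    out["prr"], out["chi2"] = prr, chi2
    out["ic"], out["e_ic"], out["v_ic"], out["ic025"] = ic, e_ic, v_ic, ic025
    out["ebgm"], out["ebgm05"] = ebgm, ebgm05
    with np.errstate(invalid="ignore"):
        out["ror_pos"] = np.nan_to_num(lo, nan=-np.inf) > 1
        out["prr_pos"] = ((np.nan_to_num(prr, nan=-np.inf) >= 2)
                          & (np.nan_to_num(chi2, nan=-np.inf) >= 4))
        out["bcpnn_pos"] = np.nan_to_num(ic025, nan=-np.inf) > 0
        out["mgps_pos"] = np.nan_to_num(ebgm05, nan=-np.inf) > 2
    n_ok = out["a"] >= 3
    out["ror_pos"] &= n_ok
    out["prr_pos"] &= n_ok
    out["combined_signal"] = (out["ror_pos"] & out["prr_pos"]
                              & out["bcpnn_pos"] & out["mgps_pos"])
    out["any_signal"] = (out["ror_pos"] | out["prr_pos"]
                         | out["bcpnn_pos"] | out["mgps_pos"])
    return out


_SORT_KEYS = ("a", "ror", "prr", "chi2", "ic", "ebgm", "ic025", "ebgm05")


def rank_table(results: pd.DataFrame, sort_key: str = "a",
               min_cases: int = 0) -> pd.DataFrame:
    """Presentation ordering and display rounding of a signal table.

    Rows with ``a >= min_cases``, sorted by ``sort_key`` descending with ties
    broken lexicographically by event label; statistics rounded half away
    from zero to 2 decimals and a formatted ``ror_ci`` / ``ic_ic025`` /
    ``ebgm_ebgm05`` column triple in the style of published signal tables.
    """
    if sort_key not in _SORT_KEYS:
        raise ValueError(f"unknown sort key {sort_key!r}; one of {_SORT_KEYS}")
    if results.empty:
        return results.copy()
    df = results[results["a"] >= min_cases].copy()
    df = df.sort_index(kind="mergesort")
    df = df.sort_values(sort_key, ascending=False, kind="mergesort")

    def _r(x):
        return round_half_up(float(x), 2) if pd.notna(x) else float("nan")

    def _fmt(v):
        return "NE" if pd.isna(v) or not math.isfinite(v) else f"{_r(v):.2f}"

    for col in ("ror", "prr", "chi2", "ic", "ic025", "ebgm", "ebgm05"):
        if col in df.columns:
            df[f"{col}_disp"] = df[col].map(_r)
    df["ror_ci"] = [f"{_fmt(r)}({_fmt(lo)}-{_fmt(hi)})"
                    for r, lo, hi in zip(df["ror"], df["ror_lo"], df["ror_hi"])]
    df["ic_ic025"] = [f"{_fmt(i)}({_fmt(j)})"
                      for i, j in zip(df["ic"], df["ic025"])]
    df["ebgm_ebgm05"] = [f"{_fmt(e)}({_fmt(j)})"
                         for e, j in zip(df["ebgm"], df["ebgm05"])]
    return df
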