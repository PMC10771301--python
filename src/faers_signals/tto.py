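"""Time to onset (TTO): days from therapy start to adverse-event onset.

TTO is the interval between the report's EVENT_DT (onset of the adverse
event) and the START_DT of the suspect drug's therapy episode.  Only fully
specified, parseable 8-digit dates are used; partial dates (YYYYMM / YYYY),
blanks, impossible calendar dates and negative intervals (event before
start) are dropped and counted in the log.  When a report carries several
valid therapy start dates for the suspect drug, the earliest (first
exposure) is used.

By default one observation is emitted per report; ``unit="event"`` emits one
per (report, PT) pair instead, leaving the interval identical within a
report.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._util import parse_yyyymmdd
from .ingest import CleanDataset

#: right-closed bin edges in days and their labels
BIN_EDGES = (30, 60, 90, 180, 360)
BIN_LABELS = ("0-30", "31-60", "61-90", "91-180", "181-360", ">360")


def assign_bin(days: int) -> str:
    """Bin label for a non-negative onset interval; exhaustive and disjoint."""
    if days < 0:
        raise ValueError("onset interval must be non-negative")
    for edge, label in zip(BIN_EDGES, BIN_LABELS):
        if days <= edge:
            return label
    return BIN_LABELS[-1]


@dataclass
class TTOSummary:
    n: int
    median_days: float
    q1: float
    q3: float
    bin_counts: pd.Series
    bin_fractions: pd.Series
    drop_log: dict | None = None


def _target_start_dates(dataset: CleanDataset) -> pd.DataFrame:
    """Therapy rows joined to the target drug's DRUG_SEQ, per target report."""
    syn = set(dataset.synonyms)
    drugs = dataset.drugs
    name = drugs["DRUGNAME"].str.strip().str.upper()
    ai = (drugs["PROD_AI"].fillna("").str.strip().str.upper()
          if "PROD_AI" in drugs.columns else name)
    tgt = drugs[(name.isin(syn) | ai.isin(syn))
                & drugs["PRIMARYID"].isin(dataset.target_ids)]
    ther = dataset.therapies.merge(
        tgt[["PRIMARYID", "DRUG_SEQ"]].drop_duplicates(),
        left_on=["PRIMARYID", "DSG_DRUG_SEQ"],
        right_on=["PRIMARYID", "DRUG_SEQ"],
    )
    return ther[["PRIMARYID", "START_DT"]]


def compute_tto(dataset: CleanDataset, unit: str = "report") -> pd.DataFrame:
    """Per-report (or per report-event) onset intervals for target reports.

    Returns a frame with ``primaryid``, ``onset_days`` and ``bin`` columns
    plus a ``drop_log`` attribute in ``DataFrame.attrs`` with the counts of
    rows discarded by each rule.
    """
    if unit not in ("report", "event"):
        raise ValueError("unit must be 'report' or 'event'")
    ther = _target_start_dates(dataset)
    ther = ther.assign(start=ther["START_DT"].map(parse_yyyymmdd))
    n_start_bad = int(ther["start"].isna().sum())
    ther = ther.dropna(subset=["start"])
    starts = ther.groupby("PRIMARYID")["start"].min()

    rep = dataset.target_reports[["primaryid", "event_dt"]].copy()
    rep["event"] = rep["event_dt"].map(parse_yyyymmdd)
    n_event_bad = int(rep["event"].isna().sum())
    rep = rep.dropna(subset=["event"])
    rep = rep[rep["primaryid"].isin(starts.index)]
    rep["start"] = rep["primaryid"].map(starts)
    delta = (rep["event"] - rep["start"]).map(lambda d: d.days)
    n_negative = int((delta < 0).sum())
    rep = rep[delta >= 0]
    rep["onset_days"] = delta[delta >= 0].astype(int)
    obs = rep[["primaryid", "onset_days"]].reset_index(drop=True)
    if unit == "event":
        ev = dataset.events[dataset.events["PRIMARYID"].isin(obs["primaryid"])]
        obs = ev.merge(obs, left_on="PRIMARYID", right_on="primaryid")
        obs = obs[["primaryid", "PT", "onset_days"]].rename(columns={"PT": "pt"})
    obs["bin"] = obs["onset_days"].map(assign_bin)
    obs.attrs["drop_log"] = {
        "start_dt_invalid_rows": n_start_bad,
        "event_dt_invalid_reports": n_event_bad,
        "event_before_start": n_negative,
    }
    return obs


def summarize_tto(observations: pd.DataFrame | np.ndarray) -> TTOSummary:
    """Median, IQR (linear-interpolation quantiles) and monthly-bin mix."""
    if isinstance(observations, pd.DataFrame):
        days = observations["onset_days"].to_numpy()
        drop_log = observations.attrs.get("drop_log")
    else:
        days = np.asarray(observations)
        drop_log = None
    n = len(days)
    labels = pd.Categorical([assign_bin(int(d)) for d in days],
                            categories=list(BIN_LABELS))
    counts = pd.Series(labels).value_counts().reindex(list(BIN_LABELS),
                                                      fill_value=0)
    if n == 0:
        return TTOSummary(0, float("nan"), float("nan"), float("nan"),
                          counts, counts.astype(float), drop_log)
    q1, med, q3 = np.percentile(days, [25, 50, 75])  # type-7 interpolation
    return TTOSummary(n=n, median_days=float(med), q1=float(q1), q3=float(q3),
                      bin_counts=counts, bin_fractions=counts / n,
                      drop_log=drop_log)
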