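"""Cohort description, pipeline orchestration and the run manifest.

The cohort summary mirrors the descriptive table of a pharmacovigilance
report: counts and percentages by age group, sex, weight group, reporter,
top-5 reporting countries, serious outcomes and top-5 indications.
Denominator conventions:

- demographic and indication percentages use the number of target reports;
- serious-outcome percentages use the number of target reports carrying at
  least one outcome code, and each such report is assigned a single category
  by severity priority DE > LT > HO > DS > other (CA/RI/OT); an outcome row
  with an empty/unrecognized code is "unknown".

All displayed percentages are rounded half away from zero to 2 decimals.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import __version__
from ._util import percentage
from .ingest import CleanDataset, load_clean_bundle, read_soc_map
from .signals import rank_table, signal_table
from .stratified import gender_volcano, subgroup_signals
from .tto import compute_tto, summarize_tto

_OUTCOME_PRIORITY = ("DE", "LT", "HO", "DS")
_OTHER_SERIOUS = ("CA", "RI", "OT")
_OUTCOME_ORDER = ("DE", "LT", "HO", "DS", "other", "unknown")


@dataclass
class RunConfig:
    bundle_dir: str
    out_dir: str
    synonyms: Sequence[str] = ("MEPOLIZUMAB", "NUCALA")
    soc_map_path: str | None = None
    roles: Sequence[str] = ("PS",)
    levels: Sequence[str] = ("PT", "SOC")
    min_cases: int = 3
    rank_min_cases: int = 20
    criteria: str = "all4"            # or "any4"
    stratify_by: Sequence[str] = ("age", "weight", "reporter", "sex")
    volcano_alpha: float = 0.05
    tto_unit: str = "report"
    seed: int = 0

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Parse a plain ``key = value`` config file (lists comma-separated)."""
        kv: dict[str, str] = {}
        for raw in Path(path).read_text().splitlines():
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"config line without '=': {raw!r}")
            k, v = line.split("=", 1)
            kv[k.strip()] = v.strip()
        kwargs: dict = {}
        fields = {f.name: f for f in dataclasses.fields(cls)}
        for k, v in kv.items():
            if k not in fields:
                raise ValueError(f"unknown config key {k!r}")
            typ = fields[k].type
            if k in ("synonyms", "roles", "levels", "stratify_by"):
                kwargs[k] = tuple(s.strip() for s in v.split(",") if s.strip())
            elif typ == "int" or k in ("min_cases", "rank_min_cases", "seed"):
                kwargs[k] = int(v)
            elif k == "volcano_alpha":
                kwargs[k] = float(v)
            else:
                kwargs[k] = v
        return cls(**kwargs)


@dataclass
class CohortSummary:
    total: int
    sections: dict[str, pd.DataFrame] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for section, df in self.sections.items():
            for _, r in df.iterrows():
                rows.append((section, r["category"], r["count"], r["pct"]))
        return pd.DataFrame(rows, columns=["section", "category", "count", "pct"])


def _section(counts: dict[str, int], denominator: int,
             order: Sequence[str] | None = None) -> pd.DataFrame:
    cats = list(order) if order else sorted(counts, key=counts.get, reverse=True)
    rows = [(c, counts.get(c, 0),
             percentage(counts.get(c, 0), denominator) if denominator else float("nan"))
            for c in cats]
    return pd.DataFrame(rows, columns=["category", "count", "pct"])


def serious_outcome_category(codes: Sequence[str]) -> str:
    """Single severity category for a report's outcome-code set."""
    up = {c.strip().upper() for c in codes}
    for c in _OUTCOME_PRIORITY:
        if c in up:
            return c
    if up & set(_OTHER_SERIOUS):
        return "other"
    return "unknown"


def describe_cohort(dataset: CleanDataset) -> CohortSummary:
    """Descriptive summary of the target-drug cohort."""
    rep = dataset.target_reports
    total = len(rep)
    summary = CohortSummary(total=total)
    if total == 0:
        return summary

    summary.sections["age"] = _section(
        rep["age_group"].value_counts().to_dict(), total,
        order=["<18", "18-64", ">64", "unknown"])
    sex_counts = rep["sex"].map({"F": "female", "M": "male"}).fillna("unknown")
    summary.sections["sex"] = _section(
        sex_counts.value_counts().to_dict(), total,
        order=["female", "male", "unknown"])
    summary.sections["weight"] = _section(
        rep["weight_group"].value_counts().to_dict(), total,
        order=["<80", "80-100", ">100", "unknown"])
    summary.sections["reporter"] = _section(
        rep["reporter"].value_counts().to_dict(), total,
        order=["health professional", "consumer", "unknown"])
    country = rep["country"].replace("", "unknown").value_counts()
    summary.sections["country_top5"] = _section(
        country.head(5).to_dict(), total, order=list(country.head(5).index))

    outc = dataset.outcomes[dataset.outcomes["PRIMARYID"].isin(rep["primaryid"])]
    per_report = outc.groupby("PRIMARYID")["OUTC_COD"].apply(list)
    cat = per_report.map(serious_outcome_category)
    n_serious = len(cat)
    summary.sections["serious_outcomes"] = _section(
        cat.value_counts().to_dict(), n_serious, order=list(_OUTCOME_ORDER))
    summary.sections["serious_outcomes"].attrs["denominator"] = n_serious

    ind = dataset.indications[
        dataset.indications["PRIMARYID"].isin(rep["primaryid"])]
    ind = ind.drop_duplicates(["PRIMARYID", "INDI_PT"])
    ind_counts = ind["INDI_PT"].value_counts()
    summary.sections["indications_top5"] = _section(
        ind_counts.head(5).to_dict(), total, order=list(ind_counts.head(5).index))
    return summary


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run ingest -> clean -> signals -> TTO -> stratified, write artifacts.

    Outputs are CSV tables plus a JSON manifest (config echo, input digests,
    per-stage row counts, package version).  Identical config and inputs give
    identical outputs.  Returns the manifest.
    """
    bundle = Path(config.bundle_dir)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    soc_map = None
    if "SOC" in [lv.upper() for lv in config.levels]:
        path = config.soc_map_path or str(bundle / "pt_soc_map.txt")
        if not Path(path).exists():
            raise FileNotFoundError(
                f"SOC level requested but no PT->SOC map at {path}")
        soc_map = read_soc_map(path)

    dataset = load_clean_bundle(bundle, config.synonyms, config.roles)

    cohort = describe_cohort(dataset)
    cohort.to_frame().to_csv(out / "cohort_summary.csv", index=False)

    stage_counts = dict(dataset.log)
    for level in config.levels:
        lvl = level.upper()
        tbl = signal_table(dataset, level=lvl, soc_map=soc_map,
                           min_cases=config.min_cases)
        ranked = rank_table(tbl, sort_key="a",
                            min_cases=config.rank_min_cases if lvl == "PT" else 0)
        tbl.to_csv(out / f"signals_{lvl.lower()}_full.csv")
        ranked.to_csv(out / f"signals_{lvl.lower()}_ranked.csv")
        key = "combined_signal" if config.criteria == "all4" else "any_signal"
        stage_counts[f"signals_{lvl.lower()}"] = int(tbl[key].sum()) if len(tbl) else 0

    obs = compute_tto(dataset, unit=config.tto_unit)
    tto_sum = summarize_tto(obs)
    obs.to_csv(out / "tto_observations.csv", index=False)
    pd.DataFrame({
        "bin": tto_sum.bin_counts.index,
        "count": tto_sum.bin_counts.values,
        "fraction": tto_sum.bin_fractions.values,
    }).to_csv(out / "tto_bins.csv", index=False)
    stage_counts["tto_observations"] = tto_sum.n
    stage_counts["tto_drops"] = tto_sum.drop_log

    for fieldname in config.stratify_by:
        tables = subgroup_signals(dataset, fieldname,
                                  min_cases=config.min_cases)
        for stratum, df in tables.items():
            safe = stratum.replace("<", "lt").replace(">", "gt").replace(" ", "_")
            df.to_csv(out / f"subgroup_{fieldname}_{safe}.csv")

    volcano = gender_volcano(dataset, min_cases=config.min_cases,
                             significance=config.volcano_alpha)
    volcano.to_csv(out / "gender_volcano.csv", index=False)
    stage_counts["volcano_rows"] = len(volcano)

    manifest = {
        "version": __version__,
        "config": dataclasses.asdict(config),
        "input_digests": {p.name: _sha256(p)
                          for p in sorted(bundle.glob("*.txt"))},
        "stage_counts": stage_counts,
        "tto_summary": {
            "n": tto_sum.n, "median_days": tto_sum.median_days,
            "q1": tto_sum.q1, "q3": tto_sum.q3,
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  sort_keys=True) + "\n")
    return manifest
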