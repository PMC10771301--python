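"""Synthetic FAERS-dialect bundle generator with known ground truth.

Spontaneous-report databases cannot be redistributed, so every downstream
stage of the pipeline is exercised against bundles generated here: quarterly
dollar-delimited DEMO/DRUG/REAC/THER/INDI/OUTC tables in the FAERS ASCII
dialect, with

- a heavy-tailed (Zipf-like) background distribution of preferred terms,
- one target drug holding a configurable share of primary-suspect reports,
- planted drug-event reporting-rate excesses (optionally sex-specific),
- duplicate case versions differing in FDA_DT / PRIMARYID,
- partial and missing dates, and demographic fields with the extreme
  missingness typical of consumer-reported data,

and a :class:`GroundTruth` record of everything the generator knows, so that
deduplication, signal detection, time-to-onset and gender contrasts can all
be verified against planted truth.

Event sampling is per-report Bernoulli inclusion: report ``i`` includes
preferred term ``k`` with probability ``q * p_k * m_ik`` where ``p_k`` is the
background probability, ``q`` scales the expected number of terms per report,
and ``m_ik`` is the planted multiplier (relative rate, times the female
multiplier when applicable) for target-drug reports and 1 otherwise.  Null
terms therefore have exactly equal inclusion rates under target and
comparator drugs, so the no-signal null is exactly true for them.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

DELIM = "$"

TABLE_COLUMNS = {
    "DEMO": [
        "PRIMARYID", "CASEID", "FDA_DT", "EVENT_DT", "AGE", "AGE_COD",
        "SEX", "WT", "WT_COD", "OCCP_COD", "OCCR_COUNTRY",
    ],
    "DRUG": ["PRIMARYID", "DRUG_SEQ", "ROLE_COD", "DRUGNAME", "PROD_AI"],
    "REAC": ["PRIMARYID", "PT"],
    "THER": ["PRIMARYID", "DSG_DRUG_SEQ", "START_DT"],
    "INDI": ["PRIMARYID", "INDI_DRUG_SEQ", "INDI_PT"],
    "OUTC": ["PRIMARYID", "OUTC_COD"],
}

COMPARATOR_POOL = [f"COMPARATOR_{i:02d}" for i in range(1, 11)]

SOC_POOL = [
    "Respiratory, thoracic and mediastinal disorders",
    "General disorders and administration site conditions",
    "Infections and infestations",
    "Injury, poisoning and procedural complications",
    "Nervous system disorders",
    "Gastrointestinal disorders",
    "Skin and subcutaneous tissue disorders",
    "Musculoskeletal and connective tissue disorders",
    "Psychiatric disorders",
    "Investigations",
]

# Cohort-level default mixes; chosen once to mimic the demographic regime of
# consumer-heavy biologic reporting (see docs/methods.md).
_AGE_CATEGORY_P = (6 / 466, 187 / 466, 273 / 466)  # <18, 18-64, >64 given known
_SEX_F_GIVEN_KNOWN = 0.68
_COUNTRIES = ["US", "CA", "JP", "GB", "AU", "FR", "DE"]
_COUNTRY_P = [0.5392, 0.2731, 0.0287, 0.0268, 0.0254, 0.05, 0.0568]
_OCCP = ["CN", "MD", "PH", "OT", ""]
_OCCP_P = [0.7369, 0.13, 0.06, 0.06, 0.0131]
_SERIOUS_RATE = 0.7822
_OUTC_CODES = ["DE", "LT", "HO", "DS", "OT", "CA", "RI", ""]
_OUTC_P = [0.0755, 0.0108, 0.3418, 0.0075, 0.48, 0.04, 0.0344, 0.01]
_TARGET_INDI = [
    "Asthma",
    "Product used for unknown indication",
    "Eosinophilic granulomatosis with polyangiitis",
    "Hypereosinophilic syndrome",
    "Nasal polyps",
    "Chronic rhinosinusitis",
]
_TARGET_INDI_P = [0.6472, 0.2586, 0.03, 0.0067, 0.0049, 0.0526]

# Rank (0-based) at which planted terms are spliced into the background list:
# deep enough in the tail that their base rate is small, frequent enough that
# moderate bundles give double-digit case counts.
_PLANT_RANK = 19
# Background rank whose name collides with the dominant indication, to
# exercise indication-term removal downstream.
_INDICATION_RANK = 4


@dataclass(frozen=True)
class PlantedSignal:
    """A drug-event excess to plant for the target drug.

    ``relative_rate`` multiplies the per-report inclusion probability of the
    term for target-drug reports (>= 1).  ``female_rate_multiplier``
    additionally multiplies it for female target-drug reports (> 0; values
    below 1 make the term male-enriched).
    """

    pt: str
    relative_rate: float
    female_rate_multiplier: float | None = None


@dataclass(frozen=True)
class GeneratorConfig:
    n_reports: int = 20_000
    n_background_pts: int = 200
    pt_freq_exponent: float = 1.2
    target_drug_share: float = 0.1
    planted_signals: Sequence[PlantedSignal] = ()
    duplicate_rate: float = 0.05
    date_window: tuple[str, str] = ("20151001", "20230331")
    missing_date_rate: float = 0.35
    missing_age_rate: float = 0.9742
    missing_sex_rate: float = 0.1803
    missing_weight_rate: float = 0.9283
    events_per_report: float = 3.5
    onset_mean_days: float = 120.0
    target_drug: str = "MEPOLIZUMAB"
    seed: int = 0

    def validate(self) -> None:
        if self.n_reports < 0:
            raise ValueError("n_reports must be non-negative")
        if self.n_background_pts <= 0:
            raise ValueError("n_background_pts must be positive")
        if self.pt_freq_exponent <= 0:
            raise ValueError("pt_freq_exponent must be positive")
        if not 0 < self.target_drug_share < 1:
            raise ValueError("target_drug_share must be in (0, 1)")
        if not 0 <= self.duplicate_rate < 1:
            raise ValueError("duplicate_rate must be in [0, 1)")
        for name in ("missing_date_rate", "missing_age_rate",
                     "missing_sex_rate", "missing_weight_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        names = [p.pt for p in self.planted_signals]
        if len(set(names)) != len(names):
            raise ValueError("planted pt names must be distinct")
        if len(names) > self.n_background_pts:
            raise ValueError("more planted pts than background pts")
        for p in self.planted_signals:
            if p.relative_rate < 1:
                raise ValueError(f"relative_rate for {p.pt} must be >= 1")
            if p.female_rate_multiplier is not None and p.female_rate_multiplier <= 0:
                raise ValueError(f"female_rate_multiplier for {p.pt} must be > 0")


@dataclass
class GroundTruth:
    """What the generator knows about a bundle."""

    planted: pd.DataFrame      # pt, relative_rate, female_rate_multiplier
    duplicates: pd.DataFrame   # caseid, survivor_primaryid, n_versions
    onsets: pd.DataFrame       # primaryid, onset_days, dates_complete
    background: pd.DataFrame   # pt, prob (background event distribution)
    target_primaryids: pd.Index = field(default_factory=lambda: pd.Index([], dtype=str))


def background_distribution(config: GeneratorConfig) -> pd.DataFrame:
    """Zipf-like background PT distribution with planted names spliced in.

    Rank ``k`` (1-based) has probability proportional to ``k**-s``.  Planted
    term names replace the names of consecutive mid-tail ranks so planted
    terms always have a well-defined background probability.
    """
    k = config.n_background_pts
    ranks = np.arange(1, k + 1, dtype=float)
    w = ranks ** (-config.pt_freq_exponent)
    probs = w / w.sum()
    names = [f"PT_{i:04d}" for i in range(1, k + 1)]
    if k > _INDICATION_RANK:
        names[_INDICATION_RANK] = "Asthma"
    start = min(_PLANT_RANK, k - len(config.planted_signals))
    for i, p in enumerate(config.planted_signals):
        names[start + i] = p.pt
    return pd.DataFrame({"pt": names, "prob": probs})


def _sample_events(rng: np.random.Generator, config: GeneratorConfig,
                   bg: pd.DataFrame, is_target: np.ndarray,
                   sex: np.ndarray) -> list[np.ndarray]:
    """Per-report lists of included PT indices (Bernoulli inclusion)."""
    n = len(is_target)
    probs = bg["prob"].to_numpy()
    base = np.minimum(config.events_per_report * probs, 0.97)
    mult_t = np.ones_like(base)
    mult_tf = np.ones_like(base)
    name_to_idx = {name: i for i, name in enumerate(bg["pt"])}
    for p in config.planted_signals:
        j = name_to_idx[p.pt]
        mult_t[j] = p.relative_rate
        fm = p.female_rate_multiplier if p.female_rate_multiplier is not None else 1.0
        mult_tf[j] = p.relative_rate * fm
    p_comp = base
    p_target = np.minimum(base * mult_t, 0.995)
    p_target_f = np.minimum(base * mult_tf, 0.995)

    out: list[np.ndarray] = []
    chunk = 20_000
    for lo in range(0, n, chunk):
        hi = min(lo + chunk, n)
        m = hi - lo
        pmat = np.tile(p_comp, (m, 1))
        tgt = is_target[lo:hi]
        f = tgt & (sex[lo:hi] == "F")
        t_only = tgt & ~f
        pmat[t_only] = p_target
        pmat[f] = p_target_f
        incl = rng.random((m, len(probs))) < pmat
        # every report carries at least one reaction term
        empty = ~incl.any(axis=1)
        if empty.any():
            fill = rng.choice(len(probs), size=int(empty.sum()), p=probs)
            incl[np.flatnonzero(empty), fill] = True
        for row in incl:
            out.append(np.flatnonzero(row))
    return out


def _format_dates(rng: np.random.Generator, dates: np.ndarray,
                  missing_rate: float) -> np.ndarray:
    """Render dates as YYYYMMDD, degrading a fraction to partial or blank.

    Half of the degraded fraction is blanked, a quarter truncated to YYYYMM,
    a quarter to YYYY — exercising every partial-date branch downstream.
    """
    full = np.array([d.strftime("%Y%m%d") if d is not None else "" for d in dates],
                    dtype=object)
    if missing_rate <= 0:
        return full
    r = rng.random(len(full))
    out = full.copy()
    out[r < missing_rate * 0.5] = ""
    mask6 = (r >= missing_rate * 0.5) & (r < missing_rate * 0.75)
    out[mask6] = [s[:6] for s in full[mask6]]
    mask4 = (r >= missing_rate * 0.75) & (r < missing_rate)
    out[mask4] = [s[:4] for s in full[mask4]]
    return out


def inject_duplicates(demo: pd.DataFrame, duplicate_rate: float,
                      seed: int | np.random.Generator) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Emit extra case versions for a random fraction of cases.

    Selected cases gain 1-2 extra DEMO rows sharing CASEID, with distinct,
    strictly larger PRIMARYID and non-decreasing FDA_DT (a fraction of the
    increments is zero so the equal-date, higher-PRIMARYID tiebreak is also
    exercised).  Returns the augmented DEMO table and the truth table of
    intended deduplication survivors: per duplicated case, the version with
    the maximal (FDA_DT, PRIMARYID).
    """
    if not 0 <= duplicate_rate < 1:
        raise ValueError("duplicate_rate must be in [0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    truth_cols = ["caseid", "survivor_primaryid", "n_versions"]
    if duplicate_rate == 0 or demo.empty:
        return demo.copy(), pd.DataFrame(columns=truth_cols)
    pick = rng.random(len(demo)) < duplicate_rate
    extra_frames = []
    truth_rows = []
    for idx in np.flatnonzero(pick):
        row = demo.iloc[idx]
        n_extra = int(rng.integers(1, 3))
        fda = int(row["FDA_DT"])
        last_pid = row["PRIMARYID"]
        for v in range(n_extra):
            # ~30% zero increments: same FDA_DT, tiebreak on PRIMARYID
            inc = int(rng.integers(0, 30))
            if rng.random() < 0.3:
                inc = 0
            fda = _shift_yyyymmdd(fda, inc)
            new = row.copy()
            new["PRIMARYID"] = str(int(row["CASEID"]) * 10 + 2 + v)
            new["FDA_DT"] = str(fda)
            last_pid = new["PRIMARYID"]
            extra_frames.append(new)
        truth_rows.append((row["CASEID"], last_pid, 1 + n_extra))
    if not extra_frames:
        return demo.copy(), pd.DataFrame(columns=truth_cols)
    aug = pd.concat([demo, pd.DataFrame(extra_frames)], ignore_index=True)
    truth = pd.DataFrame(truth_rows, columns=truth_cols)
    return aug, truth


def _shift_yyyymmdd(yyyymmdd: int, days: int) -> int:
    s = str(yyyymmdd)
    d = _dt.date(int(s[:4]), int(s[4:6]), int(s[6:8])) + _dt.timedelta(days=days)
    return int(d.strftime("%Y%m%d"))


def generate_bundle(config: GeneratorConfig, out_dir: str | Path) -> GroundTruth:
    """Generate one quarterly-style bundle and write it to ``out_dir``.

    Writes the six dollar-delimited tables, a two-column ``pt_soc_map.txt``
    standing in for a MedDRA PT-to-SOC map, and a ``TRUTH.txt`` long-format
    dump of the ground truth.  Identical (config, seed) gives byte-identical
    files.
    """
    config.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    n = config.n_reports
    bg = background_distribution(config)

    if n == 0:
        tables = {t: pd.DataFrame(columns=cols) for t, cols in TABLE_COLUMNS.items()}
        truth = GroundTruth(
            planted=pd.DataFrame(columns=["pt", "relative_rate", "female_rate_multiplier"]),
            duplicates=pd.DataFrame(columns=["caseid", "survivor_primaryid", "n_versions"]),
            onsets=pd.DataFrame(columns=["primaryid", "onset_days", "dates_complete"]),
            background=bg,
        )
        _write_bundle(tables, bg, truth, out_dir)
        return truth

    caseid = (10_000_000 + np.arange(1, n + 1)).astype(str)
    primaryid = np.array([str(int(c) * 10 + 1) for c in caseid])
    is_target = rng.random(n) < config.target_drug_share

    # --- demographics -----------------------------------------------------
    sex = np.where(rng.random(n) < config.missing_sex_rate, "UNK",
                   np.where(rng.random(n) < _SEX_F_GIVEN_KNOWN, "F", "M"))
    age_known = rng.random(n) >= config.missing_age_rate
    age_cat = rng.choice(3, size=n, p=_AGE_CATEGORY_P)
    age_years = np.select(
        [age_cat == 0, age_cat == 1, age_cat == 2],
        [rng.integers(1, 18, n), rng.integers(18, 65, n), rng.integers(65, 91, n)],
    ).astype(float)
    age_unit = rng.choice(["YR", "MON", "DEC"], size=n, p=[0.85, 0.10, 0.05])
    age_val = np.where(age_unit == "YR", age_years,
                       np.where(age_unit == "MON", age_years * 12, age_years / 10.0))
    age_str = np.where(age_known, np.char.mod("%g", age_val), "")
    age_cod = np.where(age_known, age_unit, "")

    wt_known = rng.random(n) >= config.missing_weight_rate
    wt_kg = np.clip(rng.normal(78, 18, n), 35, 160)
    wt_lbs = rng.random(n) < 0.2
    wt_val = np.where(wt_lbs, wt_kg / 0.453592, wt_kg)
    wt_str = np.where(wt_known, np.char.mod("%.1f", wt_val), "")
    wt_cod = np.where(wt_known, np.where(wt_lbs, "LBS", "KG"), "")

    country = rng.choice(_COUNTRIES, size=n, p=_COUNTRY_P)
    occp = rng.choice(_OCCP, size=n, p=_OCCP_P)

    # --- dates -------------------------------------------------------------
    w0 = _dt.datetime.strptime(config.date_window[0], "%Y%m%d").date()
    w1 = _dt.datetime.strptime(config.date_window[1], "%Y%m%d").date()
    span = (w1 - w0).days
    start_offsets = rng.integers(0, span + 1, n)
    onset_days = np.floor(rng.exponential(config.onset_mean_days, n)).astype(int)
    start_dates = np.array([w0 + _dt.timedelta(days=int(o)) for o in start_offsets])
    event_dates = np.array([s + _dt.timedelta(days=int(d))
                            for s, d in zip(start_dates, onset_days)])
    fda_lag = rng.integers(0, 91, n)
    fda_dates = np.array([e + _dt.timedelta(days=int(l))
                          for e, l in zip(event_dates, fda_lag)])
    fda_str = np.array([d.strftime("%Y%m%d") for d in fda_dates])
    event_str = _format_dates(rng, event_dates, config.missing_date_rate)
    start_str = _format_dates(rng, start_dates, config.missing_date_rate)
    dates_complete = (np.char.str_len(event_str.astype(str)) == 8) & \
                     (np.char.str_len(start_str.astype(str)) == 8)

    demo = pd.DataFrame({
        "PRIMARYID": primaryid, "CASEID": caseid, "FDA_DT": fda_str,
        "EVENT_DT": event_str.astype(str), "AGE": age_str, "AGE_COD": age_cod,
        "SEX": sex, "WT": wt_str, "WT_COD": wt_cod, "OCCP_COD": occp,
        "OCCR_COUNTRY": country,
    })

    # --- drugs / therapy / indications / outcomes --------------------------
    suspect = np.where(is_target, config.target_drug,
                       rng.choice(COMPARATOR_POOL, size=n))
    drug_rows = [pd.DataFrame({
        "PRIMARYID": primaryid, "DRUG_SEQ": "1", "ROLE_COD": "PS",
        "DRUGNAME": suspect, "PROD_AI": suspect,
    })]
    conco = rng.random(n) < 0.3
    if conco.any():
        drug_rows.append(pd.DataFrame({
            "PRIMARYID": primaryid[conco], "DRUG_SEQ": "2", "ROLE_COD": "C",
            "DRUGNAME": rng.choice(COMPARATOR_POOL, size=int(conco.sum())),
            "PROD_AI": "",
        }))
    # target drug as a concomitant on comparator reports: must NOT be selected
    conc_target = (~is_target) & (rng.random(n) < 0.05)
    if conc_target.any():
        drug_rows.append(pd.DataFrame({
            "PRIMARYID": primaryid[conc_target], "DRUG_SEQ": "3", "ROLE_COD": "C",
            "DRUGNAME": config.target_drug, "PROD_AI": config.target_drug,
        }))
    drug = pd.concat(drug_rows, ignore_index=True)

    ther = pd.DataFrame({
        "PRIMARYID": primaryid, "DSG_DRUG_SEQ": "1", "START_DT": start_str.astype(str),
    })

    indi_pt = np.where(
        is_target,
        rng.choice(_TARGET_INDI, size=n, p=_TARGET_INDI_P),
        "Product used for unknown indication",
    )
    indi = pd.DataFrame({
        "PRIMARYID": primaryid, "INDI_DRUG_SEQ": "1", "INDI_PT": indi_pt,
    })

    serious = rng.random(n) < _SERIOUS_RATE
    outc_code = rng.choice(_OUTC_CODES, size=n, p=_OUTC_P)
    outc = pd.DataFrame({
        "PRIMARYID": primaryid[serious], "OUTC_COD": outc_code[serious],
    })

    # --- reactions ----------------------------------------------------------
    event_idx = _sample_events(rng, config, bg, is_target, sex)
    pts = bg["pt"].to_numpy()
    reac = pd.DataFrame({
        "PRIMARYID": np.repeat(primaryid, [len(e) for e in event_idx]),
        "PT": pts[np.concatenate(event_idx)] if n else np.array([], dtype=object),
    })

    # --- duplicates ---------------------------------------------------------
    demo_aug, dup_truth = inject_duplicates(demo, config.duplicate_rate, rng)
    new_versions = demo_aug.iloc[len(demo):]
    if len(new_versions):
        orig_pid = {c: p for c, p in zip(caseid, primaryid)}
        child_copies = {}
        for tname, tdf in (("DRUG", drug), ("REAC", reac), ("THER", ther),
                           ("INDI", indi), ("OUTC", outc)):
            by_pid = tdf.groupby("PRIMARYID").indices
            copies = []
            for _, row in new_versions.iterrows():
                src = orig_pid[row["CASEID"]]
                block = tdf.iloc[by_pid.get(src, [])].copy()
                block["PRIMARYID"] = row["PRIMARYID"]
                copies.append(block)
            child_copies[tname] = pd.concat([tdf] + copies, ignore_index=True)
        drug, reac, ther, indi, outc = (child_copies[t] for t in
                                        ("DRUG", "REAC", "THER", "INDI", "OUTC"))

    tables = {"DEMO": demo_aug, "DRUG": drug, "REAC": reac,
              "THER": ther, "INDI": indi, "OUTC": outc}

    planted = pd.DataFrame(
        [(p.pt, p.relative_rate,
          p.female_rate_multiplier if p.female_rate_multiplier is not None else 1.0)
         for p in config.planted_signals],
        columns=["pt", "relative_rate", "female_rate_multiplier"],
    )
    onsets = pd.DataFrame({
        "primaryid": primaryid,
        "onset_days": onset_days,
        "dates_complete": dates_complete,
    })
    truth = GroundTruth(planted=planted, duplicates=dup_truth, onsets=onsets,
                        background=bg,
                        target_primaryids=pd.Index(primaryid[is_target]))
    _write_bundle(tables, bg, truth, out_dir)
    return truth


def soc_map_frame(bg: pd.DataFrame) -> pd.DataFrame:
    """Deterministic flat PT->SOC assignment over the background terms."""
    socs = [SOC_POOL[i % len(SOC_POOL)] for i in range(len(bg))]
    df = pd.DataFrame({"pt": bg["pt"], "soc": socs})
    df.loc[df["pt"] == "Asthma", "soc"] = SOC_POOL[0]
    return df


def _write_bundle(tables: dict[str, pd.DataFrame], bg: pd.DataFrame,
                  truth: GroundTruth, out_dir: Path) -> None:
    for name, df in tables.items():
        df.to_csv(out_dir / f"{name}.txt", sep=DELIM, index=False,
                  lineterminator="\n")
    soc_map_frame(bg).to_csv(out_dir / "pt_soc_map.txt", sep=DELIM, index=False,
                             lineterminator="\n")
    rows = []
    for _, r in truth.planted.iterrows():
        rows.append(("planted", r["pt"], repr(float(r["relative_rate"])),
                     repr(float(r["female_rate_multiplier"]))))
    for _, r in truth.duplicates.iterrows():
        rows.append(("duplicate", str(r["caseid"]),
                     str(r["survivor_primaryid"]), str(int(r["n_versions"]))))
    for _, r in truth.onsets.iterrows():
        rows.append(("onset", str(r["primaryid"]), str(int(r["onset_days"])),
                     str(int(r["dates_complete"]))))
    pd.DataFrame(rows, columns=["section", "key", "value1", "value2"]).to_csv(
        out_dir / "TRUTH.txt", sep=DELIM, index=False, lineterminator="\n")


def load_truth(out_dir: str | Path) -> GroundTruth:
    """Re-read a TRUTH.txt written by :func:`generate_bundle`."""
    df = pd.read_csv(Path(out_dir) / "TRUTH.txt", sep=DELIM, dtype=str,
                     keep_default_na=False)
    planted = df[df["section"] == "planted"].rename(
        columns={"key": "pt", "value1": "relative_rate", "value2": "female_rate_multiplier"}
    )[["pt", "relative_rate", "female_rate_multiplier"]].reset_index(drop=True)
    planted["relative_rate"] = planted["relative_rate"].astype(float)
    planted["female_rate_multiplier"] = planted["female_rate_multiplier"].astype(float)
    dup = df[df["section"] == "duplicate"].rename(
        columns={"key": "caseid", "value1": "survivor_primaryid", "value2": "n_versions"}
    )[["caseid", "survivor_primaryid", "n_versions"]].reset_index(drop=True)
    onsets = df[df["section"] == "onset"].rename(
        columns={"key": "primaryid", "value1": "onset_days", "value2": "dates_complete"}
    )[["primaryid", "onset_days", "dates_complete"]].reset_index(drop=True)
    onsets["onset_days"] = onsets["onset_days"].astype(int)
    onsets["dates_complete"] = onsets["dates_complete"].astype(int).astype(bool)
    return GroundTruth(planted=planted, duplicates=dup, onsets=onsets,
                       background=pd.DataFrame(columns=["pt", "prob"]))


def expected_ebgm(config: GeneratorConfig, pt: str) -> float:
    """Analytic expectation of the downstream EBGM for a planted term.

    Direct consequence of the Bernoulli sampling scheme.  With target share
    ``s`` and per-report inclusion rates ``q_t(k)`` (target, sex-averaged
    over the planted female multiplier) and ``q_c(k)`` (comparator), the
    expected relative reporting ratio of term ``k`` in (report, term)-pair
    counting is

        EBGM_k = [q_t(k)/Q_t] / [(s*q_t(k) + (1-s)*q_c(k)) /
                                 (s*Q_t + (1-s)*Q_c)]

    where ``Q_t``/``Q_c`` are the summed inclusion rates (expected pairs per
    report).  The downstream indication filter removes the dominant
    indication term from target reports before counting, so that term is
    excluded from ``q_t``/``Q_t``.  Used as the independent oracle for
    planted-signal magnitude tests; ignores the at-least-one-event fill
    (sub-percent effect at default sizes).
    """
    bg = background_distribution(config)
    name_to_idx = {name: i for i, name in enumerate(bg["pt"])}
    probs = bg["prob"].to_numpy()
    # sex-averaged multiplier per planted term
    p_f = (1 - config.missing_sex_rate) * _SEX_F_GIVEN_KNOWN
    mult = np.ones(len(probs))
    for p in config.planted_signals:
        fm = p.female_rate_multiplier if p.female_rate_multiplier is not None else 1.0
        avg = p.relative_rate * (p_f * fm + (1 - p_f))
        mult[name_to_idx[p.pt]] = avg
    q_c = np.minimum(config.events_per_report * probs, 0.97)
    q_t = np.minimum(q_c * mult, 0.995)
    # indication-term removal applies to target reports only
    if "Asthma" in name_to_idx:
        q_t = q_t.copy()
        q_t[name_to_idx["Asthma"]] = 0.0
    s = config.target_drug_share
    k = name_to_idx[pt]
    target_rate = q_t[k] / q_t.sum()
    overall_rate = (s * q_t[k] + (1 - s) * q_c[k]) / (s * q_t.sum() + (1 - s) * q_c.sum())
    return target_rate / overall_rate
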