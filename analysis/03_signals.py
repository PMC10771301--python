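#!/usr/bin/env python
"""Disproportionality screen at PT and SOC level.

Computes ROR, PRR/chi2, IC(IC025) and EBGM(EBGM05) for every event with at
least 3 target cases, applies the four signal criteria, and writes the full
and ranked (>= 20 cases, sorted by case count) tables to results/.  The
planted excesses should surface at the top with all four flags set; null
background terms should not fire.
"""

from pathlib import Path

from faers_signals.ingest import load_clean_bundle, read_soc_map
from faers_signals.signals import rank_table, signal_table

ROOT = Path(__file__).resolve().parents[1]
BUNDLE = ROOT / "scratch" / "bundle"
RESULTS = ROOT / "results"
SYNONYMS = ("MEPOLIZUMAB", "NUCALA")

if __name__ == "__main__":
    ds = load_clean_bundle(BUNDLE, SYNONYMS)
    soc_map = read_soc_map(BUNDLE / "pt_soc_map.txt")
    RESULTS.mkdir(exist_ok=True)

    pt = signal_table(ds, "PT", min_cases=3)
    ranked = rank_table(pt, sort_key="a", min_cases=20)
    pt.to_csv(RESULTS / "signals_pt_full.csv")
    ranked.to_csv(RESULTS / "signals_pt_ranked.csv")
    print(f"PT level: {len(pt)} events with >=3 cases; "
          f"{int(pt['combined_signal'].sum())} fire all four criteria, "
          f"{int(pt['any_signal'].sum())} fire at least one")
    cols = ["a", "ror_ci", "prr_disp", "chi2_disp", "ic_ic025",
            "ebgm_ebgm05", "combined_signal"]
    print(ranked[cols].head(10).to_string())

    soc = signal_table(ds, "SOC", soc_map=soc_map, min_cases=3)
    soc.to_csv(RESULTS / "signals_soc_full.csv")
    print(f"\nSOC level: {len(soc)} organ classes; "
          f"{int(soc['any_signal'].sum())} meet at least one criterion")
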