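#!/usr/bin/env python
"""Subgroup signal tables and the gender-difference volcano.

Reruns the disproportionality screen within each age/weight/reporter/sex
stratum, then computes the within-drug female-vs-male odds ratio per PT with
Fisher exact p-values and BH-FDR adjustment.  The planted female-biased
excess should be the dominant female-enriched point of the volcano.
"""

from pathlib import Path

from faers_signals.ingest import load_clean_bundle
from faers_signals.stratified import gender_volcano, subgroup_signals

ROOT = Path(__file__).resolve().parents[1]
BUNDLE = ROOT / "scratch" / "bundle"
RESULTS = ROOT / "results"
SYNONYMS = ("MEPOLIZUMAB", "NUCALA")

if __name__ == "__main__":
    ds = load_clean_bundle(BUNDLE, SYNONYMS)
    RESULTS.mkdir(exist_ok=True)

    for fieldname in ("age", "sex"):
        tables = subgroup_signals(ds, fieldname, min_cases=3)
        for stratum, df in tables.items():
            safe = stratum.replace("<", "lt").replace(">", "gt")
            df.to_csv(RESULTS / f"subgroup_{fieldname}_{safe}.csv")
            n_sig = int(df["combined_signal"].sum()) if len(df) else 0
            print(f"[{fieldname}={stratum}] {len(df)} events, "
                  f"{n_sig} all-four signals")

    volcano = gender_volcano(ds, min_cases=3, significance=0.05)
    volcano.to_csv(RESULTS / "gender_volcano.csv", index=False)
    hits = volcano[volcano["direction"] != "null"]
    print(f"\nvolcano: {len(volcano)} PTs tested, "
          f"{len(hits)} significant at adjusted p < 0.05")
    if len(hits):
        print(hits[["pt", "n_f", "n_m", "log2_or", "p_adj",
                    "direction"]].to_string(index=False))
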