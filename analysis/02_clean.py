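#!/usr/bin/env python
"""Clean the bundle and describe the target-drug cohort.

Reads scratch/bundle/, applies FDA-rule deduplication, primary-suspect
selection and indication-term removal, then writes the cleaning funnel and
the descriptive cohort table (counts and percentages by age, sex, weight,
reporter, country, serious outcome and indication) to results/.
"""

import json
from pathlib import Path

from faers_signals.ingest import load_clean_bundle
from faers_signals.report import describe_cohort

ROOT = Path(__file__).resolve().parents[1]
BUNDLE = ROOT / "scratch" / "bundle"
RESULTS = ROOT / "results"
SYNONYMS = ("MEPOLIZUMAB", "NUCALA")

if __name__ == "__main__":
    ds = load_clean_bundle(BUNDLE, SYNONYMS)
    RESULTS.mkdir(exist_ok=True)
    (RESULTS / "cleaning_log.json").write_text(
        json.dumps(ds.log, indent=2, default=str) + "\n")
    summary = describe_cohort(ds)
    summary.to_frame().to_csv(RESULTS / "cohort_summary.csv", index=False)
    print(f"reports after dedup:   {ds.log['reports_after_dedup']}"
          f"  (raw DEMO rows: {ds.log['demo_rows_raw']})")
    print(f"target-drug reports:   {ds.log['target_reports']}")
    print(f"indication PTs removed from target events: "
          f"{ds.log['indication_event_rows_removed']}")
    sex = summary.sections["sex"]
    for _, r in sex.iterrows():
        print(f"  {r['category']:>8}: {r['count']:5d}  ({r['pct']:.2f}%)")
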