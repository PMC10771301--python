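#!/usr/bin/env python
"""Generate the study bundle: a synthetic FAERS-dialect quarter.

20,000 reports, 10% with the target drug as primary suspect, three planted
drug-event excesses (relative rates 10, 5 and 3, the last female-biased
4-fold), 5% duplicated cases, and the demographic/date missingness of
consumer-heavy biologic reporting.  The bundle and its ground truth go to
scratch/bundle/ (regenerated on demand; not a tracked artifact).
"""

from pathlib import Path

from faers_signals.synthetic import GeneratorConfig, PlantedSignal, generate_bundle

ROOT = Path(__file__).resolve().parents[1]
BUNDLE = ROOT / "scratch" / "bundle"

CONFIG = GeneratorConfig(
    n_reports=20_000,
    target_drug_share=0.1,
    planted_signals=(
        PlantedSignal("Asthmatic crisis", 10.0),
        PlantedSignal("Pneumonia", 5.0),
        PlantedSignal("Headache", 3.0, female_rate_multiplier=4.0),
    ),
    duplicate_rate=0.05,
    seed=20_23,
)

if __name__ == "__main__":
    truth = generate_bundle(CONFIG, BUNDLE)
    print(f"bundle written to {BUNDLE}")
    print(f"  reports:            {CONFIG.n_reports}")
    print(f"  duplicated cases:   {len(truth.duplicates)}")
    print(f"  planted signals:    {list(truth.planted['pt'])}")
    print(f"  target reports:     {len(truth.target_primaryids)}")
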