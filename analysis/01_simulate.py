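"""Generate the synthetic mother-machine datasets used by the analysis.

Writes two event tables under results/:

* ``events_baseline.csv`` — 523 growth channels observed for 7 days under
  constant conditions (calibrated heritable generation times, constant
  death hazard 2.239e-3 1/h).
* ``events_drug.csv`` — 500 channels observed for 11 days: 96 h of
  undisturbed growth, then seven days of continuous drug exposure with
  state-dependent delayed killing.
"""

import sys
from pathlib import Path

from mmlineage.io import write_events
from mmlineage.simulate import DrugPhaseConfig, GeneratorConfig, simulate_lineages

RESULTS = Path(__file__).resolve().parents[1] / "results"
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 0


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    baseline = GeneratorConfig(n_channels=523, seed=SEED)
    events = simulate_lineages(baseline)
    write_events(events, RESULTS / "events_baseline.csv")
    n_died = sum(1 for r in events if r.event == "death")
    print(f"baseline: 523 channels over {baseline.window_h:.0f} h, "
          f"{sum(1 for r in events if r.event == 'division')} divisions, "
          f"{n_died} lineage deaths")
    (RESULTS / "config_baseline.yaml").write_text(baseline.to_yaml())

    drug = GeneratorConfig(n_channels=500, window_h=264.0, seed=SEED + 1,
                           drug=DrugPhaseConfig())
    events_d = simulate_lineages(drug)
    write_events(events_d, RESULTS / "events_drug.csv")
    print(f"drug phase: 500 channels, exposure from "
          f"{drug.drug.exposure_start_h:.0f} h, "
          f"{sum(1 for r in events_d if r.event == 'death')} deaths")
    (RESULTS / "config_drug.yaml").write_text(drug.to_yaml())


if __name__ == "__main__":
    main()
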