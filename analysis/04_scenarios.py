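#!/usr/bin/env python
"""Scenario analyses: structural and pricing assumptions.

Runs the named scenarios (psychological-cost exclusion, atrial-fibrillation
complication penalty, alternative published recurrence rates, +/-75%
procedure pricing, age subgroup) plus the horizon sweep, and reports
whether closure stays dominant under each.
"""

import json
from pathlib import Path

from pfo_cea import default_lifetable, default_parameters, scenario, sweep_horizons
from pfo_cea.uncertainty import SCENARIO_NAMES, _compare

OUT = Path(__file__).resolve().parent.parent / "results"


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    p = default_parameters()
    lt = default_lifetable()

    rows = {"base_case": _compare(p, lt).to_dict()}
    print("%-20s %10s %8s %9s  %s" % ("scenario", "dCost", "dQALY", "ICER", "class"))
    base = rows["base_case"]
    print("%-20s %10.0f %8.3f %9s  %s" % ("base_case", base["delta_cost"],
          base["delta_qaly"], base["icer"], base["dominance"]))
    for name in sorted(SCENARIO_NAMES):
        res = scenario(name, p, lt)
        rows[name] = res.to_dict()
        print("%-20s %10.0f %8.3f %9s  %s" % (
            name, res.delta_cost, res.delta_qaly, res.icer, res.dominance.value))

    print("\nhorizon sweep (years -> ICER):")
    for h, res in sweep_horizons(p, lt).items():
        print(f"  {h:4.0f} y: dCost {res.delta_cost:8,.0f}, "
              f"ICER {res.icer:>7,}, {res.dominance.value}")
        rows[f"horizon_{h:.0f}"] = res.to_dict()

    (OUT / "scenarios.json").write_text(json.dumps(rows, indent=2) + "\n")
    print(f"\nwrote {OUT}/scenarios.json")


if __name__ == "__main__":
    main()
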