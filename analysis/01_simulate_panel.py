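"""Simulate the study panel.

Generates a synthetic monthly panel with the study's dimensions — a
210-month axis (195 pre-intervention months, 15 post), bounded 0-100
integer search-intensity indices with trend, 12-month seasonality and a
known regression structure, twelve covariates per country (persistent
macro series; pandemic series that are exactly zero before the breakpoint
month), and known injected step effects in two cells.  Writes the panel as
a long-format CSV plus the injected ground truth.
"""

import argparse
import json
from pathlib import Path

from searchimpact.synthetic import SimulationConfig, simulate_study_panel

COUNTRIES = ["CT1", "CT2", "CT3"]
TERMS = ["anxiety", "boredom", "sleep", "well-being"]
EFFECTS = {("CT1", "anxiety"): 12.0, ("CT2", "well-being"): -8.0}


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=7)
    parser.add_argument("--out", type=Path, default=Path("results"))
    args = parser.parse_args()

    cfg = SimulationConfig(seed=args.seed)  # defaults: 195 + 15 months
    synth = simulate_study_panel(cfg, COUNTRIES, TERMS, effects=EFFECTS)
    args.out.mkdir(parents=True, exist_ok=True)
    synth.panel.to_csv(args.out / "panel.csv")
    truth = {
        f"{c}|{t}": {"effect_size": EFFECTS.get((c, t), 0.0)}
        for c in COUNTRIES
        for t in TERMS
    }
    (args.out / "panel_truth.json").write_text(json.dumps(truth, indent=2))
    n_series = len(synth.panel.response)
    print(
        f"simulated {synth.panel.n_months} months x {n_series} series "
        f"({len(COUNTRIES)} countries x {len(TERMS)} terms); "
        f"intervention month {synth.panel.intervention_month[COUNTRIES[0]].date()}; "
        f"injected step effects: {dict((f'{c}|{t}', v) for (c, t), v in EFFECTS.items())}"
    )
    print(f"wrote {args.out / 'panel.csv'}")


if __name__ == "__main__":
    main()
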