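"""Screen candidate covariates per country.

First step of the two-step procedure: each candidate covariate is modeled
as a response with a covariate-free structural model; covariates whose own
lockdown effect is significant are excluded from the second-step impact
models (they would leak the intervention into the counterfactual).  The
global activity and oil series are kept a priori; the stringency index is
excluded a priori by construction.  Writes one decision row per
(country, covariate).
"""

import argparse
from pathlib import Path

import pandas as pd

from searchimpact.causal import McmcSettings, screen_covariates
from searchimpact.panel import MonthlyPanel
from searchimpact.pipeline import cell_seed


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=7)
    parser.add_argument("--out", type=Path, default=Path("results"))
    parser.add_argument("--iterations", type=int, default=500)
    args = parser.parse_args()

    panel = MonthlyPanel.read_csv(args.out / "panel.csv")
    for c in panel.countries:  # interventions start with the post window
        panel.intervention_month[c] = panel.months[195]

    rows = []
    for country in panel.countries:
        decisions = screen_covariates(
            panel,
            country,
            trend_spec="semilocal_linear",
            mcmc=McmcSettings(args.iterations),
            seed=cell_seed(args.seed, country, "screen"),
        )
        for d in decisions:
            rows.append(
                {
                    "country": country,
                    "covariate": d.covariate,
                    "status": d.status,
                    "relative_effect": d.relative_effect,
                    "tail_area_p": d.tail_area_p,
                    "reason": d.reason,
                }
            )
    frame = pd.DataFrame(rows)
    frame.to_csv(args.out / "screening.csv", index=False)
    kept = frame[frame["status"].str.startswith("kept")]
    print(frame.groupby("status")["covariate"].count().to_string())
    print(
        f"\nadmissible covariates per country: "
        f"{kept.groupby('country')['covariate'].apply(list).to_dict()}"
    )
    print(f"wrote {args.out / 'screening.csv'}")


if __name__ == "__main__":
    main()
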