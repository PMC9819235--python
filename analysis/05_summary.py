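"""Summarize the synthetic study against the transcribed reference tables.

Reads the effect matrices and comparison tables produced by the earlier
steps, recounts significant/negative effects and the share of terms with a
detected effect, and prints them next to the packaged reference counts
(16 unlagged effects of which 4 negative; 9 lagged of which 7 negative;
about 48% of terms with at least one effect).
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from searchimpact.causal import EffectMatrices
from searchimpact.pipeline import reference_effect_summary


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--out", type=Path, default=Path("results"))
    args = parser.parse_args()

    no_lag = pd.read_csv(args.out / "effects_no_lag.csv", index_col=0)
    lagged = pd.read_csv(args.out / "effects_lagged.csv", index_col=0)
    mats = EffectMatrices(no_lag=no_lag, lagged=lagged)
    n_terms = no_lag.shape[1]
    share = 100.0 * len(mats.terms_with_effect) / n_terms

    print("synthetic study:")
    print(f"  unlagged: {mats.counts('no_lag')[0]} significant "
          f"({mats.counts('no_lag')[1]} negative)")
    print(f"  lagged:   {mats.counts('lagged')[0]} significant "
          f"({mats.counts('lagged')[1]} negative)")
    print(f"  term share with >=1 effect: {share:.1f}%")
    print(f"  contradictions: {mats.contradictions() or 'none'}")

    ref = reference_effect_summary()
    print("\ntranscribed reference tables:")
    print(f"  unlagged: {ref['significant_no_lag']} significant "
          f"({ref['negative_no_lag']} negative)")
    print(f"  lagged:   {ref['significant_lagged']} significant "
          f"({ref['negative_lagged']} negative)")
    print(f"  term share with >=1 effect: {ref['term_effect_share_pct']:.1f}%")

    comparison = args.out / "comparison" / "summary.json"
    if comparison.exists():
        summary = json.loads(comparison.read_text())
        print("\nforecast comparison (from step 04):")
        print(f"  best-RMSE shares: {summary.get('best_model_share')}")
        print(f"  MCS membership:   {summary.get('mcs_frequency')}")


if __name__ == "__main__":
    main()
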