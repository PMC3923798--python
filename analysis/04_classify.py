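"""Classify embryo development with the LVQ2.1 network.

For each incubation day, each pairwise contrast (N/D and D/W) and each
scalar feature, run five independent stratified 2/3-1/3 split + train +
test cycles (n=1 input, m=10 competitive neurons, l=2 outputs, learning
rate 0.1, error goal 0.01) and summarise accuracy as mean ± sd with the
integer coefficient of variance.  Writes one report table per feature and
prints the day-4 comparison between the two feature tracks.
"""

import argparse
import os

import pandas as pd

from common import RESULTS

from eggscan import evaluate as ev


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--runs", type=int, default=5)
    args = parser.parse_args()

    features = pd.read_csv(os.path.join(RESULTS, "features.tsv"), sep="\t")
    summaries = ev.run_full_evaluation(features, n_runs=args.runs,
                                       seed=args.seed)
    tables = ev.build_report(summaries)
    for feat, table in tables.items():
        out = os.path.join(RESULTS, f"report_{feat}.tsv")
        ev.report_to_tsv(table, out)
        print(f"\n=== {feat} ===")
        print(table.to_string(index=False))
        print(f"-> {out}")

    morph = summaries[(ev.MORPH_FEATURE, ("N", "D"), 4)]
    spectral = summaries[(ev.SPECTRAL_FEATURE, ("N", "D"), 4)]
    print(f"\nday-4 N/D test accuracy: morphologic W "
          f"{100 * morph.test_mean:.0f}% (cv {morph.test_cv}) vs spectral "
          f"x̄ {100 * spectral.test_mean:.0f}% (cv {spectral.test_cv})")


if __name__ == "__main__":
    main()
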