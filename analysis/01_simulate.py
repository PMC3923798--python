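"""Simulate a phantom egg cohort.

Writes one raw ENVI cube + ground-truth sidecar per egg per incubation day
(days 0-4) to scratch/cohort, plus the manifest to results/. The cohort is
a pure function of the seed.
"""

import argparse
import os
import shutil

from common import COHORT_DIR, RESULTS, analysis_config

from eggscan import phantom as ph


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=0)
    args = parser.parse_args()

    cfg = analysis_config(args.seed)
    if os.path.isdir(COHORT_DIR):
        shutil.rmtree(COHORT_DIR)
    manifest = ph.generate_cohort(cfg, COHORT_DIR)

    os.makedirs(RESULTS, exist_ok=True)
    manifest.to_csv(os.path.join(RESULTS, "manifest.tsv"), sep="\t",
                    index=False)
    counts = manifest.groupby("group")["id"].nunique()
    print(f"wrote {len(manifest)} cube records to {COHORT_DIR}")
    print("eggs per group:", dict(counts))
    print(f"manifest: {os.path.join(RESULTS, 'manifest.tsv')}")


if __name__ == "__main__":
    main()
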