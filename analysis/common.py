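"""Shared configuration for the analysis drivers.

The drivers run a scaled-down cohort (30 eggs on the smallest geometry) so
the whole narrative completes in well under a minute; the package defaults
(150 eggs, half-scale frames) are exercised by the test suite.  Cubes are
binary scratch data and go under scratch/; tables and reports go under
results/.
"""

import os

from eggscan import phantom as ph

HERE = os.path.dirname(os.path.abspath(__file__))
REPO = os.path.dirname(HERE)
RESULTS = os.path.join(REPO, "results")
SCRATCH = os.path.join(REPO, "scratch")
COHORT_DIR = os.path.join(SCRATCH, "cohort")

# tiny preset: 44x80 px, 21 bands; smallest egg that still holds a 1000-px ROI
SEGMENTATION_WINDOW = 21


def analysis_config(seed: int = 0) -> ph.PhantomConfig:
    return ph.tiny(cohort={"N": 6, "D": 12, "W": 12}, seed=seed)
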