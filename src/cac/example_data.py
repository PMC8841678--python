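"""Published multi-reader example data used in demonstrations and checks.

These small tables come from a published five-reader CT measurement study
comparing manual two-endpoint diameter placement with computer-aided
contouring.  They are self-contained inputs: the pairwise Pearson
correlation matrices of the five readers on the testing set (one matrix
per method), and a worked repeated-measurement example for one large
lesion (five readings per method, summarized by mean and SD).

The learning-set matrices of the same study are not reproduced here
because their printed values are internally inconsistent (duplicated
rows, summary entries that do not match the matrix); only the testing-set
matrices are used.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

READERS = ["analyst_1", "analyst_2", "analyst_3", "analyst_4", "analyst_5"]

# Testing-set pairwise Pearson correlations, manual measurement.
TESTING_MANUAL_PCC = pd.DataFrame(
    [
        [1.000, 0.546, 0.672, 0.605, 0.639],
        [0.546, 1.000, 0.823, 0.741, 0.796],
        [0.672, 0.823, 1.000, 0.796, 0.846],
        [0.605, 0.741, 0.796, 1.000, 0.814],
        [0.639, 0.796, 0.846, 0.814, 1.000],
    ],
    index=READERS,
    columns=READERS,
)

# Testing-set pairwise Pearson correlations, computer-aided contouring.
TESTING_CAC_PCC = pd.DataFrame(
    [
        [1.000, 0.760, 0.815, 0.815, 0.845],
        [0.760, 1.000, 0.850, 0.795, 0.828],
        [0.815, 0.850, 1.000, 0.830, 0.883],
        [0.815, 0.795, 0.830, 1.000, 0.931],
        [0.845, 0.828, 0.883, 0.931, 1.000],
    ],
    index=READERS,
    columns=READERS,
)

# Worked repeated-measurement example for one lesion: the five readings per
# method are summarized as mean +/- sample SD (mm).
EXAMPLE_MANUAL_MEAN_MM = 96.5
EXAMPLE_MANUAL_SD_MM = 4.1
EXAMPLE_CAC_MEAN_MM = 98.1
EXAMPLE_CAC_SD_MM = 0.3


def reconstruct_readings(mean: float, sd: float, n: int = 5) -> np.ndarray:
    """Five readings with exactly the given mean and sample SD.

    The individual readings behind the published summary are not printed;
    any set with matching first two moments has the same CV, so a fixed
    symmetric pattern is scaled to the target moments.
    """
    base = np.arange(n, dtype=float) - (n - 1) / 2.0
    base /= base.std(ddof=1)
    return mean + sd * base
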