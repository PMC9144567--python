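"""Published benchmark fixtures for the metric suite.

Confusion matrices reported for an attention-guided ST-GCN sleep stager
on two public datasets (sleep-EDF and ISRUC-SLEEP subgroup III), plus
the stage composition of those datasets.  They serve as golden inputs:
feeding them through :func:`somnograph.train_eval.evaluate` must
reproduce the published metric rows digit for digit.

Class order everywhere: W, N1, N2, N3, R (rows actual, columns
predicted).
"""

from __future__ import annotations

import numpy as np

from .network import STAGES

__all__ = [
    "SLEEP_EDF_CONFUSION",
    "ISRUC_CONFUSION",
    "SLEEP_EDF_STAGE_COUNTS",
    "ISRUC_STAGE_COUNTS",
]

SLEEP_EDF_CONFUSION = np.array([
    [7371,  214,    94,  147,  101],
    [  53, 2496,   201,   44,   10],
    [ 480,  552, 16019,  187,  561],
    [ 147,   93,   249, 5123,   91],
    [  21,  103,    15,  410, 7168],
], dtype=np.int64)

ISRUC_CONFUSION = np.array([
    [1682,   83,   37,    7,    8],
    [  94,  878,  183,    6,   87],
    [  19,  179, 2297,  158,   25],
    [   4,    3,  122, 1905,    1],
    [   8,   59,   37,    3, 1004],
], dtype=np.int64)

#: Per-stage epoch counts of the two datasets (whole-dataset composition).
SLEEP_EDF_STAGE_COUNTS = dict(zip(STAGES, (7927, 2804, 17799, 5703, 7717)))
ISRUC_STAGE_COUNTS = dict(zip(STAGES, (1817, 1248, 2678, 2035, 1111)))
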