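"""In-package reference tables.

``table2_fixture`` returns the published 10 x 11 contingency table between
AJCC 8th-edition stages (rows IA1..IV) and the 11 consensus-clustering
prognostic groups (columns 1..11) for the 77,953-patient lung-cancer
cohort the method was demonstrated on.  It is the worked example used by
the rank-correlation machinery and its tests.
"""

from __future__ import annotations

import numpy as np

from .compare import AJCC8_STAGES, ContingencyTable

_TABLE2_COUNTS = (
    (1656, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0),
    (7398, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0),
    (0, 5111, 0, 0, 0, 0, 0, 0, 0, 0, 0),
    (0, 0, 3411, 0, 0, 0, 0, 0, 0, 0, 0),
    (0, 0, 0, 1603, 0, 0, 0, 0, 0, 0, 0),
    (0, 0, 407, 5357, 356, 0, 0, 0, 0, 0, 0),
    (0, 0, 0, 52, 1859, 5804, 1938, 0, 0, 0, 0),
    (0, 0, 0, 0, 0, 0, 3182, 4140, 0, 0, 0),
    (0, 0, 0, 0, 0, 0, 0, 1662, 0, 0, 0),
    (0, 0, 0, 0, 0, 0, 0, 1092, 4320, 8553, 20052),
)


def table2_fixture() -> ContingencyTable:
    """The published stage-by-group patient contingency table (N = 77,953)."""
    return ContingencyTable(
        row_labels=list(AJCC8_STAGES),
        col_labels=[str(g) for g in range(1, 12)],
        counts=np.array(_TABLE2_COUNTS, dtype=np.int64),
    )
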