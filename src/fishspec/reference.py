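"""Published reference data used as worked-example inputs.

``SABLEFISH_FUSED_CONFUSION`` is the published voxel confusion matrix
for sablefish freshness-day classification with decision-level fusion
and LDA, trained on one fillet and tested on the other (unseen) fillet.
Feeding it through the metrics stack reproduces the headline accuracies:
about 94.5% exact (printed as 95%), 100% with two freshness grades, and
about 95.6% (printed as 96%) with three grades.
"""

from __future__ import annotations

import numpy as np

from .classification import ConfusionMatrix

#: ordered day classes of the reference study (day 5 excluded)
SABLEFISH_CLASS_DAYS = (1, 3, 7, 9, 11)

#: true day (rows) x predicted day (columns) voxel counts
SABLEFISH_FUSED_CONFUSION = ConfusionMatrix(
    class_days=SABLEFISH_CLASS_DAYS,
    counts=np.array(
        [
            [378, 0, 0, 0, 0],
            [0, 368, 0, 0, 0],
            [0, 0, 343, 9, 0],
            [0, 0, 65, 249, 9],
            [0, 0, 2, 10, 308],
        ]
    ),
)

#: freshness-grade groupings used in the reference report
SABLEFISH_TWO_GRADE = {1: "fresh", 3: "fresh",
                       7: "spoilt", 9: "spoilt", 11: "spoilt"}
SABLEFISH_THREE_GRADE = {1: "fresh", 3: "fresh",
                         7: "fairly_fresh", 9: "spoilt", 11: "spoilt"}
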