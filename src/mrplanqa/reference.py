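"""Reference validation data.

Plan-quality scores of a published 10-patient hypopharyngeal-carcinoma
cohort planned three ways on a 1.5-T MR-linac (no-field optimization,
recalculation at 1.5 T with fixed segments, and reoptimization at
1.5 T).  Each score is the 15-submetric PQM total (0-150) averaged over
two independent planning repeats.  Used to validate the cohort summary
statistics and the signed-rank comparison against their published
values; the underlying dose grids are not public.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .compare import CohortScores, CONDITIONS

__all__ = ["reference_cohort_scores", "reference_scores_frame"]

_PATIENTS = tuple(range(1, 11))

# columns: B0, B15_RECAL, B15_REOPT
_SCORES = np.array(
    [
        [88.4, 72.8, 81.6],
        [73.0, 58.1, 67.8],
        [89.7, 81.6, 90.0],
        [82.0, 65.6, 81.3],
        [79.7, 75.9, 79.8],
        [79.2, 62.1, 76.4],
        [88.8, 64.9, 82.2],
        [72.8, 52.2, 74.1],
        [93.0, 81.7, 92.6],
        [75.8, 65.7, 74.7],
    ]
)


def reference_cohort_scores() -> CohortScores:
    """The reference cohort as a :class:`~mrplanqa.compare.CohortScores`."""
    return CohortScores(_PATIENTS, CONDITIONS, _SCORES.copy())


def reference_scores_frame() -> pd.DataFrame:
    """The reference cohort as a tidy (patient, condition, value) frame."""
    records = [
        {"patient": p, "condition": c, "value": _SCORES[i, j]}
        for i, p in enumerate(_PATIENTS)
        for j, c in enumerate(CONDITIONS)
    ]
    return pd.DataFrame(records)
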