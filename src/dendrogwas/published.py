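"""Published summary tables for the six-population Siberian stone pine study.

These small printed tables are inputs to worked examples (the raw
sequencing data behind them were not deposited): the pairwise FST matrix,
the hierarchical AMOVA variance components, and the per-population
diversity summaries.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

POPULATIONS = ["PS", "TK", "ER", "RG", "RS", "SP"]

# pairwise Weir-Cockerham FST between the six populations (lower triangle
# as printed; symmetrized here)
_PAIRWISE_FST = {
    ("TK", "PS"): 0.0188,
    ("ER", "PS"): 0.0176,
    ("ER", "TK"): 0.0052,
    ("RG", "PS"): 0.0163,
    ("RG", "TK"): 0.0031,
    ("RG", "ER"): 0.0039,
    ("RS", "PS"): 0.0181,
    ("RS", "TK"): 0.0057,
    ("RS", "ER"): 0.0050,
    ("RS", "RG"): 0.0033,
    ("SP", "PS"): 0.0150,
    ("SP", "TK"): 0.0060,
    ("SP", "ER"): 0.0054,
    ("SP", "RG"): 0.0040,
    ("SP", "RS"): 0.0041,
}


def pairwise_fst_matrix() -> pd.DataFrame:
    """Square symmetric matrix of the published pairwise FST values."""
    m = pd.DataFrame(
        np.zeros((6, 6)), index=POPULATIONS, columns=POPULATIONS
    )
    for (a, b), v in _PAIRWISE_FST.items():
        m.loc[a, b] = v
        m.loc[b, a] = v
    return m


def pairwise_fst_values() -> np.ndarray:
    """The 15 published pairwise FST values."""
    return np.array(list(_PAIRWISE_FST.values()))


# hierarchical AMOVA variance components (among groups, among populations
# within groups, within populations)
AMOVA_SIGMA_A = 115.2
AMOVA_SIGMA_B = 47.9
AMOVA_SIGMA_C = 9405.6

# per-population diversity summary (pi per site, Ho, He, FIS)
DIVERSITY = pd.DataFrame(
    {
        "pi": [0.00085, 0.00089, 0.00091, 0.00090, 0.00087, 0.00090],
        "Ho": [0.204, 0.210, 0.220, 0.204, 0.198, 0.214],
        "He": [0.204, 0.212, 0.222, 0.219, 0.212, 0.219],
        "FIS": [0.016, 0.027, 0.017, 0.072, 0.065, 0.028],
    },
    index=POPULATIONS,
)

MEAN_INDIVIDUAL_HET = 0.212
MANTEL_R = 0.103
MANTEL_P = 0.313
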