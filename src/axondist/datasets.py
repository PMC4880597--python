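"""Small reference datasets shipped with the package.

The cross-species ranking matrix records, for seven published electron-
microscopy datasets of the corpus callosum (three regions in each of two
human specimens, one macaque region), the within-dataset AICc rank of the
six distribution families that best describe axon diameters.  It is the
standard input for the packaged rank-consistency analysis: Friedman's test
of whether the choice of family affects goodness of fit, followed by the
Nemenyi post-hoc comparison.
"""

from __future__ import annotations

import pandas as pd

from .ranktests import RankMatrix

_CROSS_SPECIES_RANKS = {
    "generalized_extreme_value": (1, 1, 1, 1, 1, 1, 1),
    "inverse_gaussian": (2, 3, 2, 2, 2, 2, 4),
    "log_normal": (3, 4, 3, 4, 3, 4, 3),
    "log_logistic": (4, 2, 4, 5, 5, 3, 2),
    "birnbaum_saunders": (5, 5, 5, 3, 4, 5, 5),
    "gamma": (6, 6, 6, 6, 6, 6, 6),
}

_CROSS_SPECIES_DATASETS = (
    "human1_cc1",
    "human1_cc2",
    "human1_cc3",
    "human2_cc1",
    "human2_cc2",
    "human2_cc3",
    "macaque_cc2",
)


def cross_species_rank_frame() -> pd.DataFrame:
    """Datasets (rows) by families (columns) rank table."""
    return pd.DataFrame(
        _CROSS_SPECIES_RANKS, index=list(_CROSS_SPECIES_DATASETS), dtype=float
    )


def cross_species_rank_matrix() -> RankMatrix:
    """The 7-dataset x 6-family rank matrix as a :class:`RankMatrix`."""
    return RankMatrix.from_frame(cross_species_rank_frame())
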