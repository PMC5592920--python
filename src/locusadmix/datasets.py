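"""Published habitat x admixture counts for the 80-strain yeast survey.

The survey classified each of 80 *S. cerevisiae* strains as admixed or not
by two methods — a model-based ancestry (structure) analysis thresholded at
0.94, and the locus-by-locus phylogenetic conflict test — and tabulated the
outcomes by isolation habitat. The printed counts below are the inputs for
the habitat-association exact tests; rows follow the canonical habitat
order, columns are (not admixed, admixed).
"""

from __future__ import annotations

import numpy as np

from .habstats import ContingencyTable
from .seqio import HABITATS

_STRUCTURE_COUNTS = [(9, 12), (3, 4), (7, 5), (0, 4), (32, 4)]
_PHYLO_COUNTS = [(11, 10), (3, 4), (9, 3), (3, 1), (32, 4)]

#: 2x2 among admixed strains: (woodland, other) x (single-locus, multi-locus)
SINGLE_LOCUS_COUNTS = [(4, 0), (4, 14)]


def structure_habitat_table() -> ContingencyTable:
    """Habitat counts under the ancestry-threshold (structure) classification."""
    return ContingencyTable(list(HABITATS), ["not_admixed", "admixed"],
                            np.array(_STRUCTURE_COUNTS))


def phylo_habitat_table() -> ContingencyTable:
    """Habitat counts under the locus-by-locus phylogenetic classification."""
    return ContingencyTable(list(HABITATS), ["not_admixed", "admixed"],
                            np.array(_PHYLO_COUNTS))


def single_locus_2x2() -> ContingencyTable:
    """Single- vs multi-locus admixture, woodland vs other habitats."""
    return ContingencyTable(
        ["oak_or_other_trees", "other_habitats"],
        ["single_locus", "multi_locus"],
        np.array(SINGLE_LOCUS_COUNTS),
    )
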