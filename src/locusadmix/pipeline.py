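"""End-to-end locus-by-locus workflow: distances -> NJ -> bootstrap -> labels.

This ties the stage modules together exactly as the analysis runs: per locus,
F84 distances with the chosen deletion policy, a neighbor-joining tree,
bootstrap support for its bipartitions, a support-threshold filter, and
reference-panel assignment; then cross-locus admixture calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .admixcall import AdmixtureCall, call_all
from .disttree import PhyloTree, distance_matrix, nj_build
from .popassign import PopulationScheme, assign_all
from .seqio import Dataset
from .support import SupportedGroups, clade_support, filter_supported, locus_rng


@dataclass
class LocusByLocusResult:
    assignments: pd.DataFrame                 # strain_id, locus_id, label
    supports: dict[str, SupportedGroups]      # unfiltered, per locus
    trees: dict[str, PhyloTree]
    calls: list[AdmixtureCall] = field(default_factory=list)

    @property
    def admixed_flags(self) -> dict[str, bool]:
        return {c.strain_id: c.admixed for c in self.calls}


def run_locus_by_locus(
    dataset: Dataset,
    scheme: PopulationScheme,
    n_bootstrap: int = 10_000,
    support_threshold: float = 70.0,
    deletion: str = "global",
    seed: int = 0,
) -> LocusByLocusResult:
    """Run the full per-locus assignment and cross-locus calling workflow.

    Each locus gets an independent, deterministic RNG stream derived from
    ``seed`` and the locus index, so results are reproducible per locus.
    """
    supports: dict[str, SupportedGroups] = {}
    trees: dict[str, PhyloTree] = {}
    filtered: dict[str, SupportedGroups] = {}
    for li, aln in enumerate(dataset.loci):
        dm = distance_matrix(aln, deletion=deletion)
        tree = nj_build(dm)
        sg = clade_support(tree, aln, n_reps=n_bootstrap, deletion=deletion,
                           rng_seed=locus_rng(seed, li))
        trees[aln.locus_id] = tree
        supports[aln.locus_id] = sg
        filtered[aln.locus_id] = filter_supported(sg, support_threshold)
    assignments = assign_all(dataset, scheme, filtered)
    calls = call_all(assignments, scheme)
    return LocusByLocusResult(assignments=assignments, supports=supports,
                              trees=trees, calls=calls)
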