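"""Nonparametric bootstrap of alignment columns and bipartition support.

Support is computed on unrooted bipartitions: for every internal edge of the
reference NJ tree, both sides of its bipartition are exposed as candidate
groups with the same support, defined as the percentage of valid bootstrap NJ
trees whose bipartition set contains that bipartition. Replicates whose
distance matrix contains a saturated (invalid) F84 entry are dropped from the
denominator; a warning is logged when more than 1% of replicates are dropped.

Random number use is seed-reproducible: one master seed yields per-locus
sub-seeds deterministically from the locus index.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .disttree import (
    PhyloTree,
    _ts_tensor,
    f84_matrix,
    joins_to_bipartitions,
    nj_joins,
    tree_bipartitions,
)
from .errors import DataError
from .seqio import LocusAlignment

log = logging.getLogger(__name__)

_CHUNK = 500  # bootstrap replicates processed per vectorized batch


@dataclass
class SupportedGroups:
    """Candidate groups (tip sets) of one locus tree with bootstrap support."""

    locus_id: str
    groups: list[tuple[frozenset[str], float]]
    n_replicates: int
    n_valid: int

    def filter(self, threshold: float = 70.0) -> "SupportedGroups":
        return SupportedGroups(
            locus_id=self.locus_id,
            groups=[(g, s) for g, s in self.groups if s >= threshold],
            n_replicates=self.n_replicates,
            n_valid=self.n_valid,
        )

    def groups_containing(self, strain: str) -> list[frozenset[str]]:
        return [g for g, _s in self.groups if strain in g]


def locus_rng(master_seed: int, locus_index: int) -> np.random.Generator:
    """Deterministic per-locus generator derived from one master seed."""
    return np.random.default_rng(
        np.random.SeedSequence(master_seed, spawn_key=(locus_index,))
    )


def bootstrap_replicate(aln: LocusAlignment,
                        rng: np.random.Generator | int) -> LocusAlignment:
    """Resample alignment columns with replacement to the original length."""
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    idx = rng.integers(0, aln.length, size=aln.length)
    seqs = ["".join(seq[i] for i in idx) for seq in aln.seqs]
    return LocusAlignment(aln.locus_id, list(aln.strains), seqs)


def _bootstrap_bipartition_counts(
    aln: LocusAlignment,
    n_reps: int,
    deletion: str,
    rng: np.random.Generator,
) -> tuple[dict[frozenset[int], int], int]:
    """Count bipartitions over bootstrap NJ trees; returns (counts, n_valid).

    Column resampling is implemented as multinomial column weights, so the
    per-replicate transition/transversion counts are weighted sums of
    precomputed per-column pair indicators.
    """
    X = aln.encoded()
    n, L = X.shape
    present = X < 4
    if deletion == "global":
        keep = present.all(axis=0)
        if not keep.any():
            raise DataError("global deletion removed every column")
    elif deletion == "pairwise":
        keep = np.ones(L, dtype=bool)
    else:
        raise DataError(f"unknown deletion policy {deletion!r}")

    Y = X[:, :]  # weights are over all original columns; deletion via masks
    # float32 tensors: entries are small integer counts, exactly representable
    ts = _ts_tensor(Y).astype(np.float32)
    both = (present[:, None, :] & present[None, :, :]).astype(np.float32)
    diff = ((Y[:, None, :] != Y[None, :, :]).astype(np.float32)) * both
    if deletion == "global":
        ts = ts * keep
        diff = diff * keep
        both = both * keep
    # per-column base counts (4, L) for replicate-wise pooled frequencies
    colbase = np.stack([((Y == b) & present).sum(axis=0) for b in range(4)])
    if deletion == "global":
        colbase = colbase * keep

    counts: dict[frozenset[int], int] = {}
    n_valid = 0
    done = 0
    while done < n_reps:
        m = min(_CHUNK, n_reps - done)
        # multinomial column weights == resampling columns with replacement
        W = rng.multinomial(L, np.full(L, 1.0 / L), size=m).astype(np.float32)
        done += m
        ts_c = np.einsum("ijl,rl->rij", ts, W).astype(np.float64)
        df_c = np.einsum("ijl,rl->rij", diff, W).astype(np.float64)
        bo_c = np.einsum("ijl,rl->rij", both, W).astype(np.float64)
        fr_c = colbase.astype(np.float64) @ W.T.astype(np.float64)  # (4, m)
        for r in range(m):
            denom = bo_c[r]
            if (denom[np.triu_indices(n, 1)] == 0).any():
                continue
            with np.errstate(invalid="ignore", divide="ignore"):
                P = ts_c[r] / np.where(denom > 0, denom, 1.0)
                Q = df_c[r] / np.where(denom > 0, denom, 1.0) - P
            ftot = fr_c[:, r].sum()
            if ftot == 0:
                continue
            freqs = fr_c[:, r] / ftot
            piR, piY = freqs[0] + freqs[2], freqs[1] + freqs[3]
            if piR <= 0 or piY <= 0:
                continue
            d, valid = f84_matrix(P, Q, freqs)
            np.fill_diagonal(valid, True)
            if not valid.all():
                continue
            np.fill_diagonal(d, 0.0)
            joins, _final = nj_joins(d)
            n_valid += 1
            for bip in joins_to_bipartitions(joins, n):
                counts[bip] = counts.get(bip, 0) + 1
    return counts, n_valid


def clade_support(
    ref_tree: PhyloTree,
    aln: LocusAlignment,
    n_reps: int = 10_000,
    deletion: str = "global",
    rng_seed: int | np.random.Generator = 0,
) -> SupportedGroups:
    """Bootstrap support for both sides of every internal edge of ``ref_tree``.

    ``ref_tree`` must be a tree over exactly the strains of ``aln`` (normally
    the NJ tree built from it).
    """
    rng = (rng_seed if isinstance(rng_seed, np.random.Generator)
           else np.random.default_rng(rng_seed))
    tips = {lf.taxon.label for lf in ref_tree.leaf_node_iter()}
    if tips != set(aln.strains):
        raise DataError("reference tree tips do not match alignment strains")
    ref_bips_labels = tree_bipartitions(ref_tree)
    idx = {s: i for i, s in enumerate(aln.strains)}
    allset = frozenset(range(aln.n_strains))

    def to_idx(side: frozenset[str]) -> frozenset[int]:
        s = frozenset(idx[x] for x in side)
        return s if 0 not in s else allset - s

    counts, n_valid = _bootstrap_bipartition_counts(aln, n_reps, deletion, rng)
    if n_valid == 0:
        raise DataError(f"locus {aln.locus_id!r}: no valid bootstrap replicate")
    n_dropped = n_reps - n_valid
    if n_dropped > 0.01 * n_reps:
        log.warning("locus %s: %d/%d bootstrap replicates dropped (invalid "
                    "distances)", aln.locus_id, n_dropped, n_reps)

    all_labels = frozenset(aln.strains)
    groups: list[tuple[frozenset[str], float]] = []
    for side in sorted(ref_bips_labels, key=lambda s: (len(s), sorted(s))):
        sup = 100.0 * counts.get(to_idx(side), 0) / n_valid
        groups.append((side, sup))
        groups.append((all_labels - side, sup))
    return SupportedGroups(
        locus_id=aln.locus_id,
        groups=groups,
        n_replicates=n_reps,
        n_valid=n_valid,
    )


def filter_supported(sg: SupportedGroups, threshold: float = 70.0) -> SupportedGroups:
    """Keep only groups with support >= ``threshold`` percent."""
    return sg.filter(threshold)


def annotate_support(tree: PhyloTree, sg: SupportedGroups) -> PhyloTree:
    """Attach ``node.support`` from a SupportedGroups onto internal nodes."""
    support = {g: s for g, s in sg.groups}
    tips = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
    allset = frozenset(tips)
    for nd in tree.preorder_node_iter():
        if nd.is_leaf() or nd.parent_node is None:
            continue
        side = frozenset(lf.taxon.label for lf in nd.leaf_iter())
        sup = support.get(side, support.get(allset - side))
        if sup is not None:
            nd.support = sup
    return tree


def write_supported_groups(sg: SupportedGroups, path) -> None:
    with open(path, "w") as fh:
        fh.write("group_id\tsupport\tstrains\n")
        for k, (g, s) in enumerate(sg.groups):
            fh.write(f"{sg.locus_id}_g{k}\t{s:.2f}\t{','.join(sorted(g))}\n")
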