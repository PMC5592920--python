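"""F84 pairwise distances and neighbor-joining tree construction.

Distances use the F84 substitution model (unequal base frequencies, separate
transition/transversion rates), whose pairwise maximum-likelihood distance has
the closed form

    d = -2A ln(1 - P/2A - (A-B)Q/2AC) + 2(A-B-C) ln(1 - Q/2C)

with P, Q the observed transition and transversion proportions and, writing
piR = piA + piG, piY = piC + piT:

    A = piT*piC/piY + piA*piG/piR,  B = piT*piC + piA*piG,  C = piR*piY.

Base frequencies are pooled over the whole alignment. Missing data (N or -)
are handled by complete deletion of affected columns by default (``global``),
or per-pair (``pairwise``). Saturated pairs (a log argument <= 0) are flagged
invalid rather than raising.

Trees are built with the Saitou-Nei neighbor-joining agglomeration using the
Studier-Keppler criterion, with a deterministic tie-break (lowest index pair),
a trifurcating root, and branch lengths retained as computed (possibly
negative). Trees are ``dendropy.Tree`` objects; newick serialization encodes
bootstrap support as internal node labels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import dendropy
import numpy as np

from .errors import DataError
from .seqio import LocusAlignment

log = logging.getLogger(__name__)

PhyloTree = dendropy.Tree

#: transition pairs under the A<->G, C<->T convention, as encoded base codes
_TRANSITIONS = {(0, 2), (2, 0), (1, 3), (3, 1)}


@dataclass(frozen=True)
class PairCounts:
    """Observed proportions for one sequence pair over comparable sites."""

    n: int       # number of compared sites
    P: float     # transition proportion
    Q: float     # transversion proportion

    def __post_init__(self) -> None:
        if self.n < 1:
            raise DataError("PairCounts requires n >= 1")
        if not (0.0 <= self.P + self.Q <= 1.0 + 1e-12):
            raise DataError("P + Q must lie in [0, 1]")


@dataclass
class DistanceMatrix:
    """Symmetric matrix of F84 distances with a validity mask.

    ``valid[i, j]`` is False where the F84 log arguments were non-positive
    (saturated pair); ``d`` is NaN there.
    """

    labels: list[str]
    d: np.ndarray
    valid: np.ndarray

    @property
    def n(self) -> int:
        return len(self.labels)

    @property
    def fully_valid(self) -> bool:
        return bool(self.valid.all())


def base_frequencies(aln: LocusAlignment) -> np.ndarray:
    """(piA, piC, piG, piT) pooled over all sequences and sites; N/- ignored."""
    X = aln.encoded()
    counts = np.bincount(X[X < 4], minlength=4).astype(float)
    total = counts.sum()
    if total == 0:
        raise DataError(f"locus {aln.locus_id!r}: no unambiguous bases")
    return counts / total


def pair_counts(s1: str, s2: str, deletion: str = "pairwise",
                global_mask: np.ndarray | None = None) -> PairCounts:
    """Transition/transversion proportions for one pair of aligned sequences.

    Only sites where both bases are in {A,C,G,T} are compared; with
    ``deletion="global"`` sites flagged True in ``global_mask`` (columns
    containing missing data anywhere in the alignment) are excluded as well.
    """
    if len(s1) != len(s2):
        raise DataError("sequences of unequal length")
    a = LocusAlignment("pair", ["a", "b"], [s1, s2]).encoded()
    both = (a[0] < 4) & (a[1] < 4)
    if deletion == "global":
        if global_mask is None:
            raise DataError("deletion='global' requires a global_mask")
        both &= ~np.asarray(global_mask, dtype=bool)
    elif deletion != "pairwise":
        raise DataError(f"unknown deletion policy {deletion!r}")
    n = int(both.sum())
    if n == 0:
        raise DataError("zero comparable sites for pair")
    x, y = a[0][both], a[1][both]
    diff = x != y
    ts = diff & (((x == 0) & (y == 2)) | ((x == 2) & (y == 0))
                 | ((x == 1) & (y == 3)) | ((x == 3) & (y == 1)))
    n_ts = int(ts.sum())
    n_tv = int(diff.sum()) - n_ts
    return PairCounts(n=n, P=n_ts / n, Q=n_tv / n)


def _f84_coeffs(freqs: np.ndarray) -> tuple[float, float, float]:
    piA, piC, piG, piT = (float(f) for f in freqs)
    piR, piY = piA + piG, piC + piT
    if piR <= 0 or piY <= 0:
        raise DataError("F84 undefined: purine or pyrimidine frequency is zero")
    A = piT * piC / piY + piA * piG / piR
    B = piT * piC + piA * piG
    C = piR * piY
    return A, B, C


def f84_distance(pc: PairCounts, freqs: np.ndarray) -> float:
    """F84 distance for one pair; NaN (invalid) if a log argument is <= 0."""
    A, B, C = _f84_coeffs(freqs)
    arg1 = 1.0 - pc.P / (2 * A) - (A - B) * pc.Q / (2 * A * C)
    arg2 = 1.0 - pc.Q / (2 * C)
    if arg1 <= 0 or arg2 <= 0:
        return float("nan")
    return -2 * A * np.log(arg1) + 2 * (A - B - C) * np.log(arg2)


def _pq_matrices(X: np.ndarray, deletion: str) -> tuple[np.ndarray, np.ndarray]:
    """Dense (n, n) transition/transversion proportion matrices."""
    n = X.shape[0]
    present = X < 4
    if deletion == "global":
        keep = present.all(axis=0)
        if not keep.any():
            raise DataError("global deletion removed every column")
        Y = X[:, keep]
        eq = Y[:, None, :] == Y[None, :, :]
        ts = _ts_tensor(Y)
        denom = float(Y.shape[1])
        P = ts.sum(axis=2) / denom
        Q = (~eq).sum(axis=2) / denom - P
    elif deletion == "pairwise":
        both = present[:, None, :] & present[None, :, :]
        denom = both.sum(axis=2).astype(float)
        bad = [(i, j) for i in range(n) for j in range(i + 1, n)
               if denom[i, j] == 0]
        if bad:
            raise DataError(f"zero comparable sites for pairs: {bad[:5]}")
        eq = (X[:, None, :] == X[None, :, :]) & both
        ts = _ts_tensor(X) & both
        P = ts.sum(axis=2) / denom
        Q = (both & ~eq).sum(axis=2) / denom - P
    else:
        raise DataError(f"unknown deletion policy {deletion!r}")
    np.fill_diagonal(P, 0.0)
    np.fill_diagonal(Q, 0.0)
    return P, Q


def _ts_tensor(X: np.ndarray) -> np.ndarray:
    """(n, n, L) boolean: site is a transition difference for the pair."""
    a = X[:, None, :]
    b = X[None, :, :]
    return (((a == 0) & (b == 2)) | ((a == 2) & (b == 0))
            | ((a == 1) & (b == 3)) | ((a == 3) & (b == 1)))


def f84_matrix(P: np.ndarray, Q: np.ndarray,
               freqs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized F84 over P/Q arrays -> (distances, validity mask)."""
    A, B, C = _f84_coeffs(freqs)
    arg1 = 1.0 - P / (2 * A) - (A - B) * Q / (2 * A * C)
    arg2 = 1.0 - Q / (2 * C)
    valid = (arg1 > 0) & (arg2 > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(
            valid,
            -2 * A * np.log(np.where(valid, arg1, 1.0))
            + 2 * (A - B - C) * np.log(np.where(valid, arg2, 1.0)),
            np.nan,
        )
    return d, valid


def distance_matrix(aln: LocusAlignment, deletion: str = "global") -> DistanceMatrix:
    """All-pairs F84 distances with alignment-wide pooled base frequencies."""
    if aln.n_strains < 3:
        raise DataError("distance matrix requires >= 3 strains")
    X = aln.encoded()
    freqs = base_frequencies(aln)
    P, Q = _pq_matrices(X, deletion)
    d, valid = f84_matrix(P, Q, freqs)
    np.fill_diagonal(d, 0.0)
    np.fill_diagonal(valid, True)
    return DistanceMatrix(labels=list(aln.strains), d=d, valid=valid)


def write_distance_matrix(dm: DistanceMatrix, path, fmt: str = "tsv") -> None:
    """Write a distance matrix as TSV or PHYLIP square format."""
    with open(path, "w") as fh:
        if fmt == "phylip":
            fh.write(f"{dm.n}\n")
            for lab, row in zip(dm.labels, dm.d):
                vals = " ".join(f"{v:.8f}" for v in row)
                fh.write(f"{lab:<10s} {vals}\n")
        else:
            fh.write("\t" + "\t".join(dm.labels) + "\n")
            for lab, row in zip(dm.labels, dm.d):
                fh.write(lab + "\t" + "\t".join(f"{v:.8f}" for v in row) + "\n")


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

def nj_joins(D: np.ndarray) -> tuple[list, list]:
    """Saitou-Nei NJ agglomeration order on a plain distance matrix.

    Returns ``(joins, final)`` where each join is ``(a, b, la, lb, new_id)``
    (node ids: 0..n-1 are tips, created nodes count up from n) and ``final``
    is the trifurcating root ``[(a, la), (b, lb), (c, lc)]``. Ties in the
    Studier-Keppler criterion break to the lowest (row, column) index pair in
    the current matrix order, so the result is deterministic.
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if n < 3:
        raise DataError("NJ requires >= 3 taxa")
    if np.isnan(D).any():
        raise DataError("NJ input contains invalid (NaN) distances")
    M = D.copy()
    active = list(range(n))
    joins = []
    next_id = n
    while len(active) > 3:
        m = len(active)
        R = M.sum(axis=1)
        Qc = (m - 2) * M - R[:, None] - R[None, :]
        iu = np.triu_indices(m, 1)
        flat = Qc[iu]
        k = int(np.argmin(flat))  # first occurrence = lowest (i, j)
        i, j = int(iu[0][k]), int(iu[1][k])
        dij = M[i, j]
        li = 0.5 * dij + (R[i] - R[j]) / (2 * (m - 2))
        lj = dij - li
        joins.append((active[i], active[j], float(li), float(lj), next_id))
        dnew = 0.5 * (M[i, :] + M[j, :] - dij)
        keep = [k2 for k2 in range(m) if k2 not in (i, j)]
        M2 = np.empty((m - 1, m - 1))
        M2[: m - 2, : m - 2] = M[np.ix_(keep, keep)]
        M2[: m - 2, m - 2] = dnew[keep]
        M2[m - 2, : m - 2] = dnew[keep]
        M2[m - 2, m - 2] = 0.0
        M = M2
        active = [active[k2] for k2 in keep] + [next_id]
        next_id += 1
    a, b, c = active
    dab, dac, dbc = M[0, 1], M[0, 2], M[1, 2]
    final = [
        (a, float(0.5 * (dab + dac - dbc))),
        (b, float(0.5 * (dab + dbc - dac))),
        (c, float(0.5 * (dac + dbc - dab))),
    ]
    return joins, final


def joins_to_bipartitions(joins: list, n: int) -> set[frozenset[int]]:
    """Unrooted bipartitions (as canonical tip-index sets) from an NJ run.

    Each created internal node corresponds to one internal edge; its side of
    the bipartition is its tip set. Sides are canonicalized to the side not
    containing tip 0.
    """
    leafset: dict[int, frozenset[int]] = {i: frozenset([i]) for i in range(n)}
    out: set[frozenset[int]] = set()
    allset = frozenset(range(n))
    for a, b, _la, _lb, new in joins:
        s = leafset[a] | leafset[b]
        leafset[new] = s
        side = s if 0 not in s else allset - s
        if 2 <= len(side) <= n - 2:
            out.add(side)
    return out


def nj_build(dm: DistanceMatrix) -> PhyloTree:
    """NJ tree from a distance matrix, as a dendropy Tree (trifurcating root).

    Negative branch lengths are retained as computed (a warning is logged);
    clamping them would silently alter topology/support comparisons.
    """
    if not dm.fully_valid:
        bad = np.argwhere(~dm.valid)
        pairs = [(dm.labels[i], dm.labels[j]) for i, j in bad[:5] if i < j]
        raise DataError(f"distance matrix has invalid (saturated) pairs: {pairs}")
    joins, final = nj_joins(dm.d)
    neg = [l for _a, _b, la, lb, _n in joins for l in (la, lb) if l < 0]
    neg += [l for _a, l in final if l < 0]
    if neg:
        log.warning("NJ produced %d negative branch length(s); retained", len(neg))

    taxa = dendropy.TaxonNamespace(dm.labels)
    tree = dendropy.Tree(taxon_namespace=taxa)
    nodes: dict[int, dendropy.Node] = {}
    for i, lab in enumerate(dm.labels):
        nd = dendropy.Node(taxon=taxa.get_taxon(lab))
        nodes[i] = nd
    for a, b, la, lb, new in joins:
        nd = dendropy.Node()
        nodes[a].edge.length = la
        nodes[b].edge.length = lb
        nd.add_child(nodes[a])
        nd.add_child(nodes[b])
        nodes[new] = nd
    root = tree.seed_node
    for a, la in final:
        nodes[a].edge.length = la
        root.add_child(nodes[a])
    tree.is_rooted = False
    return tree


def tree_bipartitions(tree: PhyloTree) -> set[frozenset[str]]:
    """Nontrivial unrooted bipartitions of a tree as canonical tip-label sets.

    Each side is canonicalized to the side not containing the lexicographically
    first tip label.
    """
    tips = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
    ref = tips[0]
    allset = frozenset(tips)
    n = len(tips)
    out: set[frozenset[str]] = set()
    for nd in tree.preorder_node_iter():
        if nd.is_leaf() or nd.parent_node is None:
            continue
        side = frozenset(lf.taxon.label for lf in nd.leaf_iter())
        if ref in side:
            side = allset - side
        if 2 <= len(side) <= n - 2:
            out.add(side)
    return out


def path_distance_matrix(tree: PhyloTree) -> DistanceMatrix:
    """Patristic (path-length) distances between tips; oracle for additivity."""
    pdm = tree.phylogenetic_distance_matrix()
    labels = sorted(t.label for t in tree.taxon_namespace)
    n = len(labels)
    d = np.zeros((n, n))
    taxon = {t.label: t for t in tree.taxon_namespace}
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pdm.patristic_distance(taxon[labels[i]],
                                                       taxon[labels[j]])
    return DistanceMatrix(labels=labels, d=d, valid=np.ones((n, n), dtype=bool))


# ---------------------------------------------------------------------------
# newick I/O (support encoded as internal node labels)
# ---------------------------------------------------------------------------

def write_newick(tree: PhyloTree) -> str:
    """Serialize a tree to newick; internal ``node.support`` -> node label."""
    for nd in tree.preorder_node_iter():
        sup = getattr(nd, "support", None)
        if sup is not None and not nd.is_leaf():
            nd.label = str(int(round(sup)))
    return tree.as_string(
        schema="newick",
        suppress_rooting=True,
        real_value_format_specifier=".10g",
    ).strip()


def read_newick(s: str) -> PhyloTree:
    """Parse newick; internal node labels that are numbers become support."""
    try:
        tree = dendropy.Tree.get(
            data=s, schema="newick",
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises various parse error types
        raise DataError(f"malformed newick: {exc}") from exc
    for nd in tree.preorder_node_iter():
        if not nd.is_leaf() and nd.label is not None:
            try:
                nd.support = float(nd.label)
            except ValueError:
                pass
    tree.is_rooted = False
    return tree
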