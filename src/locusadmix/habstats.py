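"""Habitat x admixture contingency tables and exact tests.

The two-sided exact tests use the probability-mass ordering: the p-value is
the total probability, under the (multivariate) hypergeometric distribution
with the observed margins fixed, of every table whose probability does not
exceed that of the observed table (with a small relative tolerance on the
comparison to avoid floating-point boundary misclassification). For 2x2
tables this is Fisher's exact test; for r x c tables it is the
Freeman-Halton generalization, computed by exhaustive enumeration with a
Monte-Carlo fallback for large tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .errors import ConfigError, DataError
from .seqio import HABITATS

#: relative tolerance on the "probability <= observed" comparison
_PTOL = 1e-7


@dataclass
class ContingencyTable:
    """Counts of strains by habitat (rows) and admixture status (columns)."""

    row_labels: list[str]
    col_labels: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (len(self.row_labels), len(self.col_labels)):
            raise DataError("counts shape does not match labels")
        if (self.counts < 0).any():
            raise DataError("counts must be nonnegative")

    @property
    def row_margins(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_margins(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def drop_rows(self, labels: set[str]) -> "ContingencyTable":
        keep = [i for i, l in enumerate(self.row_labels) if l not in labels]
        return ContingencyTable(
            [self.row_labels[i] for i in keep],
            list(self.col_labels),
            self.counts[keep],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.row_labels,
                            columns=self.col_labels)


def build_table(calls: dict[str, bool], meta: pd.DataFrame,
                exclude_habitats: set[str] = frozenset()) -> ContingencyTable:
    """Habitat x (not_admixed, admixed) counts for the called strains.

    ``calls`` maps strain id to its admixed flag; every called strain must
    carry habitat metadata. Rows follow the canonical habitat order; excluded
    habitats are dropped entirely.
    """
    if not calls:
        raise DataError("empty call set")
    hab = dict(zip(meta["strain_id"], meta["habitat"]))
    missing = sorted(set(calls) - set(hab))
    if missing:
        raise DataError(f"strains without habitat metadata: {missing}")
    rows = [h for h in HABITATS if h not in exclude_habitats]
    counts = np.zeros((len(rows), 2), dtype=np.int64)
    ridx = {h: i for i, h in enumerate(rows)}
    for strain, admixed in calls.items():
        h = hab[strain]
        if h in exclude_habitats:
            continue
        counts[ridx[h], 1 if admixed else 0] += 1
    return ContingencyTable(rows, ["not_admixed", "admixed"], counts)


def proportion_admixed(t: ContingencyTable,
                       rows: list[str] | None = None) -> float:
    """admixed / (admixed + not admixed) over the selected rows."""
    if rows is None:
        sel = np.ones(len(t.row_labels), dtype=bool)
    else:
        unknown = set(rows) - set(t.row_labels)
        if unknown:
            raise DataError(f"unknown rows {sorted(unknown)}")
        sel = np.array([l in rows for l in t.row_labels])
    sub = t.counts[sel]
    denom = sub.sum()
    if denom == 0:
        raise DataError("zero total in selected rows")
    return float(sub[:, 1].sum() / denom)


def _as_counts(t) -> np.ndarray:
    if isinstance(t, ContingencyTable):
        a = t.counts
    else:
        a = np.asarray(t)
    if a.ndim != 2:
        raise DataError("contingency table must be 2-dimensional")
    if not np.issubdtype(a.dtype, np.integer):
        if not np.allclose(a, np.round(a)):
            raise DataError("contingency counts must be integers")
        a = np.round(a).astype(np.int64)
    if (a < 0).any():
        raise DataError("contingency counts must be nonnegative")
    return a.astype(np.int64)


def fisher_2x2(t) -> float:
    """Two-sided Fisher exact p for a 2x2 table (probability-mass ordering).

    Degenerate tables with a zero margin return p = 1 by convention.
    """
    a = _as_counts(t)
    if a.shape != (2, 2):
        raise DataError("fisher_2x2 requires a 2x2 table")
    if (a.sum(axis=0) == 0).any() or (a.sum(axis=1) == 0).any():
        return 1.0
    return float(stats.fisher_exact(a, alternative="two-sided")[1])


def _log_table_prob(a: np.ndarray, lg_margins: float, lgN: float) -> float:
    return lg_margins - lgN - gammaln(a + 1).sum()


def _enumeration_bound(row_m: np.ndarray, n_cols: int) -> float:
    """Upper bound on the number of candidate tables (compositions per row)."""
    from math import comb
    b = 1.0
    for r in row_m[:-1]:
        b *= comb(int(r) + n_cols - 1, n_cols - 1)
    return b


def fisher_rxc(t, max_tables: float = 1e7) -> float:
    """Freeman-Halton two-sided exact p for an r x c table.

    Enumerates every table with the observed margins (depth-first by rows,
    pruning on remaining column margins) and sums the multivariate
    hypergeometric probabilities of tables no more probable than the observed
    one. Raises :class:`ConfigError` when the enumeration bound exceeds
    ``max_tables`` (use :func:`fisher_rxc_mc` then).
    """
    a = _as_counts(t)
    r, c = a.shape
    row_m = a.sum(axis=1)
    col_m = a.sum(axis=0)
    if (row_m == 0).any() or (col_m == 0).any():
        # degenerate margins carry no information
        keep_r = row_m > 0
        keep_c = col_m > 0
        if keep_r.sum() < 2 or keep_c.sum() < 2:
            return 1.0
        a = a[np.ix_(keep_r, keep_c)]
        r, c = a.shape
        row_m, col_m = a.sum(axis=1), a.sum(axis=0)
    if _enumeration_bound(row_m, c) > max_tables:
        raise ConfigError(
            "table too large for exhaustive enumeration; use fisher_rxc_mc"
        )
    N = int(a.sum())
    lg_margins = gammaln(row_m + 1).sum() + gammaln(col_m + 1).sum()
    lgN = float(gammaln(N + 1))
    logp_obs = _log_table_prob(a, lg_margins, lgN)
    cutoff = logp_obs + np.log1p(_PTOL)

    lgfact = gammaln(np.arange(N + 1) + 1)  # lookup: log k!
    total = 0.0

    def fill_row(i: int, rem_cols: np.ndarray, logacc: float) -> None:
        nonlocal total
        if i == r - 1:
            # last row is forced by the column margins
            logp = logacc - lgfact[rem_cols].sum()
            if logp <= cutoff:
                total += np.exp(logp)
            return
        ri = int(row_m[i])

        def comp(j: int, left: int, rem: np.ndarray, acc: float) -> None:
            if j == c - 1:
                if left <= rem[j]:
                    rem2 = rem.copy()
                    rem2[j] -= left
                    fill_row(i + 1, rem2, acc - lgfact[left])
                return
            hi = min(left, int(rem[j]))
            lo = max(0, left - int(rem[j + 1:].sum()))
            for x in range(lo, hi + 1):
                rem2 = rem.copy()
                rem2[j] -= x
                comp(j + 1, left - x, rem2, acc - lgfact[x])

        comp(0, ri, rem_cols, logacc)

    fill_row(0, col_m.copy(), lg_margins - lgN)
    return float(min(total, 1.0))


def fisher_rxc_mc(t, n_reps: int = 100_000,
                  seed: int = 0) -> tuple[float, float]:
    """Monte-Carlo Freeman-Halton p with standard error.

    Samples tables from the fixed-margins null by permuting individual-level
    column labels against row labels; returns ``(p, se)`` with the
    (1 + hits) / (1 + reps) estimator.
    """
    a = _as_counts(t)
    r, c = a.shape
    row_m = a.sum(axis=1)
    col_m = a.sum(axis=0)
    N = int(a.sum())
    if N == 0:
        return 1.0, 0.0
    lg_margins = gammaln(row_m + 1).sum() + gammaln(col_m + 1).sum()
    lgN = float(gammaln(N + 1))
    logp_obs = _log_table_prob(a, lg_margins, lgN)
    cutoff = logp_obs + np.log1p(_PTOL)

    rng = np.random.default_rng(seed)
    rows = np.repeat(np.arange(r), row_m)
    cols = np.repeat(np.arange(c), col_m)
    hits = 0
    for _ in range(n_reps):
        perm = rng.permutation(cols)
        tab = np.zeros((r, c), dtype=np.int64)
        np.add.at(tab, (rows, perm), 1)
        if _log_table_prob(tab, lg_margins, lgN) <= cutoff:
            hits += 1
    p = (1 + hits) / (1 + n_reps)
    se = float(np.sqrt(p * (1 - p) / n_reps))
    return float(p), se


def single_locus_table(calls_df: pd.DataFrame,
                       meta: pd.DataFrame) -> ContingencyTable:
    """2x2 table among admixed strains: woodland vs other habitats (rows)
    against single-locus vs multi-locus admixture (columns)."""
    need = {"strain_id", "admixed", "single_locus"}
    if need - set(calls_df.columns):
        raise DataError(f"calls table missing columns {sorted(need - set(calls_df.columns))}")
    hab = dict(zip(meta["strain_id"], meta["habitat"]))
    counts = np.zeros((2, 2), dtype=np.int64)
    for _, row in calls_df.iterrows():
        if not row["admixed"]:
            continue
        strain = row["strain_id"]
        if strain not in hab:
            raise DataError(f"strain {strain!r} without habitat metadata")
        i = 0 if hab[strain] == "oak_or_other_trees" else 1
        j = 0 if bool(row["single_locus"]) else 1
        counts[i, j] += 1
    return ContingencyTable(["oak_or_other_trees", "other_habitats"],
                            ["single_locus", "multi_locus"], counts)


def write_table(t: ContingencyTable, path: str | Path) -> None:
    df = t.to_frame()
    df["proportion_admixed"] = [
        row[1] / row.sum() if row.sum() else float("nan") for row in t.counts
    ]
    df.index.name = "habitat"
    df.to_csv(path, sep="\t")


def read_table(path: str | Path) -> ContingencyTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    cols = [c for c in df.columns if c != "proportion_admixed"]
    return ContingencyTable(list(df.index), cols,
                            df[cols].to_numpy(dtype=np.int64))
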