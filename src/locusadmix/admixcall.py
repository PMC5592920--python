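"""Cross-locus admixture calls, and the ancestry-threshold classifier.

A strain is called admixed when its per-locus labels conflict: two labels
conflict unless one is "undefined", they are equal, or one is the other's
supergroup. Two distinct populations always conflict, even within one
supergroup, and so do two distinct supergroups.

The alternative classifier thresholds an externally estimated ancestry
(Q) matrix: a strain is admixed when its largest ancestry proportion falls
below the threshold (default 0.94, i.e. one locus in sixteen from elsewhere).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataError
from .popassign import UNDEFINED, PopulationScheme

log = logging.getLogger(__name__)


def compatible(l1: str, l2: str, scheme: PopulationScheme) -> bool:
    """True iff the two per-locus labels do not conflict."""
    for l in (l1, l2):
        if not scheme.known_label(l):
            raise DataError(f"unknown label {l!r}")
    if l1 == UNDEFINED or l2 == UNDEFINED or l1 == l2:
        return True
    for a, b in ((l1, l2), (l2, l1)):
        if scheme.is_population(a) and scheme.supergroup_of(a) == b:
            return True
    return False


@dataclass
class AdmixtureCall:
    """Cross-locus verdict for one strain."""

    strain_id: str
    labels: dict[str, str]            # locus -> label
    admixed: bool
    populations_involved: frozenset[str]
    majority_label: str               # label of the majority-compatible component
    n_minority_loci: int              # defined loci outside the majority component

    @property
    def single_locus(self) -> bool:
        return self.admixed and self.n_minority_loci == 1


def call_admixture(strain_id: str, labels: dict[str, str],
                   scheme: PopulationScheme) -> AdmixtureCall:
    """Combine one strain's per-locus labels into an admixture call.

    Conflicts are found by collapsing each supergroup label that co-occurs
    with one of its member populations into that population; after the
    collapse any two distinct remaining labels are pairwise incompatible, so
    the strain is admixed iff more than one label remains. The "majority
    component" is the hierarchically compatible label set covering the most
    defined loci (a population together with its own supergroup, or a bare
    label); ties break toward more population-level loci, then
    lexicographically (logged).
    """
    if not labels:
        raise DataError(f"strain {strain_id!r}: no per-locus labels")
    for l in labels.values():
        if not scheme.known_label(l):
            raise DataError(f"unknown label {l!r}")
    defined = {loc: l for loc, l in labels.items() if l != UNDEFINED}
    counts: dict[str, int] = {}
    for l in defined.values():
        counts[l] = counts.get(l, 0) + 1

    # collapse supergroups that have an observed member population
    involved = set(counts)
    for l in list(involved):
        if scheme.is_supergroup(l) and any(
            scheme.is_population(p) and scheme.supergroup_of(p) == l
            for p in involved
        ):
            involved.discard(l)
    admixed = len(involved) >= 2

    # majority component: for each candidate label, the loci it covers
    def cover(label: str) -> int:
        c = counts.get(label, 0)
        if scheme.is_population(label):
            sg = scheme.supergroup_of(label)
            if sg is not None:
                c += counts.get(sg, 0)
        return c

    candidates = set(counts)
    for l in counts:
        if scheme.is_supergroup(l):
            candidates.update(scheme.supergroups[l])
    if not candidates:
        majority, n_cov = UNDEFINED, 0
    else:
        ranked = sorted(
            candidates,
            key=lambda l: (-cover(l), -counts.get(l, 0), l),
        )
        majority = ranked[0]
        n_cov = cover(majority)
        if len(ranked) > 1 and cover(ranked[1]) == n_cov:
            log.info("strain %s: majority-component tie broken toward %r",
                     strain_id, majority)
    n_minority = len(defined) - n_cov

    return AdmixtureCall(
        strain_id=strain_id,
        labels=dict(labels),
        admixed=admixed,
        populations_involved=frozenset(involved) if admixed else frozenset(),
        majority_label=majority,
        n_minority_loci=n_minority,
    )


def call_all(assignments: pd.DataFrame,
             scheme: PopulationScheme) -> list[AdmixtureCall]:
    """One admixture call per strain from a long-format assignments table."""
    calls = []
    for strain, grp in assignments.groupby("strain_id", sort=True):
        if grp["locus_id"].duplicated().any():
            raise DataError(f"strain {strain!r}: duplicate locus rows")
        labels = dict(zip(grp["locus_id"], grp["label"]))
        calls.append(call_admixture(str(strain), labels, scheme))
    return calls


def calls_table(calls: list[AdmixtureCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        rows.append({
            "strain_id": c.strain_id,
            "admixed": c.admixed,
            "populations_involved": ",".join(sorted(c.populations_involved)),
            "majority_label": c.majority_label,
            "n_minority_loci": c.n_minority_loci,
            "single_locus": c.single_locus,
            "labels": ";".join(f"{loc}={lab}" for loc, lab
                               in sorted(c.labels.items())),
        })
    return pd.DataFrame(rows)


def write_calls(calls: list[AdmixtureCall], path: str | Path) -> None:
    calls_table(calls).to_csv(path, sep="\t", index=False)


def read_calls(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if {"strain_id", "admixed"} - set(df.columns):
        raise DataError(f"calls file {path} missing strain_id/admixed columns")
    df["admixed"] = df["admixed"].astype(bool)
    return df


# ---------------------------------------------------------------------------
# ancestry-threshold classifier
# ---------------------------------------------------------------------------

@dataclass
class AncestryMatrix:
    """Per-strain ancestry proportions across populations (rows sum to 1)."""

    strains: list[str]
    populations: list[str]
    q: np.ndarray

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        if self.q.shape != (len(self.strains), len(self.populations)):
            raise DataError("ancestry matrix shape does not match labels")
        if (self.q < 0).any():
            raise DataError("ancestry proportions must be nonnegative")
        bad = np.where(np.abs(self.q.sum(axis=1) - 1.0) > 1e-6)[0]
        if bad.size:
            raise DataError(
                f"ancestry rows not summing to 1: {[self.strains[i] for i in bad[:5]]}"
            )


def read_ancestry(path: str | Path) -> AncestryMatrix:
    """Read a Q-matrix: header of population names, one row per strain.

    Accepts tab- or whitespace-delimited text with the strain id in the first
    column (the common layout of clustering-program output summaries).
    """
    df = pd.read_csv(path, sep=r"\s+", engine="python")
    first = df.columns[0]
    strains = df[first].astype(str).tolist()
    pops = list(df.columns[1:])
    if not pops:
        raise DataError(f"{path}: no population columns found")
    return AncestryMatrix(strains=strains, populations=pops,
                          q=df[pops].to_numpy(dtype=float))


def write_ancestry(am: AncestryMatrix, path: str | Path) -> None:
    df = pd.DataFrame(am.q, columns=am.populations)
    df.insert(0, "strain_id", am.strains)
    df.to_csv(path, sep="\t", index=False)


def classify_by_ancestry(am: AncestryMatrix,
                         threshold: float = 0.94) -> dict[str, bool]:
    """Admixed iff the largest ancestry proportion is strictly below threshold."""
    if not (0.0 < threshold <= 1.0):
        raise DataError(f"threshold {threshold} outside (0, 1]")
    top = am.q.max(axis=1)
    return {s: bool(t < threshold) for s, t in zip(am.strains, top)}


def concordance(calls_a: dict[str, bool],
                calls_b: dict[str, bool]) -> tuple[int, int, list[str]]:
    """(n_agree, n_total, discordant strains) between two admixed-flag maps."""
    if set(calls_a) != set(calls_b):
        raise DataError("concordance requires identical strain sets")
    discord = sorted(s for s in calls_a if calls_a[s] != calls_b[s])
    return len(calls_a) - len(discord), len(calls_a), discord
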