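"""Per-locus population assignment against a reference panel.

A :class:`PopulationScheme` names the populations, nests some of them into
supergroups (e.g. a "European" supergroup covering the Wine and European Oak
populations), and designates at least two reference strains per population.
At each locus, a query strain is assigned by the well-supported tree groups it
shares with reference strains: a group whose references all come from one
population labels the strain with that population; references spanning
several populations of a single supergroup label it with the supergroup;
groups mixing supergroups are uninformative. Conflicting group labels within
one locus collapse to "undefined" (conservative).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .errors import ConfigError, DataError
from .seqio import Dataset
from .support import SupportedGroups

UNDEFINED = "undefined"
MIXED = "mixed"


@dataclass
class PopulationScheme:
    """Populations, supergroup nesting, and the reference strains per population."""

    populations: list[str]
    supergroups: dict[str, list[str]] = field(default_factory=dict)
    refs: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.populations)) != len(self.populations):
            raise ConfigError("duplicate population ids")
        reserved = {UNDEFINED, MIXED}
        if reserved & set(self.populations) or reserved & set(self.supergroups):
            raise ConfigError(f"labels {sorted(reserved)} are reserved")
        seen: set[str] = set()
        for sg, members in self.supergroups.items():
            if sg in self.populations:
                raise ConfigError(f"supergroup {sg!r} clashes with a population id")
            unknown = set(members) - set(self.populations)
            if unknown:
                raise ConfigError(f"supergroup {sg!r} has unknown members {sorted(unknown)}")
            overlap = seen & set(members)
            if overlap:
                raise ConfigError(f"populations in multiple supergroups: {sorted(overlap)}")
            seen |= set(members)
        all_refs: list[str] = []
        for pop in self.populations:
            r = self.refs.get(pop, [])
            if len(r) < 2:
                raise ConfigError(
                    f"population {pop!r} needs >= 2 reference strains, got {len(r)}"
                )
            all_refs.extend(r)
        if len(set(all_refs)) != len(all_refs):
            raise ConfigError("a strain is listed as reference for multiple populations")
        self._pop_of_ref = {s: p for p, rr in self.refs.items() for s in rr}
        self._super_of = {p: sg for sg, mm in self.supergroups.items() for p in mm}

    # -- lookups ----------------------------------------------------------
    @property
    def reference_strains(self) -> set[str]:
        return set(self._pop_of_ref)

    def population_of_ref(self, strain: str) -> str:
        try:
            return self._pop_of_ref[strain]
        except KeyError:
            raise DataError(f"unknown reference strain {strain!r}") from None

    def supergroup_of(self, population: str) -> str | None:
        return self._super_of.get(population)

    def is_population(self, label: str) -> bool:
        return label in self.populations

    def is_supergroup(self, label: str) -> bool:
        return label in self.supergroups

    def known_label(self, label: str) -> bool:
        return (label == UNDEFINED or self.is_population(label)
                or self.is_supergroup(label))

    # -- serialization ----------------------------------------------------
    @classmethod
    def from_yaml(cls, path: str | Path) -> "PopulationScheme":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        try:
            return cls(
                populations=list(raw["populations"]),
                supergroups={k: list(v) for k, v in (raw.get("supergroups") or {}).items()},
                refs={k: list(v) for k, v in raw["refs"].items()},
            )
        except (KeyError, TypeError) as exc:
            raise ConfigError(f"malformed scheme file {path}: {exc}") from exc

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {"populations": self.populations,
                 "supergroups": self.supergroups,
                 "refs": self.refs},
                fh, sort_keys=False,
            )


def label_of_refset(refs_in_group: set[str], scheme: PopulationScheme) -> str:
    """Label implied by the reference strains found in one supported group.

    All from one population -> that population; from several populations that
    share one supergroup -> the supergroup; spanning supergroups -> "mixed".
    """
    if not refs_in_group:
        raise DataError("empty reference set")
    pops = {scheme.population_of_ref(s) for s in refs_in_group}
    if len(pops) == 1:
        return next(iter(pops))
    supers = {scheme.supergroup_of(p) for p in pops}
    if len(supers) == 1 and None not in supers:
        return next(iter(supers))
    return MIXED


def assign_locus(sg: SupportedGroups, strain: str,
                 scheme: PopulationScheme) -> str:
    """Population / supergroup / "undefined" label for one strain at one locus.

    ``sg`` should already be filtered to the support threshold. Every
    supported group containing the strain and at least one reference strain
    contributes a label via :func:`label_of_refset`; "mixed" labels are
    discarded as uninformative. If the remaining labels are hierarchically
    compatible the most specific one wins; any conflict (or no informative
    group) yields "undefined".
    """
    labels: set[str] = set()
    for group in sg.groups_containing(strain):
        refs = (group & scheme.reference_strains) - {strain}
        if not refs:
            continue
        lab = label_of_refset(refs, scheme)
        if lab != MIXED:
            labels.add(lab)
    if not labels:
        return UNDEFINED
    pops = {l for l in labels if scheme.is_population(l)}
    supers = labels - pops
    if len(pops) > 1:
        return UNDEFINED
    if pops:
        pop = next(iter(pops))
        if supers - {scheme.supergroup_of(pop)}:
            return UNDEFINED
        return pop
    if len(supers) > 1:
        return UNDEFINED
    return next(iter(supers))


def assign_all(dataset: Dataset, scheme: PopulationScheme,
               supports: dict[str, SupportedGroups]) -> pd.DataFrame:
    """Long-format table of per-locus labels for every query strain.

    One row per (query strain, locus it occurs in); reference strains are
    excluded from the output. ``supports`` maps locus id to its (filtered)
    supported groups.
    """
    missing = set(dataset.locus_ids) - set(supports)
    if missing:
        raise DataError(f"no supported groups for loci: {sorted(missing)}")
    queries = set(dataset.query_strains)
    bad = scheme.reference_strains - set(dataset.reference_strains)
    if bad:
        raise DataError(
            f"scheme reference strains absent from dataset metadata: {sorted(bad)}"
        )
    role_clash = queries & scheme.reference_strains
    if role_clash:
        raise DataError(
            f"strains listed as query in metadata but reference in scheme: "
            f"{sorted(role_clash)}"
        )
    rows = []
    for aln in dataset.loci:
        sg = supports[aln.locus_id]
        for strain in aln.strains:
            if strain not in queries:
                continue
            rows.append({
                "strain_id": strain,
                "locus_id": aln.locus_id,
                "label": assign_locus(sg, strain, scheme),
            })
    return pd.DataFrame(rows, columns=["strain_id", "locus_id", "label"])


def write_assignments(assignments: pd.DataFrame, path: str | Path) -> None:
    assignments.to_csv(path, sep="\t", index=False)


def read_assignments(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    need = {"strain_id", "locus_id", "label"}
    if need - set(df.columns):
        raise DataError(f"assignments file missing columns {sorted(need - set(df.columns))}")
    return df
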