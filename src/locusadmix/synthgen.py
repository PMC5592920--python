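"""Synthetic multi-locus datasets with known structure and planted admixture.

The generator emulates K diverged haploid populations sampled at several
unlinked loci, with between-population divergence well above within-population
diversity. Populations sit on a star phylogeny (independent stems from one
ancestral sequence); populations that share a supergroup instead share the
first half of their stem, so intermediate supergroup-level signal arises
naturally. Mutation uses a Jukes-Cantor kernel (a mutated site picks one of
the three other bases uniformly), deliberately different from the F84 model
used for inference. Admixed query strains take donor-population haplotypes at
designated loci; a truth table records every strain's per-locus source
population.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .admixcall import AncestryMatrix
from .errors import ConfigError
from .popassign import PopulationScheme
from .seqio import Dataset, LocusAlignment, write_alignment, write_metadata

#: the default seven-population / two-supergroup layout of the study system
DEFAULT_POPULATIONS = [
    "Malaysia", "Sake", "WestAfrica", "Wine", "EuropeanOak",
    "PennsylvaniaOak", "NorthCarolinaOak",
]
DEFAULT_SUPERGROUPS = {
    "European": ["Wine", "EuropeanOak"],
    "USA": ["PennsylvaniaOak", "NorthCarolinaOak"],
}

_BASES = "ACGT"


@dataclass(frozen=True)
class AdmixtureEvent:
    """One planted introgression: ``strain`` (of ``base_pop``) carries
    ``donor_pop`` haplotypes at the given locus indices."""

    strain: str
    base_pop: str
    donor_pop: str
    loci: tuple[int, ...]


@dataclass
class SimConfig:
    """Parameters of one synthetic dataset.

    ``d_between`` is the expected substitutions/site on each population's
    stem; ``d_within`` the per-strain tip diversity. Defaults mirror the
    study conditions: seven populations, two supergroups, sixteen loci,
    two reference strains per population.
    """

    populations: list[str] = field(default_factory=lambda: list(DEFAULT_POPULATIONS))
    supergroups: dict[str, list[str]] = field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_SUPERGROUPS.items()})
    n_loci: int = 16
    locus_length: int = 800
    d_between: float = 0.10
    d_within: float = 0.005
    n_refs_per_pop: int = 2
    n_queries_per_pop: int = 2
    admixture_events: list[AdmixtureEvent] = field(default_factory=list)
    habitat_rule: dict[str, str] = field(default_factory=lambda: {
        "reference": "oak_or_other_trees",
        "query": "oak_or_other_trees",
        "admixed": "fruit_or_flower",
    })
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.d_within < self.d_between < 0.75):
            raise ConfigError(
                "require 0 <= d_within < d_between < 0.75 "
                f"(got {self.d_within}, {self.d_between})"
            )
        if self.n_loci < 1 or self.locus_length < 1:
            raise ConfigError("n_loci and locus_length must be positive")
        if self.n_refs_per_pop < 2:
            raise ConfigError("need >= 2 reference strains per population")
        pops = set(self.populations)
        for ev in self.admixture_events:
            if ev.base_pop not in pops or ev.donor_pop not in pops:
                raise ConfigError(f"admixture event {ev} names unknown population")
            if ev.base_pop == ev.donor_pop:
                raise ConfigError(f"admixture event {ev}: donor equals base")
            if len(set(ev.loci)) != len(ev.loci) or any(
                not 0 <= i < self.n_loci for i in ev.loci
            ):
                raise ConfigError(f"admixture event {ev}: bad locus indices")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        events = [AdmixtureEvent(e["strain"], e["base_pop"], e["donor_pop"],
                                 tuple(e["loci"]))
                  for e in raw.pop("admixture_events", [])]
        try:
            return cls(admixture_events=events, **raw)
        except TypeError as exc:
            raise ConfigError(f"malformed simulation config {path}: {exc}") from exc


@dataclass
class TruthTable:
    """Ground truth of a simulated dataset."""

    base_pop: dict[str, str]                      # strain -> base population
    source: dict[tuple[str, str], str]            # (strain, locus) -> source pop
    habitat: dict[str, str]
    role: dict[str, str]                          # reference | query
    locus_ids: list[str]

    @property
    def admixed_strains(self) -> set[str]:
        out = set()
        for (s, _loc), pop in self.source.items():
            if pop != self.base_pop[s]:
                out.add(s)
        return out

    def n_donor_loci(self, strain: str) -> int:
        return sum(1 for (s, _l), p in self.source.items()
                   if s == strain and p != self.base_pop[s])

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"strain_id": s, "locus_id": loc, "base_pop": self.base_pop[s],
             "source_pop": pop, "habitat": self.habitat[s], "role": self.role[s]}
            for (s, loc), pop in sorted(self.source.items())
        ]
        return pd.DataFrame(rows)


def _mutate(seq: np.ndarray, p: float, rng: np.random.Generator) -> np.ndarray:
    """Jukes-Cantor kernel: each site mutates with prob p to another base."""
    out = seq.copy()
    hit = rng.random(seq.size) < p
    if hit.any():
        # add 1..3 mod 4: uniform over the three other bases
        out[hit] = (out[hit] + rng.integers(1, 4, size=int(hit.sum()))) % 4
    return out


def _decode(seq: np.ndarray) -> str:
    return "".join(_BASES[b] for b in seq)


def strain_names(cfg: SimConfig) -> tuple[dict[str, list[str]], dict[str, list[str]]]:
    """(refs per population, queries per population) with deterministic names."""
    refs = {p: [f"{p}_ref{i+1}" for i in range(cfg.n_refs_per_pop)]
            for p in cfg.populations}
    queries = {p: [f"{p}_q{i+1}" for i in range(cfg.n_queries_per_pop)]
               for p in cfg.populations}
    for ev in cfg.admixture_events:
        if ev.strain not in queries[ev.base_pop]:
            queries[ev.base_pop].append(ev.strain)
    return refs, queries


def simulate(cfg: SimConfig) -> tuple[Dataset, TruthTable]:
    """Draw one dataset under the configured population model."""
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    refs, queries = strain_names(cfg)
    events_by_strain: dict[str, AdmixtureEvent] = {}
    for ev in cfg.admixture_events:
        if ev.strain in events_by_strain:
            raise ConfigError(f"strain {ev.strain!r} has multiple admixture events")
        events_by_strain[ev.strain] = ev

    super_of = {p: sg for sg, mm in cfg.supergroups.items() for p in mm}
    locus_ids = [f"L{i+1:02d}" for i in range(cfg.n_loci)]
    loci: list[LocusAlignment] = []
    source: dict[tuple[str, str], str] = {}

    for li, locus_id in enumerate(locus_ids):
        ancestral = rng.integers(0, 4, size=cfg.locus_length).astype(np.int8)
        # supergroups share the first half of the stem
        sg_seq = {sg: _mutate(ancestral, cfg.d_between / 2, rng)
                  for sg in cfg.supergroups}
        pop_seq: dict[str, np.ndarray] = {}
        for pop in cfg.populations:
            if pop in super_of:
                pop_seq[pop] = _mutate(sg_seq[super_of[pop]],
                                       cfg.d_between / 2, rng)
            else:
                pop_seq[pop] = _mutate(ancestral, cfg.d_between, rng)

        strains: list[str] = []
        seqs: list[str] = []
        for pop in cfg.populations:
            for strain in refs[pop] + queries[pop]:
                ev = events_by_strain.get(strain)
                src = (ev.donor_pop if ev is not None and li in ev.loci else pop)
                seq = _mutate(pop_seq[src], cfg.d_within, rng)
                strains.append(strain)
                seqs.append(_decode(seq))
                source[(strain, locus_id)] = src
        loci.append(LocusAlignment(locus_id, strains, seqs))

    base_pop: dict[str, str] = {}
    habitat: dict[str, str] = {}
    role: dict[str, str] = {}
    meta_rows = []
    for pop in cfg.populations:
        for strain in refs[pop] + queries[pop]:
            is_ref = strain in refs[pop]
            base_pop[strain] = pop
            role[strain] = "reference" if is_ref else "query"
            if is_ref:
                hab = cfg.habitat_rule.get("reference", "oak_or_other_trees")
            elif strain in events_by_strain:
                hab = cfg.habitat_rule.get("admixed", "fruit_or_flower")
            else:
                hab = cfg.habitat_rule.get("query", "oak_or_other_trees")
            habitat[strain] = hab
            meta_rows.append({
                "strain_id": strain, "habitat": hab, "region": pop,
                "role": role[strain],
                "ref_population": pop if is_ref else "",
            })
    meta = pd.DataFrame(meta_rows)
    dataset = Dataset(loci=loci, meta=meta)
    truth = TruthTable(base_pop=base_pop, source=source, habitat=habitat,
                       role=role, locus_ids=locus_ids)
    return dataset, truth


def scheme_from_config(cfg: SimConfig) -> PopulationScheme:
    """The PopulationScheme matching a simulation's generated reference strains."""
    refs, _queries = strain_names(cfg)
    return PopulationScheme(
        populations=list(cfg.populations),
        supergroups={k: list(v) for k, v in cfg.supergroups.items()},
        refs={p: list(r) for p, r in refs.items()},
    )


def pseudo_ancestry(truth: TruthTable,
                    populations: list[str] | None = None) -> AncestryMatrix:
    """Ancestry matrix from truth: per-strain fraction of loci per source pop.

    Covers query strains only (references are not assessed for admixture).
    Exercises the ancestry-threshold classifier without an external
    clustering run.
    """
    if populations is None:
        populations = sorted(set(truth.base_pop.values()))
    strains = sorted(s for s, r in truth.role.items() if r == "query")
    q = np.zeros((len(strains), len(populations)))
    pidx = {p: j for j, p in enumerate(populations)}
    n_loci = len(truth.locus_ids)
    for i, s in enumerate(strains):
        for loc in truth.locus_ids:
            q[i, pidx[truth.source[(s, loc)]]] += 1.0 / n_loci
    return AncestryMatrix(strains=strains, populations=populations, q=q)


def write_simulation(dataset: Dataset, truth: TruthTable,
                     scheme: PopulationScheme, outdir: str | Path) -> None:
    """Write per-locus FASTA, metadata TSV, scheme YAML and truth TSV."""
    outdir = Path(outdir)
    (outdir / "loci").mkdir(parents=True, exist_ok=True)
    for aln in dataset.loci:
        write_alignment(aln, outdir / "loci" / f"{aln.locus_id}.fa")
    write_metadata(dataset.meta, outdir / "metadata.tsv")
    scheme.to_yaml(outdir / "scheme.yaml")
    truth.to_frame().to_csv(outdir / "truth.tsv", sep="\t", index=False)
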