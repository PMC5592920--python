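"""Reading, validating, masking and concatenating per-locus alignments.

Input data are haploid consensus sequences, one pre-aligned FASTA file per
locus. Sequences are uppercased on read and every character outside
``{A, C, G, T, -}`` (IUPAC ambiguity codes, quality-masked bases, ``?``) is
collapsed to ``N`` and treated as missing downstream. Strain metadata is a
TSV with columns ``strain_id / habitat / region / role / ref_population``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .errors import DataError

#: The five habitat classes used for the habitat-association tables.
HABITATS = (
    "fruit_or_flower",
    "human_infection",
    "fermentation",
    "soil_or_unknown",
    "oak_or_other_trees",
)

#: Internal integer encoding of the alignment alphabet. 4 = missing (N or -).
_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4, "-": 4}

# translate anything that is not A/C/G/T/- to N (after uppercasing)
_MASK_RE = re.compile(r"[^ACGT-]")


def _normalize(seq: str) -> str:
    return _MASK_RE.sub("N", seq.upper())


@dataclass
class LocusAlignment:
    """One aligned locus: ordered (strain, sequence) pairs of equal length.

    Sequences are strings over ``{A, C, G, T, N, -}``. ``partitions`` records
    0-based half-open locus boundaries when the alignment is a concatenation.
    """

    locus_id: str
    strains: list[str]
    seqs: list[str]
    partitions: list[tuple[str, int, int]] | None = None

    def __post_init__(self) -> None:
        if not self.seqs:
            raise DataError(f"locus {self.locus_id!r}: empty alignment")
        if len(self.strains) != len(self.seqs):
            raise DataError(f"locus {self.locus_id!r}: strains/seqs length mismatch")
        if len(set(self.strains)) != len(self.strains):
            dups = sorted({s for s in self.strains if self.strains.count(s) > 1})
            raise DataError(f"locus {self.locus_id!r}: duplicate strain ids {dups}")
        L = len(self.seqs[0])
        if L == 0:
            raise DataError(f"locus {self.locus_id!r}: zero-length sequences")
        for strain, seq in zip(self.strains, self.seqs):
            if len(seq) != L:
                raise DataError(
                    f"locus {self.locus_id!r}: sequence length mismatch for "
                    f"{strain!r} ({len(seq)} != {L})"
                )
            bad = set(seq) - set("ACGTN-")
            if bad:
                raise DataError(
                    f"locus {self.locus_id!r}: invalid characters {sorted(bad)} "
                    f"in {strain!r}"
                )

    @property
    def length(self) -> int:
        return len(self.seqs[0])

    @property
    def n_strains(self) -> int:
        return len(self.strains)

    def sequence(self, strain: str) -> str:
        try:
            return self.seqs[self.strains.index(strain)]
        except ValueError:
            raise DataError(f"strain {strain!r} not in locus {self.locus_id!r}") from None

    def subset(self, strains: list[str]) -> "LocusAlignment":
        """Alignment restricted to ``strains``, in the given order."""
        return LocusAlignment(self.locus_id, list(strains),
                              [self.sequence(s) for s in strains])

    def encoded(self) -> np.ndarray:
        """(n_strains, length) uint8 matrix; A,C,G,T -> 0..3, N/- -> 4."""
        out = np.empty((len(self.seqs), self.length), dtype=np.uint8)
        table = np.full(128, 4, dtype=np.uint8)
        for ch, v in _CODE.items():
            table[ord(ch)] = v
        for i, seq in enumerate(self.seqs):
            out[i] = table[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
        return out


def read_alignment(path: str | Path, locus_id: str | None = None) -> LocusAlignment:
    """Read one locus from a FASTA file.

    The strain id is the FASTA id up to the first whitespace; the locus id
    defaults to the file stem. Sequences are uppercased and any character
    outside ``{A, C, G, T, -}`` becomes ``N``.
    """
    path = Path(path)
    if locus_id is None:
        locus_id = path.stem
    strains: list[str] = []
    seqs: list[str] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        strains.append(rec.id)
        seqs.append(_normalize(str(rec.seq)))
    if len(strains) < 2:
        raise DataError(f"{path}: FASTA must contain at least 2 records")
    return LocusAlignment(locus_id, strains, seqs)


def write_alignment(aln: LocusAlignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        for strain, seq in zip(aln.strains, aln.seqs):
            fh.write(f">{strain}\n{seq}\n")


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read the strain metadata TSV and validate it.

    Columns: strain_id, habitat, region, role (reference|query),
    ref_population (population id for references, empty for queries).
    """
    meta = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"strain_id", "habitat", "region", "role", "ref_population"}
    missing = required - set(meta.columns)
    if missing:
        raise DataError(f"metadata missing columns: {sorted(missing)}")
    validate_metadata(meta)
    return meta


def validate_metadata(meta: pd.DataFrame) -> None:
    if meta["strain_id"].duplicated().any():
        dups = meta.loc[meta["strain_id"].duplicated(), "strain_id"].tolist()
        raise DataError(f"duplicate strain ids in metadata: {dups}")
    bad_hab = sorted(set(meta["habitat"]) - set(HABITATS))
    if bad_hab:
        raise DataError(
            f"unknown habitat classes {bad_hab}; expected one of {list(HABITATS)}"
        )
    bad_role = sorted(set(meta["role"]) - {"reference", "query"})
    if bad_role:
        raise DataError(f"unknown roles {bad_role}; expected reference|query")
    for _, row in meta.iterrows():
        is_ref = row["role"] == "reference"
        has_pop = bool(row["ref_population"])
        if is_ref != has_pop:
            raise DataError(
                f"strain {row['strain_id']!r}: role={row['role']!r} but "
                f"ref_population={row['ref_population']!r} (references and only "
                "references carry a ref_population)"
            )


def write_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, sep="\t", index=False)


@dataclass
class Dataset:
    """Per-locus alignments plus strain metadata.

    Invariants checked on construction: every strain in the metadata appears
    in at least one locus; loci contain no strains absent from the metadata;
    every reference strain is present, with at least one unambiguous base, at
    every locus. Query strains may be missing from individual loci (those loci
    then yield no assignment for them).
    """

    loci: list[LocusAlignment] = field(default_factory=list)
    meta: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if not self.loci:
            raise DataError("dataset has no loci")
        ids = [a.locus_id for a in self.loci]
        if len(set(ids)) != len(ids):
            raise DataError("duplicate locus ids in dataset")
        validate_metadata(self.meta)
        meta_strains = set(self.meta["strain_id"])
        in_loci: set[str] = set()
        for aln in self.loci:
            in_loci |= set(aln.strains)
            unknown = set(aln.strains) - meta_strains
            if unknown:
                raise DataError(
                    f"locus {aln.locus_id!r}: strains missing from metadata: "
                    f"{sorted(unknown)}"
                )
        orphan = meta_strains - in_loci
        if orphan:
            raise DataError(f"strains in metadata but in no locus: {sorted(orphan)}")
        refs = self.meta.loc[self.meta["role"] == "reference", "strain_id"]
        for aln in self.loci:
            for ref in refs:
                if ref not in aln.strains:
                    raise DataError(
                        f"reference strain {ref!r} missing from locus "
                        f"{aln.locus_id!r}"
                    )
                if not set(aln.sequence(ref)) & set("ACGT"):
                    raise DataError(
                        f"reference strain {ref!r} is entirely missing data at "
                        f"locus {aln.locus_id!r}"
                    )

    @property
    def locus_ids(self) -> list[str]:
        return [a.locus_id for a in self.loci]

    def locus(self, locus_id: str) -> LocusAlignment:
        for aln in self.loci:
            if aln.locus_id == locus_id:
                return aln
        raise DataError(f"no locus {locus_id!r} in dataset")

    @property
    def reference_strains(self) -> list[str]:
        return self.meta.loc[self.meta["role"] == "reference", "strain_id"].tolist()

    @property
    def query_strains(self) -> list[str]:
        return self.meta.loc[self.meta["role"] == "query", "strain_id"].tolist()


def read_dataset(loci_dir: str | Path, metadata_path: str | Path) -> Dataset:
    """Read every ``*.fa``/``*.fasta`` file in ``loci_dir`` plus the metadata."""
    loci_dir = Path(loci_dir)
    paths = sorted(loci_dir.glob("*.fa")) + sorted(loci_dir.glob("*.fasta"))
    if not paths:
        raise DataError(f"no .fa/.fasta files in {loci_dir}")
    loci = [read_alignment(p) for p in paths]
    return Dataset(loci=loci, meta=read_metadata(metadata_path))


def concatenate(loci: list[LocusAlignment],
                strain_order: list[str] | None = None) -> LocusAlignment:
    """Join loci end-to-end into one long alignment.

    Every strain in ``strain_order`` (default: the first locus's strains)
    must be present in every locus. Locus boundaries are recorded in the
    result's ``partitions`` as 0-based half-open (locus_id, start, end).
    """
    if not loci:
        raise DataError("no loci to concatenate")
    if strain_order is None:
        strain_order = list(loci[0].strains)
    for aln in loci:
        missing = [s for s in strain_order if s not in aln.strains]
        if missing:
            raise DataError(
                f"strain {missing[0]!r} missing from locus {aln.locus_id!r}"
            )
    parts: list[tuple[str, int, int]] = []
    pos = 0
    for aln in loci:
        parts.append((aln.locus_id, pos, pos + aln.length))
        pos += aln.length
    seqs = ["".join(aln.sequence(s) for aln in loci) for s in strain_order]
    return LocusAlignment("concat", list(strain_order), seqs, partitions=parts)


def write_partitions(aln: LocusAlignment, path: str | Path) -> None:
    if aln.partitions is None:
        raise DataError("alignment has no partition information")
    pd.DataFrame(aln.partitions, columns=["locus_id", "start", "end"]).to_csv(
        path, sep="\t", index=False
    )


def segregating_sites(aln: LocusAlignment) -> int:
    """Number of columns with >= 2 distinct bases among A/C/G/T (N, - missing)."""
    X = aln.encoded()
    n_seg = 0
    for col in X.T:
        bases = np.unique(col[col < 4])
        if bases.size >= 2:
            n_seg += 1
    return n_seg
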