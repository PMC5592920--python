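import numpy as np
import pandas as pd
import pytest

from locusadmix.errors import DataError
from locusadmix.seqio import (
    Dataset,
    LocusAlignment,
    concatenate,
    read_alignment,
    read_metadata,
    segregating_sites,
    write_alignment,
)


def _write_fasta(path, records):
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n{seq}\n")


class TestReadAlignment:
    def test_masks_ambiguity_codes_and_uppercases(self, tmp_path):
        p = tmp_path / "CEN4.fa"
        _write_fasta(p, [("a", "acgR" + "A" * 96), ("b", "ACGT" + "a" * 96),
                         ("c", "tcg-" + "G" * 96)])
        aln = read_alignment(p)
        assert aln.locus_id == "CEN4"
        assert aln.seqs[0].startswith("ACGN")
        assert aln.seqs[1].startswith("ACGT")
        assert aln.seqs[2].startswith("TCG-")
        assert aln.length == 100

    def test_strain_id_is_token_before_whitespace(self, tmp_path):
        p = tmp_path / "x.fa"
        _write_fasta(p, [("s1 some description", "ACGT"), ("s2", "ACGT")])
        assert read_alignment(p).strains == ["s1", "s2"]

    def test_ragged_lengths_rejected(self, tmp_path):
        p = tmp_path / "x.fa"
        _write_fasta(p, [("a", "A" * 100), ("b", "A" * 99)])
        with pytest.raises(DataError, match="length"):
            read_alignment(p)

    def test_duplicate_strain_rejected(self, tmp_path):
        p = tmp_path / "x.fa"
        _write_fasta(p, [("a", "ACGT"), ("a", "ACGT")])
        with pytest.raises(DataError, match="duplicate"):
            read_alignment(p)

    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "x.fa"
        p.write_text("")
        with pytest.raises(DataError):
            read_alignment(p)

    def test_round_trip_identity(self, tmp_path):
        aln = LocusAlignment("L1", ["a", "b", "c"],
                             ["ACGTN-", "TTTTTT", "A-N-GT"])
        write_alignment(aln, tmp_path / "rt.fa")
        back = read_alignment(tmp_path / "rt.fa", locus_id="L1")
        assert back.strains == aln.strains and back.seqs == aln.seqs


class TestConcatenate:
    def test_lengths_add(self):
        a = LocusAlignment("L1", ["x", "y"], ["A" * 120, "C" * 120])
        b = LocusAlignment("L2", ["y", "x"], ["G" * 130, "T" * 130])
        cat = concatenate([a, b], ["x", "y"])
        assert cat.length == 250
        assert cat.sequence("x") == "A" * 120 + "T" * 130
        assert cat.partitions == [("L1", 0, 120), ("L2", 120, 250)]

    def test_single_locus_identity(self):
        a = LocusAlignment("L1", ["x", "y"], ["ACGT", "TGCA"])
        cat = concatenate([a])
        assert cat.strains == a.strains and cat.seqs == a.seqs

    def test_missing_strain_names_strain_and_locus(self):
        a = LocusAlignment("L1", ["x", "y"], ["ACGT", "TGCA"])
        b = LocusAlignment("L2", ["x", "z"], ["ACGT", "ACGT"])
        with pytest.raises(DataError, match="'y'.*'L2'"):
            concatenate([a, b], ["x", "y"])


class TestSegregatingSites:
    @pytest.mark.parametrize("seqs,expected", [
        (["AAAA", "AAAA", "AAAA"], 0),
        (["AAAA", "AATA"], 1),
        (["AAC", "AAC", "NAA"], 1),   # col {A,A,N} not seg; col {C,C,A} seg
        (["A-T", "ANT", "ACT"], 0),   # col {-,N,C} has one base only
    ])
    def test_definition(self, seqs, expected):
        names = [f"s{i}" for i in range(len(seqs))]
        assert segregating_sites(LocusAlignment("L", names, seqs)) == expected

    def test_matches_per_column_brute_force(self):
        rng = np.random.default_rng(3)
        chars = np.array(list("ACGTN-"))
        seqs = ["".join(rng.choice(chars, size=60, p=[.22,.22,.22,.22,.06,.06]))
                for _ in range(5)]
        aln = LocusAlignment("L", [f"s{i}" for i in range(5)], seqs)
        brute = sum(
            1 for col in zip(*seqs)
            if len({c for c in col if c in "ACGT"}) >= 2
        )
        assert segregating_sites(aln) == brute

    def test_additive_over_concatenation(self):
        a = LocusAlignment("L1", ["x", "y"], ["AACC", "ATCC"])
        b = LocusAlignment("L2", ["x", "y"], ["GGG", "GCG"])
        cat = concatenate([a, b], ["x", "y"])
        assert segregating_sites(cat) == segregating_sites(a) + segregating_sites(b)


class TestMetadataAndDataset:
    def _meta(self, rows):
        return pd.DataFrame(rows, columns=["strain_id", "habitat", "region",
                                           "role", "ref_population"])

    def test_read_and_validate(self, tmp_path):
        p = tmp_path / "meta.tsv"
        self._meta([
            ("r1", "oak_or_other_trees", "EU", "reference", "Wine"),
            ("q1", "fruit_or_flower", "EU", "query", ""),
        ]).to_csv(p, sep="\t", index=False)
        meta = read_metadata(p)
        assert list(meta["strain_id"]) == ["r1", "q1"]

    def test_unknown_habitat_rejected(self, tmp_path):
        p = tmp_path / "meta.tsv"
        self._meta([("q1", "vineyard", "EU", "query", "")]).to_csv(
            p, sep="\t", index=False)
        with pytest.raises(DataError, match="habitat"):
            read_metadata(p)

    def test_reference_without_population_rejected(self, tmp_path):
        p = tmp_path / "meta.tsv"
        self._meta([("r1", "fermentation", "EU", "reference", "")]).to_csv(
            p, sep="\t", index=False)
        with pytest.raises(DataError, match="ref_population"):
            read_metadata(p)

    def test_reference_must_be_in_every_locus(self):
        meta = self._meta([
            ("r1", "oak_or_other_trees", "EU", "reference", "Wine"),
            ("q1", "fruit_or_flower", "EU", "query", ""),
        ])
        loci = [
            LocusAlignment("L1", ["r1", "q1"], ["ACGT", "ACGT"]),
            LocusAlignment("L2", ["q1", "x"], ["ACGT", "ACGT"]),
        ]
        with pytest.raises(DataError):
            Dataset(loci=loci, meta=meta)

    def test_query_may_be_missing_from_a_locus(self):
        meta = self._meta([
            ("r1", "oak_or_other_trees", "EU", "reference", "Wine"),
            ("q1", "fruit_or_flower", "EU", "query", ""),
            ("q2", "fruit_or_flower", "EU", "query", ""),
        ])
        loci = [
            LocusAlignment("L1", ["r1", "q1", "q2"], ["ACGT"] * 3),
            LocusAlignment("L2", ["r1", "q1"], ["ACGT"] * 2),
        ]
        ds = Dataset(loci=loci, meta=meta)
        assert ds.query_strains == ["q1", "q2"]
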