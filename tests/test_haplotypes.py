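"""Haplotype collapsing, OTU conservation and label codec round-trips."""

import io

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from barcodetree import BarcodeRecord, collapse, decode_label, encode_label
from barcodetree.haplotypes import (
    LabelCodec,
    sanitize_name,
    write_otu_fasta,
    write_otu_table,
)
from barcodetree.simulate import _SIM_LOCALITIES, default_sim_codec


def _rec(rid, seq, species="Limnephilus sp.", country="Finland", region=""):
    return BarcodeRecord(
        rid, seq, species_name=species, country=country, region=region
    )


class TestCollapse:
    def test_identical_sequences_merge(self):
        otus = collapse([_rec("a", "ACGT"), _rec("b", "acgt")])
        assert len(otus) == 1
        assert otus[0].members == ["a", "b"]

    def test_single_site_difference_separates(self):
        otus = collapse([_rec("a", "ACGT"), _rec("b", "ACGA")])
        assert len(otus) == 2

    def test_ambiguity_codes_do_not_merge(self):
        otus = collapse([_rec("a", "ACGT"), _rec("b", "ACGN")])
        assert len(otus) == 2

    def test_length_difference_never_merges(self):
        otus = collapse([_rec("a", "ACGT"), _rec("b", "ACGTA")])
        assert len(otus) == 2

    def test_grouping_matches_brute_force_and_counts_localities(self):
        records = [
            _rec("a1", "AAAA", country="Finland"),
            _rec("a2", "AAAA", country="Canada", region="Ontario"),
            _rec("b1", "CCCC", country="Finland"),
        ]
        otus = collapse(records)
        # brute force: group record ids by sequence string
        expected = {}
        for r in records:
            expected.setdefault(r.sequence.upper(), []).append(r.record_id)
        assert {o.sequence: o.members for o in otus} == expected
        a = next(o for o in otus if o.sequence == "AAAA")
        assert sum(a.locality_counts.values()) == 2
        assert a.locality_counts[("Canada", "Ontario")] == 1

    def test_first_seen_order_and_dense_ids(self):
        otus = collapse([_rec("z", "TTTT"), _rec("a", "AAAA"), _rec("m", "TTTT")])
        assert [o.members[0] for o in otus] == ["z", "a"]
        assert [o.otu_id for o in otus] == ["OTU0001", "OTU0002"]

    @given(
        st.lists(
            st.tuples(
                st.sampled_from(["AAAA", "AAAC", "AACC", "ACCC", "CCCC"]),
                st.sampled_from(_SIM_LOCALITIES),
            ),
            max_size=40,
        )
    )
    @settings(max_examples=100, deadline=None)
    def test_conservation_property(self, rows):
        records = [
            _rec(f"r{i}", seq, country=c, region=rg)
            for i, (seq, (c, rg)) in enumerate(rows)
        ]
        otus = collapse(records)
        assert sum(o.n_members for o in otus) == len(records)
        assert sum(
            n for o in otus for n in o.locality_counts.values()
        ) == len(records)
        seqs = [o.sequence for o in otus]
        assert len(seqs) == len(set(seqs))


class TestLabelCodec:
    def test_single_locality_label(self, codec):
        (otu,) = collapse([_rec("a", "ACGT", species="Agrypnia obsoleta")])
        assert encode_label(otu, codec) == "Agrypnia_obsoleta_FIN_1"

    def test_big7_country_gets_region_code(self, codec):
        otus = collapse(
            [
                _rec(f"r{i}", "ACGT", species="Chimarra minima",
                     country="Canada", region="Ontario")
                for i in range(3)
            ]
        )
        label = encode_label(otus[0], codec)
        assert "CAN" in label and "ON" in label and label.endswith("3")

    def test_every_locality_is_represented(self, codec):
        records = [
            _rec("a", "ACGT", country="Canada", region="Ontario"),
            _rec("b", "ACGT", country="Canada", region="Ontario"),
            _rec("c", "ACGT", country="Finland"),
        ]
        (otu,) = collapse(records)
        label = encode_label(otu, codec)
        assert "CAN_ON_2" in label and "FIN_1" in label

    def test_decode_example(self, codec):
        assert decode_label("Agrypnia_obsoleta_FIN_1", codec) == (
            "Agrypnia obsoleta",
            [(("Finland", ""), 1)],
        )

    def test_malformed_label_rejected(self, codec):
        with pytest.raises(ValueError):
            decode_label("___", codec)
        with pytest.raises(ValueError):
            decode_label("Name_FIN", codec)  # missing count

    def test_unknown_country_is_a_hard_error(self, codec):
        (otu,) = collapse([_rec("a", "ACGT", country="Atlantis")])
        with pytest.raises(KeyError, match="Atlantis"):
            encode_label(otu, codec)

    def test_species_name_conflict_gets_marker(self, codec):
        records = [
            _rec("a", "ACGT", species="Agrypnia czerskyi"),
            _rec("b", "ACGT", species="Agrypnia czerskyi"),
            _rec("c", "ACGT", species="Agrypnia ulmeri"),
        ]
        (otu,) = collapse(records)
        name, conflict = otu.majority_species()
        assert name == "Agrypnia czerskyi" and conflict
        assert "-cf" in encode_label(otu, codec)

    def test_sanitization_is_newick_safe(self):
        assert sanitize_name("Chimarra (s.l.) n. sp.") == "Chimarra_-s.l.-_n._sp."
        for ch in " ():,;'\"":
            assert ch not in sanitize_name(f"x{ch}y")

    @given(
        species=st.sampled_from(
            ["Agrypnia obsoleta", "Lype diversa", "Chimarra minima"]
        ),
        rows=st.lists(
            st.tuples(
                st.sampled_from(_SIM_LOCALITIES),
                st.integers(min_value=1, max_value=9),
            ),
            min_size=1,
            max_size=4,
            unique_by=lambda t: t[0],
        ),
    )
    @settings(max_examples=150, deadline=None)
    def test_encode_decode_roundtrip(self, species, rows):
        codec = default_sim_codec()
        records = []
        i = 0
        for (country, region), count in rows:
            for _ in range(count):
                records.append(
                    _rec(f"r{i}", "ACGT", species=species,
                         country=country, region=region)
                )
                i += 1
        (otu,) = collapse(records)
        label = encode_label(otu, codec)
        name, localities = decode_label(label, codec)
        assert name == species
        assert dict(localities) == otu.locality_counts


class TestBatchLabels:
    def test_colliding_base_labels_get_suffixes_and_still_decode(self, codec):
        from barcodetree.haplotypes import encode_labels

        records = [
            _rec("a", "ACGT", species="Lype diversa"),
            _rec("b", "ACGA", species="Lype diversa"),
            _rec("c", "ACGC", species="Lype diversa"),
        ]
        otus = collapse(records)
        labels = encode_labels(otus, codec)
        assert len(set(labels.values())) == 3
        assert labels["OTU0002"].endswith(".2")
        for label in labels.values():
            name, loc = decode_label(label, codec)
            assert name == "Lype diversa"
            assert dict(loc) == {("Finland", ""): 1}


class TestWriters:
    def test_otu_table_and_fasta(self, toy_records, codec, tmp_path):
        otus = collapse(toy_records)
        table = tmp_path / "otus.tsv"
        fasta = tmp_path / "otus.fasta"
        write_otu_table(otus, str(table), codec)
        write_otu_fasta(otus, str(fasta), codec)
        lines = table.read_text().splitlines()
        assert lines[0].split("\t") == ["otu_id", "label", "n_members", "member_ids"]
        assert len(lines) == 1 + len(otus)
        assert fasta.read_text().count(">") == len(otus)
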