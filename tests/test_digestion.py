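"""Tryptic digestion: Keil-rule cleavage, missed cleavages, statistics.

The digest is checked three ways: against hand-derived examples, against a
brute-force oracle that enumerates every substring with valid cut boundaries,
and against pyteomics' cleavage machinery driven by the same rule.
"""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from pyteomics import parser as pyt_parser

from proteodiff.digestion import (
    DigestionParams,
    cleavage_sites,
    digest,
    digest_database,
    filter_by_length,
    peptide_to_proteins,
    redundancy_stats,
)
from proteodiff.io_formats import ProteinRecord

from conftest import make_db

AA = "ACDEFGHIKLMNPQRSTVWY"
sequences = st.text(alphabet=AA, min_size=1, max_size=50)


def brute_force_digest(seq, mc, min_length=None, max_length=None):
    """Oracle: every substring whose boundaries are termini or valid cuts and
    which spans at most ``mc`` internal cut sites."""
    internal = [i for i in range(1, len(seq)) if seq[i - 1] in "KR" and seq[i] != "P"]
    boundaries = sorted({0, len(seq), *internal})
    out = []
    for a in boundaries:
        for b in boundaries:
            if b <= a:
                continue
            if sum(1 for c in internal if a < c < b) > mc:
                continue
            length = b - a
            if min_length is not None and length < min_length:
                continue
            if max_length is not None and length > max_length:
                continue
            out.append((a + 1, b, seq[a:b]))
    return sorted(out)


def as_tuples(occurrences):
    return sorted((o.start, o.end, o.sequence) for o in occurrences)


class TestCleavageSites:
    @pytest.mark.parametrize(
        "seq, sites",
        [
            ("AAAA", []),
            ("AKRPCK", [2]),  # R blocked by P; terminal K never cuts
            ("MKWVR", [2]),
            ("KRKR", [1, 2, 3]),
            ("KPKP", []),  # every site suppressed
        ],
    )
    def test_examples(self, seq, sites):
        assert cleavage_sites(seq) == sites

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            cleavage_sites("")

    def test_ambiguity_codes_are_inert(self):
        # B/X/Z/U/O neither cut nor suppress
        assert cleavage_sites("AXBKZU") == [4]
        assert cleavage_sites("KXKB") == [1, 3]


class TestDigest:
    @pytest.mark.parametrize(
        "seq, mc, min_length, expected",
        [
            ("AAAA", 0, None, [(1, 4, "AAAA")]),
            ("AKRPCK", 0, None, [(1, 2, "AK"), (3, 6, "RPCK")]),
            ("MKWVR", 1, None, [(1, 2, "MK"), (1, 5, "MKWVR"), (3, 5, "WVR")]),
            ("MKWVR", 0, 7, []),
        ],
    )
    def test_examples(self, seq, mc, min_length, expected):
        rec = ProteinRecord("X", seq)
        params = DigestionParams(missed_cleavages=mc, min_length=min_length)
        assert as_tuples(digest(rec, params)) == sorted(expected)

    def test_ordering_is_by_start_then_end(self):
        occs = digest(ProteinRecord("X", "MKWVRAK"), DigestionParams(missed_cleavages=2))
        keys = [(o.start, o.end) for o in occs]
        assert keys == sorted(keys)

    @given(seq=sequences, mc=st.integers(0, 3))
    @settings(max_examples=200, derandomize=True)
    def test_matches_brute_force_oracle(self, seq, mc):
        rec = ProteinRecord("X", seq)
        occs = digest(rec, DigestionParams(missed_cleavages=mc))
        assert as_tuples(occs) == brute_force_digest(seq, mc)

    @given(seq=sequences, mc=st.integers(0, 2))
    @settings(max_examples=100, derandomize=True)
    def test_matches_pyteomics_cleave(self, seq, mc):
        occs = digest(ProteinRecord("X", seq), DigestionParams(missed_cleavages=mc))
        expected = pyt_parser.cleave(seq, r"[KR](?=[^P])", missed_cleavages=mc)
        assert {o.sequence for o in occs} == expected

    @given(seq=sequences)
    @settings(max_examples=200, derandomize=True)
    def test_concatenation_and_count_laws(self, seq):
        occs = digest(ProteinRecord("X", seq), DigestionParams())
        assert "".join(o.sequence for o in occs) == seq
        assert len(occs) == len(cleavage_sites(seq)) + 1

    @given(seq=sequences)
    @settings(max_examples=200, derandomize=True)
    def test_internal_kr_only_before_proline(self, seq):
        for occ in digest(ProteinRecord("X", seq), DigestionParams()):
            for i in range(occ.start, occ.end):  # non-terminal positions of peptide
                if seq[i - 1] in "KR":
                    assert seq[i] == "P"

    @given(seq=sequences, mc=st.integers(0, 2))
    @settings(max_examples=100, derandomize=True)
    def test_distinct_set_monotone_in_missed_cleavages(self, seq, mc):
        rec = ProteinRecord("X", seq)
        smaller = {o.sequence for o in digest(rec, DigestionParams(missed_cleavages=mc))}
        larger = {o.sequence for o in digest(rec, DigestionParams(missed_cleavages=mc + 1))}
        assert smaller <= larger

    def test_coordinates_match_parent_substring(self):
        seq = "MKWVRAKRPCKAAA"
        for occ in digest(ProteinRecord("X", seq), DigestionParams(missed_cleavages=2)):
            assert seq[occ.start - 1 : occ.end] == occ.sequence


class TestDigestDatabase:
    def test_totals_and_distinct(self):
        db = make_db("d", ("A", "AKCA"), ("B", "AKDA"))
        summary = digest_database(db, DigestionParams())
        assert summary.total_count == 4
        assert summary.distinct == {"AK", "CA", "DA"}

    def test_identical_proteins_double_total_not_distinct(self):
        single = make_db("s", ("A", "MKWVRAK"))
        double = make_db("d", ("A", "MKWVRAK"), ("B", "MKWVRAK"))
        params = DigestionParams()
        s1, s2 = digest_database(single, params), digest_database(double, params)
        assert s2.total_count == 2 * s1.total_count
        assert s2.distinct == s1.distinct

    def test_empty_database_rejected(self):
        from proteodiff.io_formats import SequenceDatabase

        with pytest.raises(ValueError):
            digest_database(SequenceDatabase("e", "r", []), DigestionParams())

    def test_peptide_to_proteins_inverts_occurrences(self):
        db = make_db("d", ("A", "AKCA"), ("B", "AKDA"))
        parents = peptide_to_proteins(digest_database(db, DigestionParams()))
        assert parents["AK"] == {"A", "B"}
        assert parents["CA"] == {"A"}


class TestStats:
    def test_redundancy(self):
        db = make_db("d", ("A", "AKCA"), ("B", "AKDA"))
        assert redundancy_stats(digest_database(db, DigestionParams())) == 0.75

    def test_all_unique_gives_one(self):
        db = make_db("d", ("A", "AAAA"))
        assert redundancy_stats(digest_database(db, DigestionParams())) == 1.0

    @pytest.mark.parametrize(
        "peptides, min_length, expected",
        [
            ({"AK", "SAMPLER"}, 7, {"SAMPLER"}),
            ({"ABCDEF", "ABCDEFG"}, 7, {"ABCDEFG"}),  # "six or fewer" boundary
            ({"AK", "SAMPLER"}, 1, {"AK", "SAMPLER"}),
        ],
    )
    def test_length_filter(self, peptides, min_length, expected):
        assert filter_by_length(peptides, min_length) == expected


class TestParams:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"missed_cleavages": -1},
            {"min_length": 0},
            {"min_length": 8, "max_length": 7},
            {"enzyme": "chymotrypsin"},
        ],
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            DigestionParams(**kwargs)


def test_generated_peptide_count_matches_site_frequency():
    """With ~10% K/R content, mean mc=0 peptides per 100-residue protein
    should land near the binomial expectation (about 11)."""
    from proteodiff.synthetic import generate_protein_sequence

    rng = np.random.default_rng(11)
    counts = [
        len(cleavage_sites(generate_protein_sequence(rng, 100))) + 1 for _ in range(1000)
    ]
    assert 6 <= np.mean(counts) <= 16
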