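"""Search-space comparison, lost peptides, and detectability."""

import pytest

from proteodiff.digestion import DigestionParams, PeptideOccurrence, digest_database
from proteodiff.io_formats import ProteinRecord
from proteodiff.search_space import (
    DetectabilityReport,
    compare_search_space,
    detectability_report,
    lost_peptides,
    protein_detectability,
)

from conftest import make_db


class TestLostPeptides:
    @pytest.mark.parametrize(
        "source, target, expected",
        [
            ({"A", "B", "C"}, {"B", "C", "D"}, {"A"}),
            ({"A", "B"}, {"A", "B"}, set()),
            ({"A", "B"}, {"C"}, {"A", "B"}),
        ],
    )
    def test_set_difference(self, source, target, expected):
        assert lost_peptides(source, target) == expected

    @pytest.mark.parametrize(
        "source, target", [({"A", "B", "C"}, {"B", "C", "D"}), ({"A"}, {"A"})]
    )
    def test_lost_set_laws(self, source, target):
        lost = lost_peptides(source, target)
        assert lost | (source & target) == source
        assert (not lost) == (source <= target)


class TestCompare:
    def digests(self, src_seqs, tgt_seqs, **params):
        p = DigestionParams(**params)
        sd = digest_database(make_db("s", *src_seqs), p)
        td = digest_database(make_db("t", *tgt_seqs), p)
        return sd, td

    def test_lost_fraction(self):
        # source distinct {AK, CA, DA}; target distinct {AK, CA, EA}
        sd, td = self.digests(
            [("S1", "AKCA"), ("S2", "AKDA")], [("T1", "AKCA"), ("T2", "AKEA")]
        )
        comp = compare_search_space(sd, td)
        assert comp.lost == {"DA"}
        assert comp.lost_fraction == pytest.approx(1 / 3)
        assert comp.lost <= sd.distinct and not (comp.lost & td.distinct)

    def test_source_subset_of_target_loses_nothing(self):
        sd, td = self.digests([("S1", "AKCA")], [("T1", "AKCA"), ("T2", "AKEA")])
        assert compare_search_space(sd, td).lost_fraction == 0.0

    def test_parameter_mismatch_rejected(self):
        sd = digest_database(make_db("s", ("S1", "AKCA")), DigestionParams())
        td = digest_database(
            make_db("t", ("T1", "AKCA")), DigestionParams(missed_cleavages=1)
        )
        with pytest.raises(ValueError, match="mismatch"):
            compare_search_space(sd, td)


class TestProteinDetectability:
    def test_residue_union_count(self):
        rec = ProteinRecord("X", "MKWVR")
        occs = [PeptideOccurrence("X", 1, 2, "MK"), PeptideOccurrence("X", 3, 5, "WVR")]
        r = protein_detectability(rec, occs, {"MK"}, DigestionParams(min_length=1))
        assert (r.detectable_residues, r.fraction) == (2, 0.4)

    def test_nothing_in_target_gives_zero(self):
        rec = ProteinRecord("X", "MKWVR")
        occs = [PeptideOccurrence("X", 1, 2, "MK"), PeptideOccurrence("X", 3, 5, "WVR")]
        r = protein_detectability(rec, occs, set(), DigestionParams(min_length=1))
        assert r.fraction == 0.0

    def test_full_coverage_when_all_present(self):
        seq = "MKWVRAKRPCK"
        rec = ProteinRecord("X", seq)
        summary = digest_database(make_db("d", ("X", seq)), DigestionParams())
        occs = summary.occurrences["X"]
        r = protein_detectability(rec, occs, summary.distinct, DigestionParams(min_length=1))
        assert r.fraction == 1.0

    def test_length_bound_excludes_short_peptides(self):
        rec = ProteinRecord("X", "MKWVR")
        occs = [PeptideOccurrence("X", 1, 2, "MK"), PeptideOccurrence("X", 3, 5, "WVR")]
        r = protein_detectability(rec, occs, {"MK", "WVR"}, DigestionParams(min_length=3))
        assert r.detectable_residues == 3  # MK too short to qualify

    def test_foreign_occurrence_rejected(self):
        rec = ProteinRecord("X", "MKWVR")
        with pytest.raises(ValueError, match="Y"):
            protein_detectability(
                rec, [PeptideOccurrence("Y", 1, 2, "MK")], set(), DigestionParams()
            )


class TestDetectabilityReport:
    def test_no_lost_peptides_means_no_affected_proteins(self):
        db = make_db("d", ("A", "MKWVRAKDEFGHI"))
        summary = digest_database(db, DigestionParams())
        report, records = detectability_report(
            db, summary, summary.distinct, DigestionParams(min_length=1)
        )
        assert report == DetectabilityReport(0, 0, 0, 0)
        assert records == []

    def test_protein_absent_from_target_hits_all_thresholds(self):
        db = make_db("d", ("A", "MKWVRAAADEFGHIK"))
        summary = digest_database(db, DigestionParams())
        report, _ = detectability_report(db, summary, set(), DigestionParams(min_length=1))
        assert report == DetectabilityReport(1, 1, 1, 1)

    def test_threshold_tallies_are_nested(self):
        # fractions 0.6, 0.4, 0.0 -> counts (3, 2, 1, 1)
        db = make_db(
            "d",
            ("A", "AAAAAAKBBBK"),  # AAAAAAK (7/11 = 0.636) kept, BBBK lost
            ("B", "AAAKBBBBBBK"),  # fraction 4/11 = 0.364
            ("C", "CCCKDDDK"),  # nothing in target
        )
        summary = digest_database(db, DigestionParams())
        target = {"AAAAAAK", "AAAK"}
        report, records = detectability_report(
            db, summary, target, DigestionParams(min_length=1)
        )
        fractions = {r.protein_accession: round(r.fraction, 3) for r in records}
        assert fractions == {"A": 0.636, "B": 0.364, "C": 0.0}
        assert report == DetectabilityReport(3, 2, 1, 1)
        assert (
            report.count_zero
            <= report.count_le_10pct
            <= report.count_le_50pct
            <= report.affected_count
        )


class TestSyntheticRecovery:
    def test_planted_lost_proteins_recovered(self, small_pair, small_config):
        source, target, manifest = small_pair
        params = DigestionParams()
        sd = digest_database(source, params)
        td = digest_database(target, params)
        comp = compare_search_space(sd, td)
        assert len(comp.lost) == manifest.expected_lost_peptide_count
        report, records = detectability_report(
            source, sd, td.distinct, DigestionParams(min_length=7)
        )
        assert report.affected_count == manifest.expected_affected_count
        assert report.count_zero == manifest.expected_count_zero
        zero_accs = {r.protein_accession for r in records if r.fraction == 0.0}
        assert zero_accs == set(manifest.lost_only_accessions)

    def test_mutated_shared_fractions_match_manifest(self, small_pair):
        source, _, manifest = small_pair
        params = DigestionParams()
        sd = digest_database(source, params)
        td_distinct = digest_database(small_pair[1], params).distinct
        for acc, expected in manifest.mutated_fractions.items():
            r = protein_detectability(
                source[acc], sd.occurrences[acc], td_distinct, DigestionParams(min_length=7)
            )
            assert r.fraction == pytest.approx(expected, abs=1e-12)
            assert 0.0 < r.fraction < 1.0
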