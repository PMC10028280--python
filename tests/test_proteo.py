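"""Tryptic digestion, peptide-to-repertoire matching, specificity filters,
and attribution of specific peptides."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from clonetrack import clones, proteo, simulate
from clonetrack.errors import DataError

AA = "ACDEFGHIKLMNPQRSTVWY"


class TestTranslateBcr:
    def test_junction_codons_translate(self, small_cohort, germline_db):
        _, _, _, truth = small_cohort
        by_name = {g.name: g for g in germline_db}
        row = truth.iloc[0]
        t = proteo.translate_bcr(row, by_name)
        js = (int(row.junction_start) - int(row.v_sequence_start)) // 3
        jlen = int(row.junction_length) // 3
        assert t.aa_sequence[js : js + jlen] == row.junction_aa
        assert t.cdr_intervals[-1] == (js, js + jlen)
        assert t.aa_sequence.startswith(row.junction_aa[0:0])  # sanity

    def test_translations_match_generator_truth(self, small_cohort, germline_db):
        tc, _, _, truth = small_cohort
        by_uid = {c.clone_uid: c for c in tc}
        by_name = {g.name: g for g in germline_db}
        founders = truth[truth.sequence.isin({c.sequence_nt for c in tc})]
        assert len(founders) > 0
        for row in founders.head(20).itertuples(index=False):
            t = proteo.translate_bcr(row._asdict() if hasattr(row, "_asdict") else row, by_name)
            assert t.aa_sequence == by_uid[row.true_clone_uid].aa_sequence

    def test_unproductive_record_errors(self):
        with pytest.raises(DataError):
            proteo.translate_bcr(
                {"sequence_id": "x", "productive": False}, {}
            )


class TestTrypticDigest:
    def test_missed_cleavage_enumeration(self):
        # sites after K3 (AAAK) and R7 (GGGR): 0-missed AAAK, GGGR, CCC;
        # 1-missed adds AAAKGGGR, GGGRCCC; min length 6 keeps only those two
        seq = "AAAKGGGRCCC"
        assert proteo.base_fragments(seq) == ["AAAK", "GGGR", "CCC"]
        assert proteo.tryptic_digest(seq, max_missed=1, min_length=6) == {
            "AAAKGGGR",
            "GGGRCCC",
        }
        assert proteo.tryptic_digest(seq, max_missed=1, min_length=1) == {
            "AAAK", "GGGR", "CCC", "AAAKGGGR", "GGGRCCC",
        }

    def test_proline_blocks_cleavage(self):
        assert proteo.base_fragments("AAARPAAK") == ["AAARPAAK"]
        assert proteo.tryptic_digest("AAARPAAK", max_missed=0, min_length=6) == {
            "AAARPAAK"
        }

    def test_no_cleavage_sites_whole_sequence(self):
        assert proteo.tryptic_digest("ACDEFG", min_length=6) == {"ACDEFG"}
        assert proteo.tryptic_digest("ACDEF", min_length=6) == set()

    @given(st.text(alphabet=AA, min_size=1, max_size=60))
    def test_reconstitution_invariant(self, seq):
        assert "".join(proteo.base_fragments(seq)) == seq

    @given(st.text(alphabet=AA, min_size=6, max_size=40))
    def test_agrees_with_pyteomics(self, seq):
        """Independent oracle: pyteomics' cleavage routine with the classic
        KR-not-before-P rule."""
        from pyteomics import parser

        ours = proteo.tryptic_digest(seq, max_missed=2, min_length=6)
        theirs = {
            p
            for p in parser.cleave(seq, r"[KR](?!P)", missed_cleavages=2)
            if len(p) >= 6
        }
        assert ours == theirs


def _bcr(sid, aa, cdrs):
    return proteo.TranslatedBcr(sid, aa, tuple(cdrs))


class TestMatchPeptides:
    def test_unique_cdr_match_is_specific(self):
        db = [
            _bcr("s1", "AAAKCDEFGHIKLLLR", [(4, 12)]),
            _bcr("s2", "MMMKNNNRQQQK", [(4, 8)]),
        ]
        matches, _ = proteo.match_peptides(["CDEFGHIK"], db)
        m = matches[0]
        assert m.is_specific and m.matched_sequence_ids == ("s1",)
        assert m.cdr_overlap_aa == 8

    def test_multi_sequence_match_not_specific(self):
        db = [
            _bcr("s1", "AAAKCDEFGHIKLLLR", [(4, 12)]),
            _bcr("s2", "MMMKCDEFGHIKQQQR", [(4, 12)]),
        ]
        matches, _ = proteo.match_peptides(["CDEFGHIK"], db)
        assert not matches[0].is_specific
        assert matches[0].n_distinct == 2

    def test_identical_aa_variants_count_once(self):
        db = [
            _bcr("s1", "AAAKCDEFGHIKLLLR", [(4, 12)]),
            _bcr("s2", "AAAKCDEFGHIKLLLR", [(4, 12)]),  # nt variant, same aa
        ]
        matches, _ = proteo.match_peptides(["CDEFGHIK"], db, unique_level="aa")
        assert matches[0].is_specific and matches[0].n_distinct == 1
        matches_id, _ = proteo.match_peptides(["CDEFGHIK"], db, unique_level="id")
        assert not matches_id[0].is_specific

    def test_short_cdr_overlap_not_specific(self):
        # peptide covers CDR by only 2 residues
        db = [_bcr("s1", "AAAKCDEFGHIKLLLR", [(10, 14)])]
        matches, _ = proteo.match_peptides(["CDEFGHIK"], db)
        assert matches[0].cdr_overlap_aa == 2
        assert not matches[0].is_specific

    def test_decoy_matches_nothing(self):
        db = [_bcr("s1", "AAAKCDEFGHIKLLLR", [(4, 12)])]
        matches, _ = proteo.match_peptides(["WWWWWW"], db)
        assert matches[0].matched_sequence_ids == ()

    def test_nonstandard_characters_skipped(self):
        db = [_bcr("s1", "AAAKCDEFGHIKLLLR", [(4, 12)])]
        matches, skipped = proteo.match_peptides(["CDEFGB1K"], db)
        assert skipped == ["CDEFGB1K"] and not matches

    def test_tryptic_boundary_required(self):
        # "DEFGHIK" occurs mid-fragment (preceded by C, not K/R): no match
        db = [_bcr("s1", "AAAKCDEFGHIKLLLR", [(4, 12)])]
        matches, _ = proteo.match_peptides(["DEFGHIK"], db)
        assert matches[0].matched_sequence_ids == ()

    def test_monotone_under_database_growth(self):
        db1 = [_bcr("s1", "AAAKCDEFGHIKLLLR", [(4, 12)])]
        db2 = db1 + [_bcr("s2", "MMMKCDEFGHIKQQQR", [(4, 12)])]
        m1, _ = proteo.match_peptides(["CDEFGHIK"], db1)
        m2, _ = proteo.match_peptides(["CDEFGHIK"], db2)
        assert m1[0].is_specific and not m2[0].is_specific

    def test_matches_equal_bruteforce_scan(self, small_cohort, germline_db):
        """Index lookup equals an exhaustive position scan over all
        (peptide, sequence) pairs with explicit boundary checks."""
        tc, counts, _, truth = small_cohort
        p1 = truth[truth.patient == "P1"]
        db = proteo.build_bcr_database(p1.head(120), germline_db)
        peps = simulate.simulate_serum_peptides(
            tc, counts, n_per_sample=25, decoy_fraction=0.3, seed=13
        )
        pep_list = sorted(set(peps.peptide_aa))
        matches, _ = proteo.match_peptides(pep_list, db)
        for m in matches:
            expected = set()
            for b in db:
                aa = b.aa_sequence
                start = aa.find(m.peptide_aa)
                while start >= 0:
                    end = start + len(m.peptide_aa)
                    nterm = start == 0 or (
                        aa[start - 1] in "KR" and aa[start] != "P"
                    )
                    cterm = end == len(aa) or (
                        aa[end - 1] in "KR" and aa[end] != "P"
                    )
                    if nterm and cterm:
                        expected.add(b.sequence_id)
                    start = aa.find(m.peptide_aa, start + 1)
            assert set(m.matched_sequence_ids) == expected, m.peptide_aa


class TestAttribution:
    def _setup(self, small_cohort, germline_db):
        tc, counts, _, truth = small_cohort
        rearr, _ = clones.assign_clone_ids(truth)
        p1 = rearr[rearr.patient == "P1"]
        db = proteo.build_bcr_database(p1, germline_db)
        return tc, counts, p1, db

    def test_attribution_covers_matched_timepoints(self, small_cohort, germline_db):
        tc, counts, p1, db = self._setup(small_cohort, germline_db)
        peps = simulate.simulate_serum_peptides(
            tc, counts, n_per_sample=40, decoy_fraction=0.0, seed=14
        )
        pgrp = peps[peps.patient == "P1"]
        matches, _ = proteo.match_peptides(sorted(set(pgrp.peptide_aa)), db)
        att = proteo.attribute_specific_peptides(matches, p1, pgrp)
        by_id = p1.set_index("sequence_id")
        for row in att.itertuples(index=False):
            sids = row.matched_sequence_ids.split(";")
            tps = set(by_id.loc[sids, "timepoint"])
            assert set(row.attributed_timepoints.split(";")) == tps

    def test_referential_integrity_error(self):
        m = proteo.PeptideMatch("PEPTIDEK", ("ghost",), 1, 5, True)
        with pytest.raises(DataError, match="ghost"):
            proteo.attribute_specific_peptides(
                [m],
                pd.DataFrame(
                    {"sequence_id": ["s1"], "timepoint": ["B"],
                     "isotype": ["IgG"], "subset": ["memory"]}
                ),
            )

    def test_specific_peptides_attribute_to_true_timepoints(
        self, small_cohort, germline_db
    ):
        """>= 90% of non-decoy specific peptides attribute to the time
        points where their source clone truly has cells."""
        tc, counts, p1, db = self._setup(small_cohort, germline_db)
        peps = simulate.simulate_serum_peptides(
            tc, counts, n_per_sample=60, decoy_fraction=0.1, seed=15
        )
        pgrp = peps[(peps.patient == "P1") & ~peps.is_decoy]
        matches, _ = proteo.match_peptides(sorted(set(pgrp.peptide_aa)), db)
        att = proteo.attribute_specific_peptides(matches, p1, pgrp)
        if len(att) == 0:
            pytest.skip("no specific peptides in this tiny sample")
        true_spans = (
            counts[counts.patient == "P1"]
            .groupby("clone_uid")["timepoint"]
            .agg(set)
        )
        src = pgrp.drop_duplicates("peptide_aa").set_index("peptide_aa")
        ok = tot = 0
        for row in att.itertuples(index=False):
            if row.peptide_aa not in src.index:
                continue
            uid = src.loc[row.peptide_aa, "source_clone_uid"]
            tot += 1
            got = set(row.attributed_timepoints.split(";"))
            if got & true_spans[uid]:
                ok += 1
        assert tot == 0 or ok / tot >= 0.9
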