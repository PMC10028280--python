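"""Read-processing stages: quality filter, pairing/merging, demultiplexing,
UMI consensus, duplicate collapsing, and the conservation invariants."""

import numpy as np
import pytest

from clonetrack import readproc, simulate
from clonetrack.errors import ConfigurationError
from clonetrack.readproc import DemuxRead, Read, UmiGroup


def _read(rid, seq, q):
    return Read(rid, seq, np.full(len(seq), q))


def _demux(rid, umi, seq, subset="memory", isotype="IgG", q=35):
    return DemuxRead(rid, umi, subset, isotype, seq, np.full(len(seq), q))


class TestQualityFilter:
    def test_all_high_retained_all_low_dropped(self):
        high = [_read(f"r{i}", "ACGT", 30) for i in range(5)]
        low = [_read(f"s{i}", "ACGT", 10) for i in range(5)]
        kept, log = readproc.filter_quality(high + low, q_threshold=20)
        assert [r.id for r in kept] == [r.id for r in high]
        assert log["in"] == 10 and log["pass"] == 5 and log["fail"] == 5

    def test_mixed_set_matches_bruteforce_recount(self):
        rng = np.random.default_rng(0)
        reads = [
            Read(f"r{i}", "ACGTACGT", rng.integers(5, 40, size=8))
            for i in range(200)
        ]
        kept, _ = readproc.filter_quality(reads, q_threshold=20)
        expected = [r.id for r in reads if sum(r.qual) / len(r.qual) >= 20]
        assert [r.id for r in kept] == expected


class TestPairAndMerge:
    def test_orphan_mate_dropped_and_logged(self, small_cohort):
        _, _, cells, _ = small_cohort
        reads = simulate.simulate_reads(
            cells.head(10), error_rate=0.0, pcr_duplication=1, seed=1
        )
        m1 = [Read(r.read_id, r.mate1_seq, r.mate1_qual) for r in reads]
        m2 = [Read(r.read_id, r.mate2_seq, r.mate2_qual) for r in reads]
        merged, log = readproc.pair_and_merge(m1, m2)
        assert log["fail"] == 0 and len(merged) == 10
        merged, log = readproc.pair_and_merge(m1, m2[1:])
        assert log["orphans_mate1"] == 1 and log["pass"] == 9
        assert log["in"] == log["pass"] + log["fail"]

    def test_zero_error_merge_recovers_template(self, small_cohort):
        _, _, cells, _ = small_cohort
        sub = cells.head(25)
        reads = simulate.simulate_reads(sub, error_rate=0.0, pcr_duplication=1, seed=2)
        truth = dict(zip(cells.cell_id, cells.sequence_nt))
        m1 = [Read(r.read_id, r.mate1_seq, r.mate1_qual) for r in reads]
        m2 = [Read(r.read_id, r.mate2_seq, r.mate2_qual) for r in reads]
        merged, _ = readproc.pair_and_merge(m1, m2)
        for m, r in zip(merged, reads):
            tpl = r.subset_barcode + truth[r.truth_uid]
            assert m.seq.startswith(tpl) and len(m.seq) == len(tpl) + 8
            assert m.umi == r.umi


class TestDemultiplex:
    def _merged(self, seq):
        return readproc.MergedRead("r0", "A" * 12, seq, np.full(len(seq), 35))

    def test_exact_lookup(self):
        seq = simulate.SUBSET_BARCODES["memory"] + "ACG" * 40 + simulate.ISOTYPE_TAGS["IgG"]
        out, und, log = readproc.demultiplex([self._merged(seq)])
        assert len(out) == 1 and not und
        assert out[0].subset == "memory" and out[0].isotype == "IgG"
        assert out[0].seq == "ACG" * 40

    def test_two_mismatches_undetermined(self):
        bc = list(simulate.SUBSET_BARCODES["memory"])
        bc[0] = "C" if bc[0] != "C" else "A"
        bc[1] = "C" if bc[1] != "C" else "A"
        seq = "".join(bc) + "ACG" * 40 + simulate.ISOTYPE_TAGS["IgG"]
        out, und, log = readproc.demultiplex([self._merged(seq)], tolerance=1)
        assert not out and len(und) == 1

    def test_one_mismatch_tolerated(self):
        bc = list(simulate.SUBSET_BARCODES["naive"])
        bc[3] = "G" if bc[3] != "G" else "T"
        seq = "".join(bc) + "ACG" * 40 + simulate.ISOTYPE_TAGS["IgA"]
        out, _, _ = readproc.demultiplex([self._merged(seq)], tolerance=1)
        assert out and out[0].subset == "naive" and out[0].isotype == "IgA"

    def test_duplicate_barcodes_config_error(self):
        with pytest.raises(ConfigurationError):
            readproc.demultiplex(
                [], subset_barcodes={"a": "AAAA", "b": "AAAA"}
            )

    def test_zero_error_subset_counts_match_truth(self, small_cohort):
        _, _, cells, _ = small_cohort
        sub = cells.head(80)
        reads = simulate.simulate_reads(sub, error_rate=0.0, pcr_duplication=1, seed=3)
        m1 = [Read(r.read_id, r.mate1_seq, r.mate1_qual) for r in reads]
        m2 = [Read(r.read_id, r.mate2_seq, r.mate2_qual) for r in reads]
        merged, _ = readproc.pair_and_merge(m1, m2)
        demuxed, _, _ = readproc.demultiplex(merged)
        got = {}
        for d in demuxed:
            got[d.subset] = got.get(d.subset, 0) + 1
        expected = sub.groupby("subset").size().to_dict()
        assert got == expected


class TestConsensus:
    def test_identical_reads_consensus(self):
        g = UmiGroup("AAAA", "memory", [_demux(f"r{i}", "AAAA", "ACGTACGTAC") for i in range(3)])
        c = readproc.build_consensus(g)
        assert isinstance(c, readproc.ConsensusSequence)
        assert c.sequence == "ACGTACGTAC" and c.umi_count_support == 3

    def test_single_read_rejected_below_min(self):
        g = UmiGroup("AAAA", "memory", [_demux("r0", "AAAA", "ACGTACGTAC")])
        res = readproc.build_consensus(g, min_reads=2)
        assert isinstance(res, dict) and res["reason"] == "too_few_reads"

    def test_one_disagreeing_base_mean_mismatch(self):
        """10 reads, one base wrong in one read: consensus is the majority
        sequence and the mean mismatch rate is (1/L)/10."""
        L = 20
        base = ("ACGT" * 5)[:L]
        variant = "T" + base[1:]
        reads = [_demux(f"r{i}", "AAAA", base) for i in range(9)]
        reads.append(_demux("r9", "AAAA", variant))
        c = readproc.build_consensus(UmiGroup("AAAA", "memory", reads))
        assert c.sequence == base
        # recompute the group error exactly as defined
        rates = [sum(a != b for a, b in zip(r.seq, base)) / L for r in reads]
        assert np.mean(rates) == pytest.approx((1 / L) / 10)

    def test_high_error_group_rejected(self):
        a = "A" * 20
        b = "T" * 20
        reads = [_demux("r0", "AAAA", a), _demux("r1", "AAAA", b)]
        res = readproc.build_consensus(UmiGroup("AAAA", "memory", reads), max_error=0.1)
        assert isinstance(res, dict) and res["reason"] == "high_error"

    def test_permutation_invariance(self):
        rng = np.random.default_rng(1)
        seqs = ["ACGTACGTACGTACGTACGT"]
        for _ in range(5):
            s = list(seqs[0])
            pos = rng.integers(0, len(s))
            s[pos] = "ACGT"[rng.integers(0, 4)]
            seqs.append("".join(s))
        reads = [_demux(f"r{i}", "AAAA", s, q=30 + i) for i, s in enumerate(seqs)]
        c1 = readproc.build_consensus(UmiGroup("AAAA", "memory", reads))
        c2 = readproc.build_consensus(UmiGroup("AAAA", "memory", reads[::-1]))
        assert c1.sequence == c2.sequence

    def test_length_discordant_members_set_aside(self):
        reads = [_demux(f"r{i}", "AAAA", "ACGTACGTAC") for i in range(3)]
        reads.append(_demux("r3", "AAAA", "ACGTACGT"))
        c = readproc.build_consensus(UmiGroup("AAAA", "memory", reads))
        assert isinstance(c, readproc.ConsensusSequence)
        assert c.umi_count_support == 3


class TestCollapse:
    def test_identical_sequences_distinct_umis(self):
        cons = [
            readproc.ConsensusSequence("ACGT", f"UMI{i}", "memory", "IgG", 2)
            for i in range(5)
        ]
        out, log = readproc.collapse_duplicates(cons)
        assert len(out) == 1 and out[0].duplicate_count == 5

    def test_all_distinct(self):
        cons = [
            readproc.ConsensusSequence(b * 4, f"U{i}", "naive", "IgM", 2)
            for i, b in enumerate("ACGT")
        ]
        out, _ = readproc.collapse_duplicates(cons)
        assert all(c.duplicate_count == 1 for c in out)

    def test_conservation_of_duplicate_counts(self):
        rng = np.random.default_rng(2)
        seq_pool = ["AAAA", "CCCC", "GGGG"]
        cons = [
            readproc.ConsensusSequence(
                seq_pool[rng.integers(0, 3)], f"U{i}", "DN", "IgG", 2
            )
            for i in range(50)
        ]
        out, log = readproc.collapse_duplicates(cons)
        assert sum(c.duplicate_count for c in out) == 50
        assert log["total_duplicate_count"] == 50


class TestEndToEnd:
    def test_zero_error_recovers_truth_molecules_exactly(self, small_cohort):
        """Zero sequencing error with guaranteed >= 2 copies per molecule:
        the collapsed consensus table equals the ground-truth molecule table
        in every (subset, isotype, sequence, count)."""
        _, _, cells, _ = small_cohort
        sample = cells[(cells.patient == "P1") & (cells.timepoint == "B")]
        reads = simulate.simulate_reads(
            sample, error_rate=0.0, pcr_duplication=3, min_copies=2, seed=5
        )
        m1 = [Read(r.read_id, r.mate1_seq, r.mate1_qual) for r in reads]
        m2 = [Read(r.read_id, r.mate2_seq, r.mate2_qual) for r in reads]
        df, logs = readproc.process_sample(m1, m2)
        truth = (
            sample.groupby(["subset", "isotype", "sequence_nt"])
            .size()
            .reset_index(name="duplicate_count")
            .sort_values(["subset", "isotype", "sequence_nt"])
            .reset_index(drop=True)
        )
        got = (
            df[["subset", "isotype", "sequence", "duplicate_count"]]
            .rename(columns={"sequence": "sequence_nt"})
            .sort_values(["subset", "isotype", "sequence_nt"])
            .reset_index(drop=True)
        )
        assert truth.equals(got)

    def test_conservation_logged_per_step(self, small_cohort):
        _, _, cells, _ = small_cohort
        sample = cells[(cells.patient == "P1") & (cells.timepoint == "6M")]
        reads = simulate.simulate_reads(
            sample, error_rate=0.01, pcr_duplication=3, seed=6
        )
        m1 = [Read(r.read_id, r.mate1_seq, r.mate1_qual) for r in reads]
        m2 = [Read(r.read_id, r.mate2_seq, r.mate2_qual) for r in reads]
        _, logs = readproc.process_sample(m1, m2)
        for log in logs:
            if log["step"] == "collapse_duplicates":
                # records merge here: duplicate counts, not rows, conserve
                assert log["total_duplicate_count"] == log["in"]
            else:
                assert log["in"] == log["pass"] + log["fail"], log["step"]
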