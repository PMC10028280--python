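"""Raw paired reads -> deduplicated consensus sequences with copy numbers.

The stages mirror a standard UMI amplicon workflow: mean-quality filtering,
mate pairing and overlap merging, constant-region barcode demultiplexing
(subset + isotype), position-wise majority consensus per UMI group, and
collapsing identical consensus sequences across UMIs into copy numbers.
Each stage returns a log entry with input/pass/fail counts and the
conservation invariant records_in == retained + dropped holds per stage.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError
from .simulate import ISOTYPE_TAGS, SUBSET_BARCODES, revcomp


@dataclass
class Read:
    id: str
    seq: str
    qual: np.ndarray  # per-base Phred scores


@dataclass
class MergedRead:
    id: str
    umi: str
    seq: str
    qual: np.ndarray


@dataclass
class DemuxRead:
    id: str
    umi: str
    subset: str
    isotype: str
    seq: str  # trimmed to the VDJ amplicon
    qual: np.ndarray


@dataclass
class UmiGroup:
    """Reads sharing one UMI within one subset."""

    umi: str
    subset: str
    reads: list[DemuxRead] = field(default_factory=list)


@dataclass
class ConsensusSequence:
    sequence: str
    umi: str
    subset: str
    isotype: str
    umi_count_support: int  # reads in the group
    duplicate_count: int = 1  # identical sequences with distinct UMIs


def read_fastq(path) -> list[Read]:
    """Parse a FASTQ file; malformed records raise DataError with the index."""
    from Bio import SeqIO

    reads = []
    try:
        for i, rec in enumerate(SeqIO.parse(str(path), "fastq")):
            reads.append(
                Read(
                    rec.id,
                    str(rec.seq).upper(),
                    np.asarray(rec.letter_annotations["phred_quality"]),
                )
            )
    except ValueError as exc:
        raise DataError(f"malformed FASTQ record at index {len(reads)}: {exc}")
    return reads


# ---------------------------------------------------------------------------


def filter_quality(
    reads: list[Read], q_threshold: float = 20.0
) -> tuple[list[Read], dict]:
    """Keep reads whose mean Phred score is >= the threshold; order preserved."""
    if q_threshold < 0:
        raise ConfigurationError("q_threshold must be >= 0")
    kept = [r for r in reads if r.qual.size and r.qual.mean() >= q_threshold]
    log = {"step": "filter_quality", "in": len(reads), "pass": len(kept)}
    log["fail"] = log["in"] - log["pass"]
    return kept, log


def filter_quality_pairs(
    mates1: list[Read], mates2: list[Read], q_threshold: float = 20.0
) -> tuple[list[Read], list[Read], dict]:
    """Pairwise variant: a pair is kept only if both mates pass."""
    by_id2 = {r.id: r for r in mates2}
    k1, k2 = [], []
    n_in = len(mates1)
    for r1 in mates1:
        r2 = by_id2.get(r1.id)
        if r2 is None:
            continue
        if (
            r1.qual.size
            and r2.qual.size
            and r1.qual.mean() >= q_threshold
            and r2.qual.mean() >= q_threshold
        ):
            k1.append(r1)
            k2.append(r2)
    log = {"step": "filter_quality", "in": n_in, "pass": len(k1)}
    log["fail"] = n_in - len(k1)
    return k1, k2, log


def _merge_overlap(
    s1: str, q1: np.ndarray, s2rc: str, q2rc: np.ndarray,
    min_overlap: int, max_mismatch_frac: float,
) -> tuple[str, np.ndarray] | None:
    """Merge two mate sequences by their 3' overlap.

    Seeds on an exact match of the mate-1 tail inside mate 2 (two seed
    offsets tolerate one error in the tail region), falling back to an
    exhaustive overlap scan; among acceptable overlaps the largest wins.
    """
    a1 = np.frombuffer(s1.encode(), dtype=np.uint8)
    a2 = np.frombuffer(s2rc.encode(), dtype=np.uint8)
    lim = min(len(s1), len(s2rc))

    def check(o: int) -> bool:
        if o < min_overlap or o > lim:
            return False
        mism = int((a1[len(a1) - o :] != a2[:o]).sum())
        return mism <= max_mismatch_frac * o

    k = min(20, lim)
    candidates: list[int] = []
    for back in (0, k):  # seed from the tail, then one seed-length earlier
        seed = s1[len(s1) - k - back : len(s1) - back]
        start = 0
        while True:
            i = s2rc.find(seed, start)
            if i < 0:
                break
            candidates.append(i + k + back)
            start = i + 1
        ok = [o for o in candidates if check(o)]
        if ok:
            o = max(ok)
            merged = s1 + s2rc[o:]
            qual = np.concatenate([q1, q2rc[o:]])
            return merged, qual
    for o in range(lim, min_overlap - 1, -1):  # exhaustive fallback
        if check(o):
            return s1 + s2rc[o:], np.concatenate([q1, q2rc[o:]])
    return None


def pair_and_merge(
    mates1: list[Read],
    mates2: list[Read],
    umi_length: int = 12,
    min_overlap: int = 20,
    max_mismatch_frac: float = 0.15,
) -> tuple[list[MergedRead], dict]:
    """Pair mates by read ID, strip the UMI from mate 1, and merge by overlap.

    Orphan mates (present in only one file) and unmergeable pairs are dropped
    and counted in the log.
    """
    by_id2 = {r.id: r for r in mates2}
    if len(by_id2) != len(mates2):
        raise DataError("duplicate read IDs in mate-2 input")
    merged: list[MergedRead] = []
    orphans1 = 0
    unmerged = 0
    seen = set()
    for r1 in mates1:
        r2 = by_id2.get(r1.id)
        if r2 is None:
            orphans1 += 1
            continue
        seen.add(r1.id)
        umi = r1.seq[:umi_length]
        core = r1.seq[umi_length:]
        coreq = r1.qual[umi_length:]
        res = _merge_overlap(
            core, coreq, revcomp(r2.seq), r2.qual[::-1], min_overlap,
            max_mismatch_frac,
        )
        if res is None:
            unmerged += 1
            continue
        seq, qual = res
        merged.append(MergedRead(r1.id, umi, seq, qual))
    # units are mate-1 records (= pairs once matched): in == pass + fail
    log = {
        "step": "pair_and_merge",
        "in": len(mates1),
        "pass": len(merged),
        "orphans_mate1": orphans1,
        "orphans_mate2": len(mates2) - len(seen),
        "unmerged_pairs": unmerged,
        "fail": orphans1 + unmerged,
    }
    return merged, log


# ---------------------------------------------------------------------------


def _best_tag(segment: str, table: dict[str, str], tolerance: int) -> str | None:
    best_name, best_d = None, None
    for name in sorted(table):
        tag = table[name]
        d = sum(a != b for a, b in zip(segment, tag))
        if best_d is None or d < best_d:
            best_name, best_d = name, d
    if best_d is not None and best_d <= tolerance:
        return best_name
    return None


def _validate_tables(*tables: dict[str, str]) -> None:
    for table in tables:
        seqs = list(table.values())
        if len(set(seqs)) != len(seqs):
            raise ConfigurationError("duplicate barcode definitions in table")
        if len({len(s) for s in seqs}) != 1:
            raise ConfigurationError("barcodes within a table must share a length")


def demultiplex(
    merged: list[MergedRead],
    subset_barcodes: dict[str, str] | None = None,
    isotype_tags: dict[str, str] | None = None,
    tolerance: int = 1,
) -> tuple[list[DemuxRead], list[MergedRead], dict]:
    """Assign subset (5' barcode) and isotype (3' constant-region tag) and
    trim both; unmatched records go to the undetermined bin."""
    subset_barcodes = subset_barcodes or SUBSET_BARCODES
    isotype_tags = isotype_tags or ISOTYPE_TAGS
    _validate_tables(subset_barcodes, isotype_tags)
    bc_len = len(next(iter(subset_barcodes.values())))
    tag_len = len(next(iter(isotype_tags.values())))
    out: list[DemuxRead] = []
    undetermined: list[MergedRead] = []
    for rec in merged:
        subset = _best_tag(rec.seq[:bc_len], subset_barcodes, tolerance)
        isotype = _best_tag(rec.seq[-tag_len:], isotype_tags, tolerance)
        if subset is None or isotype is None or len(rec.seq) <= bc_len + tag_len:
            undetermined.append(rec)
            continue
        out.append(
            DemuxRead(
                rec.id,
                rec.umi,
                subset,
                isotype,
                rec.seq[bc_len : len(rec.seq) - tag_len],
                rec.qual[bc_len : len(rec.seq) - tag_len],
            )
        )
    log = {
        "step": "demultiplex",
        "in": len(merged),
        "pass": len(out),
        "fail": len(undetermined),
    }
    return out, undetermined, log


def group_by_umi(reads: list[DemuxRead]) -> list[UmiGroup]:
    """Group reads by (UMI, subset); deterministic order."""
    groups: dict[tuple[str, str], UmiGroup] = {}
    for r in reads:
        key = (r.umi, r.subset)
        if key not in groups:
            groups[key] = UmiGroup(umi=r.umi, subset=r.subset)
        groups[key].reads.append(r)
    return [groups[k] for k in sorted(groups)]


def build_consensus(
    group: UmiGroup, max_error: float = 0.1, min_reads: int = 2
) -> ConsensusSequence | dict:
    """Position-wise majority consensus of one UMI group.

    Members whose length differs from the modal length are set aside; the
    group is rejected (a dict with a reason code is returned) when fewer than
    ``min_reads`` members remain or when the mean per-read normalized
    mismatch rate against the consensus exceeds ``max_error``. Base ties are
    resolved by highest summed quality, then lexicographically.
    """
    if not group.reads:
        raise DataError("empty UMI group")
    lengths = Counter(len(r.seq) for r in group.reads)
    top = max(lengths.values())
    modal_len = min(l for l, n in lengths.items() if n == top)
    members = [r for r in group.reads if len(r.seq) == modal_len]
    if len(members) < min_reads:
        reason = (
            "length_discordant" if len(members) < len(group.reads) else "too_few_reads"
        )
        return {"rejected": True, "reason": reason, "umi": group.umi}
    arr = np.vstack(
        [np.frombuffer(r.seq.encode(), dtype=np.uint8) for r in members]
    )
    quals = np.vstack([r.qual for r in members]).astype(float)
    base_codes = np.frombuffer(b"ACGT", dtype=np.uint8)
    votes = np.stack([(arr == b).sum(axis=0) for b in base_codes])  # 4 x L
    qvotes = np.stack([((arr == b) * quals).sum(axis=0) for b in base_codes])
    # majority vote; ties by summed quality; argmax's first-index rule then
    # picks the lexicographically smallest base (A<C<G<T) — all exact in
    # float64 since both terms are integer-valued and well below 2**53
    score = votes.astype(float) * 1e7 + qvotes
    winner = score.argmax(axis=0)
    cons = base_codes[winner]
    mism = (arr != cons).mean(axis=1)
    if mism.mean() > max_error:
        return {"rejected": True, "reason": "high_error", "umi": group.umi}
    isotype = Counter(r.isotype for r in members).most_common(1)[0][0]
    return ConsensusSequence(
        sequence=cons.tobytes().decode(),
        umi=group.umi,
        subset=group.subset,
        isotype=isotype,
        umi_count_support=len(members),
    )


def build_consensuses(
    groups: list[UmiGroup], max_error: float = 0.1, min_reads: int = 2
) -> tuple[list[ConsensusSequence], dict]:
    out, reasons = [], Counter()
    for g in groups:
        res = build_consensus(g, max_error=max_error, min_reads=min_reads)
        if isinstance(res, ConsensusSequence):
            out.append(res)
        else:
            reasons[res["reason"]] += 1
    log = {
        "step": "build_consensus",
        "in": len(groups),
        "pass": len(out),
        "fail": sum(reasons.values()),
        "reasons": dict(reasons),
    }
    return out, log


def collapse_duplicates(
    consensuses: list[ConsensusSequence],
) -> tuple[list[ConsensusSequence], dict]:
    """Collapse exact-identical sequences within a (subset, isotype) stratum;
    the duplicate count is the number of distinct UMIs carrying the
    sequence."""
    bins: dict[tuple[str, str, str], list[ConsensusSequence]] = defaultdict(list)
    for c in consensuses:
        bins[(c.subset, c.isotype, c.sequence)].append(c)
    out = []
    for key in sorted(bins):
        members = bins[key]
        out.append(
            ConsensusSequence(
                sequence=key[2],
                umi=min(m.umi for m in members),
                subset=key[0],
                isotype=key[1],
                umi_count_support=sum(m.umi_count_support for m in members),
                duplicate_count=len({m.umi for m in members}),
            )
        )
    log = {
        "step": "collapse_duplicates",
        "in": len(consensuses),
        "pass": len(out),
        "fail": 0,
        "total_duplicate_count": sum(c.duplicate_count for c in out),
    }
    return out, log


# ---------------------------------------------------------------------------


def process_sample(
    mates1: list[Read],
    mates2: list[Read],
    q_threshold: float = 20.0,
    umi_length: int = 12,
    max_error: float = 0.1,
    min_reads: int = 2,
    subset_barcodes: dict[str, str] | None = None,
    isotype_tags: dict[str, str] | None = None,
) -> tuple[pd.DataFrame, list[dict]]:
    """Full per-sample processing chain; returns unique consensus records
    (sequence, subset, isotype, duplicate_count) and the per-step log."""
    logs = []
    k1, k2, log = filter_quality_pairs(mates1, mates2, q_threshold)
    logs.append(log)
    merged, log = pair_and_merge(k1, k2, umi_length=umi_length)
    logs.append(log)
    demuxed, _, log = demultiplex(merged, subset_barcodes, isotype_tags)
    logs.append(log)
    groups = group_by_umi(demuxed)
    consensuses, log = build_consensuses(groups, max_error=max_error, min_reads=min_reads)
    logs.append(log)
    collapsed, log = collapse_duplicates(consensuses)
    logs.append(log)
    df = pd.DataFrame(
        [
            {
                "sequence": c.sequence,
                "subset": c.subset,
                "isotype": c.isotype,
                "duplicate_count": c.duplicate_count,
                "umi_count_support": c.umi_count_support,
            }
            for c in collapsed
        ]
    )
    return df, logs
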