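"""Serum Ig peptide to BCR transcriptome overlap.

Each patient's productive rearrangements are translated into a personal
protein database; observed serum peptides (tryptic, from an upstream search
engine or the synthetic generator) are matched as exact amino-acid
substrings with tryptic-consistent boundaries. A peptide is *specific* when
it matches exactly one amino-acid-distinct BCR sequence and covers at least
3 residues of a CDR. Specific peptides are then attributed to the time
points, isotypes, and subsets of their matched transcriptome sequences.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from Bio.Seq import Seq

from .errors import ConfigurationError, DataError
from .germline import GermlineSegment

STANDARD_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")


@dataclass
class TranslatedBcr:
    sequence_id: str
    aa_sequence: str
    cdr_intervals: tuple[tuple[int, int], ...]  # 0-based half-open, aa coords

    def __post_init__(self) -> None:
        prev = 0
        for start, end in self.cdr_intervals:
            if not (prev <= start < end <= len(self.aa_sequence)):
                raise DataError(
                    f"{self.sequence_id}: CDR intervals must be ordered, "
                    "disjoint and within the sequence"
                )
            prev = end


@dataclass
class PeptideMatch:
    peptide_aa: str
    matched_sequence_ids: tuple[str, ...]
    n_distinct: int  # distinct matches at the configured uniqueness level
    cdr_overlap_aa: int
    is_specific: bool


def translate_bcr(
    row, germline_by_name: dict[str, GermlineSegment]
) -> TranslatedBcr:
    """Translate one productive rearrangement and map its CDR intervals.

    CDR1/CDR2 come from the called V segment's germline annotation (the V
    aligns at the start of the translated region, so aa coordinates carry
    over); CDR3 is the translated junction interval.
    """
    get = row.get if hasattr(row, "get") else lambda k: getattr(row, k)
    if not bool(get("productive")):
        raise DataError(f"{get('sequence_id')}: unproductive record")
    seq = get("sequence")
    v_start = int(get("v_sequence_start")) - 1
    j_start_nt = int(get("junction_start")) - 1
    j_len = int(get("junction_length"))
    region = seq[v_start:]
    region = region[: 3 * (len(region) // 3)]
    aa = str(Seq(region).translate())
    if "*" in aa:
        raise DataError(
            f"{get('sequence_id')}: internal stop in productive record"
        )
    v_seg = germline_by_name.get(get("v_call"))
    cdrs: list[tuple[int, int]] = []
    cdr3 = ((j_start_nt - v_start) // 3, (j_start_nt - v_start + j_len) // 3)
    if v_seg is not None:
        # germline CDR intervals minus the CDR3-proximal one (covered by the
        # junction interval), clipped to the translated length
        for start, end in v_seg.cdr_regions:
            if end <= cdr3[0] and end <= len(aa):
                cdrs.append((start, end))
    cdrs.append((cdr3[0], min(cdr3[1], len(aa))))
    return TranslatedBcr(
        sequence_id=get("sequence_id"), aa_sequence=aa, cdr_intervals=tuple(cdrs)
    )


def build_bcr_database(
    records: pd.DataFrame, germline: list[GermlineSegment]
) -> list[TranslatedBcr]:
    """Translate all productive records of one patient."""
    by_name = {g.name: g for g in germline}
    out = []
    for row in records[records["productive"].astype(bool)].to_dict("records"):
        out.append(translate_bcr(row, by_name))
    return out


# ---------------------------------------------------------------------------
# tryptic digestion


def cleavage_sites(aa_sequence: str) -> list[int]:
    """Positions after which trypsin cleaves: C-terminal of K or R, except
    when the next residue is proline."""
    return [
        i + 1
        for i in range(len(aa_sequence) - 1)
        if aa_sequence[i] in "KR" and aa_sequence[i + 1] != "P"
    ]


def base_fragments(aa_sequence: str) -> list[str]:
    """Ordered zero-missed-cleavage fragments; their concatenation
    reconstitutes the input sequence."""
    bounds = [0] + cleavage_sites(aa_sequence) + [len(aa_sequence)]
    return [
        aa_sequence[bounds[i] : bounds[i + 1]] for i in range(len(bounds) - 1)
    ]


def tryptic_digest(
    aa_sequence: str,
    max_missed: int = 2,
    min_length: int = 6,
    with_positions: bool = False,
):
    """In-silico tryptic peptides with up to ``max_missed`` internal missed
    cleavages and length >= ``min_length``.

    Returns a set of peptides, or a sorted list of (start, peptide) when
    ``with_positions`` is requested.
    """
    if not aa_sequence:
        raise DataError("cannot digest an empty sequence")
    bounds = [0] + cleavage_sites(aa_sequence) + [len(aa_sequence)]
    out = []
    for i in range(len(bounds) - 1):
        for m in range(max_missed + 1):
            j = i + 1 + m
            if j >= len(bounds):
                break
            frag = aa_sequence[bounds[i] : bounds[j]]
            if len(frag) >= min_length:
                out.append((bounds[i], frag))
    if with_positions:
        return sorted(out)
    return {frag for _, frag in out}


# ---------------------------------------------------------------------------
# matching


def build_peptide_index(
    bcr_db: list[TranslatedBcr],
) -> dict[str, list[tuple[int, int]]]:
    """Index every tryptic-consistent fragment (any number of missed
    cleavages, ends included) to its (sequence index, start) occurrences."""
    index: dict[str, list[tuple[int, int]]] = {}
    for si, bcr in enumerate(bcr_db):
        aa = bcr.aa_sequence
        bounds = [0] + cleavage_sites(aa) + [len(aa)]
        for i in range(len(bounds) - 1):
            for j in range(i + 1, len(bounds)):
                frag = aa[bounds[i] : bounds[j]]
                index.setdefault(frag, []).append((si, bounds[i]))
    return index


def _cdr_overlap(
    start: int, end: int, intervals: tuple[tuple[int, int], ...]
) -> int:
    """Residues of [start, end) inside any single CDR interval (max over
    intervals)."""
    best = 0
    for a, b in intervals:
        best = max(best, min(end, b) - max(start, a))
    return best


def match_peptides(
    peptides,
    bcr_db: list[TranslatedBcr],
    min_cdr_overlap: int = 3,
    unique_level: str = "aa",
) -> tuple[list[PeptideMatch], list[str]]:
    """Match observed peptides against a patient's translated BCR database.

    A match is an exact substring occurrence with tryptic-consistent
    boundaries. ``unique_level='aa'`` counts amino-acid-distinct sequences
    when deciding specificity (nucleotide variants with identical protein
    are one sequence); ``'id'`` counts every sequence record separately.
    Returns the matches and a list of skipped peptides (non-standard
    characters).
    """
    if unique_level not in ("aa", "id"):
        raise ConfigurationError("unique_level must be 'aa' or 'id'")
    index = build_peptide_index(bcr_db)
    matches = []
    skipped = []
    for pep in peptides:
        if not pep or set(pep) - STANDARD_AA:
            skipped.append(pep)
            continue
        occs = index.get(pep, [])
        ids = tuple(sorted({bcr_db[si].sequence_id for si, _ in occs}))
        if unique_level == "aa":
            distinct = len({bcr_db[si].aa_sequence for si, _ in occs})
        else:
            distinct = len(ids)
        overlap = 0
        for si, start in occs:
            overlap = max(
                overlap,
                _cdr_overlap(start, start + len(pep), bcr_db[si].cdr_intervals),
            )
        matches.append(
            PeptideMatch(
                peptide_aa=pep,
                matched_sequence_ids=ids,
                n_distinct=distinct,
                cdr_overlap_aa=overlap,
                is_specific=(distinct == 1 and overlap >= min_cdr_overlap),
            )
        )
    # both filter clauses hold on everything reported as specific
    for m in matches:
        assert not m.is_specific or (
            m.n_distinct == 1 and m.cdr_overlap_aa >= min_cdr_overlap
        )
    return matches, skipped


def attribute_specific_peptides(
    matches: list[PeptideMatch],
    rearrangements: pd.DataFrame,
    peptide_meta: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Attribute each specific peptide to the time points, isotypes, and
    subsets of its matched transcriptome sequences.

    ``peptide_meta`` (optional, columns peptide_aa/patient/timepoint) adds
    the peptide library's own time point. A matched sequence id absent from
    the rearrangement table is a referential integrity error.
    """
    by_id = rearrangements.set_index("sequence_id")
    meta_lookup = {}
    if peptide_meta is not None:
        for rec in peptide_meta.itertuples(index=False):
            meta_lookup.setdefault(rec.peptide_aa, []).append(rec.timepoint)
    rows = []
    for m in matches:
        if not m.is_specific:
            continue
        tps, isos, subs = set(), set(), set()
        for sid in m.matched_sequence_ids:
            if sid not in by_id.index:
                raise DataError(
                    f"matched sequence id {sid} absent from rearrangement table"
                )
            rec = by_id.loc[sid]
            recs = rec.to_frame().T if isinstance(rec, pd.Series) else rec
            tps.update(recs["timepoint"])
            isos.update(recs["isotype"])
            subs.update(recs["subset"])
        rows.append(
            {
                "peptide_aa": m.peptide_aa,
                "library_timepoints": ";".join(
                    sorted(set(meta_lookup.get(m.peptide_aa, [])))
                ),
                "matched_sequence_ids": ";".join(m.matched_sequence_ids),
                "cdr_overlap_aa": m.cdr_overlap_aa,
                "attributed_timepoints": ";".join(sorted(tps)),
                "attributed_isotypes": ";".join(sorted(isos)),
                "attributed_subsets": ";".join(sorted(subs)),
            }
        )
    return pd.DataFrame(rows)
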