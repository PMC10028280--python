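"""Germline V/J assignment, junction extraction, productivity, and AIRR I/O.

A semi-global (infix) aligner over the toy germline database substitutes for
IgBLAST at desk scale: the best-identity V and J segments locate the
conserved Cys and Trp codons, between which the junction (CDR3 plus its
conserved flanks) is taken. Records falling below the identity floor are
excluded as unannotatable. Real-data users can instead ingest externally
annotated AIRR Rearrangement TSV via :func:`read_airr`.

Coordinates are 0-based half-open internally; the AIRR TSV columns
``v_sequence_start`` and ``junction_start`` follow the AIRR 1-based
convention, and the junction includes both conserved residues.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import edlib
import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .errors import SchemaError
from .germline import GermlineSegment

AIRR_REQUIRED = ("sequence_id", "v_call", "j_call", "junction", "duplicate_count")

_AIRR_INT_COLS = ("junction_length", "duplicate_count", "v_sequence_start", "junction_start")
_AIRR_FLOAT_COLS = ("v_identity", "j_identity")
_AIRR_BOOL_COLS = ("productive",)


@dataclass
class Annotation:
    v_call: str
    j_call: str
    v_identity: float
    j_identity: float
    v_start: int  # 0-based start of the V alignment on the query
    junction_start: int  # 0-based, points at the conserved Cys codon
    junction_end: int  # 0-based exclusive, just past the conserved Trp codon
    tie: bool = False  # another segment scored identically (lexicographic pick)


def _best_segment(
    seq: str, segments: Sequence[GermlineSegment]
) -> tuple[GermlineSegment, int, tuple[int, int], bool]:
    best = None
    tie = False
    for seg in sorted(segments, key=lambda s: s.name):
        res = edlib.align(seg.sequence, seq, mode="HW", task="locations")
        dist = res["editDistance"]
        if best is None or dist < best[1]:
            best = (seg, dist, res["locations"][0])
            tie = False
        elif dist == best[1]:
            tie = True
    seg, dist, loc = best
    return seg, dist, loc, tie


def _snap_codon(
    seq: str, pos: int, frame_anchor: int, targets: tuple[str, ...]
) -> int:
    """Snap ``pos`` to the closest in-frame codon start (relative to
    ``frame_anchor``) whose codon is one of ``targets``; falls back to the
    frame-corrected position when no target codon is nearby."""
    base = frame_anchor + 3 * round((pos - frame_anchor) / 3)
    for off in (0, -3, 3, -6, 6):
        cand = base + off
        if 0 <= cand and cand + 3 <= len(seq) and seq[cand : cand + 3] in targets:
            return cand
    return base


def assign_germline(
    seq: str,
    germline_db: Sequence[GermlineSegment],
    identity_floor: float = 0.70,
) -> Annotation | None:
    """Locate the best V and J segments and the junction between them.

    Returns ``None`` when no segment reaches the identity floor or the
    implied junction is degenerate (record unannotatable).
    """
    v_segs = [s for s in germline_db if s.kind == "V"]
    j_segs = [s for s in germline_db if s.kind == "J"]
    if not v_segs or not j_segs:
        raise SchemaError("germline database must contain V and J segments")
    v, v_dist, v_loc, v_tie = _best_segment(seq, v_segs)
    j, j_dist, j_loc, j_tie = _best_segment(seq, j_segs)
    v_identity = 1.0 - v_dist / len(v.sequence)
    j_identity = 1.0 - j_dist / len(j.sequence)
    if v_identity < identity_floor or j_identity < identity_floor:
        return None
    v_start, v_end = v_loc  # end inclusive
    j_start = j_loc[0]
    # raw boundaries from the alignment ends, then snapped to the nearest
    # in-frame conserved codon (Cys at the V end, Trp at the J start) —
    # alignment ends can drift by a base or two when a mutation sits next
    # to the boundary, but the conserved codons anchor the junction
    junction_start = _snap_codon(
        seq, v_end - 2, frame_anchor=v_start, targets=("TGT", "TGC")
    )
    junction_end = (
        _snap_codon(seq, j_start, frame_anchor=junction_start, targets=("TGG",))
        + 3
    )
    if not (0 <= junction_start < junction_end <= len(seq)):
        return None
    if junction_end - junction_start < 6:
        return None
    return Annotation(
        v_call=v.name,
        j_call=j.name,
        v_identity=v_identity,
        j_identity=j_identity,
        v_start=v_start,
        junction_start=junction_start,
        junction_end=junction_end,
        tie=v_tie or j_tie,
    )


def check_productivity(seq: str, ann: Annotation) -> bool:
    """Productive iff the junction is in-frame with the V start and the
    translated region from the V start carries no stop codon."""
    jlen = ann.junction_end - ann.junction_start
    if jlen % 3 != 0:
        return False
    if (ann.junction_start - ann.v_start) % 3 != 0:
        return False
    region = seq[ann.v_start :]
    region = region[: 3 * (len(region) // 3)]
    return "*" not in str(Seq(region).translate())


def annotate_rearrangements(
    records: pd.DataFrame,
    germline_db: Sequence[GermlineSegment],
    identity_floor: float = 0.70,
    sequence_col: str = "sequence",
) -> tuple[pd.DataFrame, dict]:
    """Annotate consensus records (one row per unique sequence).

    Input must carry ``sequence`` and ``duplicate_count``; passthrough
    metadata columns (patient, timepoint, subset, isotype) are preserved.
    Unannotatable records are excluded and counted in the log. Output order
    is deterministic and independent of input order (sorted by sequence and
    metadata).
    """
    meta_cols = [
        c
        for c in ("patient", "timepoint", "subset", "isotype", "umi_count_support")
        if c in records.columns
    ]
    work = records.sort_values(
        [sequence_col] + meta_cols, kind="mergesort"
    ).reset_index(drop=True)
    rows = []
    n_unannotatable = 0
    n_ties = 0
    cache: dict[str, Annotation | None] = {}
    for i, rec in enumerate(work.itertuples(index=False)):
        seq = getattr(rec, sequence_col)
        if seq in cache:
            ann = cache[seq]
        else:
            ann = assign_germline(seq, germline_db, identity_floor)
            cache[seq] = ann
        if ann is None:
            n_unannotatable += 1
            continue
        n_ties += int(ann.tie)
        junction = seq[ann.junction_start : ann.junction_end]
        jlen = len(junction)
        productive = check_productivity(seq, ann)
        row = {
            "sequence_id": f"seq-{i:07d}",
            "sequence": seq,
            "v_call": ann.v_call,
            "j_call": ann.j_call,
            "junction": junction,
            "junction_aa": (
                str(Seq(junction).translate()) if jlen % 3 == 0 else ""
            ),
            "junction_length": jlen,
            "v_identity": round(ann.v_identity, 4),
            "j_identity": round(ann.j_identity, 4),
            "v_sequence_start": ann.v_start + 1,
            "junction_start": ann.junction_start + 1,
            "productive": productive,
            "duplicate_count": int(getattr(rec, "duplicate_count", 1)),
        }
        for c in meta_cols:
            row[c] = getattr(rec, c)
        rows.append(row)
    out = pd.DataFrame(rows)
    log = {
        "step": "annotate",
        "in": len(work),
        "pass": len(rows),
        "fail": n_unannotatable,
        "ties": n_ties,
    }
    return out, log


# ---------------------------------------------------------------------------
# AIRR Rearrangement TSV


def write_airr(df: pd.DataFrame, path) -> None:
    """Write an AIRR Rearrangement TSV (booleans as T/F, missing as empty)."""
    for col in AIRR_REQUIRED:
        if col not in df.columns:
            raise SchemaError(f"missing required AIRR column: {col}")
    out = df.copy()
    for col in _AIRR_BOOL_COLS:
        if col in out.columns:
            out[col] = out[col].map(lambda v: "T" if bool(v) else "F")
    out.to_csv(path, sep="\t", index=False, na_rep="")


def read_airr(path) -> pd.DataFrame:
    """Read an AIRR Rearrangement TSV; extra columns are preserved opaquely.

    Raises SchemaError naming the first missing required column.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in AIRR_REQUIRED:
        if col not in df.columns:
            raise SchemaError(f"missing required AIRR column: {col}")
    for col in _AIRR_INT_COLS:
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce").astype("Int64")
            if not df[col].isna().any():
                df[col] = df[col].astype(int)
    for col in _AIRR_FLOAT_COLS:
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    for col in _AIRR_BOOL_COLS:
        if col in df.columns:
            df[col] = df[col].map({"T": True, "F": False})
    return df
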