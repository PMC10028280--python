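"""Clonal inference: group rearrangements into clones per patient.

A clone is defined by the three-part rule used throughout the analysis:
(1) identical CDR3/junction nucleotide length, (2) the same V gene and
J gene (allele suffixes stripped), and (3) junction nucleotide identity of
at least 88%, linked by single-linkage clustering. With equal lengths inside
a group the identity is 1 - hamming/L, so the link condition is an integer
mismatch threshold floor(0.12 * L) and no alignment is needed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import DataError


def gene_of(call: str) -> str:
    """Gene-level name: first listed call, allele suffix stripped."""
    if not call:
        return ""
    return call.split(",")[0].strip().split("*")[0]


def partition(df: pd.DataFrame) -> tuple[dict, pd.DataFrame, dict]:
    """Partition records by (patient, v_gene, j_gene, junction_length).

    Returns ``(groups, ungrouped, log)`` where ``groups`` maps each key to
    the integer index array of member rows. Records with empty V or J calls
    are routed to the ungrouped bin. The partition is exhaustive and
    disjoint: group sizes plus ungrouped rows equal the input size.
    """
    if len(df) == 0:
        return {}, df, {"step": "partition", "in": 0, "groups": 0, "ungrouped": 0}
    v_gene = df["v_call"].map(gene_of)
    j_gene = df["j_call"].map(gene_of)
    jlen = df["junction"].str.len()
    ok = (v_gene != "") & (j_gene != "")
    groups: dict[tuple, np.ndarray] = {}
    sub = pd.DataFrame(
        {
            "patient": df.loc[ok, "patient"],
            "v_gene": v_gene[ok],
            "j_gene": j_gene[ok],
            "junction_length": jlen[ok],
        }
    )
    for key, idx in sub.groupby(
        ["patient", "v_gene", "j_gene", "junction_length"], sort=True
    ).groups.items():
        groups[key] = np.asarray(idx)
    ungrouped = df.loc[~ok]
    log = {
        "step": "partition",
        "in": len(df),
        "groups": len(groups),
        "ungrouped": len(ungrouped),
    }
    return groups, ungrouped, log


def max_mismatches(length: int, min_identity: float) -> int:
    """Largest mismatch count still linking two junctions of this length
    (identity >= min_identity inclusive, guarded against float fuzz)."""
    return int(np.floor((1.0 - min_identity) * length + 1e-9))


def cluster_junctions(
    junctions: list[str], min_identity: float = 0.88
) -> list[int]:
    """Single-linkage clusters over equal-length junctions.

    Two junctions link iff their nucleotide identity is >= ``min_identity``
    (boundary inclusive). Returns a cluster label per input junction;
    labels are assigned deterministically (clusters ordered by their
    lexicographically smallest member) and are invariant to input order.
    """
    if not junctions:
        return []
    lengths = {len(j) for j in junctions}
    if len(lengths) != 1:
        raise DataError("cluster_junctions requires equal-length junctions")
    L = lengths.pop()
    uniq = sorted(set(junctions))
    n = len(uniq)
    if L == 0:
        # degenerate: every sequence its own clone
        label_of = {u: i for i, u in enumerate(uniq)}
        return [label_of[j] for j in junctions]
    thresh = max_mismatches(L, min_identity)

    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: int, b: int) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)

    arr = np.vstack([np.frombuffer(u.encode(), dtype=np.uint8) for u in uniq])
    for i in range(n - 1):
        mism = (arr[i + 1 :] != arr[i]).sum(axis=1)
        for off in np.flatnonzero(mism <= thresh):
            union(i, i + 1 + int(off))

    roots = [find(i) for i in range(n)]
    # relabel clusters by smallest member junction (uniq is sorted, so the
    # root index order already is that order)
    relabel: dict[int, int] = {}
    for r in roots:
        if r not in relabel:
            relabel[r] = len(relabel)
    label_of = {u: relabel[roots[i]] for i, u in enumerate(uniq)}
    return [label_of[j] for j in junctions]


def assign_clone_ids(
    df: pd.DataFrame, min_identity: float = 0.88
) -> tuple[pd.DataFrame, dict]:
    """Assign a ``clone_id`` to every record, pooling all time points and
    subsets within a patient; IDs are never shared across patients and the
    assignment is deterministic and independent of record order."""
    groups, ungrouped, plog = partition(df)
    out = df.copy()
    out["clone_id"] = pd.Series([""] * len(df), index=df.index, dtype=str)
    counters: dict[str, int] = {}
    for key in sorted(groups):
        patient = key[0]
        idx = groups[key]
        junctions = df.loc[idx, "junction"].tolist()
        labels = cluster_junctions(junctions, min_identity=min_identity)
        base = counters.get(patient, 0)
        out.loc[idx, "clone_id"] = [f"{patient}_{base + l:06d}" for l in labels]
        counters[patient] = base + max(labels) + 1
    n_multi_call = int(
        df["v_call"].astype(str).str.contains(",").sum()
        + df["j_call"].astype(str).str.contains(",").sum()
    )
    log = {
        "step": "assign_clone_ids",
        "in": len(df),
        "clones": sum(counters.values()),
        "ungrouped": plog["ungrouped"],
        "ambiguous_multi_gene_calls": n_multi_call,
    }
    return out, log


def clone_summary(df: pd.DataFrame) -> pd.DataFrame:
    """Per-clone summary: sizes in sequences and copies, samples present."""
    if "clone_id" not in df.columns:
        raise DataError("records carry no clone_id; run assign_clone_ids first")
    rows = []
    for clone_id, grp in df[df["clone_id"] != ""].groupby("clone_id", sort=True):
        rows.append(
            {
                "clone_id": clone_id,
                "patient": grp["patient"].iloc[0],
                "v_gene": gene_of(grp["v_call"].iloc[0]),
                "j_gene": gene_of(grp["j_call"].iloc[0]),
                "junction_length": len(grp["junction"].iloc[0]),
                "size_sequences": len(grp),
                "size_copies": int(grp["duplicate_count"].sum()),
                "samples_present": ";".join(
                    sorted(
                        {
                            f"{t}|{s}"
                            for t, s in zip(grp["timepoint"], grp["subset"])
                        }
                    )
                )
                if "timepoint" in grp.columns and "subset" in grp.columns
                else "",
            }
        )
    return pd.DataFrame(rows)
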