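"""Longitudinal clone tracking: span classes and overlap proportions.

A clone's *span* is the exact set of time points at which any of its member
sequences was observed; the seven non-empty subsets of {B, 6M, 12M} form
mutually exclusive *span classes* (a clone of class B+6M has no sequence at
12M). Spans are also computed per B-cell subset, where one clone may occupy
different classes in different subsets. Overlap proportions default to the
multi-time-point denominator (clones spanning >= 2 time points), which is
the convention behind statements like "60% of clones relate to all three
time points".
"""

from __future__ import annotations

from itertools import combinations

import pandas as pd

from .errors import DataError
from .simulate import TIMEPOINTS


def span_label(timepoints) -> str:
    """Canonical class label: time points joined with '+' in study order."""
    tps = set(timepoints)
    unknown = tps - set(TIMEPOINTS)
    if unknown:
        raise DataError(f"unknown time points: {sorted(unknown)}")
    return "+".join(t for t in TIMEPOINTS if t in tps)


def all_span_classes() -> list[str]:
    """The seven non-empty span classes in canonical order."""
    out = []
    for r in range(1, len(TIMEPOINTS) + 1):
        for combo in combinations(TIMEPOINTS, r):
            out.append("+".join(combo))
    return out


def compute_spans(records: pd.DataFrame) -> pd.DataFrame:
    """Span per clone, overall and per subset.

    Returns one row per (patient, clone_id, level) where level is 'all' or a
    subset name, with the span class label. Records lacking a time point
    raise a DataError naming the offending record.
    """
    for col in ("clone_id", "patient", "timepoint", "subset"):
        if col not in records.columns:
            raise DataError(f"span computation requires column {col}")
    bad = records[
        records["timepoint"].isna() | (records["timepoint"].astype(str) == "")
    ]
    if len(bad):
        raise DataError(
            f"record without timepoint: sequence_id="
            f"{bad.iloc[0].get('sequence_id', bad.index[0])}"
        )
    rows = []
    for (patient, clone_id), grp in records.groupby(
        ["patient", "clone_id"], sort=True
    ):
        rows.append(
            {
                "patient": patient,
                "clone_id": clone_id,
                "level": "all",
                "span": span_label(grp["timepoint"]),
            }
        )
        for subset, sgrp in grp.groupby("subset", sort=True):
            rows.append(
                {
                    "patient": patient,
                    "clone_id": clone_id,
                    "level": subset,
                    "span": span_label(sgrp["timepoint"]),
                }
            )
    return pd.DataFrame(rows)


def span_class_counts(
    spans: pd.DataFrame, level: str = "all"
) -> pd.DataFrame:
    """Clone counts per span class and patient at the requested level
    ('all' or a subset name). Classes are exclusive and exhaustive: per
    patient the counts sum to the number of clones observed at that level."""
    sel = spans[spans["level"] == level]
    classes = all_span_classes()
    table = (
        sel.groupby(["patient", "span"]).size().unstack(fill_value=0)
    )
    for c in classes:
        if c not in table.columns:
            table[c] = 0
    return table[classes]


def overlap_proportions(
    counts: pd.DataFrame, denominator: str = "multi"
) -> pd.DataFrame:
    """Fractions of clones per span class and patient.

    ``denominator='multi'`` divides by clones spanning at least two time
    points (the convention for cross-time-point overlap percentages);
    ``denominator='all'`` divides by all clones. Raises on zero clones.
    """
    if denominator not in ("multi", "all"):
        raise DataError("denominator must be 'multi' or 'all'")
    multi = [c for c in counts.columns if "+" in c]
    cols = multi if denominator == "multi" else list(counts.columns)
    denom = counts[cols].sum(axis=1)
    if (denom == 0).any():
        bad = denom[denom == 0].index[0]
        raise DataError(f"zero clones in denominator for patient {bad}")
    return counts[cols].div(denom, axis=0)
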