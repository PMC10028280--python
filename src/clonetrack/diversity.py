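"""Clonal diversity: Hill numbers with bootstrap resampling.

The Hill number of order q for clone abundances p_i is

    qD = (sum_i p_i^q)^(1/(1-q)),    q != 1
    1D = exp(-sum_i p_i ln p_i)      (the q -> 1 limit)

so q=0 is clone richness and q=1 the exponential Shannon entropy (the
abundance-weighted effective number of clones). Bootstrap estimates draw a
fixed number of sequence records with replacement, copy-weighted by
duplicate_count, recompute clone abundances, and report the mean and sd of
the Hill number over repetitions — the procedure used for repertoire
diversity panels (n = 951 sequences, 200 repetitions by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError

#: near-1 band inside which the entropy limit is used for numerical continuity
_Q1_EPS = 1e-9


@dataclass
class HillDiversity:
    q: float
    point_estimate: float
    bootstrap_mean: float
    bootstrap_sd: float
    n_boot: int
    n_resample: int
    small_sample: bool = False  # sample held fewer records than n_resample


def hill_number(abundances, q: float) -> float:
    """Hill diversity of order q >= 0 for an abundance vector.

    Accepts raw counts or proportions (normalized internally); zero entries
    are ignored. Empty or all-zero input is undefined and raises DataError.
    """
    p = np.asarray(abundances, dtype=float)
    if p.size == 0:
        raise DataError("Hill number undefined for an empty abundance vector")
    if np.any(p < 0):
        raise DataError("abundances must be non-negative")
    p = p[p > 0]
    if p.size == 0:
        raise DataError("Hill number undefined when all abundances are zero")
    if q < 0:
        raise ConfigurationError("order q must be >= 0")
    p = p / p.sum()
    if abs(q - 1.0) < _Q1_EPS:
        return float(np.exp(-np.sum(p * np.log(p))))
    if q == 0:
        return float(p.size)
    return float(np.sum(p**q) ** (1.0 / (1.0 - q)))


def clonal_abundance(sample: pd.DataFrame) -> pd.Series:
    """Clone abundances (sum of duplicate_count) for one sample's records."""
    if len(sample) == 0:
        raise DataError("empty sample: no records")
    counts = sample.groupby("clone_id", sort=True)["duplicate_count"].sum()
    return counts.astype(float)


def bootstrap_diversity(
    counts: pd.Series | np.ndarray,
    q: float,
    n_resample: int = 951,
    n_boot: int = 200,
    seed: int = 0,
) -> HillDiversity:
    """Bootstrap a Hill number from clone copy counts.

    Each repetition draws ``n_resample`` sequence records with replacement,
    weighted by copy number, and recomputes the Hill number on the resampled
    clone abundances. Samples holding fewer records than ``n_resample`` are
    resampled with replacement regardless and flagged.
    """
    c = np.asarray(counts, dtype=float)
    if c.size == 0 or c.sum() <= 0:
        raise DataError("bootstrap requires at least one record")
    if n_boot < 1 or n_resample < 1:
        raise ConfigurationError("n_boot and n_resample must be >= 1")
    p = c / c.sum()
    rng = np.random.default_rng(seed)
    draws = rng.multinomial(n_resample, p, size=n_boot)
    values = np.empty(n_boot)
    for i in range(n_boot):
        values[i] = hill_number(draws[i], q)
    return HillDiversity(
        q=q,
        point_estimate=hill_number(c, q),
        bootstrap_mean=float(values.mean()),
        bootstrap_sd=float(values.std(ddof=1)) if n_boot > 1 else 0.0,
        n_boot=n_boot,
        n_resample=n_resample,
        small_sample=bool(c.sum() < n_resample),
    )


def expanded_clone_fraction(
    clone_sizes, min_sequences: int = 100
) -> float:
    """Percentage of clones with strictly more than ``min_sequences``
    member sequences."""
    sizes = np.asarray(clone_sizes)
    if sizes.size == 0:
        raise DataError("expanded-clone fraction undefined for zero clones")
    return float(100.0 * (sizes > min_sequences).sum() / sizes.size)


def diversity_table(
    records: pd.DataFrame,
    q_values=(0.0, 1.0),
    n_resample: int = 951,
    n_boot: int = 200,
    seed: int = 0,
    group_cols=("patient", "timepoint", "subset"),
) -> pd.DataFrame:
    """Bootstrap Hill numbers for every (patient, timepoint, subset) sample.

    Per-sample seeds are derived deterministically from ``seed`` and the
    sorted sample order, so the whole table is reproducible bit-for-bit.
    """
    if "clone_id" not in records.columns:
        raise DataError("records carry no clone_id; run clonal inference first")
    rows = []
    group_cols = list(group_cols)
    for gi, (key, grp) in enumerate(records.groupby(group_cols, sort=True)):
        counts = clonal_abundance(grp)
        sizes = grp.groupby("clone_id").size()
        for q in q_values:
            hd = bootstrap_diversity(
                counts, q, n_resample=n_resample, n_boot=n_boot,
                seed=(seed * 100003 + gi) % (2**31),
            )
            row = dict(zip(group_cols, key if isinstance(key, tuple) else (key,)))
            row.update(
                q=q,
                point_estimate=hd.point_estimate,
                bootstrap_mean=hd.bootstrap_mean,
                bootstrap_sd=hd.bootstrap_sd,
                n_records=int(counts.sum()),
                n_clones=len(counts),
                small_sample=hd.small_sample,
                expanded_clone_pct=expanded_clone_fraction(sizes.values),
            )
            rows.append(row)
    return pd.DataFrame(rows)
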