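"""Cohort summaries and the non-parametric test battery.

Two gatekept comparison schemes are provided, matching common practice for
small longitudinal cohorts: Friedman's test with Dunn's pairwise post-hoc
(for complete patient x time-point blocks, e.g. subset percentages), and
Kruskal-Wallis with paired Wilcoxon signed-rank post-hocs (for repertoire
metrics). Post-hoc results are reported only when the omnibus test is
significant. The "rank-sum paired" wording sometimes seen for the post-hoc
is internally contradictory; the paired test (signed-rank) is used, with
rank-sum available by flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import ConfigurationError, DataError


def round_half_up(x: float) -> int:
    """Round to the nearest integer with halves away from zero upward."""
    return int(Decimal(repr(float(x))).quantize(0, rounding=ROUND_HALF_UP))


@dataclass
class PosthocPair:
    pair: tuple[str, str]
    statistic: float
    p_value: float
    p_adjusted: float


@dataclass
class ComparisonResult:
    metric: str
    grouping: tuple[str, ...]
    omnibus_name: str
    statistic: float
    p_value: float
    alpha: float
    adjustment: str
    posthoc: list[PosthocPair] = field(default_factory=list)

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


def summarize_cohort(
    counts: pd.DataFrame,
    metrics: tuple[str, ...],
    by: str = "timepoint",
) -> pd.DataFrame:
    """Mean (half-up integer) and (min, max) range per group for each metric.

    Input: one row per patient x group with numeric metric columns.
    """
    if len(counts) == 0:
        raise DataError("empty cohort")
    rows = []
    for group, grp in counts.groupby(by, sort=False, observed=True):
        for metric in metrics:
            vals = grp[metric].astype(float)
            rows.append(
                {
                    by: group,
                    "metric": metric,
                    "n": len(vals),
                    "mean": round_half_up(vals.mean()),
                    "min": int(vals.min()),
                    "max": int(vals.max()),
                }
            )
    return pd.DataFrame(rows)


def _friedman(values: np.ndarray) -> tuple[float, float]:
    """Friedman chi-square on within-block ranks; degenerate all-constant
    blocks give statistic 0, p 1 rather than a division by zero."""
    if np.all(values == values[:, [0]]):
        return 0.0, 1.0
    stat, p = sps.friedmanchisquare(*[values[:, j] for j in range(values.shape[1])])
    if np.isnan(stat):
        return 0.0, 1.0
    return float(stat), float(p)


def friedman_dunn(
    blocks: pd.DataFrame,
    alpha: float = 0.05,
    adjust: str = "holm",
    metric: str = "",
) -> ComparisonResult:
    """Friedman omnibus over complete blocks (rows = patients, columns =
    time points) with Dunn's pairwise z-tests on mean within-block ranks,
    reported only when the omnibus is significant."""
    if blocks.isna().any().any():
        pat = blocks.index[blocks.isna().any(axis=1)][0]
        col = blocks.columns[blocks.isna().any(axis=0)][0]
        raise DataError(f"missing cell: patient {pat}, time point {col}")
    if adjust not in ("none", "bonferroni", "holm"):
        raise ConfigurationError(f"unknown adjustment {adjust!r}")
    values = blocks.to_numpy(dtype=float)
    n, k = values.shape
    if n < 2 or k < 2:
        raise DataError("need at least 2 blocks and 2 treatments")
    stat, p = _friedman(values)
    result = ComparisonResult(
        metric=metric,
        grouping=tuple(map(str, blocks.columns)),
        omnibus_name="friedman",
        statistic=stat,
        p_value=p,
        alpha=alpha,
        adjustment=adjust,
    )
    if p >= alpha:
        return result
    ranks = np.apply_along_axis(sps.rankdata, 1, values)
    mean_ranks = ranks.mean(axis=0)
    se = np.sqrt(k * (k + 1) / (6.0 * n))
    pairs, zs, ps = [], [], []
    cols = list(blocks.columns)
    for i in range(k):
        for j in range(i + 1, k):
            z = abs(mean_ranks[i] - mean_ranks[j]) / se
            pairs.append((str(cols[i]), str(cols[j])))
            zs.append(z)
            ps.append(2.0 * sps.norm.sf(z))
    if adjust == "none":
        adj = ps
    else:
        adj = multipletests(ps, method=adjust)[1]
    result.posthoc = [
        PosthocPair(pair, float(z), float(pr), float(pa))
        for pair, z, pr, pa in zip(pairs, zs, ps, adj)
    ]
    return result


def kw_then_wilcoxon(
    groups: dict[str, np.ndarray],
    paired_pairs: list[tuple[str, str]],
    alpha: float = 0.05,
    paired_test: str = "signed_rank",
    metric: str = "",
) -> ComparisonResult:
    """Kruskal-Wallis omnibus; if significant, paired Wilcoxon tests on the
    stated pairs (exact p for n <= 25 without ties, normal approximation
    above — scipy's automatic policy)."""
    for name, vals in groups.items():
        if len(vals) < 2:
            raise DataError(f"group {name!r} has fewer than 2 observations")
    if paired_test not in ("signed_rank", "rank_sum"):
        raise ConfigurationError(f"unknown paired_test {paired_test!r}")
    names = sorted(groups)
    arrays = [np.asarray(groups[n], dtype=float) for n in names]
    if all(np.array_equal(a, arrays[0]) for a in arrays[1:]) and np.all(
        arrays[0] == arrays[0][0]
    ):
        stat, p = 0.0, 1.0
    else:
        stat, p = sps.kruskal(*arrays)
    result = ComparisonResult(
        metric=metric,
        grouping=tuple(names),
        omnibus_name="kruskal_wallis",
        statistic=float(stat),
        p_value=float(p),
        alpha=alpha,
        adjustment="none",
    )
    if p >= alpha:
        return result
    for a, b in paired_pairs:
        x, y = np.asarray(groups[a], float), np.asarray(groups[b], float)
        if paired_test == "signed_rank":
            if len(x) != len(y):
                raise DataError(f"paired test needs equal sizes for {(a, b)}")
            st, pv = sps.wilcoxon(x, y, method="auto")
        else:
            st, pv = sps.ranksums(x, y)
        result.posthoc.append(PosthocPair((a, b), float(st), float(pv), float(pv)))
    return result
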