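"""Small bundled datasets.

``load_cohort_counts`` returns the published per-patient sequencing yields
of an 8-patient cladribine-treated MS cohort sampled at baseline, 6 and 12
months: sorted B cells per sample, unique consensus sequences with >= 2
representative reads, and sequences surviving germline annotation. It is
the worked-example input for :func:`clonetrack.stats.summarize_cohort`.
"""

from importlib import resources

import pandas as pd

_TIMEPOINT_ORDER = ("B", "6M", "12M")


def load_cohort_counts() -> pd.DataFrame:
    with resources.files("clonetrack.data").joinpath(
        "cladribine_cohort_counts.tsv"
    ).open() as fh:
        df = pd.read_csv(fh, sep="\t")
    df["timepoint"] = pd.Categorical(
        df["timepoint"], categories=_TIMEPOINT_ORDER, ordered=True
    )
    return df
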