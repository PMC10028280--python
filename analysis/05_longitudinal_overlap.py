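#!/usr/bin/env python
"""Classify every inferred clone by the exact set of time points its
sequences span (overall and per subset) and report the overlap proportions
among multi-time-point clones."""

from pathlib import Path

from clonetrack import annotate, overlap

OUT = Path("results/analysis")


def main() -> None:
    rearr = annotate.read_airr(OUT / "rearrangements.tsv")
    spans = overlap.compute_spans(rearr)
    spans.to_csv(OUT / "clone_spans.tsv", sep="\t", index=False)

    counts = overlap.span_class_counts(spans, level="all")
    counts.to_csv(OUT / "span_class_counts.tsv", sep="\t")
    props = 100.0 * overlap.overlap_proportions(counts, denominator="multi")
    props.round(2).to_csv(OUT / "span_proportions_pct.tsv", sep="\t")

    mean_props = props.mean(axis=0)
    print("multi-time-point clone classes, cohort mean percentages:")
    for cls in ("B+6M", "B+12M", "6M+12M", "B+6M+12M"):
        print(f"  {cls}: {mean_props[cls]:.1f}%")
    for subset in ("naive", "memory", "DN", "plasmablast"):
        sc = overlap.span_class_counts(spans, level=subset)
        sc.to_csv(OUT / f"span_class_counts_{subset}.tsv", sep="\t")
    print(f"wrote {OUT}/clone_spans.tsv, span_class_counts*.tsv, "
          f"span_proportions_pct.tsv")


if __name__ == "__main__":
    main()
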