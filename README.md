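# clonetrack

Longitudinal B-cell receptor (BCR) repertoire analysis for treatment-effect
studies, built around the kind of design used to follow B-cell-depleting
therapies in multiple sclerosis: peripheral blood B cells sorted into
naive, memory, double-negative (DN) and plasmablast subsets at baseline (B),
6 months (6M) and 12 months (12M); heavy-chain (IGH) amplicon sequencing
with unique molecular identifiers (UMIs) and constant-region barcodes; and
serum immunoglobulin mass-spectrometry peptides overlapped with each
patient's own transcriptome.

The package provides every computational stage as a tested library, plus a
synthetic cohort generator that emulates the study structure so the whole
pipeline is verifiable end-to-end without any sequencing download:

1. **Read processing** (`clonetrack.readproc`) — mean-Phred quality filter
   (threshold 20), mate pairing and overlap merging, subset/isotype
   demultiplexing, position-wise majority consensus per UMI group (maximum
   group mismatch rate 0.1, at least 2 reads per consensus), and collapsing
   identical sequences across UMIs into copy numbers.
2. **Annotation** (`clonetrack.annotate`) — semi-global V/J germline
   assignment, junction extraction between the conserved Cys and Trp
   codons, productivity calls, and AIRR Rearrangement TSV I/O for
   interoperability with externally annotated data.
3. **Clonal inference** (`clonetrack.clones`) — the three-part clone
   definition: identical junction (CDR3) nucleotide length, same V gene and
   J gene, and junction identity >= 88%, linked by single-linkage
   clustering. With equal lengths the identity is `1 - hamming/L`, so the
   link rule is exact integer arithmetic.
4. **Diversity** (`clonetrack.diversity`) — Hill numbers
   `qD = (sum p_i^q)^(1/(1-q))` (q=0 clone richness; q=1 the exponential
   Shannon entropy), bootstrapped by resampling n=951 sequence records,
   copy-weighted, over 200 repetitions; expanded-clone fractions
   (> 100 sequences per clone).
5. **Longitudinal overlap** (`clonetrack.overlap`) — every clone classified
   by the exact set of time points its sequences span (the seven exclusive
   classes of {B, 6M, 12M}), overall and per subset.
6. **Ig proteogenomics** (`clonetrack.proteo`) — in-silico tryptic digestion
   (cleave after K/R except before P, <= 2 missed cleavages, >= 6 residues),
   exact peptide matching with tryptic-consistent boundaries, and the
   specificity filter: a peptide is *specific* when it matches exactly one
   amino-acid-distinct BCR sequence and covers >= 3 residues of a CDR.
7. **Statistics** (`clonetrack.stats`) — cohort summary tables, Friedman +
   Dunn's post-hoc for complete patient x time-point blocks, and
   Kruskal-Wallis gatekeeping paired Wilcoxon signed-rank tests.
8. **Synthetic cohort** (`clonetrack.simulate`) — ground-truth clones with
   Zipf-distributed sizes, persistence classes across time points, subset
   propensities, somatic hypermutation, UMI-tagged paired reads with
   sequencing error, and serum tryptic peptides with decoys; a clone-level
   memory depletion models the treatment effect.

## Worked example

The numbered scripts under `analysis/` run the full study on a simulated
8-patient cohort (150 clones per patient, 3-fold memory depletion after
baseline). After `python analysis/01_simulate_cohort.py` through
`07_cohort_statistics.py`, the drivers print, among other things:

```
memory q=0: KW p = 0.0004; Wilcoxon 6M vs B p = 0.0078
memory q=1: KW p = 0.0167; Wilcoxon 6M vs B p = 0.0156
mean memory clone richness by time point: {'12M': 12.9, '6M': 11.4, 'B': 32.2}

multi-time-point clone classes, cohort mean percentages:
  B+6M: 1.8%
  B+12M: 9.8%
  6M+12M: 25.6%
  B+6M+12M: 62.8%

specific peptides attributed to all three time points: 37%
```

Reading: the memory compartment loses roughly two thirds of its clones
after treatment (richness 32 -> 11), significant by the gatekept paired
test, while clones spanning all three time points dominate the
multi-time-point overlap — the configured persistence structure
(60/26/12/2%) is recovered by the inference chain. A stable share of serum
Ig peptides aligns to transcriptome sequences present at every time point,
the signature of clones that persist through treatment.

`07_cohort_statistics.py` also reproduces the published per-patient yield
table bundled with the package, e.g. sorted B cells at baseline:
mean 211193, range 80298-308219 (n = 8 patients).

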