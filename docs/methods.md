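# Methods

This note documents the models, conventions and numerical choices behind
`clonetrack`, in the order data flows through the pipeline.

## Synthetic cohort model

The generator (`clonetrack.simulate`) produces ground truth for every
pipeline stage. Its defaults encode the study conditions the package is
built around: 8 patients, time points B/6M/12M, subsets
naive/memory/DN/plasmablast, ~1500 clones per patient at full scale
(analysis drivers and the acceptance script run 150-800 clones per patient,
which preserves every distributional property at a fraction of the cost;
those are the problem sizes reported alongside each result).

**Clone sizes.** Base sizes follow a truncated discrete power law
(Zipf, exponent 1.5, support 1..1000). The exponent is the conventional
repertoire assumption; the truncation keeps expected cell counts finite.
Because the distribution is discrete and heavily tied, the generator's
distributional self-test uses a randomized probability-integral transform
before the Kolmogorov-Smirnov comparison.

**Persistence classes.** Each clone is assigned one of the seven non-empty
subsets of {B, 6M, 12M} and receives expected cells only at those time
points. The default class probabilities put half the mass on single time
points (1/6 each) and split the multi-time-point half 60:26:12:2 across
B+6M+12M / 6M+12M / B+12M / B+6M, the structure observed in the cohort the
package models. Two helper constructors exist for experiments:
`null_scenario()` (no depletion, fully time-point-exchangeable classes, so
every contrast is a true null) and `treatment_scenario()` (the same plus
depletion). The exchangeable variant matters: with the study-shaped class
probabilities, B and 6M genuinely differ (more clones appear at 6M), so a
"null" built from them would not be a null.

**Subsets and isotypes.** Per-clone subset weights are Dirichlet(0.5)
draws, giving dominant-subset clones; the isotype distribution is keyed to
the dominant subset (naive clones IgM/IgD-heavy, memory and plasmablast
clones mostly switched).

**Treatment effect.** The depletion is clone-level: after baseline, a
clone's memory compartment survives with probability proportional to
`size^0.3` (capped at 1), normalized so that the *observed* memory clone
count drops by exactly the configured factor (default 3) in expectation.
The normalization weights each clone by its probability of being detected
in the memory compartment at all (1 - e^-lambda, plus the forced-presence
term), because survival bias toward large clones would otherwise make the
realized count ratio smaller than the configured factor. The size bias is
what makes the surviving memory compartment enriched for expanded clones,
mirroring the observed biology; the exponent 0.3 keeps the abundance-
weighted diversity (q=1) responsive to the depletion as well.

**Sampling.** Realized cells per (clone, time point, subset) are Poisson
with mean size x subset weight x scale; each clone is guaranteed at least
one cell at every time point of its persistence class while any compartment
remains eligible, so in the no-treatment case realized spans equal designed
classes exactly.

**Somatic hypermutation.** Each clone carries a lineage pool: the founder
plus 1 + Poisson(2) variants mutated uniformly per base at 2%. Cells draw
from the pool with founder-heavy weights (1/(rank+1)). This yields both
copy numbers > 1 (many cells with identical sequence, as in expanded
clones) and intra-clone variation safely below the 12% junction-divergence
clustering threshold. The conserved Cys/Trp junction-boundary codons are
protected and substitutions creating in-frame stops are reverted, so
generated cells stay productive; sequencing errors can still produce
unproductive records downstream. Hotspot-aware mutation models are out of
scope.

**Reads.** Template = subset barcode (8 nt) + VDJ + isotype tag (8 nt);
mate 1 = 12-nt UMI + template 5' end, mate 2 = reverse complement of the
template 3' end (250-nt reads, guaranteed overlap). Copies per molecule are
`min_copies + Poisson(mean - min_copies)`; substitution errors are uniform
per base (including UMI and barcode regions). Barcode/tag tables have
pairwise Hamming distance >= 6, safely demultiplexable at tolerance 1.

**Serum peptides.** Peptides are drawn per (patient, time point) from the
tryptic digests of clone founder proteins, with clone weights proportional
to realized cells and plasmablast cells up-weighted 5x (serum Ig comes from
antibody-secreting cells). A configurable fraction is replaced by decoys
(shuffled until they match no clone), emulating non-BCR serum background.

**What the generator does not emulate** — and hence what passing tests do
not establish about real data: realistic IMGT germline alleles and allele
ambiguity, SHM hotspot structure, indels (sequencing or biological), primer
artifacts and chimeras, class-switch lineage structure, UMI collisions
(same UMI on different molecules is a documented, unsplit limitation), and
spectrum-level mass-spectrometry effects (FDR, intensity, modifications).

## Read processing

Quality filtering keeps reads whose mean Phred score is >= 20 (the
pRESTO-style mean-quality semantic). Pairs merge by 3' overlap: an exact
20-mer seed (two offsets, tolerating one error near the tail) proposes
candidate overlaps, verified at <= 15% mismatches, largest overlap wins; an
exhaustive scan is the fallback. UMI groups are (UMI, subset) keyed.
Consensus is position-wise majority; members off the modal length are set
aside (groups failing `min_reads`=2 afterwards are rejected); the group is
rejected when the mean per-read normalized Hamming distance to the
consensus exceeds 0.1 — the published threshold does not say whether the
rate is per position, per read, or group-mean, and the group-mean reading
(BuildConsensus behavior) is used. Base ties resolve by summed quality,
then alphabetically, making the consensus order-invariant and
deterministic. Collapsing is exact sequence identity within (subset,
isotype); the duplicate count (number of distinct UMIs) is the copy-number
proxy used by all abundance analyses.

## Annotation

A semi-global (infix) edlib alignment of every germline segment against the
query picks the best V and J by identity (ties broken by name and flagged);
records below a 70% identity floor are unannotatable and excluded. Junction
boundaries come from the alignment ends snapped to the nearest in-frame
conserved codon (Cys TGT/TGC at the V end, Trp TGG at the J start, search
window +-2 codons): alignment ends can drift a base or two when a mutation
sits at the boundary, but the conserved codons anchor the junction. A
record is productive iff its junction is in-frame with the V start and the
translated region is stop-free; unproductive records are excluded before
cloning. Coordinates are 0-based half-open internally; the TSV columns
`v_sequence_start`/`junction_start` are 1-based following AIRR convention,
and the junction includes both conserved residues. Gene-level grouping
strips allele suffixes and, for multi-gene calls, uses the first listed
gene (flagged in logs). This simplified aligner substitutes for full
IgBLAST/IMGT inference, which is out of scope; externally annotated AIRR
TSV can be ingested instead.

## Clonal inference

Records are partitioned by (patient, V gene, J gene, junction length) —
pooling all time points and subsets of a patient, which is what makes
cross-time-point span analysis well-defined — then single-linkage
clustered: two junctions link iff identity >= 0.88, i.e. mismatches <=
floor(0.12 L) (inclusive boundary; ties at the boundary are links; exact
integer comparison, no float fuzz). Hamming distance is the right metric
because lengths are equal within a group, so no indels are possible.
Cluster labels are deterministic: clusters are ordered by their
lexicographically smallest member, IDs assigned per patient in sorted group
order, and the partition is invariant to record order. A brute-force
connected-components oracle (independent BFS implementation) verifies the
clustering on random small groups in the test suite.

## Diversity

Hill numbers with q=1 as the entropy limit (used within 1e-9 of q=1; the
generic formula is numerically stable elsewhere, checked to 1e-3 across
the q=1 boundary). Bootstrap: each repetition is a multinomial draw of
n=951 records with clone probabilities proportional to copy numbers
(duplicate counts), i.e. resampling is copy-weighted — copies approximate
cells; unique-record weighting is available by passing duplicate counts of
1. Samples smaller than the resample size are resampled with replacement
anyway and flagged rather than dropped. Per-sample seeds derive
deterministically from the global seed and sorted sample order, so
diversity tables are bit-for-bit reproducible. Expanded-clone fraction uses
strictly more than 100 member sequences. Richness estimators
(Chao/ACE/iNEXT-style extrapolation) are out of scope.

## Longitudinal overlap

A clone's span is the set of time points where it has any member sequence;
the seven exclusive classes partition clones. Per-subset spans are computed
the same way within each subset, so one clone may occupy different classes
in different subsets and contributes once per subset it appears in.
Overlap proportions default to the multi-time-point denominator (clones
spanning >= 2 time points), the convention under which the observed
percentages (around 60% of clones relating to all three time points, 2% /
12% / 26% for the pairs) are expressed; division by all clones is available
via `denominator="all"`.

## Ig proteome overlap

Productive rearrangements are translated from the V start; CDR1/CDR2
intervals carry over from the called germline V (the V aligns at the start
of the translated region) and CDR3 is the translated junction. Digestion
cleaves C-terminal of K/R except before P (classic trypsin; the
Trypsin/P-style variant is a config change away), up to 2 missed cleavages,
minimum length 6. Matching requires tryptic-consistent boundaries on both
ends (start of sequence or after K/R-not-P; end of sequence or at
K/R-not-before-P) — implemented as an index of all boundary-to-boundary
fragments, verified against an exhaustive position scan in tests. The
specificity filter is two clauses, both asserted on every reported
peptide: exactly one match at the amino-acid-distinct sequence level
(nucleotide variants with identical protein count once; record-level
uniqueness is available), and >= 3 peptide residues inside a single CDR
interval (inclusive). Specific peptides are attributed to the time points,
isotypes and subsets of their matched sequences. Light-chain peptides
cannot match an IGH database and simply fail to match. Spectral search,
FDR and quantification are replaced by the peptide-list interface.

## Statistics

Cohort summary means are rounded half-up to integers, matching how the
published per-patient table's averages are printed; the bundled
`cladribine_cohort_counts.tsv` carries that table (one prose value, the 6M
sorted-cell range minimum, disagrees with the table by 2 cells; the table
value is the one consistent with the printed mean and is used). Friedman's
test runs on within-patient ranks with Dunn's pairwise z-tests on mean
ranks as post-hoc, Holm-adjusted by default (the original adjustment is
unstated; none/Bonferroni/Holm are selectable); all-constant blocks return
statistic 0, p 1 rather than a division by zero. Kruskal-Wallis gates
paired Wilcoxon signed-rank post-hocs — the "rank-sum paired" phrasing
sometimes attached to this design is internally contradictory, and the
paired (signed-rank) test is used, with rank-sum behind a flag; exact
p-values for n <= 25 without ties, normal approximation above (scipy's
policy). Post-hoc results are only reported when the omnibus p < alpha
(0.05 default). Null calibration is verified by simulation at sizes where
the asymptotic approximations hold (Friedman: 50 blocks x 3; KW: 3 x 30;
Wilcoxon: n=30), chosen as design sizes for the approximation check.

## Pipeline and problem sizes

`clonetrack.pipeline.run_pipeline` chains simulate -> process -> annotate ->
clone -> diversity -> overlap -> proteome -> stats, writing per-stage TSVs
and JSON logs; reruns under a fixed configuration are byte-identical (all
per-sample seeds derive from the configured seed, never from process
state). The numbered `analysis/` drivers are the narrative version of the
same chain at 8 patients x 150 clones; the acceptance script uses 300-800
clones per patient and 20 seeded reruns for the detection-rate estimates.
These scales were chosen so each distributional claim is tested with
adequate power while a full run stays in the tens of seconds; all reported
quantities carry their problem size (`n`) alongside.

## Known limitations

Single heavy-chain locus only; no D-segment calls or lineage trees; no
indel handling in clustering (precluded by the equal-length rule) or in
the simulated data; UMI collisions are not split; the aligner is a
desk-scale stand-in, not an IgBLAST replacement, and real-data users
should ingest externally annotated AIRR tables; peptide matching is exact
(no isobaric I/L equivalence or modifications).
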