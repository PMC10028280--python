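"""Toy germline V/J segment database for desk-scale repertoire simulation.

Real heavy-chain annotation uses curated IMGT germline alleles; here we
generate random but structurally faithful segments: V segments end in the
conserved second cysteine codon (the 5' boundary of the CDR3/junction) and
carry CDR1/CDR2 amino-acid intervals, J segments begin with the conserved
tryptophan codon (the 3' junction boundary) followed by a stop-free FR4.
Distinct genes are kept mutually distinguishable (pairwise nucleotide
identity < 90%) so that germline assignment on mutated sequences is
well-posed; alleles of one gene differ by only a few point substitutions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import edlib
import numpy as np

from .errors import ConfigurationError

BASES = "ACGT"
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
NONSTOP_CODONS = tuple(
    a + b + c
    for a in BASES
    for b in BASES
    for c in BASES
    if a + b + c not in STOP_CODONS
)
CYS_CODON = "TGT"
TRP_CODON = "TGG"

#: default CDR1/CDR2 amino-acid intervals on the translated V segment
#: (0-based half-open), loosely following heavy-chain numbering conventions
CDR1_AA = (26, 34)
CDR2_AA = (50, 58)


@dataclass(frozen=True)
class GermlineSegment:
    """One germline V or J segment.

    ``cdr_regions`` are 0-based half-open amino-acid intervals on the
    translated segment. For V segments these are CDR1, CDR2 and the
    CDR3-proximal conserved cysteine; J segments carry no CDR annotation.
    """

    name: str
    kind: str  # "V" or "J"
    sequence: str
    cdr_regions: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if not self.sequence or set(self.sequence) - set(BASES):
            raise ConfigurationError(
                f"segment {self.name}: sequence must be non-empty over ACGT"
            )
        if self.kind not in ("V", "J"):
            raise ConfigurationError(f"segment {self.name}: kind must be V or J")
        aa_len = len(self.sequence) // 3
        prev_end = 0
        for start, end in self.cdr_regions:
            if not (prev_end <= start < end <= aa_len):
                raise ConfigurationError(
                    f"segment {self.name}: CDR intervals must be ordered, "
                    f"disjoint and within the translated length"
                )
            prev_end = end

    @property
    def gene(self) -> str:
        """Gene-level name with any allele suffix stripped."""
        return self.name.split("*")[0]


def _identity(a: str, b: str) -> float:
    """Global-alignment nucleotide identity, normalized by the longer length."""
    dist = edlib.align(a, b, mode="NW")["editDistance"]
    return 1.0 - dist / max(len(a), len(b))


def _random_codons(rng: np.random.Generator, n: int) -> str:
    idx = rng.integers(0, len(NONSTOP_CODONS), size=n)
    return "".join(NONSTOP_CODONS[i] for i in idx)


def _mutate_allele(rng: np.random.Generator, sequence: str, n_subs: int) -> str:
    """Introduce ``n_subs`` point substitutions, avoiding stop codons and the
    conserved terminal cysteine codon."""
    seq = list(sequence)
    editable = len(seq) - 3  # protect the terminal Cys codon
    tries = 0
    made = 0
    while made < n_subs and tries < 100 * n_subs:
        tries += 1
        pos = int(rng.integers(0, editable))
        old = seq[pos]
        new = BASES[int(rng.integers(0, 4))]
        if new == old:
            continue
        seq[pos] = new
        cstart = 3 * (pos // 3)
        if "".join(seq[cstart : cstart + 3]) in STOP_CODONS:
            seq[pos] = old
            continue
        made += 1
    return "".join(seq)


def generate_germline_db(
    n_v_families: int = 5,
    n_j: int = 6,
    seed: int = 0,
    alleles_per_family: int = 1,
    max_gene_identity: float = 0.90,
) -> list[GermlineSegment]:
    """Generate a reproducible toy germline database.

    Parameters
    ----------
    n_v_families
        Number of distinct V genes (one per family), >= 2.
    n_j
        Number of J segments, >= 1.
    alleles_per_family
        Alleles generated per V gene; alleles differ by a handful of point
        substitutions (so they collapse to the same gene for clonal grouping).

    Returns segments sorted by name; deterministic for a fixed seed.
    """
    if n_v_families < 2 or n_j < 1:
        raise ConfigurationError(
            f"need n_v_families >= 2 and n_j >= 1, got {n_v_families}, {n_j}"
        )
    if alleles_per_family < 1:
        raise ConfigurationError("alleles_per_family must be >= 1")
    rng = np.random.default_rng(seed)
    segments: list[GermlineSegment] = []

    v_bases: list[str] = []
    for fam in range(n_v_families):
        n_codons = 94 + (fam % 5)  # mild length variation between genes
        while True:
            body = _random_codons(rng, n_codons - 1)
            seq = body + CYS_CODON
            if all(_identity(seq, other) < max_gene_identity for other in v_bases):
                break
        v_bases.append(seq)
        cdrs = (CDR1_AA, CDR2_AA, (n_codons - 1, n_codons))
        for allele in range(alleles_per_family):
            allele_seq = (
                seq if allele == 0 else _mutate_allele(rng, seq, n_subs=4)
            )
            segments.append(
                GermlineSegment(
                    name=f"IGHV{fam + 1}-1*{allele + 1:02d}",
                    kind="V",
                    sequence=allele_seq,
                    cdr_regions=cdrs,
                )
            )

    j_seqs: list[str] = []
    for j in range(n_j):
        while True:
            seq = TRP_CODON + _random_codons(rng, 15)
            if all(_identity(seq, other) < max_gene_identity for other in j_seqs):
                break
        j_seqs.append(seq)
        segments.append(
            GermlineSegment(name=f"IGHJ{j + 1}*01", kind="J", sequence=seq)
        )

    return sorted(segments, key=lambda s: (s.kind, s.name))


def write_germline_fasta(segments: Iterable[GermlineSegment], path) -> None:
    """Write segments as FASTA; CDR intervals are kept in the description."""
    with open(path, "w") as fh:
        for seg in sorted(segments, key=lambda s: (s.kind, s.name)):
            cdrs = ";".join(f"{a}-{b}" for a, b in seg.cdr_regions)
            fh.write(f">{seg.name} kind={seg.kind} cdrs={cdrs}\n{seg.sequence}\n")


def read_germline_fasta(path) -> list[GermlineSegment]:
    from Bio import SeqIO

    segments = []
    for rec in SeqIO.parse(str(path), "fasta"):
        fields = dict(
            kv.split("=", 1) for kv in rec.description.split()[1:] if "=" in kv
        )
        cdrs = tuple(
            tuple(int(x) for x in iv.split("-"))
            for iv in fields.get("cdrs", "").split(";")
            if iv
        )
        segments.append(
            GermlineSegment(
                name=rec.id,
                kind=fields.get("kind", "V"),
                sequence=str(rec.seq).upper(),
                cdr_regions=cdrs,  # type: ignore[arg-type]
            )
        )
    return sorted(segments, key=lambda s: (s.kind, s.name))
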