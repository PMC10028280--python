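"""Synthetic longitudinal BCR repertoire generator.

Emulates the structure of an 8-patient cladribine-treatment cohort sampled at
baseline (B), 6 months (6M) and 12 months (12M), with four sorted B-cell
subsets (naive, memory, DN, plasmablast) per sample:

* power-law (Zipf) clone sizes,
* per-clone persistence classes (the exact set of time points a clone
  occupies), defaulting to the observed structure where clones spanning all
  three time points dominate the multi-time-point fraction,
* a treatment effect modeled as clone-level loss of the memory compartment
  after baseline, with mean survival probability 1/depletion_factor and a
  size bias so surviving memory clones are preferentially the expanded ones,
* somatic hypermutation (uniform per-base substitutions within clones),
* UMI-tagged paired reads with PCR duplication and sequencing error,
* serum tryptic peptides drawn preferentially from expanded/plasmablast
  clones, plus configurable decoys.

Every output is deterministic for a fixed seed, and the ground-truth tables
determine every downstream expectation, which is what makes end-to-end
recovery tests possible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .errors import ConfigurationError, DataError
from .germline import (
    BASES,
    CYS_CODON,
    NONSTOP_CODONS,
    STOP_CODONS,
    TRP_CODON,
    GermlineSegment,
    generate_germline_db,
)

TIMEPOINTS = ("B", "6M", "12M")
SUBSETS = ("naive", "memory", "DN", "plasmablast")
ISOTYPES = ("IgM", "IgD", "IgG", "IgA")

#: constant-region barcodes identifying the sorted population of origin
#: (pairwise Hamming distance >= 6, safe for 1-mismatch demultiplexing)
SUBSET_BARCODES = {
    "naive": "AAAACCCC",
    "memory": "GGGGTTTT",
    "DN": "AACCGGTT",
    "plasmablast": "CCAATTGG",
}

#: isotype-specific constant-region primer tags (pairwise distance >= 6)
ISOTYPE_TAGS = {
    "IgM": "ACACACAC",
    "IgD": "GTGTGTGT",
    "IgG": "AATTCCGG",
    "IgA": "TTGGAACC",
}

#: isotype propensities by the clone's dominant subset: naive cells are
#: unswitched (IgM/IgD-heavy), memory and plasmablasts mostly class-switched
_ISOTYPE_BASE = {
    "naive": (0.62, 0.28, 0.07, 0.03),
    "memory": (0.15, 0.05, 0.55, 0.25),
    "DN": (0.40, 0.10, 0.35, 0.15),
    "plasmablast": (0.10, 0.02, 0.55, 0.33),
}

_COMP = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def _default_persistence() -> dict[tuple[str, ...], float]:
    # multi-time-point mass 0.5 split 60:26:12:2 as observed in the cohort;
    # single-time-point mass split evenly
    return {
        ("B",): 1 / 6,
        ("6M",): 1 / 6,
        ("12M",): 1 / 6,
        ("B", "6M"): 0.01,
        ("B", "12M"): 0.06,
        ("6M", "12M"): 0.13,
        ("B", "6M", "12M"): 0.30,
    }


@dataclass
class ScenarioConfig:
    """Study-scale scenario parameters.

    ``memory_depletion`` is the expected fold-reduction of memory clone
    counts after baseline (1.0 = no treatment effect). ``clone_size_exponent``
    is the Zipf exponent of the clone-size law. ``cell_scale`` multiplies all
    expected cell counts (use < 1 for quick, small samples).
    """

    n_patients: int = 8
    n_clones_per_patient: int = 1500
    clone_size_exponent: float = 1.5
    clone_size_max: int = 1000
    memory_depletion: float = 3.0
    depletion_size_bias: float = 0.3
    depleted_subset: str = "memory"
    depleted_timepoints: tuple[str, ...] = ("6M", "12M")
    persistence_probs: dict[tuple[str, ...], float] = field(
        default_factory=_default_persistence
    )
    subset_concentration: float = 0.5
    shm_rate: float = 0.02
    cell_scale: float = 1.0

    def validate(self) -> None:
        total = sum(self.persistence_probs.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(
                f"persistence-class probabilities sum to {total}, expected 1"
            )
        for cls in self.persistence_probs:
            if not cls or any(t not in TIMEPOINTS for t in cls):
                raise ConfigurationError(f"invalid persistence class {cls!r}")
        if self.n_patients < 1 or self.n_clones_per_patient < 1:
            raise ConfigurationError("need at least one patient and one clone")
        if self.memory_depletion < 1.0:
            raise ConfigurationError("memory_depletion must be >= 1")
        if self.clone_size_exponent <= 1.0:
            raise ConfigurationError("clone_size_exponent must be > 1")
        if not 0.0 <= self.shm_rate <= 0.2:
            raise ConfigurationError("shm_rate must be in [0, 0.2]")


def _symmetric_persistence() -> dict[tuple[str, ...], float]:
    # time-point-exchangeable classes: every single class 1/6, every pair
    # equal, triple 0.25 — used when isolating the treatment effect so that
    # baseline and follow-up samples are identical in distribution except
    # for the depletion itself
    pair = (0.5 - 0.25) / 3
    return {
        ("B",): 1 / 6,
        ("6M",): 1 / 6,
        ("12M",): 1 / 6,
        ("B", "6M"): pair,
        ("B", "12M"): pair,
        ("6M", "12M"): pair,
        ("B", "6M", "12M"): 0.25,
    }


def null_scenario(**overrides) -> ScenarioConfig:
    """No-treatment scenario with time-point-exchangeable persistence:
    every time-point contrast is a true null."""
    kwargs = dict(
        memory_depletion=1.0, persistence_probs=_symmetric_persistence()
    )
    kwargs.update(overrides)
    return ScenarioConfig(**kwargs)


def treatment_scenario(depletion: float = 3.0, **overrides) -> ScenarioConfig:
    """Treatment scenario differing from :func:`null_scenario` only by the
    memory clone depletion after baseline."""
    kwargs = dict(
        memory_depletion=depletion, persistence_probs=_symmetric_persistence()
    )
    kwargs.update(overrides)
    return ScenarioConfig(**kwargs)


@dataclass
class TrueClone:
    """Ground-truth clone: one ancestral rearrangement and its design."""

    clone_uid: str
    patient: str
    v_name: str
    j_name: str
    junction_nt: str
    sequence_nt: str
    junction_start: int  # 0-based position of the junction on sequence_nt
    base_size: int
    subset_weights: dict[str, float]
    persistence_class: tuple[str, ...]
    isotype_distribution: dict[str, float]
    memory_survives: bool = True

    @property
    def junction_end(self) -> int:
        return self.junction_start + len(self.junction_nt)

    @property
    def aa_sequence(self) -> str:
        return str(Seq(self.sequence_nt).translate())

    def abundance_by_timepoint(self, cell_scale: float = 1.0) -> dict:
        """Expected cell counts per (time point, subset); zero exactly at
        time points outside the persistence class."""
        out = {}
        for t in TIMEPOINTS:
            for s in SUBSETS:
                lam = (
                    self.base_size * self.subset_weights[s] * cell_scale
                    if t in self.persistence_class
                    else 0.0
                )
                out[(t, s)] = lam
        return out


def _truncated_zipf_pmf(exponent: float, smax: int) -> np.ndarray:
    support = np.arange(1, smax + 1, dtype=float)
    pmf = support**-exponent
    return pmf / pmf.sum()


def sample_clone_sizes(
    n: int, exponent: float, smax: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw clone base sizes from a truncated discrete power law."""
    pmf = _truncated_zipf_pmf(exponent, smax)
    return rng.choice(np.arange(1, smax + 1), size=n, p=pmf)


def survival_probabilities(
    sizes: np.ndarray,
    factor: float,
    gamma: float,
    presence_weights: np.ndarray | None = None,
) -> np.ndarray:
    """Per-clone treatment-survival probabilities.

    Probabilities are proportional to ``size**gamma`` (capped at 1), found
    by bisection on the proportionality constant, so larger clones are more
    likely to survive treatment. ``presence_weights`` — each clone's
    probability of actually being detected in the depleted compartment —
    makes the *observed* clone-count reduction equal the configured factor
    in expectation: sum(p * w) = sum(w) / factor.
    """
    if factor <= 1.0:
        return np.ones_like(sizes, dtype=float)
    w = sizes.astype(float) ** gamma
    pres = (
        np.ones_like(w)
        if presence_weights is None
        else np.asarray(presence_weights, dtype=float)
    )
    target = pres.sum() / factor
    lo, hi = 0.0, 1e9
    for _ in range(100):
        mid = 0.5 * (lo + hi)
        if (np.minimum(1.0, mid * w) * pres).sum() < target:
            lo = mid
        else:
            hi = mid
    return np.minimum(1.0, 0.5 * (lo + hi) * w)


def _make_junction(rng: np.random.Generator, v_seq: str) -> str:
    """Random in-frame CDR3 flanked by the conserved Cys (from V) and Trp
    (from J): length a multiple of 3 between 21 and 72 nt."""
    k = int(rng.integers(5, 23))  # middle codons -> junction 21..72 nt
    idx = rng.integers(0, len(NONSTOP_CODONS), size=k)
    middle = "".join(NONSTOP_CODONS[i] for i in idx)
    return v_seq[-3:] + middle + TRP_CODON


def simulate_cohort(
    config: ScenarioConfig,
    seed: int = 0,
    germline: Sequence[GermlineSegment] | None = None,
) -> tuple[list[TrueClone], pd.DataFrame]:
    """Generate ground-truth clones and realized per-sample cell counts.

    Returns ``(clones, counts)`` where ``counts`` has one row per
    (patient, timepoint, subset, clone_uid) with a positive realized cell
    count. Each clone is guaranteed at least one cell at every time point of
    its persistence class unless the treatment effect removed its only
    compartment there.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    if germline is None:
        germline = generate_germline_db(seed=int(rng.integers(0, 2**31)))
    v_segs = sorted([s for s in germline if s.kind == "V"], key=lambda s: s.name)
    j_segs = sorted([s for s in germline if s.kind == "J"], key=lambda s: s.name)
    if not v_segs or not j_segs:
        raise ConfigurationError("germline database must contain V and J segments")

    classes = sorted(config.persistence_probs)
    class_p = np.array([config.persistence_probs[c] for c in classes])
    tp_index = {t: i for i, t in enumerate(TIMEPOINTS)}
    s_index = {s: i for i, s in enumerate(SUBSETS)}
    mem_i = s_index.get(config.depleted_subset)

    clones: list[TrueClone] = []
    rows: list[tuple] = []
    for p in range(config.n_patients):
        patient = f"P{p + 1}"
        n = config.n_clones_per_patient
        sizes = sample_clone_sizes(
            n, config.clone_size_exponent, config.clone_size_max, rng
        )
        cls_idx = rng.choice(len(classes), size=n, p=class_p)
        weights = rng.dirichlet([config.subset_concentration] * len(SUBSETS), size=n)
        presence = None
        if mem_i is not None:
            # probability a clone is detected in the depleted compartment at
            # one of its time points: >=1 Poisson cell, or the forced cell
            # when the whole clone drew zero and its dominant subset is the
            # depleted one; used to make the observed clone-count reduction
            # match the configured factor
            lam_mem = sizes * weights[:, mem_i] * config.cell_scale
            lam_tot = sizes * config.cell_scale
            dominant_mem = np.argmax(weights, axis=1) == mem_i
            presence = 1.0 - np.exp(-lam_mem) + np.exp(-lam_tot) * dominant_mem
        surv_p = survival_probabilities(
            sizes,
            config.memory_depletion,
            config.depletion_size_bias,
            presence_weights=presence,
        )
        survives = rng.random(n) < surv_p

        for c in range(n):
            v = v_segs[int(rng.integers(0, len(v_segs)))]
            j = j_segs[int(rng.integers(0, len(j_segs)))]
            junction = _make_junction(rng, v.sequence)
            sequence = v.sequence + junction[3:-3] + j.sequence
            dominant = SUBSETS[int(np.argmax(weights[c]))]
            iso = dict(zip(ISOTYPES, _ISOTYPE_BASE[dominant]))
            clone = TrueClone(
                clone_uid=f"{patient}:TC{c:05d}",
                patient=patient,
                v_name=v.name,
                j_name=j.name,
                junction_nt=junction,
                sequence_nt=sequence,
                junction_start=len(v.sequence) - 3,
                base_size=int(sizes[c]),
                subset_weights=dict(zip(SUBSETS, weights[c])),
                persistence_class=classes[int(cls_idx[c])],
                isotype_distribution=iso,
                memory_survives=bool(survives[c]),
            )
            clones.append(clone)

            lam = np.zeros((len(TIMEPOINTS), len(SUBSETS)))
            for t in clone.persistence_class:
                lam[tp_index[t]] = sizes[c] * weights[c] * config.cell_scale
                if (
                    mem_i is not None
                    and config.memory_depletion > 1.0
                    and t in config.depleted_timepoints
                    and not survives[c]
                ):
                    lam[tp_index[t], mem_i] = 0.0
            counts = rng.poisson(lam)
            # ensure presence at every designed time point when any
            # compartment is still eligible there
            for t in clone.persistence_class:
                ti = tp_index[t]
                if counts[ti].sum() == 0:
                    eligible = lam[ti] > 0
                    if eligible.any():
                        best = int(np.argmax(np.where(eligible, weights[c], -1)))
                        counts[ti, best] = 1
            for ti, t in enumerate(TIMEPOINTS):
                for si, s in enumerate(SUBSETS):
                    if counts[ti, si] > 0:
                        rows.append(
                            (patient, t, s, clone.clone_uid, int(counts[ti, si]))
                        )

    counts_df = pd.DataFrame(
        rows, columns=["patient", "timepoint", "subset", "clone_uid", "n_cells"]
    )
    return clones, counts_df


# ---------------------------------------------------------------------------
# cells and somatic hypermutation


def _apply_shm(
    founder: np.ndarray,
    n_cells: int,
    rate: float,
    protected: np.ndarray,
    rng: np.random.Generator,
) -> list[str]:
    """Uniform per-base substitutions per cell; the conserved junction
    boundary codons are protected and substitutions creating in-frame stop
    codons are reverted (keeping every mutated cell productive)."""
    L = founder.size
    out = []
    base_codes = np.frombuffer(b"ACGT", dtype=np.uint8)
    stop_set = {b"TAA", b"TAG", b"TGA"}
    for _ in range(n_cells):
        seq = founder.copy()
        if rate > 0:
            hits = np.flatnonzero(rng.random(L) < rate)
            hits = hits[~protected[hits]]
            for pos in hits:
                new = base_codes[int(rng.integers(0, 4))]
                if new == seq[pos]:
                    continue
                old = seq[pos]
                seq[pos] = new
                cstart = 3 * (pos // 3)
                if seq[cstart : cstart + 3].tobytes() in stop_set:
                    seq[pos] = old
        out.append(seq.tobytes().decode())
    return out


def materialize_cells(
    clones: Sequence[TrueClone],
    counts: pd.DataFrame,
    shm_rate: float = 0.02,
    mean_variants: float = 2.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Expand realized counts into one row per cell with a sequence and an
    isotype drawn from the clone's isotype distribution.

    Each clone carries a small lineage pool: the founder plus
    ``1 + Poisson(mean_variants)`` hypermutated variants (uniform per-base
    substitutions at ``shm_rate``); cells draw from the pool with
    founder-heavy weights. Expanded clones therefore contain many cells with
    identical sequences (copy numbers > 1) alongside intra-clone variation
    that stays well below the 12% junction-divergence clustering threshold.
    """
    rng = np.random.default_rng(seed)
    by_uid = {c.clone_uid: c for c in clones}
    pools: dict[str, list[str]] = {}
    rows = []
    for rec in counts.sort_values(
        ["patient", "timepoint", "subset", "clone_uid"]
    ).itertuples(index=False):
        clone = by_uid[rec.clone_uid]
        if clone.clone_uid not in pools:
            founder = np.frombuffer(
                clone.sequence_nt.encode(), dtype=np.uint8
            ).copy()
            protected = np.zeros(founder.size, dtype=bool)
            protected[clone.junction_start : clone.junction_start + 3] = True
            protected[clone.junction_end - 3 : clone.junction_end] = True
            n_var = 0 if shm_rate <= 0 else 1 + int(rng.poisson(mean_variants))
            pools[clone.clone_uid] = [clone.sequence_nt] + _apply_shm(
                founder, n_var, shm_rate, protected, rng
            )
        pool = pools[clone.clone_uid]
        w = 1.0 / (1.0 + np.arange(len(pool)))  # founder-heavy
        variant_idx = rng.choice(len(pool), size=rec.n_cells, p=w / w.sum())
        seqs = [pool[i] for i in variant_idx]
        iso_p = np.array([clone.isotype_distribution[i] for i in ISOTYPES])
        isotypes = rng.choice(ISOTYPES, size=rec.n_cells, p=iso_p / iso_p.sum())
        for i, (s, iso) in enumerate(zip(seqs, isotypes)):
            rows.append(
                (
                    f"{rec.clone_uid}:{rec.timepoint}:{rec.subset}:{i}",
                    rec.patient,
                    rec.timepoint,
                    rec.subset,
                    rec.clone_uid,
                    str(iso),
                    s,
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "cell_id",
            "patient",
            "timepoint",
            "subset",
            "clone_uid",
            "isotype",
            "sequence_nt",
        ],
    )


def cells_to_rearrangements(
    cells: pd.DataFrame, clones: Sequence[TrueClone]
) -> pd.DataFrame:
    """Collapse cells into ground-truth rearrangement records (what a perfect
    read-processing + annotation stage would recover), with duplicate_count =
    number of cells carrying the identical sequence in a (patient, timepoint,
    subset, isotype) stratum."""
    by_uid = {c.clone_uid: c for c in clones}
    grouped = (
        cells.groupby(
            ["patient", "timepoint", "subset", "isotype", "clone_uid", "sequence_nt"],
            sort=True,
        )
        .size()
        .reset_index(name="duplicate_count")
    )
    recs = []
    for i, rec in enumerate(grouped.itertuples(index=False)):
        clone = by_uid[rec.clone_uid]
        junction = rec.sequence_nt[clone.junction_start : clone.junction_end]
        recs.append(
            {
                "sequence_id": f"truth-{i:07d}",
                "sequence": rec.sequence_nt,
                "v_call": clone.v_name,
                "j_call": clone.j_name,
                "junction": junction,
                "junction_aa": str(Seq(junction).translate()),
                "junction_length": len(junction),
                "v_sequence_start": 1,
                "junction_start": clone.junction_start + 1,
                "productive": True,
                "duplicate_count": int(rec.duplicate_count),
                "patient": rec.patient,
                "timepoint": rec.timepoint,
                "subset": rec.subset,
                "isotype": rec.isotype,
                "true_clone_uid": rec.clone_uid,
            }
        )
    return pd.DataFrame(recs)


# ---------------------------------------------------------------------------
# sequencing reads


@dataclass
class SimulatedRead:
    read_id: str
    umi: str
    subset_barcode: str
    mate1_seq: str
    mate2_seq: str
    mate1_qual: np.ndarray
    mate2_qual: np.ndarray
    truth_uid: str


def _with_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hits = np.flatnonzero(rng.random(arr.size) < rate)
    base_codes = np.frombuffer(b"ACGT", dtype=np.uint8)
    for pos in hits:
        choices = base_codes[base_codes != arr[pos]]
        arr[pos] = choices[int(rng.integers(0, 3))]
    return arr.tobytes().decode()


def simulate_reads(
    cells: pd.DataFrame,
    error_rate: float = 0.005,
    pcr_duplication: float = 3.0,
    read_length: int = 250,
    umi_length: int = 12,
    mean_quality: float = 36.0,
    min_copies: int = 1,
    seed: int = 0,
) -> list[SimulatedRead]:
    """Turn cells into UMI-tagged paired reads.

    Template layout: [subset barcode][VDJ][isotype tag]. Mate 1 carries the
    UMI followed by the template 5' end; mate 2 is the reverse complement of
    the template 3' end. Every molecule yields at least ``min_copies`` read
    pairs sharing one UMI; copies are min_copies + Poisson(mean - min_copies).
    """
    if not 0.0 <= error_rate <= 0.05:
        raise ConfigurationError("error_rate must be in [0, 0.05]")
    if pcr_duplication < min_copies:
        raise ConfigurationError(
            "pcr_duplication (mean copies) must be >= min_copies"
        )
    rng = np.random.default_rng(seed)
    reads: list[SimulatedRead] = []
    for rec in cells.itertuples(index=False):
        umi = "".join(BASES[i] for i in rng.integers(0, 4, size=umi_length))
        barcode = SUBSET_BARCODES[rec.subset]
        template = barcode + rec.sequence_nt + ISOTYPE_TAGS[rec.isotype]
        m1_core = template[: read_length - umi_length]
        m2 = revcomp(template[-read_length:])
        n_copies = min_copies + int(rng.poisson(pcr_duplication - min_copies))
        for copy in range(n_copies):
            m1 = _with_errors(umi + m1_core, error_rate, rng)
            m2e = _with_errors(m2, error_rate, rng)
            q1 = np.clip(
                rng.normal(mean_quality, 2.0, size=len(m1)).round(), 2, 40
            ).astype(int)
            q2 = np.clip(
                rng.normal(mean_quality, 2.0, size=len(m2e)).round(), 2, 40
            ).astype(int)
            reads.append(
                SimulatedRead(
                    read_id=f"{rec.cell_id}|c{copy}",
                    umi=umi,
                    subset_barcode=barcode,
                    mate1_seq=m1,
                    mate2_seq=m2e,
                    mate1_qual=q1,
                    mate2_qual=q2,
                    truth_uid=rec.cell_id,
                )
            )
    return reads


def write_fastq_pair(reads: Sequence[SimulatedRead], path1, path2) -> None:
    """Write mate FASTQ files (four-line records, matching IDs across mates)."""
    with open(path1, "w") as f1, open(path2, "w") as f2:
        for r in reads:
            f1.write(
                f"@{r.read_id}\n{r.mate1_seq}\n+\n"
                + "".join(chr(q + 33) for q in r.mate1_qual)
                + "\n"
            )
            f2.write(
                f"@{r.read_id}\n{r.mate2_seq}\n+\n"
                + "".join(chr(q + 33) for q in r.mate2_qual)
                + "\n"
            )


# ---------------------------------------------------------------------------
# serum peptides


def simulate_serum_peptides(
    clones: Sequence[TrueClone],
    counts: pd.DataFrame,
    n_per_sample: int = 100,
    decoy_fraction: float = 0.1,
    plasmablast_boost: float = 5.0,
    max_missed: int = 2,
    min_length: int = 6,
    seed: int = 0,
) -> pd.DataFrame:
    """Sample observed serum peptides per (patient, time point).

    Real peptides are tryptic fragments of a clone's translated sequence,
    drawn with probability proportional to the clone's realized cell count at
    the time point with plasmablast cells up-weighted (serum Ig is secreted
    by antibody-secreting cells). A ``decoy_fraction`` of emitted peptides is
    replaced by shuffled sequences matching no clone, emulating the non-BCR
    serum background.
    """
    from .proteo import tryptic_digest

    if len(clones) == 0:
        raise ConfigurationError("no clones supplied: nothing to digest")
    if not 0.0 <= decoy_fraction <= 1.0:
        raise ConfigurationError("decoy_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    by_uid = {c.clone_uid: c for c in clones}
    aa_cache: dict[str, str] = {}
    digest_cache: dict[str, list[str]] = {}

    def _aa(uid: str) -> str:
        if uid not in aa_cache:
            aa_cache[uid] = by_uid[uid].aa_sequence
        return aa_cache[uid]

    def _digest(uid: str) -> list[str]:
        if uid not in digest_cache:
            digest_cache[uid] = sorted(
                tryptic_digest(_aa(uid), max_missed=max_missed, min_length=min_length)
            )
        return digest_cache[uid]

    all_aa = sorted({_aa(c.clone_uid) for c in clones})

    def _make_decoy(template: str) -> str:
        pep = list(template)
        for _ in range(20):
            rng.shuffle(pep)
            cand = "".join(pep)
            if not any(cand in aa for aa in all_aa):
                return cand
        # fall back to a random peptide of the same length
        alphabet = "ACDEFGHIKLMNPQRSTVWY"
        while True:
            cand = "".join(
                alphabet[i] for i in rng.integers(0, len(alphabet), len(template))
            )
            if not any(cand in aa for aa in all_aa):
                return cand

    rows = []
    for (patient, timepoint), sample in counts.groupby(
        ["patient", "timepoint"], sort=True
    ):
        weights = {}
        for rec in sample.itertuples(index=False):
            boost = plasmablast_boost if rec.subset == "plasmablast" else 1.0
            weights[rec.clone_uid] = weights.get(rec.clone_uid, 0.0) + (
                rec.n_cells * boost
            )
        uids = sorted(weights)
        w = np.array([weights[u] for u in uids], dtype=float)
        w /= w.sum()
        for _ in range(n_per_sample):
            uid = uids[int(rng.choice(len(uids), p=w))]
            frags = _digest(uid)
            if not frags:
                continue
            pep = frags[int(rng.integers(0, len(frags)))]
            if rng.random() < decoy_fraction:
                rows.append((_make_decoy(pep), patient, timepoint, "", True))
            else:
                rows.append((pep, patient, timepoint, uid, False))
    return pd.DataFrame(
        rows,
        columns=["peptide_aa", "patient", "timepoint", "source_clone_uid", "is_decoy"],
    )
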