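"""End-to-end pipeline orchestration over a synthetic cohort.

``run_pipeline`` executes the stages in order — simulate, process reads,
annotate, clone, diversity, longitudinal overlap, proteome overlap,
statistics — writing each stage's TSV plus a JSON log under the output
directory. Everything is seeded, so a rerun with the same configuration is
byte-identical. Configuration may be a mapping or a YAML file path; scale
keys default to a small demonstration cohort because the full read
simulation is the expensive stage.
"""

from __future__ import annotations

import json
from dataclasses import asdict, replace
from pathlib import Path

import pandas as pd
import yaml

from . import annotate, clones, diversity, overlap, proteo, readproc, simulate, stats
from .errors import ClonetrackError, ConfigurationError
from .germline import generate_germline_db, write_germline_fasta

STAGES = (
    "simulate",
    "process",
    "annotate",
    "clone",
    "diversity",
    "overlap",
    "proteome",
    "stats",
)

DEFAULT_CONFIG = {
    "seed": 1,
    "outdir": "results/pipeline",
    "n_patients": 3,
    "n_clones_per_patient": 60,
    "cell_scale": 0.5,
    "memory_depletion": 3.0,
    "shm_rate": 0.02,
    "error_rate": 0.003,
    "pcr_duplication": 3.0,
    "n_peptides_per_sample": 60,
    "decoy_fraction": 0.1,
    "n_resample": 951,
    "n_boot": 50,
    "write_fastq": False,
}


def load_config(config) -> dict:
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    if not isinstance(config, dict):
        raise ConfigurationError("config must be a mapping or a YAML file path")
    merged = dict(DEFAULT_CONFIG)
    unknown = set(config) - set(merged)
    if unknown:
        raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
    merged.update(config)
    return merged


def run_pipeline(config=None, outdir: str | Path | None = None) -> dict:
    """Run every stage on a simulated cohort; returns a summary dict."""
    cfg = load_config(config or {})
    out = Path(outdir or cfg["outdir"])
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    logs: list[dict] = []

    def _log(stage: str, entry) -> None:
        logs.append({"stage": stage, "log": entry})

    # --- simulate -----------------------------------------------------
    germline = generate_germline_db(seed=seed)
    write_germline_fasta(germline, out / "germline.fasta")
    scenario = simulate.ScenarioConfig(
        n_patients=int(cfg["n_patients"]),
        n_clones_per_patient=int(cfg["n_clones_per_patient"]),
        cell_scale=float(cfg["cell_scale"]),
        memory_depletion=float(cfg["memory_depletion"]),
        shm_rate=float(cfg["shm_rate"]),
    )
    true_clones, counts = simulate.simulate_cohort(scenario, seed=seed, germline=germline)
    cells = simulate.materialize_cells(
        true_clones, counts, shm_rate=scenario.shm_rate, seed=seed + 1
    )
    counts.to_csv(out / "truth_cell_counts.tsv", sep="\t", index=False)
    truth = simulate.cells_to_rearrangements(cells, true_clones)
    annotate.write_airr(truth, out / "truth_rearrangements.tsv")
    _log("simulate", {"clones": len(true_clones), "cells": len(cells)})

    # --- process reads per (patient, timepoint) sample ----------------
    processed = []
    for si, ((patient, timepoint), sample_cells) in enumerate(
        cells.groupby(["patient", "timepoint"], sort=True)
    ):
        reads = simulate.simulate_reads(
            sample_cells,
            error_rate=float(cfg["error_rate"]),
            pcr_duplication=float(cfg["pcr_duplication"]),
            seed=(seed * 1009 + si) % (2**31),
        )
        if cfg["write_fastq"]:
            rdir = out / "reads"
            rdir.mkdir(exist_ok=True)
            simulate.write_fastq_pair(
                reads,
                rdir / f"{patient}_{timepoint}_R1.fastq",
                rdir / f"{patient}_{timepoint}_R2.fastq",
            )
        mates1 = [readproc.Read(r.read_id, r.mate1_seq, r.mate1_qual) for r in reads]
        mates2 = [readproc.Read(r.read_id, r.mate2_seq, r.mate2_qual) for r in reads]
        df, step_logs = readproc.process_sample(mates1, mates2)
        df["patient"] = patient
        df["timepoint"] = timepoint
        processed.append(df)
        _log("process", {"sample": f"{patient}:{timepoint}", "steps": step_logs})
    consensus = pd.concat(processed, ignore_index=True)
    consensus.to_csv(out / "consensus_sequences.tsv", sep="\t", index=False)

    # --- annotate -----------------------------------------------------
    rearr, alog = annotate.annotate_rearrangements(consensus, germline)
    rearr = rearr[rearr["productive"].astype(bool)].reset_index(drop=True)
    _log("annotate", alog)

    # --- clone --------------------------------------------------------
    rearr, clog = clones.assign_clone_ids(rearr)
    annotate.write_airr(rearr, out / "rearrangements.tsv")
    clones.clone_summary(rearr).to_csv(out / "clone_summary.tsv", sep="\t", index=False)
    _log("clone", clog)

    # --- diversity ----------------------------------------------------
    div = diversity.diversity_table(
        rearr,
        n_resample=int(cfg["n_resample"]),
        n_boot=int(cfg["n_boot"]),
        seed=seed + 2,
    )
    div.to_csv(out / "diversity.tsv", sep="\t", index=False)
    _log("diversity", {"rows": len(div)})

    # --- overlap ------------------------------------------------------
    spans = overlap.compute_spans(rearr)
    spans.to_csv(out / "clone_spans.tsv", sep="\t", index=False)
    counts_all = overlap.span_class_counts(spans, level="all")
    counts_all.to_csv(out / "span_class_counts.tsv", sep="\t")
    _log("overlap", {"clones": int(counts_all.sum().sum())})

    # --- proteome -----------------------------------------------------
    peptides = simulate.simulate_serum_peptides(
        true_clones,
        counts,
        n_per_sample=int(cfg["n_peptides_per_sample"]),
        decoy_fraction=float(cfg["decoy_fraction"]),
        seed=seed + 3,
    )
    peptides.drop(columns=["source_clone_uid", "is_decoy"]).to_csv(
        out / "serum_peptides.tsv", sep="\t", index=False
    )
    attribution = []
    n_specific = 0
    for patient, pgrp in peptides.groupby("patient", sort=True):
        prearr = rearr[rearr["patient"] == patient]
        if len(prearr) == 0:
            continue
        db = proteo.build_bcr_database(prearr, germline)
        matches, _ = proteo.match_peptides(sorted(set(pgrp["peptide_aa"])), db)
        n_specific += sum(m.is_specific for m in matches)
        att = proteo.attribute_specific_peptides(matches, prearr, pgrp)
        att["patient"] = patient
        attribution.append(att)
    att_df = (
        pd.concat(attribution, ignore_index=True) if attribution else pd.DataFrame()
    )
    att_df.to_csv(out / "peptide_attribution.tsv", sep="\t", index=False)
    _log("proteome", {"peptides": len(peptides), "specific": n_specific})

    # --- stats --------------------------------------------------------
    results = {}
    for q in (0.0, 1.0):
        mem = div[(div["subset"] == "memory") & (div["q"] == q)]
        piv = mem.pivot_table(
            index="patient", columns="timepoint", values="point_estimate"
        )
        if piv.notna().all().all() and piv.shape[0] >= 2 and piv.shape[1] >= 2:
            groups = {str(t): piv[t].to_numpy() for t in piv.columns}
            pairs = [("B", "6M")] if "B" in groups and "6M" in groups else []
            cmp = stats.kw_then_wilcoxon(groups, pairs, metric=f"memory_q{int(q)}")
            results[f"memory_q{int(q)}"] = {
                "omnibus_p": cmp.p_value,
                "posthoc": [
                    {"pair": list(ph.pair), "p": ph.p_value} for ph in cmp.posthoc
                ],
            }
    with open(out / "stats.json", "w") as fh:
        json.dump(results, fh, indent=2, sort_keys=True)
    _log("stats", results)

    with open(out / "pipeline_log.json", "w") as fh:
        json.dump(logs, fh, indent=2, sort_keys=True)
    return {
        "outdir": str(out),
        "n_rearrangements": len(rearr),
        "n_clones": int(clog["clones"]),
        "stats": results,
    }
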