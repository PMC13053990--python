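"""End-to-end orchestration: simulate → call → differential → motifs → report.

A single YAML config (one seed) drives the whole run; every output TSV plus a
``run_metadata.json`` (parameters, seed, computed ratio threshold, per-stage
record counts) lands in the output directory. Identical config + seed gives
byte-identical outputs.

Stages
------
1. Simulate a bait/control AP-MS table and call interactors.
2. Simulate the motif-mutant bait IP (a configurable subset of planted
   interactors loses enrichment) and test differential association of the
   called interactors.
3. Simulate a two-condition proteome and class differential proteins.
4. Generate sequences with a planted motif, scan them against the motif
   library, mutate the first planted match and rescan, infer candidate
   partners from domain annotations, and intersect predictions with the
   experimental interactor set.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .diffstats import differential_interactome, differential_proteome, results_to_frame
from .interactome import CallingParameters, call_interactors
from .io_formats import write_fasta, write_quant_table
from .motifs import (
    DomainAnnotation,
    MotifClass,
    infer_partners,
    mutate_motif,
    overlap_predicted_experimental,
    read_motif_library,
    scan_motifs,
    toy_motif_library,
)
from .synthetic import APMSSimConfig, generate_apms, generate_proteome, generate_sequences

log = logging.getLogger("mipepkit.pipeline")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Parameters of one reproducible pipeline run."""

    seed: int = 0
    outdir: str = "run_output"
    apms: dict[str, Any] = field(default_factory=dict)
    calling: dict[str, Any] = field(default_factory=dict)
    proteome: dict[str, Any] = field(
        default_factory=lambda: {"n_proteins": 1000, "n_diff": 18, "diff_log2": 3.0, "sd": 0.3}
    )
    # fraction of planted interactors whose enrichment the mutant bait loses,
    # and the residual log2 enrichment they keep in the mutant IP
    slim_dependent_fraction: float = 0.3
    mutant_residual_log2: float = 1.0
    sequences: dict[str, Any] = field(
        default_factory=lambda: {"n_seqs": 1, "length": 71, "plant": [["REKSIL", 21]]}
    )
    disorder_regions: list[list[int]] = field(default_factory=lambda: [[36, 71]])
    motif_library_path: str | None = None
    # fraction of called interactors annotated with a template partner domain
    annotated_fraction: float = 0.25

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # surface the failing stage
                raise StageError(name, exc) from exc

        return inner

    return wrap


def run(config: RunConfig) -> Path:
    """Execute the full pipeline; returns the run directory."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.seed)
    metadata: dict[str, Any] = {
        "version": __version__,
        "seed": seed,
        "config": dataclasses.asdict(config),
        "counts": {},
    }

    # stage: simulate + call interactors ------------------------------------
    @_stage("call_interactors")
    def stage_calls():
        apms_cfg = APMSSimConfig(seed=seed, **config.apms)
        table, truth = generate_apms(apms_cfg)
        params = CallingParameters(**config.calling)
        result = call_interactors(table, params)
        write_quant_table(table, outdir / "apms_table.tsv")
        frame = result.to_frame()
        frame.to_csv(outdir / "calls.tsv", sep="\t")
        metadata["log2_ratio_threshold"] = result.log2_ratio_threshold
        metadata["pooled_q1_intensity"] = result.pooled_q1_intensity
        metadata["counts"]["proteins_quantified"] = len(result)
        metadata["counts"]["interactors_called"] = len(result.interactor_ids())
        metadata["counts"]["routes"] = result.route_counts
        log.info("called %d interactors from %d proteins",
                 len(result.interactor_ids()), len(result))
        return apms_cfg, truth, result

    apms_cfg, apms_truth, calls = stage_calls()

    # stage: mutant-bait IP + differential interactome -----------------------
    @_stage("differential_interactome")
    def stage_diff_int():
        planted = sorted(apms_truth.interactor_ids)
        n_dep = int(round(config.slim_dependent_fraction * len(planted)))
        dependent = planted[:n_dep]
        overrides = {pid: config.mutant_residual_log2 for pid in dependent}
        mut_cfg = dataclasses.replace(apms_cfg, seed=seed + 1)
        mut_table, _ = generate_apms(mut_cfg, effects_log2=overrides)
        wt_cfg = dataclasses.replace(apms_cfg, seed=seed + 1)
        wt_table, _ = generate_apms(wt_cfg)
        results = differential_interactome(calls, wt_table, mut_table)
        results_to_frame(results).to_csv(outdir / "diff_interactome.tsv", sep="\t")
        metadata["counts"]["interactors_tested"] = len(results)
        metadata["counts"]["differentially_associated"] = sum(
            1 for r in results if r.cls in ("up", "down")
        )
        metadata["slim_dependent_planted"] = dependent
        return results

    stage_diff_int()

    # stage: differential proteome -------------------------------------------
    @_stage("differential_proteome")
    def stage_diff_prot():
        table, truth = generate_proteome(seed=seed + 2, **config.proteome)
        write_quant_table(table, outdir / "proteome_table.tsv")
        results = differential_proteome(table)
        results_to_frame(results).to_csv(outdir / "diff_proteome.tsv", sep="\t")
        metadata["counts"]["proteome_proteins"] = len(results)
        metadata["counts"]["differential_proteins"] = sum(
            1 for r in results if r.cls in ("up", "down")
        )
        return results

    stage_diff_prot()

    # stage: motif scan / mutate / infer / overlap ----------------------------
    @_stage("motif_inference")
    def stage_motifs():
        library = (
            read_motif_library(config.motif_library_path)
            if config.motif_library_path
            else toy_motif_library()
        )
        seq_cfg = dict(config.sequences)
        plant = [tuple(p) for p in seq_cfg.pop("plant", [])]
        records, seq_truth = generate_sequences(seed=seed + 3, plant=plant, **seq_cfg)
        write_fasta(records, outdir / "sequences.fasta")
        disorder = [tuple(r) for r in config.disorder_regions]
        matches = [m for rec in records for m in scan_motifs(rec, library, disorder)]
        pd.DataFrame([dataclasses.asdict(m) for m in matches]).to_csv(
            outdir / "slim_matches.tsv", sep="\t", index=False
        )
        if matches:
            rec_by_id = {r.id: r for r in records}
            first = matches[0]
            mutated = mutate_motif(rec_by_id[first.sequence_id], first)
            write_fasta([mutated], outdir / "mutated_sequence.fasta")
            rescan = scan_motifs(mutated, library, disorder)
            metadata["counts"]["matches_after_mutation"] = len(
                [m for m in rescan if not (m.end < first.start or m.start > first.end)]
            )

        # synthetic domain annotations: a deterministic fraction of called
        # interactors carries the first template domain of the library
        interactors = sorted(calls.interactor_ids())
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(99,)))
        n_annot = int(round(config.annotated_fraction * len(interactors)))
        chosen = list(rng.choice(interactors, size=n_annot, replace=False)) if n_annot else []
        template_domains = [d for cls in library for d in cls.partner_domain_ids]
        annotations = [
            DomainAnnotation(pid, frozenset({template_domains[0]})) for pid in chosen
        ] if template_domains else []
        predictions = infer_partners(matches, library, annotations, taxon_validated_only=True)
        pd.DataFrame(
            [
                {"protein_id": pid, "support": ";".join(f"{c}|{d}" for c, d in sorted(pairs))}
                for pid, pairs in sorted(predictions.items())
            ]
        ).to_csv(outdir / "predictions.tsv", sep="\t", index=False)
        overlap = overlap_predicted_experimental(predictions, interactors)
        pd.DataFrame({"protein_id": overlap}).to_csv(outdir / "overlap.tsv", sep="\t", index=False)
        metadata["counts"]["slim_matches"] = len(matches)
        metadata["counts"]["predicted_partners"] = len(predictions)
        metadata["counts"]["overlap_predicted_experimental"] = len(overlap)
        return matches

    stage_motifs()

    with open(outdir / "run_metadata.json", "w") as fh:
        json.dump(metadata, fh, indent=2, sort_keys=True, default=str)
    return outdir
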