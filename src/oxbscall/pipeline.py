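"""End-to-end pipeline: simulate/load -> filter -> QC -> call -> enrich -> evaluate.

Driven by a single YAML/dict configuration so a whole analysis is
reproducible from one file plus one seed.  Every stage failure is wrapped in
a :class:`StageError` naming the stage, which the CLI maps to a
stage-specific exit code.  All artifacts are plain text and, for a fixed
config and seed, byte-identical across runs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import scipy
import statsmodels

from . import __version__
from .calling import GroupDesign, call_hmc, compute_delta_beta
from .enrichment import cgi_enrichment, permutation_enrichment, write_enrichment
from .filtering import filter_probes
from .model import (
    BetaMatrix,
    CallConfig,
    read_annotation,
    read_beta_matrix,
    read_sample_sheet,
    write_beta_matrix,
    write_call_table,
    write_sample_sheet,
    write_annotation,
)
from .qc import replicate_correlation
from .synthetic import (
    GroupProfile,
    SimulationConfig,
    simulate_dataset,
    truth_evaluation,
    write_truth,
)

log = logging.getLogger(__name__)

#: Stage names in execution order; the CLI derives exit codes from this.
STAGES = ("simulate", "inputs", "filter", "qc", "call", "enrich", "evaluate")


class StageError(RuntimeError):
    """A pipeline stage failed; ``stage`` names which one."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}' failed: {message}")
        self.stage = stage


def _call_config(cfg: dict) -> CallConfig:
    call_cfg = cfg.get("call", {})
    filt_cfg = cfg.get("filter", {})
    return CallConfig(
        mode=call_cfg.get("mode", "threshold"),
        delta_threshold=call_cfg.get("delta_threshold", 0.30),
        nominal_p_threshold=call_cfg.get("nominal_p_threshold", 0.05),
        q_threshold=call_cfg.get("q_threshold", 0.05),
        detection_p_threshold=filt_cfg.get("detection_p", 0.01),
        drop_sex_chromosomes=filt_cfg.get("drop_sex_chromosomes", True),
        filter_detection=filt_cfg.get("filter_detection", True),
    )


def _simulation_config(sim_cfg: dict, seed) -> SimulationConfig:
    groups = tuple(
        GroupProfile(**g) if isinstance(g, dict) else GroupProfile(str(g))
        for g in sim_cfg.get("groups", [{"name": "brain1"}])
    )
    kwargs = {k: v for k, v in sim_cfg.items() if k not in ("groups", "seed")}
    return SimulationConfig(groups=groups, seed=seed, **kwargs)


def run_all(config: dict, out_dir) -> dict:
    """Run every configured stage; return (and write) the run manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config.get("seed")
    manifest: dict = {
        "versions": {
            "oxbscall": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
            "statsmodels": statsmodels.__version__,
        },
        "seed": seed,
        "config": config,
        "artifacts": [],
        "counts": {},
    }

    def artifact(path: Path) -> str:
        manifest["artifacts"].append(path.name)
        return str(path)

    # -- simulate / inputs ---------------------------------------------------
    truth = None
    if "simulate" in config:
        try:
            sim = simulate_dataset(_simulation_config(config["simulate"], seed))
            matrix, sheet, annotation, truth = sim.matrix, sim.sheet, sim.annotation, sim.truth
            write_beta_matrix(
                matrix,
                artifact(out / "beta.tsv"),
                artifact(out / "detection_p.tsv"),
            )
            write_sample_sheet(sheet, artifact(out / "samples.csv"))
            write_annotation(annotation, artifact(out / "annotation.tsv"))
            write_truth(truth, artifact(out / "truth.tsv"))
        except StageError:
            raise
        except Exception as exc:
            raise StageError("simulate", str(exc)) from exc
    else:
        try:
            inputs = config["inputs"]
            matrix = read_beta_matrix(inputs["beta"], inputs.get("detection"))
            annotation = read_annotation(inputs["annotation"])
        except StageError:
            raise
        except Exception as exc:
            raise StageError("inputs", str(exc)) from exc
        sheet = None  # read lazily in the call stage

    call_config = _call_config(config)
    if matrix.detection_p is None:
        call_config.filter_detection = False

    # -- filter --------------------------------------------------------------
    try:
        filtered, report = filter_probes(matrix, annotation, call_config)
        manifest["counts"]["filter"] = report.as_dict()
        write_beta_matrix(filtered, artifact(out / "filtered.tsv"))
        with open(artifact(out / "filter_report.json"), "w") as fh:
            json.dump(report.as_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")
    except Exception as exc:
        raise StageError("filter", str(exc)) from exc

    # -- call (reads the sample sheet; per group) -----------------------------
    try:
        if sheet is None:
            sheet = read_sample_sheet(config["inputs"]["sheet"])
        sheet.validate_matrix(filtered)
        groups = config.get("call", {}).get("groups") or sheet.groups
        tables = {}
        for group in groups:
            design = GroupDesign.from_sheet(sheet, group)
            delta = compute_delta_beta(filtered, design)
            table = call_hmc(delta, call_config, group=group)
            tables[group] = table
            write_call_table(table, artifact(out / f"calls_{group}.tsv"))
            manifest["counts"][f"call_{group}"] = table.summary.as_dict()
        with open(artifact(out / "call_summaries.json"), "w") as fh:
            json.dump(
                {g: t.summary.as_dict() for g, t in tables.items()},
                fh,
                indent=2,
                sort_keys=True,
            )
            fh.write("\n")
    except StageError:
        raise
    except Exception as exc:
        raise StageError("call", str(exc)) from exc

    # -- qc -------------------------------------------------------------------
    try:
        qc_report = replicate_correlation(
            filtered, sheet, r2_floor=config.get("qc", {}).get("r2_floor", 0.95)
        )
        with open(artifact(out / "qc.json"), "w") as fh:
            json.dump(qc_report.as_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")
        manifest["counts"]["qc_flagged_pairs"] = int(qc_report.pair_r2["flagged"].sum())
    except Exception as exc:
        raise StageError("qc", str(exc)) from exc

    # -- enrichment -----------------------------------------------------------
    try:
        n_perm = config.get("enrich", {}).get("permutations", 1000)
        background = filtered.probe_ids
        for group, table in tables.items():
            calls = table.called_probe_ids
            if len(calls) == 0:
                log.warning("group %s: no 5hmC calls; enrichment skipped", group)
                continue
            feat = permutation_enrichment(
                calls, background, annotation, n_permutations=n_perm, seed=seed
            )
            write_enrichment(feat, artifact(out / f"enrichment_feature_{group}.tsv"))
            cgi = cgi_enrichment(
                calls, background, annotation, n_permutations=n_perm, seed=seed
            )
            write_enrichment(cgi, artifact(out / f"enrichment_cgi_{group}.tsv"))
    except Exception as exc:
        raise StageError("enrich", str(exc)) from exc

    # -- evaluate (only when truth is available) ------------------------------
    if truth is not None:
        try:
            level_floor = config.get("evaluate", {}).get("level_floor", 0.0)
            metrics = {
                group: truth_evaluation(table, truth, level_floor=level_floor).as_dict()
                for group, table in tables.items()
            }
            with open(artifact(out / "evaluation.json"), "w") as fh:
                json.dump(metrics, fh, indent=2, sort_keys=True)
                fh.write("\n")
            manifest["counts"]["evaluation"] = metrics
        except Exception as exc:
            raise StageError("evaluate", str(exc)) from exc

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    manifest["artifacts"].append("manifest.json")
    return manifest
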