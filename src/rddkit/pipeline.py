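"""End-to-end orchestration: BAM -> candidates -> training data -> forest
-> predictions -> report, driven by a single config mapping.

Each stage writes its output atomically (tmp file + rename) and is skipped
on re-run if the output already exists, so an interrupted run resumes at
the failed stage.  A manifest records every parameter, seed and per-stage
count; a failing stage leaves a FAILED marker naming itself.
"""

from __future__ import annotations

import json
import logging
import os
import time
from pathlib import Path
from typing import Dict, Optional

import pandas as pd

from . import evaluation, io_formats, mes_artefacts, rf_model, training_compiler
from .pileup_features import detect_candidates
from .synthetic_data import SyntheticGenome, read_transcripts

log = logging.getLogger("rddkit")

DEFAULT_CONFIG = {
    "threshold": 0.5,
    "seed": 0,
    "call": {"min_depth": 10, "min_alt": 2, "min_alt_frac": 0.0,
             "min_baseq": 13, "vdb_m": 1000},
    "compile": {"match_mode": "class", "window": 0, "balance": "none"},
    "forest": {"n_trees": 100, "max_depth": None},
    "mes": {"rate": 0.01, "n_reads": 10000, "trials": 10, "recurrence": 1,
            "read_len": 100, "error_rate": 0.005, "misplacement": 0.5},
}


class ConfigError(ValueError):
    pass


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _merged(config: Dict) -> Dict:
    out = {k: (dict(v) if isinstance(v, dict) else v)
           for k, v in DEFAULT_CONFIG.items()}
    for k, v in config.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k].update(v)
        else:
            out[k] = v
    return out


def validate_config(config: Dict) -> Dict:
    cfg = _merged(config)
    if "outdir" not in cfg:
        raise ConfigError("config requires 'outdir'")
    if "candidates" not in cfg:
        for key in ("bam", "ref"):
            if key not in cfg:
                raise ConfigError(f"config requires {key!r} (or 'candidates')")
    for key in ("bam", "ref", "db", "candidates", "mes_bed", "exclude",
                "validation"):
        if key in cfg and cfg[key] is not None and not Path(cfg[key]).exists():
            raise ConfigError(f"{key} path does not exist: {cfg[key]}")
    if "db" not in cfg:
        raise ConfigError("config requires 'db' (known editing sites)")
    return cfg


def _atomic(path: Path, writer) -> None:
    tmp = path.with_name(path.name + ".tmp")
    writer(tmp)
    os.replace(tmp, path)


def genome_from_fasta(path, repeats=None) -> SyntheticGenome:
    """Load a reference as a SyntheticGenome shell (optionally with repeat
    family coordinates supplied as dicts of chrom/length/starts) so the MES
    fabricator can be run against a real FASTA."""
    import pysam
    from .synthetic_data import RepeatFamily
    seqs = {}
    with pysam.FastaFile(str(path)) as fa:
        for name in fa.references:
            seqs[name] = fa.fetch(name).upper()
    fams = []
    for k, spec in enumerate(repeats or []):
        chrom, length = spec["chrom"], int(spec["length"])
        starts = [int(s) for s in spec["starts"]]
        template = seqs[chrom][starts[0]:starts[0] + length]
        fams.append(RepeatFamily(name=spec.get("name", f"repfam{k}"),
                                 template=template, chrom=chrom,
                                 starts=starts,
                                 divergence=float(spec.get("divergence", 0.0))))
    return SyntheticGenome(sequences=seqs, repeat_families=fams, seed=0)


def run(config: Dict) -> Dict:
    """Execute the workflow; returns the manifest dict (also written to
    ``outdir/manifest.json``)."""
    cfg = validate_config(config)
    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    failed_marker = outdir / "FAILED"
    if failed_marker.exists():
        failed_marker.unlink()

    handler = logging.FileHandler(outdir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    manifest: Dict = {"config": _jsonable(cfg), "stages": {}, "counts": {}}
    t0 = time.time()

    def stage(name: str, fn):
        try:
            t = time.time()
            result = fn()
            manifest["stages"][name] = {"seconds": round(time.time() - t, 2)}
            log.info("stage %s done in %.1fs", name, time.time() - t)
            return result
        except Exception as exc:
            failed_marker.write_text(f"{name}: {exc}\n")
            log.error("stage %s FAILED: %s", name, exc)
            raise StageError(name, exc) from exc

    try:
        # -- candidates ----------------------------------------------------
        cand_path = outdir / "candidates.tsv"

        def _candidates():
            if "candidates" in cfg:
                return io_formats.read_candidates(cfg["candidates"],
                                                  require_features=True)
            if cand_path.exists():
                return io_formats.read_candidates(cand_path,
                                                  require_features=True)
            table = detect_candidates(cfg["bam"], cfg["ref"],
                                      seed=cfg["seed"], **cfg["call"])
            _atomic(cand_path, lambda p: io_formats.write_candidates(table, p))
            return table

        candidates = stage("call", _candidates)
        manifest["counts"]["candidates"] = len(candidates)

        # -- MES error-prone sites ----------------------------------------
        mes_path = outdir / "mes.bed"

        def _mes():
            if "mes_bed" in cfg:
                regions = io_formats.read_bed_regions(cfg["mes_bed"])
                return mes_artefacts.ErrorProneSiteSet.from_regions(regions)
            if mes_path.exists():
                regions = io_formats.read_bed_regions(mes_path)
                return mes_artefacts.ErrorProneSiteSet.from_regions(regions)
            m = cfg["mes"]
            genome = genome_from_fasta(cfg["ref"], repeats=m.get("repeats"))
            transcripts = read_transcripts(m["transcripts"])
            eps, report = mes_artefacts.run_mes(
                genome, transcripts, rate=m["rate"], n_reads=m["n_reads"],
                n_trials=m["trials"], seed=cfg["seed"] + 500_000,
                recurrence=m["recurrence"], read_len=m["read_len"],
                error_rate=m["error_rate"], misplacement=m["misplacement"],
                workdir=outdir / "mes_work")
            _atomic(mes_path,
                    lambda p: io_formats.write_bed_regions(eps.to_regions(), p))
            _atomic(outdir / "mes_report.tsv",
                    lambda p: report.to_csv(p, sep="\t"))
            return eps

        mes_sites = stage("mes", _mes)
        manifest["counts"]["mes_sites"] = len(mes_sites)

        # -- training compilation -----------------------------------------
        def _compile():
            db = io_formats.read_editing_db(cfg["db"])
            exclusion = []
            if cfg.get("exclude"):
                exclusion = [(c, p) for c, p, _l in
                             evaluation.read_validation(cfg["exclude"])]
            ts, targets = training_compiler.compile(
                candidates, db, mes_sites, test_exclusion=exclusion,
                match_mode=cfg["compile"]["match_mode"],
                window=cfg["compile"]["window"])
            ts = training_compiler.class_balance(
                ts, strategy=cfg["compile"]["balance"], seed=cfg["seed"])
            _atomic(outdir / "training.tsv",
                    lambda p: training_compiler.write_training(ts, p))
            _atomic(outdir / "targets.tsv",
                    lambda p: io_formats.write_candidates(
                        io_formats.CandidateTable(df=targets.df), p))
            return ts, targets

        ts, targets = stage("compile", _compile)
        manifest["counts"]["positives"] = ts.class_counts.get("positive", 0)
        manifest["counts"]["negatives"] = ts.class_counts.get("negative", 0)
        manifest["counts"]["targets"] = len(targets)
        manifest["counts"]["excluded"] = ts.excluded

        # -- train + predict ----------------------------------------------
        def _train():
            model = rf_model.train(ts, n_trees=cfg["forest"]["n_trees"],
                                   max_depth=cfg["forest"]["max_depth"],
                                   seed=cfg["seed"])
            rf_model.save_model(model, outdir / "model.rdd")
            return model

        model = stage("train", _train)

        def _predict():
            preds = rf_model.predict(model, targets,
                                     threshold=cfg["threshold"])
            _atomic(outdir / "predictions.tsv",
                    lambda p: _write_predictions(preds, p))
            return preds

        preds = stage("predict", _predict)
        manifest["counts"]["accepted"] = int(preds["accepted"].sum())

        # -- evaluation -----------------------------------------------------
        if cfg.get("validation"):
            def _evaluate():
                val = evaluation.read_validation(cfg["validation"])
                report = evaluation.evaluate(preds, val,
                                             n_candidates=len(candidates))
                _atomic(outdir / "report.tsv",
                        lambda p: report.to_frame().to_csv(p, sep="\t",
                                                           index=False))
                return report

            report = stage("evaluate", _evaluate)
            manifest["counts"]["reproduction_rate_pct"] = report.reproduction_rate
            manifest["counts"]["npv_pct"] = report.npv
            manifest["counts"]["reduction_pct"] = report.reduction
    finally:
        log.removeHandler(handler)
        handler.close()

    manifest["total_seconds"] = round(time.time() - t0, 2)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                     default=str))
    return manifest


def _write_predictions(preds: pd.DataFrame, path) -> None:
    cols = list(preds.columns)
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(cols) + "\n")
        for row in preds.itertuples(index=False):
            fh.write("\t".join(repr(v) if isinstance(v, float) else str(v)
                               for v in row) + "\n")


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, Path):
        return str(obj)
    return obj
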