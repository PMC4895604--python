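"""The shipped synthetic study: fixture generation and its answer key.

``prepare_study`` materialises, under one directory, everything a full
pipeline run consumes — reference FASTA, transcript models, a known-
editing-site database of planted A-to-I edits, a fabricated BAM with
engineered repeat mis-placements, the per-read truth table — plus a
labeled validation site list (held-out edits as positives, truth-known
artefact columns as negatives) and a ready-to-run pipeline config.

The artefact answer key is computed straight from the BAM and truth table
(mismatch support of mis-placed reads against the reference), not through
the candidate caller, so it can serve as an independent oracle for the
MES stage and for end-to-end scoring.
"""

from __future__ import annotations

from collections import Counter
from pathlib import Path
from typing import Dict, Optional, Sequence, Set, Tuple

import numpy as np
import pysam
import yaml

from . import io_formats
from .evaluation import write_validation
from .synthetic_data import (SCENE_DEFAULTS, build_scene, fabricate_alignments,
                             plant_editing_sites, simulate_reads, write_fasta,
                             write_fastq, write_transcripts, write_truth)


def artefact_truth_columns(bam_path, ref_path, truth,
                           exclude_positions: Set[Tuple[str, int]] = frozenset(),
                           min_support: int = 2, min_depth: int = 30,
                           min_baseq: int = 13):
    """Answer key for mis-alignment artefacts, direct from the alignment.

    A column is a truth-known artefact iff at least ``min_support``
    mis-placed reads carry the same non-reference base there (base quality
    passing) and total depth is >= ``min_depth``; positions in
    ``exclude_positions`` (planted variants) are never artefacts.  Returns
    (artefact column set, per-position depth dict).
    """
    misplaced_ids = set(truth.loc[truth["misplaced"], "read_id"])
    depth: Counter = Counter()
    support: Counter = Counter()   # (chrom, pos1, base) -> misplaced support
    with pysam.AlignmentFile(str(bam_path), "rb") as bam, \
            pysam.FastaFile(str(ref_path)) as fasta:
        refs = {c: fasta.fetch(c).upper() for c in fasta.references}
        for read in bam.fetch():
            if read.is_unmapped or read.is_secondary:
                continue
            chrom = read.reference_name
            seq = read.query_sequence
            quals = read.query_qualities
            mis = read.query_name in misplaced_ids
            for qpos, rpos in read.get_aligned_pairs(matches_only=True):
                if quals[qpos] < min_baseq:
                    continue
                depth[(chrom, rpos + 1)] += 1
                if mis and seq[qpos] != refs[chrom][rpos]:
                    support[(chrom, rpos + 1, seq[qpos])] += 1
    columns = {(c, p) for (c, p, _b), n in support.items()
               if n >= min_support and depth[(c, p)] >= min_depth
               and (c, p) not in exclude_positions}
    return columns, depth


def prepare_study(outdir, seed: int = 0,
                  n_val_pos: int = 60, n_val_neg: int = 40,
                  mes_trials: int = 10, mes_n_reads: int = 10000,
                  **scene_overrides) -> Dict:
    """Write the full synthetic study to ``outdir``; returns a dict with
    file paths, the pipeline config, and the truth answer key."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    genome, transcripts, cfg = build_scene(seed=seed, **scene_overrides)

    ref_path = out / "ref.fa"
    write_fasta(genome, ref_path)
    tx_path = out / "transcripts.tsv"
    write_transcripts(transcripts, tx_path)

    edits, db = plant_editing_sites(genome, transcripts, cfg["n_edits"],
                                    seed=seed + 10)
    db_path = out / "editing_db.tsv"
    io_formats.write_editing_db(db, db_path)

    reads = simulate_reads(genome, transcripts, edits,
                           n_reads=cfg["n_reads"], read_len=cfg["read_len"],
                           error_rate=cfg["error_rate"], seed=seed + 20,
                           application_prob=cfg["edit_application_prob"])
    bam_path = out / "aligned.bam"
    truth = fabricate_alignments(reads, genome,
                                 misplacement=cfg["misplacement"],
                                 seed=seed + 30, bam_path=bam_path,
                                 mapq_mis=cfg["mapq_mis"],
                                 mapq0_frac=cfg["mapq0_frac"])
    truth_path = out / "truth.tsv"
    write_truth(truth, truth_path)

    edit_positions = edits.positions()
    artefacts, depth = artefact_truth_columns(
        bam_path, ref_path, truth, exclude_positions=edit_positions,
        min_depth=20)

    # validation split: held-out edits (adequately covered, so the caller
    # can see them at all) + truth-known artefact columns
    rng = np.random.default_rng(seed + 40)
    covered_edits = sorted(p for p in edit_positions if depth[p] >= 15)
    artefact_list = sorted(artefacts)
    n_val_pos = min(n_val_pos, len(covered_edits))
    n_val_neg = min(n_val_neg, len(artefact_list))
    pos_idx = rng.choice(len(covered_edits), size=n_val_pos, replace=False)
    neg_idx = rng.choice(len(artefact_list), size=n_val_neg, replace=False)
    val_pos = [covered_edits[i] for i in sorted(pos_idx)]
    val_neg = [artefact_list[i] for i in sorted(neg_idx)]
    validation_path = out / "validation.tsv"
    write_validation([(c, p, "positive") for c, p in val_pos]
                     + [(c, p, "negative") for c, p in val_neg],
                     validation_path)

    run_config = {
        "outdir": str(out / "run"),
        "seed": seed,
        "bam": str(bam_path),
        "ref": str(ref_path),
        "db": str(db_path),
        "exclude": str(validation_path),
        "validation": str(validation_path),
        "mes": {
            "transcripts": str(tx_path),
            "rate": cfg["snv_rate"],
            "n_reads": mes_n_reads,
            "trials": mes_trials,
            "recurrence": 1,
            "read_len": cfg["read_len"],
            "error_rate": cfg["error_rate"],
            "misplacement": cfg["misplacement"],
            "repeats": [dict(name=f.name, chrom=f.chrom, length=f.length,
                             starts=list(f.starts)) for f in
                        genome.repeat_families],
        },
    }
    config_path = out / "config.yaml"
    config_path.write_text(yaml.safe_dump(run_config))

    return {
        "rundir": out / "run",
        "paths": {"ref": ref_path, "bam": bam_path, "db": db_path,
                  "transcripts": tx_path, "truth": truth_path,
                  "validation": validation_path, "config": config_path},
        "config": run_config,
        "genome": genome,
        "transcripts": transcripts,
        "scene": cfg,
        "edits": edits,
        "truth": truth,
        "artefact_columns": artefacts,
        "validation": {"positive": val_pos, "negative": val_neg},
    }
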