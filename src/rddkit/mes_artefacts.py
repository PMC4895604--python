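"""MES: error-prone-site calculation by planted-SNV simulation.

The idea: plant random SNVs into simulated reads, align them (here: the
truth-controlled fabricator, or any external BAM), call raw variants, and
flag every called-but-not-planted site as a location where the alignment
configuration manufactures variants.  Pooling several trials with
independent SNV sets yields a condition-specific error-prone-site mask
used downstream as the negative-example source.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .io_formats import Region, merge_regions
from .pileup_features import build_pileup, call_candidates
from .synthetic_data import (PlantedVariantSet, SimulatedReadSet,
                             SyntheticGenome, Transcript, fabricate_alignments,
                             plant_variants, simulate_reads, write_fasta)

REPORT_COLUMNS = ["mapped_reads", "mapped_sites", "raw_snps",
                  "unintended_snps", "caller_passed", "filtered"]

#: QC gate separating "Raw SNPs" from "Caller passed" in the trial report.
CALLER_PASS_MIN_FRAC = 0.2
CALLER_PASS_MIN_DEPTH = 10


@dataclass
class ErrorProneSiteSet:
    """Sites where the aligner provably produces unintended variants."""

    sites: Set[Tuple[str, int]] = field(default_factory=set)  # (chrom, 1-based)
    trials_observed: Counter = field(default_factory=Counter)
    n_trials: int = 1

    def __len__(self) -> int:
        return len(self.sites)

    def __contains__(self, key: Tuple[str, int]) -> bool:
        return key in self.sites

    def to_regions(self, pad: int = 0, merge_distance: int = 0) -> List[Region]:
        """Sites -> merged, sorted 0-based half-open regions, optionally
        padded by +-pad bases and merged across gaps <= merge_distance."""
        raw = [(c, max(0, p - 1 - pad), p + pad) for c, p in sorted(self.sites)]
        if merge_distance > 0:
            raw = [(c, s, e + merge_distance) for c, s, e in raw]
            merged = merge_regions(raw)
            return [(c, s, max(s + 1, e - merge_distance)) for c, s, e in merged]
        return merge_regions(raw) if raw else []

    @classmethod
    def from_regions(cls, regions: Iterable[Region]) -> "ErrorProneSiteSet":
        sites = set()
        for chrom, start, end in regions:
            for pos0 in range(start, end):
                sites.add((chrom, pos0 + 1))
        return cls(sites=sites, trials_observed=Counter(sites), n_trials=1)


@dataclass
class MesTrialRow:
    mapped_reads: int
    mapped_sites: int
    raw_snps: int
    unintended_snps: int
    caller_passed: int
    filtered: int

    def __post_init__(self) -> None:
        assert self.unintended_snps <= self.raw_snps
        assert self.caller_passed <= self.unintended_snps
        assert self.filtered <= self.caller_passed


def trial_report(rows: Sequence[MesTrialRow]) -> pd.DataFrame:
    """Per-trial counts plus an Average row (means rounded to nearest int)."""
    df = pd.DataFrame([[getattr(r, c) for c in REPORT_COLUMNS] for r in rows],
                      columns=REPORT_COLUMNS,
                      index=[f"Trial.{i + 1}" for i in range(len(rows))])
    avg = df.mean(axis=0).round().astype(int)
    df.loc["Average"] = avg
    return df


def run_mes_trial(genome: SyntheticGenome, transcripts: Sequence[Transcript],
                  rate: float, n_reads: int, seed: int,
                  read_len: int = 100, error_rate: float = 0.005,
                  misplacement: float = 0.5, mapq_mis: int = 20,
                  mapq0_frac: float = 0.2,
                  bam_path=None, ref_path=None, workdir=None,
                  min_depth: int = 10, min_alt: int = 2,
                  known_regions: Optional[Sequence[Region]] = None):
    """One MES iteration: plant, simulate, fabricate (or use a supplied
    BAM), call, and difference against the planted set.

    Returns (called site set, candidate table, planted set, MesTrialRow).
    When ``bam_path`` is given the simulation steps are skipped and the
    alignment is taken as-is (the external-aligner path).
    """
    import tempfile
    from pathlib import Path

    planted = plant_variants(genome, transcripts, rate, seed=seed)
    if bam_path is None:
        reads = simulate_reads(genome, transcripts, planted, n_reads=n_reads,
                               read_len=read_len, error_rate=error_rate,
                               seed=seed + 1)
        if workdir is None:
            tmp = tempfile.TemporaryDirectory()
            workdir = Path(tmp.name)
        workdir = Path(workdir)
        workdir.mkdir(parents=True, exist_ok=True)
        bam_path = workdir / f"mes_trial_{seed}.bam"
        ref_path = workdir / "mes_ref.fa"
        if not Path(ref_path).exists():
            write_fasta(genome, ref_path)
        truth = fabricate_alignments(reads, genome, misplacement=misplacement,
                                     seed=seed + 2, bam_path=bam_path,
                                     mapq_mis=mapq_mis, mapq0_frac=mapq0_frac)
        from .synthetic_data import write_truth
        write_truth(truth, Path(bam_path).with_suffix(".truth.tsv"))
        mapped_reads = len(truth)
    else:
        import pysam
        with pysam.AlignmentFile(str(bam_path), "rb") as bf:
            mapped_reads = sum(1 for r in bf if not r.is_unmapped
                               and not r.is_secondary)
    columns = list(build_pileup(bam_path, ref_path))
    if not columns:
        raise ValueError("empty alignment: no covered positions")
    mapped_sites = len(columns)
    table = call_candidates(columns, min_depth=min_depth, min_alt=min_alt)
    called = {(c, int(p)) for c, p in zip(table.df["chrom"], table.df["pos"])}
    planted_pos = planted.positions()
    unintended = called - planted_pos

    passed = set()
    for row in table.df.itertuples(index=False):
        key = (row.chrom, int(row.pos))
        if key in unintended and row.depth >= CALLER_PASS_MIN_DEPTH \
                and row.alt_count / row.depth >= CALLER_PASS_MIN_FRAC:
            passed.add(key)
    filtered = apply_region_filter(passed, known_regions or [])
    report = MesTrialRow(mapped_reads=mapped_reads, mapped_sites=mapped_sites,
                         raw_snps=len(called), unintended_snps=len(unintended),
                         caller_passed=len(passed), filtered=len(filtered))
    return unintended, table, planted, report


def aggregate_trials(trial_sites: Sequence[Set[Tuple[str, int]]],
                     rows: Sequence[MesTrialRow],
                     recurrence: int = 1) -> Tuple[ErrorProneSiteSet, pd.DataFrame]:
    """Pool trials: a site enters the error-prone set iff observed in at
    least ``recurrence`` trials (default 1 = union, the most conservative
    artefact mask)."""
    if not trial_sites:
        raise ValueError("at least one trial required")
    if not 1 <= recurrence <= len(trial_sites):
        raise ValueError(f"recurrence must be in [1, {len(trial_sites)}]")
    counts: Counter = Counter()
    for sites in trial_sites:
        counts.update(set(sites))
    kept = {s for s, n in counts.items() if n >= recurrence}
    eps = ErrorProneSiteSet(sites=kept,
                            trials_observed=Counter({s: counts[s] for s in kept}),
                            n_trials=len(trial_sites))
    return eps, trial_report(rows)


def apply_region_filter(sites: Iterable[Tuple[str, int]],
                        regions: Sequence[Region]) -> Set[Tuple[str, int]]:
    """Remove sites inside any region (0-based half-open; a 1-based site p
    is inside (chrom, start, end) iff start <= p-1 < end)."""
    if not regions:
        return set(sites)
    merged = merge_regions(regions)
    by_chrom: dict = {}
    for chrom, start, end in merged:
        by_chrom.setdefault(chrom, []).append((start, end))
    out = set()
    for chrom, pos in sites:
        pos0 = pos - 1
        inside = any(s <= pos0 < e for s, e in by_chrom.get(chrom, ()))
        if not inside:
            out.add((chrom, pos))
    return out


def run_mes(genome: SyntheticGenome, transcripts: Sequence[Transcript],
            rate: float = 0.01, n_reads: int = 10000, n_trials: int = 10,
            seed: int = 0, recurrence: int = 1, workdir=None,
            known_regions: Optional[Sequence[Region]] = None,
            **trial_kwargs) -> Tuple[ErrorProneSiteSet, pd.DataFrame]:
    """Full MES: ``n_trials`` iterations with independent SNV sets, pooled
    at the given recurrence threshold."""
    trial_sites, rows = [], []
    for i in range(n_trials):
        unintended, _table, _planted, row = run_mes_trial(
            genome, transcripts, rate=rate, n_reads=n_reads,
            seed=seed + 1000 * i, workdir=workdir,
            known_regions=known_regions, **trial_kwargs)
        trial_sites.append(unintended)
        rows.append(row)
    return aggregate_trials(trial_sites, rows, recurrence=recurrence)
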