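"""Truth-controlled synthetic RNA-seq data.

This module fabricates everything the pipeline consumes — a genome with
near-identical repeat families (the substrate of systematic mis-alignment
artefacts), spliced transcript models, reads carrying planted SNVs and
sequencing errors, and BAM alignments in which a configurable fraction of
repeat-origin reads is deliberately placed on the wrong repeat copy.

No aligner is run: mis-alignment is *injected* with known truth, so every
downstream stage (artefact detection, feature extraction, classification)
can be scored against an exact answer key.  A hook to run a real aligner on
the emitted FASTQ exists in the CLI for use on real data.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import pysam

from .sites import BASES, EDIT_CLASS, EditingSiteDB, revcomp

_BASE_ARR = np.frombuffer(b"ACGT", dtype="S1")


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------

@dataclass
class RepeatFamily:
    name: str
    template: str
    chrom: str
    starts: List[int]              # 0-based start of each copy
    divergence: float

    @property
    def length(self) -> int:
        return len(self.template)

    def copy_span(self, i: int) -> Tuple[int, int]:
        """0-based half-open span of copy i."""
        return self.starts[i], self.starts[i] + self.length


@dataclass
class SyntheticGenome:
    sequences: Dict[str, str]
    repeat_families: List[RepeatFamily]
    seed: int

    def fetch(self, chrom: str, pos: int) -> str:
        """Reference base at a 1-based position."""
        return self.sequences[chrom][pos - 1]


def _random_seq(rng: np.random.Generator, n: int) -> np.ndarray:
    return _BASE_ARR[rng.integers(0, 4, size=n)]


def _diverge(rng: np.random.Generator, template: np.ndarray,
             divergence: float) -> np.ndarray:
    """Copy with exactly round(divergence * len) substitutions."""
    n_sub = round(divergence * len(template))
    copy = template.copy()
    if n_sub:
        idx = rng.choice(len(template), size=n_sub, replace=False)
        for i in idx:
            choices = [b for b in _BASE_ARR if b != copy[i]]
            copy[i] = choices[rng.integers(0, 3)]
    return copy


def make_genome(chrom_lengths: Dict[str, int],
                repeats: Sequence[dict] = (),
                seed: int = 0) -> SyntheticGenome:
    """Random genome with planted near-identical repeat families.

    Each repeat spec is a dict with keys ``chrom``, ``length``, ``copies``,
    ``divergence`` and optionally explicit 0-based ``starts``.  Every copy
    differs from the family template at exactly ``round(divergence*length)``
    positions; independent substitution sets per copy make homologous copies
    differ from *each other* at roughly twice that many columns — the
    positions where a mis-placed read manufactures a variant.
    """
    rng = np.random.default_rng(seed)
    seqs = {name: _random_seq(rng, n) for name, n in chrom_lengths.items()}
    families: List[RepeatFamily] = []
    for k, spec in enumerate(repeats):
        chrom = spec["chrom"]
        length, copies = int(spec["length"]), int(spec["copies"])
        div = float(spec["divergence"])
        if not 0.0 <= div <= 0.2:
            raise ValueError(f"divergence must be in [0, 0.2], got {div}")
        chrom_len = chrom_lengths[chrom]
        starts = spec.get("starts")
        if starts is None:
            margin = (chrom_len - copies * length) // (copies + 1)
            if margin < 0:
                raise ValueError(
                    f"chromosome {chrom} ({chrom_len} bp) too short for "
                    f"{copies} repeat copies of {length} bp")
            starts = [margin * (i + 1) + length * i for i in range(copies)]
        if any(s < 0 or s + length > chrom_len for s in starts):
            raise ValueError(f"repeat copies fall outside {chrom}")
        template = _random_seq(rng, length)
        for s in starts:
            seqs[chrom][s:s + length] = _diverge(rng, template, div)
        families.append(RepeatFamily(
            name=spec.get("name", f"repfam{k}"),
            template=template.tobytes().decode(), chrom=chrom,
            starts=list(starts), divergence=div))
    return SyntheticGenome(
        sequences={n: s.tobytes().decode() for n, s in seqs.items()},
        repeat_families=families, seed=seed)


def write_fasta(genome: SyntheticGenome, path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# transcripts
# ---------------------------------------------------------------------------

@dataclass
class Transcript:
    name: str
    chrom: str
    strand: str
    exons: List[Tuple[int, int]]   # 1-based inclusive, ascending

    def __post_init__(self) -> None:
        prev_end = 0
        for s, e in self.exons:
            if s > e:
                raise ValueError(f"{self.name}: exon {s}-{e} reversed")
            if s <= prev_end:
                raise ValueError(f"{self.name}: exons overlap or are unordered")
            prev_end = e

    @property
    def spliced_length(self) -> int:
        return sum(e - s + 1 for s, e in self.exons)

    def spliced_positions(self) -> np.ndarray:
        """Genomic 1-based position of every spliced base, 5'->3' of the
        transcript (descending for minus-strand transcripts)."""
        pos = np.concatenate([np.arange(s, e + 1) for s, e in self.exons])
        return pos[::-1] if self.strand == "-" else pos

    def spliced_sequence(self, genome: SyntheticGenome) -> str:
        seq = "".join(genome.sequences[self.chrom][s - 1:e]
                      for s, e in self.exons)
        return revcomp(seq) if self.strand == "-" else seq


def make_transcripts(genome: SyntheticGenome, seed: int = 0,
                     exon_len: Tuple[int, int] = (300, 700),
                     intron_len: Tuple[int, int] = (100, 400),
                     gene_gap: Tuple[int, int] = (100, 300),
                     n_exons: Tuple[int, int] = (2, 3),
                     min_spliced: int = 150) -> List[Transcript]:
    """Tile each chromosome with two/three-exon gene models on alternating
    strands.  Tiling (rather than sparse placement) guarantees that repeat
    copies are transcribed, so repeat-origin reads exist."""
    rng = np.random.default_rng(seed)
    out: List[Transcript] = []
    idx = 0
    for chrom, seq in genome.sequences.items():
        cursor = 1 + int(rng.integers(*gene_gap))
        while True:
            k = int(rng.integers(n_exons[0], n_exons[1] + 1))
            exons = []
            p = cursor
            for j in range(k):
                length = int(rng.integers(*exon_len))
                exons.append((p, p + length - 1))
                p += length + int(rng.integers(*intron_len))
            if exons[-1][1] > len(seq):
                break
            t = Transcript(f"tx{idx}", chrom, "+" if idx % 2 == 0 else "-", exons)
            if t.spliced_length >= min_spliced:
                out.append(t)
                idx += 1
            cursor = exons[-1][1] + 1 + int(rng.integers(*gene_gap))
    return out


def write_transcripts(transcripts: Sequence[Transcript], path) -> None:
    with open(path, "w") as fh:
        fh.write("#name\tchrom\tstrand\texons\n")
        for t in transcripts:
            blocks = ",".join(f"{s}-{e}" for s, e in t.exons)
            fh.write(f"{t.name}\t{t.chrom}\t{t.strand}\t{blocks}\n")


def read_transcripts(path) -> List[Transcript]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            name, chrom, strand, blocks = line.rstrip("\n").split("\t")
            exons = [tuple(map(int, b.split("-"))) for b in blocks.split(",")]
            out.append(Transcript(name, chrom, strand, exons))
    return out


def transcribed_positions(transcripts: Sequence[Transcript]) -> List[Tuple[str, int]]:
    """Sorted unique (chrom, 1-based pos) over all exons."""
    seen = set()
    for t in transcripts:
        for s, e in t.exons:
            for p in range(s, e + 1):
                seen.add((t.chrom, p))
    return sorted(seen)


# ---------------------------------------------------------------------------
# planted variants
# ---------------------------------------------------------------------------

@dataclass
class PlantedVariantSet:
    """Genomic positions mutated in the simulated transcriptome.

    ``alleles`` maps (chrom, 1-based pos) -> (ref, alt) on the genomic plus
    strand.  Used both for the random SNVs of artefact simulation and for
    planted editing events."""

    alleles: Dict[Tuple[str, int], Tuple[str, str]]
    rate: float
    seed: int

    def __len__(self) -> int:
        return len(self.alleles)

    def positions(self) -> set:
        return set(self.alleles)


def plant_variants(genome: SyntheticGenome, transcripts: Sequence[Transcript],
                   rate: float, seed: int = 0) -> PlantedVariantSet:
    """Plant SNVs uniformly over transcribed positions without replacement;
    the planted count is exactly round(rate * eligible positions)."""
    if not 0 <= rate < 0.1:
        raise ValueError(f"rate must be in [0, 0.1), got {rate}")
    rng = np.random.default_rng(seed)
    eligible = transcribed_positions(transcripts)
    count = round(rate * len(eligible))
    alleles: Dict[Tuple[str, int], Tuple[str, str]] = {}
    if count:
        idx = rng.choice(len(eligible), size=count, replace=False)
        for i in sorted(idx):
            chrom, pos = eligible[i]
            ref = genome.fetch(chrom, pos)
            alts = [b for b in "ACGT" if b != ref]
            alleles[(chrom, pos)] = (ref, alts[rng.integers(0, 3)])
    return PlantedVariantSet(alleles=alleles, rate=rate, seed=seed)


def plant_editing_sites(genome: SyntheticGenome,
                        transcripts: Sequence[Transcript],
                        n_sites: int, seed: int = 0,
                        edit_type: str = "A-to-I"
                        ) -> Tuple[PlantedVariantSet, EditingSiteDB]:
    """Pick transcript positions whose transcript-strand base is editable
    (A for A-to-I, C for C-to-U) and return both the genomic variant set to
    plant into reads and the matching known-editing-site database."""
    rng = np.random.default_rng(seed)
    candidates = []  # (chrom, pos, strand)
    for t in transcripts:
        ref_plus, _ = EDIT_CLASS[(edit_type, "+")]
        ref_minus, _ = EDIT_CLASS[(edit_type, "-")]
        want = ref_plus if t.strand == "+" else ref_minus
        for s, e in t.exons:
            block = genome.sequences[t.chrom][s - 1:e]
            for off, b in enumerate(block):
                if b == want:
                    candidates.append((t.chrom, s + off, t.strand))
    if n_sites > len(candidates):
        raise ValueError(f"only {len(candidates)} editable positions available")
    idx = rng.choice(len(candidates), size=n_sites, replace=False)
    alleles = {}
    db = EditingSiteDB(source_tag="synthetic-consensus")
    for i in sorted(idx):
        chrom, pos, strand = candidates[i]
        ref, alt = EDIT_CLASS[(edit_type, strand)]
        alleles[(chrom, pos)] = (ref, alt)
        db.add(chrom, pos, strand, edit_type)
    planted = PlantedVariantSet(alleles=alleles, rate=n_sites / max(len(candidates), 1),
                                seed=seed)
    return planted, db


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------

@dataclass
class SimRead:
    read_id: str
    sequence: str                  # transcript orientation (as sequenced)
    quality: int                   # constant Phred Q per base
    transcript: str
    chrom: str
    strand: str
    origins: np.ndarray            # genomic 1-based pos per base, 5'->3'
    planted_covered: List[Tuple[str, int]]
    n_errors: int


@dataclass
class SimulatedReadSet:
    reads: List[SimRead]
    error_rate: float
    read_len: int
    seed: int

    def __len__(self) -> int:
        return len(self.reads)


def phred_from_error(error_rate: float, cap: int = 60) -> int:
    """Q = -10 log10 e, capped; an error-free simulation reports Q=cap."""
    if error_rate <= 0:
        return cap
    return int(min(cap, max(2, round(-10.0 * math.log10(error_rate)))))


def simulate_reads(genome: SyntheticGenome,
                   transcripts: Sequence[Transcript],
                   planted: Optional[PlantedVariantSet],
                   n_reads: int, read_len: int,
                   error_rate: float, seed: int = 0,
                   weights: Optional[Sequence[float]] = None,
                   application_prob: float = 1.0) -> SimulatedReadSet:
    """Sample single-end reads uniformly over transcript positions.

    Planted alleles are substituted (each occurrence independently with
    ``application_prob``; 1.0 plants at full allele fraction), then i.i.d.
    per-base sequencing errors are applied at ``error_rate``.  Base
    qualities encode the true error model (Q = -10 log10 e).
    """
    if n_reads <= 0:
        raise ValueError("n_reads must be positive")
    usable = [t for t in transcripts if t.spliced_length >= read_len]
    if not usable:
        raise ValueError(f"no transcript as long as read_len={read_len}")
    rng = np.random.default_rng(seed)
    q = phred_from_error(error_rate)
    if weights is not None:
        w = np.asarray([weights[i] for i, t in enumerate(transcripts)
                        if t.spliced_length >= read_len], dtype=float)
        w = w / w.sum()
    else:
        w = None
    # per-transcript caches
    seqs = [t.spliced_sequence(genome) for t in usable]
    poss = [t.spliced_positions() for t in usable]
    alleles = planted.alleles if planted is not None else {}
    reads: List[SimRead] = []
    tx_idx = rng.choice(len(usable), size=n_reads, p=w)
    for i in range(n_reads):
        t = usable[tx_idx[i]]
        sseq, spos = seqs[tx_idx[i]], poss[tx_idx[i]]
        start = int(rng.integers(0, t.spliced_length - read_len + 1))
        bases = list(sseq[start:start + read_len])
        origins = spos[start:start + read_len].copy()
        covered: List[Tuple[str, int]] = []
        if alleles:
            for j in range(read_len):
                key = (t.chrom, int(origins[j]))
                allele = alleles.get(key)
                if allele is None:
                    continue
                if application_prob >= 1.0 or rng.random() < application_prob:
                    alt = allele[1]
                    bases[j] = alt if t.strand == "+" else revcomp(alt)
                    covered.append(key)
        n_err = 0
        if error_rate > 0:
            err_mask = rng.random(read_len) < error_rate
            for j in np.flatnonzero(err_mask):
                wrong = [b for b in "ACGT" if b != bases[j]]
                bases[j] = wrong[rng.integers(0, 3)]
                n_err += 1
        reads.append(SimRead(
            read_id=f"read{i}", sequence="".join(bases), quality=q,
            transcript=t.name, chrom=t.chrom, strand=t.strand,
            origins=origins, planted_covered=covered, n_errors=n_err))
    return SimulatedReadSet(reads=reads, error_rate=error_rate,
                            read_len=read_len, seed=seed)


def write_fastq(readset: SimulatedReadSet, path) -> None:
    with open(path, "w") as fh:
        for r in readset.reads:
            qual = chr(r.quality + 33) * len(r.sequence)
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{qual}\n")


# ---------------------------------------------------------------------------
# alignment fabrication
# ---------------------------------------------------------------------------

TRUTH_COLUMNS = ["read_id", "transcript", "strand", "chrom_true", "pos_true",
                 "chrom_placed", "pos_placed", "misplaced", "mapq",
                 "n_planted_covered"]


def _cigar_blocks(positions: np.ndarray) -> List[Tuple[int, int]]:
    """CIGAR ops for ascending genomic positions: M runs split by N gaps."""
    ops: List[Tuple[int, int]] = []
    run = 1
    for i in range(1, len(positions)):
        gap = int(positions[i] - positions[i - 1]) - 1
        if gap == 0:
            run += 1
        else:
            ops.append((0, run))           # M
            ops.append((3, gap))           # N
            run = 1
    ops.append((0, run))
    return ops


def fabricate_alignments(readset: SimulatedReadSet, genome: SyntheticGenome,
                         misplacement: float, seed: int, bam_path,
                         mapq_true: int = 60, mapq_mis: int = 20,
                         mapq0_frac: float = 0.2) -> pd.DataFrame:
    """Write a coordinate-sorted, indexed BAM plus a per-read truth table.

    Non-repeat reads go to their true locus at MAPQ ``mapq_true``.  A read
    whose genomic span lies entirely inside one copy of a multi-copy repeat
    family is, with probability ``misplacement``, shifted onto a homologous
    copy (MAPQ ``mapq_mis``; a ``mapq0_frac`` fraction of those at MAPQ 0) —
    the engineered systematic artefact.  Exon junctions become N CIGAR ops.
    Returns the truth table (one row per read: true vs. placed locus).
    """
    if not 0.0 <= misplacement <= 1.0:
        raise ValueError("misplacement must be in [0, 1]")
    rng = np.random.default_rng(seed)
    names = list(genome.sequences)
    lengths = [len(genome.sequences[n]) for n in names]
    header = pysam.AlignmentHeader.from_dict({
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": n, "LN": l} for n, l in zip(names, lengths)],
    })
    tid = {n: i for i, n in enumerate(names)}

    records = []
    truth_rows = []
    for r in readset.reads:
        if r.strand == "-":
            seq_fwd = revcomp(r.sequence)
            pos_fwd = r.origins[::-1].copy()
        else:
            seq_fwd = r.sequence
            pos_fwd = r.origins.copy()
        true_start = int(pos_fwd[0])
        placed_pos = pos_fwd
        chrom_placed = r.chrom
        mapq = mapq_true
        misplaced = False
        if misplacement > 0:
            span = (int(pos_fwd[0]) - 1, int(pos_fwd[-1]))  # 0-based half-open
            for fam in genome.repeat_families:
                if fam.chrom != r.chrom or len(fam.starts) < 2:
                    continue
                home = [i for i in range(len(fam.starts))
                        if fam.copy_span(i)[0] <= span[0] and span[1] <= fam.copy_span(i)[1]]
                if not home:
                    continue
                if rng.random() < misplacement:
                    others = [i for i in range(len(fam.starts)) if i != home[0]]
                    dest = others[rng.integers(0, len(others))]
                    delta = fam.starts[dest] - fam.starts[home[0]]
                    placed_pos = pos_fwd + delta
                    misplaced = True
                    mapq = 0 if rng.random() < mapq0_frac else mapq_mis
                break
        a = pysam.AlignedSegment(header)
        a.query_name = r.read_id
        a.query_sequence = seq_fwd
        a.flag = 16 if r.strand == "-" else 0
        a.reference_id = tid[chrom_placed]
        a.reference_start = int(placed_pos[0]) - 1
        a.mapping_quality = mapq
        a.cigartuples = _cigar_blocks(placed_pos)
        quals = [r.quality] * len(seq_fwd)
        a.query_qualities = pysam.qualitystring_to_array(
            "".join(chr(q + 33) for q in quals))
        records.append(a)
        truth_rows.append((r.read_id, r.transcript, r.strand,
                           r.chrom, true_start,
                           chrom_placed, int(placed_pos[0]),
                           misplaced, mapq, len(r.planted_covered)))

    records.sort(key=lambda a: (a.reference_id, a.reference_start))
    with pysam.AlignmentFile(str(bam_path), "wb", header=header) as out:
        for a in records:
            out.write(a)
    pysam.index(str(bam_path))
    return pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)


def write_truth(truth: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(TRUTH_COLUMNS) + "\n")
        truth.to_csv(fh, sep="\t", header=False, index=False)


def read_truth(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment=None, skiprows=1,
                     names=TRUTH_COLUMNS, dtype={"chrom_true": str,
                                                 "chrom_placed": str})
    df["misplaced"] = df["misplaced"].astype(bool)
    return df


# ---------------------------------------------------------------------------
# the default study scene
# ---------------------------------------------------------------------------

#: Conditions of the shipped synthetic study: a two-copy 3 kb repeat family
#: at 2 % per-copy divergence inside a 40 kb chromosome plus a 20 kb unique
#: chromosome; 100 bp single-end reads at per-base error 0.005 (Q23); half
#: of the repeat-confined reads mis-placed, a fifth of those at MAPQ 0.
SCENE_DEFAULTS = dict(
    chrom_lengths={"chr1": 40000, "chr2": 20000},
    repeats=[dict(name="repfam0", chrom="chr1", length=3000, copies=2,
                  divergence=0.02)],
    read_len=100,
    error_rate=0.005,
    misplacement=0.5,
    mapq_mis=20,
    mapq0_frac=0.2,
    n_reads=16000,
    snv_rate=0.01,
    n_edits=200,
    edit_application_prob=0.8,
)


def build_scene(seed: int = 0, **overrides):
    """Genome + transcripts under the default study conditions."""
    cfg = {**SCENE_DEFAULTS, **overrides}
    genome = make_genome(cfg["chrom_lengths"], cfg["repeats"], seed=seed)
    transcripts = make_transcripts(genome, seed=seed + 1,
                                   min_spliced=cfg["read_len"] + 50)
    return genome, transcripts, cfg
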