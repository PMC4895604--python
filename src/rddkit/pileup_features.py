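"""Raw RDD candidate detection and the 15 read-alignment-pattern attributes.

A candidate site's feature vector summarises how reads carrying the variant
base differ from reads carrying the reference base: depth and allele
fraction, a three-hypothesis genotype-likelihood block (SGB/FQ/CallQual),
rank-sum bias tests on mapping quality, base quality, read position and
tail distance, Fisher's exact test on read strand, mapping-quality
summaries (RMS MQ, MQ0 fraction) and a Monte-Carlo variant-distance-bias
statistic that flags variants clustered at a fixed offset within reads —
the signature of splice-site mis-alignment.

Feature names and column order follow the canonical attribute table
(:data:`rddkit.io_formats.FEATURE_ORDER`).
"""

from __future__ import annotations

import math
import warnings
import zlib
from dataclasses import dataclass
from typing import Dict, Iterable, Iterator, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import pysam
from scipy import stats
from scipy.special import logsumexp, ndtr

from .io_formats import CandidateTable, FEATURE_ORDER

P_FLOOR = 1e-300          # p-values live in (0, 1]
QUAL_CAP = 9999.0         # cap for phred-scaled posteriors

DEFAULT_MIN_BASEQ = 13
DEFAULT_MIN_DEPTH = 10
DEFAULT_MIN_ALT = 2


@dataclass(frozen=True)
class Observation:
    """One read's contribution to a pileup column."""
    base: str
    baseq: int
    mapq: int
    strand: str
    offset: int          # 0-based offset from the 5' end of the read
    dist_end: int        # min(offset, read_length-1-offset)
    read_length: int


@dataclass
class PileupColumn:
    chrom: str
    pos: int             # 1-based
    ref_base: str
    observations: List[Observation]

    @property
    def depth(self) -> int:
        return len(self.observations)

    def base_counts(self) -> Dict[str, int]:
        counts: Dict[str, int] = {}
        for o in self.observations:
            counts[o.base] = counts.get(o.base, 0) + 1
        return counts


# ---------------------------------------------------------------------------
# pileup construction
# ---------------------------------------------------------------------------

def build_pileup(bam_path, ref_path, region: Optional[Tuple[str, int, int]] = None,
                 min_baseq: int = DEFAULT_MIN_BASEQ) -> Iterator[PileupColumn]:
    """Stream pileup columns from a sorted, indexed BAM.

    Skips unmapped/secondary/duplicate reads and bases below ``min_baseq``;
    N CIGAR gaps (introns) contribute no observation.  The read-position
    attributes are measured from the sequencing 5' end, so offsets of
    reverse-strand reads are flipped relative to query coordinates.
    """
    with pysam.AlignmentFile(str(bam_path), "rb") as bam, \
            pysam.FastaFile(str(ref_path)) as fasta:
        bad = [n for n in bam.references if n not in fasta.references]
        bad += [n for n in bam.references if n in fasta.references
                and bam.get_reference_length(n) != fasta.get_reference_length(n)]
        if bad:
            raise ValueError(
                f"BAM/reference mismatch for sequences: {sorted(set(bad))}")
        if region is None:
            chroms = [(c, None, None) for c in bam.references]
        else:
            chroms = [region]
        for chrom, start, stop in chroms:
            columns: Dict[int, List[Observation]] = {}
            for read in bam.fetch(chrom, start, stop):
                if read.is_unmapped or read.is_secondary or read.is_duplicate:
                    continue
                seq = read.query_sequence
                quals = read.query_qualities
                length = read.query_length
                mapq = read.mapping_quality
                strand = "-" if read.is_reverse else "+"
                for qpos, rpos in read.get_aligned_pairs(matches_only=True):
                    q = quals[qpos]
                    if q < min_baseq:
                        continue
                    offset = length - 1 - qpos if read.is_reverse else qpos
                    columns.setdefault(rpos, []).append(Observation(
                        base=seq[qpos], baseq=q, mapq=mapq, strand=strand,
                        offset=offset,
                        dist_end=min(qpos, length - 1 - qpos),
                        read_length=length))
            ref_seq = fasta.fetch(chrom).upper()
            for rpos in sorted(columns):
                if region is not None:
                    if (start is not None and rpos < start) or \
                            (stop is not None and rpos >= stop):
                        continue
                yield PileupColumn(chrom=chrom, pos=rpos + 1,
                                   ref_base=ref_seq[rpos],
                                   observations=columns[rpos])


# ---------------------------------------------------------------------------
# candidate detection
# ---------------------------------------------------------------------------

def call_candidates(columns: Iterable[PileupColumn],
                    min_depth: int = DEFAULT_MIN_DEPTH,
                    min_alt: int = DEFAULT_MIN_ALT,
                    min_alt_frac: float = 0.0,
                    keep_columns: bool = False):
    """Detect raw RDD candidate sites from pileup columns.

    A column is a candidate iff depth >= min_depth and exactly one
    non-reference base occurs >= min_alt times at fraction >= min_alt_frac;
    columns with two such non-reference bases are dropped as multi-allelic
    and counted.  Returns a :class:`CandidateTable` of sites (strand is
    recorded as '+': raw RDDs are unstranded until database matching) and,
    if ``keep_columns``, the per-site columns for feature computation.
    """
    rows = []
    kept: List[PileupColumn] = []
    n_multi = 0
    for col in columns:
        if col.depth < min_depth or col.ref_base not in "ACGT":
            continue
        counts = col.base_counts()
        alt_counts = {b: c for b, c in counts.items()
                      if b != col.ref_base and b in "ACGT" and c >= min_alt}
        if not alt_counts:
            continue
        if len(alt_counts) > 1:
            n_multi += 1
            continue
        (alt, n_alt), = alt_counts.items()
        if n_alt / col.depth < min_alt_frac:
            continue
        rows.append((col.chrom, col.pos, "+", col.ref_base, alt,
                     col.depth, n_alt))
        if keep_columns:
            kept.append(col)
    df = pd.DataFrame(rows, columns=["chrom", "pos", "strand", "ref", "alt",
                                     "depth", "alt_count"])
    table = CandidateTable(df=df, n_multiallelic_dropped=n_multi,
                           provenance=dict(min_depth=min_depth, min_alt=min_alt,
                                           min_alt_frac=min_alt_frac))
    return (table, kept) if keep_columns else table


# ---------------------------------------------------------------------------
# statistical primitives
# ---------------------------------------------------------------------------

def rank_sum_bias(values_alt: Sequence[float],
                  values_ref: Sequence[float]) -> Tuple[float, float]:
    """Two-sided Mann-Whitney U with tie-corrected normal approximation.

    z = (U - mu_U -/+ 0.5)/sigma_U with continuity correction toward zero;
    p = 2*Phi(-|z|).  Degenerate inputs (an empty group, or zero variance
    from all-tied values) return the sentinel (z=0, p=1).
    """
    x = np.asarray(values_alt, dtype=float)
    y = np.asarray(values_ref, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        return 0.0, 1.0
    combined = np.concatenate([x, y])
    ranks = stats.rankdata(combined)
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    n = n1 + n2
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = ((tie_counts ** 3 - tie_counts).sum() / (n * (n - 1.0))
                if n > 1 else 0.0)
    var = n1 * n2 / 12.0 * ((n + 1.0) - tie_term)
    if var <= 0:
        return 0.0, 1.0
    diff = u1 - mu
    cc = 0.5 * np.sign(diff)
    z = (diff - cc) / math.sqrt(var)
    p = 2.0 * ndtr(-abs(z))
    return float(z), float(min(1.0, max(P_FLOOR, p)))


def fisher_strand(alt_fwd: int, alt_rev: int,
                  ref_fwd: int, ref_rev: int) -> float:
    """Two-sided Fisher exact p for the strand-by-allele 2x2 table
    (sum of hypergeometric probabilities <= the observed table's)."""
    counts = (alt_fwd, alt_rev, ref_fwd, ref_rev)
    if any(c < 0 for c in counts):
        raise ValueError(f"negative count in {counts}")
    if sum(counts) == 0:
        raise ValueError("empty 2x2 table")
    _, p = stats.fisher_exact([[alt_fwd, alt_rev], [ref_fwd, ref_rev]],
                              alternative="two-sided")
    return float(min(1.0, max(P_FLOOR, p)))


def segregation_features(column: PileupColumn, alt: str) -> Tuple[float, float, float]:
    """(SGB, FQ, CallQual) from a three-hypothesis genotype model.

    With per-base error e_i = 10^(-Q_i/10) over ref- and alt-base reads:
    hom-ref likelihood  = prod_alt(e_i/3) * prod_ref(1-e_i)   ("error-only")
    het likelihood      = prod_all(0.5(1-e_i) + 0.5 e_i/3)
    hom-alt likelihood  = prod_alt(1-e_i) * prod_ref(e_i/3)
    SGB = ln(hom-ref) - ln(het); with a uniform prior, FQ = -10 log10 of the
    posterior of the best *monomorphic* hypothesis and CallQual =
    -10 log10 posterior(hom-ref), both capped at 9999.
    """
    log_e = []
    is_alt = []
    for o in column.observations:
        if o.base == alt:
            is_alt.append(True)
        elif o.base == column.ref_base:
            is_alt.append(False)
        else:
            continue
        e = 10.0 ** (-o.baseq / 10.0)
        log_e.append(math.log(min(max(e, 1e-10), 0.75)))
    if not log_e:
        return 0.0, 0.0, 0.0
    e = np.exp(np.asarray(log_e))
    is_alt = np.asarray(is_alt)
    with np.errstate(divide="ignore"):
        ll_homref = (np.log(e[is_alt] / 3.0).sum()
                     + np.log1p(-e[~is_alt]).sum())
        ll_het = np.log(0.5 * (1.0 - e) + 0.5 * e / 3.0).sum()
        ll_homalt = (np.log1p(-e[is_alt]).sum()
                     + np.log(e[~is_alt] / 3.0).sum())
    sgb = ll_homref - ll_het
    lls = np.array([ll_homref, ll_het, ll_homalt])
    log_post = lls - logsumexp(lls)
    log10 = math.log(10.0)
    post_best_mono = max(log_post[0], log_post[2])
    fq = min(QUAL_CAP, max(0.0, -10.0 * post_best_mono / log10))
    callqual = min(QUAL_CAP, max(0.0, -10.0 * log_post[0] / log10))
    return float(sgb), float(fq), float(callqual)


def variant_distance_bias(alt_obs: Sequence[Observation],
                          m: int = 1000, seed: int = 0) -> Tuple[float, bool]:
    """Monte-Carlo probability that the variance of alt-base read offsets
    under uniform placement within each read is <= the observed variance.

    Small VDB means the variant clusters at one read position (a splice-site
    mis-alignment signature).  Returns (vdb, degenerate_flag); fewer than
    two alt observations yield the sentinel (1.0, True).
    """
    if len(alt_obs) < 2:
        return 1.0, True
    rng = np.random.default_rng(seed)
    offsets = np.array([o.offset for o in alt_obs], dtype=float)
    obs_var = offsets.var()
    lengths = np.array([o.read_length for o in alt_obs])
    sim = rng.random((m, len(alt_obs))) * lengths[None, :]
    sim_offsets = np.floor(sim)
    sim_var = sim_offsets.var(axis=1)
    vdb = (np.count_nonzero(sim_var <= obs_var) + 1) / (m + 1)
    return float(vdb), False


# ---------------------------------------------------------------------------
# feature assembly
# ---------------------------------------------------------------------------

def _vdb_seed(base_seed: int, chrom: str, pos: int) -> int:
    """Stable per-site seed so feature extraction is a pure function."""
    return (zlib.crc32(f"{base_seed}:{chrom}:{pos}".encode()) & 0x7FFFFFFF)


def compute_features(column: PileupColumn, alt: str,
                     vdb_m: int = 1000, seed: int = 0) -> Dict[str, float]:
    """The full 15-attribute vector for one candidate column.

    Degenerate sub-statistics (empty reference group, single alt read)
    resolve to their documented sentinels, so the vector never has missing
    values.
    """
    obs = column.observations
    depth = len(obs)
    alt_obs = [o for o in obs if o.base == alt]
    ref_obs = [o for o in obs if o.base == column.ref_base]
    n_alt = len(alt_obs)

    mapqs = np.array([o.mapq for o in obs], dtype=float)
    mq = math.sqrt(float(np.mean(mapqs ** 2))) if depth else 0.0
    mq0f = float(np.mean(mapqs == 0)) if depth else 0.0

    mqb, pv3 = rank_sum_bias([o.mapq for o in alt_obs],
                             [o.mapq for o in ref_obs])
    bqb, pv2 = rank_sum_bias([o.baseq for o in alt_obs],
                             [o.baseq for o in ref_obs])
    rpb, _ = rank_sum_bias([o.offset / max(o.read_length - 1, 1) for o in alt_obs],
                           [o.offset / max(o.read_length - 1, 1) for o in ref_obs])
    _, pv4 = rank_sum_bias([o.dist_end for o in alt_obs],
                           [o.dist_end for o in ref_obs])
    alt_fwd = sum(1 for o in alt_obs if o.strand == "+")
    ref_fwd = sum(1 for o in ref_obs if o.strand == "+")
    pv1 = fisher_strand(alt_fwd, n_alt - alt_fwd,
                        ref_fwd, len(ref_obs) - ref_fwd)
    vdb, _ = variant_distance_bias(alt_obs, m=vdb_m,
                                   seed=_vdb_seed(seed, column.chrom, column.pos))
    sgb, fq, callqual = segregation_features(column, alt)
    return {
        "ReadDepth": float(depth),
        "VAF": n_alt / depth if depth else 0.0,
        "SGB": sgb,
        "FQ": fq,
        "CallQual": callqual,
        "PV3": pv3,
        "MQB": mqb,
        "MQ0F": mq0f,
        "MQ": mq,
        "VDB": vdb,
        "RPB": rpb,
        "PV4": pv4,
        "PV2": pv2,
        "BQB": bqb,
        "PV1": pv1,
    }


def featurize_candidates(table: CandidateTable, columns: Sequence[PileupColumn],
                         vdb_m: int = 1000, seed: int = 0) -> CandidateTable:
    """Attach the 15 feature columns to a candidate table (columns must be
    the per-site pileups returned by ``call_candidates(keep_columns=True)``)."""
    if len(columns) != len(table):
        raise ValueError("one pileup column required per candidate row")
    feats = [compute_features(col, alt, vdb_m=vdb_m, seed=seed)
             for col, alt in zip(columns, table.df["alt"])]
    fdf = pd.DataFrame(feats, columns=FEATURE_ORDER)
    out = table.df.reset_index(drop=True).join(fdf)
    return CandidateTable(df=out, provenance=dict(table.provenance, vdb_m=vdb_m,
                                                  feature_seed=seed),
                          n_multiallelic_dropped=table.n_multiallelic_dropped)


def detect_candidates(bam_path, ref_path,
                      min_depth: int = DEFAULT_MIN_DEPTH,
                      min_alt: int = DEFAULT_MIN_ALT,
                      min_alt_frac: float = 0.0,
                      min_baseq: int = DEFAULT_MIN_BASEQ,
                      vdb_m: int = 1000, seed: int = 0,
                      with_features: bool = True) -> CandidateTable:
    """BAM + reference -> featurized raw RDD candidate table (one pass)."""
    cols = build_pileup(bam_path, ref_path, min_baseq=min_baseq)
    table, kept = call_candidates(cols, min_depth=min_depth, min_alt=min_alt,
                                  min_alt_frac=min_alt_frac, keep_columns=True)
    if with_features:
        return featurize_candidates(table, kept, vdb_m=vdb_m, seed=seed)
    return table
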