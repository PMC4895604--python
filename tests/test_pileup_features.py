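"""Pileup construction, candidate calling, and the 15 attributes."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats

from rddkit.pileup_features import (Observation, PileupColumn, build_pileup,
                                    call_candidates, compute_features,
                                    fisher_strand, rank_sum_bias,
                                    segregation_features,
                                    variant_distance_bias)
from conftest import make_bam

RNG = np.random.default_rng(2024)


def _obs(base, baseq=30, mapq=60, strand="+", offset=10, read_length=100):
    return Observation(base=base, baseq=baseq, mapq=mapq, strand=strand,
                       offset=offset, dist_end=min(offset, read_length - 1 - offset),
                       read_length=read_length)


def _column(bases, **kw):
    return PileupColumn("chr1", 500, "A",
                        [_obs(b, **kw) for b in bases])


# ---------------------------------------------------------------------------
# pileup construction
# ---------------------------------------------------------------------------

class TestBuildPileup:
    def test_single_read_depth_one(self, tmp_path):
        ref = "".join(RNG.choice(list("ACGT"), 200))
        bam, fa = make_bam(tmp_path, ref,
                           [dict(name="r1", pos=11, cigar="50M",
                                 seq=ref[10:60])])
        cols = list(build_pileup(bam, fa))
        assert len(cols) == 50
        assert all(c.depth == 1 for c in cols)
        assert [c.pos for c in cols] == list(range(11, 61))
        assert all(c.ref_base == c.observations[0].base for c in cols)

    def test_n_gap_contributes_no_columns(self, tmp_path):
        ref = "".join(RNG.choice(list("ACGT"), 200))
        seq = ref[0:25] + ref[125:150]
        bam, fa = make_bam(tmp_path, ref,
                           [dict(name="r1", pos=1, cigar="25M100N25M", seq=seq)])
        cols = list(build_pileup(bam, fa))
        assert [c.pos for c in cols] == list(range(1, 26)) + list(range(126, 151))

    def test_overlapping_reads_depth_pattern(self, tmp_path):
        ref = "".join(RNG.choice(list("ACGT"), 200))
        bam, fa = make_bam(tmp_path, ref, [
            dict(name="a", pos=1, cigar="30M", seq=ref[0:30]),
            dict(name="b", pos=21, cigar="30M", seq=ref[20:50]),
        ])
        depths = {c.pos: c.depth for c in build_pileup(bam, fa)}
        assert all(depths[p] == 1 for p in range(1, 21))
        assert all(depths[p] == 2 for p in range(21, 31))
        assert all(depths[p] == 1 for p in range(31, 51))

    def test_low_baseq_bases_skipped(self, tmp_path):
        ref = "".join(RNG.choice(list("ACGT"), 100))
        quals = [30] * 50
        quals[10] = 5
        bam, fa = make_bam(tmp_path, ref,
                           [dict(name="r1", pos=1, cigar="50M",
                                 seq=ref[:50], baseq=quals)])
        cols = {c.pos for c in build_pileup(bam, fa)}
        assert 11 not in cols and 10 in cols

    def test_reverse_read_offset_from_five_prime(self, tmp_path):
        ref = "".join(RNG.choice(list("ACGT"), 100))
        bam, fa = make_bam(tmp_path, ref,
                           [dict(name="r1", pos=1, cigar="50M",
                                 seq=ref[:50], flag=16)])
        cols = list(build_pileup(bam, fa))
        # leftmost genomic base is the 3' end of a reverse read
        assert cols[0].observations[0].offset == 49
        assert cols[-1].observations[0].offset == 0

    def test_reference_mismatch_error(self, tmp_path):
        ref = "".join(RNG.choice(list("ACGT"), 100))
        bam, _fa = make_bam(tmp_path, ref,
                            [dict(name="r1", pos=1, cigar="20M", seq=ref[:20])])
        other = tmp_path / "other.fa"
        other.write_text(">chrX\n" + ref + "\n")
        with pytest.raises(ValueError, match="chr1"):
            list(build_pileup(bam, other))


# ---------------------------------------------------------------------------
# candidate calling
# ---------------------------------------------------------------------------

class TestCallCandidates:
    def test_pure_reference_column(self):
        t = call_candidates([_column("A" * 10)])
        assert len(t) == 0

    def test_min_alt_threshold_edge(self):
        t = call_candidates([_column("A" * 8 + "GG")], min_alt=2)
        assert len(t) == 1
        row = t.df.iloc[0]
        assert (row.ref, row.alt, row.depth, row.alt_count) == ("A", "G", 10, 2)
        t2 = call_candidates([_column("A" * 9 + "G")], min_alt=2)
        assert len(t2) == 0

    def test_multiallelic_dropped_and_counted(self):
        t = call_candidates([_column("A" * 6 + "GG" + "TT")])
        assert len(t) == 0
        assert t.n_multiallelic_dropped == 1

    def test_min_depth(self):
        t = call_candidates([_column("A" * 7 + "GG")], min_depth=10)
        assert len(t) == 0

    def test_min_alt_frac(self):
        col = _column("A" * 18 + "GG")
        assert len(call_candidates([col], min_alt_frac=0.2)) == 0
        assert len(call_candidates([col], min_alt_frac=0.1)) == 1


# ---------------------------------------------------------------------------
# rank-sum bias
# ---------------------------------------------------------------------------

class TestRankSum:
    def test_identical_multisets(self):
        z, p = rank_sum_bias([1, 2, 3], [1, 2, 3])
        assert (z, p) == (0.0, 1.0)

    def test_swap_negates_z_preserves_p(self):
        z1, p1 = rank_sum_bias([1, 2], [3, 4])
        z2, p2 = rank_sum_bias([3, 4], [1, 2])
        assert z1 == -z2 and p1 == p2

    def test_empty_group_sentinel(self):
        assert rank_sum_bias([], [1, 2]) == (0.0, 1.0)

    def test_matches_scipy_asymptotic(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            n1, n2 = rng.integers(2, 9, 2)
            x = rng.normal(size=n1)
            y = rng.normal(size=n2)
            z, p = rank_sum_bias(x, y)
            ref = stats.mannwhitneyu(x, y, alternative="two-sided",
                                     method="asymptotic", use_continuity=True)
            assert p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_small_sample_against_exact_enumeration(self):
        """The tie-corrected normal approximation tracks the exact
        enumeration p: monotone agreement everywhere, numerically close
        once both groups are reasonably sized."""
        rng = np.random.default_rng(2)
        pairs = []
        for n1, n2 in itertools.product(range(1, 7), range(1, 7)):
            for _ in range(3):
                x = rng.integers(0, 8, n1).astype(float)
                y = rng.integers(0, 8, n2).astype(float)
                z, p = rank_sum_bias(x, y)
                comb = np.concatenate([x, y])
                ranks = stats.rankdata(comb)
                obs = abs(ranks[:n1].sum() - n1 * (n1 + n2 + 1) / 2)
                hits = total = 0
                for idx in itertools.combinations(range(n1 + n2), n1):
                    s = abs(ranks[list(idx)].sum() - n1 * (n1 + n2 + 1) / 2)
                    total += 1
                    hits += s >= obs - 1e-9
                p_exact = hits / total
                pairs.append((p, p_exact))
                if min(n1, n2) >= 4 and n1 + n2 >= 10:
                    assert p == pytest.approx(p_exact, abs=0.12)
                if abs(z) > 1e-12:
                    # z and the exact statistic agree on direction
                    assert np.sign(z) == np.sign(ranks[:n1].sum()
                                                 - n1 * (n1 + n2 + 1) / 2)
        approx, exact = zip(*pairs)
        rho, _ = stats.spearmanr(approx, exact)
        assert rho > 0.9


# ---------------------------------------------------------------------------
# Fisher strand
# ---------------------------------------------------------------------------

class TestFisherStrand:
    def test_balanced_table(self):
        assert fisher_strand(5, 5, 5, 5) == 1.0

    def test_extreme_table_matches_enumeration(self):
        p = fisher_strand(10, 0, 0, 10)
        assert p == pytest.approx(_fisher_enum(10, 0, 0, 10), abs=1e-12)

    def test_transpose_invariance(self):
        assert fisher_strand(7, 2, 3, 8) == pytest.approx(
            fisher_strand(7, 3, 2, 8), abs=1e-12)

    def test_all_small_tables_match_enumeration(self):
        for total in range(1, 13):
            for a in range(total + 1):
                for b in range(total - a + 1):
                    for c in range(total - a - b + 1):
                        d = total - a - b - c
                        assert fisher_strand(a, b, c, d) == pytest.approx(
                            _fisher_enum(a, b, c, d), abs=1e-9)

    def test_empty_table_error(self):
        with pytest.raises(ValueError):
            fisher_strand(0, 0, 0, 0)


def _fisher_enum(a, b, c, d):
    """Brute-force two-sided Fisher p: sum hypergeometric probabilities
    not exceeding the observed table's."""
    n, r1, c1 = a + b + c + d, a + b, a + c
    p_obs = stats.hypergeom.pmf(a, n, r1, c1)
    total = 0.0
    for aa in range(max(0, r1 + c1 - n), min(r1, c1) + 1):
        p = stats.hypergeom.pmf(aa, n, r1, c1)
        if p <= p_obs * (1 + 1e-7):
            total += p
    return min(1.0, total)


# ---------------------------------------------------------------------------
# segregation features
# ---------------------------------------------------------------------------

class TestSegregation:
    def test_all_reference_limit(self):
        sgb, fq, callqual = segregation_features(_column("A" * 20), "G")
        assert callqual == pytest.approx(0.0, abs=0.01)
        assert fq == pytest.approx(0.0, abs=0.01)

    def test_balanced_column_prefers_het(self):
        sgb, fq, callqual = segregation_features(_column("A" * 10 + "G" * 10), "G")
        assert sgb < 0          # error-only fits worse than het
        assert callqual > 30    # hom-ref posterior is tiny

    def test_depth_four_longhand_oracle(self):
        # direct-summation oracle with plain products, no logs
        quals = [20, 25, 30, 35]
        bases = ["G", "A", "G", "A"]
        obs = [_obs(b, baseq=q) for b, q in zip(bases, quals)]
        col = PileupColumn("chr1", 1, "A", obs)
        e = [10 ** (-q / 10) for q in quals]
        p_err = p_het = p_hom = 1.0
        for ei, b in zip(e, bases):
            p_err *= (ei / 3) if b == "G" else (1 - ei)
            p_het *= 0.5 * (1 - ei) + 0.5 * ei / 3
            p_hom *= (1 - ei) if b == "G" else (ei / 3)
        total = p_err + p_het + p_hom
        exp_sgb = math.log(p_err) - math.log(p_het)
        exp_fq = -10 * math.log10(max(p_err, p_hom) / total)
        exp_cq = -10 * math.log10(p_err / total)
        sgb, fq, callqual = segregation_features(col, "G")
        assert sgb == pytest.approx(exp_sgb, rel=1e-9)
        assert fq == pytest.approx(exp_fq, rel=1e-9)
        assert callqual == pytest.approx(exp_cq, rel=1e-9)


# ---------------------------------------------------------------------------
# variant distance bias
# ---------------------------------------------------------------------------

class TestVDB:
    def test_clustered_offsets_small_vdb(self):
        obs = [_obs("G", offset=37) for _ in range(6)]
        vdb, flag = variant_distance_bias(obs, seed=3)
        assert not flag and vdb <= 0.05

    def test_single_observation_sentinel(self):
        vdb, flag = variant_distance_bias([_obs("G")], seed=3)
        assert (vdb, flag) == (1.0, True)

    def test_seed_determinism(self):
        obs = [_obs("G", offset=o) for o in (5, 40, 80)]
        assert variant_distance_bias(obs, seed=9) == \
            variant_distance_bias(obs, seed=9)


# ---------------------------------------------------------------------------
# full feature vectors
# ---------------------------------------------------------------------------

class TestComputeFeatures:
    def test_homogeneous_column(self):
        col = _column("A" * 5 + "G" * 5)
        f = compute_features(col, "G")
        assert f["ReadDepth"] == 10
        assert f["VAF"] == 0.5
        assert f["MQ"] == 60
        assert f["MQ0F"] == 0.0
        assert f["MQB"] == 0.0 and f["PV3"] == 1.0

    def test_mq0_fraction(self):
        obs = [_obs("A", mapq=0)] * 2 + [_obs("A", mapq=60)] * 6 + \
              [_obs("G", mapq=60)] * 2
        f = compute_features(PileupColumn("chr1", 1, "A", obs), "G")
        assert f["MQ0F"] == pytest.approx(0.2)
        assert f["MQ"] == pytest.approx(math.sqrt((2 * 0 + 8 * 3600) / 10))

    def test_crafted_column_matches_longhand(self):
        """12-read column checked field-by-field against independent
        spreadsheet-style arithmetic (scipy for the tests)."""
        specs = [  # (base, baseq, mapq, strand, offset)
            ("A", 31, 60, "+", 10), ("A", 33, 60, "-", 20),
            ("A", 35, 55, "+", 30), ("A", 30, 60, "-", 40),
            ("A", 32, 58, "+", 50), ("A", 34, 60, "-", 60),
            ("A", 36, 60, "+", 70), ("A", 29, 52, "-", 80),
            ("G", 25, 30, "+", 15), ("G", 26, 0, "+", 25),
            ("G", 27, 35, "+", 35), ("G", 24, 30, "+", 45),
        ]
        obs = [_obs(b, baseq=q, mapq=m, strand=s, offset=o)
               for b, q, m, s, o in specs]
        col = PileupColumn("chr1", 77, "A", obs)
        f = compute_features(col, "G")
        alt = [s for s in specs if s[0] == "G"]
        ref = [s for s in specs if s[0] == "A"]
        assert f["ReadDepth"] == 12
        assert f["VAF"] == pytest.approx(4 / 12)
        assert f["VAF"] * f["ReadDepth"] == pytest.approx(4)
        assert f["MQ"] == pytest.approx(
            math.sqrt(sum(s[2] ** 2 for s in specs) / 12))
        assert f["MQ0F"] == pytest.approx(1 / 12)
        # rank-sum features against scipy
        for key, idx in (("PV3", 2), ("PV2", 1)):
            got = stats.mannwhitneyu([s[idx] for s in alt],
                                     [s[idx] for s in ref],
                                     alternative="two-sided",
                                     method="asymptotic",
                                     use_continuity=True)
            assert f[key] == pytest.approx(got.pvalue, abs=1e-12)
        got = stats.mannwhitneyu([min(s[4], 99 - s[4]) for s in alt],
                                 [min(s[4], 99 - s[4]) for s in ref],
                                 alternative="two-sided",
                                 method="asymptotic", use_continuity=True)
        assert f["PV4"] == pytest.approx(got.pvalue, abs=1e-12)
        # strand 2x2: alt 4+/0-, ref 4+/4-
        _, p = stats.fisher_exact([[4, 0], [4, 4]])
        assert f["PV1"] == pytest.approx(p, abs=1e-12)
        assert 0 < f["VDB"] <= 1

    def test_purity_same_column_same_vector(self):
        col = _column("A" * 7 + "G" * 3)
        assert compute_features(col, "G", seed=4) == \
            compute_features(col, "G", seed=4)

    def test_vaf_one_column_has_sentinels(self):
        f = compute_features(_column("G" * 12), "G")
        assert f["PV3"] == 1.0 and f["MQB"] == 0.0
        assert f["VAF"] == 1.0
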