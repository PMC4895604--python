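"""Shared fixtures: hand-built alignments and the synthetic study.

Everything is generated at test time; session scope keeps the expensive
end-to-end artifacts to a single build.
"""

from __future__ import annotations

from pathlib import Path

import pysam
import pytest

from rddkit import pipeline
from rddkit.study import prepare_study


def make_bam(dirpath: Path, ref_seq: str, reads, chrom: str = "chr1"):
    """Write a reference FASTA and a sorted/indexed BAM from read dicts
    (name, pos [1-based], cigar, seq, mapq=60, flag=0, baseq=30)."""
    dirpath.mkdir(parents=True, exist_ok=True)
    ref_path = dirpath / "ref.fa"
    with open(ref_path, "w") as fh:
        fh.write(f">{chrom}\n{ref_seq}\n")
    header = pysam.AlignmentHeader.from_dict({
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": chrom, "LN": len(ref_seq)}],
    })
    records = []
    for spec in reads:
        a = pysam.AlignedSegment(header)
        a.query_name = spec["name"]
        a.query_sequence = spec["seq"]
        a.flag = spec.get("flag", 0)
        a.reference_id = 0
        a.reference_start = spec["pos"] - 1
        a.mapping_quality = spec.get("mapq", 60)
        a.cigarstring = spec["cigar"]
        q = spec.get("baseq", 30)
        quals = q if isinstance(q, list) else [q] * len(spec["seq"])
        a.query_qualities = quals
        records.append(a)
    records.sort(key=lambda a: a.reference_start)
    bam_path = dirpath / "reads.bam"
    with pysam.AlignmentFile(bam_path, "wb", header=header) as out:
        for a in records:
            out.write(a)
    pysam.index(str(bam_path))
    return bam_path, ref_path


@pytest.fixture(scope="session")
def study(tmp_path_factory):
    """The full synthetic study under default conditions, pipeline executed.

    Returns the prepare_study dict extended with the run manifest and the
    run output directory."""
    root = tmp_path_factory.mktemp("study")
    info = prepare_study(root, seed=7)
    manifest = pipeline.run(info["config"])
    info["manifest"] = manifest
    info["rundir"] = Path(info["config"]["outdir"])
    return info


@pytest.fixture(scope="session")
def small_scene():
    """A cheap genome + transcripts for generator unit tests."""
    from rddkit.synthetic_data import build_scene
    genome, transcripts, cfg = build_scene(
        seed=11,
        chrom_lengths={"chr1": 12000},
        repeats=[dict(name="repfam0", chrom="chr1", length=1000, copies=2,
                      divergence=0.02)],
    )
    return genome, transcripts, cfg
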