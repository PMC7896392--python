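"""Shared fixtures: synthetic genomes, reads and a trained profile.

Everything is generated at test time from seeded generators; the heavier
artefacts (fixture SAM, trained profile) are session-scoped so the many
tests that need them pay the cost once.
"""

import numpy as np
import pysam
import pytest

from readsmith.fixtures import (
    TruthProfile, make_genome, make_mapped_reads,
)

TRUSEQ1 = "AGATCGGAAGAGCACACGTCTGAACTCCAGTCAC"
TRUSEQ2 = "AGATCGGAAGAGCGTCGTGTAGGGAAAGAGTGTA"


@pytest.fixture(scope="session")
def toy_genome():
    return make_genome(11, [30_000], gc=0.5)


@pytest.fixture(scope="session")
def toy_truth():
    return TruthProfile.smooth(
        12, alpha=0.3, beta=0.05, sys_density=1e-3,
        adapter1=TRUSEQ1, adapter2=TRUSEQ2,
        frag_mean=150, frag_sd=40, min_frag=40,
    )


@pytest.fixture(scope="session")
def fixture_bundle(tmp_path_factory, toy_genome, toy_truth):
    """A fixture SAM with planted adapters/systematics plus its ground truth."""
    d = tmp_path_factory.mktemp("fixture")
    sam = d / "fixture.sam"
    planted = make_mapped_reads(toy_genome, toy_truth, 40_000, 99, sam,
                                fastq_prefix=str(d / "fixture"))
    return {"genome": toy_genome, "truth": toy_truth, "sam": str(sam),
            "planted": planted, "dir": d}


@pytest.fixture(scope="session")
def trained_profile(fixture_bundle):
    from readsmith.train import TrainingReport, train_profile

    report = TrainingReport()
    profile = train_profile(
        fixture_bundle["sam"], fixture_bundle["genome"],
        min_fit_sites=5_000, max_fits=4, ipf_sweeps=100, report=report,
    )
    profile._report = report
    return profile


def write_sam(path, genome, records):
    """Write simple SAM records: dicts with keys matching AlignedSegment."""
    header = pysam.AlignmentHeader.from_dict({
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": n, "LN": genome.length(n)} for n in genome.names],
    })
    segs = []
    for r in records:
        a = pysam.AlignedSegment(header)
        a.query_name = r.get("name", "r")
        a.reference_id = genome.names.index(r["seq"])
        a.reference_start = r["pos"]
        a.mapping_quality = r.get("mapq", 60)
        a.cigartuples = r["cigar"]
        a.query_sequence = r["bases"]
        a.query_qualities = r.get("quals", [30] * len(r["bases"]))
        a.is_paired = True
        a.is_proper_pair = True
        a.is_read1 = r.get("segment", 0) == 0
        a.is_read2 = r.get("segment", 0) == 1
        a.is_reverse = r.get("reverse", False)
        a.mate_is_reverse = not a.is_reverse
        a.template_length = r.get("tlen", len(r["bases"]))
        a.next_reference_id = a.reference_id
        a.next_reference_start = r.get("mate_pos", r["pos"])
        segs.append(a)
    segs.sort(key=lambda a: (a.reference_id, a.reference_start))
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for a in segs:
            out.write(a)
    return str(path)


@pytest.fixture()
def sam_writer():
    return write_sam
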