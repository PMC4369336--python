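"""Shared fixtures: tiny in-memory BAMs and a small simulated dataset."""

from __future__ import annotations

import numpy as np
import pysam
import pytest

from rdcnv import simulate
from rdcnv.config import Config


def make_bam(path, records, chrom_lengths):
    """Write a coordinate-ordered BAM from (chrom, start, length, flags, mapq, tlen) tuples.

    ``records`` must already be sorted by (chrom index, start).
    """
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c, "LN": n} for c, n in chrom_lengths.items()],
    }
    chrom_ids = {c: i for i, c in enumerate(chrom_lengths)}
    with pysam.AlignmentFile(str(path), "wb", header=header) as bam:
        for i, (chrom, start, length, flag, mapq, tlen) in enumerate(records):
            a = pysam.AlignedSegment()
            a.query_name = f"r{i}"
            a.reference_id = chrom_ids[chrom]
            a.reference_start = start
            a.flag = flag
            a.mapping_quality = mapq
            a.cigar = [(0, length)]
            a.query_sequence = "A" * length
            a.template_length = tlen
            if flag & 1:
                a.next_reference_id = chrom_ids[chrom]
                a.next_reference_start = start
            bam.write(a)
    pysam.index(str(path))
    return str(path)


@pytest.fixture(scope="session")
def small_fixture(tmp_path_factory):
    """2 x 400 kb simulated dataset with 2 deletions + 2 duplications."""
    out = tmp_path_factory.mktemp("small_fixture")
    spec = simulate.default_fixture_spec(
        seed=3, chrom_length=400_000, n_del=2, n_dup=2
    )
    paths = simulate.build_fixture(spec, str(out))
    return {**paths, "spec": spec}


@pytest.fixture()
def config():
    return Config(seed=7)
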