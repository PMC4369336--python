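"""Alignment and reference I/O: per-base depth, window mapping quality, library stats.

Depth is a full aligned-span pileup: every reference-consuming CIGAR block of a
retained read increments each base it covers.  Reads are additionally counted
once per 100-base window by read center, which feeds the window mean mapping
quality (used for distribution stratification) and the fixed-window
mean-normalization diagnostic.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np
import pysam


@dataclass
class LibraryModel:
    """Sequencing-library summary used throughout normalization and calling.

    ``mean_insert`` is the average outer fragment length for paired-end data;
    for single-end libraries the insert size is the read length.
    """

    read_length: int
    mean_insert: int
    paired: bool
    chrom_mean_depth: dict[str, float] = field(default_factory=dict)
    genome_mean_depth: float = 0.0
    genome_depth_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.read_length < 1:
            raise ValueError("read_length must be >= 1")
        if self.mean_insert < self.read_length:
            raise ValueError("mean_insert must be >= read_length")


@dataclass
class DepthTrack:
    """Per-base read depth for one chromosome plus per-window read statistics."""

    chrom: str
    depth: np.ndarray          # int32, len == chromosome length
    window_mq: np.ndarray      # float, mean MAPQ of reads centered in each window
    window_reads: np.ndarray   # int32, reads centered in each window
    window_size: int = 100


@dataclass
class RecordFilters:
    """Which alignment records contribute to depth.

    MAPQ-0 reads are kept by default; low-confidence placements are handled by
    the mapping-quality stratification of the normalization bins rather than
    by discarding reads.
    """

    drop_unmapped: bool = True
    drop_secondary: bool = True
    drop_supplementary: bool = True
    drop_duplicate: bool = True
    drop_qcfail: bool = True
    min_mapq: int = 0

    def keep(self, read: pysam.AlignedSegment) -> bool:
        if self.drop_unmapped and read.is_unmapped:
            return False
        if self.drop_secondary and read.is_secondary:
            return False
        if self.drop_supplementary and read.is_supplementary:
            return False
        if self.drop_duplicate and read.is_duplicate:
            return False
        if self.drop_qcfail and read.is_qcfail:
            return False
        if read.mapping_quality < self.min_mapq:
            return False
        return True


def estimate_library_model(
    alignments: Iterable[pysam.AlignedSegment], sample_size: int = 10_000
) -> LibraryModel:
    """Estimate read length and mean insert size from the head of a BAM stream.

    The insert size is the rounded mean of absolute template lengths over the
    first ``sample_size`` properly-paired, primary, non-duplicate records.
    Read length is the modal aligned length; mixed lengths trigger a warning.
    """
    if sample_size < 1:
        raise ValueError("sample_size must be >= 1")
    lengths: Counter[int] = Counter()
    tlens: list[int] = []
    any_paired = False
    n_seen = 0
    for read in alignments:
        if read.is_unmapped or read.is_secondary or read.is_supplementary or read.is_duplicate:
            continue
        n_seen += 1
        alen = read.query_alignment_length or read.infer_read_length() or 0
        if alen > 0:
            lengths[alen] += 1
        if read.is_paired:
            any_paired = True
            if read.is_proper_pair and read.template_length != 0:
                tlens.append(abs(read.template_length))
        if len(tlens) >= sample_size or (not any_paired and n_seen >= sample_size):
            break
    if not lengths:
        raise ValueError("no usable alignments")
    if len(lengths) > 1:
        warnings.warn(
            f"mixed read lengths {sorted(lengths)}; using mode", stacklevel=2
        )
    read_length = lengths.most_common(1)[0][0]
    if any_paired and tlens:
        mean_insert = int(round(float(np.mean(tlens))))
        mean_insert = max(mean_insert, read_length)
    else:
        mean_insert = read_length
    return LibraryModel(read_length=read_length, mean_insert=mean_insert, paired=any_paired)


def compute_depth_track(
    alignments: Iterable[pysam.AlignedSegment],
    chrom: str,
    chrom_length: int,
    filters: RecordFilters | None = None,
    window_size: int = 100,
) -> DepthTrack:
    """Pileup depth over one chromosome from a coordinate-sorted record stream."""
    if chrom_length <= 0:
        raise ValueError("chrom_length must be > 0")
    filters = filters or RecordFilters()
    n_windows = (chrom_length + window_size - 1) // window_size
    diff = np.zeros(chrom_length + 1, dtype=np.int64)
    mq_sum = np.zeros(n_windows, dtype=np.float64)
    mq_n = np.zeros(n_windows, dtype=np.int64)
    last_start = -1
    for read in alignments:
        start = read.reference_start
        if start < last_start:
            raise ValueError(f"alignments for {chrom} are not coordinate-sorted")
        last_start = start
        if not filters.keep(read):
            continue
        end = read.reference_end
        if end is None:
            continue
        cigar = read.cigartuples
        if cigar is not None and any(op in (3,) for op, _ in cigar):
            # spliced alignment: count each reference block separately
            for bstart, bend in read.get_blocks():
                diff[max(bstart, 0)] += 1
                diff[min(bend, chrom_length)] -= 1
        else:
            diff[max(start, 0)] += 1
            diff[min(end, chrom_length)] -= 1
        center = (start + end) // 2
        w = min(center // window_size, n_windows - 1)
        mq_sum[w] += read.mapping_quality
        mq_n[w] += 1
    depth = np.cumsum(diff[:-1]).astype(np.int32)
    with np.errstate(invalid="ignore"):
        window_mq = np.where(mq_n > 0, mq_sum / np.maximum(mq_n, 1), 0.0)
    return DepthTrack(
        chrom=chrom,
        depth=depth,
        window_mq=window_mq,
        window_reads=mq_n.astype(np.int32),
        window_size=window_size,
    )


def depth_tracks_from_bam(
    bam_path: str,
    chrom_lengths: dict[str, int],
    filters: RecordFilters | None = None,
    window_size: int = 100,
) -> dict[str, DepthTrack]:
    """Depth tracks for every reference chromosome; missing chromosomes yield empty tracks."""
    tracks: dict[str, DepthTrack] = {}
    with pysam.AlignmentFile(bam_path, "rb") as bam:
        for chrom, length in chrom_lengths.items():
            if chrom not in bam.references:
                warnings.warn(f"chromosome {chrom} absent from {bam_path}; empty track")
                tracks[chrom] = compute_depth_track(iter(()), chrom, length, filters, window_size)
                continue
            tracks[chrom] = compute_depth_track(
                bam.fetch(chrom), chrom, length, filters, window_size
            )
    return tracks


def n_mask_from_sequence(seq: str) -> np.ndarray:
    """Boolean array, True at reference N (or other ambiguous) bases."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    acgt = (arr == ord("A")) | (arr == ord("C")) | (arr == ord("G")) | (arr == ord("T"))
    return ~acgt


def summarize_depth(
    tracks: dict[str, DepthTrack],
    n_masks: dict[str, np.ndarray] | None,
    library: LibraryModel,
) -> LibraryModel:
    """Fill chromosome / genome depth means and the genome per-base depth SD.

    All statistics exclude reference N bases.  Chromosomes that are entirely N
    are dropped with a warning.
    """
    if not tracks:
        raise ValueError("at least one depth track required")
    pooled: list[np.ndarray] = []
    for chrom, track in tracks.items():
        if n_masks is not None and chrom in n_masks:
            valid = track.depth[~n_masks[chrom]]
        else:
            valid = track.depth
        if valid.size == 0:
            warnings.warn(f"chromosome {chrom} is entirely N; excluded from depth summary")
            continue
        library.chrom_mean_depth[chrom] = float(valid.mean())
        pooled.append(valid)
    if not pooled:
        raise ValueError("no non-N bases in any chromosome")
    allv = np.concatenate(pooled)
    library.genome_mean_depth = float(allv.mean())
    library.genome_depth_sd = float(allv.std())
    return library


def write_bedgraph(path: str, chrom: str, values: np.ndarray) -> None:
    """Write a per-base value array as a run-length encoded BedGraph."""
    vals = np.asarray(values, dtype=np.float64)
    if vals.size == 0:
        open(path, "w").close()
        return
    isnan = np.isnan(vals)
    rle = np.where(isnan, np.inf, vals)  # collapse NaN stretches into single runs
    change = np.nonzero(rle[1:] != rle[:-1])[0] + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [vals.size]))
    with open(path, "w") as fh:
        for s, e in zip(starts, ends):
            if isnan[s]:
                continue
            fh.write(f"{chrom}\t{s}\t{e}\t{vals[s]:g}\n")
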