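"""End-to-end orchestration of the two-pipeline CNV caller.

Order of operations: library estimation -> per-base depth -> depth summary ->
GC weighting -> dinucleotide run detection and bias assessment ->
excessive-coverage clustering -> per pipeline (masked / unmasked): bin
partition, quantile normalization, window-distribution sampling, breakpoint
screen and sliding-window search -> union merge of the two call sets.

When masking finds no clusters the two pipelines are identical, so the search
runs once and tags its calls ``both``.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np
import pysam

from . import alignment_io, cnv_caller, coverage_mask, gc_model, repeat_model
from .alignment_io import DepthTrack, LibraryModel, RecordFilters
from .cnv_caller import CNVCall, WindowDistribution
from .config import Config
from .coverage_mask import MaskCluster
from .gc_model import BinAssignment
from .repeat_model import RepeatBiasModel

log = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    calls: list[CNVCall]
    calls_masked: list[CNVCall]
    calls_unmasked: list[CNVCall]
    clusters: list[MaskCluster]
    library: LibraryModel
    repeat_bias: RepeatBiasModel
    binned_bases: dict[str, int]          # pipeline -> bases covered by bins
    gc_diagnostic: "object" = None        # pandas DataFrame from the mean-normalization diagnostic
    timings: dict[str, float] = field(default_factory=dict)


def _gap_guard(n_mask: np.ndarray, guard: int) -> np.ndarray:
    """True within ``guard`` bases of an N base or a chromosome end.

    Fragments cannot span unsequenceable territory, so depth drops to about
    half coverage over the last insert-length of sequence approaching an
    N-gap or a chromosome end; screening there would produce spurious
    deletion candidates.
    """
    n = n_mask.size
    cs = np.concatenate(([0], np.cumsum(n_mask)))
    idx = np.arange(n)
    lo = np.maximum(idx - guard, 0)
    hi = np.minimum(idx + guard + 1, n)
    out = (cs[hi] - cs[lo]) > 0
    out[:guard] = True
    out[n - guard :] = True
    return out


def _read_exclude_bed(path: str, chrom_lengths: dict[str, int]) -> dict[str, np.ndarray]:
    masks = {c: np.zeros(n, dtype=bool) for c, n in chrom_lengths.items()}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.split("\t")
            chrom, s, t = f[0], int(f[1]), int(f[2])
            if chrom in masks:
                masks[chrom][s:t] = True
    return masks


def _combine_masks(*masks: dict[str, np.ndarray] | None) -> dict[str, np.ndarray] | None:
    present = [m for m in masks if m]
    if not present:
        return None
    out: dict[str, np.ndarray] = {}
    for m in present:
        for c, arr in m.items():
            out[c] = out.get(c, np.zeros(arr.size, dtype=bool)) | arr
    return out


def run_pipeline(
    bam_path: str,
    fasta_path: str,
    config: Config | None = None,
    exclude_bed: str | None = None,
    filters: RecordFilters | None = None,
) -> PipelineResult:
    """Call CNVs from a coordinate-sorted indexed BAM and its reference FASTA."""
    config = config or Config()
    t0 = time.time()
    timings: dict[str, float] = {}

    with pysam.FastaFile(fasta_path) as fa:
        chrom_lengths = dict(zip(fa.references, fa.lengths))
        seqs = {c: fa.fetch(c) for c in fa.references}
    n_masks = {c: alignment_io.n_mask_from_sequence(s) for c, s in seqs.items()}

    with pysam.AlignmentFile(bam_path, "rb") as bam:
        library = alignment_io.estimate_library_model(bam.fetch(until_eof=True))
    log.info("library: read_length=%d mean_insert=%d paired=%s",
             library.read_length, library.mean_insert, library.paired)
    timings["library"] = time.time() - t0

    t = time.time()
    depth = alignment_io.depth_tracks_from_bam(
        bam_path, chrom_lengths, filters, config.window_base
    )
    alignment_io.summarize_depth(depth, n_masks, library)
    timings["depth"] = time.time() - t
    log.info("genome mean depth %.2f (sd %.2f)",
             library.genome_mean_depth, library.genome_depth_sd)

    t = time.time()
    weights = {
        c: gc_model.compute_gc_weights(seqs[c], library, chrom=c) for c in chrom_lengths
    }
    timings["gc_weights"] = time.time() - t

    t = time.time()
    runs = [
        r for c in chrom_lengths
        for r in repeat_model.find_dinucleotide_runs(seqs[c], c, config.min_repeat_len)
    ]
    bias = repeat_model.assess_motif_bias(
        runs, depth, library, config.min_motif_occurrences, config.repeat_bias_sd
    )
    timings["repeat_bias"] = time.time() - t
    log.info("dinucleotide runs: %d; biased motifs: %s", len(runs),
             sorted(bias.biased_motifs) or "none")

    exclude = _read_exclude_bed(exclude_bed, chrom_lengths) if exclude_bed else None

    clusters: list[MaskCluster] = []
    if config.masking:
        t = time.time()
        for c in chrom_lengths:
            flags = coverage_mask.compute_block_flags(
                depth[c], library.chrom_mean_depth[c], n_masks[c],
                config.block_size, config.mask_multiple,
            )
            clusters.extend(
                coverage_mask.find_excess_clusters(
                    flags, c, config.block_size, chrom_lengths[c],
                    config.min_cluster_high, config.min_cluster_density,
                )
            )
        timings["masking"] = time.time() - t
        log.info("mask clusters: %d", len(clusters))

    diagnostic = _gc_diagnostic(depth, seqs, config)

    def run_one(pipeline: str, mask: dict[str, np.ndarray] | None):
        t = time.time()
        full_mask = _combine_masks(mask, exclude)
        assignment = repeat_model.normalize_repeat_regions(
            bias, weights, depth, library, config, mask=full_mask
        )
        x = gc_model.quantile_normalize(assignment, depth, library, config)
        r_ave = gc_model.r_ave_track(assignment)
        sizes = cnv_caller.window_size_grid(
            config.min_window, config.max_window, config.n_window_sizes
        )
        dists = cnv_caller.sample_window_distributions(
            x, sizes, config.n_sample_windows,
            seed=config.seed + (1 if pipeline == "masked" else 2),
        )
        calls: list[CNVCall] = []
        # fragments need a full insert of contiguous sequence, so depth sits
        # at roughly half coverage for insert-minus-read-length bases before
        # unsequenceable territory
        guard = library.mean_insert
        for c in chrom_lengths:
            eligible = ~_gap_guard(n_masks[c], guard)
            if full_mask is not None and c in full_mask:
                eligible = eligible & ~full_mask[c]
            calls.extend(
                cnv_caller.scan_chromosome(
                    c, x[c].x, depth[c].depth, r_ave[c], eligible, dists,
                    library.chrom_mean_depth[c], config, pipeline,
                )
            )
        timings[f"scan_{pipeline}"] = time.time() - t
        return calls, assignment.total_binned()

    binned: dict[str, int] = {}
    if config.masking and clusters:
        mask = coverage_mask.apply_mask(clusters, chrom_lengths)
        calls_masked, binned["masked"] = run_one("masked", mask)
        calls_unmasked, binned["unmasked"] = run_one("unmasked", None)
        final = cnv_caller.merge_pipeline_union(calls_masked, calls_unmasked)
    elif config.masking:
        # no clusters: both pipelines are identical; run once, tag both
        calls, nb = run_one("both", None)
        binned["masked"] = binned["unmasked"] = nb
        calls_masked = calls_unmasked = calls
        final = calls
    else:
        calls_unmasked, binned["unmasked"] = run_one("unmasked", None)
        calls_masked = []
        final = calls_unmasked

    timings["total"] = time.time() - t0
    log.info("calls: %d (%.1f s total)", len(final), timings["total"])
    return PipelineResult(
        calls=final,
        calls_masked=calls_masked,
        calls_unmasked=calls_unmasked,
        clusters=clusters,
        library=library,
        repeat_bias=bias,
        binned_bases=binned,
        gc_diagnostic=diagnostic,
        timings=timings,
    )


def _gc_diagnostic(depth: dict[str, DepthTrack], seqs: dict[str, str], config: Config):
    """Classical mean-normalization diagnostic over fixed windows, all chromosomes."""
    counts, gcs = [], []
    for c, track in depth.items():
        gc = gc_model.window_gc_content(seqs[c], track.window_size)
        m = min(gc.size, track.window_reads.size)
        counts.append(track.window_reads[:m].astype(float))
        gcs.append(gc[:m])
    return gc_model.gc_mean_normalize_diagnostic(
        np.concatenate(counts), np.concatenate(gcs), config.gc_bin_width
    )
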