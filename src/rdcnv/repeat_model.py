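"""Dinucleotide repeat annotation, motif bias assessment, and distance-binned
replacement of GC normalization near biased repeats.

Tandem runs of a two-base motif as short as 20 bases can carry motif-specific
coverage suppression (or inflation).  A motif is flagged biased when the mean
per-base coverage over all of its runs deviates from the genome mean by more
than 1.5 genome per-base depth SDs.  Bases within half an insert size of a
biased run are pulled out of their GC bins and quantile-normalized within
(motif, distance-from-run) populations instead, with distances binned in
10-base increments; distance 0 means inside the run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .alignment_io import DepthTrack, LibraryModel
from .config import Config
from .gc_model import Bin, BinAssignment, GCWeightTrack, assign_gc_bins

log = logging.getLogger(__name__)


@dataclass
class RepeatRun:
    """A maximal period-2 tandem run (two distinct bases, homopolymers excluded)."""

    chrom: str
    start: int  # 0-based half-open
    end: int
    motif: str  # canonical rotation, e.g. TATA... reports "AT"

    @property
    def length(self) -> int:
        return self.end - self.start


def canonical_motif(two_mer: str) -> str:
    """Lexicographically smaller rotation of a 2-mer."""
    return min(two_mer, two_mer[1] + two_mer[0])


def find_dinucleotide_runs(
    seq: str, chrom: str = "", min_len: int = 20
) -> list[RepeatRun]:
    """Maximal runs of period-2 repetition with two distinct bases.

    N terminates runs; homopolymer runs are not dinucleotide repeats and are
    dropped.  A run cannot be extended by one base in either direction.
    """
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    n = arr.size
    if n < min_len:
        return []
    valid = (
        (arr == ord("A")) | (arr == ord("C")) | (arr == ord("G")) | (arr == ord("T"))
    )
    eq = (arr[2:] == arr[:-2]) & valid[2:] & valid[:-2]
    # maximal stretches of True in eq -> runs [a, c+3)
    padded = np.concatenate(([False], eq, [False]))
    d = np.diff(padded.astype(np.int8))
    starts = np.nonzero(d == 1)[0]
    ends = np.nonzero(d == -1)[0]  # exclusive in eq coordinates
    runs: list[RepeatRun] = []
    for a, c in zip(starts, ends):
        run_start, run_end = int(a), int(c) + 2  # half-open in sequence coordinates
        if run_end - run_start < min_len:
            continue
        b0, b1 = chr(arr[run_start]), chr(arr[run_start + 1])
        if b0 == b1:
            continue  # homopolymer
        runs.append(
            RepeatRun(chrom=chrom, start=run_start, end=run_end, motif=canonical_motif(b0 + b1))
        )
    return runs


@dataclass
class MotifBias:
    motif: str
    n_runs: int
    n_bases: int
    mean_coverage: float
    sd_coverage: float
    direction: str  # "low", "high", or "none"


@dataclass
class RepeatBiasModel:
    runs: list[RepeatRun]
    motif_bias: dict[str, MotifBias] = field(default_factory=dict)

    @property
    def biased_motifs(self) -> set[str]:
        return {m for m, b in self.motif_bias.items() if b.direction != "none"}

    def biased_runs(self) -> list[RepeatRun]:
        biased = self.biased_motifs
        return [r for r in self.runs if r.motif in biased]


def assess_motif_bias(
    runs: list[RepeatRun],
    depth: dict[str, DepthTrack],
    library: LibraryModel,
    min_occurrences: int = 50,
    bias_sd: float = 1.5,
) -> RepeatBiasModel:
    """Flag motifs whose run coverage deviates from the genome mean by > bias_sd SDs.

    The deviation is tested in both framings: the motif mean against the
    genome mean using the genome-wide per-base depth SD, and the genome mean
    against the motif mean using the motif's own per-base depth SD.  The
    second clause matters: a suppressed motif has a correspondingly tighter
    depth distribution, so at modest coverage only its own SD gives the test
    useful power.  Motifs with fewer than ``min_occurrences`` runs are left
    unflagged (too few to estimate).
    """
    model = RepeatBiasModel(runs=runs)
    by_motif: dict[str, list[RepeatRun]] = {}
    for r in runs:
        by_motif.setdefault(r.motif, []).append(r)
    gmean, gsd = library.genome_mean_depth, library.genome_depth_sd
    for motif, mruns in sorted(by_motif.items()):
        vals = [depth[r.chrom].depth[r.start : r.end] for r in mruns]
        pooled = np.concatenate(vals) if vals else np.empty(0)
        nb = pooled.size
        mean_cov = float(pooled.mean()) if nb else float("nan")
        sd_cov = float(pooled.std()) if nb else float("nan")
        if len(mruns) < min_occurrences:
            log.info(
                "motif %s: %d runs < %d occurrences; not assessed for bias",
                motif, len(mruns), min_occurrences,
            )
            direction = "none"
        else:
            margin = bias_sd * min(gsd, sd_cov)
            if mean_cov < gmean - margin:
                direction = "low"
            elif mean_cov > gmean + margin:
                direction = "high"
            else:
                direction = "none"
        model.motif_bias[motif] = MotifBias(
            motif=motif, n_runs=len(mruns), n_bases=nb, mean_coverage=mean_cov,
            sd_coverage=sd_cov, direction=direction,
        )
    return model


def _repeat_claims(
    model: RepeatBiasModel,
    chrom_lengths: dict[str, int],
    reach: int,
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Per-chromosome (distance, run-motif-id, claimed) arrays for biased runs.

    Distance is measured to the nearest boundary base of the closest biased
    run (0 inside the run); only bases with distance < ``reach`` are claimed.
    Ties between runs go to the earlier (lower-start) run.
    """
    biased = model.biased_runs()
    motifs = sorted({r.motif for r in biased})
    motif_id = {m: i for i, m in enumerate(motifs)}
    dist: dict[str, np.ndarray] = {}
    rid: dict[str, np.ndarray] = {}
    for chrom, n in chrom_lengths.items():
        dist[chrom] = np.full(n, np.iinfo(np.int32).max, dtype=np.int32)
        rid[chrom] = np.full(n, -1, dtype=np.int32)
    for run in sorted(biased, key=lambda r: (r.chrom, r.start)):
        n = chrom_lengths[run.chrom]
        lo = max(0, run.start - reach + 1)
        hi = min(n, run.end + reach - 1)
        idx = np.arange(lo, hi)
        d = np.maximum(0, np.maximum(run.start - idx, idx - run.end + 1)).astype(np.int32)
        better = d < dist[run.chrom][lo:hi]
        dist[run.chrom][lo:hi][better] = d[better]
        rid[run.chrom][lo:hi][better] = motif_id[run.motif]
    claimed = {c: rid[c] >= 0 for c in chrom_lengths}
    return dist, rid, claimed


def normalize_repeat_regions(
    model: RepeatBiasModel,
    weights: dict[str, GCWeightTrack],
    depth: dict[str, DepthTrack],
    library: LibraryModel,
    config: Config | None = None,
    mask: dict[str, np.ndarray] | None = None,
) -> BinAssignment:
    """Build the full bin partition: repeat distance bins near biased runs,
    GC bins everywhere else.

    Each base within half an insert of a biased run joins a (motif,
    floor(distance/10)) population; distance bins under ``min_bin_size``
    members merge with the adjacent farther bin; motifs whose merged
    population is still too small fall back to GC normalization.
    """
    config = config or Config()
    chrom_lengths = {c: w.h.size for c, w in weights.items()}
    biased = model.biased_runs()
    if not biased:
        return assign_gc_bins(weights, depth, library, config, mask=mask)
    reach = library.mean_insert // 2
    dist, rid, claimed = _repeat_claims(model, chrom_lengths, reach)
    motifs = sorted({r.motif for r in biased})
    dbin_width = config.distance_bin

    def dbin_of(d: np.ndarray) -> np.ndarray:
        # run-internal bases (distance 0) form their own population; the
        # 10-base increments start at the first base outside the run
        return np.where(d == 0, 0, 1 + (d - 1) // dbin_width)

    n_dbins = 2 + max(reach - 2, 0) // dbin_width
    # eligibility: claimed, non-N (finite h), unmasked
    for chrom in chrom_lengths:
        ok = claimed[chrom] & np.isfinite(weights[chrom].h)
        if mask is not None and chrom in mask:
            ok &= ~mask[chrom]
        claimed[chrom] = ok
    # counts per (motif, distance bin)
    counts = np.zeros((len(motifs), n_dbins), dtype=np.int64)
    for chrom in chrom_lengths:
        sel = claimed[chrom]
        if not sel.any():
            continue
        code = rid[chrom][sel].astype(np.int64) * n_dbins + dbin_of(dist[chrom][sel])
        counts += np.bincount(code, minlength=len(motifs) * n_dbins).reshape(
            len(motifs), n_dbins
        )
    # merge underfull distance bins with the adjacent farther bin
    dbin_map = np.full((len(motifs), n_dbins), -1, dtype=np.int32)
    fallback = np.zeros(len(motifs), dtype=bool)
    bins: list[Bin] = []
    for mi, motif in enumerate(motifs):
        groups: list[list[int]] = []
        pending: list[int] = []
        pend_n = 0
        for db in range(n_dbins):
            if counts[mi, db] == 0 and not pending:
                continue
            pending.append(db)
            pend_n += counts[mi, db]
            if pend_n >= config.min_bin_size:
                groups.append(pending)
                pending, pend_n = [], 0
        if pending:
            if groups:
                groups[-1].extend(pending)  # farthest leftover merges inward
            elif pend_n > 0:
                groups.append(pending)
        total = counts[mi].sum()
        if not groups or total < config.min_bin_size:
            fallback[mi] = True
            log.info(
                "motif %s repeat population %d < %d after merging; "
                "falling back to GC normalization", motif, int(total), config.min_bin_size,
            )
            continue
        for g in groups:
            row = len(bins)
            bins.append(Bin(key=("rep", motif, g[0])))
            for db in g:
                dbin_map[mi, db] = row
    # fallback motifs release their bases to GC binning
    if fallback.any():
        for chrom in chrom_lengths:
            fb = fallback[rid[chrom].clip(min=0)] & claimed[chrom]
            claimed[chrom][fb] = False
    gc_assign = assign_gc_bins(
        weights, depth, library, config, mask=mask, claimed=claimed
    )
    offset = len(gc_assign.bins)
    combined_bins = gc_assign.bins + bins
    bin_index: dict[str, np.ndarray] = {}
    for chrom in chrom_lengths:
        idx = gc_assign.bin_index[chrom].copy()
        sel = claimed[chrom]
        if sel.any():
            rows = dbin_map[rid[chrom][sel], dbin_of(dist[chrom][sel])]
            idx[sel] = np.where(rows >= 0, rows + offset, -1)
        bin_index[chrom] = idx
    out = BinAssignment(chroms=gc_assign.chroms, bin_index=bin_index, bins=combined_bins)
    out.fill_counts()
    return out


def write_runs_bed(path: str, runs: list[RepeatRun]) -> None:
    with open(path, "w") as fh:
        for r in sorted(runs, key=lambda r: (r.chrom, r.start)):
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.motif}\n")


def write_bias_report(path: str, model: RepeatBiasModel) -> None:
    with open(path, "w") as fh:
        fh.write("motif\toccurrences\tbases\tmean_coverage\tdirection\n")
        for motif in sorted(model.motif_bias):
            b = model.motif_bias[motif]
            fh.write(
                f"{b.motif}\t{b.n_runs}\t{b.n_bases}\t{b.mean_coverage:.4f}\t{b.direction}\n"
            )
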