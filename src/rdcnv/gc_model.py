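"""GC weighting, GC-bin assignment and rank-based quantile normalization.

The central idea: per-base coverage depends on the GC content of the whole
sequenced fragment, and both the *mean* and the *variance* of read depth vary
with GC after the usual mean-only bin correction.  So instead of rescaling
depth, each base is ranked within a bin of bases sharing the same GC context
(and mapping-quality stratum), the rank proportion

    p = R/n            if 2R <= n
    p = (n - R)/n      if 2R >  n        (numerator floored at 0.5)

is converted to standard-deviation units x = +/- Phi^{-1}(p), giving every bin
an (approximately) standard-normal depth signal regardless of its raw mean or
variance.

The GC context of base i is the insert-placement weighted GC fraction

    h_i = sum_j w_j a_j / sum_j w_j

where w_j counts distinct placements of an average-sized insert covering both
i and j (placements are clipped to the chromosome), and a_j is 1 for G/C.

The classical mean normalization r_norm = r * m / m_GC is provided only as a
diagnostic to expose the residual variance-vs-GC effect; it plays no role in
calling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ndtri

from .alignment_io import DepthTrack, LibraryModel
from .config import Config

LOW, HIGH = 0, 1  # mapping-quality strata


@dataclass
class GCWeightTrack:
    """Per-base insert-weighted GC fraction h for one chromosome."""

    chrom: str
    h: np.ndarray  # float64 in [0,1], NaN where the context is all-N or the base is N


@dataclass
class Bin:
    """One normalization population (a GC bin or a repeat distance bin)."""

    key: tuple          # ("gc", stratum, level) or ("rep", motif, distance_bin)
    n: int = 0
    r_ave: float = float("nan")  # mean raw depth of members


@dataclass
class BinAssignment:
    """Partition of all binnable bases into normalization populations.

    ``bin_index[chrom][pos]`` is the row into ``bins`` (or -1 for N/masked
    bases).  Every non-N, unmasked base belongs to exactly one bin.
    """

    chroms: list[str]
    bin_index: dict[str, np.ndarray]
    bins: list[Bin] = field(default_factory=list)

    def total_binned(self) -> int:
        return int(sum((idx >= 0).sum() for idx in self.bin_index.values()))

    def fill_counts(self) -> None:
        counts = np.zeros(len(self.bins), dtype=np.int64)
        for idx in self.bin_index.values():
            sel = idx[idx >= 0]
            counts += np.bincount(sel, minlength=len(self.bins))
        for b, c in zip(self.bins, counts):
            b.n = int(c)


def _base_arrays(seq: str) -> tuple[np.ndarray, np.ndarray]:
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    is_gc = (arr == ord("G")) | (arr == ord("C"))
    is_valid = is_gc | (arr == ord("A")) | (arr == ord("T"))
    return is_gc, is_valid


def compute_gc_weights(seq: str, library: LibraryModel, chrom: str = "") -> GCWeightTrack:
    """Insert-placement weighted GC fraction h for every base of ``seq``.

    Equivalent to enumerating every placement of a ``mean_insert``-length
    window that fits the chromosome and covers base i, summing the placement's
    GC and non-N counts; computed in O(N) with cumulative sums.
    """
    L = int(library.mean_insert)
    if L < 1:
        raise ValueError("mean_insert must be >= 1")
    is_gc, is_valid = _base_arrays(seq)
    n = is_gc.size
    eff_l = min(L, n)  # chromosomes shorter than the insert use one full-length window
    cg = np.concatenate(([0.0], np.cumsum(is_gc & is_valid)))
    cv = np.concatenate(([0.0], np.cumsum(is_valid)))
    # per-placement window sums, placements s in [0, n - eff_l]
    wgc = cg[eff_l:] - cg[:-eff_l] if eff_l < n + 1 else cg[-1:]
    wva = cv[eff_l:] - cv[:-eff_l]
    cwgc = np.concatenate(([0.0], np.cumsum(wgc)))
    cwva = np.concatenate(([0.0], np.cumsum(wva)))
    idx = np.arange(n)
    lo = np.maximum(0, idx - eff_l + 1)
    hi = np.minimum(idx, n - eff_l)
    num = cwgc[hi + 1] - cwgc[lo]
    den = cwva[hi + 1] - cwva[lo]
    with np.errstate(invalid="ignore", divide="ignore"):
        h = np.where(den > 0, num / np.maximum(den, 1.0), np.nan)
    h[~is_valid] = np.nan
    return GCWeightTrack(chrom=chrom, h=h)


def _merge_small_levels(counts: dict[int, int], min_size: int) -> dict[int, int]:
    """Map each populated gc level to a representative so merged counts >= min_size.

    Smallest underfull level is merged into its nearest surviving neighbor
    (ties to the lower level) until all survivors reach ``min_size`` or one
    remains.
    """
    level_to = {lv: lv for lv in counts}
    sizes = dict(counts)
    while len(sizes) > 1:
        under = [(c, lv) for lv, c in sizes.items() if c < min_size]
        if not under:
            break
        _, lv = min(under)
        others = [o for o in sizes if o != lv]
        target = min(others, key=lambda o: (abs(o - lv), o))
        sizes[target] += sizes.pop(lv)
        for k, v in level_to.items():
            if v == lv:
                level_to[k] = target
    return level_to


def assign_gc_bins(
    weights: dict[str, GCWeightTrack],
    depth: dict[str, DepthTrack],
    library: LibraryModel,
    config: Config | None = None,
    mask: dict[str, np.ndarray] | None = None,
    claimed: dict[str, np.ndarray] | None = None,
) -> BinAssignment:
    """Partition non-N, unmasked, unclaimed bases into (gc level, MQ stratum) bins.

    h is discretized at ``gc_bin_width``; each base joins the bin matching its
    discretized h and the mean-MAPQ stratum of its containing window; bins
    under ``min_bin_size`` bases are merged into the nearest gc level of the
    same stratum.  ``claimed`` marks bases already owned by the repeat model.
    """
    config = config or Config()
    nlevels = int(round(1.0 / config.gc_bin_width)) + 1
    chroms = list(weights)
    level_of: dict[str, np.ndarray] = {}
    stratum_of: dict[str, np.ndarray] = {}
    eligible: dict[str, np.ndarray] = {}
    counts = np.zeros((2, nlevels), dtype=np.int64)
    for chrom in chroms:
        h = weights[chrom].h
        track = depth[chrom]
        ok = np.isfinite(h)
        if mask is not None and chrom in mask:
            ok &= ~mask[chrom]
        if claimed is not None and chrom in claimed:
            ok &= ~claimed[chrom]
        lev = np.zeros(h.size, dtype=np.int32)
        lev[ok] = np.minimum((h[ok] / config.gc_bin_width).astype(np.int32), nlevels - 1)
        widx = np.minimum(np.arange(h.size) // track.window_size, track.window_mq.size - 1)
        # zero-read windows carry no mapping-quality evidence; keep them high
        low = (track.window_mq[widx] < config.mq_threshold) & (track.window_reads[widx] > 0)
        strat = (~low).astype(np.int8)
        level_of[chrom] = lev
        stratum_of[chrom] = strat
        eligible[chrom] = ok
        for s in (LOW, HIGH):
            sel = ok & (strat == s)
            counts[s] += np.bincount(lev[sel], minlength=nlevels)
    bins: list[Bin] = []
    bin_row: dict[tuple, int] = {}
    remap: dict[int, dict[int, int]] = {}
    for s in (LOW, HIGH):
        populated = {lv: int(c) for lv, c in enumerate(counts[s]) if c > 0}
        if not populated:
            warnings.warn(f"no bases in MQ stratum {s}; stratum dropped")
            remap[s] = {}
            continue
        remap[s] = _merge_small_levels(populated, config.min_bin_size)
        for rep in sorted(set(remap[s].values())):
            key = ("gc", s, rep)
            bin_row[key] = len(bins)
            bins.append(Bin(key=key))
    bin_index: dict[str, np.ndarray] = {}
    for chrom in chroms:
        idx = np.full(level_of[chrom].size, -1, dtype=np.int32)
        for s in (LOW, HIGH):
            table = remap[s]
            if not table:
                continue
            lut = np.full(nlevels, -1, dtype=np.int32)
            for lv, rep in table.items():
                lut[lv] = bin_row[("gc", s, rep)]
            sel = eligible[chrom] & (stratum_of[chrom] == s)
            idx[sel] = lut[level_of[chrom][sel]]
        bin_index[chrom] = idx
    out = BinAssignment(chroms=chroms, bin_index=bin_index, bins=bins)
    out.fill_counts()
    return out


def interpolated_rank(sorted_depths: np.ndarray, value: float) -> float:
    """Rank the given depth value would take in a sorted bin (fractional).

    Ties take the mean rank of the tied block; values between observed depths
    interpolate linearly between neighbors; values outside clamp to the ends.
    """
    n = sorted_depths.size
    left = int(np.searchsorted(sorted_depths, value, side="left"))
    right = int(np.searchsorted(sorted_depths, value, side="right"))
    if right > left:
        return (left + right - 1) / 2.0
    if left == 0:
        return 0.0
    if left == n:
        return float(n - 1)
    lo, hi = sorted_depths[left - 1], sorted_depths[left]
    return (left - 1) + (value - lo) / (hi - lo)


def cap_high_coverage_ranks(
    depths: np.ndarray,
    ranks: np.ndarray,
    chrom_mean: float | np.ndarray,
    multiple: float = 2.0,
) -> np.ndarray:
    """Shrink the ranks of bases whose depth exceeds ``multiple`` x chromosome mean.

    The adjusted rank is the average of the observed rank and the rank that a
    depth of exactly ``multiple * chrom_mean`` would take in the bin.
    ``chrom_mean`` may be per-member (bins span chromosomes).  Depth exactly at
    the threshold is left unchanged.
    """
    depths = np.asarray(depths, dtype=np.float64)
    out = np.asarray(ranks, dtype=np.float64).copy()
    thr = np.broadcast_to(np.asarray(chrom_mean, dtype=np.float64) * multiple, depths.shape)
    exceed = depths > thr
    if not exceed.any():
        return out
    sorted_d = np.sort(depths)
    for t in np.unique(thr[exceed]):
        r2x = interpolated_rank(sorted_d, t)
        sel = exceed & (thr == t)
        out[sel] = (out[sel] + r2x) / 2.0
    return out


def rank_to_sd_units(R: np.ndarray | float, n: int) -> np.ndarray | float:
    """Convert a (possibly fractional) depth rank into standard-deviation units.

    Below-median ranks map to negative x, above-median to positive; the rank
    proportion numerator is floored at 0.5 so extreme ranks stay finite.
    R = n/2 maps exactly to 0.
    """
    Rarr = np.asarray(R, dtype=np.float64)
    if n < 1:
        raise ValueError("n must be >= 1")
    if np.any(Rarr < 0) or np.any(Rarr > n - 1):
        raise ValueError("rank outside [0, n-1]")
    below = 2.0 * Rarr <= n
    x = np.where(
        below,
        ndtri(np.maximum(Rarr, 0.5) / n),
        -ndtri(np.maximum(n - Rarr, 0.5) / n),
    )
    if np.isscalar(R):
        return float(x)
    return x


@dataclass
class NormalizedTrack:
    """Per-base depth in standard-deviation units; NaN on N/masked bases."""

    chrom: str
    x: np.ndarray


def quantile_normalize(
    assignment: BinAssignment,
    depth: dict[str, DepthTrack],
    library: LibraryModel,
    config: Config | None = None,
) -> dict[str, NormalizedTrack]:
    """Rank every bin, cap high-coverage ranks, and map ranks to SD units.

    Tied depths share their block's mean rank (midranks).  Breaking ties by
    genome position instead would hand the low end of every tie block to
    early coordinates, imprinting a chromosome-scale gradient on x that
    inflates the variance of large windows; midranks are deterministic and
    spatially unbiased.  Also fills each bin's ``n`` and ``r_ave`` (mean raw
    depth), which the breakpoint screen consumes.
    """
    config = config or Config()
    chroms = assignment.chroms
    ci_all, pos_all, bidx_all, dep_all = [], [], [], []
    for ci, chrom in enumerate(chroms):
        idx = assignment.bin_index[chrom]
        sel = np.nonzero(idx >= 0)[0]
        ci_all.append(np.full(sel.size, ci, dtype=np.int16))
        pos_all.append(sel.astype(np.int64))
        bidx_all.append(idx[sel])
        dep_all.append(depth[chrom].depth[sel].astype(np.float64))
    ci_arr = np.concatenate(ci_all) if ci_all else np.empty(0, dtype=np.int16)
    pos_arr = np.concatenate(pos_all) if pos_all else np.empty(0, dtype=np.int64)
    bidx_arr = np.concatenate(bidx_all) if bidx_all else np.empty(0, dtype=np.int32)
    dep_arr = np.concatenate(dep_all) if dep_all else np.empty(0)
    x_out = {c: np.full(assignment.bin_index[c].size, np.nan) for c in chroms}
    chrom_means = np.array(
        [library.chrom_mean_depth.get(c, library.genome_mean_depth) for c in chroms]
    )
    order_all = np.argsort(bidx_arr, kind="stable")
    bounds = np.searchsorted(bidx_arr[order_all], np.arange(len(assignment.bins) + 1))
    for b in range(len(assignment.bins)):
        members = order_all[bounds[b] : bounds[b + 1]]
        nb = members.size
        assignment.bins[b].n = int(nb)
        if nb == 0:
            continue
        d = dep_arr[members]
        assignment.bins[b].r_ave = float(d.mean())
        _, inv, cnt = np.unique(d, return_inverse=True, return_counts=True)
        block_start = np.cumsum(cnt) - cnt
        ranks = block_start[inv] + (cnt[inv] - 1) / 2.0
        capped = cap_high_coverage_ranks(
            d, ranks, chrom_means[ci_arr[members]], config.cap_multiple
        )
        x = rank_to_sd_units(capped, nb)
        for ci, chrom in enumerate(chroms):
            sel = ci_arr[members] == ci
            if sel.any():
                x_out[chrom][pos_arr[members][sel]] = x[sel]
    return {c: NormalizedTrack(chrom=c, x=x_out[c]) for c in chroms}


def r_ave_track(assignment: BinAssignment) -> dict[str, np.ndarray]:
    """Per-base expected (bin-average) raw depth; NaN where unbinned."""
    r = np.array([b.r_ave for b in assignment.bins] + [np.nan])
    out: dict[str, np.ndarray] = {}
    for chrom in assignment.chroms:
        idx = assignment.bin_index[chrom]
        out[chrom] = r[np.where(idx >= 0, idx, len(assignment.bins))]
    return out


def gc_mean_normalize_diagnostic(
    window_counts: np.ndarray,
    window_gc: np.ndarray,
    bin_width: float = 0.01,
) -> pd.DataFrame:
    """Per-GC-bin SD of classical mean-normalized window read counts.

    Windows are binned by GC fraction; counts are rescaled by m/m_GC so every
    bin's mean equals the global mean; the returned table exposes how the SD
    still varies with GC.  Diagnostic only -- not part of the calling path.
    """
    counts = np.asarray(window_counts, dtype=np.float64)
    gc = np.asarray(window_gc, dtype=np.float64)
    ok = np.isfinite(gc) & np.isfinite(counts)
    counts, gc = counts[ok], gc[ok]
    if counts.size == 0:
        return pd.DataFrame(columns=["gc_level", "n", "mean", "sd"])
    m = counts.mean()
    nlevels = int(round(1.0 / bin_width)) + 1
    level = np.minimum((gc / bin_width).astype(int), nlevels - 1)
    rows = []
    for lv in np.unique(level):
        sel = level == lv
        m_gc = counts[sel].mean()
        if m_gc == 0:
            continue
        r_norm = counts[sel] * m / m_gc
        rows.append(
            {
                "gc_level": lv * bin_width,
                "n": int(sel.sum()),
                "mean": float(r_norm.mean()),
                "sd": float(r_norm.std()),
            }
        )
    return pd.DataFrame(rows)


def window_gc_content(seq: str, window_size: int = 100) -> np.ndarray:
    """GC fraction per non-overlapping window; NaN for windows containing N."""
    is_gc, is_valid = _base_arrays(seq)
    n_full = is_gc.size // window_size
    gcs = is_gc[: n_full * window_size].reshape(n_full, window_size).sum(axis=1)
    val = is_valid[: n_full * window_size].reshape(n_full, window_size).sum(axis=1)
    with np.errstate(invalid="ignore"):
        out = np.where(val == window_size, gcs / window_size, np.nan)
    return out
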