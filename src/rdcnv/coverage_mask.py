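"""Excessive-coverage masking for the two-pipeline design.

Complex and repetitive regions (centromere/telomere neighborhoods in real
genomes) show clusters of blocks with abnormally high coverage.  Pipeline 1
masks such clusters before normalization and scanning, improving sensitivity
elsewhere; pipeline 2 runs unmasked so CNVs inside the clusters remain
detectable.  A cluster is a stretch of 10 kb blocks, starting and ending on a
high block, with at least four high blocks and more than 25% of its blocks
high (block is "high" when its mean depth strictly exceeds 2x the chromosome
average).

Clustering is single-linkage over high blocks with the maximum low-gap
implied by the density bound (the largest gap g with 2/(g+2) > min_density),
followed by the density and minimum-count filters.  This rule is
deterministic and symmetric under reversal of the block sequence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .alignment_io import DepthTrack


@dataclass
class MaskCluster:
    chrom: str
    start: int      # block-aligned base coordinates, half-open
    end: int
    n_blocks: int
    n_high: int

    @property
    def density(self) -> float:
        return self.n_high / self.n_blocks


def compute_block_flags(
    depth: DepthTrack,
    chrom_mean: float,
    n_mask: np.ndarray | None = None,
    block_size: int = 10_000,
    multiple: float = 2.0,
) -> np.ndarray:
    """Flag blocks whose mean depth strictly exceeds ``multiple`` x chromosome mean.

    The trailing partial block is evaluated on its actual (non-N) length;
    block means exclude reference N bases when a mask is supplied.
    """
    if chrom_mean <= 0:
        raise ValueError("chrom_mean must be > 0")
    d = depth.depth.astype(np.float64)
    n = d.size
    n_blocks = (n + block_size - 1) // block_size
    flags = np.zeros(n_blocks, dtype=bool)
    valid = np.ones(n, dtype=bool) if n_mask is None else ~n_mask
    for b in range(n_blocks):
        s, e = b * block_size, min((b + 1) * block_size, n)
        sel = valid[s:e]
        if not sel.any():
            continue
        flags[b] = d[s:e][sel].mean() > multiple * chrom_mean
    return flags


def max_linkage_gap(min_density: float) -> int:
    """Largest low-block gap g for which a two-high-block cluster keeps density above the bound."""
    return int(math.floor(2.0 / min_density - 2.0 - 1e-9))


def find_excess_clusters(
    flags: np.ndarray,
    chrom: str = "",
    block_size: int = 10_000,
    chrom_length: int | None = None,
    min_high: int = 4,
    min_density: float = 0.25,
) -> list[MaskCluster]:
    """Merge nearby high blocks into clusters and keep those passing both rules.

    Clusters are trimmed to start and end on high blocks.
    """
    high = np.nonzero(np.asarray(flags, dtype=bool))[0]
    if high.size == 0:
        return []
    gap_max = max_linkage_gap(min_density)
    breaks = np.nonzero(np.diff(high) - 1 > gap_max)[0] + 1
    clusters: list[MaskCluster] = []
    for group in np.split(high, breaks):
        n_high = group.size
        n_blocks = int(group[-1] - group[0] + 1)
        if n_high < min_high or n_high / n_blocks <= min_density:
            continue
        start = int(group[0]) * block_size
        end = (int(group[-1]) + 1) * block_size
        if chrom_length is not None:
            end = min(end, chrom_length)
        clusters.append(
            MaskCluster(chrom=chrom, start=start, end=end, n_blocks=n_blocks, n_high=n_high)
        )
    return clusters


def apply_mask(
    clusters: list[MaskCluster], chrom_lengths: dict[str, int]
) -> dict[str, np.ndarray]:
    """Boolean per-base mask arrays (True = excluded) from cluster intervals."""
    masks = {c: np.zeros(n, dtype=bool) for c, n in chrom_lengths.items()}
    for cl in clusters:
        masks[cl.chrom][cl.start : cl.end] = True
    return masks


def write_clusters_bed(path: str, clusters: list[MaskCluster]) -> None:
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tn_blocks\tn_high\n")
        for cl in sorted(clusters, key=lambda c: (c.chrom, c.start)):
            fh.write(f"{cl.chrom}\t{cl.start}\t{cl.end}\t{cl.n_blocks}\t{cl.n_high}\n")
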