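"""Tunable parameters for the full calling pipeline.

Defaults follow the published read-depth method: 100-base minimum /
10,000-base maximum sliding windows, alpha = 1e-6, 10 kb masking blocks at
>2x chromosome average, >25% density / >=4 high blocks per mask cluster,
>=100 bases per normalization bin, mapping-quality stratification at MAPQ < 5,
rank capping at 2x chromosome average, 20-base dinucleotide-run floor with a
1.5-SD bias test, 10-base distance bins reaching half an insert size, and
0.70x / 1.3x diploid screening ratios.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict


@dataclass
class Config:
    # depth / binning
    window_base: int = 100          # window for mean MAPQ and the mean-normalization diagnostic
    gc_bin_width: float = 0.01      # discretization of the GC weighting h
    min_bin_size: int = 100         # minimum bases per normalization bin
    mq_threshold: int = 5           # window mean MAPQ below this -> low stratum
    cap_multiple: float = 2.0       # rank-cap depth at cap_multiple * chromosome mean

    # dinucleotide repeat bias
    min_repeat_len: int = 20        # shortest run treated as a repeat
    repeat_bias_sd: float = 1.5     # |repeat mean - genome mean| > this * genome SD -> biased
    min_motif_occurrences: int = 50 # runs needed before a motif is assessed
    distance_bin: int = 10          # bases per distance bin around biased runs

    # excessive-coverage masking
    block_size: int = 10_000
    mask_multiple: float = 2.0      # block mean > mask_multiple * chromosome mean -> high
    min_cluster_high: int = 4
    min_cluster_density: float = 0.25
    masking: bool = True            # False -> single unmasked pipeline

    # CNV search
    del_ratio: float = 0.70         # diploid deletion screening threshold (x bin average)
    dup_ratio: float = 1.3          # diploid duplication screening threshold
    alpha: float = 1e-6             # one-sided tail probability to call
    min_window: int = 100
    max_window: int = 10_000
    n_window_sizes: int = 20        # geometric grid of sampled window sizes
    n_sample_windows: int = 2000    # windows sampled per size for mu/sigma
    ploidy: int = 2                 # informational; ratios above are the operative knobs

    seed: int = 17

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "Config":
        known = {f for f in cls.__dataclass_fields__}
        return cls(**{k: v for k, v in d.items() if k in known})
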