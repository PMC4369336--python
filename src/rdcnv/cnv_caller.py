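"""Size-varying sliding-window CNV search over the normalized depth signal.

Candidate breakpoints are bases whose *raw* depth deviates from their bin's
average by the diploid screening ratios (<=0.70x for deletions, >=1.3x for
duplications) and that head a minimum window in which at least half the bases
deviate the same way.  From each candidate the window grows in one-base
increments; the window mean of the normalized signal x is compared to an
empirically sampled (mu_l, sigma_l) for that window size, and a CNV fires
when the one-sided normal tail probability of the z-score drops below alpha
(default 1e-6).  Windows reaching the maximum size extend by sliding; the end
breakpoint is trimmed to the last abnormal base.  Two pipeline runs (masked /
unmasked) are merged into a union call set.

"z < alpha" is read as the tail *probability* of z falling below alpha;
comparing a z-score directly with 1e-6 would be dimensionally inconsistent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import ndtri
from scipy.stats import norm

from .config import Config
from .gc_model import NormalizedTrack

DEL, DUP = "DEL", "DUP"


@dataclass
class WindowDistribution:
    """Empirical mean/SD of window-averaged x, per sampled window size."""

    sizes: np.ndarray   # sorted window sizes actually sampled
    mu: np.ndarray
    sigma: np.ndarray
    n_sampled: int

    def interpolate(self, min_window: int, max_window: int) -> tuple[np.ndarray, np.ndarray]:
        """mu and sigma for every integer size in [min_window, max_window], log-linear in l."""
        ls = np.arange(min_window, max_window + 1)
        logl = np.log(ls)
        mu = np.interp(logl, np.log(self.sizes), self.mu)
        sigma = np.interp(logl, np.log(self.sizes), self.sigma)
        return mu, sigma


@dataclass
class CNVCall:
    chrom: str
    start: int          # 0-based half-open
    end: int
    type: str           # DEL or DUP
    z: float            # most extreme window z over the sweep
    log10p: float       # log10 one-sided tail probability of z
    fold: float         # mean raw depth over the call / chromosome mean
    pipeline: str       # "masked", "unmasked", or "both"

    @property
    def score(self) -> int:
        if not np.isfinite(self.log10p):
            return 1000
        return min(1000, int(round(-10.0 * self.log10p)))


def window_size_grid(min_window: int, max_window: int, n_sizes: int) -> np.ndarray:
    """Geometric grid of window sizes including both endpoints."""
    grid = np.unique(
        np.round(np.geomspace(min_window, max_window, n_sizes)).astype(int)
    )
    return grid


def sample_window_distributions(
    x_tracks: dict[str, NormalizedTrack],
    sizes: np.ndarray,
    n_sample: int,
    seed: int,
) -> WindowDistribution:
    """Sample uniformly placed windows free of N/masked bases for each size.

    Returns the empirical location and scale of window-averaged x per size;
    deterministic given the seed.  Location is the median and scale the
    normal-consistent MAD (1.4826 * median absolute deviation): on genomes
    small enough that CNV-overlapping windows are a non-negligible fraction
    of the sample, a plain SD would be inflated by the very signal being
    tested, while the robust pair estimates the null scale.  If fewer
    eligible windows than requested exist, all of them are used (with a
    warning).
    """
    rng = np.random.default_rng(seed)
    chroms = sorted(x_tracks)
    cums, valids = {}, {}
    for c in chroms:
        x = x_tracks[c].x
        valid = np.isfinite(x)
        cums[c] = np.concatenate(([0.0], np.cumsum(np.where(valid, x, 0.0))))
        valids[c] = np.concatenate(([0], np.cumsum(valid)))
    mus, sigmas, kept_sizes = [], [], []
    n_used = n_sample
    for l in sizes:
        starts_all, chrom_of = [], []
        for ci, c in enumerate(chroms):
            v = valids[c]
            if v.size - 1 < l:
                continue
            ok = (v[l:] - v[:-l]) == l
            s = np.nonzero(ok)[0]
            starts_all.append(s)
            chrom_of.append(np.full(s.size, ci, dtype=np.int16))
        if not starts_all:
            continue
        starts = np.concatenate(starts_all)
        chrom_of = np.concatenate(chrom_of)
        if starts.size == 0:
            continue
        if starts.size <= n_sample:
            if starts.size < n_sample:
                warnings.warn(
                    f"only {starts.size} eligible windows of size {l}; using all"
                )
            pick = np.arange(starts.size)
            n_used = min(n_used, starts.size)
        else:
            pick = rng.integers(0, starts.size, size=n_sample)
        means = np.empty(pick.size)
        for ci, c in enumerate(chroms):
            sel = chrom_of[pick] == ci
            if sel.any():
                s = starts[pick][sel]
                means[sel] = (cums[c][s + l] - cums[c][s]) / l
        med = float(np.median(means))
        mus.append(med)
        sigmas.append(1.4826 * float(np.median(np.abs(means - med))))
        kept_sizes.append(int(l))
    if not kept_sizes:
        raise ValueError("no eligible windows at any size")
    return WindowDistribution(
        sizes=np.array(kept_sizes), mu=np.array(mus), sigma=np.array(sigmas),
        n_sampled=n_used,
    )


def screen_breakpoints(
    depth: np.ndarray,
    r_ave: np.ndarray,
    eligible: np.ndarray,
    config: Config,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-base abnormality flags and candidate breakpoints for each direction.

    Returns (abnormal_del, abnormal_dup, cand_del, cand_dup).  A base is a
    candidate when it is abnormal and at least half of the following
    ``min_window`` bases are abnormal in the same direction.
    """
    w = config.min_window
    with np.errstate(invalid="ignore"):
        ab_del = eligible & np.isfinite(r_ave) & (depth <= config.del_ratio * r_ave)
        ab_dup = eligible & np.isfinite(r_ave) & (depth >= config.dup_ratio * r_ave)
    n = depth.size
    cands = []
    for ab in (ab_del, ab_dup):
        cs = np.concatenate(([0], np.cumsum(ab)))
        cand = np.zeros(n, dtype=bool)
        if n >= w:
            cnt = cs[w:] - cs[:-w]
            cand[: n - w + 1] = ab[: n - w + 1] & (2 * cnt >= w)
        cands.append(cand)
    return ab_del, ab_dup, cands[0], cands[1]


@dataclass
class _ChromScanState:
    x_cum: np.ndarray       # cumsum of x (NaN -> 0), length n+1
    v_cum: np.ndarray       # cumsum of finite-x indicator
    ab_cum: dict[str, np.ndarray]   # per direction cumsum of abnormal flags
    ab: dict[str, np.ndarray]
    mu_all: np.ndarray      # interpolated mu for l in [min_window, max_window]
    sig_all: np.ndarray


def _window_stats(state: _ChromScanState, j: int, ls: np.ndarray, direction: str):
    means_num = state.x_cum[j + ls] - state.x_cum[j]
    nvalid = state.v_cum[j + ls] - state.v_cum[j]
    means = means_num / np.maximum(nvalid, 1)
    abcnt = state.ab_cum[direction][j + ls] - state.ab_cum[direction][j]
    return means, abcnt


def _test_and_grow(
    j: int,
    direction: str,
    state: _ChromScanState,
    n: int,
    config: Config,
    z_crit: float,
) -> tuple[int, int, float] | None:
    """Grow a window from candidate j; return (start, end, extreme_z) or None.

    The sweep over window sizes is evaluated in doubling chunks so candidates
    whose abnormal fraction collapses early (the overwhelming majority on a
    null background) cost only a handful of array operations.
    """
    wmin, wmax = config.min_window, config.max_window
    lmax = min(wmax, n - j)
    if lmax < wmin:
        return None
    z_ext = None        # most extreme z over the sweep
    l_best = None       # size of the most extreme *passing* window
    z_best = None
    l_ok = None         # largest size with abnormal fraction >= 1/2
    frac_failed = False
    l0, chunk = wmin, wmin
    while l0 <= lmax and not frac_failed:
        ls = np.arange(l0, min(l0 + chunk, lmax + 1))
        means, abcnt = _window_stats(state, j, ls, direction)
        ok = 2 * abcnt >= ls
        bad = np.nonzero(~ok)[0]
        if bad.size:
            frac_failed = True
            if bad[0] == 0:
                break
            ls, means = ls[: bad[0]], means[: bad[0]]
        z = (means - state.mu_all[ls - wmin]) / np.maximum(
            state.sig_all[ls - wmin], 1e-12
        )
        l_ok = int(ls[-1])
        zc = float(z.min()) if direction == DEL else float(z.max())
        if z_ext is None or (zc < z_ext if direction == DEL else zc > z_ext):
            z_ext = zc
        passing = z < z_crit if direction == DEL else z > -z_crit
        if passing.any():
            zp = z[passing]
            i = int(np.argmin(zp) if direction == DEL else np.argmax(zp))
            zpi = float(zp[i])
            if z_best is None or (zpi < z_best if direction == DEL else zpi > z_best):
                z_best, l_best = zpi, int(ls[passing][i])
        l0 += chunk
        chunk *= 2
    if l_best is None:
        return None
    end = j + l_best
    refine_hi = j + (l_ok if l_ok is not None else l_best)
    if l_best == wmax == lmax and not frac_failed:
        end, z_ext = _extend(j, direction, state, n, config, z_crit, z_ext)
        refine_hi = end
    start, end = _refine_breakpoints(
        j, max(end, refine_hi), state.ab[direction], config.min_window
    )
    if start is None:
        return None
    return start, end, z_ext


def _refine_breakpoints(
    j: int, end: int, ab: np.ndarray, min_window: int
) -> tuple[int | None, int]:
    """Sharpen both breakpoints to the boundaries of the sustained abnormal run.

    The end is the argmax of the cumulative abnormal excess (+1/2 for an
    abnormal base, -1/2 otherwise) scanning right from the call start -- the
    last abnormal base of the maximal-excess prefix; the start is refined
    symmetrically scanning left from the end.  The call never shrinks below
    the minimum window.
    """
    seg = ab[j:end].astype(np.float64) - 0.5
    if seg.size == 0 or not (seg > 0).any():
        return None, end
    cum = np.cumsum(seg)
    new_end = j + int(np.argmax(cum)) + 1
    new_end = max(new_end, j + min_window)
    rev = np.cumsum(seg[: new_end - j][::-1])
    new_start = new_end - (int(np.argmax(rev)) + 1)
    new_start = min(new_start, new_end - min_window)
    new_start = max(new_start, j)
    return new_start, new_end


def _extend(
    j: int,
    direction: str,
    state: _ChromScanState,
    n: int,
    config: Config,
    z_crit: float,
    z_ext: float,
) -> tuple[int, float]:
    """Slide a max-size window past j while it keeps passing; chunked scan."""
    wmax = config.max_window
    s = j + 1
    last_pass_start = j
    chunk = 100_000
    while s <= n - wmax:
        hi = min(s + chunk, n - wmax + 1)
        starts = np.arange(s, hi)
        means = (state.x_cum[starts + wmax] - state.x_cum[starts]) / np.maximum(
            state.v_cum[starts + wmax] - state.v_cum[starts], 1
        )
        abcnt = state.ab_cum[direction][starts + wmax] - state.ab_cum[direction][starts]
        mu = state.mu_all[wmax - config.min_window]
        sig = max(state.sig_all[wmax - config.min_window], 1e-12)
        z = (means - mu) / sig
        ok = (2 * abcnt >= wmax) & ((z < z_crit) if direction == DEL else (z > -z_crit))
        bad = np.nonzero(~ok)[0]
        limit = bad[0] if bad.size else ok.size
        if limit > 0:
            zc = z[:limit]
            z_ext = min(z_ext, float(zc.min())) if direction == DEL else max(
                z_ext, float(zc.max())
            )
            last_pass_start = int(starts[limit - 1])
        if bad.size:
            break
        s = hi
    return last_pass_start + wmax, z_ext


def scan_chromosome(
    chrom: str,
    x: np.ndarray,
    depth: np.ndarray,
    r_ave: np.ndarray,
    eligible: np.ndarray,
    dists: WindowDistribution,
    chrom_mean: float,
    config: Config,
    pipeline: str,
) -> list[CNVCall]:
    """Run the full breakpoint screen + grow/extend search over one chromosome."""
    n = x.size
    if n < config.min_window:
        return []
    ab_del, ab_dup, cand_del, cand_dup = screen_breakpoints(depth, r_ave, eligible, config)
    valid = np.isfinite(x)
    state = _ChromScanState(
        x_cum=np.concatenate(([0.0], np.cumsum(np.where(valid, x, 0.0)))),
        v_cum=np.concatenate(([0], np.cumsum(valid))),
        ab_cum={
            DEL: np.concatenate(([0], np.cumsum(ab_del))),
            DUP: np.concatenate(([0], np.cumsum(ab_dup))),
        },
        ab={DEL: ab_del, DUP: ab_dup},
        mu_all=None,
        sig_all=None,
    )
    state.mu_all, state.sig_all = dists.interpolate(config.min_window, config.max_window)
    z_crit = float(ndtri(config.alpha))
    pos_del = np.nonzero(cand_del)[0]
    pos_dup = np.nonzero(cand_dup)[0]
    merged = np.concatenate(
        [np.stack([pos_del, np.zeros_like(pos_del)], axis=1),
         np.stack([pos_dup, np.ones_like(pos_dup)], axis=1)]
    )
    merged = merged[np.lexsort((merged[:, 1], merged[:, 0]))]
    calls: list[CNVCall] = []
    resume = 0
    for j, dcode in merged:
        j = int(j)
        if j < resume:
            continue
        direction = DEL if dcode == 0 else DUP
        result = _test_and_grow(j, direction, state, n, config, z_crit)
        if result is None:
            continue
        start, end, z_ext = result
        log10p = float(norm.logcdf(z_ext) / np.log(10)) if direction == DEL else float(
            norm.logsf(z_ext) / np.log(10)
        )
        fold = float(depth[start:end].mean() / chrom_mean) if chrom_mean > 0 else float("nan")
        calls.append(
            CNVCall(
                chrom=chrom, start=start, end=end, type=direction, z=z_ext,
                log10p=log10p, fold=fold, pipeline=pipeline,
            )
        )
        resume = end
    return calls


def merge_pipeline_union(
    calls_masked: list[CNVCall], calls_unmasked: list[CNVCall]
) -> list[CNVCall]:
    """Union of the two pipelines; same-type overlapping calls merge into the
    spanning interval tagged ``both`` with the more extreme z."""
    merged: list[CNVCall] = []
    pool = sorted(
        list(calls_masked) + list(calls_unmasked),
        key=lambda c: (c.chrom, c.type, c.start, c.end),
    )
    for call in pool:
        prev = merged[-1] if merged else None
        if (
            prev is not None
            and prev.chrom == call.chrom
            and prev.type == call.type
            and call.start < prev.end
            and prev.pipeline != call.pipeline
        ):
            extreme = call if abs(call.z) > abs(prev.z) else prev
            merged[-1] = replace(
                extreme,
                start=min(prev.start, call.start),
                end=max(prev.end, call.end),
                pipeline="both",
            )
        else:
            merged.append(call)
    return sorted(merged, key=lambda c: (c.chrom, c.start, c.end, c.type))


def write_calls(path: str, calls: list[CNVCall]) -> None:
    """BED6+ output: chrom, start, end, type, score, strand, fold, pipeline, z, log10p."""
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tname\tscore\tstrand\tfold\tpipeline\tz\tlog10p\n")
        for c in sorted(calls, key=lambda c: (c.chrom, c.start, c.end, c.type)):
            fh.write(
                f"{c.chrom}\t{c.start}\t{c.end}\t{c.type}\t{c.score}\t.\t"
                f"{c.fold:.6g}\t{c.pipeline}\t{c.z:.6g}\t{c.log10p:.6g}\n"
            )


def read_calls(path: str) -> list[CNVCall]:
    calls: list[CNVCall] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            calls.append(
                CNVCall(
                    chrom=f[0], start=int(f[1]), end=int(f[2]), type=f[3],
                    z=float(f[8]), log10p=float(f[9]), fold=float(f[6]), pipeline=f[7],
                )
            )
    return calls
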