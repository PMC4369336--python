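"""Synthetic references and alignments with controllable coverage biases.

The generator emulates, at desk scale, the phenomena the caller corrects:

* a GC-content gradient along each chromosome plus a fragment-level GC bias
  curve (PCR acts on the whole insert, so the bias multiplier is a function
  of the fragment's GC fraction);
* embedded dinucleotide runs with motif-specific coverage suppression;
* excessive-coverage hotspots (exposure multipliers over intervals);
* N-gaps;
* spiked deletions (copy number 0 or 1) and multi-copy duplications, with a
  truth BED.

Fragment starts are drawn from a Poisson process whose local rate is
coverage/(2*read_length) times the product of all multipliers evaluated at
the fragment (GC over the nominal insert window, copy number and hotspot at
the fragment midpoint, minimum suppression over the span).  Paired 100-base
reads are emitted from the fragment ends as perfectly aligned records.
Everything is deterministic given the seed.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pysam

from .repeat_model import find_dinucleotide_runs

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class CNVEvent:
    chrom: str
    start: int
    length: int
    type: str          # "DEL" or "DUP"
    copy_number: int   # DEL: 0 or 1; DUP: >= 3

    @property
    def end(self) -> int:
        return self.start + self.length


@dataclass
class FixtureSpec:
    """Complete description of one synthetic dataset."""

    chrom_lengths: dict[str, int]
    gc_profile: list[tuple[float, float]] = field(
        default_factory=lambda: [(0.0, 0.30), (1.0, 0.60)]
    )
    repeat_inserts: list[tuple[str, int, int]] = field(default_factory=list)
    n_gaps: list[tuple[str, int, int]] = field(default_factory=list)
    cnv_events: list[CNVEvent] = field(default_factory=list)
    gc_bias: list[tuple[float, float]] | None = None  # (gc fraction, multiplier)
    motif_suppression: dict[str, float] = field(default_factory=dict)
    hotspots: list[tuple[str, int, int, float]] = field(default_factory=list)
    low_mq_regions: list[tuple[str, int, int, int]] = field(default_factory=list)
    coverage: float = 10.0
    read_length: int = 100
    mean_insert: int = 500
    insert_sd: float = 25.0
    seed: int = 1

    def validate(self) -> None:
        if self.coverage <= 0:
            raise ValueError("coverage must be > 0")
        for m in self.motif_suppression.values():
            if m <= 0:
                raise ValueError("multipliers must be > 0")
        events = sorted(self.cnv_events, key=lambda e: (e.chrom, e.start))
        for a, b in zip(events, events[1:]):
            if a.chrom == b.chrom and b.start < a.end:
                raise ValueError(f"overlapping events at {a.chrom}:{a.start}/{b.start}")
        for e in events:
            for chrom, s, t in self.n_gaps:
                if chrom == e.chrom and e.start < t and s < e.end:
                    raise ValueError(f"event at {e.chrom}:{e.start} overlaps N-gap")


DEFAULT_GC_BIAS = [(0.0, 0.35), (0.20, 0.35), (0.45, 1.15), (0.70, 0.55), (1.0, 0.55)]


def default_fixture_spec(
    seed: int = 1,
    with_events: bool = True,
    chrom_length: int = 2_000_000,
    n_chroms: int = 2,
    n_del: int = 10,
    n_dup: int = 10,
    hotspots: list[tuple[str, int, int, float]] | None = None,
) -> FixtureSpec:
    """The standard desk-scale study conditions.

    Two 2 Mb chromosomes at 10x coverage with a 0.30-0.60 GC gradient, a
    unimodal fragment-GC bias curve, AT/AC/AG/CG repeat runs with AT coverage
    suppressed to 0.5x, one N-gap per chromosome, and (optionally) 10
    heterozygous deletions + 10 duplications (CN 3-4) of 500-10,000 bases
    drawn log-uniformly, spaced well apart.
    """
    rng = np.random.default_rng(seed)
    chroms = [f"chr{i + 1}" for i in range(n_chroms)]
    spec = FixtureSpec(
        chrom_lengths={c: chrom_length for c in chroms},
        repeat_inserts=[("AT", 40, 60), ("AC", 40, 60), ("AG", 30, 40), ("CG", 24, 30)],
        n_gaps=[(c, int(chrom_length * 0.45), int(chrom_length * 0.45) + 25_000) for c in chroms],
        gc_bias=list(DEFAULT_GC_BIAS),
        motif_suppression={"AT": 0.5},
        hotspots=list(hotspots or []),
        seed=seed,
    )
    if with_events:
        spec.cnv_events = _draw_events(rng, spec, n_del=n_del, n_dup=n_dup)
    spec.validate()
    return spec


def _draw_events(
    rng: np.random.Generator,
    spec: FixtureSpec,
    n_del: int,
    n_dup: int,
    min_size: int = 500,
    max_size: int = 10_000,
    min_gap: int = 30_000,
    margin: int = 60_000,
) -> list[CNVEvent]:
    """Place non-overlapping events clear of N-gaps, hotspots and chromosome ends."""
    chroms = list(spec.chrom_lengths)
    types = [("DEL", None)] * n_del + [("DUP", None)] * n_dup
    events: list[CNVEvent] = []
    blocked: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    for chrom, s, t in spec.n_gaps:
        blocked[chrom].append((s - min_gap, t + min_gap))
    for chrom, s, t, _ in spec.hotspots:
        blocked[chrom].append((s - min_gap, t + min_gap))
    for i, (etype, _) in enumerate(types):
        chrom = chroms[i % len(chroms)]
        length = int(round(np.exp(rng.uniform(np.log(min_size), np.log(max_size)))))
        for _attempt in range(1000):
            start = int(rng.integers(margin, spec.chrom_lengths[chrom] - margin - length))
            lo, hi = start - min_gap, start + length + min_gap
            if any(lo < b and a < hi for a, b in blocked[chrom]):
                continue
            blocked[chrom].append((lo, hi))
            cn = 1 if etype == "DEL" else int(rng.integers(3, 11))
            events.append(
                CNVEvent(chrom=chrom, start=start, length=length, type=etype, copy_number=cn)
            )
            break
        else:
            raise ValueError("could not place event; relax spacing or enlarge chromosomes")
    return sorted(events, key=lambda e: (e.chrom, e.start))


def build_reference(spec: FixtureSpec) -> dict[str, str]:
    """Random sequences matching the GC profile, with repeats and N-gaps placed.

    Deterministic given the spec seed.
    """
    spec.validate()
    seqs: dict[str, str] = {}
    for ci, (chrom, n) in enumerate(spec.chrom_lengths.items()):
        rng = np.random.default_rng(spec.seed * 1000 + ci)
        fracs = np.array([f for f, _ in spec.gc_profile])
        gcs = np.array([g for _, g in spec.gc_profile])
        target = np.interp(np.arange(n) / max(n - 1, 1), fracs, gcs)
        is_gc = rng.random(n) < target
        second = rng.integers(0, 2, size=n)
        arr = np.where(is_gc, np.where(second == 0, ord("G"), ord("C")),
                       np.where(second == 0, ord("A"), ord("T"))).astype(np.uint8)
        occupied: list[tuple[int, int]] = [
            (s, t) for c, s, t in spec.n_gaps if c == chrom
        ]
        for motif, length, count in spec.repeat_inserts:
            unit = motif.upper().encode("ascii")
            for _ in range(count):
                for _attempt in range(1000):
                    pos = int(rng.integers(1000, n - 1000 - length))
                    if any(pos - 2 < t and s < pos + length + 2 for s, t in occupied):
                        continue
                    tile = np.frombuffer(unit * (length // 2 + 1), dtype=np.uint8)[:length]
                    arr[pos : pos + length] = tile
                    occupied.append((pos, pos + length))
                    break
                else:
                    raise ValueError(f"could not place repeat {motif} x{length}")
        for c, s, t in spec.n_gaps:
            if c == chrom:
                arr[s:t] = ord("N")
        seqs[chrom] = arr.tobytes().decode("ascii")
    return seqs


def write_reference(seqs: dict[str, str], path: str, line_width: int = 80) -> None:
    with open(path, "w") as fh:
        for chrom, seq in seqs.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), line_width):
                fh.write(seq[i : i + line_width] + "\n")
    pysam.faidx(path)


def _interval_multiplier(n: int, intervals: list[tuple[int, int, float]]) -> np.ndarray:
    arr = np.ones(n)
    for s, t, m in intervals:
        arr[max(0, s) : min(n, t)] = m
    return arr


def simulate_alignments(
    spec: FixtureSpec, seqs: dict[str, str], out_dir: str, bam_name: str = "reads.bam"
) -> tuple[str, str]:
    """Write a sorted, indexed BAM of biased paired reads plus a truth BED."""
    spec.validate()
    os.makedirs(out_dir, exist_ok=True)
    bam_path = os.path.join(out_dir, bam_name)
    truth_path = os.path.join(out_dir, "truth.bed")
    rl, flen = spec.read_length, spec.mean_insert
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c, "LN": len(seqs[c])} for c in spec.chrom_lengths],
    }
    with pysam.AlignmentFile(bam_path, "wb", header=dict(header)) as bam:
        for ci, chrom in enumerate(spec.chrom_lengths):
            rng = np.random.default_rng(spec.seed * 1000 + 500 + ci)
            seq = seqs[chrom]
            n = len(seq)
            arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
            is_gc = (arr == ord("G")) | (arr == ord("C"))
            is_valid = is_gc | (arr == ord("A")) | (arr == ord("T"))
            if n < flen:
                raise ValueError(f"chromosome {chrom} shorter than the insert size")
            cg = np.concatenate(([0], np.cumsum(is_gc)))
            cv = np.concatenate(([0], np.cumsum(is_valid)))
            nstarts = n - flen + 1
            frag_valid = (cv[flen:] - cv[:-flen]) == flen
            with np.errstate(invalid="ignore"):
                frag_gc = (cg[flen:] - cg[:-flen]) / flen
            w = frag_valid.astype(np.float64)
            if spec.gc_bias:
                gx = np.array([g for g, _ in spec.gc_bias])
                gm = np.array([m for _, m in spec.gc_bias])
                w *= np.interp(frag_gc, gx, gm)
            # motif suppression: min multiplier over the fragment span
            supp_events: list[tuple[int, int, float]] = []
            if spec.motif_suppression:
                for run in find_dinucleotide_runs(seq, chrom, min_len=20):
                    m = spec.motif_suppression.get(run.motif)
                    if m is not None:
                        supp_events.append((run.start, run.end, m))
            supp = np.ones(nstarts)
            for s, t, m in supp_events:
                lo, hi = max(0, s - flen + 1), min(nstarts, t)
                supp[lo:hi] = np.minimum(supp[lo:hi], m)
            w *= supp
            mid = np.arange(nstarts) + flen // 2
            hot = _interval_multiplier(
                n, [(s, t, m) for c, s, t, m in spec.hotspots if c == chrom]
            )
            w *= hot[mid]
            lam = spec.coverage * w / (2.0 * rl)
            total = lam.sum()
            if total <= 0:
                raise ValueError(f"zero fragment rate on {chrom}")
            k = int(rng.poisson(total))
            starts = np.sort(rng.choice(nstarts, size=k, p=w / w.sum()))
            flens = np.round(rng.normal(flen, spec.insert_sd, size=k)).astype(int)
            flens = np.clip(flens, 2 * rl, None)
            flens = np.minimum(flens, n - starts)
            mapqs = np.full(k, 60, dtype=int)
            for c, s, t, q in spec.low_mq_regions:
                if c == chrom:
                    inside = (starts + flens // 2 >= s) & (starts + flens // 2 < t)
                    mapqs[inside] = q
            # copy number acts per read: each mate is emitted with multiplicity
            # of mean CN/2 evaluated at the read center, so depth transitions
            # at event breakpoints are sharp at read-length scale (junction
            # fragments still contribute their mapped-side read).
            cn = np.full(n, 2.0)
            for e in spec.cnv_events:
                if e.chrom == chrom:
                    cn[e.start : e.end] = e.copy_number
            r1s, r2s = starts, starts + flens - rl
            copies = []
            for pos in (r1s, r2s):
                m = cn[np.minimum(pos + rl // 2, n - 1)] / 2.0
                base = np.floor(m).astype(int)
                copies.append(base + (rng.random(k) < m - base))
            allpos = np.concatenate([np.repeat(r1s, copies[0]), np.repeat(r2s, copies[1])])
            allfirst = np.concatenate(
                [np.ones(copies[0].sum(), bool), np.zeros(copies[1].sum(), bool)]
            )
            allfrag = np.concatenate(
                [np.repeat(np.arange(k), copies[0]), np.repeat(np.arange(k), copies[1])]
            )
            cum = [np.concatenate(([0], np.cumsum(c)[:-1])) for c in copies]
            allcopy = np.concatenate(
                [np.arange(copies[0].sum()) - np.repeat(cum[0], copies[0]),
                 np.arange(copies[1].sum()) - np.repeat(cum[1], copies[1])]
            )
            o2 = np.lexsort((allcopy, ~allfirst, allpos))
            for idx in o2:
                fi = int(allfrag[idx])
                first = bool(allfirst[idx])
                s, fl, mq = int(starts[fi]), int(flens[fi]), int(mapqs[fi])
                a = pysam.AlignedSegment()
                a.query_name = f"frag_{chrom}_{fi}_{int(allcopy[idx])}"
                a.reference_id = ci
                a.mapping_quality = mq
                a.cigar = [(0, rl)]
                a.next_reference_id = ci
                if first:
                    a.reference_start = s
                    a.flag = 99  # paired, proper, mate reverse, first
                    a.next_reference_start = s + fl - rl
                    a.template_length = fl
                    a.query_sequence = seq[s : s + rl]
                else:
                    a.reference_start = s + fl - rl
                    a.flag = 147  # paired, proper, reverse, second
                    a.next_reference_start = s
                    a.template_length = -fl
                    a.query_sequence = seq[s + fl - rl : s + fl]
                bam.write(a)
    pysam.index(bam_path)
    with open(truth_path, "w") as fh:
        for e in sorted(spec.cnv_events, key=lambda e: (e.chrom, e.start)):
            fh.write(f"{e.chrom}\t{e.start}\t{e.end}\t{e.type}\t{e.copy_number}\n")
    return bam_path, truth_path


def build_fixture(spec: FixtureSpec, out_dir: str) -> dict[str, str]:
    """Reference FASTA (+fai), sorted indexed BAM, truth BED and spec JSON."""
    os.makedirs(out_dir, exist_ok=True)
    seqs = build_reference(spec)
    fasta_path = os.path.join(out_dir, "ref.fa")
    write_reference(seqs, fasta_path)
    bam_path, truth_path = simulate_alignments(spec, seqs, out_dir)
    spec_path = os.path.join(out_dir, "spec.json")
    with open(spec_path, "w") as fh:
        json.dump(asdict(spec), fh, indent=1, default=str)
    return {
        "fasta": fasta_path,
        "bam": bam_path,
        "truth": truth_path,
        "spec": spec_path,
    }


def load_spec(path: str) -> FixtureSpec:
    with open(path) as fh:
        d = json.load(fh)
    d["cnv_events"] = [CNVEvent(**e) for e in d.get("cnv_events", [])]
    d["repeat_inserts"] = [tuple(x) for x in d.get("repeat_inserts", [])]
    d["n_gaps"] = [tuple(x) for x in d.get("n_gaps", [])]
    d["hotspots"] = [tuple(x) for x in d.get("hotspots", [])]
    d["low_mq_regions"] = [tuple(x) for x in d.get("low_mq_regions", [])]
    if d.get("gc_bias") is not None:
        d["gc_bias"] = [tuple(x) for x in d["gc_bias"]]
    d["gc_profile"] = [tuple(x) for x in d.get("gc_profile", [(0.0, 0.5), (1.0, 0.5)])]
    return FixtureSpec(**d)
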