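"""Benchmark a call set against a truth set with reciprocal-overlap matching.

A call matches a truth event when both share the same type and the reciprocal
overlap min(|intersection|/|call|, |intersection|/|truth|) reaches the chosen
threshold (the standard SV benchmarking criterion; 10% or 50% are common).
Matching is greedy by descending overlap, one-to-one.  Breakpoint error per
match is, by default, the mean of the two endpoint distances.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class BedInterval:
    chrom: str
    start: int
    end: int
    type: str

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"malformed interval {self.chrom}:{self.start}-{self.end}")


def read_bed(path: str) -> list[BedInterval]:
    out: list[BedInterval] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            out.append(BedInterval(chrom=f[0], start=int(f[1]), end=int(f[2]), type=f[3]))
    return out


def reciprocal_overlap(a, b) -> float:
    inter = min(a.end, b.end) - max(a.start, b.start)
    if a.chrom != b.chrom or inter <= 0:
        return 0.0
    return min(inter / (a.end - a.start), inter / (b.end - b.start))


@dataclass
class TypeMetrics:
    n_truth: int = 0
    n_calls: int = 0
    true_positives: int = 0
    other: int = 0                    # calls matching no truth event
    sensitivity: float = float("nan")
    fdr: float = float("nan")
    mean_breakpoint_error: float = float("nan")


@dataclass
class EvalReport:
    min_reciprocal: float
    by_type: dict[str, TypeMetrics] = field(default_factory=dict)
    matches: list[tuple[int, int, float]] = field(default_factory=list)  # (call idx, truth idx, RO)

    def overall(self) -> TypeMetrics:
        m = TypeMetrics()
        errs = []
        for t in self.by_type.values():
            m.n_truth += t.n_truth
            m.n_calls += t.n_calls
            m.true_positives += t.true_positives
            m.other += t.other
            if np.isfinite(t.mean_breakpoint_error) and t.true_positives:
                errs.append((t.mean_breakpoint_error, t.true_positives))
        m.sensitivity = m.true_positives / m.n_truth if m.n_truth else float("nan")
        m.fdr = m.other / m.n_calls if m.n_calls else float("nan")
        if errs:
            m.mean_breakpoint_error = sum(e * n for e, n in errs) / sum(n for _, n in errs)
        return m


def match_calls(
    calls,
    truth,
    min_reciprocal: float = 0.5,
    endpoint: str = "mean",
) -> EvalReport:
    """Greedy one-to-one matching of same-type calls to truth events.

    ``calls`` and ``truth`` are sequences of objects with chrom/start/end/type
    attributes (CNVCall and BedInterval both qualify).  ``endpoint`` selects
    the per-match breakpoint error: "mean" of the two endpoint distances or
    "max".
    """
    if endpoint not in ("mean", "max"):
        raise ValueError("endpoint must be 'mean' or 'max'")
    report = EvalReport(min_reciprocal=min_reciprocal)
    types = sorted({t.type for t in truth} | {c.type for c in calls})
    call_matched = [False] * len(calls)
    truth_matched = [False] * len(truth)
    pairs = []
    for ci, c in enumerate(calls):
        for ti, t in enumerate(truth):
            if c.type != t.type:
                continue
            ro = reciprocal_overlap(c, t)
            if ro >= min_reciprocal:
                pairs.append((-ro, ci, ti))
    for _, ci, ti in sorted(pairs):
        if call_matched[ci] or truth_matched[ti]:
            continue
        call_matched[ci] = True
        truth_matched[ti] = True
        report.matches.append((ci, ti, reciprocal_overlap(calls[ci], truth[ti])))
    for tp in types:
        m = TypeMetrics(
            n_truth=sum(1 for t in truth if t.type == tp),
            n_calls=sum(1 for c in calls if c.type == tp),
        )
        errs = []
        for ci, ti, _ in report.matches:
            if calls[ci].type != tp:
                continue
            m.true_positives += 1
            ds = abs(calls[ci].start - truth[ti].start)
            de = abs(calls[ci].end - truth[ti].end)
            errs.append((ds + de) / 2.0 if endpoint == "mean" else max(ds, de))
        m.other = m.n_calls - m.true_positives
        m.sensitivity = m.true_positives / m.n_truth if m.n_truth else float("nan")
        m.fdr = m.other / m.n_calls if m.n_calls else float("nan")
        m.mean_breakpoint_error = float(np.mean(errs)) if errs else float("nan")
        report.by_type[tp] = m
    return report


def write_report_tsv(path: str, report: EvalReport) -> None:
    with open(path, "w") as fh:
        fh.write(
            "type\tn_truth\tn_calls\ttrue_positives\tother\t"
            "sensitivity\tfdr\tmean_breakpoint_error\tmin_reciprocal\n"
        )
        rows = list(report.by_type.items()) + [("ALL", report.overall())]
        for name, m in rows:
            fh.write(
                f"{name}\t{m.n_truth}\t{m.n_calls}\t{m.true_positives}\t{m.other}\t"
                f"{m.sensitivity:.4f}\t{m.fdr:.4f}\t{m.mean_breakpoint_error:.1f}\t"
                f"{report.min_reciprocal}\n"
            )
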