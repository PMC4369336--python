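"""Score a call BED against a truth BED with reciprocal-overlap matching.

Reciprocal overlap = min(shared/|call|, shared/|truth|); a match requires the
same event type and one-to-one greedy assignment by descending overlap.
"""

from rdcnv.evaluation import BedInterval, match_calls, write_report_tsv

truth = [
    BedInterval("chr1", 10_000, 14_000, "DEL"),
    BedInterval("chr1", 50_000, 51_000, "DEL"),
    BedInterval("chr1", 80_000, 86_000, "DUP"),
]
calls = [
    BedInterval("chr1", 10_050, 13_900, "DEL"),   # good match
    BedInterval("chr1", 80_200, 90_000, "DUP"),   # overhanging match
    BedInterval("chr1", 120_000, 125_000, "DEL"),  # false positive
]

for thr in (0.1, 0.5):
    rep = match_calls(calls, truth, thr)
    o = rep.overall()
    print(f"reciprocal overlap >= {thr:.0%}: "
          f"sensitivity {o.sensitivity:.2f}, FDR {o.fdr:.2f}, "
          f"mean breakpoint error {o.mean_breakpoint_error:.0f} bases")

write_report_tsv("scratch/example_eval_report.tsv", match_calls(calls, truth, 0.5))
print("\nper-type table written to scratch/example_eval_report.tsv")
print("the 6-kb DUP call matches at 50% despite 4 kb of overhang; the 1-kb "
      "DEL is missed at both thresholds (no call overlaps it)")
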