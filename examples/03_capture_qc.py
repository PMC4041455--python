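"""Simulate a gene-panel capture and compute QC metrics.

Designs probes for three exon-sized targets on a 20 kb genome,
simulates capture (fragments ~500 b, 4.9% mean efficiency, 80x40
reads), assigns reads to probes via the Read 2 prefix and reports
capture rate, on-target fraction, 1-log uniformity and ROI coverage.
"""

from osseq.workflows import panel_experiment

pe = panel_experiment(seed=3)
report = pe.report

print(f"probes: {len(pe.probes)}; reads: {report['total_reads']}")
print(f"capture rate (probes with >=1 on-target read): {report['capture_rate']:.3f}")
print(f"on-target fraction of assigned reads: {report['on_target_fraction_of_assigned']:.3f}")
print(f"uniformity (yield within 1 log of median): {report['uniformity_1log']:.3f}")
for row in report["roi_coverage"][:3]:
    print(
        f"  ROI {row['chrom']}:{row['start']}-{row['end']}  "
        f"mean depth {row['mean_coverage']:.1f}x, >=10x over "
        f"{row['frac_ge_10x']:.0%} of bases"
    )
print(
    "On a clean synthetic panel every probe captures, mirroring the >90% "
    "capture and uniformity regime of well-designed pools."
)
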