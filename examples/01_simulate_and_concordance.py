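"""Simulate a matched-pair cohort and measure pairwise genome concordance.

Builds a small synthetic cohort, runs normalization -> segmentation ->
cellularity-corrected calling, and compares each metastasis with its
matched primary: percent of the genome with the same three-state call,
next to the exact value known from the simulation's ground truth.
"""

import paircn as pc
from paircn.calling import call_segments
from paircn.concordance import bin_concordance, pair_concordance
from paircn.segmentation import SegmentationParams, segment

params = pc.SimParams(n_patients=4, seed=42)
cases, truth = pc.generate_cohort(params)
seg_params = SegmentationParams(n_permutations=200)

print(f"{'pair':<12}{'estimated':>10}{'true':>8}   bin")
for case in cases:
    prim = call_segments(
        segment(pc.median_normalize(case.primary), seg_params),
        cellularity=case.primary.cellularity,
    )
    for k, met in enumerate(case.metastases):
        called_met = call_segments(
            segment(pc.median_normalize(met), seg_params),
            cellularity=met.cellularity,
        )
        est = pair_concordance(prim, called_met)
        exact = pc.expected_concordance(truth, case.patient_id, k)
        pair = f"{case.primary.sample_id}/{met.sample_id}"
        print(f"{pair:<12}{est:>9.1f}%{exact:>7.1f}%   {bin_concordance(est)}")

print(
    "\nEach row is one metastasis vs its matched primary: the pipeline's\n"
    "bp-weighted three-state concordance, the exact value from the planted\n"
    "events, and the histogram bin (>95 / 70-95 / <70)."
)
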