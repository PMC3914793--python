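"""Shared test construction helpers."""

import numpy as np

from paircn.core import GenomeGrid, Segment, SegmentedProfile


def make_segmented(grid: GenomeGrid, level_runs, sample_id="s") -> SegmentedProfile:
    """Build a SegmentedProfile from (chromosome, n_probes, mean) runs."""
    istart, iend = grid.probe_intervals()
    segs = []
    cursor = {}
    for chrom, n, mean in level_runs:
        sl = grid.chrom_slice(chrom)
        first = cursor.get(chrom, sl.start)
        last = first + n - 1
        cursor[chrom] = last + 1
        segs.append(
            Segment(chrom, int(istart[first]), int(iend[last] - 1), first, last, float(mean))
        )
    return SegmentedProfile.from_segments(sample_id, grid, segs)


def brute_force_concordance_bp(grid, states_a, states_b, missing=None) -> float:
    """Per-bp oracle: expand three-state calls to every bp and compare."""
    istart, iend = grid.probe_intervals()
    agree = total = 0
    sa = np.sign(states_a)
    sb = np.sign(states_b)
    for j in range(grid.n_probes):
        if missing is not None and missing[j]:
            continue
        width = int(iend[j] - istart[j])
        total += width
        if sa[j] == sb[j]:
            agree += width
    return 100.0 * agree / total
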