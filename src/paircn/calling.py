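"""Five-state copy-number calling from segment means, after cellularity
correction.

Thresholds are fixed log2 cut-offs (defaults: gain/loss at +/-0.2,
amplification at +0.6, homozygous deletion at -1.0). Boundary values are
called aberrant (>= / <=). Segment means are corrected for tumor-cell
fraction before thresholding, so the cut-offs act on the inferred
tumor-cell signal rather than the admixture-diluted one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import CalledProfile, CallState, SegmentedProfile, three_state_array
from .io import correct_cellularity

__all__ = ["CallThresholds", "call_segments", "percent_aberrant"]


@dataclass(frozen=True)
class CallThresholds:
    """log2 cut-offs for the five call states; must satisfy
    homdel < loss < 0 < gain < amp."""

    gain: float = 0.2
    loss: float = -0.2
    amp: float = 0.6
    homdel: float = -1.0

    def __post_init__(self) -> None:
        if not (self.homdel < self.loss < 0 < self.gain < self.amp):
            raise ValueError(
                "thresholds must satisfy homdel < loss < 0 < gain < amp, got "
                f"{self.homdel} < {self.loss} < 0 < {self.gain} < {self.amp}"
            )


def classify_means(means: np.ndarray, thresholds: CallThresholds) -> np.ndarray:
    """Vectorized state assignment for (already corrected) segment means."""
    m = np.asarray(means, dtype=float)
    states = np.zeros(m.shape, dtype=np.int8)
    states[m >= thresholds.gain] = CallState.GAIN
    states[m >= thresholds.amp] = CallState.AMP
    states[m <= thresholds.loss] = CallState.LOSS
    states[m <= thresholds.homdel] = CallState.HOMDEL
    return states


def call_segments(
    segprofile: SegmentedProfile,
    thresholds: CallThresholds | None = None,
    cellularity: float = 1.0,
) -> CalledProfile:
    """Assign a five-state call to every segment and replicate it per probe.

    Each segment mean is first corrected for cellularity (identity at
    c = 1), then compared to the cut-offs: AMP if m >= amp, GAIN if
    gain <= m < amp, HOMDEL if m <= homdel, LOSS if homdel < m <= loss,
    NEUTRAL otherwise.
    """
    thresholds = thresholds or CallThresholds()
    means = np.array([s.mean_log2 for s in segprofile.segments])
    # c = 1 is the exact identity; skip the exp2/log2 round-trip, which
    # could nudge a mean off a threshold boundary
    corrected = means if cellularity == 1.0 else np.asarray(
        correct_cellularity(means, cellularity)
    )
    per_segment = classify_means(corrected, thresholds)
    per_probe = np.zeros(segprofile.grid.n_probes, dtype=np.int8)
    for seg, st in zip(segprofile.segments, per_segment):
        per_probe[seg.first_probe : seg.last_probe + 1] = st
    return CalledProfile(
        segprofile.sample_id, segprofile.grid, list(segprofile.segments),
        per_segment, per_probe,
    )


def percent_aberrant(called: CalledProfile, bp_weighted: bool = True) -> float:
    """Percent of the analysed genome with a non-neutral three-state call.

    bp-weighted by default (each probe weighted by its bp interval);
    ``bp_weighted=False`` gives the probe-counted variant.
    """
    aberrant = three_state_array(called.per_probe_state) != 0
    if bp_weighted:
        w = called.grid.probe_weights_bp()
        return 100.0 * float(w[aberrant].sum()) / float(w.sum())
    return 100.0 * float(aberrant.mean())
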