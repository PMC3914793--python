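"""High-level amplification screening and FISH signal-count scoring.

A segment counts as a high-level amplification only when its segmented
log2 ratio exceeds 2 (i.e. more than an 8-copy signal in pure tissue);
adjacent qualifying segments are merged into one region. A sample is
co-amplified for a locus pair when both loci intersect one of its
amplification regions; the cohort screen additionally flags
metastasis-specific co-amplifications (present in a metastasis, absent in
the matched primary).

FISH scoring follows the standard per-cell counting rule: a sample is
positive for amplification when the locus/centromere signal ratio exceeds
3 in at least 10% of cells, counted over at least 40 cells.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core import SegmentedProfile, _normalize_chrom

__all__ = [
    "FISHAssay",
    "AmpRegion",
    "find_high_level_amps",
    "detect_coamp",
    "cohort_coamp_screen",
    "fish_score",
    "read_fish_table",
]


@dataclass
class FISHAssay:
    """Per-cell locus and centromere signal counts for one sample/locus."""

    sample_id: str
    locus: str
    locus_signals: np.ndarray  # int >= 0 per cell
    centromere_signals: np.ndarray  # int >= 1 per cell (0 -> cell excluded)

    def __post_init__(self) -> None:
        self.locus_signals = np.asarray(self.locus_signals, dtype=int)
        self.centromere_signals = np.asarray(self.centromere_signals, dtype=int)
        if len(self.locus_signals) != len(self.centromere_signals):
            raise ValueError("locus and centromere count vectors differ in length")
        if np.any(self.locus_signals < 0):
            raise ValueError("locus signal counts must be >= 0")

    @property
    def n_cells(self) -> int:
        return len(self.locus_signals)


@dataclass
class AmpRegion:
    """A maximal genomic run of segments above the amplification threshold."""

    sample_id: str
    chromosome: str
    start_bp: int
    end_bp: int
    mean_log2: float  # probe-weighted mean over the merged run


def find_high_level_amps(
    segprofile: SegmentedProfile, threshold: float = 2.0, cellularity: float = 1.0
) -> list[AmpRegion]:
    """Maximal merged runs of segments with mean log2 strictly above ``threshold``.

    ``cellularity`` corrects segment means for normal-cell admixture before
    thresholding (identity at 1), so the screen acts on the inferred
    tumor-cell signal like the calls do.
    """
    from .io import correct_cellularity

    regions: list[AmpRegion] = []
    segs = sorted(segprofile.segments, key=lambda s: s.first_probe)
    corrected = {
        id(s): float(np.asarray(correct_cellularity(s.mean_log2, cellularity)))
        for s in segs
    }
    run: list = []

    def _flush() -> None:
        if not run:
            return
        n = sum(s.n_probes for s in run)
        mean = sum(corrected[id(s)] * s.n_probes for s in run) / n
        regions.append(
            AmpRegion(segprofile.sample_id, run[0].chromosome, run[0].start_bp,
                      run[-1].end_bp, float(mean))
        )
        run.clear()

    for seg in segs:
        if corrected[id(seg)] > threshold:
            if run and (run[-1].chromosome != seg.chromosome
                        or seg.first_probe != run[-1].last_probe + 1):
                _flush()
            run.append(seg)
        else:
            _flush()
    _flush()
    return regions


Locus = tuple[str, int, int]  # chromosome, start_bp, end_bp (1-based inclusive)


def _check_locus(locus: Locus) -> Locus:
    try:
        chrom, s, e = locus
        chrom = _normalize_chrom(chrom)
        s, e = int(s), int(e)
    except (TypeError, ValueError) as err:
        raise ValueError(f"malformed locus {locus!r}: expected (chromosome, start, end)") from err
    if s > e or s < 1:
        raise ValueError(f"malformed locus {locus!r}: need 1 <= start <= end")
    return chrom, s, e


def _locus_hit(regions: list[AmpRegion], locus: Locus) -> bool:
    chrom, s, e = locus
    return any(
        r.chromosome == chrom and r.start_bp <= e and r.end_bp >= s for r in regions
    )


def detect_coamp(regions: list[AmpRegion], locus_a: Locus, locus_b: Locus) -> bool:
    """True iff both loci overlap (>=1 bp) an amplification region of the sample."""
    locus_a, locus_b = _check_locus(locus_a), _check_locus(locus_b)
    return _locus_hit(regions, locus_a) and _locus_hit(regions, locus_b)


def cohort_coamp_screen(
    segmented: dict[str, SegmentedProfile],
    pairs: dict[str, tuple[str, list[str]]],
    locus_a: Locus,
    locus_b: Locus,
    threshold: float = 2.0,
    cellularity: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Screen every sample of a cohort for the two-locus co-amplification.

    Parameters
    ----------
    segmented : dict sample_id -> SegmentedProfile
    pairs : dict patient_id -> (primary sample_id, [metastasis sample_ids])
    cellularity : optional dict sample_id -> tumor-cell fraction, used to
        correct segment means before thresholding.

    Returns one row per sample with amp flags per locus, the co-amp flag,
    and ``metastasis_specific`` (co-amp in a metastasis whose matched
    primary lacks it).
    """
    locus_a, locus_b = _check_locus(locus_a), _check_locus(locus_b)
    cellularity = cellularity or {}
    amp = {
        sid: find_high_level_amps(sp, threshold, cellularity.get(sid, 1.0))
        for sid, sp in segmented.items()
    }
    rows = []
    for patient, (p_id, met_ids) in pairs.items():
        for sid, role in [(p_id, "primary")] + [(m, "metastasis") for m in met_ids]:
            regions = amp[sid]
            hit_a, hit_b = _locus_hit(regions, locus_a), _locus_hit(regions, locus_b)
            co = hit_a and hit_b
            met_specific = (
                role == "metastasis"
                and co
                and not detect_coamp(amp[p_id], locus_a, locus_b)
            )
            rows.append(
                dict(patient_id=patient, sample_id=sid, role=role,
                     amp_locus_a=hit_a, amp_locus_b=hit_b, coamp=co,
                     metastasis_specific=met_specific)
            )
    return pd.DataFrame(rows)


def fish_score(
    assay: FISHAssay,
    ratio_cutoff: float = 3.0,
    cell_fraction: float = 0.10,
    min_cells: int = 40,
) -> str:
    """Score a FISH assay ``"positive"`` or ``"negative"`` for amplification.

    Positive iff the fraction of cells with locus/centromere ratio strictly
    greater than ``ratio_cutoff`` is at least ``cell_fraction``. Requires at
    least ``min_cells`` counted cells; cells with zero centromere signals
    are excluded with a warning.
    """
    if assay.n_cells < min_cells:
        raise ValueError(
            f"sample {assay.sample_id}: only {assay.n_cells} cells counted; "
            f"at least {min_cells} cells are required"
        )
    cen = assay.centromere_signals
    ok = cen > 0
    if not ok.all():
        warnings.warn(
            f"sample {assay.sample_id}: {int((~ok).sum())} cell(s) with zero "
            "centromere signals excluded"
        )
    ratios = assay.locus_signals[ok] / cen[ok]
    frac = float(np.mean(ratios > ratio_cutoff)) if ok.any() else 0.0
    return "positive" if frac >= cell_fraction else "negative"


def read_fish_table(path: str | Path, sample_id: str, locus: str) -> FISHAssay:
    """Read tab-delimited per-cell counts (columns: locus_signals, centromere_signals)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    return FISHAssay(sample_id, locus,
                     df["locus_signals"].to_numpy(), df["centromere_signals"].to_numpy())
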