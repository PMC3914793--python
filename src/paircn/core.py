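"""Shared coordinate system and profile/segment/call data types.

All downstream stages (segmentation, calling, concordance, clustering,
difference analysis) operate on profiles bound to one :class:`GenomeGrid`,
the ordered probe map of the array platform. Copy-number states are the
five-level calls used throughout array-CGH analysis (homozygous deletion,
loss, neutral, gain, amplification); pairwise genome comparison collapses
them to three states (gain / loss / normal).

Coordinates: segments are 1-based inclusive in bp (SEG convention); the
per-probe bp intervals used for bp-weighted statistics are half-open
``[start, end)`` and tile each chromosome exactly.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from enum import IntEnum
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: Fixed chromosome order of the analysed genome: autosomes then X. Y is absent.
CHROMOSOMES: tuple[str, ...] = tuple(str(i) for i in range(1, 23)) + ("X",)

_CHROM_RANK = {c: i for i, c in enumerate(CHROMOSOMES)}

#: Metastatic sites recognised in sample metadata.
SITES: tuple[str, ...] = ("liver", "lung", "ovary", "omentum", "lymph_node", "none")


class CallState(IntEnum):
    """Five-level copy-number call."""

    HOMDEL = -2
    LOSS = -1
    NEUTRAL = 0
    GAIN = 1
    AMP = 2


def three_state(call: CallState | int) -> CallState:
    """Collapse a five-level call to gain / loss / normal.

    AMP maps to GAIN and HOMDEL to LOSS; NEUTRAL is fixed. This is the
    state space used for pairwise genome concordance.
    """
    v = int(call)
    if v > 0:
        return CallState.GAIN
    if v < 0:
        return CallState.LOSS
    return CallState.NEUTRAL


def three_state_array(calls: np.ndarray) -> np.ndarray:
    """Vectorised :func:`three_state` on an integer state array."""
    return np.sign(np.asarray(calls, dtype=np.int8)).astype(np.int8)


def _normalize_chrom(c: object) -> str:
    s = str(c)
    if s.startswith("chr"):
        s = s[3:]
    if s not in _CHROM_RANK:
        raise ValueError(f"unknown chromosome label {c!r}; expected one of 1..22, X")
    return s


@dataclass(frozen=True, eq=False)
class GenomeGrid:
    """Ordered probe map defining the shared coordinate axis of all profiles.

    Parameters
    ----------
    probe_ids : array of str
        Unique probe identifiers, in genome order.
    chromosomes : array of str
        Chromosome label per probe (``1``..``22``, ``X``), grouped and
        ordered by the fixed chromosome order.
    positions : array of int
        1-based bp position per probe, strictly increasing within each
        chromosome and never exceeding the chromosome length.
    chromosome_lengths : dict
        Mapping chromosome label -> length in bp.
    """

    probe_ids: np.ndarray
    chromosomes: np.ndarray
    positions: np.ndarray
    chromosome_lengths: dict[str, int]
    _chrom_slices: dict[str, slice] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        probe_ids = np.asarray(self.probe_ids, dtype=object)
        chroms = np.asarray([_normalize_chrom(c) for c in self.chromosomes], dtype=object)
        positions = np.asarray(self.positions, dtype=np.int64)
        if not (len(probe_ids) == len(chroms) == len(positions)):
            raise ValueError("probe_ids, chromosomes and positions must have equal length")
        object.__setattr__(self, "probe_ids", probe_ids)
        object.__setattr__(self, "chromosomes", chroms)
        object.__setattr__(self, "positions", positions)
        lengths = {_normalize_chrom(k): int(v) for k, v in self.chromosome_lengths.items()}
        object.__setattr__(self, "chromosome_lengths", lengths)

        ranks = np.array([_CHROM_RANK[c] for c in chroms])
        if np.any(np.diff(ranks) < 0):
            raise ValueError("probes must be sorted by chromosome in the fixed order 1..22, X")
        slices: dict[str, slice] = {}
        for r in np.unique(ranks):
            idx = np.nonzero(ranks == r)[0]
            c = CHROMOSOMES[r]
            slices[c] = slice(int(idx[0]), int(idx[-1]) + 1)
            pos = positions[slices[c]]
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"positions on chromosome {c} must be strictly increasing/unique")
            if pos[0] < 1:
                raise ValueError(f"positions must be >= 1 (chromosome {c})")
            if c not in lengths:
                raise ValueError(f"no length given for chromosome {c}")
            if pos[-1] > lengths[c]:
                raise ValueError(
                    f"probe position {pos[-1]} exceeds length {lengths[c]} of chromosome {c}"
                )
        object.__setattr__(self, "_chrom_slices", slices)

    # -- basic accessors ---------------------------------------------------
    @property
    def n_probes(self) -> int:
        return len(self.positions)

    @property
    def chromosome_list(self) -> list[str]:
        """Chromosomes that carry at least one probe, in genome order."""
        return [c for c in CHROMOSOMES if c in self._chrom_slices]

    def chrom_slice(self, chrom: str) -> slice:
        """Probe index range of one chromosome."""
        return self._chrom_slices[_normalize_chrom(chrom)]

    @property
    def total_bp(self) -> int:
        """Total analysed genome size: sum of lengths of chromosomes with probes."""
        return sum(self.chromosome_lengths[c] for c in self.chromosome_list)

    # -- bp intervals ------------------------------------------------------
    def probe_intervals(self) -> tuple[np.ndarray, np.ndarray]:
        """Half-open bp interval ``[start, end)`` assigned to each probe.

        Interval boundaries are the midpoints between adjacent probes,
        clipped to ``[1, chromosome length + 1)``; the intervals of a
        chromosome tile it exactly, so interval widths are the bp weights
        used by concordance and percent-aberrant statistics. Chromosomes
        present in ``chromosome_lengths`` but carrying no probes are
        excluded with a warning.
        """
        starts = np.empty(self.n_probes, dtype=np.int64)
        ends = np.empty(self.n_probes, dtype=np.int64)
        for c in self.chromosome_lengths:
            if c not in self._chrom_slices:
                warnings.warn(f"chromosome {c} has no probes; excluded from bp intervals")
        for c, sl in self._chrom_slices.items():
            pos = self.positions[sl]
            length = self.chromosome_lengths[c]
            mids = (pos[:-1] + pos[1:]) // 2
            starts[sl] = np.concatenate(([1], mids))
            ends[sl] = np.concatenate((mids, [length + 1]))
        return starts, ends

    def probe_weights_bp(self) -> np.ndarray:
        """Width in bp of each probe's interval."""
        s, e = self.probe_intervals()
        return (e - s).astype(np.int64)

    @classmethod
    def uniform(
        cls,
        chromosome_lengths: dict[str, int],
        spacing_bp: int = 17_000,
        first_offset: int | None = None,
    ) -> "GenomeGrid":
        """Evenly spaced grid emulating an oligo array laid out at fixed intervals.

        Probes are placed at ``first_offset, first_offset+spacing, ...`` on
        each chromosome (default offset: spacing//2). A chromosome shorter
        than the spacing still receives one probe at its midpoint.
        """
        if spacing_bp < 1:
            raise ValueError("spacing_bp must be >= 1")
        off = spacing_bp // 2 if first_offset is None else first_offset
        ids, chroms, pos = [], [], []
        ordered = sorted(
            (_normalize_chrom(c) for c in chromosome_lengths), key=_CHROM_RANK.__getitem__
        )
        for c in ordered:
            length = int(chromosome_lengths[c])
            p = np.arange(max(off, 1), length + 1, spacing_bp, dtype=np.int64)
            if len(p) == 0:
                warnings.warn(
                    f"spacing {spacing_bp} exceeds length of chromosome {c}; placing 1 probe"
                )
                p = np.array([max(length // 2, 1)], dtype=np.int64)
            ids.extend(f"P_{c}_{int(x)}" for x in p)
            chroms.extend([c] * len(p))
            pos.extend(p.tolist())
        return cls(np.array(ids, dtype=object), np.array(chroms, dtype=object),
                   np.array(pos, dtype=np.int64), dict(chromosome_lengths))


def grids_equal(a: GenomeGrid, b: GenomeGrid) -> bool:
    """Whether two grids define the same probe map (identity short-circuits)."""
    if a is b:
        return True
    return (
        a.n_probes == b.n_probes
        and a.chromosome_lengths == b.chromosome_lengths
        and bool(np.all(a.chromosomes == b.chromosomes))
        and bool(np.all(a.positions == b.positions))
    )


@dataclass
class RatioProfile:
    """One sample's per-probe log2 tumor/normal ratios plus metadata.

    ``log2`` is aligned to the grid; missing measurements are NaN, never
    silently zero. ``cellularity`` is the pathologist's estimate of the
    tumor-cell fraction, in (0, 1].
    """

    sample_id: str
    role: str  # "primary" | "metastasis"
    site: str  # one of SITES; "none" for primaries
    grid: GenomeGrid
    log2: np.ndarray
    cellularity: float = 1.0

    def __post_init__(self) -> None:
        if self.role not in ("primary", "metastasis"):
            raise ValueError(f"role must be 'primary' or 'metastasis', got {self.role!r}")
        if self.site not in SITES:
            raise ValueError(f"unknown site {self.site!r}")
        self.log2 = np.asarray(self.log2, dtype=float)
        if len(self.log2) != self.grid.n_probes:
            raise ValueError(
                f"log2 length {len(self.log2)} != grid probe count {self.grid.n_probes}"
            )
        if not (0 < self.cellularity <= 1):
            raise ValueError(f"cellularity must be in (0, 1], got {self.cellularity}")

    @property
    def n_missing(self) -> int:
        return int(np.isnan(self.log2).sum())


@dataclass
class Segment:
    """A run of probes with constant estimated copy number.

    bp coordinates are 1-based inclusive and derived from the probe
    intervals of the end probes, so a chromosome's segments tile it.
    Never spans a chromosome boundary.
    """

    chromosome: str
    start_bp: int
    end_bp: int
    first_probe: int  # global probe index, inclusive
    last_probe: int  # global probe index, inclusive
    mean_log2: float

    def __post_init__(self) -> None:
        if self.start_bp > self.end_bp:
            raise ValueError("segment start_bp > end_bp")
        if self.first_probe > self.last_probe:
            raise ValueError("segment first_probe > last_probe")

    @property
    def n_probes(self) -> int:
        return self.last_probe - self.first_probe + 1


@dataclass
class SegmentedProfile:
    """Piecewise-constant representation of one profile."""

    sample_id: str
    grid: GenomeGrid
    segments: list[Segment]
    per_probe_mean: np.ndarray

    def __post_init__(self) -> None:
        self.per_probe_mean = np.asarray(self.per_probe_mean, dtype=float)
        if len(self.per_probe_mean) != self.grid.n_probes:
            raise ValueError("per_probe_mean length != grid probe count")
        self._check_partition()

    def _check_partition(self) -> None:
        by_chrom: dict[str, list[Segment]] = {}
        for seg in self.segments:
            by_chrom.setdefault(seg.chromosome, []).append(seg)
        for c in self.grid.chromosome_list:
            sl = self.grid.chrom_slice(c)
            segs = by_chrom.get(c, [])
            if not segs:
                raise ValueError(f"chromosome {c} has probes but no segments")
            segs.sort(key=lambda s: s.first_probe)
            if segs[0].first_probe != sl.start or segs[-1].last_probe != sl.stop - 1:
                raise ValueError(f"segments do not span probe range of chromosome {c}")
            for a, b in zip(segs, segs[1:]):
                if b.first_probe != a.last_probe + 1:
                    raise ValueError(f"gap or overlap between segments on chromosome {c}")

    @classmethod
    def from_segments(
        cls, sample_id: str, grid: GenomeGrid, segments: Sequence[Segment]
    ) -> "SegmentedProfile":
        """Build the profile, replicating each segment's mean over its probes."""
        per_probe = np.empty(grid.n_probes, dtype=float)
        per_probe.fill(np.nan)
        for seg in segments:
            per_probe[seg.first_probe : seg.last_probe + 1] = seg.mean_log2
        return cls(sample_id, grid, list(segments), per_probe)


@dataclass
class CalledProfile:
    """Discrete five-state calls per segment and per probe."""

    sample_id: str
    grid: GenomeGrid
    segments: list[Segment]
    per_segment_state: np.ndarray  # int8, aligned with segments
    per_probe_state: np.ndarray  # int8, aligned with grid

    def __post_init__(self) -> None:
        self.per_segment_state = np.asarray(self.per_segment_state, dtype=np.int8)
        self.per_probe_state = np.asarray(self.per_probe_state, dtype=np.int8)
        if len(self.per_segment_state) != len(self.segments):
            raise ValueError("per_segment_state length != number of segments")
        if len(self.per_probe_state) != self.grid.n_probes:
            raise ValueError("per_probe_state length != grid probe count")

    def three_state_per_probe(self) -> np.ndarray:
        return three_state_array(self.per_probe_state)


@dataclass
class PairedCase:
    """One patient: a primary profile plus >=1 site-labelled metastases."""

    patient_id: str
    primary: RatioProfile
    metastases: list[RatioProfile]

    def __post_init__(self) -> None:
        if self.primary.role != "primary":
            raise ValueError("primary profile must have role 'primary'")
        if not self.metastases:
            raise ValueError(f"patient {self.patient_id} has no metastasis profile")
        for m in self.metastases:
            if m.role != "metastasis":
                raise ValueError(f"sample {m.sample_id} in metastases list has role {m.role!r}")
            if not grids_equal(m.grid, self.primary.grid):
                raise ValueError("all profiles of a case must share one GenomeGrid")

    @property
    def samples(self) -> list[RatioProfile]:
        return [self.primary, *self.metastases]
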