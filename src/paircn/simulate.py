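"""Synthetic matched primary/metastasis cohorts with known ground truth.

The generator emulates the structure of a paired tumor aCGH cohort: an
evenly spaced oligo grid (~17 kb) over chromosomes 1-22 and X; per patient
a set of *ancestral* copy-number events shared by the primary tumor and its
metastases, plus *private* events in each sample; observed per-probe log2
ratios diluted by tumor cellularity and perturbed by i.i.d. Gaussian probe
noise:

    y = log2(c * 2**t + (1 - c)) + N(0, noise_sd**2)

where ``t`` is the true log2 ratio of the tumor-cell population (0 outside
events) and ``c`` the sample's tumor-cell fraction. The true event maps are
kept as bp-resolution interval maps, so the expected three-state genome
concordance of any pair can be computed exactly, independent of the
pipeline, and serves as the recovery target for the estimated statistic.

The default genome is a scaled-down one (23 chromosomes x 2 Mb) so that
full cohort simulations and the segmentation that follows run in seconds;
the probe spacing, event amplitudes, cellularity range and noise level are
kept realistic for a 180K tumor/normal platform.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .amplification import FISHAssay
from .core import CHROMOSOMES, CallState, GenomeGrid, PairedCase, RatioProfile

__all__ = [
    "SimEvent",
    "SimParams",
    "SimTruth",
    "generate_cohort",
    "expected_concordance",
    "generate_fish_counts",
    "write_cohort",
]

# single-copy gain/loss and high-level event amplitudes, log2(CN/2)
LOG2_GAIN = float(np.log2(3 / 2))
LOG2_LOSS = float(np.log2(1 / 2))
LOG2_AMP = float(np.log2(6 / 2))
LOG2_COAMP = float(np.log2(12 / 2))
LOG2_HOMDEL = -4.0  # residual signal of a homozygous deletion in impure tissue

_STATE_LOG2 = {
    CallState.GAIN: LOG2_GAIN,
    CallState.LOSS: LOG2_LOSS,
    CallState.AMP: LOG2_AMP,
    CallState.HOMDEL: LOG2_HOMDEL,
}


@dataclass(frozen=True)
class SimEvent:
    """One planted copy-number event, before overlap resolution."""

    chromosome: str
    start_bp: int
    end_bp: int  # 1-based inclusive
    true_state: CallState
    true_log2: float
    origin: str  # "ancestral" | "primary_private" | "metastasis_private"


@dataclass
class SimParams:
    """Study conditions of a simulated cohort.

    Counts are inclusive integer ranges; amplitudes are fixed per state
    (single-copy gain/loss, 6-copy amplification, 12-copy co-amplification).
    """

    n_patients: int = 20
    chromosome_lengths: dict[str, int] = field(
        default_factory=lambda: {c: 2_000_000 for c in CHROMOSOMES}
    )
    spacing_bp: int = 17_000
    shared_event_count: tuple[int, int] = (14, 20)
    private_event_count: tuple[int, int] = (1, 3)
    arm_level_probability: float = 0.5
    focal_amp_probability: float = 0.05
    homdel_probability: float = 0.05
    focal_length_bp: tuple[int, int] = (100_000, 600_000)
    noise_sd: float = 0.1
    cellularity_range: tuple[float, float] = (0.7, 1.0)
    two_site_probability: float = 0.1
    # metastasis-private focal co-amplification planted in the first
    # `coamp_patients` patients, at the two loci below (exercises the screen)
    coamp_patients: int = 0
    coamp_locus_a: tuple[str, int, int] = ("6", 1_000_000, 1_150_000)
    coamp_locus_b: tuple[str, int, int] = ("8", 1_200_000, 1_350_000)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        lo, hi = self.cellularity_range
        if not (0 < lo <= hi <= 1):
            raise ValueError("cellularity_range must lie in (0, 1]")
        for name in ("shared_event_count", "private_event_count"):
            a, b = getattr(self, name)
            if a < 0 or b < a:
                raise ValueError(f"{name} must be a non-negative inclusive range")


# ---------------------------------------------------------------------------
# interval maps: per-chromosome non-overlapping (start, end, state, log2)

TruthMap = dict[str, list[tuple[int, int, int, float]]]


def _overlay(intervals: list[tuple[int, int, int, float]], ev: SimEvent) -> None:
    """Overwrite ``intervals`` in place with the event (later-applied wins)."""
    s, e = ev.start_bp, ev.end_bp
    out: list[tuple[int, int, int, float]] = []
    for a, b, st, t in intervals:
        if b < s or a > e:  # disjoint
            out.append((a, b, st, t))
            continue
        if a < s:
            out.append((a, s - 1, st, t))
        if b > e:
            out.append((e + 1, b, st, t))
    out.append((s, e, int(ev.true_state), ev.true_log2))
    out.sort()
    intervals[:] = out


def _truth_map(events: list[SimEvent]) -> TruthMap:
    m: TruthMap = {}
    for ev in events:
        m.setdefault(ev.chromosome, [])
        _overlay(m[ev.chromosome], ev)
    return m


def _probe_truth(grid: GenomeGrid, truth: TruthMap) -> np.ndarray:
    """True log2 per probe (0 outside events)."""
    t = np.zeros(grid.n_probes)
    for c, ivals in truth.items():
        if c not in grid.chromosome_list:
            continue
        sl = grid.chrom_slice(c)
        pos = grid.positions[sl]
        for a, b, _st, val in ivals:
            lo = int(np.searchsorted(pos, a, side="left"))
            hi = int(np.searchsorted(pos, b, side="right"))
            t[sl.start + lo : sl.start + hi] = val
    return t


@dataclass
class SimTruth:
    """Ground truth of one simulated cohort: resolved event maps per sample."""

    params: SimParams
    chromosome_lengths: dict[str, int]
    events: dict[str, list[SimEvent]]  # sample_id -> raw events in application order
    maps: dict[str, TruthMap]  # sample_id -> resolved interval map
    pairs: dict[str, tuple[str, list[str]]]  # patient_id -> (primary_id, met ids)
    cellularity: dict[str, float]


def _sample_event(
    rng: np.random.Generator, params: SimParams, origin: str
) -> SimEvent:
    chrom = str(rng.choice(list(params.chromosome_lengths)))
    length = params.chromosome_lengths[chrom]
    if rng.random() < params.arm_level_probability:
        # arm-level: one half of the chromosome
        mid = length // 2
        s, e = (1, mid) if rng.random() < 0.5 else (mid + 1, length)
    else:
        ev_len = int(rng.integers(params.focal_length_bp[0], params.focal_length_bp[1] + 1))
        ev_len = min(ev_len, length)
        s = int(rng.integers(1, length - ev_len + 2))
        e = s + ev_len - 1
    u = rng.random()
    if u < params.focal_amp_probability:
        state = CallState.AMP
    elif u < params.focal_amp_probability + params.homdel_probability:
        state = CallState.HOMDEL
    elif rng.random() < 0.5:
        state = CallState.GAIN
    else:
        state = CallState.LOSS
    return SimEvent(chrom, s, e, state, _STATE_LOG2[state], origin)


def _count(rng: np.random.Generator, rng_range: tuple[int, int]) -> int:
    return int(rng.integers(rng_range[0], rng_range[1] + 1))


def generate_cohort(params: SimParams) -> tuple[list[PairedCase], SimTruth]:
    """Simulate a matched-pair cohort; identical params (incl. seed) give
    bit-identical output."""
    rng = np.random.default_rng(params.seed)
    grid = GenomeGrid.uniform(params.chromosome_lengths, params.spacing_bp)

    cases: list[PairedCase] = []
    events: dict[str, list[SimEvent]] = {}
    maps: dict[str, TruthMap] = {}
    pairs: dict[str, tuple[str, list[str]]] = {}
    cellularities: dict[str, float] = {}
    c_lo, c_hi = params.cellularity_range

    for i in range(params.n_patients):
        pid = f"case{i + 1:02d}"
        ancestral = [
            _sample_event(rng, params, "ancestral")
            for _ in range(_count(rng, params.shared_event_count))
        ]
        n_mets = 2 if rng.random() < params.two_site_probability else 1
        sites = [str(s) for s in rng.choice(
            ["liver", "lung", "ovary", "omentum", "lymph_node"], size=n_mets, replace=False
        )]

        def _make(sample_id: str, role: str, site: str, private: list[SimEvent]) -> RatioProfile:
            evs = ancestral + private
            events[sample_id] = evs
            maps[sample_id] = _truth_map(evs)
            t = _probe_truth(grid, maps[sample_id])
            c = float(rng.uniform(c_lo, c_hi))
            cellularities[sample_id] = c
            y = np.log2(c * np.exp2(t) + (1 - c))
            if params.noise_sd > 0:
                y = y + rng.normal(0.0, params.noise_sd, size=grid.n_probes)
            return RatioProfile(sample_id, role, site, grid, y, cellularity=c)

        p_private = [
            _sample_event(rng, params, "primary_private")
            for _ in range(_count(rng, params.private_event_count))
        ]
        primary = _make(f"p{i + 1:02d}", "primary", "none", p_private)

        mets: list[RatioProfile] = []
        for k in range(n_mets):
            m_private = [
                _sample_event(rng, params, "metastasis_private")
                for _ in range(_count(rng, params.private_event_count))
            ]
            if i < params.coamp_patients:
                for chrom, s, e in (params.coamp_locus_a, params.coamp_locus_b):
                    m_private.append(
                        SimEvent(chrom, s, e, CallState.AMP, LOG2_COAMP, "metastasis_private")
                    )
            suffix = "" if n_mets == 1 else "ab"[k]
            mets.append(_make(f"m{i + 1:02d}{suffix}", "metastasis", sites[k], m_private))

        cases.append(PairedCase(pid, primary, mets))
        pairs[pid] = (primary.sample_id, [m.sample_id for m in mets])

    truth = SimTruth(params, dict(params.chromosome_lengths), events, maps, pairs, cellularities)
    return cases, truth


# ---------------------------------------------------------------------------
# exact expected concordance from the event maps (noise-free, per-bp)


def _merged_states(
    ivals_a: list[tuple[int, int, int, float]],
    ivals_b: list[tuple[int, int, int, float]],
    length: int,
) -> int:
    """bp on one chromosome where the two three-state truths agree."""
    bps = {1, length + 1}
    for ivals in (ivals_a, ivals_b):
        for a, b, _s, _t in ivals:
            bps.add(a)
            bps.add(b + 1)
    cuts = sorted(bps)

    def state_at(ivals: list[tuple[int, int, int, float]], x: int) -> int:
        for a, b, s, _t in ivals:
            if a <= x <= b:
                return int(np.sign(s))
        return 0

    agree = 0
    for a, b in zip(cuts[:-1], cuts[1:]):
        if state_at(ivals_a, a) == state_at(ivals_b, a):
            agree += b - a
    return agree


def expected_concordance(truth: SimTruth, patient_id: str, metastasis_index: int = 0) -> float:
    """Exact three-state genome concordance (%) of a pair, from events alone.

    Computed at bp resolution on the true (noise-free) event maps; this is
    the oracle value the pipeline estimate is expected to recover.
    """
    if patient_id not in truth.pairs:
        raise KeyError(f"unknown patient {patient_id!r}")
    p_id, met_ids = truth.pairs[patient_id]
    m_id = met_ids[metastasis_index]
    total = sum(truth.chromosome_lengths.values())
    agree = 0
    for c, length in truth.chromosome_lengths.items():
        agree += _merged_states(
            truth.maps[p_id].get(c, []), truth.maps[m_id].get(c, []), length
        )
    return 100.0 * agree / total


# ---------------------------------------------------------------------------
# FISH fixture generator


def generate_fish_counts(
    amplified: bool,
    n_cells: int = 40,
    seed: int | np.random.Generator = 0,
    sample_id: str = "synthetic",
    locus: str = "synthetic-locus",
) -> FISHAssay:
    """Per-cell locus/centromere signal counts for the FISH scoring rule.

    Amplified samples carry a subpopulation (~30% of cells) with a
    locus/centromere ratio far above 3; non-amplified samples have ratios
    near 1 everywhere, so the >3-ratio-in->=10%-of-cells rule separates the
    two by construction.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    centromere = rng.integers(2, 4, size=n_cells)
    if amplified:
        amp_cell = rng.random(n_cells) < 0.3
        # guarantee the >=10% qualifying fraction even at small n
        need = int(np.ceil(0.1 * n_cells))
        if amp_cell.sum() < need:
            amp_cell[rng.choice(n_cells, size=need, replace=False)] = True
        locus_counts = np.where(
            amp_cell, centromere * rng.integers(5, 15, size=n_cells), centromere
        )
    else:
        locus_counts = centromere + rng.integers(-1, 2, size=n_cells)
        locus_counts = np.maximum(locus_counts, 1)
    return FISHAssay(
        sample_id=sample_id,
        locus=locus,
        locus_signals=locus_counts.astype(int),
        centromere_signals=centromere.astype(int),
    )


# ---------------------------------------------------------------------------
# on-disk cohort


def write_cohort(cases: list[PairedCase], truth: SimTruth, outdir: str | Path) -> Path:
    """Write per-sample probe tables, a manifest TSV and a truth JSON."""
    from .io import write_probe_table  # local import to avoid a cycle

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for case in cases:
        for prof in case.samples:
            path = outdir / f"{prof.sample_id}.tsv"
            write_probe_table(prof, path)
            rows.append(
                (case.patient_id, prof.sample_id, prof.role, prof.site,
                 f"{prof.cellularity:.4f}", path.name)
            )
    with open(outdir / "manifest.tsv", "w") as fh:
        fh.write("patient_id\tsample_id\trole\tsite\tcellularity\tpath\n")
        for r in rows:
            fh.write("\t".join(map(str, r)) + "\n")
    truth_json = {
        "chromosome_lengths": truth.chromosome_lengths,
        "pairs": {k: {"primary": v[0], "metastases": v[1]} for k, v in truth.pairs.items()},
        "maps": {
            sid: {c: [[a, b, s, t] for a, b, s, t in ivals] for c, ivals in m.items()}
            for sid, m in truth.maps.items()
        },
        "cellularity": truth.cellularity,
    }
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth_json, fh)
    return outdir / "manifest.tsv"
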