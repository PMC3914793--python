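"""Probe-table / manifest I/O, median normalization and cellularity correction.

File dialect: UTF-8 tab-delimited text with a header line; lines starting
with ``#`` are comments. Probe tables carry columns
``probe_id, chromosome, position, log2``; a cohort manifest lists
``patient_id, sample_id, role, site, cellularity, path``.
"""

from __future__ import annotations

import io as _io
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    CallState,
    CalledProfile,
    GenomeGrid,
    PairedCase,
    RatioProfile,
    Segment,
    SegmentedProfile,
    grids_equal,
    three_state,
    _CHROM_RANK,
    _normalize_chrom,
)

__all__ = [
    "read_probe_table",
    "write_probe_table",
    "read_manifest",
    "median_normalize",
    "correct_cellularity",
    "mixture_forward",
    "write_seg",
    "read_seg",
    "write_bed",
]

#: floor applied to the inferred tumor ratio during cellularity inversion,
#: so that near-zero or negative intermediate ratios (deep deletions in
#: impure tissue plus noise) stay finite on the log scale.
CELLULARITY_FLOOR = 2.0 ** -8


# ---------------------------------------------------------------------------
# probe tables


def _grid_from_table(df: pd.DataFrame, chromosome_lengths: dict[str, int] | None) -> GenomeGrid:
    if chromosome_lengths is None:
        # infer: last probe position plus the chromosome's median spacing
        chromosome_lengths = {}
        for c, grp in df.groupby("chromosome", sort=False):
            pos = np.sort(grp["position"].to_numpy())
            pad = int(np.median(np.diff(pos))) if len(pos) > 1 else int(pos[0])
            chromosome_lengths[c] = int(pos[-1]) + max(pad // 2, 1)
    return GenomeGrid(
        df["probe_id"].to_numpy(object),
        df["chromosome"].to_numpy(object),
        df["position"].to_numpy(np.int64),
        chromosome_lengths,
    )


def read_probe_table(
    source: str | Path | _io.IOBase,
    grid: GenomeGrid | None = None,
    *,
    sample_id: str | None = None,
    role: str = "primary",
    site: str = "none",
    cellularity: float = 1.0,
    chromosome_lengths: dict[str, int] | None = None,
) -> RatioProfile:
    """Read one sample's probe table into a :class:`RatioProfile`.

    Rows need not be sorted; they are reordered into genome order on load.
    Unparseable log2 entries (``NA``, empty, non-numeric) become missing
    values. When ``grid`` is given, the table's probe set must match it
    exactly; otherwise a grid is built from the table (lengths inferred
    from probe spacing unless ``chromosome_lengths`` is supplied).
    """
    df = pd.read_csv(
        source, sep="\t", comment="#",
        dtype={"probe_id": str, "chromosome": str},
    )
    required = {"probe_id", "chromosome", "position", "log2"}
    if missing := required - set(df.columns):
        raise ValueError(f"probe table missing column(s): {sorted(missing)}")
    if df.empty:
        raise ValueError("empty probe table")
    df["chromosome"] = df["chromosome"].map(_normalize_chrom)
    df["position"] = df["position"].astype(np.int64)
    df["log2"] = pd.to_numeric(df["log2"], errors="coerce")
    df = df.sort_values(
        by=["chromosome", "position"],
        key=lambda s: s.map(_CHROM_RANK) if s.name == "chromosome" else s,
        kind="mergesort",
    ).reset_index(drop=True)
    dup = df.duplicated(subset=["chromosome", "position"])
    if dup.any():
        r = df[dup].iloc[0]
        raise ValueError(
            f"duplicate probe position {r.chromosome}:{r.position} in probe table"
        )

    if grid is None:
        grid = _grid_from_table(df, chromosome_lengths)
        log2 = df["log2"].to_numpy(float)
    else:
        if len(df) != grid.n_probes:
            raise ValueError(
                f"probe table has {len(df)} probes but cohort grid has {grid.n_probes}"
            )
        same = (df["chromosome"].to_numpy(object) == grid.chromosomes) & (
            df["position"].to_numpy(np.int64) == grid.positions
        )
        if not same.all():
            i = int(np.nonzero(~same)[0][0])
            raise ValueError(
                f"probe table inconsistent with cohort grid at index {i}: "
                f"table has {df.chromosome[i]}:{df.position[i]}, grid has "
                f"{grid.chromosomes[i]}:{grid.positions[i]}"
            )
        log2 = df["log2"].to_numpy(float)

    sid = sample_id or (str(source) if not hasattr(source, "read") else "sample")
    return RatioProfile(sid, role, site, grid, log2, cellularity=cellularity)


def write_probe_table(profile: RatioProfile, sink: str | Path | _io.IOBase) -> None:
    """Write a probe table (missing values as ``NA``)."""
    g = profile.grid
    df = pd.DataFrame(
        {
            "probe_id": g.probe_ids,
            "chromosome": g.chromosomes,
            "position": g.positions,
            "log2": [f"{x:.6f}" if np.isfinite(x) else "NA" for x in profile.log2],
        }
    )
    df.to_csv(sink, sep="\t", index=False)


def read_manifest(
    path: str | Path, chromosome_lengths: dict[str, int] | None = None
) -> tuple[list[PairedCase], GenomeGrid]:
    """Read a cohort manifest and all its probe tables into paired cases.

    The first sample read defines the cohort grid; every other table must
    match it. Each patient must have exactly one primary and >=1 metastasis.
    """
    path = Path(path)
    man = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if man["sample_id"].duplicated().any():
        raise ValueError("manifest sample_ids are not unique")
    grid: GenomeGrid | None = None
    cases: list[PairedCase] = []
    for patient, grp in man.groupby("patient_id", sort=False):
        primary = None
        mets = []
        for row in grp.itertuples():
            prof = read_probe_table(
                path.parent / row.path,
                grid,
                sample_id=row.sample_id,
                role=row.role,
                site=row.site,
                cellularity=float(row.cellularity),
                chromosome_lengths=chromosome_lengths,
            )
            if grid is None:
                grid = prof.grid
            if row.role == "primary":
                if primary is not None:
                    raise ValueError(f"patient {patient} has more than one primary")
                primary = prof
            else:
                mets.append(prof)
        if primary is None:
            raise ValueError(f"patient {patient} has no primary sample")
        cases.append(PairedCase(str(patient), primary, mets))
    assert grid is not None
    return cases, grid


# ---------------------------------------------------------------------------
# normalization and cellularity


def median_normalize(profile: RatioProfile) -> RatioProfile:
    """Center the profile on the median of all non-missing log2 ratios.

    The median is taken over every probe of the grid (chromosomes 1-22 and
    X alike); the returned profile has median exactly 0. Idempotent.
    """
    finite = np.isfinite(profile.log2)
    if not finite.any():
        raise ValueError(f"sample {profile.sample_id}: all log2 values missing")
    med = float(np.median(profile.log2[finite]))
    return replace(profile, log2=profile.log2 - med)


def mixture_forward(log2_tumor: np.ndarray | float, c: float) -> np.ndarray | float:
    """Observed log2 ratio of a tumor signal diluted to cellularity ``c``."""
    return np.log2(c * np.exp2(log2_tumor) + (1.0 - c))


def correct_cellularity(
    log2_obs: np.ndarray | float, c: float, floor: float = CELLULARITY_FLOOR
) -> np.ndarray | float:
    """Invert normal-cell admixture: recover the tumor-cell log2 ratio.

    Solves ``2**obs = c * 2**t + (1 - c)`` for ``t``; the inferred tumor
    ratio is floored at ``floor`` (default 2**-8) so that observations
    below the admixture baseline stay finite. ``c = 1`` is the identity.
    """
    if not (0 < c <= 1):
        raise ValueError(f"cellularity must be in (0, 1], got {c}")
    ratio = (np.exp2(log2_obs) - (1.0 - c)) / c
    return np.log2(np.maximum(ratio, floor))


# ---------------------------------------------------------------------------
# SEG / BED


def write_seg(segprofile: SegmentedProfile, sink: str | Path | _io.IOBase) -> None:
    """Write standard SEG (sample, chrom, start, end, num_probes, seg_mean);
    1-based inclusive coordinates."""
    rows = [
        (segprofile.sample_id, s.chromosome, s.start_bp, s.end_bp, s.n_probes,
         f"{s.mean_log2:.4f}")
        for s in segprofile.segments
    ]
    pd.DataFrame(
        rows, columns=["sample", "chrom", "start", "end", "num_probes", "seg_mean"]
    ).to_csv(sink, sep="\t", index=False)


def read_seg(source: str | Path | _io.IOBase, grid: GenomeGrid) -> SegmentedProfile:
    """Read a SEG file written by :func:`write_seg` back onto its grid."""
    df = pd.read_csv(source, sep="\t", comment="#", dtype={"chrom": str})
    segs = []
    for row in df.itertuples():
        chrom = _normalize_chrom(row.chrom)
        sl = grid.chrom_slice(chrom)
        pos = grid.positions[sl]
        first = sl.start + int(np.searchsorted(pos, row.start, side="left"))
        last = sl.start + int(np.searchsorted(pos, row.end, side="right")) - 1
        segs.append(Segment(chrom, int(row.start), int(row.end), first, last,
                            float(row.seg_mean)))
    sample = str(df["sample"].iloc[0]) if len(df) else "sample"
    return SegmentedProfile.from_segments(sample, grid, segs)


def write_bed(
    called: CalledProfile, sink: str | Path | _io.IOBase, include_neutral: bool = False
) -> None:
    """Write calls as BED4+score: 0-based half-open, state name, state value.

    NEUTRAL segments are omitted unless ``include_neutral`` is set.
    """
    lines = []
    for seg, state in zip(called.segments, called.per_segment_state):
        st = CallState(int(state))
        if st == CallState.NEUTRAL and not include_neutral:
            continue
        lines.append(f"{seg.chromosome}\t{seg.start_bp - 1}\t{seg.end_bp}\t{st.name}\t{int(st)}")
    text = "\n".join(lines) + ("\n" if lines else "")
    if hasattr(sink, "write"):
        sink.write(text)
    else:
        Path(sink).write_text(text)
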