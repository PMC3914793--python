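"""Paired metastasis-minus-primary difference analysis with a GISTIC-style
G score and permutation FDR, plus a group-level frequency comparison.

For every metastasis the segmented log2 ratios of its matched primary are
subtracted per probe, giving one difference profile per metastasis. The
G score at marker ``j`` aggregates frequency and amplitude of recurrent
differences across the cohort:

    higher:  G_j = sum_i max(0, d_ij - theta)
    lower:   G_j = sum_i max(0, -d_ij - theta)

with exceedance threshold ``theta`` (default 0.2, the gain/loss calling
cut-off magnitude). Significance comes from a permutation null that
cyclically shifts each sample's difference vector by an independent random
offset — preserving every sample's segmental autocorrelation while
destroying cross-sample positional alignment. Marker p-values pool all
permuted G values over all markers; Benjamini-Hochberg control across
markers gives q-values, and peaks are maximal runs of contiguous markers
with q below the FDR level (runs never span chromosomes), each annotated
with its maximal-G core.

The group-level comparison tests, per probe and per aberration type, a
2x2 table of aberration frequency (Fisher's exact test) between the
primary and metastasis groups, again with BH correction across probes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

from .core import CalledProfile, GenomeGrid, PairedCase, SegmentedProfile, three_state_array

__all__ = [
    "DifferenceProfile",
    "GScorePeak",
    "difference_profiles",
    "gscore",
    "group_frequency_comparison",
]


@dataclass
class DifferenceProfile:
    """Per-probe segmented log2 difference, metastasis minus primary."""

    patient_id: str
    sample_id: str  # the metastasis
    d: np.ndarray  # NaN where either sample is unobserved


def difference_profiles(
    cases: list[PairedCase], segmented: dict[str, SegmentedProfile]
) -> list[DifferenceProfile]:
    """One difference vector per metastasis (not per patient).

    Probes missing in either sample (NaN in a segmented per-probe mean,
    which only happens when a whole chromosome was unobserved) propagate
    as NaN and are masked downstream.
    """
    out = []
    for case in cases:
        if case.primary.sample_id not in segmented:
            raise KeyError(f"patient {case.patient_id}: primary profile not segmented")
        p = segmented[case.primary.sample_id].per_probe_mean
        for met in case.metastases:
            if met.sample_id not in segmented:
                raise KeyError(
                    f"patient {case.patient_id}: metastasis {met.sample_id} not segmented"
                )
            m = segmented[met.sample_id].per_probe_mean
            out.append(DifferenceProfile(case.patient_id, met.sample_id, m - p))
    return out


@dataclass
class GScorePeak:
    """A contiguous genomic run of markers significant at the FDR level."""

    chromosome: str
    start_bp: int
    end_bp: int
    direction: str  # "higher" | "lower"
    G: float  # maximum G inside the run
    p_empirical: float  # minimum marker p inside the run
    q_fdr: float  # minimum marker q inside the run
    core_start_bp: int  # maximal-G core of the run
    core_end_bp: int


def _g_vector(d: np.ndarray, theta: float, direction: str) -> np.ndarray:
    if direction == "higher":
        exc = d - theta
    elif direction == "lower":
        exc = -d - theta
    else:
        raise ValueError(f"direction must be 'higher' or 'lower', got {direction!r}")
    return np.nansum(np.maximum(exc, 0.0), axis=0)


def gscore(
    differences: list[DifferenceProfile],
    grid: GenomeGrid,
    direction: str = "higher",
    theta: float = 0.2,
    n_permutations: int = 1_000,
    seed: int = 0,
    fdr_level: float = 0.05,
) -> tuple[pd.DataFrame, list[GScorePeak]]:
    """Per-marker G score track with permutation p / BH q, and peak calls.

    Returns ``(track, peaks)``: the track has one row per marker
    (chromosome, position, G, p, q); peaks are maximal runs of contiguous
    markers with ``q < fdr_level`` within one chromosome, with bp bounds
    taken from the run's outer probe intervals and a ``core`` marking the
    contiguous sub-run of near-maximal G (within 5% of the run maximum)
    around the run's argmax.
    """
    if len(differences) < 2:
        raise ValueError("need >= 2 difference profiles")
    if n_permutations < 100:
        import warnings

        warnings.warn(f"n_permutations={n_permutations} is low; p-values will be coarse")
    D = np.vstack([dp.d for dp in differences])
    n, m = D.shape
    g_obs = _g_vector(D, theta, direction)

    # permutation null: per-sample random cyclic shifts of the exceedance
    rng = np.random.default_rng(seed)
    exc = np.maximum((D - theta) if direction == "higher" else (-D - theta), 0.0)
    exc = np.nan_to_num(exc, nan=0.0)
    cols = np.arange(m)
    null = np.zeros((n_permutations, m))
    for i in range(n):
        offsets = rng.integers(0, m, size=n_permutations)
        null += exc[i][(cols[None, :] - offsets[:, None]) % m]
    pool = np.sort(null.ravel())
    # p_j = fraction of pooled permuted G values >= G_j (add-one smoothed)
    exceed = pool.size - np.searchsorted(pool, g_obs - 1e-12, side="left")
    p = (1.0 + exceed) / (pool.size + 1.0)
    q = multipletests(p, method="fdr_bh")[1]

    track = pd.DataFrame(
        {
            "chromosome": grid.chromosomes,
            "position": grid.positions,
            "G": g_obs,
            "p": p,
            "q": q,
        }
    )
    peaks = _call_peaks(track, grid, direction, fdr_level)
    return track, peaks


def _call_peaks(
    track: pd.DataFrame, grid: GenomeGrid, direction: str, fdr_level: float
) -> list[GScorePeak]:
    istart, iend = grid.probe_intervals()
    sig = (track["q"] < fdr_level).to_numpy()
    peaks: list[GScorePeak] = []
    for chrom in grid.chromosome_list:
        sl = grid.chrom_slice(chrom)
        s = sig[sl]
        if not s.any():
            continue
        # maximal runs of consecutive significant markers
        edges = np.diff(np.concatenate(([0], s.view(np.int8), [0])))
        for run_s, run_e in zip(np.nonzero(edges == 1)[0], np.nonzero(edges == -1)[0]):
            lo, hi = sl.start + run_s, sl.start + run_e  # half-open global
            g_run = track["G"].to_numpy()[lo:hi]
            peak_idx = int(np.argmax(g_run))
            near = g_run >= 0.95 * g_run[peak_idx]
            cs = peak_idx
            while cs > 0 and near[cs - 1]:
                cs -= 1
            ce = peak_idx
            while ce < len(near) - 1 and near[ce + 1]:
                ce += 1
            peaks.append(
                GScorePeak(
                    chromosome=chrom,
                    start_bp=int(istart[lo]),
                    end_bp=int(iend[hi - 1] - 1),
                    direction=direction,
                    G=float(g_run[peak_idx]),
                    p_empirical=float(track["p"].to_numpy()[lo:hi].min()),
                    q_fdr=float(track["q"].to_numpy()[lo:hi].min()),
                    core_start_bp=int(istart[lo + cs]),
                    core_end_bp=int(iend[lo + ce] - 1),
                )
            )
    return peaks


def group_frequency_comparison(
    primary_calls: list[CalledProfile],
    metastasis_calls: list[CalledProfile],
    fdr_level: float = 0.05,
) -> pd.DataFrame:
    """Per-probe Fisher exact comparison of aberration frequency between groups.

    For each probe and each aberration type (gain, loss, on the three-state
    collapse), tests the 2x2 table [aberrant vs not] x [primary vs
    metastasis]; BH correction runs across probes within each type.
    Returns a per-probe table with counts, p and q per type.
    """
    if not primary_calls or not metastasis_calls:
        raise ValueError("both groups must be non-empty")
    grid = primary_calls[0].grid
    P = np.vstack([three_state_array(c.per_probe_state) for c in primary_calls])
    M = np.vstack([three_state_array(c.per_probe_state) for c in metastasis_calls])
    n_p, n_m = P.shape[0], M.shape[0]
    out = {"chromosome": grid.chromosomes, "position": grid.positions}
    cache: dict[tuple[int, int, int, int], float] = {}
    for name, state in (("gain", 1), ("loss", -1)):
        a = (P == state).sum(axis=0)
        b = (M == state).sum(axis=0)
        pvals = np.empty(grid.n_probes)
        for j in range(grid.n_probes):
            key = (int(a[j]), n_p - int(a[j]), int(b[j]), n_m - int(b[j]))
            if key not in cache:
                cache[key] = fisher_exact([[key[0], key[1]], [key[2], key[3]]])[1]
            pvals[j] = cache[key]
        q = multipletests(pvals, method="fdr_bh")[1]
        out[f"{name}_primary"] = a
        out[f"{name}_metastasis"] = b
        out[f"{name}_p"] = pvals
        out[f"{name}_q"] = q
        out[f"{name}_significant"] = q < fdr_level
    return pd.DataFrame(out)
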