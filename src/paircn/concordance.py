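"""Pairwise genome concordance of matched called profiles.

Concordance is the percent of the analysed genome on which a metastasis
and its matched primary carry the same three-state call (gain, loss or
normal). The comparison overlays the union of both samples' segment
boundaries; because calls are constant within segments and probe bp
intervals tile each chromosome, this equals a bp-weighted comparison of
per-probe three-state calls, which is how it is computed. Probes missing
in either sample are excluded from numerator and denominator alike.

Cohort pairs are reported in three bins — above 95%, 70-95% (boundaries
inclusive), below 70% — together with per-bin medians and ranges.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calling import percent_aberrant
from .core import CalledProfile, grids_equal, three_state_array

__all__ = ["ConcordanceResult", "pair_concordance", "bin_concordance", "cohort_summary"]

BIN_LABELS = ("gt95", "b70_95", "lt70")


@dataclass
class ConcordanceResult:
    """Concordance of one metastasis against its matched primary."""

    patient_id: str
    sample_id: str  # the metastasis
    site: str
    percent_same: float
    bin: str
    percent_aberrant_primary: float
    percent_aberrant_metastasis: float


def pair_concordance(
    called_p: CalledProfile,
    called_m: CalledProfile,
    missing: np.ndarray | None = None,
    five_state: bool = False,
) -> float:
    """Percent of analysed bp where two called profiles agree.

    ``missing`` optionally marks probes (boolean, grid-aligned) to exclude
    from both numerator and denominator, e.g. probes unobserved in either
    underlying sample. ``five_state=True`` compares the full five-state
    calls instead of the three-state collapse.
    """
    if not grids_equal(called_p.grid, called_m.grid):
        raise ValueError("profiles are on different grids")
    if five_state:
        a, b = called_p.per_probe_state, called_m.per_probe_state
    else:
        a = three_state_array(called_p.per_probe_state)
        b = three_state_array(called_m.per_probe_state)
    w = called_p.grid.probe_weights_bp().astype(float)
    if missing is not None:
        w = np.where(np.asarray(missing, bool), 0.0, w)
    total = w.sum()
    if total <= 0:
        raise ValueError("no analysable probes left after exclusions")
    return 100.0 * float(w[a == b].sum()) / float(total)


def bin_concordance(percent: float) -> str:
    """Histogram bin of a concordance value: >95 / 70-95 (inclusive) / <70."""
    if percent > 95.0:
        return "gt95"
    if percent >= 70.0:
        return "b70_95"
    return "lt70"


def case_concordance(
    patient_id: str,
    primary_called: CalledProfile,
    met_called: CalledProfile,
    site: str,
    missing: np.ndarray | None = None,
) -> ConcordanceResult:
    """Assemble the full per-pair record, including aberrant-genome fractions."""
    pct = pair_concordance(primary_called, met_called, missing=missing)
    return ConcordanceResult(
        patient_id=patient_id,
        sample_id=met_called.sample_id,
        site=site,
        percent_same=pct,
        bin=bin_concordance(pct),
        percent_aberrant_primary=percent_aberrant(primary_called),
        percent_aberrant_metastasis=percent_aberrant(met_called),
    )


def cohort_summary(results: list[ConcordanceResult]) -> dict:
    """Per-bin counts/medians/ranges plus cohort medians of aberrant genome.

    Also returns the raw per-pair table (as a DataFrame) for plotting the
    concordance histogram; site strata with no pairs are simply absent.
    """
    if not results:
        raise ValueError("no concordance results to summarize")
    df = pd.DataFrame([vars(r) for r in results])
    bins = {}
    for label in BIN_LABELS:
        vals = df.loc[df["bin"] == label, "percent_same"]
        bins[label] = {
            "count": int(len(vals)),
            "median": float(vals.median()) if len(vals) else None,
            "range": [float(vals.min()), float(vals.max())] if len(vals) else None,
        }
    by_site = {
        site: {"count": int(len(g)), "median": float(g["percent_same"].median())}
        for site, g in df.groupby("site")
        if len(g)
    }
    return {
        "n_pairs": int(len(df)),
        "median_percent_same": float(df["percent_same"].median()),
        "bins": bins,
        "by_site": by_site,
        "median_percent_aberrant_primary": float(df["percent_aberrant_primary"].median()),
        "median_percent_aberrant_metastasis": float(df["percent_aberrant_metastasis"].median()),
        "table": df,
    }
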