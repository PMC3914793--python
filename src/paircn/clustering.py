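"""Hierarchical clustering of segmented profiles with Spearman distance.

The distance between two samples is ``1 - rho`` where ``rho`` is the
Spearman rank correlation of their segmented per-probe means, so the
clustering sees the same piecewise-constant signal the rest of the
pipeline does and is invariant to monotone transforms of each profile.
Agglomeration is standard scipy linkage (average by default).

The pairwise-joining diagnostic asks, for every matched primary/metastasis
pair, whether the two samples are joined before any other patient's sample
enters their cluster ("joined pairwise"); when they are not, the number of
foreign samples lying strictly between them in the dendrogram leaf order
is reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy.stats import spearmanr

from .core import SegmentedProfile

__all__ = [
    "Dendrogram",
    "PairJoinReport",
    "spearman_distance_matrix",
    "hierarchical_cluster",
    "pair_adjacency",
]


def spearman_distance_matrix(profiles: list[SegmentedProfile]) -> pd.DataFrame:
    """Pairwise ``1 - Spearman rho`` of segmented per-probe mean vectors.

    Values lie in [0, 2] with a zero diagonal. A profile with zero
    variance (a flat genome) has undefined rank correlations and is
    rejected by name.
    """
    if len(profiles) < 2:
        raise ValueError("need at least 2 profiles to build a distance matrix")
    labels = [p.sample_id for p in profiles]
    mat = np.column_stack([p.per_probe_mean for p in profiles])
    for j, p in enumerate(profiles):
        col = mat[:, j]
        col = col[np.isfinite(col)]
        if len(col) == 0 or np.all(col == col[0]):
            raise ValueError(
                f"sample {p.sample_id} has zero variance; Spearman correlation undefined"
            )
    rho = spearmanr(mat, nan_policy="omit").statistic
    if np.ndim(rho) == 0:  # scipy collapses the 2-sample case to a scalar
        rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
    d = 1.0 - rho
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0  # enforce exact symmetry against fp jitter
    return pd.DataFrame(d, index=labels, columns=labels)


@dataclass
class Dendrogram:
    """Agglomerative merge tree over sample leaves."""

    labels: list[str]
    linkage_matrix: np.ndarray  # scipy (n-1, 4) format
    method: str

    @property
    def leaf_order(self) -> list[str]:
        return [self.labels[i] for i in hierarchy.leaves_list(self.linkage_matrix)]

    def to_newick(self) -> str:
        """Newick string with branch lengths derived from merge heights."""
        tree = hierarchy.to_tree(self.linkage_matrix)

        def rec(node, parent_height: float) -> str:
            length = max(parent_height - node.dist, 0.0)
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:.6g}"
            left = rec(node.left, node.dist)
            right = rec(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        return rec(tree, tree.dist) + ";"


def hierarchical_cluster(
    distance: pd.DataFrame, linkage: str = "average"
) -> Dendrogram:
    """Agglomerative clustering of a symmetric distance matrix.

    ``linkage`` is one of ``average`` (default), ``complete``, ``single``.
    """
    if linkage not in ("average", "complete", "single"):
        raise ValueError(f"unsupported linkage {linkage!r}")
    d = np.asarray(distance, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    if np.any(d < 0):
        raise ValueError("distances must be non-negative")
    Z = hierarchy.linkage(squareform(d, checks=False), method=linkage)
    return Dendrogram(list(distance.index), Z, linkage)


@dataclass
class PairJoinReport:
    """Pairwise-joining diagnostics for every primary/metastasis pair."""

    table: pd.DataFrame  # patient_id, primary, metastasis, joined_pairwise, leaves_between

    @property
    def fraction_joined(self) -> float:
        return float(self.table["joined_pairwise"].mean())


def _merge_members(Z: np.ndarray, n: int) -> list[set[int]]:
    """Leaf sets of every internal node of a scipy linkage matrix."""
    members: dict[int, set[int]] = {i: {i} for i in range(n)}
    out = []
    for i, (a, b, _h, _c) in enumerate(Z):
        s = members[int(a)] | members[int(b)]
        members[n + i] = s
        out.append(s)
    return out


def pair_adjacency(
    dendrogram: Dendrogram, pairs: dict[str, tuple[str, list[str]]]
) -> PairJoinReport:
    """Evaluate pairwise joining of matched samples in the dendrogram.

    ``pairs`` maps patient_id -> (primary sample_id, metastasis sample_ids).
    A pair is ``joined_pairwise`` when the smallest cluster containing both
    samples contains only that patient's samples (so a patient's two
    metastases merging first still counts). Otherwise ``leaves_between``
    counts other patients' samples strictly between the two leaves in the
    dendrogram leaf order.
    """
    idx = {lab: i for i, lab in enumerate(dendrogram.labels)}
    patient_of: dict[int, str] = {}
    for patient, (p_id, met_ids) in pairs.items():
        for sid in [p_id, *met_ids]:
            if sid not in idx:
                raise ValueError(f"sample {sid} missing from dendrogram")
            patient_of[idx[sid]] = patient
    merges = _merge_members(dendrogram.linkage_matrix, len(dendrogram.labels))
    order = dendrogram.leaf_order
    pos = {lab: i for i, lab in enumerate(order)}

    rows = []
    for patient, (p_id, met_ids) in pairs.items():
        for m_id in met_ids:
            a, b = idx[p_id], idx[m_id]
            smallest = next(s for s in merges if a in s and b in s)
            joined = all(patient_of.get(i) == patient for i in smallest)
            lo, hi = sorted((pos[p_id], pos[m_id]))
            between = [
                order[i] for i in range(lo + 1, hi)
                if patient_of.get(idx[order[i]]) != patient
            ]
            rows.append(
                dict(patient_id=patient, primary=p_id, metastasis=m_id,
                     joined_pairwise=bool(joined),
                     leaves_between=0 if joined else len(between))
            )
    return PairJoinReport(pd.DataFrame(rows))
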