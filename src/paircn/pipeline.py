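"""End-to-end orchestration: cohort -> preprocess -> segment -> call ->
concordance / clustering / difference significance / co-amp screen.

One :class:`RunConfig` drives the whole run; every stage's randomness is
derived from the single config seed via named substreams, so a run is
reproducible bit-for-bit. Parameters the upstream literature leaves
unstated (segmentation alpha, linkage, exceedance threshold theta, bin
boundary convention) are logged at INFO for every run.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .amplification import cohort_coamp_screen
from .calling import CallThresholds, call_segments
from .clustering import hierarchical_cluster, pair_adjacency, spearman_distance_matrix
from .concordance import case_concordance, cohort_summary
from .core import PairedCase
from .io import median_normalize, read_manifest, write_seg
from .segmentation import SegmentationParams, segment
from .significance import difference_profiles, group_frequency_comparison, gscore
from .simulate import SimParams, generate_cohort

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Everything one pipeline run needs; validated before any stage runs."""

    seed: int = 0
    manifest: str | None = None  # read a cohort from disk ...
    simulation: SimParams | dict | None = None  # ... or simulate one
    segmentation: SegmentationParams | dict = field(default_factory=SegmentationParams)
    thresholds: CallThresholds | dict = field(default_factory=CallThresholds)
    linkage: str = "average"
    theta: float = 0.2
    gscore_permutations: int = 1_000
    fdr_level: float = 0.05
    coamp_locus_a: tuple[str, int, int] = ("6", 1_000_000, 1_150_000)
    coamp_locus_b: tuple[str, int, int] = ("8", 1_200_000, 1_350_000)
    site_stratified: bool = True
    cellularity_stage: str = "calling"  # "calling" | "probes"
    outdir: str | None = None

    def __post_init__(self) -> None:
        if isinstance(self.simulation, dict):
            self.simulation = SimParams(**self.simulation)
        if isinstance(self.segmentation, dict):
            self.segmentation = SegmentationParams(**self.segmentation)
        if isinstance(self.thresholds, dict):
            self.thresholds = CallThresholds(**self.thresholds)
        if (self.manifest is None) == (self.simulation is None):
            raise ValueError("exactly one of manifest / simulation must be given")
        if self.linkage not in ("average", "complete", "single"):
            raise ValueError(f"unsupported linkage {self.linkage!r}")
        if self.cellularity_stage not in ("calling", "probes"):
            raise ValueError("cellularity_stage must be 'calling' or 'probes'")
        if self.theta < 0 or not (0 < self.fdr_level < 1):
            raise ValueError("theta must be >= 0 and fdr_level in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        for key in ("coamp_locus_a", "coamp_locus_b"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _substream_seeds(seed: int, n: int) -> list[int]:
    """Named per-stage seeds derived from the single run seed (< 2**31)."""
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages in flowchart order and return the run report.

    The report is a JSON-serializable dict of cohort summaries; when
    ``config.outdir`` is set, per-stage tables (SEG, concordance TSV,
    Newick dendrogram, G-score tracks and peaks, co-amp screen) and the
    report itself are also written there.
    """
    sim_seed, seg_seed, g_seed = _substream_seeds(config.seed, 3)

    # --- cohort -----------------------------------------------------------
    stage = "cohort"
    try:
        if config.simulation is not None:
            params = config.simulation
            if params.seed != sim_seed:
                params = SimParams(**{**asdict(params), "seed": sim_seed})
            cases, truth = generate_cohort(params)
            grid = cases[0].primary.grid
        else:
            cases, grid = read_manifest(config.manifest)
            truth = None
        logger.info(
            "run: alpha=%s linkage=%s theta=%s bins=[>95, 70-95 incl., <70] "
            "cellularity_stage=%s",
            _seg(config).alpha, config.linkage, config.theta, config.cellularity_stage,
        )

        # --- preprocess + segment + call ---------------------------------
        stage = "preprocess"
        from .io import correct_cellularity  # late import keeps module load light

        segmented, called, missing = {}, {}, {}
        seg_params = _seg(config)
        seg_params = SegmentationParams(**{**asdict(seg_params), "seed": seg_seed})
        for case in cases:
            for prof in case.samples:
                stage = f"preprocess:{prof.sample_id}"
                norm = median_normalize(prof)
                if config.cellularity_stage == "probes":
                    norm.log2 = np.asarray(
                        correct_cellularity(norm.log2, norm.cellularity)
                    )
                stage = f"segment:{prof.sample_id}"
                sp = segment(norm, seg_params)
                segmented[prof.sample_id] = sp
                stage = f"call:{prof.sample_id}"
                c = prof.cellularity if config.cellularity_stage == "calling" else 1.0
                called[prof.sample_id] = call_segments(sp, config.thresholds, c)
                missing[prof.sample_id] = ~np.isfinite(prof.log2)

        # --- concordance --------------------------------------------------
        stage = "concordance"
        results = []
        for case in cases:
            for met in case.metastases:
                mask = missing[case.primary.sample_id] | missing[met.sample_id]
                results.append(
                    case_concordance(
                        case.patient_id, called[case.primary.sample_id],
                        called[met.sample_id], met.site, missing=mask,
                    )
                )
        summary = cohort_summary(results)
        conc_table = summary.pop("table")

        # --- clustering -----------------------------------------------------
        stage = "clustering"
        profiles = [segmented[p.sample_id] for case in cases for p in case.samples]
        dist = spearman_distance_matrix(profiles)
        dendro = hierarchical_cluster(dist, config.linkage)
        pairs = {
            case.patient_id: (case.primary.sample_id,
                              [m.sample_id for m in case.metastases])
            for case in cases
        }
        join_report = pair_adjacency(dendro, pairs)

        # --- difference significance ---------------------------------------
        stage = "difference_significance"
        diffs = difference_profiles(cases, segmented)
        gtracks, gpeaks = {}, {}
        for direction in ("higher", "lower"):
            track, peaks = gscore(
                diffs, grid, direction=direction, theta=config.theta,
                n_permutations=config.gscore_permutations, seed=g_seed,
                fdr_level=config.fdr_level,
            )
            gtracks[direction] = track
            gpeaks[direction] = peaks
        site_peaks = {}
        if config.site_stratified:
            site_of = {m.sample_id: m.site for case in cases for m in case.metastases}
            for site in sorted({s for s in site_of.values() if s != "none"}):
                sub = [d for d in diffs if site_of[d.sample_id] == site]
                if len(sub) < 2:
                    continue
                site_peaks[site] = {
                    direction: gscore(
                        sub, grid, direction=direction, theta=config.theta,
                        n_permutations=config.gscore_permutations, seed=g_seed,
                        fdr_level=config.fdr_level,
                    )[1]
                    for direction in ("higher", "lower")
                }
        freq = group_frequency_comparison(
            [called[c.primary.sample_id] for c in cases],
            [called[m.sample_id] for c in cases for m in c.metastases],
            fdr_level=config.fdr_level,
        )

        # --- co-amplification screen ----------------------------------------
        stage = "coamp_screen"
        cellularity = {
            p.sample_id: (p.cellularity if config.cellularity_stage == "calling" else 1.0)
            for case in cases for p in case.samples
        }
        coamp = cohort_coamp_screen(
            segmented, pairs, config.coamp_locus_a, config.coamp_locus_b,
            cellularity=cellularity,
        )

    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    # --- report ------------------------------------------------------------
    def _peak_rows(peaks):
        return [
            dict(chromosome=p.chromosome, start_bp=p.start_bp, end_bp=p.end_bp,
                 direction=p.direction, G=round(p.G, 6), p=p.p_empirical,
                 q=p.q_fdr, core_start_bp=p.core_start_bp, core_end_bp=p.core_end_bp)
            for p in peaks
        ]

    report = {
        "seed": config.seed,
        "n_patients": len(cases),
        "n_metastases": sum(len(c.metastases) for c in cases),
        "parameters": {
            "segmentation_alpha": seg_params.alpha,
            "segmentation_min_probes": seg_params.min_probes_per_segment,
            "linkage": config.linkage,
            "theta": config.theta,
            "thresholds": asdict(config.thresholds),
            "cellularity_stage": config.cellularity_stage,
        },
        "concordance": {k: v for k, v in summary.items()},
        "clustering": {
            "fraction_joined_pairwise": join_report.fraction_joined,
            "n_not_joined": int((~join_report.table["joined_pairwise"]).sum()),
        },
        "gscore_peaks": {d: _peak_rows(gpeaks[d]) for d in gpeaks},
        "gscore_site_peaks": {
            site: {d: _peak_rows(pk) for d, pk in by_dir.items()}
            for site, by_dir in site_peaks.items()
        },
        "group_frequency": {
            "n_gain_significant": int(freq["gain_significant"].sum()),
            "n_loss_significant": int(freq["loss_significant"].sum()),
        },
        "coamp": {
            "n_coamplified_samples": int(coamp["coamp"].sum()),
            "metastasis_specific_samples": sorted(
                coamp.loc[coamp["metastasis_specific"], "sample_id"].tolist()
            ),
        },
    }

    if config.outdir is not None:
        out = Path(config.outdir)
        out.mkdir(parents=True, exist_ok=True)
        seg_dir = out / "segments"
        seg_dir.mkdir(exist_ok=True)
        for sid, sp in segmented.items():
            write_seg(sp, seg_dir / f"{sid}.seg")
        conc_table.to_csv(out / "concordance.tsv", sep="\t", index=False)
        (out / "dendrogram.newick").write_text(dendro.to_newick() + "\n")
        join_report.table.to_csv(out / "pair_join.tsv", sep="\t", index=False)
        for d, track in gtracks.items():
            track.to_csv(out / f"gscore_{d}.tsv", sep="\t", index=False)
        freq.to_csv(out / "group_frequency.tsv", sep="\t", index=False)
        coamp.to_csv(out / "coamp_screen.tsv", sep="\t", index=False)
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)

    report["_objects"] = {
        "cases": cases, "truth": truth, "segmented": segmented, "called": called,
        "concordance_results": results, "dendrogram": dendro,
        "pair_join": join_report, "gscore_tracks": gtracks, "gscore_peaks": gpeaks,
        "group_frequency": freq, "coamp": coamp,
    }
    return report


def _seg(config: RunConfig) -> SegmentationParams:
    assert isinstance(config.segmentation, SegmentationParams)
    return config.segmentation
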