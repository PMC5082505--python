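"""End-to-end orchestration of the three analyses: pairwise DMN-style ROI
tests, the network contrast matrix with segregation, and the graph-metric
threshold sweep.

A run is a pure function of (inputs, configuration, seed): per-subject
connectivity matrices, group-level motion residualization, statistics and
a JSON run log are written under the configured output directory.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import CohortSpec, NetworkPartition, SubjectRecord, \
    generate_cohort, generate_partition
from .confounds import F_HIGH_HZ, F_LOW_HZ, VARIANCE_FRACTION, \
    build_confound_design
from .glm import DEFAULT_HALF_LIVES, ar_family, connectivity_matrix, \
    residualize_motion
from .graphs import DEFAULT_PERCENTILES, graph_summary
from .networks import block_means, lesion_profile, network_contrast_matrix, \
    segregation
from .preprocess import DEFAULT_RADIUS_MM, despike_interpolate, \
    flag_motion_outliers, relative_displacement
from .stats import bonferroni_adjust, pooled_t_covariate
from . import io as lio

__all__ = ["RunConfig", "RunResult", "analyse_cohort", "run_pipeline"]


@dataclass
class RunConfig:
    """Validated configuration of a pipeline run."""

    output_dir: str = "results/run"
    data_dir: str | None = None          # read a written dataset; else simulate
    n_controls: int = 20
    n_patients: int = 6
    seed: int = 0
    TR: float = 2.0
    f_low: float = F_LOW_HZ
    f_high: float = F_HIGH_HZ
    rd_radius: float = DEFAULT_RADIUS_MM
    variance_fraction: float = VARIANCE_FRACTION
    half_lives: tuple[float, ...] = DEFAULT_HALF_LIVES
    percentiles: tuple[int, ...] = DEFAULT_PERCENTILES
    exclude_motion_outliers: bool = False
    despike: bool = False
    despike_z: float = 5.0
    connectivity_method: str = "pooled"
    write_files: bool = True
    write_subject_matrices: bool = True   # bulky at many ROIs; toggleable
    spec: CohortSpec = field(default_factory=CohortSpec)

    def validate(self) -> None:
        if self.n_controls < 4:
            raise ValueError("need >= 4 controls for outlier fences")
        if self.n_patients < 1:
            raise ValueError("need >= 1 patient")
        if not 0 <= self.f_low < self.f_high <= 1 / (2 * self.TR) + 1e-12:
            raise ValueError("invalid band for this TR")
        if self.connectivity_method not in ("pooled", "per-edge"):
            raise ValueError("connectivity_method must be pooled or per-edge")
        if self.rd_radius <= 0 or not 0 < self.variance_fraction <= 1:
            raise ValueError("invalid radius or variance fraction")
        self.spec.validate()

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = lio.read_config(path)
        spec_raw = raw.pop("spec", None)
        cfg = cls(**{k: tuple(v) if isinstance(v, list) else v
                     for k, v in raw.items()})
        if spec_raw:
            cfg.spec = CohortSpec(**{k: tuple(v) if isinstance(v, list) else v
                                     for k, v in spec_raw.items()})
        cfg.validate()
        return cfg


@dataclass
class RunResult:
    subjects: list[SubjectRecord]
    partition: NetworkPartition
    mean_rd: np.ndarray
    outlier_flags: np.ndarray
    conn: list                        # per-subject ConnectivityMatrix
    blocks: np.ndarray                # (n, K, K), motion-residualized
    lesion_profiles: np.ndarray       # (n, K)
    segregation: np.ndarray           # per subject
    pairwise: pd.DataFrame | None     # DMN-style ROI pair tests
    contrast: object                  # ContrastResult
    segregation_test: object          # TestResult
    sweep_tests: pd.DataFrame
    log: dict


def _preprocess(subjects, cfg: RunConfig):
    rd = [relative_displacement(s.motion_params, cfg.rd_radius)
          for s in subjects]
    mean_rd = np.array([r.mean() for r in rd])
    controls = np.array([s.group == "control" for s in subjects])
    flags = flag_motion_outliers(mean_rd[controls], mean_rd)
    return rd, mean_rd, flags


def _subject_connectivity(sub: SubjectRecord, rd: np.ndarray,
                          cfg: RunConfig, family):
    roi = sub.roi_series
    if cfg.despike:
        roi = np.vstack([despike_interpolate(row, cfg.despike_z)
                         for row in roi])
    design = build_confound_design(rd, sub.artifact_series, cfg.TR,
                                   cfg.f_low, cfg.f_high,
                                   cfg.variance_fraction)
    conn = connectivity_matrix(roi, design, family,
                               method=cfg.connectivity_method)
    return conn, design


def analyse_cohort(subjects: list[SubjectRecord],
                   partition: NetworkPartition,
                   cfg: RunConfig) -> RunResult:
    """Run every analysis stage on an in-memory cohort."""
    cfg.validate()
    t0 = time.time()
    rd, mean_rd, flags = _preprocess(subjects, cfg)

    family = ar_family(subjects[0].T, cfg.half_lives)
    conns, designs = [], []
    for sub, r in zip(subjects, rd):
        conn, design = _subject_connectivity(sub, r, cfg, family)
        conns.append(conn)
        designs.append(design)

    use = ~flags if cfg.exclude_motion_outliers else np.ones(len(subjects), bool)
    idx = np.flatnonzero(use)
    groups = np.array([subjects[i].group for i in idx])
    sexes = np.array([subjects[i].sex for i in idx])

    # group-level motion residualization on the edge values
    N = conns[0].n_rois
    iu = np.triu_indices(N, 1)
    edges = np.array([conns[i].z[iu] for i in idx])
    edges_res = residualize_motion(edges, mean_rd[idx])
    zmats = []
    for row in edges_res:
        z = np.full((N, N), np.nan)
        z[iu] = row
        z.T[iu] = row
        zmats.append(z)

    block_objs = [block_means(z, partition) for z in zmats]
    blocks = np.array([b.values for b in block_objs])
    les_prof = np.array([lesion_profile(z, partition) for z in zmats])
    if np.isfinite(np.diagonal(blocks, axis1=1, axis2=2)).all():
        seg = np.array([segregation(b) for b in block_objs])
    else:
        # a network emptied by lesion exclusion leaves S undefined
        seg = np.full(len(block_objs), np.nan)

    gind = (groups == "patient").astype(float)
    sx = (sexes == "F").astype(float)
    cov = sx if 0 < sx.sum() < sx.size else None

    # DMN-style pairwise ROI tests (family = all unique pairs; 28 for 8 ROIs)
    pairwise = None
    if N <= 12:
        m_fam = N * (N - 1) // 2
        rows = []
        for a in range(N):
            for b in range(a + 1, N):
                vals = np.array([z[a, b] for z in zmats])
                res = pooled_t_covariate(vals, gind, cov)
                rows.append({
                    "roi_a": conns[0].roi_ids[a], "roi_b": conns[0].roi_ids[b],
                    "t": res.statistic, "df": res.df, "p": res.p,
                    "p_bonferroni": bonferroni_adjust(res.p, m_fam),
                })
        pairwise = pd.DataFrame(rows)

    contrast = network_contrast_matrix(blocks, groups, sexes,
                                       names=partition.names,
                                       lesion_profiles=les_prof)
    seg_test = (pooled_t_covariate(seg, gind, cov)
                if np.isfinite(seg).all() else None)

    # graph-metric sweep with Bonferroni over the thresholds
    sweeps = np.array([
        [list(graph_summary(z, P).values())[1:5] for P in cfg.percentiles]
        for z in zmats])            # (n, n_thr, [C, E, SW, isolates])
    m_thr = len(cfg.percentiles)
    rows = []
    for t_i, P in enumerate(cfg.percentiles):
        for m_i, metric in enumerate(
                ["clustering", "efficiency", "small_worldness",
                 "isolate_fraction"]):
            res = pooled_t_covariate(sweeps[:, t_i, m_i], gind, cov)
            rows.append({"P": P, "metric": metric, "t": res.statistic,
                         "p": res.p,
                         "p_bonferroni": bonferroni_adjust(res.p, m_thr)})
    sweep_tests = pd.DataFrame(rows)

    log = {
        "version": __version__,
        "seed": cfg.seed,
        "n_subjects": len(subjects),
        "n_used": int(use.sum()),
        "outliers": [subjects[i].id for i in np.flatnonzero(flags)],
        "n_volterra": 90,
        "n_dct": int(designs[0].n_dct),
        "m_confounds": [int(d.m) for d in designs],
        "eff_df": [float(c.eff_df) for c in conns],
        "elapsed_s": round(time.time() - t0, 2),
    }
    return RunResult(subjects=subjects, partition=partition, mean_rd=mean_rd,
                     outlier_flags=flags, conn=conns, blocks=blocks,
                     lesion_profiles=les_prof, segregation=seg,
                     pairwise=pairwise, contrast=contrast,
                     segregation_test=seg_test, sweep_tests=sweep_tests,
                     log=log)


def run_pipeline(cfg: RunConfig) -> RunResult:
    """Simulate or load a cohort, run all stages, write the report bundle."""
    cfg.validate()
    if cfg.data_dir:
        subjects, partition = lio.read_dataset(cfg.data_dir)
    else:
        subjects = generate_cohort(cfg.spec, cfg.n_controls, cfg.n_patients,
                                   seed=cfg.seed)
        partition = generate_partition(cfg.spec)
    result = analyse_cohort(subjects, partition, cfg)

    if cfg.write_files:
        out = Path(cfg.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        if cfg.write_subject_matrices:
            for sub, conn in zip(subjects, result.conn):
                lio.write_matrix(out / f"{sub.id}_z.tsv", conn.z,
                                 conn.roi_ids)
        if result.pairwise is not None:
            result.pairwise.to_csv(out / "pairwise_tests.tsv", sep="\t",
                                   index=False)
        names = list(partition.names)
        lio.write_matrix(out / "contrast_t.tsv", result.contrast.t, names)
        lio.write_matrix(out / "contrast_mask.tsv",
                         result.contrast.mask.astype(float), names)
        pd.DataFrame({"network": names,
                      "lesion_t": result.contrast.lesion_t,
                      "lesion_p": result.contrast.lesion_p,
                      "mask": result.contrast.lesion_mask}
                     ).to_csv(out / "lesion_row.tsv", sep="\t", index=False)
        pd.DataFrame({"id": [s.id for s in subjects],
                      "group": [s.group for s in subjects],
                      "mean_rd": result.mean_rd,
                      "outlier": result.outlier_flags}
                     ).to_csv(out / "motion.tsv", sep="\t", index=False)
        result.sweep_tests.to_csv(out / "sweep_tests.tsv", sep="\t",
                                  index=False)
        seg_df = pd.DataFrame({
            "id": [subjects[i].id for i in range(len(subjects))
                   if (not cfg.exclude_motion_outliers
                       or not result.outlier_flags[i])],
            "segregation": result.segregation})
        seg_df.to_csv(out / "segregation.tsv", sep="\t", index=False)
        (out / "run_log.json").write_text(json.dumps(result.log, indent=2))
        lio.write_config(out / "config.yaml", _config_dict(cfg))
    return result


def _config_dict(cfg: RunConfig) -> dict:
    d = asdict(cfg)
    d["half_lives"] = list(cfg.half_lives)
    d["percentiles"] = list(cfg.percentiles)
    d["spec"] = {k: (list(v) if isinstance(v, tuple) else v)
                 for k, v in asdict(cfg.spec).items()}
    return d
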