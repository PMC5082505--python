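"""Synthetic resting-state cohorts with planted lesion effects.

Generates control and patient groups whose ROI time series carry the
statistical structure the downstream connectivity analysis assumes:
network-structured latent signals, a shared global signal, head-motion
traces with occasional spikes, and artifact (white-matter / CSF /
whole-brain) nuisance series.  Patients differ from controls by

* attenuated signal in a designated set of lesion ROIs,
* a decrement of the thalamic <-> precuneus latent correlation,
* an increment of the DMN <-> frontal-executive latent correlation,
* a uniform increase in within-network coupling (higher segregation).

The generative model for ROI ``i`` in network ``k(i)`` is

    x_i(t) = a_i * g_{k(i)}(t) + g * G(t) + noise_sd * eps_i(t)

with unit-variance AR(1) latents ``g_k`` whose innovations are correlated
across networks by a specified K x K matrix, an independent AR(1) global
signal ``G``, and white Gaussian noise.  For patients the whole signal part
of a lesion ROI is multiplied by ``1 - alpha_lesion`` (the noise is not),
so lesion connectivity drops while the series stays noisy.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

__all__ = [
    "CohortSpec",
    "NetworkPartition",
    "SubjectRecord",
    "generate_partition",
    "generate_subject",
    "generate_cohort",
    "generate_voxel_block",
    "desk_spec",
    "dmn_spec",
]


class ConfigurationError(ValueError):
    """Raised when a cohort specification is internally inconsistent."""


@dataclass(frozen=True)
class NetworkPartition:
    """Assignment of ROIs to networks plus the designated lesion ROI set."""

    labels: np.ndarray          # int network index per ROI, 0..K-1
    names: tuple[str, ...]      # network names, length K
    lesion: frozenset[int]      # ROI indices forming the lesion set

    @property
    def n_rois(self) -> int:
        return self.labels.size

    @property
    def n_networks(self) -> int:
        return len(self.names)

    def members(self, k: int) -> np.ndarray:
        return np.flatnonzero(self.labels == k)

    def index_of(self, name: str) -> int:
        return self.names.index(name)


@dataclass(frozen=True)
class CohortSpec:
    """All knobs of the synthetic generator.

    Couplings are unitless loadings; ``latent_ar`` is the AR(1) coefficient
    of the network latents; motion amplitudes are in mm at the head surface.
    """

    n_rois: int = 120
    partition_sizes: tuple[int, ...] = (15,) * 8
    network_names: tuple[str, ...] = (
        "DMN", "FEN", "thalamic", "precuneus",
        "visual", "somatomotor", "salience", "cingulate",
    )
    T: int = 148
    TR: float = 2.0
    latent_ar: float = 0.4
    within_coupling: float = 0.42
    global_coupling: float = 0.32
    noise_sd: float = 1.0
    between_corr: float = 0.3          # baseline latent innovation correlation
    lesion_rois: tuple[int, ...] = (0, 1, 2, 3)   # default: first DMN ROIs
    # patient effects (large by design: the lesion effects they emulate
    # survived correction over 120 network-pair tests with 6 patients)
    alpha_lesion: float = 0.6
    delta_within: float = 0.10
    delta_tp: float = 0.4              # thalamic<->precuneus decrement
    delta_df: float = 0.4              # DMN<->FEN increment
    # motion / artifact model
    baseline_rd: float = 0.08          # mm per-volume displacement scale
    spike_rate: float = 0.05           # expected spikes per volume
    spike_amp: float = 1.0             # mm
    female_fraction: float = 0.5
    seed: int = 0

    @property
    def n_networks(self) -> int:
        return len(self.partition_sizes)

    def validate(self) -> None:
        if sum(self.partition_sizes) != self.n_rois:
            raise ConfigurationError(
                f"partition sizes {self.partition_sizes} sum to "
                f"{sum(self.partition_sizes)}, expected n_rois={self.n_rois}"
            )
        if len(self.network_names) != self.n_networks:
            raise ConfigurationError("one name per network required")
        if not -1.0 < self.latent_ar < 1.0:
            raise ConfigurationError("latent_ar must lie in (-1, 1)")
        if not 0.0 <= self.alpha_lesion <= 1.0:
            raise ConfigurationError("alpha_lesion must lie in [0, 1]")
        if self.noise_sd < 0 or self.baseline_rd < 0 or self.spike_amp < 0:
            raise ConfigurationError("scales must be non-negative")
        if any(r < 0 or r >= self.n_rois for r in self.lesion_rois):
            raise ConfigurationError("lesion ROI index out of range")
        for role, delta in (("thalamic", self.delta_tp), ("precuneus", self.delta_tp),
                            ("DMN", self.delta_df), ("FEN", self.delta_df)):
            if delta != 0.0 and role not in self.network_names:
                raise ConfigurationError(
                    f"effect requires a network named {role!r}"
                )

    def replace(self, **kw) -> "CohortSpec":
        return dataclasses.replace(self, **kw)


@dataclass
class SubjectRecord:
    """One participant: ROI x T signals, motion, artifacts, labels."""

    roi_series: np.ndarray        # (n_rois, T)
    motion_params: np.ndarray     # (T, 6): 3 translations mm, 3 rotations rad
    artifact_series: np.ndarray   # (3, T): WM, CSF, whole-brain proxies
    group: str                    # "control" | "patient"
    sex: str                      # "M" | "F"
    id: str

    def __post_init__(self) -> None:
        T = self.roi_series.shape[1]
        if self.motion_params.shape != (T, 6):
            raise ValueError("motion_params must be (T, 6)")
        if self.artifact_series.shape != (3, T):
            raise ValueError("artifact_series must be (3, T)")
        for arr in (self.roi_series, self.motion_params, self.artifact_series):
            if not np.all(np.isfinite(arr)):
                raise ValueError("non-finite values in subject record")

    @property
    def T(self) -> int:
        return self.roi_series.shape[1]


def desk_spec(**overrides) -> CohortSpec:
    """Desk-scale default: 120 ROIs over 8 named networks, 148 volumes at
    TR = 2 s (150 acquired, two dummies dropped)."""
    return CohortSpec(**overrides)


def dmn_spec(**overrides) -> CohortSpec:
    """8-ROI default-mode configuration: two medial-temporal (hippocampal)
    ROIs forming the lesion set plus six cortical DMN ROIs."""
    base = dict(
        n_rois=8,
        partition_sizes=(2, 6),
        network_names=("MTL", "DMN"),
        lesion_rois=(0, 1),
        delta_tp=0.0,
        delta_df=0.0,
        between_corr=0.45,   # MTL latent strongly coupled to DMN latent
    )
    base.update(overrides)
    return CohortSpec(**base)


def generate_partition(spec: CohortSpec) -> NetworkPartition:
    """ROI -> network labels in block order, plus the lesion ROI set."""
    spec.validate()
    labels = np.repeat(np.arange(spec.n_networks), spec.partition_sizes)
    return NetworkPartition(
        labels=labels,
        names=tuple(spec.network_names),
        lesion=frozenset(spec.lesion_rois),
    )


def _latent_innovation_corr(spec: CohortSpec, group: str) -> np.ndarray:
    """K x K innovation correlation; patient deltas applied on the
    correlation scale and projected back to a valid correlation matrix
    (eigenvalue floor 1e-6, then unit-diagonal renormalization)."""
    K = spec.n_networks
    C = np.full((K, K), spec.between_corr)
    np.fill_diagonal(C, 1.0)
    if group == "patient":
        names = spec.network_names
        if spec.delta_tp != 0.0:
            i, j = names.index("thalamic"), names.index("precuneus")
            C[i, j] -= spec.delta_tp
            C[j, i] = C[i, j]
        if spec.delta_df != 0.0:
            i, j = names.index("DMN"), names.index("FEN")
            C[i, j] += spec.delta_df
            C[j, i] = C[i, j]
        C = np.clip(C, -0.999, 0.999)
        np.fill_diagonal(C, 1.0)
    w, U = np.linalg.eigh(C)
    if w.min() < 1e-6:
        w = np.maximum(w, 1e-6)
        C = (U * w) @ U.T
        d = np.sqrt(np.diag(C))
        C = C / np.outer(d, d)
    return C


def _ar1_latents(rng: np.random.Generator, K: int, T: int, phi: float,
                 C: np.ndarray) -> np.ndarray:
    """K unit-variance AR(1) latents with innovation correlation C."""
    w, U = np.linalg.eigh(C)
    sq = U * np.sqrt(np.maximum(w, 0.0))
    z0 = sq @ rng.standard_normal(K)
    innov = (sq @ rng.standard_normal((K, T))) * np.sqrt(1.0 - phi * phi)
    g = np.empty((K, T))
    prev = z0
    for t in range(T):
        prev = phi * prev + innov[:, t]
        g[:, t] = prev
    return g


def _motion_and_artifacts(rng: np.random.Generator, spec: CohortSpec
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Random-walk rigid-body parameters with Poisson-thinned spikes, and
    3 artifact series built from low-pass noise plus the spike indicator."""
    T = spec.T
    # E|step| for a 3-D Gaussian step of per-axis sd s is ~1.6 s
    step_sd = spec.baseline_rd / 1.6
    trans = np.cumsum(rng.normal(0.0, step_sd, size=(T, 3)), axis=0)
    rot = np.cumsum(rng.normal(0.0, 5e-4, size=(T, 3)), axis=0)
    spikes = rng.random(T) < spec.spike_rate
    spikes[0] = False
    if spikes.any():
        direc = rng.standard_normal((int(spikes.sum()), 3))
        direc /= np.linalg.norm(direc, axis=1, keepdims=True)
        trans[spikes] += spec.spike_amp * direc       # transient excursion
    params = np.hstack([trans, rot])

    kernel = np.hanning(9)
    kernel /= kernel.sum()
    art = np.empty((3, T))
    for a in range(3):
        smooth = np.convolve(rng.standard_normal(T + 8), kernel, mode="valid")
        smooth = smooth[:T]
        series = smooth + 2.0 * spikes.astype(float)
        art[a] = (series - series.mean()) / max(series.std(), 1e-12)
    return params, art


def generate_subject(spec: CohortSpec, group: str, sex: str,
                     seed: int, subject_id: str | None = None
                     ) -> SubjectRecord:
    """Draw one subject from the generative model; reproducible from seed."""
    spec.validate()
    if group not in ("control", "patient"):
        raise ValueError(f"unknown group {group!r}")
    rng = np.random.default_rng(seed)
    part = generate_partition(spec)
    C = _latent_innovation_corr(spec, group)
    g_lat = _ar1_latents(rng, spec.n_networks, spec.T, spec.latent_ar, C)
    G = _ar1_latents(rng, 1, spec.T, spec.latent_ar, np.eye(1))[0]

    a = np.full(spec.n_rois, spec.within_coupling)
    if group == "patient":
        a = a + spec.delta_within
    signal = a[:, None] * g_lat[part.labels] + spec.global_coupling * G
    if group == "patient" and spec.alpha_lesion > 0 and spec.lesion_rois:
        idx = np.array(sorted(spec.lesion_rois))
        signal[idx] *= (1.0 - spec.alpha_lesion)
    noise = spec.noise_sd * rng.standard_normal((spec.n_rois, spec.T))
    roi = signal + noise

    params, art = _motion_and_artifacts(rng, spec)
    return SubjectRecord(
        roi_series=roi,
        motion_params=params,
        artifact_series=art,
        group=group,
        sex=sex,
        id=subject_id or f"{group[:3]}-{seed}",
    )


def generate_cohort(spec: CohortSpec, n_controls: int, n_patients: int,
                    seed: int | None = None) -> list[SubjectRecord]:
    """Controls then patients, each with an independent child seed derived
    deterministically from the master seed; sexes interleaved at the
    configured female fraction."""
    if n_controls < 1 or n_patients < 1:
        raise ConfigurationError("need at least one subject per group")
    master = spec.seed if seed is None else seed
    ss = np.random.SeedSequence(master)
    children = ss.spawn(n_controls + n_patients)
    sex_rng = np.random.default_rng(ss.spawn(1)[0])
    subjects: list[SubjectRecord] = []
    groups = ["control"] * n_controls + ["patient"] * n_patients
    for i, (grp, child) in enumerate(zip(groups, children)):
        sub_seed = int(child.generate_state(1)[0] % (2**31))
        sex = "F" if sex_rng.random() < spec.female_fraction else "M"
        label = "c" if grp == "control" else "p"
        subjects.append(
            generate_subject(spec, grp, sex, sub_seed,
                             subject_id=f"{label}{i:03d}")
        )
    return subjects


def generate_voxel_block(series: np.ndarray, n_voxels: int,
                         voxel_noise_sd: float = 0.0,
                         sign_flips: np.ndarray | None = None,
                         seed: int = 0) -> np.ndarray:
    """Voxel x T fixture for SVD time-series extraction: each voxel is
    +/- the input series plus white noise."""
    series = np.asarray(series, dtype=float)
    if n_voxels < 1:
        raise ValueError("n_voxels must be >= 1")
    rng = np.random.default_rng(seed)
    signs = np.ones(n_voxels)
    if sign_flips is not None:
        flips = np.asarray(sign_flips)
        if flips.dtype == bool:
            signs[flips] = -1.0
        else:
            signs[np.asarray(flips, dtype=int)] = -1.0
    block = signs[:, None] * series[None, :]
    if voxel_noise_sd > 0:
        block = block + voxel_noise_sd * rng.standard_normal(block.shape)
    return block
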