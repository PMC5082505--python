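"""Subject-level preprocessing: ROI series extraction, motion summaries,
outlier flagging, and a simple robust despiker.

The motion summary is the per-volume root-mean-square relative displacement
(RD) of a sphere of configurable radius under the rigid transform between
consecutive volumes.  ROI time series are the first temporal SVD mode over
voxels, sign-matched to the across-voxel mean and z-scored to unit variance
over volumes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "MotionTrace",
    "StandardizedSeries",
    "standardize",
    "extract_roi_series",
    "relative_displacement",
    "motion_trace",
    "flag_motion_outliers",
    "despike_interpolate",
    "DEFAULT_RADIUS_MM",
]

DEFAULT_RADIUS_MM = 80.0


class DegenerateInputError(ValueError):
    """Raised for all-constant input where variance normalization is undefined."""


@dataclass(frozen=True)
class MotionTrace:
    """Rigid-body parameters plus the derived RD series (mm)."""

    params: np.ndarray    # (T, 6)
    rd: np.ndarray        # (T,), rd[0] = 0
    radius: float

    @property
    def mean_rd(self) -> float:
        return float(self.rd.mean())


@dataclass(frozen=True)
class StandardizedSeries:
    """Unit-variance series with a record of how it was obtained."""

    values: np.ndarray
    provenance: str       # "svd_mode" | "plain_mean" | "zscore"


def standardize(x: np.ndarray, provenance: str = "zscore") -> StandardizedSeries:
    x = np.asarray(x, dtype=float)
    sd = x.std(ddof=1)
    if not np.isfinite(sd) or sd < 1e-12:
        raise DegenerateInputError("cannot standardize an all-constant series")
    return StandardizedSeries((x - x.mean()) / sd, provenance)


def extract_roi_series(voxel_matrix: np.ndarray) -> StandardizedSeries:
    """First temporal SVD mode across voxels, sign-matched to the mean.

    Each voxel's temporal mean is removed first so the leading mode captures
    shared temporal covariance rather than baseline offsets.  The mode is
    flipped if it correlates negatively with the across-voxel mean series,
    then z-scored to unit variance over volumes.
    """
    V = np.asarray(voxel_matrix, dtype=float)
    if V.ndim != 2 or V.shape[0] < 1 or V.shape[1] < 3:
        raise ValueError("need a voxels x T matrix with T >= 3")
    Vc = V - V.mean(axis=1, keepdims=True)
    if np.allclose(Vc, 0.0):
        raise DegenerateInputError("all voxels constant over time")
    # first right-singular vector of the centred voxels x time matrix
    _, _, vt = np.linalg.svd(Vc, full_matrices=False)
    mode = vt[0]
    mean_series = Vc.mean(axis=0)
    if mode @ mean_series < 0:
        mode = -mode
    return standardize(mode, provenance="svd_mode")


def _rigid(params6: np.ndarray) -> np.ndarray:
    """4x4 rigid transform: rotations (radians) applied as Rx @ Ry @ Rz,
    then translation (mm)."""
    tx, ty, tz, rx, ry, rz = params6
    cx, sx = np.cos(rx), np.sin(rx)
    cy, sy = np.cos(ry), np.sin(ry)
    cz, sz = np.cos(rz), np.sin(rz)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    M = np.eye(4)
    M[:3, :3] = Rx @ Ry @ Rz
    M[:3, 3] = (tx, ty, tz)
    return M


def relative_displacement(params: np.ndarray,
                          radius: float = DEFAULT_RADIUS_MM) -> np.ndarray:
    """RMS displacement of a sphere of ``radius`` mm between consecutive
    volumes.

    The relative motion between volumes t-1 and t is taken as the relative
    rotation A = R_t R_{t-1}' - I (rotations about the volume centre) and
    the translation step d = trans_t - trans_{t-1}; then
    rd_t = sqrt(radius^2/5 * trace(A'A) + d'd), with rd_0 = 0 by
    convention.  Using parameter steps makes rd exactly invariant to a
    constant offset of the translation columns.
    """
    P = np.asarray(params, dtype=float)
    if P.ndim != 2 or P.shape[1] != 6:
        raise ValueError("params must be (T, 6)")
    if not np.all(np.isfinite(P)):
        raise ValueError("non-finite motion parameters")
    if radius <= 0:
        raise ValueError("radius must be positive")
    T = P.shape[0]
    rd = np.zeros(T)
    prev = _rigid(P[0])[:3, :3]
    for t in range(1, T):
        cur = _rigid(P[t])[:3, :3]
        A = cur @ prev.T - np.eye(3)
        d = P[t, :3] - P[t - 1, :3]
        rd[t] = np.sqrt(radius * radius / 5.0 * np.sum(A * A) + d @ d)
        prev = cur
    return rd


def motion_trace(params: np.ndarray,
                 radius: float = DEFAULT_RADIUS_MM) -> MotionTrace:
    return MotionTrace(np.asarray(params, float),
                       relative_displacement(params, radius), radius)


def flag_motion_outliers(mean_rd_controls: np.ndarray,
                         mean_rd_all: np.ndarray) -> np.ndarray:
    """Upper-fence outlier flags relative to the control interquartile range.

    A subject is flagged iff its mean RD exceeds Q3 + 1.5 * IQR of the
    control distribution (linear-interpolation / type-7 quartiles).  Only
    the upper fence is used: low movers are unremarkable.
    """
    ctrl = np.asarray(mean_rd_controls, dtype=float)
    if ctrl.size < 4:
        raise ValueError("need at least 4 control values for a stable IQR")
    q1, q3 = np.percentile(ctrl, [25, 75], method="linear")
    fence = q3 + 1.5 * (q3 - q1)
    return np.asarray(mean_rd_all, dtype=float) > fence


def despike_interpolate(series: np.ndarray, z_threshold: float = 5.0
                        ) -> np.ndarray:
    """Replace points with robust z-score (median / 1.4826 MAD) beyond the
    threshold by linear interpolation of the surrounding clean points.
    Optional plumbing stage, off by default in the pipeline."""
    x = np.asarray(series, dtype=float).copy()
    if x.size < 5:
        raise ValueError("series too short to despike")
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad < 1e-12:
        return x
    z = (x - med) / (1.4826 * mad)
    bad = np.abs(z) > z_threshold
    if not bad.any():
        return x
    if bad.all():
        warnings.warn("every point flagged as spike; series returned unchanged")
        return x
    idx = np.arange(x.size)
    x[bad] = np.interp(idx[bad], idx[~bad], x[~bad])
    return x
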