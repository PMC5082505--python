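"""Nuisance design for the connectivity GLM.

Three pieces, kept exactly separable for audit:

1. ``volterra_expansion`` — a second-order, lag-five expansion of the RD
   motion index: 9 first-order columns (lags 0-4 plus the 4 successive
   differences between consecutive lags) and all 81 ordered pairwise
   products, 90 columns in total.
2. ``assemble_confounds`` — the motion expansion and the 3 artifact series
   are standardized, stacked and reduced by SVD to the smallest number of
   orthonormal temporal components explaining the requested variance
   fraction (default 99%).
3. ``dct_bandpass_set`` — a discrete cosine nuisance set implementing a
   band-pass filter by regression: the constant term plus every DCT
   component whose frequency f_k = k / (2 T TR) falls outside the pass
   band (defaults 0.009-0.1 Hz).  At T = 148, TR = 2 s this yields 94
   columns (1 constant + 5 low-band + 88 high-band).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ConfoundDesign",
    "volterra_expansion",
    "dct_bandpass_set",
    "assemble_confounds",
    "build_confound_design",
    "F_LOW_HZ",
    "F_HIGH_HZ",
    "VARIANCE_FRACTION",
]

F_LOW_HZ = 0.009
F_HIGH_HZ = 0.1
VARIANCE_FRACTION = 0.99


@dataclass(frozen=True)
class ConfoundDesign:
    """Assembled nuisance side of the connectivity GLM."""

    reduced_components: np.ndarray   # (T, m) orthonormal SVD components
    dct_block: np.ndarray            # (T, K) unit-norm DCT nuisance columns
    m: int
    n_dct: int
    f_low: float = F_LOW_HZ
    f_high: float = F_HIGH_HZ
    variance_fraction: float = VARIANCE_FRACTION

    @property
    def nuisance(self) -> np.ndarray:
        """Full T x (m + K) nuisance matrix (includes the DCT constant)."""
        return np.hstack([self.reduced_components, self.dct_block])


def volterra_expansion(rd: np.ndarray) -> np.ndarray:
    """T x 90 motion regressor matrix from the RD series.

    Column order (fixed): lag0..lag4, diff1..diff4 (diff_j = lag_{j-1} -
    lag_j), then the 81 ordered products prod_i_j of first-order columns
    i, j = 0..8.  Lagged columns are zero-padded at the start so T is
    preserved.  Symmetric duplicate products are retained; the subsequent
    SVD removes the redundancy.
    """
    rd = np.asarray(rd, dtype=float)
    T = rd.size
    if T <= 5:
        raise ValueError("need more than 5 volumes for a lag-5 expansion")
    lags = np.zeros((T, 5))
    for k in range(5):
        lags[k:, k] = rd[: T - k]
    diffs = lags[:, :-1] - lags[:, 1:]          # 4 successive differences
    first = np.hstack([lags, diffs])            # (T, 9)
    prods = (first[:, :, None] * first[:, None, :]).reshape(T, 81)
    return np.hstack([first, prods])            # (T, 90)


def volterra_column_names() -> list[str]:
    names = [f"lag{k}" for k in range(5)] + [f"diff{j}" for j in range(1, 5)]
    names += [f"prod_{i}_{j}" for i in range(9) for j in range(9)]
    return names


def dct_bandpass_set(T: int, TR: float,
                     f_low: float = F_LOW_HZ,
                     f_high: float = F_HIGH_HZ) -> np.ndarray:
    """Unit-norm DCT nuisance columns implementing band-pass by projection.

    Component k (k = 1..T-1) is cos(pi k (2t+1) / (2T)) with frequency
    f_k = k / (2 T TR); the returned set is the constant (k = 0) plus every
    component with f_k strictly below f_low or strictly above f_high.
    """
    nyquist = 1.0 / (2.0 * TR)
    if not (0.0 <= f_low < f_high <= nyquist + 1e-12):
        raise ValueError(f"invalid band [{f_low}, {f_high}] for TR={TR}")
    t = np.arange(T)
    k_all = np.arange(T)
    f_k = k_all / (2.0 * T * TR)
    keep = (k_all == 0) | (f_k < f_low) | (f_k > f_high)
    ks = k_all[keep]
    basis = np.cos(np.pi * np.outer(2 * t + 1, ks) / (2.0 * T))
    basis /= np.linalg.norm(basis, axis=0, keepdims=True)
    return basis


def assemble_confounds(motion_block: np.ndarray, artifact_block: np.ndarray,
                       variance_fraction: float = VARIANCE_FRACTION
                       ) -> tuple[np.ndarray, int]:
    """SVD reduction of the stacked, standardized nuisance columns.

    Columns are mean-centred and scaled to unit variance (constant columns
    dropped), stacked, and reduced to the smallest m left temporal
    components whose squared singular values reach the requested variance
    fraction.  Returns (T x m orthonormal components, m).
    """
    if not 0.0 < variance_fraction <= 1.0:
        raise ValueError("variance_fraction must lie in (0, 1]")
    blocks = []
    for blk in (motion_block, artifact_block):
        if blk is None:
            continue
        B = np.atleast_2d(np.asarray(blk, dtype=float))
        if B.shape[0] < B.shape[1] and B.shape[0] <= 3:
            B = B.T                      # accept (3, T) artifact orientation
        blocks.append(B)
    X = np.hstack(blocks)
    X = X - X.mean(axis=0, keepdims=True)
    sd = X.std(axis=0, ddof=1)
    keep = sd > 1e-12
    if not keep.any():
        raise ValueError("all nuisance columns are constant")
    X = X[:, keep] / sd[keep]
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    power = s * s
    frac = np.cumsum(power) / power.sum()
    m = int(np.searchsorted(frac, variance_fraction - 1e-12) + 1)
    return U[:, :m], m


def build_confound_design(rd: np.ndarray, artifact_series: np.ndarray,
                          TR: float,
                          f_low: float = F_LOW_HZ, f_high: float = F_HIGH_HZ,
                          variance_fraction: float = VARIANCE_FRACTION
                          ) -> ConfoundDesign:
    """Full nuisance design for one subject from RD and artifact series."""
    motion = volterra_expansion(rd)
    comps, m = assemble_confounds(motion, artifact_series, variance_fraction)
    dct = dct_bandpass_set(motion.shape[0], TR, f_low, f_high)
    return ConfoundDesign(
        reduced_components=comps, dct_block=dct, m=m, n_dct=dct.shape[1],
        f_low=f_low, f_high=f_high, variance_fraction=variance_fraction,
    )
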