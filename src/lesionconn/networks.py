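"""Network-level aggregation of edge statistics.

Block means over a network partition, the segregation summary (mean
within-network minus mean between-network connectivity), lesion
connectivity profiles, and the group contrast matrix with Bonferroni
families matching the analysis design (K tests for the lesion row,
K(K-1)/2 for the unique between/within pairs).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .cohort import NetworkPartition
from .stats import pooled_t_covariate

__all__ = [
    "BlockMatrix",
    "ContrastResult",
    "block_means",
    "segregation",
    "lesion_profile",
    "network_contrast_matrix",
]


@dataclass
class BlockMatrix:
    """K x K network-block summary of an edge-Z matrix.

    Diagonal entries average unique within-network pairs (NaN for
    singleton networks); off-diagonal entries average all pairs spanning
    the two networks.
    """

    values: np.ndarray
    names: tuple[str, ...]

    @property
    def K(self) -> int:
        return self.values.shape[0]


def _pair_mask(conn: np.ndarray) -> np.ndarray:
    m = np.isfinite(conn)
    np.fill_diagonal(m, False)
    return m


def block_means(conn: np.ndarray, partition: NetworkPartition,
                exclude_lesion: bool = True) -> BlockMatrix:
    """Mean edge Z within and between networks.

    Lesion ROIs are excluded from their host network by default so the
    lesion profile and the block matrix do not double-count them.
    """
    conn = np.asarray(conn, dtype=float)
    labels = np.asarray(partition.labels)
    if conn.shape[0] != labels.size:
        raise ValueError("partition does not cover the connectivity matrix")
    K = partition.n_networks
    keep = np.ones(labels.size, dtype=bool)
    if exclude_lesion and partition.lesion:
        keep[list(partition.lesion)] = False
    out = np.full((K, K), np.nan)
    members = [np.flatnonzero((labels == k) & keep) for k in range(K)]
    for k in range(K):
        mk = members[k]
        if mk.size >= 2:
            sub = conn[np.ix_(mk, mk)]
            iu = np.triu_indices(mk.size, 1)
            out[k, k] = np.nanmean(sub[iu])
        for l in range(k + 1, K):
            ml = members[l]
            if mk.size and ml.size:
                out[k, l] = out[l, k] = np.nanmean(conn[np.ix_(mk, ml)])
    return BlockMatrix(values=out, names=partition.names)


def segregation(block: BlockMatrix) -> float:
    """Mean of the leading diagonal minus the mean of the off-diagonal
    (unique upper-triangle) entries."""
    v = block.values
    diag = np.diag(v)
    if np.isnan(diag).any():
        raise ValueError("undefined within-network entries (singleton network)")
    iu = np.triu_indices(block.K, 1)
    off = v[iu]
    if np.isnan(off).any():
        raise ValueError("undefined between-network entries")
    return float(diag.mean() - off.mean())


def lesion_profile(conn: np.ndarray, partition: NetworkPartition
                   ) -> np.ndarray:
    """Length-K vector: mean edge Z between the lesion ROI set and each
    network (lesion-internal pairs excluded)."""
    if not partition.lesion:
        raise ValueError("empty lesion ROI set")
    conn = np.asarray(conn, dtype=float)
    labels = np.asarray(partition.labels)
    les = np.array(sorted(partition.lesion))
    other = np.setdiff1d(np.arange(labels.size), les)
    prof = np.full(partition.n_networks, np.nan)
    for k in range(partition.n_networks):
        targets = other[labels[other] == k]
        if targets.size:
            prof[k] = np.nanmean(conn[np.ix_(les, targets)])
    return prof


@dataclass
class ContrastResult:
    """Patient-vs-control contrast over network blocks.

    ``mask`` codes each cell 0 (n.s.), 1 (p < alpha uncorrected) or
    2 (survives Bonferroni for its family).
    """

    t: np.ndarray
    p: np.ndarray
    mask: np.ndarray
    names: tuple[str, ...]
    lesion_t: np.ndarray | None = None
    lesion_p: np.ndarray | None = None
    lesion_mask: np.ndarray | None = None


def network_contrast_matrix(blocks: np.ndarray, groups: np.ndarray,
                            sex: np.ndarray | None = None,
                            names: tuple[str, ...] | None = None,
                            alpha: float = 0.05,
                            lesion_profiles: np.ndarray | None = None
                            ) -> ContrastResult:
    """Cell-wise group test on per-subject block matrices.

    ``blocks`` is (n_subjects, K, K); groups is 'control'/'patient' per
    subject; sex enters as a covariate of no interest when it varies.
    Bonferroni families: K(K-1)/2 for off-diagonal cells, K for diagonal
    cells and for the lesion profile row.
    """
    blocks = np.asarray(blocks, dtype=float)
    n, K, _ = blocks.shape
    groups = np.asarray(groups)
    gind = (groups == "patient").astype(float)
    if gind.sum() < 3 or (1 - gind).sum() < 3:
        raise ValueError("need at least 3 subjects per group")
    cov = None
    if sex is not None:
        sx = (np.asarray(sex) == "F").astype(float)
        if 0 < sx.sum() < n:
            cov = sx
        else:
            warnings.warn("single-sex sample; sex covariate dropped")
    names = names or tuple(f"net{k}" for k in range(K))

    tmat = np.full((K, K), np.nan)
    pmat = np.full((K, K), np.nan)
    for k in range(K):
        for l in range(k, K):
            vals = blocks[:, k, l]
            if np.isnan(vals).any():
                continue
            res = pooled_t_covariate(vals, gind, cov)
            tmat[k, l] = tmat[l, k] = res.statistic
            pmat[k, l] = pmat[l, k] = res.p

    m_off = K * (K - 1) // 2
    mask = np.zeros((K, K), dtype=int)
    off = ~np.eye(K, dtype=bool)
    mask[(pmat < alpha)] = 1
    mask[off & (pmat * m_off < alpha)] = 2
    mask[~off & (pmat * K < alpha)] = 2
    mask[~np.isfinite(pmat)] = 0

    lt = lp = lmask = None
    if lesion_profiles is not None:
        prof = np.asarray(lesion_profiles, dtype=float)
        lt = np.full(K, np.nan)
        lp = np.full(K, np.nan)
        for k in range(K):
            vals = prof[:, k]
            if np.isnan(vals).any():
                continue
            res = pooled_t_covariate(vals, gind, cov)
            lt[k], lp[k] = res.statistic, res.p
        lmask = np.zeros(K, dtype=int)
        lmask[lp < alpha] = 1
        lmask[lp * K < alpha] = 2
        lmask[~np.isfinite(lp)] = 0
    return ContrastResult(t=tmat, p=pmat, mask=mask, names=names,
                          lesion_t=lt, lesion_p=lp, lesion_mask=lmask)
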