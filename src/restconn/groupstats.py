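"""Group-level statistics on matched component maps.

Voxelwise random-effects comparison of subjects' z-scored component
maps (ordinary least squares with group, age and sex regressors),
multiple-comparison control by a Monte-Carlo calibrated minimum cluster
extent, restriction of comparisons to network masks derived from
one-sample t-tests, and severity--connectivity correlation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats

from .preprocess import gaussian_smooth

__all__ = [
    "StatMap",
    "fit_group_glm",
    "mc_cluster_extent",
    "apply_threshold",
    "make_rsn_mask",
    "severity_correlation",
]

#: 6-neighbour (face adjacency) connectivity for 3D cluster labelling.
FACE_STRUCTURE = ndimage.generate_binary_structure(3, 1)


@dataclass
class StatMap:
    """A 3D t-statistic map with its thresholding state.

    ``clusters`` lists surviving clusters after :func:`apply_threshold`,
    each a dict with ``size``, ``peak_index`` (voxel tuple), ``peak_t``
    and a boolean ``mask`` of the cluster's voxels.
    """

    values: np.ndarray
    df: int
    voxel_p_threshold: float | None = None
    extent_threshold_k: int | None = None
    clusters: list[dict] = field(default_factory=list)


def fit_group_glm(maps, groups, age=None, sex=None, mask=None) -> StatMap:
    """Per-voxel OLS of subject maps on intercept + group [+ age + sex].

    ``maps`` is (n_subjects, n_voxels) or (n_subjects, x, y, z); the
    returned t is the group-contrast statistic (positive when the group
    coded 1 — conventionally the patient group — has the larger mean),
    with ``df = n - rank(design)``.  With both covariates omitted this
    is exactly the pooled-variance two-sample t-test.
    """
    maps = np.asarray(maps, dtype=float)
    spatial_shape = None
    if maps.ndim > 2:
        spatial_shape = maps.shape[1:]
        maps = maps.reshape(maps.shape[0], -1)
    n = maps.shape[0]
    g = np.asarray(groups, dtype=float)
    cols, names = [np.ones(n), g], ["intercept", "group"]
    if age is not None:
        cols.append(np.asarray(age, float))
        names.append("age")
    if sex is not None:
        cols.append(np.asarray(sex, float))
        names.append("sex")
    X = np.column_stack(cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        bad = _collinear_columns(X, names)
        raise ValueError("rank-deficient design matrix; collinear column(s): "
                         + ", ".join(bad))
    pinv = np.linalg.pinv(X)
    beta = pinv @ maps
    resid = maps - X @ beta
    df = n - rank
    sigma2 = (resid ** 2).sum(axis=0) / df
    xtx_inv = np.linalg.inv(X.T @ X)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta[1] / np.sqrt(sigma2 * xtx_inv[1, 1])
    t[~np.isfinite(t)] = 0.0
    if spatial_shape is not None:
        t = t.reshape(spatial_shape)
    return StatMap(values=t, df=df)


def _collinear_columns(X, names):
    bad = []
    for j in range(X.shape[1]):
        others = np.delete(X, j, axis=1)
        proj, *_ = np.linalg.lstsq(others, X[:, j], rcond=None)
        if np.allclose(others @ proj, X[:, j]):
            bad.append(names[j])
    return bad or ["<unidentified>"]


def mc_cluster_extent(grid, mask, voxel_p, fwhm_mm, voxel_size_mm,
                      n_sims=1000, corrected_alpha=0.05, seed=0,
                      return_null=False):
    """Monte-Carlo calibrated minimum cluster extent.

    Each simulation draws a Gaussian noise volume on ``grid``, smooths
    it with ``fwhm_mm``, re-standardizes it over ``mask`` (so the
    per-voxel threshold stays calibrated after smoothing), thresholds
    two-sided at ``voxel_p``, and records the largest suprathreshold
    cluster (face adjacency).  The returned ``k`` is the smallest extent
    whose exceedance probability under this null is <= ``corrected_alpha``.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty analysis mask")
    if not (0 < voxel_p < 1):
        raise ValueError("voxel_p must lie in (0, 1)")
    if n_sims < 100:
        raise ValueError("n_sims must be >= 100")
    rng = np.random.default_rng(seed)
    zcrit = stats.norm.isf(voxel_p / 2.0)
    max_sizes = np.zeros(n_sims, dtype=int)
    for s in range(n_sims):
        vol = rng.standard_normal(tuple(grid))
        if fwhm_mm > 0:
            vol = gaussian_smooth(vol, fwhm_mm, voxel_size_mm)
        v = vol[mask]
        vol = (vol - v.mean()) / v.std()
        supra = (np.abs(vol) > zcrit) & mask
        max_sizes[s] = _max_cluster_size(supra)
    k = 1
    while np.mean(max_sizes >= k) > corrected_alpha:
        k += 1
    return (k, max_sizes) if return_null else k


def _max_cluster_size(supra: np.ndarray) -> int:
    labels, n = ndimage.label(supra, structure=FACE_STRUCTURE)
    if n == 0:
        return 0
    return int(np.max(ndimage.sum_labels(np.ones_like(labels), labels,
                                         index=np.arange(1, n + 1))))


def apply_threshold(statmap: StatMap, voxel_p, extent_k, mask=None) -> StatMap:
    """Voxel-p threshold plus minimum-extent cluster filtering.

    Voxels with two-sided p >= ``voxel_p`` are zeroed; positive and
    negative suprathreshold voxels are labelled separately (face
    adjacency) and clusters smaller than ``extent_k`` removed.  The
    surviving clusters are listed with size, peak voxel and signed peak t.
    """
    t = np.asarray(statmap.values, dtype=float)
    if mask is None:
        mask = np.ones(t.shape, dtype=bool)
    tcrit = stats.t.isf(voxel_p / 2.0, statmap.df)
    out = np.zeros_like(t)
    clusters = []
    for sign in (1.0, -1.0):
        supra = (sign * t > tcrit) & mask
        labels, n = ndimage.label(supra, structure=FACE_STRUCTURE)
        for lab in range(1, n + 1):
            cmask = labels == lab
            size = int(cmask.sum())
            if size < extent_k:
                continue
            out[cmask] = t[cmask]
            peak_flat = np.argmax(np.where(cmask, sign * t, -np.inf))
            peak_idx = np.unravel_index(peak_flat, t.shape)
            clusters.append({"size": size, "peak_index": tuple(int(i) for i in peak_idx),
                             "peak_t": float(t[peak_idx]), "mask": cmask})
    clusters.sort(key=lambda c: -c["size"])
    return StatMap(values=out, df=statmap.df, voxel_p_threshold=voxel_p,
                   extent_threshold_k=int(extent_k), clusters=clusters)


def make_rsn_mask(onesample_statmap: StatMap, mask_p=0.001, base_mask=None):
    """Network mask: voxels with one-sample p < ``mask_p`` (positive tail)."""
    if onesample_statmap.df < 1:
        raise ValueError("one-sample map needs df >= 1")
    t = np.asarray(onesample_statmap.values, dtype=float)
    tcrit = stats.t.isf(mask_p, onesample_statmap.df)
    out = t > tcrit
    if base_mask is not None:
        out &= np.asarray(base_mask, dtype=bool)
    if not out.any():
        warnings.warn("network mask is empty at the requested mask_p")
    return out


def severity_correlation(subject_scores, severities):
    """Pearson correlation between per-subject connectivity and severity.

    Returns ``(r, p)`` with the two-sided p from the t transform
    ``t = r * sqrt((n - 2) / (1 - r^2))``.
    """
    x = np.asarray(subject_scores, dtype=float)
    y = np.asarray(severities, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need >= 3 paired observations")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance; correlation undefined")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
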