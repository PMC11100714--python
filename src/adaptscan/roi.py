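"""Category-selective ROI definition with cluster-extent correction.

A CS ROI is the set of ventral-mask voxels whose balanced category contrast
is positive and voxelwise significant (one-sided p < 0.001 by default),
restricted to connected clusters at least as large as a Monte-Carlo-derived
minimum extent: pure-noise volumes are simulated in the mask geometry
(optionally smoothed), thresholded, and the largest surviving component per
iteration forms the null distribution of cluster sizes.  CS amplitude is the
median held-out contrast within the ROI — ROI definition and amplitude use
disjoint runs, enforced through run provenance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
from scipy import ndimage, stats

from .glm import BetaMap

__all__ = [
    "ClusterNull",
    "ROIDefinition",
    "estimate_cluster_threshold",
    "define_cs_roi",
    "cs_amplitude",
]


@dataclass(frozen=True)
class ClusterNull:
    """Monte-Carlo null distribution of maximal cluster extents."""

    max_cluster_sizes: np.ndarray
    k_min: int
    voxel_p: float
    alpha: float
    n_iter: int
    mask_shape: tuple[int, ...]
    fwhm: float
    seed: int

    @staticmethod
    def k_from_sizes(sizes: np.ndarray, alpha: float) -> int:
        """Smallest k with fraction(max sizes >= k) <= alpha."""
        sizes = np.asarray(sizes)
        for k in range(1, int(sizes.max(initial=0)) + 2):
            if np.mean(sizes >= k) <= alpha:
                return k
        return int(sizes.max(initial=0)) + 1


@dataclass(frozen=True)
class ROIDefinition:
    """A category-selective ROI: voxel indices plus provenance."""

    category: str
    hemisphere: str
    voxels: np.ndarray  # flat indices into the mask grid
    cluster_sizes: tuple[int, ...]
    runs_used: tuple[int, ...]
    voxel_p: float
    k_min: int

    @property
    def n_voxels(self) -> int:
        return int(self.voxels.size)

    @property
    def empty(self) -> bool:
        return self.voxels.size == 0


def _face_structure(ndim: int) -> np.ndarray:
    return ndimage.generate_binary_structure(ndim, 1)


def estimate_cluster_threshold(
    mask: np.ndarray,
    fwhm: float = 2.0,
    voxel_p: float = 0.001,
    alpha: float = 0.05,
    n_iter: int = 10_000,
    seed: int = 0,
) -> ClusterNull:
    """Monte-Carlo minimum significant cluster size for a mask geometry.

    Each iteration draws Gaussian noise on the mask grid, smooths it to
    ``fwhm`` voxels (0 disables smoothing), re-standardises within the mask,
    thresholds one-sided at ``voxel_p`` and records the largest
    face-connected component.  ``k_min`` is the smallest extent whose
    exceedance fraction is at most ``alpha``.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0, 1)")
    if n_iter < 1:
        raise ValueError("n_iter must be positive")
    if voxel_p >= 1.0:
        warnings.warn("voxel_p >= 1 makes every voxel suprathreshold", stacklevel=2)
        zc = -np.inf
    else:
        zc = stats.norm.isf(voxel_p)
    rng = np.random.default_rng(seed)
    sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0))) if fwhm > 0 else 0.0
    struct = _face_structure(mask.ndim)
    sizes = np.zeros(n_iter, dtype=int)
    for it in range(n_iter):
        noise = rng.standard_normal(mask.shape)
        if sigma > 0:
            noise = ndimage.gaussian_filter(noise, sigma)
        vals = noise[mask]
        noise = (noise - vals.mean()) / vals.std()
        supra = (noise > zc) & mask
        if supra.any():
            lab, n_lab = ndimage.label(supra, structure=struct)
            if n_lab:
                sizes[it] = int(np.bincount(lab.ravel())[1:].max())
    k_min = ClusterNull.k_from_sizes(sizes, alpha)
    return ClusterNull(
        max_cluster_sizes=sizes,
        k_min=k_min,
        voxel_p=voxel_p,
        alpha=alpha,
        n_iter=n_iter,
        mask_shape=tuple(mask.shape),
        fwhm=fwhm,
        seed=seed,
    )


def define_cs_roi(
    betas: BetaMap,
    category: str,
    null: ClusterNull,
    mask: np.ndarray,
    hemisphere: str = "",
) -> ROIDefinition:
    """Cluster-thresholded positive-contrast ROI for one category.

    Voxels must lie in the ventral ``mask``, show a positive balanced
    contrast with one-sided p < the null's voxel threshold, and belong to a
    face-connected cluster of at least ``k_min`` voxels.  An empty result is
    returned (with a warning) rather than raised.
    """
    if category not in betas.conditions:
        raise ValueError(f"category {category!r} absent from BetaMap")
    if betas.voxel_coords is None or betas.grid_shape is None:
        raise ValueError("BetaMap lacks voxel coordinates for clustering")
    mask = np.asarray(mask, dtype=bool)
    con, t = betas.contrast(category)
    pvals = stats.t.sf(t, betas.df)
    grid = np.zeros(mask.shape, dtype=bool)
    coords = tuple(betas.voxel_coords.T)
    sig = (con > 0) & (pvals < null.voxel_p)
    grid[coords] = sig
    grid &= mask
    lab, n_lab = ndimage.label(grid, structure=_face_structure(mask.ndim))
    member_sizes: list[int] = []
    keep = np.zeros_like(grid)
    for l in range(1, n_lab + 1):
        size = int((lab == l).sum())
        if size >= null.k_min:
            keep |= lab == l
            member_sizes.append(size)
    flat = np.ravel_multi_index(betas.voxel_coords.T, mask.shape)
    voxels = flat[keep.ravel()[flat]]
    if voxels.size == 0:
        warnings.warn(
            f"no suprathreshold cluster survives for {category!r}", stacklevel=2
        )
    return ROIDefinition(
        category=category,
        hemisphere=hemisphere,
        voxels=np.sort(voxels),
        cluster_sizes=tuple(sorted(member_sizes, reverse=True)),
        runs_used=betas.runs,
        voxel_p=null.voxel_p,
        k_min=null.k_min,
    )


def roi_voxel_rows(betas: BetaMap, roi: ROIDefinition) -> np.ndarray:
    """Row indices into ``betas`` for the ROI's voxels."""
    if betas.voxel_coords is None or betas.grid_shape is None:
        raise ValueError("BetaMap lacks voxel coordinates")
    flat = np.ravel_multi_index(betas.voxel_coords.T, betas.grid_shape)
    lookup = {int(f): i for i, f in enumerate(flat)}
    return np.array([lookup[int(v)] for v in roi.voxels if int(v) in lookup], dtype=int)


def cs_amplitude(
    heldout_betas: BetaMap,
    roi: ROIDefinition,
    use_contrast: bool = True,
) -> float:
    """Median held-out responsiveness within the ROI (NaN when ROI is empty).

    By default the balanced contrast (β_category minus the mean of the other
    categories) is used, symmetric with ROI definition; ``use_contrast=False``
    takes the raw category β instead.  Held-out and definition runs must not
    overlap.
    """
    if roi.empty:
        return float("nan")
    if set(roi.runs_used) & set(heldout_betas.runs):
        raise ValueError(
            "held-out BetaMap shares runs with the ROI definition: "
            f"{sorted(set(roi.runs_used) & set(heldout_betas.runs))}"
        )
    rows = roi_voxel_rows(heldout_betas, roi)
    if rows.size == 0:
        return float("nan")
    if use_contrast:
        vals, _ = heldout_betas.contrast(roi.category)
    else:
        vals = heldout_betas.beta(roi.category)
    return float(np.median(vals[rows]))
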