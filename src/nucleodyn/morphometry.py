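"""3-D nucleus denoising, segmentation and shape quantification.

The chain mirrors a standard confocal morphometry workflow: median
pre-filter, Rudin–Osher–Fatemi (total-variation) denoising, automatic
global (Otsu) thresholding, 26-connected component labeling with
slice-wise hole filling and physical size gating, then per-nucleus
volume, iso-surface area and sphericity::

    psi = pi^{1/3} (6 V)^{2/3} / A

Surface area comes from a marching-cubes triangulation of the binary
mask at level 0.5 with anisotropic voxel spacing honored in physical
coordinates — voxel-face counting overestimates the area of smooth
bodies by up to 6/pi and would corrupt the sphericity. On coarse grids
the mesh may exceed psi = 1 by a small discretization margin (default
tolerance 0.02).
"""

from __future__ import annotations

from typing import List, Optional

import numpy as np
from scipy import ndimage
from skimage import filters, measure as skmeasure, morphology, restoration
from sklearn.base import BaseEstimator, TransformerMixin

from .types import MorphometryRecord, NucleusImage, NucleusMask

__all__ = [
    "denoise",
    "segment_nuclei",
    "measure",
    "NucleusSegmenter",
    "total_variation",
]


def total_variation(image: np.ndarray) -> float:
    """Isotropic discrete total variation Σ |∇u| over the voxel grid."""
    grads = np.gradient(np.asarray(image, dtype=float))
    return float(np.sqrt(sum(g * g for g in grads)).sum())


def denoise(
    image: NucleusImage,
    median_radius: int = 1,
    rof_weight: Optional[float] = None,
    rof_iters: int = 50,
) -> NucleusImage:
    """Median pre-filter followed by ROF total-variation denoising.

    The ROF step minimizes ||u - f||² + 2 w TV(u) by Chambolle's
    projection algorithm. ``rof_weight`` defaults to 0.1 × the intensity
    range of the median-filtered image; ``median_radius = 0`` skips the
    median filter and ``rof_weight = 0`` the TV step.
    """
    if median_radius < 0:
        raise ValueError("median_radius must be >= 0")
    data = np.asarray(image.data, dtype=float)
    if not np.all(np.isfinite(data)):
        raise ValueError("non-finite input values")
    if median_radius > 0:
        data = filters.median(data, footprint=morphology.ball(median_radius))
    rng_span = float(data.max() - data.min())
    if rof_weight is None:
        rof_weight = 0.1 * rng_span
    if rof_weight < 0:
        raise ValueError("rof_weight must be >= 0")
    if rof_weight > 0 and rng_span > 0:
        data = restoration.denoise_tv_chambolle(
            data, weight=rof_weight, max_num_iter=rof_iters
        )
    return NucleusImage(
        data=np.clip(data, 0.0, None),
        voxel_size=image.voxel_size,
        channel=image.channel,
    )


def segment_nuclei(
    image: NucleusImage,
    threshold_method: str = "otsu",
    min_volume: float = 50.0,
    max_volume: float = 4000.0,
) -> NucleusMask:
    """Automatic global threshold + 26-connected components.

    Foreground voxels above the threshold are labeled with full 3-D
    (26-)connectivity, holes are filled slice-by-slice along z, and
    components outside [min_volume, max_volume] μm³ are discarded.
    Raises if no nucleus survives.
    """
    data = np.asarray(image.data, dtype=float)
    if threshold_method == "otsu":
        thresh = filters.threshold_otsu(data)
    elif threshold_method == "mean":
        thresh = data.mean()
    else:
        raise ValueError(f"unknown threshold method: {threshold_method!r}")
    fg = data > thresh
    # fill internal holes per z-slice (nuclei often have dim interiors)
    for z in range(fg.shape[0]):
        fg[z] = ndimage.binary_fill_holes(fg[z])
    labels = skmeasure.label(fg, connectivity=3)
    if labels.max() == 0:
        raise ValueError("no nuclei found")
    voxvol = image.voxel_volume
    counts = np.bincount(labels.ravel())
    keep_ids = [
        lab
        for lab in range(1, counts.size)
        if min_volume <= counts[lab] * voxvol <= max_volume
    ]
    if not keep_ids:
        raise ValueError("no nuclei found within the size bounds")
    out = np.zeros_like(labels, dtype=np.int32)
    for new_id, lab in enumerate(keep_ids, start=1):
        out[labels == lab] = new_id
    return NucleusMask(labels=out, voxel_size=image.voxel_size)


def _touches_border(mask: np.ndarray) -> bool:
    return bool(
        mask[0].any()
        or mask[-1].any()
        or mask[:, 0].any()
        or mask[:, -1].any()
        or mask[:, :, 0].any()
        or mask[:, :, -1].any()
    )


def measure(
    mask: NucleusMask, condition: str = "", mesh_smoothing: float = 1.0
) -> List[MorphometryRecord]:
    """Per-nucleus volume, surface area and sphericity.

    Volume is the voxel count times the physical voxel volume. Area is a
    marching-cubes iso-surface at level 0.5 with spacing (dz, dy, dx); the
    binary label is first smoothed by a Gaussian of physical width
    ``mesh_smoothing`` × the coarsest voxel dimension, which removes the
    voxel staircase (raw binary iso-surfaces overestimate a sphere's area
    by ~12%) at the cost of a small curvature bias — the residual error on
    a well-resolved sphere is within the mesh tolerance of 0.02 on psi.
    Labels touching the image border are flagged as truncated, not
    dropped — downstream statistics exclude them.
    """
    ids = mask.label_ids
    if ids.size == 0:
        raise ValueError("mask contains no labels")
    dx, dy, dz = mask.voxel_size
    voxvol = mask.voxel_volume
    sigma_um = mesh_smoothing * max(mask.voxel_size)
    records = []
    for lab in ids:
        binary = mask.labels == lab
        volume = float(binary.sum()) * voxvol
        pad = max(2, int(np.ceil(3 * mesh_smoothing)) + 1)
        padded = np.pad(binary, pad).astype(float)
        if sigma_um > 0:
            smoothed = ndimage.gaussian_filter(
                padded, sigma=(sigma_um / dz, sigma_um / dy, sigma_um / dx)
            )
            if smoothed.max() <= 0.5:  # object thinner than the smoother
                smoothed = padded
        else:
            smoothed = padded
        verts, faces, _, _ = skmeasure.marching_cubes(
            smoothed, level=0.5, spacing=(dz, dy, dx)
        )
        area = float(skmeasure.mesh_surface_area(verts, faces))
        psi = float(np.pi ** (1 / 3) * (6.0 * volume) ** (2 / 3) / area)
        records.append(
            MorphometryRecord(
                nucleus_id=int(lab),
                volume=volume,
                surface_area=area,
                sphericity=psi,
                touches_border=_touches_border(binary),
                condition=condition,
            )
        )
    return records


class NucleusSegmenter(BaseEstimator, TransformerMixin):
    """Denoise + segment + measure as one sklearn-style transformer.

    Stateless: :meth:`fit` only validates parameters; :meth:`transform`
    maps a :class:`NucleusImage` to a :class:`NucleusMask`;
    :meth:`measure` returns the per-nucleus records.
    """

    def __init__(
        self,
        median_radius: int = 1,
        rof_weight: Optional[float] = None,
        rof_iters: int = 50,
        threshold_method: str = "otsu",
        min_volume: float = 50.0,
        max_volume: float = 4000.0,
    ) -> None:
        self.median_radius = median_radius
        self.rof_weight = rof_weight
        self.rof_iters = rof_iters
        self.threshold_method = threshold_method
        self.min_volume = min_volume
        self.max_volume = max_volume

    def fit(self, X=None, y=None):
        if self.median_radius < 0:
            raise ValueError("median_radius must be >= 0")
        if self.min_volume >= self.max_volume:
            raise ValueError("min_volume must be < max_volume")
        return self

    def transform(self, image: NucleusImage) -> NucleusMask:
        self.fit()
        smooth = denoise(
            image,
            median_radius=self.median_radius,
            rof_weight=self.rof_weight,
            rof_iters=self.rof_iters,
        )
        return segment_nuclei(
            smooth,
            threshold_method=self.threshold_method,
            min_volume=self.min_volume,
            max_volume=self.max_volume,
        )

    def measure(self, image: NucleusImage, condition: str = "") -> List[MorphometryRecord]:
        return measure(self.transform(image), condition=condition)
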