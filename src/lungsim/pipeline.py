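"""Subject-level image-analysis pipeline: segmentation -> clustering -> defects.

Bundles the imaging stages the way they are applied to each subject-condition:
automatic seed proposal from the ventilation image, seeded region growing of
the thoracic cavity on the proton image, background-anchored five-cluster
classification of the ventilation image, VDP, and size-filtered defect regions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import DomainError
from .imaging import (
    ClusterMap,
    DefectRegion,
    VolumetricImage,
    cluster_ventilation,
    compute_vdp,
    extract_defect_regions,
    segment_thoracic_cavity,
)


def auto_seeds(ventilation: VolumetricImage, n_lungs: int = 2) -> list[tuple[int, int, int]]:
    """Propose one cavity seed per lung from the ventilation image.

    The ventilation signal exists only inside the lungs, so the brightest voxel
    of a smoothed copy in each left/right half of the grid is a reliable
    in-cavity seed for the proton-image region growing.
    """
    if n_lungs < 1:
        raise DomainError("n_lungs must be >= 1")
    smooth = ndimage.gaussian_filter(ventilation.data, sigma=(2, 2, 0.5))
    nx = smooth.shape[0]
    seeds = []
    bounds = np.linspace(0, nx, n_lungs + 1).astype(int)
    for i in range(n_lungs):
        sub = smooth[bounds[i]:bounds[i + 1]]
        flat = int(np.argmax(sub))
        idx = np.unravel_index(flat, sub.shape)
        seeds.append((int(idx[0] + bounds[i]), int(idx[1]), int(idx[2])))
    return seeds


@dataclass
class SubjectImaging:
    """Image-analysis outputs for one subject-condition."""

    cavity_mask: np.ndarray
    cluster_map: ClusterMap
    vdp: float
    defect_regions: list[DefectRegion]
    seeds: list[tuple[int, int, int]]


def process_subject_images(
    proton: VolumetricImage,
    ventilation: VolumetricImage,
    seed: int = 0,
    tolerance: float = 0.15,
    k: int = 5,
    min_inplane_extent: int = 10,
    void_anchor: float | str | None = "background",
    seeds: list[tuple[int, int, int]] | None = None,
) -> SubjectImaging:
    """Run the full per-subject image analysis and return all intermediates."""
    if seeds is None:
        seeds = auto_seeds(ventilation)
    cavity = segment_thoracic_cavity(proton, seeds, tolerance=tolerance)
    clusters = cluster_ventilation(
        ventilation, cavity, k=k, seed=seed, void_anchor=void_anchor
    )
    vdp = compute_vdp(clusters)
    regions = extract_defect_regions(clusters, min_inplane_extent=min_inplane_extent)
    return SubjectImaging(
        cavity_mask=cavity,
        cluster_map=clusters,
        vdp=vdp,
        defect_regions=regions,
        seeds=seeds,
    )
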