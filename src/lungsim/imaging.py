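"""Ventilation-image analysis: cavity segmentation, clustering, VDP, defects.

The pipeline mirrors the established hyperpolarised-gas workflow: a seeded
region-growing segmentation of the thoracic cavity on the proton image, a
five-cluster K-means classification of ventilation-image intensities inside the
cavity (cluster 1 = signal void = ventilation defect, cluster 5 = hyperintense),
ventilation defect percent VDP = 100 * |C1| / |cavity|, and extraction of
26-connected defect regions large enough in-plane (> 10 voxels, about 3 cm at
3.13 mm spacing) to drive airway closure.

Images are plain numpy volumes indexed (x, y, z) with world coordinates
mm = origin + index * spacing; NIfTI round-tripping goes through nibabel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
from scipy import ndimage

from .errors import (
    DegenerateClusteringError,
    DomainError,
    GridMismatchError,
    ValidationError,
)

#: in-plane x/y and slice z voxel size of the emulated acquisition, mm
DEFAULT_SPACING = (3.13, 3.13, 15.0)

#: 26-connectivity structuring element for 3-D components and dilation
STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class VolumetricImage:
    """A 3-D image with voxel spacing and origin in mm."""

    data: np.ndarray
    spacing: tuple[float, float, float] = DEFAULT_SPACING
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    modality: str = "unknown"  # "proton" | "ventilation" | ...

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValidationError("image data must be 3-D")
        if any(s <= 0 for s in self.spacing):
            raise ValidationError("voxel spacing must be positive on every axis")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_ml(self) -> float:
        return float(np.prod(self.spacing)) / 1000.0

    def voxel_centers_mm(self) -> np.ndarray:
        """(n, 3) world coordinates of every voxel centre."""
        idx = np.indices(self.shape).reshape(3, -1).T.astype(float)
        return np.asarray(self.origin) + idx * np.asarray(self.spacing)

    def to_nifti(self, path: str | Path) -> None:
        affine = np.diag(list(self.spacing) + [1.0])
        affine[:3, 3] = self.origin
        nib.save(nib.Nifti1Image(self.data.astype(np.float32), affine), str(path))

    @classmethod
    def from_nifti(cls, path: str | Path, modality: str = "unknown") -> "VolumetricImage":
        img = nib.load(str(path))
        affine = img.affine
        spacing = tuple(float(s) for s in np.abs(np.diag(affine)[:3]))
        origin = tuple(float(o) for o in affine[:3, 3])
        return cls(
            data=np.asarray(img.dataobj, dtype=float),
            spacing=spacing,
            origin=origin,
            modality=modality,
        )


def mask_volume_ml(mask: np.ndarray, spacing: Sequence[float] = DEFAULT_SPACING) -> float:
    return float(mask.sum()) * float(np.prod(spacing)) / 1000.0


# ---------------------------------------------------------------------------
# cavity segmentation
# ---------------------------------------------------------------------------

def segment_thoracic_cavity(
    proton: VolumetricImage,
    seeds: Sequence[Sequence[int]],
    tolerance: float = 0.15,
) -> np.ndarray:
    """Seeded region growing on the proton image.

    A voxel joins the cavity when its intensity lies within the seed-voxel
    intensity range widened by ``tolerance`` times the global intensity range,
    and it is 26-connected to a seed. Returns a boolean mask covering the
    connected components that contain the seeds (one per lung is typical).
    """
    if not 0 <= tolerance <= 1:
        raise DomainError("tolerance must be in [0, 1]")
    data = proton.data
    seeds = [tuple(int(c) for c in s) for s in seeds]
    if not seeds:
        raise DomainError("at least one seed is required")
    for s in seeds:
        if len(s) != 3 or any(c < 0 or c >= n for c, n in zip(s, data.shape)):
            raise IndexError(f"seed {s} outside image grid {data.shape}")
    seed_vals = np.array([data[s] for s in seeds])
    band = tolerance * float(data.max() - data.min())
    include = (data >= seed_vals.min() - band) & (data <= seed_vals.max() + band)
    labels, _ = ndimage.label(include, structure=STRUCT_26)
    keep = {int(labels[s]) for s in seeds} - {0}
    mask = np.isin(labels, sorted(keep))
    if not mask.any():
        warnings.warn("region growing produced an empty mask", stacklevel=2)
    return mask


# ---------------------------------------------------------------------------
# ventilation clustering
# ---------------------------------------------------------------------------

@dataclass
class ClusterMap:
    """Per-voxel ventilation class: 0 outside the cavity, 1..k inside.

    Cluster labels are ordered by ascending mean intensity, so label 1 is the
    signal-void (defect) class and label k the hyperintense class.
    """

    labels: np.ndarray
    cavity: np.ndarray
    means: np.ndarray  # (k,) ascending cluster mean intensities
    spacing: tuple[float, float, float] = DEFAULT_SPACING
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    @property
    def k(self) -> int:
        return len(self.means)

    def mask(self, label: int) -> np.ndarray:
        return self.labels == label

    def to_nifti(self, path: str | Path) -> None:
        affine = np.diag(list(self.spacing) + [1.0])
        affine[:3, 3] = self.origin
        nib.save(nib.Nifti1Image(self.labels.astype(np.int16), affine), str(path))


def cluster_ventilation(
    ventilation: VolumetricImage,
    cavity: np.ndarray,
    k: int = 5,
    seed: int = 0,
    void_anchor: float | str | None = None,
    max_iter: int = 100,
    tol: float = 1e-6,
) -> ClusterMap:
    """Classify cavity voxels of a ventilation image into k intensity clusters.

    ``void_anchor=None`` runs plain Lloyd's K-means (k-means++ seeding,
    deterministic under ``seed``) on the 1-D intensity feature. With
    ``void_anchor="background"`` the lowest cluster centre is pinned to the
    noise floor estimated from outside-cavity voxels (hyperpolarised-gas images
    carry no tissue signal, so everything outside the cavity is noise); only
    the remaining k-1 centres are updated. Anchoring gives cluster 1 a fixed
    signal-void reference, which keeps VDP near zero on defect-free lungs
    instead of letting the lowest cluster absorb dim but ventilated voxels.
    A float anchors the void centre at that intensity directly.
    """
    if cavity.shape != ventilation.shape:
        raise GridMismatchError("cavity mask and image shapes differ")
    if not cavity.any():
        raise DomainError("cavity mask is empty")
    if k < 2:
        raise DomainError("k must be >= 2")
    vals = ventilation.data[cavity]
    if np.unique(vals).size < k:
        raise DegenerateClusteringError(
            f"only {np.unique(vals).size} distinct intensities for k={k}"
        )

    if void_anchor is None:
        from sklearn.cluster import KMeans

        km = KMeans(n_clusters=k, random_state=int(seed), n_init=10)
        raw = km.fit_predict(vals.reshape(-1, 1))
        centers = km.cluster_centers_.ravel()
    else:
        if void_anchor == "background":
            bg = ventilation.data[~cavity]
            anchor = float(np.median(bg)) if bg.size else float(vals.min())
            noise_sd = (
                1.4826 * float(np.median(np.abs(bg - anchor))) if bg.size else 0.0
            )
        else:
            anchor = float(void_anchor)
            noise_sd = 0.0
        centers, raw = _anchored_lloyd(vals, k, anchor, noise_sd, max_iter, tol)

    order = np.argsort(centers)
    rank = np.empty(k, dtype=int)
    rank[order] = np.arange(1, k + 1)
    labels = np.zeros(ventilation.shape, dtype=np.int16)
    labels[cavity] = rank[raw]
    means = np.full(k, np.nan)
    for lab in range(1, k + 1):
        sel = labels[cavity] == lab
        if sel.any():
            means[lab - 1] = vals[sel].mean()
    return ClusterMap(
        labels=labels,
        cavity=cavity,
        means=means,
        spacing=ventilation.spacing,
        origin=ventilation.origin,
    )


def _anchored_lloyd(
    vals: np.ndarray, k: int, anchor: float, noise_sd: float, max_iter: int, tol: float
) -> tuple[np.ndarray, np.ndarray]:
    """1-D Lloyd iteration with the first centre pinned at ``anchor``.

    The anchored centre represents the signal-void (noise-floor) class; the
    free centres describe the ventilated-signal distribution, so they are
    initialised at evenly spaced quantiles of the values above the noise floor
    (anchor + 4 noise sd). Deterministic without any random seeding.
    """
    qs = (np.arange(1, k) - 0.5) / (k - 1)
    above = vals[vals > anchor + 4.0 * noise_sd]
    free = np.quantile(above if above.size >= k - 1 else vals, qs)
    centers = np.concatenate([[anchor], free])
    assign = np.zeros(vals.size, dtype=int)
    for _ in range(max_iter):
        assign = np.argmin(np.abs(vals[:, None] - centers[None, :]), axis=1)
        new_centers = centers.copy()
        for j in range(1, k):  # centre 0 stays anchored
            sel = assign == j
            if sel.any():
                new_centers[j] = vals[sel].mean()
        shift = np.max(np.abs(new_centers - centers))
        scale = max(np.max(np.abs(centers)), 1e-12)
        centers = new_centers
        if shift <= tol * scale:
            break
    assign = np.argmin(np.abs(vals[:, None] - centers[None, :]), axis=1)
    return centers, assign


def compute_vdp(clusters: ClusterMap) -> float:
    """Ventilation defect percent: 100 * |cluster 1| / |cavity|."""
    n_cavity = int(clusters.cavity.sum())
    if n_cavity == 0:
        raise DomainError("cavity mask is empty")
    n_defect = int((clusters.labels == 1).sum())
    return 100.0 * n_defect / n_cavity


# ---------------------------------------------------------------------------
# defect regions
# ---------------------------------------------------------------------------

@dataclass
class DefectRegion:
    """A 26-connected component of the signal-void cluster."""

    region_id: int
    voxels: np.ndarray  # (n, 3) integer indices
    bbox_extent: tuple[int, int, int]  # voxels per axis
    volume_ml: float
    centroid_mm: np.ndarray

    @property
    def n_voxels(self) -> int:
        return int(self.voxels.shape[0])

    def to_dict(self) -> dict:
        return {
            "id": self.region_id,
            "voxel_count": self.n_voxels,
            "bbox": list(self.bbox_extent),
            "volume_ml": self.volume_ml,
            "centroid_mm": [float(c) for c in self.centroid_mm],
        }


def extract_defect_regions(
    clusters: ClusterMap,
    min_inplane_extent: int = 10,
) -> list[DefectRegion]:
    """Connected signal-void components exceeding the in-plane size threshold.

    Components are 26-connected; a region is retained when its bounding-box
    extent strictly exceeds ``min_inplane_extent`` voxels in x OR y (10 voxels
    at 3.13 mm is about 3 cm). Regions are returned sorted by descending
    volume and re-numbered 1..m.
    """
    c1 = clusters.labels == 1
    labels, n = ndimage.label(c1, structure=STRUCT_26)
    voxel_ml = float(np.prod(clusters.spacing)) / 1000.0
    regions: list[DefectRegion] = []
    for lab in range(1, n + 1):
        where = np.argwhere(labels == lab)
        ext = tuple(int(e) for e in (where.max(axis=0) - where.min(axis=0) + 1))
        if not (ext[0] > min_inplane_extent or ext[1] > min_inplane_extent):
            continue
        centroid = (
            np.asarray(clusters.origin)
            + where.mean(axis=0) * np.asarray(clusters.spacing)
        )
        regions.append(
            DefectRegion(
                region_id=0,
                voxels=where,
                bbox_extent=ext,
                volume_ml=where.shape[0] * voxel_ml,
                centroid_mm=centroid,
            )
        )
    regions.sort(key=lambda r: -r.n_voxels)
    for i, r in enumerate(regions, start=1):
        r.region_id = i
    return regions


def regions_to_mask(regions: Sequence[DefectRegion], shape: tuple[int, int, int]) -> np.ndarray:
    """Binary mask of the union of the given defect regions."""
    mask = np.zeros(shape, dtype=bool)
    for r in regions:
        mask[tuple(r.voxels.T)] = True
    return mask
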