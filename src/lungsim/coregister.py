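"""Fiducial-based rigid coregistration of the airway-tree model to image space.

Paired fiducial landmarks (typically 8-10 points on the outer lung boundaries)
in the model-mm frame and the image-mm frame yield a least-squares rigid
transform via the orthogonal-Procrustes (Kabsch) solution with a reflection
guard. The transformed tree is expressed in continuous voxel coordinates; the
z axis can be regrouped into 15 mm coronal slabs matching the acquisition, and
overlap is scored with the Dice similarity coefficient.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DegenerateFiducialsError, DomainError, GridMismatchError
from .imaging import DEFAULT_SPACING, VolumetricImage
from .tree import AirwayTree


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid map p -> R p + t between mm frames, with its fit residual.

    ``fre`` is the fiducial registration error: the RMS distance between the
    transformed moving fiducials and the fixed fiducials (mm); 0 for exact fits
    and for transforms constructed analytically.
    """

    rotation: np.ndarray  # (3, 3), orthonormal, det +1
    translation: np.ndarray  # (3,), mm
    fre: float = 0.0

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        if R.shape != (3, 3):
            raise DomainError("rotation must be 3x3")
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-8) or np.linalg.det(R) < 0:
            raise DomainError("rotation must be orthonormal with determinant +1")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", np.asarray(self.translation, dtype=float))

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(rotation=np.eye(3), translation=np.zeros(3))

    def apply(self, points_mm: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points_mm, dtype=float))
        out = pts @ self.rotation.T + self.translation
        return out[0] if np.asarray(points_mm).ndim == 1 else out

    def inverse(self) -> "RigidTransform":
        Rt = self.rotation.T
        return RigidTransform(rotation=Rt, translation=-Rt @ self.translation, fre=self.fre)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self after other: (self o other)(p) = self(other(p))."""
        return RigidTransform(
            rotation=self.rotation @ other.rotation,
            translation=self.rotation @ other.translation + self.translation,
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "rotation": self.rotation.tolist(),
                    "translation": self.translation.tolist(),
                    "fre_mm": self.fre,
                }
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "RigidTransform":
        d = json.loads(Path(path).read_text())
        return cls(
            rotation=np.array(d["rotation"]),
            translation=np.array(d["translation"]),
            fre=float(d.get("fre_mm", 0.0)),
        )


def rigid_from_fiducials(
    moving_points_mm: np.ndarray, fixed_points_mm: np.ndarray
) -> RigidTransform:
    """Least-squares rigid transform mapping moving fiducials onto fixed ones.

    Closed-form Kabsch/orthogonal-Procrustes solution: centre both sets, take
    the SVD of the cross-covariance, and correct the sign of the smallest
    singular direction so the result is a proper rotation. Requires >= 3
    non-collinear point pairs.
    """
    mov = np.asarray(moving_points_mm, dtype=float)
    fix = np.asarray(fixed_points_mm, dtype=float)
    if mov.shape != fix.shape or mov.ndim != 2 or mov.shape[1] != 3:
        raise DomainError("fiducial sets must be paired (n, 3) arrays")
    if mov.shape[0] < 3:
        raise DegenerateFiducialsError("need at least 3 fiducial pairs")
    mc, fc = mov.mean(axis=0), fix.mean(axis=0)
    a, b = mov - mc, fix - fc
    for pts, name in ((a, "moving"), (b, "fixed")):
        s = np.linalg.svd(pts, compute_uv=False)
        if s[1] <= 1e-9 * max(s[0], 1e-12):
            raise DegenerateFiducialsError(f"{name} fiducials are collinear or coincident")
    H = a.T @ b
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = fc - R @ mc
    residual = mov @ R.T + t - fix
    fre = float(np.sqrt(np.mean(np.sum(residual**2, axis=1))))
    return RigidTransform(rotation=R, translation=t, fre=fre)


# ---------------------------------------------------------------------------
# voxel mapping
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GridSpec:
    """Shape, spacing and origin of a voxel grid (world mm = origin + idx*spacing)."""

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float] = DEFAULT_SPACING
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    @classmethod
    def from_image(cls, image: VolumetricImage) -> "GridSpec":
        return cls(shape=image.shape, spacing=image.spacing, origin=image.origin)

    def to_voxel(self, points_mm: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points_mm, dtype=float))
        return (pts - np.asarray(self.origin)) / np.asarray(self.spacing)

    def in_grid(self, voxel_coords: np.ndarray) -> np.ndarray:
        v = np.atleast_2d(voxel_coords)
        shape = np.asarray(self.shape)
        return np.all((v > -0.5) & (v < shape - 0.5), axis=1)


@dataclass
class VoxelMappedTree:
    """Airway-tree geometry expressed in continuous voxel coordinates.

    Out-of-grid branches are flagged, not dropped. Indexing matches the source
    tree's branch ids.
    """

    grid: GridSpec
    proximal_vox: np.ndarray
    distal_vox: np.ndarray
    midpoint_vox: np.ndarray
    in_grid: np.ndarray  # midpoint inside the grid

    def midpoint_indices(self) -> np.ndarray:
        """Nearest-voxel indices of branch midpoints (may lie outside the grid)."""
        return np.rint(self.midpoint_vox).astype(int)


def apply_transform(
    tree: AirwayTree, transform: RigidTransform, grid: GridSpec | VolumetricImage
) -> VoxelMappedTree:
    """Map a model-frame tree into the voxel coordinates of an image grid."""
    if isinstance(grid, VolumetricImage):
        grid = GridSpec.from_image(grid)
    prox = grid.to_voxel(transform.apply(tree.proximal_mm))
    dist = grid.to_voxel(transform.apply(tree.distal_mm))
    mid = 0.5 * (prox + dist)
    return VoxelMappedTree(
        grid=grid,
        proximal_vox=prox,
        distal_vox=dist,
        midpoint_vox=mid,
        in_grid=grid.in_grid(mid),
    )


# ---------------------------------------------------------------------------
# slab resampling and overlap
# ---------------------------------------------------------------------------

def slab_index(
    z_mm: float | np.ndarray, thickness_mm: float = 15.0, z0_mm: float = 0.0
) -> int | np.ndarray:
    """0-based slab of a z position under half-open intervals [z0+k*t, z0+(k+1)*t)."""
    if thickness_mm <= 0:
        raise DomainError("slab thickness must be positive")
    idx = np.floor((np.asarray(z_mm, dtype=float) - z0_mm) / thickness_mm).astype(int)
    return int(idx) if np.isscalar(z_mm) else idx


def resample_to_slabs(
    occupancy: np.ndarray,
    z_centers_mm: np.ndarray,
    n_slabs: int,
    thickness_mm: float = 15.0,
    z0_mm: float = 0.0,
) -> np.ndarray:
    """Regroup the z axis of a boolean volume into contiguous slabs.

    ``occupancy`` is (nx, ny, nz_fine) with plane centres at ``z_centers_mm``;
    each output slab is the union (any-voxel projection) of the planes whose
    centre falls in its half-open interval. Every plane must map to exactly one
    slab in range, otherwise the slab count does not match the image and a
    dimension error is raised.
    """
    occ = np.asarray(occupancy, dtype=bool)
    z = np.asarray(z_centers_mm, dtype=float)
    if occ.ndim != 3 or occ.shape[2] != z.size:
        raise GridMismatchError("occupancy z planes and z_centers_mm differ in length")
    idx = slab_index(z, thickness_mm, z0_mm)
    if np.any(idx < 0) or np.any(idx >= n_slabs):
        raise GridMismatchError(
            f"plane centres map to slabs outside 0..{n_slabs - 1}"
        )
    out = np.zeros(occ.shape[:2] + (n_slabs,), dtype=bool)
    for k in range(z.size):
        out[:, :, idx[k]] |= occ[:, :, k]
    return out


def dice_coefficient(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Dice similarity 2|A&B| / (|A| + |B|); 0 (with a warning) if both empty."""
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    if a.shape != b.shape:
        raise GridMismatchError(f"mask shapes differ: {a.shape} vs {b.shape}")
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        warnings.warn("Dice of two empty masks defined as 0", stacklevel=2)
        return 0.0
    return 2.0 * int((a & b).sum()) / denom


def per_slab_dice(mask_a: np.ndarray, mask_b: np.ndarray) -> np.ndarray:
    """Dice per z slab (NaN where both slabs are empty)."""
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    if a.shape != b.shape:
        raise GridMismatchError("mask shapes differ")
    out = np.full(a.shape[2], np.nan)
    for k in range(a.shape[2]):
        denom = int(a[:, :, k].sum()) + int(b[:, :, k].sum())
        if denom:
            out[k] = 2.0 * int((a[:, :, k] & b[:, :, k]).sum()) / denom
    return out


# ---------------------------------------------------------------------------
# fiducial I/O
# ---------------------------------------------------------------------------

def fiducials_to_csv(path: str | Path, model_mm: np.ndarray, image_mm: np.ndarray) -> None:
    rows = [("model", *p) for p in np.asarray(model_mm)] + [
        ("image", *p) for p in np.asarray(image_mm)
    ]
    pd.DataFrame(rows, columns=["frame", "x_mm", "y_mm", "z_mm"]).to_csv(path, index=False)


def fiducials_from_csv(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path)
    model = df[df["frame"] == "model"][["x_mm", "y_mm", "z_mm"]].to_numpy(float)
    image = df[df["frame"] == "image"][["x_mm", "y_mm", "z_mm"]].to_numpy(float)
    return model, image
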