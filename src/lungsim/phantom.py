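"""Synthetic thoracic phantoms: proton + ventilation images with ground truth.

A phantom stands in for one subject-condition acquisition. Its geometry is a
bright body ellipsoid containing two darker lung ellipsoids (the thoracic
cavity) on the default 128 x 128 x 14 grid at 3.13 x 3.13 x 15 mm spacing. The
ventilation image carries signal only inside the cavity: a smoothly varying
ventilated field plus zero-mean Gaussian noise at the requested SNR, with
signal-void defect blobs grown until the defect volume fraction is within 0.5
percentage points of the target. When an airway tree and a model-to-image
transform are supplied, blobs are grown from the terminal territory of randomly
chosen subtrees so that defects are segmental/subsegmental and spatially
aligned with closable airways; otherwise random ellipsoidal blobs are used.

Each phantom also emits paired fiducial landmarks on the lung boundary in both
the model-mm and image-mm frames (image side perturbed by the fiducial
localisation error) plus the true transform, so the registration stage can be
exercised and scored against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

from .coregister import GridSpec, RigidTransform
from .errors import PhantomSpecError, ValidationError
from .imaging import DEFAULT_SPACING, STRUCT_26, VolumetricImage
from .tree import AirwayTree

#: lung/body geometry as fractions of the field of view, so phantoms scale
#: coherently to smaller test grids
_BODY_SEMI_FRAC = (0.40, 0.31, 0.476)
_LUNG_SEMI_FRAC = (0.175, 0.287, 0.429)
_LUNG_OFFSET_X_FRAC = 0.187


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic subject-condition acquisition."""

    shape: tuple[int, int, int] = (128, 128, 14)
    spacing: tuple[float, float, float] = DEFAULT_SPACING
    defect_fraction_pct: float = 10.0
    defect_tolerance_pct: float = 0.5
    snr: float = 20.0
    n_fiducials: int = 10
    fiducial_noise_mm: float = 1.0
    rotation_max_deg: float = 3.0
    translation_jitter_mm: float = 5.0
    proton_body: float = 800.0
    proton_cavity: float = 100.0
    proton_background: float = 30.0
    ventilation_mean: float = 600.0
    ventilation_texture: float = 0.08
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.defect_fraction_pct <= 100:
            raise PhantomSpecError("defect fraction must be in [0, 100] percent")
        if self.snr <= 0:
            raise PhantomSpecError("SNR must be positive")
        if self.n_fiducials < 3:
            raise PhantomSpecError("need at least 3 fiducials for a rigid fit")


@dataclass
class Phantom:
    """One generated subject-condition with full ground truth."""

    spec: PhantomSpec
    proton: VolumetricImage
    ventilation: VolumetricImage
    cavity_mask: np.ndarray
    defect_mask: np.ndarray
    true_vdp: float
    fiducials_model_mm: np.ndarray
    fiducials_image_mm: np.ndarray  # with localisation noise applied
    transform_true: RigidTransform  # model frame -> image frame
    lung_centers_mm: np.ndarray  # (2, 3), image frame
    lung_semi_mm: np.ndarray  # (3,)

    @property
    def grid(self) -> GridSpec:
        return GridSpec.from_image(self.proton)

    def registered_model_mask(self, transform_est: RigidTransform) -> np.ndarray:
        """Model-frame lung volume mapped into the image grid by an estimate.

        The model-frame lung surface is the true-transform preimage of the
        image-frame lung ellipsoids, so with a perfect estimate this mask
        equals the cavity mask exactly; the Dice against the cavity therefore
        isolates registration error.
        """
        centers = self.proton.voxel_centers_mm()
        back = self.transform_true.apply(transform_est.inverse().apply(centers))
        inside = np.zeros(centers.shape[0], dtype=bool)
        for c in self.lung_centers_mm:
            u = (back - c) / self.lung_semi_mm
            inside |= np.einsum("ij,ij->i", u, u) <= 1.0
        return inside.reshape(self.proton.shape)


def _ellipsoid_mask(grid: GridSpec, center_mm: np.ndarray, semi_mm: np.ndarray) -> np.ndarray:
    idx = np.indices(grid.shape).astype(float)
    coords = np.stack(
        [idx[a] * grid.spacing[a] + grid.origin[a] for a in range(3)], axis=-1
    )
    u = (coords - center_mm) / semi_mm
    return np.einsum("...i,...i->...", u, u) <= 1.0


def _random_rotation(rng: np.random.Generator, max_deg: float) -> np.ndarray:
    angles = np.deg2rad(rng.uniform(-max_deg, max_deg, size=3))
    cx, cy, cz = np.cos(angles)
    sx, sy, sz = np.sin(angles)
    rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return rz @ ry @ rx


def _subtree_terminal_voxels(
    tree: AirwayTree,
    children: list[list[int]],
    root: int,
    term_vox: np.ndarray,
) -> np.ndarray:
    """Nearest-voxel indices of the terminal branches of one subtree."""
    stack = [root]
    terms = []
    while stack:
        b = stack.pop()
        if tree.is_terminal[b]:
            terms.append(b)
        stack.extend(children[b])
    return term_vox[terms]


def _grow_defects_from_tree(
    rng: np.random.Generator,
    spec: PhantomSpec,
    grid: GridSpec,
    cavity: np.ndarray,
    tree: AirwayTree,
    transform: RigidTransform,
) -> np.ndarray:
    """Accumulate subtree-aligned signal-void blobs up to the target fraction."""
    children = tree.children_lists()
    term_vox = np.rint(grid.to_voxel(transform.apply(tree.distal_mm))).astype(int)
    mid_vox = np.rint(grid.to_voxel(transform.apply(tree.midpoints_mm))).astype(int)
    in_grid = np.all((mid_vox >= 0) & (mid_vox < np.asarray(grid.shape)), axis=1)
    in_cavity = np.zeros(tree.n_branches, dtype=bool)
    ig = np.flatnonzero(in_grid)
    in_cavity[ig] = cavity[mid_vox[ig, 0], mid_vox[ig, 1], mid_vox[ig, 2]]

    gen_lo, gen_hi = 9, int(tree.generation.max())
    candidates = {
        g: list(np.flatnonzero((tree.generation == g) & in_cavity))
        for g in range(gen_lo, gen_hi + 1)
    }
    n_cavity = int(cavity.sum())
    target = spec.defect_fraction_pct
    tol = spec.defect_tolerance_pct
    defect = np.zeros(grid.shape, dtype=bool)
    shape = np.asarray(grid.shape)

    for _ in range(2000):
        achieved = 100.0 * defect.sum() / n_cavity
        if achieved >= target - tol:
            break
        deficit_vox = (target - achieved) / 100.0 * n_cavity
        placed = False
        for g in range(gen_lo, gen_hi + 1):
            pool = candidates.get(g) or []
            if not pool:
                continue
            i = int(rng.integers(len(pool)))
            b = pool.pop(i)
            tv = _subtree_terminal_voxels(tree, children, b, term_vox)
            tv = tv[np.all((tv >= 0) & (tv < shape), axis=1)]
            if tv.size == 0:
                continue
            blob = np.zeros(grid.shape, dtype=bool)
            blob[tv[:, 0], tv[:, 1], tv[:, 2]] = True
            blob = ndimage.binary_dilation(blob, structure=STRUCT_26) & cavity
            gained = int((blob & ~defect).sum())
            if gained == 0:
                continue
            # take the blob unless it overshoots the band; then try deeper
            # (smaller) subtrees
            if gained <= deficit_vox + tol / 100.0 * n_cavity or g == gen_hi:
                defect |= blob
                placed = True
                break
        if not placed:
            raise PhantomSpecError(
                f"cannot reach defect fraction {target}% "
                f"(achieved {achieved:.2f}% before exhausting subtrees)"
            )
    else:
        raise PhantomSpecError("defect growth did not converge")
    return defect


def _grow_defects_blobs(
    rng: np.random.Generator,
    spec: PhantomSpec,
    grid: GridSpec,
    cavity: np.ndarray,
) -> np.ndarray:
    """Random compact ellipsoidal signal-void blobs (no tree alignment)."""
    n_cavity = int(cavity.sum())
    target = spec.defect_fraction_pct
    tol = spec.defect_tolerance_pct
    defect = np.zeros(grid.shape, dtype=bool)
    cavity_idx = np.argwhere(cavity)
    for _ in range(5000):
        achieved = 100.0 * defect.sum() / n_cavity
        if achieved >= target - tol:
            return defect
        deficit_vox = (target - achieved) / 100.0 * n_cavity
        # in-plane radius sized to the remaining deficit, down to single voxels
        r_inplane = int(np.clip(np.sqrt(deficit_vox / 6.0), 1, 8))
        r_z = 1 if r_inplane >= 4 else 0
        center = cavity_idx[int(rng.integers(len(cavity_idx)))]
        semi = np.array([r_inplane, r_inplane, max(r_z, 0.5)])
        lo = np.maximum(center - [r_inplane, r_inplane, r_z], 0)
        hi = np.minimum(center + [r_inplane, r_inplane, r_z] + 1, grid.shape)
        sub = np.indices(tuple(hi - lo)).reshape(3, -1).T + lo
        u = (sub - center) / semi
        blob_idx = sub[np.einsum("ij,ij->i", u, u) <= 1.0]
        blob = np.zeros(grid.shape, dtype=bool)
        blob[blob_idx[:, 0], blob_idx[:, 1], blob_idx[:, 2]] = True
        blob &= cavity
        gained = int((blob & ~defect).sum())
        if gained == 0:
            continue
        if gained > deficit_vox + tol / 100.0 * n_cavity and r_inplane > 1:
            continue  # resample with the shrinking radius schedule
        defect |= blob
    raise PhantomSpecError(
        f"cannot reach defect fraction {target}% within the cavity"
    )


def generate_phantom(
    spec: PhantomSpec,
    tree: AirwayTree | None = None,
    model_center_mm: Sequence[float] = (0.0, 0.0, 0.0),
) -> Phantom:
    """Generate one phantom; identical specs (and tree) give identical phantoms."""
    rng = np.random.default_rng(spec.seed)
    grid = GridSpec(shape=spec.shape, spacing=spec.spacing, origin=(0.0, 0.0, 0.0))
    fov = np.asarray(spec.shape) * np.asarray(spec.spacing)
    center = fov / 2.0
    body_semi = fov * np.asarray(_BODY_SEMI_FRAC)
    lung_semi = fov * np.asarray(_LUNG_SEMI_FRAC)
    dx = fov[0] * _LUNG_OFFSET_X_FRAC
    lung_centers = np.array(
        [center - [dx, 0.0, 0.0], center + [dx, 0.0, 0.0]]
    )

    cavity = np.zeros(spec.shape, dtype=bool)
    for c in lung_centers:
        cavity |= _ellipsoid_mask(grid, c, lung_semi)
    if not cavity.any():
        raise PhantomSpecError("phantom grid too small to contain a cavity")
    # body = ellipsoid plus a closed shell of tissue around the lungs, so the
    # dark cavity is never 26-connected to the dark background
    body = _ellipsoid_mask(grid, center, body_semi)
    body |= ndimage.binary_dilation(cavity, structure=STRUCT_26, iterations=3)

    # true model->image transform: small rotation, translate model centre to
    # the cavity centre with jitter
    rot = _random_rotation(rng, spec.rotation_max_deg)
    jitter = rng.uniform(-spec.translation_jitter_mm, spec.translation_jitter_mm, 3)
    translation = center + jitter - rot @ np.asarray(model_center_mm, dtype=float)
    transform_true = RigidTransform(rotation=rot, translation=translation)

    # defects
    if spec.defect_fraction_pct <= spec.defect_tolerance_pct:
        defect = np.zeros(spec.shape, dtype=bool)
    elif tree is not None:
        defect = _grow_defects_from_tree(rng, spec, grid, cavity, tree, transform_true)
    else:
        defect = _grow_defects_blobs(rng, spec, grid, cavity)
    true_vdp = 100.0 * defect.sum() / cavity.sum()

    # proton image: bright body, dark cavity, dark background
    proton_data = np.full(spec.shape, spec.proton_background)
    proton_data[body] = spec.proton_body
    proton_data[cavity] = spec.proton_cavity
    proton_data = proton_data + rng.normal(
        0.0, spec.proton_body / spec.snr, size=spec.shape
    )

    # ventilation image: smooth ventilated field, zeroed in defects
    texture = ndimage.gaussian_filter(
        rng.standard_normal(spec.shape), sigma=(6.0, 6.0, 1.0)
    )
    sd = texture.std()
    if sd > 0:
        texture /= sd
    vent_data = np.zeros(spec.shape)
    vent_data[cavity] = spec.ventilation_mean * (
        1.0 + spec.ventilation_texture * texture[cavity]
    )
    vent_data[defect] = 0.0
    vent_data = vent_data + rng.normal(
        0.0, spec.ventilation_mean / spec.snr, size=spec.shape
    )

    # fiducials on the lung boundaries, paired across frames
    n_f = spec.n_fiducials
    which = rng.integers(0, 2, size=n_f)
    theta = rng.uniform(0, np.pi, size=n_f)
    phi = rng.uniform(0, 2 * np.pi, size=n_f)
    unit = np.stack(
        [np.sin(theta) * np.cos(phi), np.sin(theta) * np.sin(phi), np.cos(theta)],
        axis=1,
    )
    fid_image = lung_centers[which] + unit * lung_semi
    fid_model = transform_true.inverse().apply(fid_image)
    fid_image_noisy = fid_image + rng.normal(0.0, spec.fiducial_noise_mm, fid_image.shape)

    proton = VolumetricImage(proton_data, spec.spacing, (0.0, 0.0, 0.0), "proton")
    ventilation = VolumetricImage(vent_data, spec.spacing, (0.0, 0.0, 0.0), "ventilation")
    return Phantom(
        spec=spec,
        proton=proton,
        ventilation=ventilation,
        cavity_mask=cavity,
        defect_mask=defect,
        true_vdp=float(true_vdp),
        fiducials_model_mm=fid_model,
        fiducials_image_mm=fid_image_noisy,
        transform_true=transform_true,
        lung_centers_mm=lung_centers,
        lung_semi_mm=lung_semi,
    )
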