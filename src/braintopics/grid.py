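"""Analysis grids: masked brain volumes, coordinate transforms, NIfTI I/O.

All spatial computation in this package happens either in continuous MNI
millimetre space (peak coordinates, Gaussian spatial distributions) or on a
masked voxel grid (topic maps, decoding inputs).  :class:`BrainGrid` owns the
mapping between the two: a volume shape, a voxel->mm affine, a boolean mask,
and a bijection between masked voxels and the dense index range ``0..V-1``
used by every length-``V`` vector elsewhere in the package.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

logger = logging.getLogger(__name__)

#: Standard MNI152 2mm template geometry (RAS- affine, FSL/nilearn convention).
MNI152_2MM_SHAPE = (91, 109, 91)
MNI152_2MM_AFFINE = np.array(
    [
        [-2.0, 0.0, 0.0, 90.0],
        [0.0, 2.0, 0.0, -126.0],
        [0.0, 0.0, 2.0, -72.0],
        [0.0, 0.0, 0.0, 1.0],
    ]
)


def synthetic_brain_mask(shape, affine) -> np.ndarray:
    """Ellipsoidal stand-in for a gray-matter mask, generated in code.

    This is a synthetic mask: an ellipsoid roughly matching adult brain
    extents in MNI space (semi-axes 70 x 85 x 75 mm about (0, -18, 10)).  It
    exists so the package runs end to end without an external atlas file;
    real analyses should supply an actual gray-matter mask NIfTI.
    """
    ijk = np.indices(shape).reshape(3, -1)
    hom = np.vstack([ijk, np.ones((1, ijk.shape[1]))])
    mm = (np.asarray(affine) @ hom)[:3]
    center = np.array([0.0, -18.0, 10.0])
    semi = np.array([70.0, 85.0, 75.0])
    d = ((mm - center[:, None]) / semi[:, None]) ** 2
    return (d.sum(axis=0) <= 1.0).reshape(shape)


@dataclass
class BrainGrid:
    """A masked analysis grid in MNI space.

    Parameters
    ----------
    shape : tuple of int
        Voxels per axis.
    affine : (4, 4) ndarray
        Voxel-index -> MNI-mm transform.
    mask : ndarray of bool
        In-analysis voxels; must match ``shape``.
    """

    shape: tuple
    affine: np.ndarray
    mask: np.ndarray
    _flat_to_dense: np.ndarray = field(init=False, repr=False)
    _dense_to_flat: np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        self.shape = tuple(int(s) for s in self.shape)
        self.affine = np.asarray(self.affine, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if np.linalg.det(self.affine[:3, :3]) == 0:
            raise ValueError("affine is singular")
        if self.mask.shape != self.shape:
            raise ValueError("mask shape does not match grid shape")
        if not self.mask.any():
            raise ValueError("mask selects no voxels")
        self._dense_to_flat = np.flatnonzero(self.mask.ravel(order="C"))
        inv = np.full(int(np.prod(self.shape)), -1, dtype=np.int64)
        inv[self._dense_to_flat] = np.arange(self._dense_to_flat.size)
        self._flat_to_dense = inv

    @property
    def n_voxels(self) -> int:
        """Number of masked voxels V."""
        return int(self._dense_to_flat.size)

    @property
    def voxel_size(self) -> np.ndarray:
        """Edge lengths (mm) of one voxel along each axis."""
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    def masked_coordinates(self) -> np.ndarray:
        """(V, 3) MNI-mm centers of the masked voxels, in index order."""
        ijk = np.array(np.unravel_index(self._dense_to_flat, self.shape)).T
        return self.voxel_to_mm(ijk)

    def voxel_to_mm(self, ijk) -> np.ndarray:
        ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    def mm_to_voxel(self, mm) -> np.ndarray:
        """Nearest voxel index for each mm coordinate (may lie off-grid)."""
        mm = np.atleast_2d(np.asarray(mm, dtype=float))
        inv = np.linalg.inv(self.affine)
        ijk = mm @ inv[:3, :3].T + inv[:3, 3]
        return np.rint(ijk).astype(np.int64)

    def mm_to_masked_index(self, mm, snap_mm: float = 0.0) -> np.ndarray:
        """Masked-voxel index for each mm coordinate; -1 if unmappable.

        A coordinate whose containing voxel is off-grid or unmasked is
        snapped to the nearest masked voxel center if one lies within
        ``snap_mm`` millimetres (ties broken by smallest voxel index),
        otherwise reported as -1.
        """
        mm = np.atleast_2d(np.asarray(mm, dtype=float))
        ijk = self.mm_to_voxel(mm)
        out = np.full(len(mm), -1, dtype=np.int64)
        inside = np.all((ijk >= 0) & (ijk < np.array(self.shape)), axis=1)
        flat = np.zeros(len(mm), dtype=np.int64)
        flat[inside] = np.ravel_multi_index(tuple(ijk[inside].T), self.shape)
        out[inside] = self._flat_to_dense[flat[inside]]
        if snap_mm > 0 and (out < 0).any():
            centers = self.masked_coordinates()
            for i in np.flatnonzero(out < 0):
                d2 = ((centers - mm[i]) ** 2).sum(axis=1)
                j = int(np.argmin(d2))  # argmin takes the smallest index on ties
                if d2[j] <= snap_mm**2:
                    out[i] = j
        return out

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_mask_img(cls, img) -> "BrainGrid":
        """Build a grid from a mask NIfTI image (path or nibabel image)."""
        if isinstance(img, (str,)) or hasattr(img, "__fspath__"):
            img = nib.load(str(img))
        data = np.asarray(img.dataobj)
        return cls(shape=data.shape, affine=img.affine, mask=data > 0)

    @classmethod
    def mni152(cls, mask=None) -> "BrainGrid":
        """The standard MNI152 2mm grid.

        ``mask`` may be a NIfTI path/image resampled-compatible with the grid;
        when omitted a synthetic ellipsoid mask is used (see
        :func:`synthetic_brain_mask`).
        """
        if mask is None:
            m = synthetic_brain_mask(MNI152_2MM_SHAPE, MNI152_2MM_AFFINE)
        else:
            if isinstance(mask, (str,)) or hasattr(mask, "__fspath__"):
                mask = nib.load(str(mask))
            if tuple(mask.shape) != MNI152_2MM_SHAPE:
                raise ValueError("mask is not on the MNI152 2mm grid")
            m = np.asarray(mask.dataobj) > 0
        return cls(shape=MNI152_2MM_SHAPE, affine=MNI152_2MM_AFFINE, mask=m)

    @classmethod
    def toy(cls, shape=(12, 12, 12), spacing=4.0, mask=None) -> "BrainGrid":
        """Small centered grid for tests and synthetic experiments."""
        shape = tuple(int(s) for s in shape)
        spacing = float(spacing)
        affine = np.eye(4)
        affine[0, 0] = affine[1, 1] = affine[2, 2] = spacing
        affine[:3, 3] = -spacing * (np.array(shape) - 1) / 2.0
        if mask is None:
            mask = np.ones(shape, dtype=bool)
        return cls(shape=shape, affine=affine, mask=mask)

    def to_mask_img(self) -> nib.Nifti1Image:
        return nib.Nifti1Image(self.mask.astype(np.uint8), self.affine)


def resample_to_grid(image, grid: BrainGrid) -> np.ndarray:
    """Resample a NIfTI volume onto ``grid`` and return its masked values.

    Uses an affine transform with continuous interpolation onto the grid's
    voxel centers; voxels outside the mask are discarded.  Returns a length-V
    vector in masked-voxel order.
    """
    from nilearn.image import resample_img

    if isinstance(image, (str,)) or hasattr(image, "__fspath__"):
        image = nib.load(str(image))
    if np.linalg.det(np.asarray(image.affine)[:3, :3]) == 0:
        raise ValueError("image affine is singular")
    if tuple(image.shape) == grid.shape and np.allclose(image.affine, grid.affine):
        data = np.asarray(image.dataobj, dtype=float)
    else:
        res = resample_img(
            image,
            target_affine=grid.affine,
            target_shape=grid.shape,
            interpolation="continuous",
            force_resample=True,
            copy_header=True,
        )
        data = np.asarray(res.dataobj, dtype=float)
    return data[grid.mask]


def write_map(values, grid: BrainGrid, path, dtype=np.float32) -> None:
    """Write a masked voxel vector as a NIfTI volume (unmasked voxels = 0)."""
    values = np.asarray(values)
    if values.ndim != 1 or values.size != grid.n_voxels:
        raise ValueError(
            f"expected a length-{grid.n_voxels} masked vector, got shape {values.shape}"
        )
    vol = np.zeros(grid.shape, dtype=dtype)
    vol[grid.mask] = values.astype(dtype)
    nib.Nifti1Image(vol, grid.affine).to_filename(str(path))


def read_map(path, grid: BrainGrid) -> np.ndarray:
    """Read a NIfTI volume written on ``grid`` back as a masked vector."""
    img = nib.load(str(path))
    if tuple(img.shape) != grid.shape:
        raise ValueError("image shape does not match grid")
    return np.asarray(img.dataobj)[grid.mask]
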