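"""Gray-matter volumes, ROI atlases, masks, NIfTI I/O and smoothing.

All volumes in a run live on one common grid (identical shape and voxel
size); no resampling is performed. Data are handled in voxel space — the
atlas is assumed pre-aligned to the volumes, as after template-space
normalization.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

from .errors import FormatError, GridMismatchError, ParameterError

#: FWHM of a Gaussian = sigma * 2*sqrt(2*ln 2)
FWHM_PER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))

ROI_NAMES = ("MTL", "frontal", "temporal", "parietal", "occipital", "other-GM")


def _grid_token(shape, voxel_size) -> str:
    s = "x".join(str(int(n)) for n in shape)
    v = "x".join(f"{float(z):g}" for z in voxel_size)
    return f"{s}@{v}mm"


@dataclass
class GMVolume:
    """One subject's gray-matter concentration map on a fixed grid.

    ``data`` is dimensionless GM concentration/amount (modulated segment
    values, typically in [0, ~1.5]); ``voxel_size`` is the physical edge
    length in mm per axis.
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float]
    affine: np.ndarray | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise FormatError(f"volume must be 3-D, got ndim={self.data.ndim}")
        if not np.all(np.isfinite(self.data)):
            raise ParameterError("volume contains non-finite values")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ParameterError(f"voxel_size must be 3 positive lengths, got {self.voxel_size}")

    @property
    def grid_id(self) -> str:
        return _grid_token(self.data.shape, self.voxel_size)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size))

    def like(self, data: np.ndarray) -> "GMVolume":
        """New volume with the same grid and metadata but different data."""
        return GMVolume(data, self.voxel_size, affine=self.affine)


@dataclass
class ROIAtlas:
    """Integer-labeled parcellation on the common grid (0 = background).

    ``label_table`` maps each nonzero label to an ROI name. "Total GM" is
    defined as the union of all nonzero labels.
    """

    labels: np.ndarray
    label_table: dict[int, str]
    voxel_size: tuple[float, float, float]
    affine: np.ndarray | None = None

    def __post_init__(self):
        arr = np.asarray(self.labels)
        if arr.ndim != 3:
            raise FormatError(f"atlas must be 3-D, got ndim={arr.ndim}")
        if not np.all(np.isfinite(np.asarray(arr, dtype=np.float64))):
            raise FormatError("atlas contains non-finite values")
        if not np.all(np.equal(np.mod(arr, 1), 0)):
            raise FormatError("atlas data are not integer-valued")
        self.labels = arr.astype(np.int32)
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        present = set(np.unique(self.labels)) - {0}
        missing = present - set(self.label_table)
        if missing:
            raise FormatError(f"labels without a name in label_table: {sorted(missing)}")

    @property
    def grid_id(self) -> str:
        return _grid_token(self.labels.shape, self.voxel_size)

    @property
    def roi_names(self) -> list[str]:
        return [self.label_table[k] for k in sorted(self.label_table)]

    def roi_mask(self, roi: str) -> np.ndarray:
        """Boolean mask of one named ROI, or the union of all for ``total``."""
        if roi == "total":
            return self.labels > 0
        labels = [k for k, v in self.label_table.items() if v == roi]
        if not labels:
            raise ParameterError(f"unknown ROI {roi!r}; atlas has {self.roi_names}")
        return np.isin(self.labels, labels)


@dataclass
class BrainMask:
    """Boolean field restricting Z computation to voxels with reference support."""

    mask: np.ndarray
    voxel_size: tuple[float, float, float]

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        self.voxel_size = tuple(float(v) for v in self.voxel_size)

    @property
    def grid_id(self) -> str:
        return _grid_token(self.mask.shape, self.voxel_size)

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


def assert_same_grid(a, b) -> None:
    """Raise :class:`GridMismatchError` unless a and b share shape and voxel size."""
    if a.grid_id != b.grid_id:
        raise GridMismatchError(f"grid mismatch: {a.grid_id} vs {b.grid_id}")


def fwhm_to_sigma(fwhm_mm: float) -> float:
    """Convert Gaussian kernel FWHM (mm) to standard deviation (mm).

    sigma = FWHM / (2 * sqrt(2 * ln 2)) ≈ FWHM / 2.35482.
    """
    if fwhm_mm < 0:
        raise ParameterError(f"FWHM must be >= 0, got {fwhm_mm}")
    return float(fwhm_mm) / FWHM_PER_SIGMA


def gaussian_smooth(vol: GMVolume, fwhm_mm: float) -> GMVolume:
    """Smooth a volume with an isotropic Gaussian of the given FWHM in mm.

    Anisotropic voxels are handled by per-axis sigmas in voxel units.
    Boundary handling is zero-padding (standard VBM practice): signal near
    the grid edge is attenuated. ``fwhm_mm = 0`` returns the input unchanged.
    """
    sigma_mm = fwhm_to_sigma(fwhm_mm)
    if sigma_mm == 0:
        return vol
    sigma_vox = [sigma_mm / v for v in vol.voxel_size]
    # truncate at 8 sigma: kernel tails < 1e-14, so the separable filter is
    # indistinguishable from dense convolution with the sampled Gaussian
    out = ndimage.gaussian_filter(
        vol.data, sigma=sigma_vox, mode="constant", cval=0.0, truncate=8.0
    )
    return vol.like(out)


def make_brain_mask(mean_vol: GMVolume, epsilon: float = 0.05) -> BrainMask:
    """Mask of voxels where the reference mean exceeds ``epsilon``.

    Prevents division by near-zero SD in background. The default 0.05 GM
    concentration excludes background while keeping the cortical ribbon.
    """
    if epsilon < 0:
        raise ParameterError(f"epsilon must be >= 0, got {epsilon}")
    return BrainMask(mean_vol.data > epsilon, mean_vol.voxel_size)


# ---------------------------------------------------------------------------
# NIfTI and label-table I/O


def _load_nifti(path) -> tuple[np.ndarray, tuple, np.ndarray]:
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several types for bad files
        raise FormatError(f"{path}: not a readable NIfTI file ({exc})") from exc
    if len(img.shape) != 3:
        raise FormatError(f"{path}: expected a 3-D scalar image, got shape {img.shape}")
    data = np.asanyarray(img.dataobj, dtype=np.float64)
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    return data, zooms, np.asarray(img.affine)


def read_volume(path) -> GMVolume:
    """Read a scalar 3-D NIfTI image as a :class:`GMVolume`."""
    data, zooms, affine = _load_nifti(path)
    if not np.all(np.isfinite(data)):
        raise FormatError(f"{path}: volume contains non-finite values")
    return GMVolume(data, zooms, affine=affine)


def read_atlas(path, label_table_path=None) -> ROIAtlas:
    """Read an integer-labeled NIfTI atlas plus its TSV label table.

    The TSV has two columns, ``label<TAB>name``. If no path is given,
    ``<atlas>.labels.tsv`` next to the atlas is used.
    """
    data, zooms, affine = _load_nifti(path)
    if not np.all(np.equal(np.mod(data, 1), 0)):
        raise FormatError(f"{path}: atlas data are not integer-valued")
    if label_table_path is None:
        label_table_path = Path(str(path)).with_suffix("").with_suffix("")
        label_table_path = Path(str(label_table_path) + ".labels.tsv")
    table = read_label_table(label_table_path)
    return ROIAtlas(data.astype(np.int32), table, zooms, affine=affine)


def read_label_table(path) -> dict[int, str]:
    table: dict[int, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line.lower().startswith("label\t"):
            continue
        label, name = line.split("\t")
        table[int(label)] = name
    return table


def write_label_table(table: dict[int, str], path) -> None:
    lines = ["label\tname"] + [f"{k}\t{table[k]}" for k in sorted(table)]
    Path(path).write_text("\n".join(lines) + "\n")


def write_volume(obj, path) -> None:
    """Write a GMVolume, ROIAtlas or BrainMask as NIfTI-1.

    The affine recorded at read time is preserved; volumes created in
    memory get a diagonal affine from their voxel size.
    """
    if isinstance(obj, GMVolume):
        data, dtype = obj.data, np.float64
    elif isinstance(obj, ROIAtlas):
        data, dtype = obj.labels, np.int32
    elif isinstance(obj, BrainMask):
        data, dtype = obj.mask.astype(np.uint8), np.uint8
    else:
        raise ParameterError(f"cannot write object of type {type(obj).__name__}")
    affine = getattr(obj, "affine", None)
    if affine is None:
        affine = np.diag(list(obj.voxel_size) + [1.0])
    img = nib.Nifti1Image(np.asarray(data, dtype=dtype), affine)
    img.header.set_zooms(obj.voxel_size)
    nib.save(img, str(path))


def write_atlas(atlas: ROIAtlas, path) -> None:
    """Write atlas NIfTI plus its ``<path>.labels.tsv`` sidecar."""
    write_volume(atlas, path)
    base = Path(str(path)).with_suffix("").with_suffix("")
    write_label_table(atlas.label_table, Path(str(base) + ".labels.tsv"))
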