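"""Volumetric images, atlases, and PET-style preprocessing.

The unit of imaging data throughout the package is :class:`Volume`, a dense 3D
scalar grid with voxel spacing carried in millimetres.  An :class:`Atlas` is an
integer-labelled grid of the same shape plus a region table; label 0 is
background and is excluded from every regional statistic.

Preprocessing mirrors standard FDG-PET practice: isotropic Gaussian smoothing
specified as FWHM in millimetres, and intensity normalization to the mean of a
reference region (classically the cerebellum), after which image values are
dimensionless ratios with the reference mean pinned at 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

__all__ = [
    "Volume",
    "Atlas",
    "read_volume",
    "write_volume",
    "read_atlas",
    "write_atlas",
    "smooth_gaussian",
    "normalize_to_reference",
    "roi_means",
    "FWHM_TO_SIGMA",
]

#: FWHM = sigma * 2*sqrt(2*ln 2) for a Gaussian kernel.
FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class Volume:
    """A 3D scalar image with voxel size metadata.

    Parameters
    ----------
    data:
        3D array of finite values.
    voxel_size_mm:
        Edge length of a voxel along each axis, in mm.
    space_tag:
        Free-text identifier of the spatial reference frame.  Carried
        opaquely; the package never interprets it beyond equality checks.
    """

    data: np.ndarray
    voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    space_tag: str = "synthetic"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"volume must be 3D, got shape {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite values")
        vs = tuple(float(v) for v in self.voxel_size_mm)
        if len(vs) != 3 or any(v <= 0 for v in vs):
            raise ValueError(f"voxel sizes must be 3 positive reals, got {vs}")
        self.voxel_size_mm = vs

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def copy_with(self, data: np.ndarray) -> "Volume":
        return Volume(data, self.voxel_size_mm, self.space_tag)


@dataclass
class Atlas:
    """Integer-labelled parcellation aligned to a :class:`Volume` grid.

    ``regions`` is a table with columns ``region_id``, ``name``,
    ``abbreviation`` (and optionally ``is_reference``); every non-zero label in
    ``labels`` must appear in it.  ``reference_ids`` are the regions whose
    pooled mean defines the intensity-normalization denominator.
    """

    labels: np.ndarray
    regions: pd.DataFrame
    reference_ids: frozenset[int] = field(default_factory=frozenset)
    voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("atlas labels must be integers")
        if self.labels.ndim != 3:
            raise ValueError("atlas labels must form a 3D grid")
        present = set(np.unique(self.labels)) - {0}
        table_ids = set(int(i) for i in self.regions["region_id"])
        if len(table_ids) != len(self.regions):
            raise ValueError("duplicate region_id in region table")
        missing = present - table_ids
        if missing:
            raise ValueError(f"labels present in grid but absent from region table: {sorted(missing)}")
        self.reference_ids = frozenset(int(i) for i in self.reference_ids)
        if not self.reference_ids and "is_reference" in self.regions.columns:
            self.reference_ids = frozenset(
                int(r) for r in self.regions.loc[self.regions["is_reference"].astype(bool), "region_id"]
            )

    @property
    def region_ids(self) -> np.ndarray:
        """Region ids in region-table order (the canonical column order)."""
        return np.asarray(self.regions["region_id"], dtype=int)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]


# ---------------------------------------------------------------------------
# NIfTI I/O


def _affine(voxel_size_mm: tuple[float, float, float]) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = voxel_size_mm
    return aff


def read_volume(path: str | Path) -> Volume:
    """Read a NIfTI-1 image as a :class:`Volume`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such volume file: {path}")
    try:
        img = nib.load(str(path))
    except Exception as exc:  # malformed file
        raise ValueError(f"cannot parse {path} as NIfTI: {exc}") from exc
    data = np.asanyarray(img.dataobj, dtype=np.float64)
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    return Volume(data, zooms, space_tag=str(path.name))


def write_volume(volume: Volume, path: str | Path) -> Path:
    """Write a :class:`Volume` as NIfTI-1 (.nii or .nii.gz by extension)."""
    path = Path(path)
    img = nib.Nifti1Image(volume.data.astype(np.float32), _affine(volume.voxel_size_mm))
    img.header.set_zooms(volume.voxel_size_mm)
    nib.save(img, str(path))
    return path


def read_atlas(label_path: str | Path, region_table_path: str | Path) -> Atlas:
    """Read an integer label volume plus a region table CSV.

    The CSV needs columns ``region_id``, ``name``, ``abbreviation`` and may
    carry ``is_reference`` flags marking normalization reference regions.
    """
    vol = read_volume(label_path)
    labels = np.rint(vol.data).astype(np.int32)
    if np.abs(vol.data - labels).max() > 1e-6:
        raise ValueError(f"{label_path} does not hold integer labels")
    regions = pd.read_csv(region_table_path)
    return Atlas(labels, regions, voxel_size_mm=vol.voxel_size_mm)


def write_atlas(atlas: Atlas, label_path: str | Path, region_table_path: str | Path) -> None:
    img = nib.Nifti1Image(atlas.labels.astype(np.int16), _affine(atlas.voxel_size_mm))
    img.header.set_zooms(atlas.voxel_size_mm)
    nib.save(img, str(label_path))
    atlas.regions.to_csv(region_table_path, index=False)


# ---------------------------------------------------------------------------
# Preprocessing


def smooth_gaussian(volume: Volume, fwhm_mm: float) -> Volume:
    """Isotropic Gaussian smoothing with the kernel width given as FWHM in mm.

    The per-axis sigma in voxels is ``fwhm * FWHM_TO_SIGMA / voxel_size``, so
    anisotropic voxels still receive isotropic smoothing in millimetres.
    Boundaries are zero-padded (constant mode), the common convention for
    preprocessed PET in a common space.
    """
    if fwhm_mm < 0:
        raise ValueError(f"fwhm_mm must be non-negative, got {fwhm_mm}")
    if fwhm_mm == 0:
        return volume.copy_with(volume.data.copy())
    sigma_vox = [fwhm_mm * FWHM_TO_SIGMA / vs for vs in volume.voxel_size_mm]
    out = gaussian_filter(volume.data, sigma=sigma_vox, mode="constant", cval=0.0)
    return volume.copy_with(out)


def normalize_to_reference(volume: Volume, atlas: Atlas) -> Volume:
    """Divide every voxel by the mean intensity over the reference region(s).

    After normalization the mean of the output over reference voxels is exactly
    1 (to floating tolerance), and the operation is invariant to any positive
    global rescaling of the input.
    """
    if volume.shape != atlas.shape:
        raise ValueError(f"volume shape {volume.shape} != atlas shape {atlas.shape}")
    if not atlas.reference_ids:
        raise ValueError("atlas defines no reference region for normalization")
    mask = np.isin(atlas.labels, list(atlas.reference_ids))
    if not mask.any():
        raise ValueError("reference region is empty in the label grid")
    ref_mean = float(volume.data[mask].mean())
    if ref_mean <= 0:
        raise ValueError(f"degenerate reference region: mean {ref_mean} <= 0")
    return volume.copy_with(volume.data / ref_mean)


def roi_means(volume: Volume | np.ndarray, atlas: Atlas) -> pd.Series:
    """Mean image value inside each atlas region, in region-table order.

    Background (label 0) is excluded.  Returns a Series indexed by region_id;
    regions with no voxels get NaN (cannot happen for generated atlases, which
    guarantee non-empty regions).
    """
    data = volume.data if isinstance(volume, Volume) else np.asarray(volume, dtype=np.float64)
    if data.shape != atlas.shape:
        raise ValueError(f"volume shape {data.shape} != atlas shape {atlas.shape}")
    ids = atlas.region_ids
    labels = atlas.labels.ravel()
    vals = data.ravel()
    max_id = int(ids.max())
    sums = np.bincount(labels, weights=vals, minlength=max_id + 1)
    counts = np.bincount(labels, minlength=max_id + 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        means = sums / counts
    return pd.Series(means[ids], index=pd.Index(ids, name="region_id"), name="roi_mean")


def roi_means_matrix(volumes: list[Volume] | list[np.ndarray], atlas: Atlas,
                     scan_ids: list[str] | None = None) -> pd.DataFrame:
    """Stack :func:`roi_means` over scans into a scans x regions DataFrame."""
    rows = [roi_means(v, atlas).to_numpy() for v in volumes]
    idx = scan_ids if scan_ids is not None else list(range(len(rows)))
    return pd.DataFrame(np.asarray(rows), index=pd.Index(idx, name="scan_id"),
                        columns=pd.Index(atlas.region_ids, name="region_id"))
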