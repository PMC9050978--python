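"""Image and mask containers plus file I/O.

Images are 2-D intensity rasters (HU-like; negative values allowed) with a
physical pixel spacing in mm.  Masks are binary rasters aligned with their
image.  On disk, images are 16-bit TIFF (or NIfTI slices, or read-only DICOM)
and masks are 8-bit PNG with values {0, 255}.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np


@dataclass(frozen=True)
class GrayImage:
    """2-D grayscale image with pixel spacing.

    Parameters
    ----------
    pixels : (H, W) float or integer array of intensities.
    spacing : (row, col) pixel spacing in mm.
    """

    pixels: np.ndarray
    spacing: tuple[float, float] = (1.0, 1.0)

    def __post_init__(self):
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError(f"image must be 2-D, got shape {px.shape}")
        if not np.all(np.isfinite(px)):
            raise ValueError("image contains non-finite values")
        if self.spacing[0] <= 0 or self.spacing[1] <= 0:
            raise ValueError(f"pixel spacing must be positive, got {self.spacing}")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class LesionMask:
    """Binary lesion mask aligned with a :class:`GrayImage`."""

    pixels: np.ndarray
    spacing: tuple[float, float] = (1.0, 1.0)

    def __post_init__(self):
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError(f"mask must be 2-D, got shape {px.shape}")
        object.__setattr__(self, "pixels", px.astype(bool))

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def area_px(self) -> int:
        return int(self.pixels.sum())

    @property
    def area_mm2(self) -> float:
        return self.area_px * self.spacing[0] * self.spacing[1]


def write_image(path: str | Path, image: GrayImage) -> Path:
    """Write an image as 16-bit TIFF (.tif/.tiff) or NIfTI (.nii/.nii.gz).

    TIFF output requires intensities representable in uint16; the round trip
    through :func:`read_image` is then exact.
    """
    path = Path(path)
    suffixes = "".join(path.suffixes)
    if suffixes.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        affine = np.diag([image.spacing[1], image.spacing[0], 1.0, 1.0])
        nib.save(nib.Nifti1Image(image.pixels.astype(np.float32), affine), str(path))
    else:
        import tifffile

        px = image.pixels
        rounded = np.round(px)
        if (np.abs(px - rounded) > 1e-9).any() or rounded.min() < 0 or rounded.max() > 65535:
            raise ValueError("16-bit TIFF requires integer intensities in [0, 65535]")
        tifffile.imwrite(
            str(path),
            rounded.astype(np.uint16),
            resolution=(1.0 / image.spacing[1], 1.0 / image.spacing[0]),
            resolutionunit="NONE",
        )
    return path


def read_image(path: str | Path, spacing: tuple[float, float] | None = None) -> GrayImage:
    """Read TIFF/PNG, NIfTI, or DICOM into a :class:`GrayImage`.

    ``spacing`` overrides any spacing stored in the file; defaults to (1, 1)
    when neither is available.
    """
    path = Path(path)
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
        if data.ndim == 3 and data.shape[2] == 1:
            data = data[:, :, 0]
        if data.ndim != 2:
            raise ValueError(f"expected a 2-D NIfTI slice, got shape {data.shape}")
        if spacing is None:
            zooms = img.header.get_zooms()
            spacing = (float(zooms[1]), float(zooms[0]))
        return GrayImage(np.asarray(data, dtype=float), spacing)
    if name.endswith(".dcm"):
        import pydicom

        ds = pydicom.dcmread(str(path))
        data = ds.pixel_array.astype(float)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        data = data * slope + intercept
        if spacing is None:
            ps = getattr(ds, "PixelSpacing", [1.0, 1.0])
            spacing = (float(ps[0]), float(ps[1]))
        return GrayImage(data, spacing)
    if name.endswith((".tif", ".tiff")):
        import tifffile

        data = tifffile.imread(str(path)).astype(float)
        return GrayImage(data, spacing or (1.0, 1.0))
    import imageio.v3 as iio

    data = np.asarray(iio.imread(str(path)), dtype=float)
    if data.ndim == 3:
        data = data[..., 0]
    return GrayImage(data, spacing or (1.0, 1.0))


def write_mask(path: str | Path, mask: LesionMask) -> Path:
    """Write a mask as 8-bit PNG with foreground 255."""
    import imageio.v3 as iio

    path = Path(path)
    iio.imwrite(str(path), (mask.pixels.astype(np.uint8) * 255))
    return path


def read_mask(path: str | Path, spacing: tuple[float, float] = (1.0, 1.0)) -> LesionMask:
    import imageio.v3 as iio

    data = np.asarray(iio.imread(str(path)))
    if data.ndim == 3:
        data = data[..., 0]
    return LesionMask(data > 127, spacing)
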