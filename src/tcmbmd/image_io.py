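"""CT image containers and IO: DICOM series and a portable array format.

All voxel data is held in Hounsfield units (float); stored DICOM values are
mapped through RescaleSlope/RescaleIntercept on read and write so a write ->
read round trip preserves HU to the integer storage precision.  Coordinates
are 0-based ``(row, col)`` pixel indices; line profiles are parameterized in
mm from their start point.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import CTImageStorage, ExplicitVRLittleEndian, generate_uid
from scipy.ndimage import map_coordinates

__all__ = [
    "CTImage",
    "ImageIOError",
    "LineProfile",
    "extract_profile",
    "read_ct",
    "read_portable",
    "write_dicom",
    "write_portable",
]

PORTABLE_SUFFIX = ".npz"


class ImageIOError(ValueError):
    """Raised for unreadable images or missing required metadata."""


@dataclass
class CTImage:
    """A 2D slice or 3D volume of CT numbers with geometry metadata.

    ``pixel_spacing`` is (row, col) mm; for a 3D array the first axis is the
    slice axis and ``slice_thickness`` its spacing in mm.
    """

    voxels: np.ndarray
    pixel_spacing: tuple[float, float]
    slice_thickness: float = 1.0
    kvp: int | None = None
    orientation_label: str = ""
    provenance: str = ""

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=float)
        if self.voxels.ndim not in (2, 3):
            raise ImageIOError(f"voxels must be 2D or 3D, got ndim={self.voxels.ndim}")
        if not np.isfinite(self.voxels).all():
            raise ImageIOError("voxel array contains non-finite values")
        sr, sc = self.pixel_spacing
        if sr <= 0 or sc <= 0 or self.slice_thickness <= 0:
            raise ImageIOError(
                f"spacing and thickness must be positive, got "
                f"{self.pixel_spacing}, {self.slice_thickness}"
            )
        self.pixel_spacing = (float(sr), float(sc))

    @property
    def n_slices(self) -> int:
        return 1 if self.voxels.ndim == 2 else self.voxels.shape[0]

    def get_slice(self, index: int = 0) -> np.ndarray:
        if self.voxels.ndim == 2:
            if index != 0:
                raise IndexError("2D image has a single slice")
            return self.voxels
        return self.voxels[index]


@dataclass
class LineProfile:
    """Values sampled along a straight segment, positions in mm."""

    positions: np.ndarray
    values: np.ndarray
    endpoints: tuple[tuple[float, float], tuple[float, float]]

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.positions) != len(self.values):
            raise ValueError("positions and values must have equal length")
        if len(self.positions) > 1 and not (np.diff(self.positions) > 0).all():
            raise ValueError("positions must be strictly increasing")


# ---------------------------------------------------------------------------
# portable single-file format: voxels + JSON metadata inside an .npz

def write_portable(image: CTImage, path: str) -> str:
    """Write a CTImage to a self-describing ``.npz`` container."""
    if not path.endswith(PORTABLE_SUFFIX):
        path += PORTABLE_SUFFIX
    meta = {
        "pixel_spacing": list(image.pixel_spacing),
        "slice_thickness": image.slice_thickness,
        "kvp": image.kvp,
        "orientation_label": image.orientation_label,
        "provenance": image.provenance,
    }
    np.savez(path, voxels=image.voxels, meta=np.array(json.dumps(meta)))
    return path


def read_portable(path: str) -> CTImage:
    with np.load(path, allow_pickle=False) as archive:
        if "voxels" not in archive or "meta" not in archive:
            raise ImageIOError(f"{path} is not a portable CT image container")
        voxels = archive["voxels"]
        meta = json.loads(str(archive["meta"]))
    return CTImage(
        voxels=voxels,
        pixel_spacing=tuple(meta["pixel_spacing"]),
        slice_thickness=meta["slice_thickness"],
        kvp=meta["kvp"],
        orientation_label=meta.get("orientation_label", ""),
        provenance=meta.get("provenance", path),
    )


# ---------------------------------------------------------------------------
# DICOM

def _slice_dataset(
    image: CTImage, slab: np.ndarray, index: int, series_uid: str
) -> Dataset:
    stored = np.round(slab).astype(np.int16)
    ds = Dataset()
    ds.SOPClassUID = CTImageStorage
    ds.SOPInstanceUID = generate_uid()
    ds.SeriesInstanceUID = series_uid
    ds.StudyInstanceUID = series_uid  # synthetic study
    ds.Modality = "CT"
    ds.Rows, ds.Columns = stored.shape
    ds.PixelSpacing = [float(image.pixel_spacing[0]), float(image.pixel_spacing[1])]
    ds.SliceThickness = float(image.slice_thickness)
    if image.kvp is not None:
        ds.KVP = float(image.kvp)
    ds.ImagePositionPatient = [0.0, 0.0, float(index) * image.slice_thickness]
    ds.ImageOrientationPatient = [1.0, 0.0, 0.0, 0.0, 1.0, 0.0]
    ds.InstanceNumber = index + 1
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 1  # signed
    ds.RescaleSlope = 1.0
    ds.RescaleIntercept = 0.0
    ds.SeriesDescription = image.provenance[:64]
    ds.PixelData = stored.tobytes()
    fm = FileMetaDataset()
    fm.TransferSyntaxUID = ExplicitVRLittleEndian
    fm.MediaStorageSOPClassUID = ds.SOPClassUID
    fm.MediaStorageSOPInstanceUID = ds.SOPInstanceUID
    ds.file_meta = fm
    return ds


def write_dicom(image: CTImage, path: str) -> str:
    """Write a 2D image to one file, or a 3D volume to a directory of files.

    Stored values are HU rounded to integers with RescaleSlope 1 and
    RescaleIntercept 0, so reading back recovers HU to 0.5 HU.
    """
    series_uid = generate_uid()
    if image.voxels.ndim == 2:
        ds = _slice_dataset(image, image.voxels, 0, series_uid)
        ds.save_as(path, enforce_file_format=True)
        return path
    os.makedirs(path, exist_ok=True)
    for i in range(image.n_slices):
        ds = _slice_dataset(image, image.voxels[i], i, series_uid)
        ds.save_as(os.path.join(path, f"slice_{i:04d}.dcm"), enforce_file_format=True)
    return path


def _require(ds: Dataset, name: str, path: str):
    value = ds.get(name)
    if value is None:
        raise ImageIOError(f"{path}: missing required DICOM attribute {name}")
    return value


def _read_dicom_slice(path: str):
    ds = pydicom.dcmread(path)
    spacing = _require(ds, "PixelSpacing", path)
    slope = float(_require(ds, "RescaleSlope", path))
    intercept = float(_require(ds, "RescaleIntercept", path))
    hu = ds.pixel_array.astype(float) * slope + intercept
    pos = ds.get("ImagePositionPatient")
    z = float(pos[2]) if pos is not None else float(ds.get("InstanceNumber", 0))
    return {
        "hu": hu,
        "spacing": (float(spacing[0]), float(spacing[1])),
        "thickness": float(ds.get("SliceThickness", 1.0)),
        "kvp": int(ds.KVP) if ds.get("KVP") is not None else None,
        "z": z,
    }


def read_ct(path: str) -> CTImage:
    """Read a portable container, a single DICOM file, or a DICOM series dir.

    Series slices are sorted by ImagePositionPatient regardless of file
    order; inconsistent pixel spacing across a series is an error.
    """
    if os.path.isdir(path):
        files = sorted(
            os.path.join(path, f)
            for f in os.listdir(path)
            if f.lower().endswith(".dcm")
        )
        if not files:
            raise ImageIOError(f"no DICOM files found in {path}")
        slices = [_read_dicom_slice(f) for f in files]
        spacings = {s["spacing"] for s in slices}
        if len(spacings) > 1:
            raise ImageIOError(f"inconsistent pixel spacing across series: {spacings}")
        slices.sort(key=lambda s: s["z"])
        vol = np.stack([s["hu"] for s in slices])
        first = slices[0]
        return CTImage(
            voxels=vol,
            pixel_spacing=first["spacing"],
            slice_thickness=first["thickness"],
            kvp=first["kvp"],
            provenance=path,
        )
    if path.endswith(PORTABLE_SUFFIX):
        return read_portable(path)
    s = _read_dicom_slice(path)
    return CTImage(
        voxels=s["hu"],
        pixel_spacing=s["spacing"],
        slice_thickness=s["thickness"],
        kvp=s["kvp"],
        provenance=path,
    )


# ---------------------------------------------------------------------------
# profiles

def extract_profile(source, start, end, n_samples: int = 200) -> LineProfile:
    """Sample ``source`` along the segment start->end by bilinear interpolation.

    ``source`` may be a 2D array, a 2D :class:`CTImage`, or an object with a
    2D ``vbmd`` attribute (a density map).  Endpoints are (row, col) pixel
    coordinates and must lie inside the image.
    """
    spacing = (1.0, 1.0)
    if isinstance(source, CTImage):
        arr, spacing = source.voxels, source.pixel_spacing
    elif hasattr(source, "vbmd"):
        arr = np.asarray(source.vbmd)
        calib_img = getattr(source, "pixel_spacing", None)
        if calib_img is not None:
            spacing = calib_img
    else:
        arr = np.asarray(source, dtype=float)
    if arr.ndim != 2:
        raise ValueError("profiles are extracted from 2D slices; select a slice first")
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    for pt in (start, end):
        r, c = pt
        if not (0 <= r <= arr.shape[0] - 1 and 0 <= c <= arr.shape[1] - 1):
            raise ValueError(
                f"profile endpoint {pt} outside image of shape {arr.shape}"
            )
    rr = np.linspace(start[0], end[0], n_samples)
    cc = np.linspace(start[1], end[1], n_samples)
    values = map_coordinates(arr, np.vstack([rr, cc]), order=1, mode="nearest")
    length_mm = float(
        np.hypot((end[0] - start[0]) * spacing[0], (end[1] - start[1]) * spacing[1])
    )
    positions = np.linspace(0.0, length_mm, n_samples)
    if length_mm == 0.0:
        raise ValueError("profile endpoints coincide")
    return LineProfile(positions=positions, values=values, endpoints=(tuple(start), tuple(end)))
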