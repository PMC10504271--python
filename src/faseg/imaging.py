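"""CT image I/O, Hounsfield-unit windowing, resizing and patient splits.

Chest CT arrives either as single-frame DICOM slices or as 3-D NIfTI
volumes; lesion annotations are binary masks (PNG or NIfTI labels).  This
module converts those to model-ready arrays: HU values are recovered via
the stored rescale (slope/intercept), remapped through a display window to
[0, 1], and resized to the network's input side.  Rows index the image
top-to-bottom and columns left-to-right everywhere in the package.

A *window* (width w, centre c) maps HU linearly from [c - w/2, c + w/2]
onto [0, 1] with clipping.  The default follows the lung parenchyma
convention used for pneumothorax reading (width 1500 HU).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pydicom
from pydicom.dataset import FileDataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid
import nibabel as nib
from PIL import Image
from scipy import ndimage


class FormatError(ValueError):
    """A file violates the expected imaging-format contract."""


@dataclasses.dataclass
class CTImage:
    """A single axial CT slice in Hounsfield units."""

    pixels: np.ndarray
    patient_id: str = ""
    slice_index: int = 0
    pixel_spacing: tuple[float, float] | None = None

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2 or min(self.pixels.shape) < 8:
            raise ValueError(f"CT slice must be 2-D with sides >= 8, "
                             f"got shape {self.pixels.shape}")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("CT slice contains non-finite HU values")
        if self.slice_index < 0:
            raise ValueError("slice_index must be >= 0")


@dataclasses.dataclass(frozen=True)
class WindowSpec:
    """HU display window; width must be positive."""

    width: float = 1500.0
    center: float = 600.0

    def __post_init__(self):
        if not self.width > 0:
            raise ValueError(f"window width must be > 0, got {self.width}")


#: Standard lung-parenchyma window; the pipeline default for phantoms and
#: training configs (a negative centre keeps aerated lung on the ramp).
LUNG_WINDOW = WindowSpec(width=1500.0, center=-600.0)


@dataclasses.dataclass
class SegmentationMask:
    """Binary lesion mask paired with a CT slice (1 = lesion)."""

    pixels: np.ndarray

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("mask must be 2-D")
        if not np.isin(self.pixels, (0, 1)).all():
            raise ValueError("mask values must be exactly 0 or 1")
        self.pixels = self.pixels.astype(np.uint8)


@dataclasses.dataclass(frozen=True)
class DatasetSplit:
    train_ids: frozenset[str]
    val_ids: frozenset[str]
    test_ids: frozenset[str]

    def __post_init__(self):
        sets = (self.train_ids, self.val_ids, self.test_ids)
        total = sum(len(s) for s in sets)
        if len(frozenset().union(*sets)) != total:
            raise ValueError("split sets must be pairwise disjoint")

    def subset_of(self, patient_id: str) -> str:
        for name, ids in (("train", self.train_ids), ("val", self.val_ids),
                          ("test", self.test_ids)):
            if patient_id in ids:
                return name
        raise KeyError(patient_id)


# ---------------------------------------------------------------------------
# Readers / writers

def read_dicom_slice(path: str | Path) -> CTImage:
    """Read a single-frame DICOM CT slice, returning HU values.

    The stored integers are mapped through the file's RescaleSlope /
    RescaleIntercept.  Non-monochrome images are rejected.
    """
    try:
        ds = pydicom.dcmread(str(path))
    except Exception as exc:  # noqa: BLE001 - re-raise as format error
        raise FormatError(f"unreadable DICOM file {path}: {exc}") from exc
    if "PixelData" not in ds:
        raise FormatError(f"{path}: missing PixelData")
    photometric = getattr(ds, "PhotometricInterpretation", "MONOCHROME2")
    if not str(photometric).startswith("MONOCHROME"):
        raise FormatError(
            f"{path}: PhotometricInterpretation must be monochrome, "
            f"got {photometric}")
    arr = ds.pixel_array.astype(np.float64)
    if arr.ndim != 2:
        raise FormatError(f"{path}: expected a single frame, "
                          f"got array of shape {arr.shape}")
    slope = float(getattr(ds, "RescaleSlope", 1.0))
    intercept = float(getattr(ds, "RescaleIntercept", 0.0))
    hu = arr * slope + intercept
    spacing = None
    if getattr(ds, "PixelSpacing", None) is not None:
        spacing = (float(ds.PixelSpacing[0]), float(ds.PixelSpacing[1]))
    return CTImage(
        pixels=hu,
        patient_id=str(getattr(ds, "PatientID", "")),
        slice_index=max(int(getattr(ds, "InstanceNumber", 1)) - 1, 0),
        pixel_spacing=spacing,
    )


def write_dicom_slice(path: str | Path, img: CTImage) -> None:
    """Write a CT slice as a minimal single-frame DICOM (HU stored as
    int16 with identity slope and zero intercept, so reads round-trip)."""
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = pydicom.uid.CTImageStorage
    meta.MediaStorageSOPInstanceUID = generate_uid(entropy_srcs=[str(path)])
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = FileDataset(str(path), {}, file_meta=meta, preamble=b"\0" * 128)
    ds.SOPClassUID = meta.MediaStorageSOPClassUID
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "CT"
    ds.PatientID = img.patient_id or "anon"
    ds.PatientName = img.patient_id or "anon"
    ds.InstanceNumber = img.slice_index + 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.SamplesPerPixel = 1
    ds.Rows, ds.Columns = img.pixels.shape
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 1  # signed
    ds.RescaleSlope = 1
    ds.RescaleIntercept = 0
    if img.pixel_spacing is not None:
        ds.PixelSpacing = list(img.pixel_spacing)
    hu = np.rint(img.pixels).astype(np.int16)
    ds.PixelData = hu.tobytes()
    ds.save_as(str(path), enforce_file_format=True)


def read_nifti_volume(path: str | Path) -> list[CTImage]:
    """Read a 3-D NIfTI volume as a list of axial slices.

    Slices are taken along the third axis with increasing ``slice_index``;
    the header's scaling (scl_slope/scl_inter) is applied.
    """
    vol = nib.load(str(path))
    data = np.asanyarray(vol.get_fdata(dtype=np.float64))
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a 3-D volume, got shape {data.shape}")
    zooms = vol.header.get_zooms()
    spacing = (float(zooms[0]), float(zooms[1])) if len(zooms) >= 2 else None
    pid = Path(path).name.split(".")[0]
    return [
        CTImage(pixels=data[:, :, k], patient_id=pid, slice_index=k,
                pixel_spacing=spacing)
        for k in range(data.shape[2])
    ]


def write_nifti_volume(path: str | Path, slices: list[np.ndarray]) -> None:
    """Stack 2-D arrays along the third axis and save as NIfTI."""
    vol = np.stack([np.asarray(s) for s in slices], axis=2)
    nib.save(nib.Nifti1Image(vol.astype(np.float64), affine=np.eye(4)), str(path))


def read_mask_png(path: str | Path) -> SegmentationMask:
    """8-bit PNG mask; any nonzero pixel counts as lesion."""
    arr = np.asarray(Image.open(str(path)).convert("L"))
    return SegmentationMask((arr > 0).astype(np.uint8))


def write_mask_png(path: str | Path, mask: SegmentationMask) -> None:
    Image.fromarray((mask.pixels * 255).astype(np.uint8), mode="L").save(str(path))


# ---------------------------------------------------------------------------
# Windowing and resizing

def apply_window(img: CTImage | np.ndarray, w: WindowSpec) -> np.ndarray:
    """Map HU through a linear ramp with clipping onto [0, 1].

    value = clip((HU - (center - width/2)) / width, 0, 1); monotone
    non-decreasing in HU.
    """
    hu = img.pixels if isinstance(img, CTImage) else np.asarray(img, dtype=np.float64)
    low = w.center - w.width / 2.0
    return np.clip((hu - low) / w.width, 0.0, 1.0)


def _resample(arr: np.ndarray, side: int, order: int) -> np.ndarray:
    if side < 8:
        raise ValueError(f"target side must be >= 8, got {side}")
    h, w = arr.shape
    # pixel-centre aligned sampling grid, matching the decoder's frame
    rows = (np.arange(side) + 0.5) * (h / side) - 0.5
    cols = (np.arange(side) + 0.5) * (w / side) - 0.5
    grid = np.meshgrid(rows, cols, indexing="ij")
    return ndimage.map_coordinates(arr.astype(np.float64), grid, order=order,
                                   mode="nearest")


def resize_to_model(img: np.ndarray, side: int) -> np.ndarray:
    """Bilinear resize of a normalized image to ``side`` x ``side``."""
    return _resample(np.asarray(img), side, order=1)


def resize_mask(mask: SegmentationMask, side: int) -> SegmentationMask:
    """Nearest-neighbour resize of a binary mask (values stay in {0,1})."""
    out = _resample(mask.pixels.astype(np.float64), side, order=0)
    return SegmentationMask(out.astype(np.uint8))


# ---------------------------------------------------------------------------
# Dataset splitting

def split_by_patient(patient_ids, counts: tuple[int, int, int],
                     seed: int) -> DatasetSplit:
    """Partition patients into train/val/test with the requested sizes.

    The shuffle is deterministic given ``seed``; splitting at patient level
    guarantees no patient contributes slices to two subsets.
    """
    ids = sorted(str(p) for p in patient_ids)
    n_train, n_val, n_test = counts
    if n_train + n_val + n_test != len(ids):
        raise ValueError(
            f"counts {counts} must sum to the number of patients ({len(ids)})")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    shuffled = [ids[i] for i in perm]
    return DatasetSplit(
        train_ids=frozenset(shuffled[:n_train]),
        val_ids=frozenset(shuffled[n_train:n_train + n_val]),
        test_ids=frozenset(shuffled[n_train + n_val:]),
    )
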