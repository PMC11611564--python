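"""DICOM greyscale overlay of scaffold designs.

The design workflow never moves the patient's coordinate frame: the defect
mesh comes out of segmentation in patient coordinates and every scaffold
is designed in place, so the final designs can be painted straight into a
copy of the CT series — no registration.  Voxels whose centers fall inside
a scaffold get a fixed intensity increment (saturating at the stored-type
maximum), all other voxels are bit-identical, and the original image data
remains recoverable inside the mask by subtracting the increment.  The
output is a fresh (optionally anonymised) series any DICOM viewer can
scroll.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import CTImageStorage, ExplicitVRLittleEndian, generate_uid

from . import _raster

__all__ = ["DicomVolume", "read_dicom_series", "overlay_scaffold",
           "write_dicom_series", "ANONYMISED_TAGS"]

# Patient-identifying attributes cleared on anonymised export (subset of the
# DICOM basic confidentiality profile relevant to CT series-level tags).
ANONYMISED_TAGS = {
    "PatientName": "ANONYMOUS",
    "PatientID": "ANON",
    "PatientBirthDate": "",
    "PatientSex": "",
    "PatientAge": "",
    "PatientAddress": "",
    "ReferringPhysicianName": "",
    "InstitutionName": "",
    "InstitutionAddress": "",
    "OperatorsName": "",
    "AccessionNumber": "",
    "StationName": "",
    "OtherPatientIDs": "",
}


@dataclass
class DicomVolume:
    """CT intensity volume in the patient frame.

    ``intensities`` is indexed [row, column, slice] in stored units;
    ``spacing`` = (row, column, slice) distances in mm; ``origin`` is the
    world position of voxel (0, 0, 0); ``row_dir``/``col_dir`` are the
    direction cosines along increasing column / row index respectively and
    ``slice_dir`` the slice normal.
    """

    intensities: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float]
    row_dir: tuple[float, float, float] = (1.0, 0.0, 0.0)
    col_dir: tuple[float, float, float] = (0.0, 1.0, 0.0)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.intensities = np.asarray(self.intensities)
        if self.intensities.ndim != 3:
            raise ValueError("intensities must be a 3D array")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")

    @property
    def slice_dir(self) -> np.ndarray:
        return np.cross(self.row_dir, self.col_dir)

    def world_to_index(self, pts: np.ndarray) -> np.ndarray:
        """Continuous (row, col, slice) indices for world points."""
        rel = np.asarray(pts, dtype=float) - np.asarray(self.origin)
        r = rel @ np.asarray(self.col_dir) / self.spacing[0]
        c = rel @ np.asarray(self.row_dir) / self.spacing[1]
        s = rel @ self.slice_dir / self.spacing[2]
        return np.stack([r, c, s], axis=-1)

    def copy(self) -> "DicomVolume":
        return DicomVolume(self.intensities.copy(), tuple(self.spacing),
                           tuple(self.origin), tuple(self.row_dir),
                           tuple(self.col_dir), dict(self.metadata))


def read_dicom_series(directory) -> DicomVolume:
    """Read one CT series from a directory, slices sorted along the normal."""
    directory = Path(directory)
    files = sorted(p for p in directory.iterdir() if p.is_file())
    datasets = []
    for p in files:
        try:
            ds = pydicom.dcmread(str(p))
        except Exception:
            continue
        if hasattr(ds, "PixelData"):
            datasets.append(ds)
    if not datasets:
        raise ValueError(f"no DICOM image files found in {directory}")

    series = {ds.SeriesInstanceUID for ds in datasets}
    if len(series) != 1:
        raise ValueError(f"directory holds {len(series)} series; expected one")
    for ds in datasets:
        if not hasattr(ds, "ImagePositionPatient"):
            raise ValueError("slice missing ImagePositionPatient tag")

    iop = np.asarray(datasets[0].ImageOrientationPatient, dtype=float)
    row_dir, col_dir = iop[:3], iop[3:]
    normal = np.cross(row_dir, col_dir)
    datasets.sort(key=lambda ds: float(
        np.dot(np.asarray(ds.ImagePositionPatient, dtype=float), normal)))

    first = datasets[0]
    px = np.asarray(first.PixelSpacing, dtype=float)  # (row, col)
    if len(datasets) > 1:
        positions = [np.dot(np.asarray(d.ImagePositionPatient, dtype=float), normal)
                     for d in datasets]
        dz = float(np.mean(np.diff(positions)))
    else:
        dz = float(getattr(first, "SliceThickness", 1.0))

    slices = [ds.pixel_array for ds in datasets]
    vol = np.stack(slices, axis=-1)

    meta = {
        "SeriesInstanceUID": first.SeriesInstanceUID,
        "StudyInstanceUID": getattr(first, "StudyInstanceUID", generate_uid()),
        "RescaleSlope": float(getattr(first, "RescaleSlope", 1.0)),
        "RescaleIntercept": float(getattr(first, "RescaleIntercept", 0.0)),
    }
    for tag in ANONYMISED_TAGS:
        if hasattr(first, tag):
            meta[tag] = str(getattr(first, tag))

    return DicomVolume(
        intensities=vol,
        spacing=(float(px[0]), float(px[1]), abs(dz)),
        origin=tuple(np.asarray(first.ImagePositionPatient, dtype=float)),
        row_dir=tuple(row_dir),
        col_dir=tuple(col_dir),
        metadata=meta,
    )


def scaffold_mask(vol: DicomVolume, meshes) -> np.ndarray:
    """Boolean voxel mask: centers inside any of the (watertight) meshes."""
    mask = np.zeros(vol.intensities.shape, dtype=bool)
    for mesh in meshes:
        if not mesh.is_watertight:
            raise ValueError("scaffold mesh is not watertight")
        idx = vol.world_to_index(np.asarray(mesh.vertices, dtype=np.float64))
        if (idx.max(axis=0) < 0).any() or \
           (idx.min(axis=0) > np.asarray(mask.shape) - 1).any():
            warnings.warn("scaffold mesh lies wholly outside the volume; skipped")
            continue
        mask |= _raster.parity_fill(idx, np.asarray(mesh.faces), mask.shape)
    return mask


def overlay_scaffold(vol: DicomVolume, scaffolds, delta: int) -> DicomVolume:
    """Additive greyscale mask: +delta inside the scaffold union, saturating
    at the stored-type limits; voxels outside are bit-identical."""
    out = vol.copy()
    if delta == 0:
        return out
    mask = scaffold_mask(vol, scaffolds)
    arr = out.intensities
    info = np.iinfo(arr.dtype) if np.issubdtype(arr.dtype, np.integer) else None
    vals = arr[mask].astype(np.int64) + int(delta)
    if info is not None:
        vals = np.clip(vals, info.min, info.max)
    arr[mask] = vals.astype(arr.dtype)
    return out


def write_dicom_series(vol: DicomVolume, directory, anonymise: bool = True) -> list[Path]:
    """Write the volume as a fresh CT series (new Series/SOP UIDs).

    Geometry tags reproduce the volume exactly; intensity round trip is
    bit-exact.  With ``anonymise``, the tags in :data:`ANONYMISED_TAGS` are
    cleared or replaced.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    arr = vol.intensities
    if arr.dtype != np.int16:
        arr = arr.astype(np.int16)
    series_uid = generate_uid()
    study_uid = vol.metadata.get("StudyInstanceUID", generate_uid())
    normal = vol.slice_dir
    paths = []
    for s in range(arr.shape[2]):
        ds = Dataset()
        ds.file_meta = FileMetaDataset()
        ds.file_meta.MediaStorageSOPClassUID = CTImageStorage
        ds.file_meta.MediaStorageSOPInstanceUID = generate_uid()
        ds.file_meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds.SOPClassUID = CTImageStorage
        ds.SOPInstanceUID = ds.file_meta.MediaStorageSOPInstanceUID
        ds.Modality = "CT"
        ds.SeriesInstanceUID = series_uid
        ds.StudyInstanceUID = study_uid
        ds.SeriesNumber = 999
        ds.InstanceNumber = s + 1

        if anonymise:
            for tag, repl in ANONYMISED_TAGS.items():
                setattr(ds, tag, repl)
        else:
            for tag in ANONYMISED_TAGS:
                if tag in vol.metadata:
                    setattr(ds, tag, vol.metadata[tag])

        ds.ImageOrientationPatient = [*map(float, vol.row_dir),
                                      *map(float, vol.col_dir)]
        pos = np.asarray(vol.origin) + s * vol.spacing[2] * normal
        ds.ImagePositionPatient = [float(x) for x in pos]
        ds.PixelSpacing = [float(vol.spacing[0]), float(vol.spacing[1])]
        ds.SliceThickness = float(vol.spacing[2])
        ds.RescaleSlope = vol.metadata.get("RescaleSlope", 1.0)
        ds.RescaleIntercept = vol.metadata.get("RescaleIntercept", 0.0)

        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.Rows = arr.shape[0]
        ds.Columns = arr.shape[1]
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 1  # signed
        ds.PixelData = np.ascontiguousarray(arr[:, :, s]).tobytes()

        path = directory / f"slice_{s:04d}.dcm"
        ds.save_as(str(path), enforce_file_format=True)
        paths.append(path)
    return paths
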