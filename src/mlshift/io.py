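"""Readers and writers for CT volumes, landmark annotations and MLS results.

Volumes are held as :class:`CTVolume`: a 3-D array of Hounsfield units with
axes ``(slice, row, col)``, ascending axial position, plus per-axis spacing
in mm. DICOM series have the rescale slope/intercept applied at load; NIfTI
files written by this package use a diagonal affine so that a write/read
round trip preserves voxels bit-exactly and spacing to float precision.

Annotations travel in a small JSON schema (a list of records, each naming a
scan, a 0-based slice index, an annotator and the four landmarks); results
are written as CSV or JSON, both losslessly parseable back.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import nibabel as nib
import numpy as np
import pydicom

from .geometry import KeypointSet, MLSResult

__all__ = [
    "CTVolume",
    "AnnotationRecord",
    "load_ct_volume",
    "save_nifti",
    "load_annotations",
    "save_annotations",
    "write_results",
    "read_results",
]


@dataclass
class CTVolume:
    """A CT volume in Hounsfield units.

    ``voxels`` has axes ``(slice, row, col)`` with slices ordered by ascending
    axial position; ``spacing`` is ``(slice_mm, row_mm, col_mm)``.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    scan_id: str
    patient_id: str = ""

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(f"voxels must be 3-D, got {self.voxels.ndim}-D")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("voxels contain non-finite HU values")

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]

    @property
    def slice_shape(self) -> tuple[int, int]:
        return self.voxels.shape[1], self.voxels.shape[2]

    @property
    def in_plane_spacing(self) -> tuple[float, float]:
        """(row_mm, col_mm)."""
        return self.spacing[1], self.spacing[2]


@dataclass
class AnnotationRecord:
    """One annotated axial slice: scan, slice index, annotator, 4 landmarks."""

    scan_id: str
    slice_index: int
    keypoints: KeypointSet
    annotator: str = "unknown"

    def validate_against(self, volume: CTVolume) -> None:
        """Check slice index and keypoint coordinates against a volume."""
        if not 0 <= self.slice_index < volume.n_slices:
            raise ValueError(
                f"slice_index {self.slice_index} out of range for scan "
                f"{self.scan_id!r} with {volume.n_slices} slices"
            )
        h, w = volume.slice_shape
        for name, (x, y) in zip(
            ("falx_anterior", "falx_posterior", "septum_anterior", "septum_posterior"),
            self.keypoints.as_array(),
        ):
            if not (0 <= x <= w - 1 and 0 <= y <= h - 1):
                raise ValueError(
                    f"keypoint {name} = ({x}, {y}) outside {h}x{w} image "
                    f"bounds (scan {self.scan_id!r}, slice {self.slice_index})"
                )


def load_ct_volume(
    path: str | Path,
    format_hint: Literal["auto", "dicom", "nifti"] = "auto",
) -> CTVolume:
    """Load a CT volume from a DICOM series directory or a NIfTI file.

    DICOM: slices are sorted by ascending axial position (Image Position
    (Patient) z, falling back to Instance Number), the rescale slope and
    intercept are applied so voxels are in HU, and spacing is read from Pixel
    Spacing plus the inter-slice distance. Missing spacing metadata and
    mixed-orientation series are hard errors.
    """
    path = Path(path)
    if format_hint == "auto":
        if path.is_dir():
            format_hint = "dicom"
        elif path.suffix in (".nii", ".gz") or path.name.endswith(".nii.gz"):
            format_hint = "nifti"
        else:
            raise ValueError(f"cannot infer format of {path}; pass format_hint")
    if format_hint == "dicom":
        return _load_dicom_series(path)
    if format_hint == "nifti":
        return _load_nifti(path)
    raise ValueError(f"unknown format_hint {format_hint!r}")


def _load_dicom_series(directory: Path) -> CTVolume:
    files = sorted(p for p in directory.iterdir() if p.is_file())
    datasets = []
    for p in files:
        try:
            datasets.append(pydicom.dcmread(p))
        except pydicom.errors.InvalidDicomError:
            continue
    if not datasets:
        raise ValueError(f"no DICOM files found in {directory}")

    orientations = {
        tuple(np.round(np.asarray(ds.ImageOrientationPatient, dtype=float), 6))
        for ds in datasets
        if "ImageOrientationPatient" in ds
    }
    if len(orientations) > 1:
        raise ValueError(f"mixed-orientation DICOM series in {directory}")

    def z_pos(ds):
        if "ImagePositionPatient" in ds:
            return float(ds.ImagePositionPatient[2])
        if "InstanceNumber" in ds:
            return float(ds.InstanceNumber)
        raise ValueError("DICOM slice lacks both ImagePositionPatient and InstanceNumber")

    datasets.sort(key=z_pos)

    first = datasets[0]
    if "PixelSpacing" not in first:
        raise ValueError("DICOM series missing PixelSpacing metadata")
    row_mm, col_mm = (float(v) for v in first.PixelSpacing)

    if len(datasets) >= 2 and all("ImagePositionPatient" in ds for ds in datasets):
        zs = [float(ds.ImagePositionPatient[2]) for ds in datasets]
        slice_mm = float(np.mean(np.diff(zs)))
    elif "SliceThickness" in first:
        slice_mm = float(first.SliceThickness)
    elif "SpacingBetweenSlices" in first:
        slice_mm = float(first.SpacingBetweenSlices)
    else:
        raise ValueError(
            "DICOM series missing slice spacing metadata "
            "(ImagePositionPatient / SliceThickness / SpacingBetweenSlices)"
        )
    if slice_mm <= 0:
        raise ValueError(f"non-positive slice spacing {slice_mm}")

    shape = datasets[0].pixel_array.shape
    slices = []
    for ds in datasets:
        arr = ds.pixel_array.astype(np.float64)
        if arr.shape != shape:
            raise ValueError(
                f"DICOM series has inconsistent slice shapes: {shape} vs {arr.shape}"
            )
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        slices.append(arr * slope + intercept)

    scan_id = str(getattr(first, "SeriesInstanceUID", directory.name))
    patient_id = str(getattr(first, "PatientID", ""))
    return CTVolume(
        voxels=np.stack(slices, axis=0),
        spacing=(slice_mm, row_mm, col_mm),
        scan_id=scan_id,
        patient_id=patient_id,
    )


def _load_nifti(path: Path) -> CTVolume:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"expected a 3-D NIfTI, got {data.ndim}-D")
    zooms = img.header.get_zooms()[:3]
    if any(not math.isfinite(z) or z <= 0 for z in zooms):
        raise ValueError(f"NIfTI {path} has invalid voxel spacing {zooms}")
    # this package writes (col, row, slice) on disk; transpose back
    voxels = np.transpose(data, (2, 1, 0))
    spacing = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
    scan_id = path.name.removesuffix(".gz").removesuffix(".nii")
    return CTVolume(voxels=voxels, spacing=spacing, scan_id=scan_id)


def save_nifti(vol: CTVolume, path: str | Path) -> None:
    """Write a volume as NIfTI with a diagonal affine (round-trip safe)."""
    slice_mm, row_mm, col_mm = vol.spacing
    affine = np.diag([col_mm, row_mm, slice_mm, 1.0])
    data = np.transpose(vol.voxels, (2, 1, 0))
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms((col_mm, row_mm, slice_mm))
    nib.save(img, str(path))


def load_annotations(
    path: str | Path,
    scans: dict[str, CTVolume] | None = None,
) -> list[AnnotationRecord]:
    """Load landmark annotations from JSON; order preserved.

    When ``scans`` maps scan_id to its volume, each record is validated
    against the scan's bounds. Duplicate (scan_id, slice_index, annotator)
    triples and unknown keypoint names are errors.
    """
    with open(path) as fh:
        raw = json.load(fh)
    if not isinstance(raw, list):
        raise ValueError("annotation file must contain a JSON array")
    records: list[AnnotationRecord] = []
    seen: set[tuple[str, int, str]] = set()
    for entry in raw:
        rec = AnnotationRecord(
            scan_id=str(entry["scan_id"]),
            slice_index=int(entry["slice_index"]),
            annotator=str(entry.get("annotator", "unknown")),
            keypoints=KeypointSet.from_dict(entry["keypoints"]),
        )
        key = (rec.scan_id, rec.slice_index, rec.annotator)
        if key in seen:
            raise ValueError(f"duplicate annotation record {key}")
        seen.add(key)
        if scans is not None and rec.scan_id in scans:
            rec.validate_against(scans[rec.scan_id])
        records.append(rec)
    return records


def save_annotations(records: Sequence[AnnotationRecord], path: str | Path) -> None:
    payload = [
        {
            "scan_id": r.scan_id,
            "slice_index": r.slice_index,
            "annotator": r.annotator,
            "keypoints": r.keypoints.to_dict(),
        }
        for r in records
    ]
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


_CSV_HEADER = ["scan_id", "slice_index_of_max", "mls_mm", "n_slices_detected", "per_slice"]


def _encode_per_slice(per_slice: list[tuple[int, float]]) -> str:
    return ";".join(f"{i}:{v!r}" for i, v in per_slice)


def _decode_per_slice(text: str) -> list[tuple[int, float]]:
    if not text:
        return []
    out = []
    for chunk in text.split(";"):
        i, v = chunk.split(":")
        out.append((int(i), float(v)))
    return out


def write_results(
    results: Sequence[MLSResult],
    path: str | Path,
    format: Literal["csv", "json"] = "csv",
) -> None:
    """Write per-scan MLS results; one row/object per scan, lossless."""
    if format == "csv":
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(_CSV_HEADER)
            for r in results:
                writer.writerow(
                    [
                        r.scan_id,
                        "" if r.argmax_slice_index is None else r.argmax_slice_index,
                        repr(r.scan_mls_mm),
                        len(r.per_slice),
                        _encode_per_slice(r.per_slice),
                    ]
                )
    elif format == "json":
        payload = [
            {
                "scan_id": r.scan_id,
                "slice_index_of_max": r.argmax_slice_index,
                "mls_mm": None if not r.defined else r.scan_mls_mm,
                "n_slices_detected": len(r.per_slice),
                "per_slice": [[i, v] for i, v in r.per_slice],
                "source": r.source,
                "defined": r.defined,
            }
            for r in results
        ]
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)
    else:
        raise ValueError(f"unknown format {format!r}; expected 'csv' or 'json'")


def read_results(path: str | Path, format: Literal["csv", "json"] = "csv") -> list[MLSResult]:
    results: list[MLSResult] = []
    if format == "csv":
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh)
            for row in reader:
                per_slice = _decode_per_slice(row["per_slice"])
                mls = float(row["mls_mm"])
                results.append(
                    MLSResult(
                        scan_id=row["scan_id"],
                        per_slice=per_slice,
                        scan_mls_mm=mls,
                        argmax_slice_index=(
                            None
                            if row["slice_index_of_max"] == ""
                            else int(row["slice_index_of_max"])
                        ),
                        defined=not math.isnan(mls),
                    )
                )
    elif format == "json":
        with open(path) as fh:
            payload = json.load(fh)
        for obj in payload:
            results.append(
                MLSResult(
                    scan_id=obj["scan_id"],
                    per_slice=[(int(i), float(v)) for i, v in obj["per_slice"]],
                    scan_mls_mm=float("nan") if obj["mls_mm"] is None else obj["mls_mm"],
                    argmax_slice_index=obj["slice_index_of_max"],
                    source=obj.get("source", "annotation"),
                    defined=obj["defined"],
                )
            )
    else:
        raise ValueError(f"unknown format {format!r}")
    return results
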