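"""Image and report I/O: 16-bit TIFF and DICOM (MG, FOR PROCESSING) with
JSON sidecars carrying the acquisition metadata and seed.

Pixels are stored as uint16 (rounded); reading restores the float container.
The pixel pitch is never guessed: it must come from the DICOM PixelSpacing,
the sidecar, or an explicit argument.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np
import tifffile

from .exceptions import ImageReadError
from .specs import Image

__all__ = ["write_image", "read_image"]

_SIDE_SUFFIX = ".json"


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + _SIDE_SUFFIX)


def _jsonable(value):
    if isinstance(value, (np.integer,)):
        return int(value)
    if isinstance(value, (np.floating,)):
        return float(value)
    return value


def write_image(image: Image, path: str | Path) -> Path:
    """Write an image as .tif/.tiff or .dcm plus a JSON sidecar; returns the path."""
    path = Path(path)
    pixels = np.round(image.pixels)
    if pixels.max() > np.iinfo(np.uint16).max:
        raise ImageReadError("pixel values exceed the 16-bit range")
    pixels16 = pixels.astype(np.uint16)

    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, pixels16)
    elif path.suffix.lower() == ".dcm":
        _write_dicom(image, pixels16, path)
    else:
        raise ImageReadError(f"unsupported image format {path.suffix!r}")

    sidecar = {
        "pitch_um": image.pitch_um,
        "dc_offset": image.dc_offset,
        "meta": {k: _jsonable(v) for k, v in image.meta.items()},
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))
    return path


def _write_dicom(image: Image, pixels16: np.ndarray, path: Path) -> None:
    import pydicom
    from pydicom.dataset import FileDataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, generate_uid

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = pydicom.uid.DigitalMammographyXRayImageStorageForProcessing
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = FileDataset(str(path), {}, file_meta=meta, preamble=b"\0" * 128)
    ds.SOPClassUID = meta.MediaStorageSOPClassUID
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "MG"
    ds.PresentationIntentType = "FOR PROCESSING"
    ds.BodyPartExamined = "BREAST"
    pitch_mm = image.pitch_um / 1000.0
    ds.PixelSpacing = [f"{pitch_mm:.6g}", f"{pitch_mm:.6g}"]
    if image.meta.get("kvp") is not None:
        ds.KVP = str(image.meta["kvp"])
    if image.meta.get("mas") is not None:
        ds.ExposureInuAs = int(round(float(image.meta["mas"]) * 1000))
    ds.Rows, ds.Columns = pixels16.shape
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 0
    ds.PixelData = pixels16.tobytes()
    ds.save_as(path, enforce_file_format=True)


def read_image(path: str | Path, *, pitch_um: Optional[float] = None,
               dc_offset: Optional[float] = None) -> Image:
    """Read a 16-bit TIFF or FOR PROCESSING DICOM back into an Image.

    Metadata precedence: file tags, then JSON sidecar, then the explicit
    arguments. A missing pitch is an error (never guessed); 8-bit or
    presentation-intent files are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise ImageReadError(f"no such file: {path}")
    sidecar = {}
    sc_path = _sidecar_path(path)
    if sc_path.exists():
        try:
            sidecar = json.loads(sc_path.read_text())
        except json.JSONDecodeError as exc:
            raise ImageReadError(f"corrupt sidecar {sc_path}: {exc}") from exc

    if path.suffix.lower() in (".tif", ".tiff"):
        try:
            pixels = tifffile.imread(path)
        except Exception as exc:
            raise ImageReadError(f"cannot parse TIFF {path}: {exc}") from exc
        if pixels.dtype == np.uint8:
            raise ImageReadError("8-bit input rejected: linear 'for processing' "
                                 "data must be 16-bit")
        meta = dict(sidecar.get("meta", {}))
    elif path.suffix.lower() == ".dcm":
        import pydicom
        try:
            ds = pydicom.dcmread(path)
            pixels = ds.pixel_array
        except Exception as exc:
            raise ImageReadError(f"cannot parse DICOM {path}: {exc}") from exc
        intent = getattr(ds, "PresentationIntentType", "")
        if intent and intent != "FOR PROCESSING":
            raise ImageReadError(
                f"presentation-intent {intent!r} rejected: metrics need linear "
                "'FOR PROCESSING' data")
        if int(getattr(ds, "BitsAllocated", 16)) < 16:
            raise ImageReadError("8-bit DICOM rejected")
        meta = dict(sidecar.get("meta", {}))
        if getattr(ds, "PixelSpacing", None):
            pitch_um = float(ds.PixelSpacing[0]) * 1000.0
        if getattr(ds, "KVP", None):
            meta.setdefault("kvp", float(ds.KVP))
        if getattr(ds, "ExposureInuAs", None):
            meta.setdefault("mas", float(ds.ExposureInuAs) / 1000.0)
    else:
        raise ImageReadError(f"unsupported image format {path.suffix!r}")

    if pitch_um is None:
        pitch_um = sidecar.get("pitch_um")
    if pitch_um is None:
        raise ImageReadError("pixel pitch missing (no tag, sidecar or argument); "
                             "pitch is never guessed")
    if dc_offset is None:
        dc_offset = sidecar.get("dc_offset", 0.0)
    meta = {**sidecar.get("meta", {}), **meta, "source_file": str(path)}
    return Image(pixels=np.asarray(pixels, dtype=np.float64), pitch_um=float(pitch_um),
                 dc_offset=float(dc_offset), meta=meta)
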