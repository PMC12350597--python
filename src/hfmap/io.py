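"""Readers and writers for the formats the pipeline touches.

CT slices arrive as DICOM (HU via RescaleSlope/RescaleIntercept), NIfTI, or
PNG with a JSON pixel-spacing sidecar. HF maps leave as float NIfTI (default)
or visualization-grade 16-bit PNG with the linear scale recorded in a sidecar.
"""
from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import pydicom
from PIL import Image

from .classify import ExperimentParams
from .core import CTSlice
from .hf_map import HFMap, MapParams
from .hp_profile import ProfileParams
from .lungseg import SegParams
from .phantom import PhantomSample
from .topology import ConnectivityRule

__all__ = [
    "read_ct",
    "read_mask",
    "write_ct_nifti",
    "write_mask",
    "write_hf_map",
    "write_cohort",
    "RunConfig",
]

logger = logging.getLogger(__name__)


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json") if path.suffix != ".json" else path


def read_ct(path: str | Path, label: str = "unknown") -> CTSlice:
    """Read a CT slice from DICOM, NIfTI or PNG (+ optional JSON sidecar).

    DICOM stored values are converted to HU via the rescale tags; a missing
    tag raises a format error naming it. A PNG without sidecar gets spacing
    (1.0, 1.0) with a warning.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".dcm", ".dicom", "") or suffix == ".ima":
        ds = pydicom.dcmread(path)
        for tag in ("RescaleSlope", "RescaleIntercept"):
            if getattr(ds, tag, None) is None:
                raise ValueError(f"DICOM file {path} is missing the {tag} tag")
        hu = ds.pixel_array.astype(np.float64) * float(ds.RescaleSlope) + float(
            ds.RescaleIntercept
        )
        spacing = tuple(float(v) for v in ds.PixelSpacing)
        pid = str(getattr(ds, "PatientID", ""))
        sid = str(getattr(ds, "SOPInstanceUID", path.stem))
        return CTSlice(hu, spacing, pid, sid, label)
    if suffix in (".nii", ".gz"):
        img = nib.load(path)
        data = np.squeeze(np.asarray(img.dataobj, dtype=np.float64))
        if data.ndim != 2:
            raise ValueError(f"{path} does not hold a single 2D slice")
        zooms = img.header.get_zooms()[:2]
        # NIfTI stores zooms as float32; round back to micrometre precision
        spacing = (round(float(zooms[0]), 6), round(float(zooms[1]), 6))
        return CTSlice(data, spacing, slice_id=path.stem, label=label)
    if suffix == ".png":
        data = np.asarray(Image.open(path), dtype=np.float64)
        sidecar = _sidecar_path(path)
        spacing = (1.0, 1.0)
        slope, intercept = 1.0, 0.0
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
            spacing = tuple(meta.get("spacing", spacing))
            slope = float(meta.get("slope", 1.0))
            intercept = float(meta.get("intercept", 0.0))
        else:
            warnings.warn(f"{path}: no spacing sidecar; assuming 1.0 mm pixels")
        return CTSlice(data * slope + intercept, spacing, slice_id=path.stem, label=label)
    raise ValueError(f"unsupported CT format: {path}")


def read_mask(path: str | Path) -> np.ndarray:
    path = Path(path)
    if path.suffix.lower() == ".png":
        return np.asarray(Image.open(path)) > 0
    data = np.squeeze(np.asarray(nib.load(path).dataobj))
    return data > 0


def write_ct_nifti(ct: CTSlice, path: str | Path) -> None:
    path = Path(path)
    affine = np.diag([ct.spacing[0], ct.spacing[1], 1.0, 1.0])
    img = nib.Nifti1Image(ct.hu.astype(np.float64), affine)
    img.header.set_zooms((ct.spacing[0], ct.spacing[1]))
    nib.save(img, path)


def write_mask(mask: np.ndarray, path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() == ".png":
        Image.fromarray((mask.astype(np.uint8) * 255)).save(path)
    else:
        nib.save(nib.Nifti1Image(mask.astype(np.uint8), np.eye(4)), path)


def write_hf_map(hf: HFMap, path: str | Path) -> None:
    """Write an HF map with a JSON sidecar carrying params and provenance.

    NIfTI keeps the float values exactly; PNG export scales linearly to 16-bit
    (lossy, visualization only) and records the scale in the sidecar.
    Coordinate convention everywhere: row-major, 0-based, origin top-left,
    half-open tile footprints.
    """
    path = Path(path)
    meta = {
        "params": dataclasses.asdict(hf.params),
        "spacing": list(hf.spacing),
        "provenance": hf.provenance,
        "n_tiles": hf.n_tiles,
        "n_skipped": hf.n_skipped,
        "slice_feature": float(hf.values.max()),
        "coordinates": "row-major, 0-based, origin top-left, half-open tiles",
    }
    if path.suffix.lower() == ".png":
        vmax = float(hf.values.max())
        scale = 65535.0 / vmax if vmax > 0 else 1.0
        Image.fromarray(np.round(hf.values * scale).astype(np.uint16)).save(path)
        meta["png_scale"] = scale
    else:
        affine = np.diag([hf.spacing[0], hf.spacing[1], 1.0, 1.0])
        nib.save(nib.Nifti1Image(hf.values, affine), path)
    _sidecar_path(path).write_text(json.dumps(meta, indent=2))


def write_cohort(manifest: pd.DataFrame, samples: list[PhantomSample], out_dir: str | Path) -> pd.DataFrame:
    """Write phantom slices + ground-truth masks as NIfTI and the manifest CSV.

    Returns the manifest augmented with file paths. Refuses to overwrite an
    existing slice file (path collision).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = manifest.copy()
    image_paths, mask_paths = [], []
    for (_, row), sample in zip(manifest.iterrows(), samples):
        ipath = out / f"{row.slice_id}.nii"
        mpath = out / f"{row.slice_id}_mask.nii"
        if ipath.exists():
            raise FileExistsError(f"output path collision: {ipath}")
        write_ct_nifti(sample.ct, ipath)
        write_mask(sample.mask, mpath)
        image_paths.append(str(ipath))
        mask_paths.append(str(mpath))
    manifest["image_path"] = image_paths
    manifest["mask_path"] = mask_paths
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest


@dataclass
class RunConfig:
    """One-file configuration for a full run; round-trips through JSON."""

    map_params: MapParams = field(default_factory=MapParams)
    seg_params: SegParams = field(default_factory=SegParams)
    experiment: ExperimentParams = field(default_factory=ExperimentParams)
    input_path: str = ""
    mask_path: str = ""
    output_path: str = ""
    log_level: str = "INFO"

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        raw = json.loads(text)
        mp = raw.get("map_params", {})
        profile = mp.pop("profile", {})
        conn = profile.pop("connectivity", {})
        map_params = MapParams(
            profile=ProfileParams(connectivity=ConnectivityRule(**conn), **profile), **mp
        )
        return cls(
            map_params=map_params,
            seg_params=SegParams(**raw.get("seg_params", {})),
            experiment=ExperimentParams(**raw.get("experiment", {})),
            input_path=raw.get("input_path", ""),
            mask_path=raw.get("mask_path", ""),
            output_path=raw.get("output_path", ""),
            log_level=raw.get("log_level", "INFO"),
        )
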