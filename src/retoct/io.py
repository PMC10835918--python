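"""Readers/writers for volumes, labels, surfaces, models, tables, manifests."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .config import SegModelConfig
from .types import LabelVolume, OCTVolume, SurfaceStack

# nibabel is imported lazily so TIFF-only use does not require it at import time
def _nib():
    import nibabel
    return nibabel


def _is_nifti(path: str | Path) -> bool:
    s = str(path)
    return s.endswith(".nii") or s.endswith(".nii.gz")


def write_volume(volume: OCTVolume, path: str | Path) -> None:
    """Write a volume as multi-page TIFF (pages = B-scans) or NIfTI.

    Voxel spacing and metadata ride along in the container (TIFF image
    description JSON; NIfTI affine in mm).
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if _is_nifti(path):
        nib = _nib()
        affine = np.diag([s / 1000.0 for s in volume.spacing_um] + [1.0])
        img = nib.Nifti1Image(np.asarray(volume.intensity), affine)
        img.header.set_xyzt_units("mm")
        if volume.meta:
            img.header["descrip"] = json.dumps(volume.meta)[:79].encode()
        nib.save(img, str(path))
    else:
        desc = json.dumps({"spacing_um": list(volume.spacing_um), "meta": volume.meta})
        tifffile.imwrite(str(path), np.asarray(volume.intensity), description=desc)


def read_volume(path: str | Path, spacing_um: tuple[float, float, float] | None = None) -> OCTVolume:
    """Read a TIFF/NIfTI volume; spacing from metadata unless overridden."""
    path = Path(path)
    if _is_nifti(path):
        nib = _nib()
        img = nib.load(str(path))
        data = np.asarray(img.dataobj)
        if spacing_um is None:
            zooms = img.header.get_zooms()[:3]
            spacing_um = tuple(float(z) * 1000.0 for z in zooms)
        meta = {}
        raw = bytes(img.header["descrip"].tobytes()).rstrip(b"\x00")
        if raw:
            try:
                meta = json.loads(raw.decode())
            except (ValueError, UnicodeDecodeError):
                meta = {}
        return OCTVolume(intensity=data, spacing_um=spacing_um, meta=meta)

    with tifffile.TiffFile(str(path)) as tif:
        data = tif.asarray()
        desc = tif.pages[0].description
    meta = {}
    if spacing_um is None:
        if desc:
            try:
                payload = json.loads(desc)
                spacing_um = tuple(payload["spacing_um"])
                meta = payload.get("meta", {})
            except (ValueError, KeyError):
                spacing_um = None
        if spacing_um is None:
            raise ValueError(f"{path}: no voxel spacing in metadata and no override given")
    elif desc:
        try:
            meta = json.loads(desc).get("meta", {})
        except ValueError:
            meta = {}
    return OCTVolume(intensity=data, spacing_um=spacing_um, meta=meta)


def write_labels(labels: LabelVolume, path: str | Path) -> None:
    vol = OCTVolume(
        intensity=labels.classes.astype(np.int16),
        spacing_um=labels.spacing_um,
        meta=labels.meta,
    )
    write_volume(vol, path)


def read_labels(path: str | Path, spacing_um=None) -> LabelVolume:
    vol = read_volume(path, spacing_um=spacing_um)
    return LabelVolume(
        classes=np.asarray(vol.intensity).astype(np.int16),
        spacing_um=vol.spacing_um,
        meta=vol.meta,
    )


def write_surfaces(stack: SurfaceStack, path: str | Path) -> None:
    """NPZ container with a JSON header naming boundary order and spacing."""
    from .types import BOUNDARY_NAMES

    header = {
        "boundaries": list(BOUNDARY_NAMES),
        "lateral_spacing_um": list(stack.lateral_spacing_um),
        "axial_spacing_um": stack.axial_spacing_um,
        "units": stack.units,
    }
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    np.savez(
        str(path),
        heights=stack.heights,
        valid=stack.valid,
        header=np.frombuffer(json.dumps(header).encode(), dtype=np.uint8),
    )


def read_surfaces(path: str | Path) -> SurfaceStack:
    with np.load(str(path)) as payload:
        header = json.loads(payload["header"].tobytes().decode())
        return SurfaceStack(
            heights=payload["heights"],
            valid=payload["valid"].astype(bool),
            lateral_spacing_um=tuple(header["lateral_spacing_um"]),
            axial_spacing_um=float(header["axial_spacing_um"]),
            units=header["units"],
        )


def save_model(model, path: str | Path) -> None:
    """Single-file versioned checkpoint (NPZ + JSON config)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    meta = {
        "format_version": 1,
        "cfg": model.cfg.model_dump(mode="json"),
        "train_shape": list(model.train_shape),
    }
    arrays = {f"param::{k}": v for k, v in model.params.items()}
    np.savez(
        str(path),
        meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
        **arrays,
    )


def load_model(path: str | Path):
    from .segment.train import SegModel

    with np.load(str(path)) as payload:
        meta = json.loads(payload["meta"].tobytes().decode())
        params = {
            k[len("param::"):]: payload[k]
            for k in payload.files if k.startswith("param::")
        }
    return SegModel(
        params=params,
        cfg=SegModelConfig.model_validate(meta["cfg"]),
        train_shape=tuple(meta["train_shape"]),
    )


MANIFEST_COLUMNS = ("subject", "eye", "day", "volume_path", "label_path", "surfaces_path")


def write_manifest(rows: list[dict], path: str | Path) -> None:
    df = pd.DataFrame(rows)
    for col in MANIFEST_COLUMNS:
        if col not in df.columns:
            df[col] = ""
    df[list(MANIFEST_COLUMNS)].to_csv(path, index=False)


def read_manifest(path: str | Path, check_files: bool = True) -> pd.DataFrame:
    """Cohort manifest CSV: (subject, eye, day) unique, referenced files exist."""
    df = pd.read_csv(path, dtype={"subject": int, "day": int}, keep_default_na=False)
    missing_cols = {"subject", "eye", "day", "volume_path"} - set(df.columns)
    if missing_cols:
        raise ValueError(f"manifest missing columns: {sorted(missing_cols)}")
    key = df[["subject", "eye", "day"]].apply(tuple, axis=1)
    if key.duplicated().any():
        raise ValueError("duplicate (subject, eye, day) rows in manifest")
    if check_files:
        base = Path(path).parent
        for col in ("volume_path", "label_path", "surfaces_path"):
            if col not in df.columns:
                continue
            for p in df[col]:
                if p and not (base / p).exists() and not Path(p).exists():
                    raise FileNotFoundError(f"manifest references missing file {p}")
    return df


def resolve_manifest_path(manifest_path: str | Path, p: str) -> Path:
    cand = Path(p)
    if cand.exists():
        return cand
    return Path(manifest_path).parent / p
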