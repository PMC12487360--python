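"""Surface and metric file I/O: GIFTI (.surf.gii/.func.gii), OBJ, CSV."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import nibabel as nib

from .exceptions import DataError
from .surface_morphometry import CorticalMesh

__all__ = [
    "save_surface",
    "load_surface",
    "save_metric",
    "load_metric",
]


def save_surface(mesh: CorticalMesh, path: str | Path) -> Path:
    """Write a triangle mesh as GIFTI (.gii) or Wavefront OBJ (.obj)."""
    path = Path(path)
    if path.suffix == ".obj":
        mesh.to_trimesh().export(str(path))
        return path
    if path.suffix == ".gii":
        coords = nib.gifti.GiftiDataArray(
            mesh.vertices.astype(np.float32),
            intent="NIFTI_INTENT_POINTSET",
        )
        tris = nib.gifti.GiftiDataArray(
            mesh.faces.astype(np.int32),
            intent="NIFTI_INTENT_TRIANGLE",
        )
        nib.save(nib.gifti.GiftiImage(darrays=[coords, tris]), str(path))
        return path
    raise DataError(f"unsupported surface format: {path.suffix!r}")


def load_surface(path: str | Path, hemisphere: str = "both") -> CorticalMesh:
    """Read a GIFTI or OBJ triangle mesh into a :class:`CorticalMesh`."""
    path = Path(path)
    if path.suffix == ".obj":
        import trimesh

        tm = trimesh.load(str(path), process=False)
        return CorticalMesh(np.asarray(tm.vertices), np.asarray(tm.faces),
                            hemisphere=hemisphere)
    if path.suffix == ".gii":
        img = nib.load(str(path))
        coords = tris = None
        for arr in img.darrays:
            if arr.intent == nib.nifti1.intent_codes["NIFTI_INTENT_POINTSET"]:
                coords = arr.data
            elif arr.intent == nib.nifti1.intent_codes["NIFTI_INTENT_TRIANGLE"]:
                tris = arr.data
        if coords is None or tris is None:
            raise DataError(f"{path} lacks pointset/triangle arrays")
        return CorticalMesh(np.asarray(coords, dtype=float),
                            np.asarray(tris, dtype=np.int64),
                            hemisphere=hemisphere)
    raise DataError(f"unsupported surface format: {path.suffix!r}")


def save_metric(values: np.ndarray, path: str | Path) -> Path:
    """Write a per-vertex scalar map as GIFTI metric (.gii) or CSV."""
    path = Path(path)
    values = np.asarray(values, dtype=np.float32).ravel()
    if path.suffix == ".csv":
        np.savetxt(path, values, delimiter=",", header="value", comments="")
        return path
    if path.suffix == ".gii":
        arr = nib.gifti.GiftiDataArray(values, intent="NIFTI_INTENT_SHAPE")
        nib.save(nib.gifti.GiftiImage(darrays=[arr]), str(path))
        return path
    raise DataError(f"unsupported metric format: {path.suffix!r}")


def load_metric(path: str | Path) -> np.ndarray:
    path = Path(path)
    if path.suffix == ".csv":
        return np.loadtxt(path, delimiter=",", skiprows=1, dtype=float)
    if path.suffix == ".gii":
        img = nib.load(str(path))
        return np.asarray(img.darrays[0].data, dtype=float)
    raise DataError(f"unsupported metric format: {path.suffix!r}")
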