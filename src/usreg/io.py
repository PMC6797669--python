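"""Readers and writers for volumes, landmarks and transform chains.

Volumes go through SimpleITK (NIfTI ``.nii``/``.nii.gz`` and MetaImage
``.mha``/``.mhd``).  Headers are interpreted in the LPS world frame that ITK
uses natively; everything downstream stays in that one frame.

Landmarks use a small CSV dialect (header ``label,x,y,z``, world mm, UTF-8,
LF).  The MNI ``.tag`` dialect used by the public ultrasound registration
datasets is supported read-only.

Transform chains serialize to a YAML document; each dense displacement field
is stored as a 3-component NIfTI volume (mm) next to the YAML file.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd
import SimpleITK as sitk
import yaml

from .core import LandmarkSet, Mask3D, Volume3D
from .errors import CorrespondenceError, FormatError, GeometryError, ParseError
from .transforms import DeformationField, RigidTransform, TransformChain

__all__ = [
    "read_volume",
    "write_volume",
    "read_landmarks",
    "write_landmarks",
    "save_chain",
    "load_chain",
]

_VOLUME_EXT = (".nii", ".nii.gz", ".mha", ".mhd")


def _check_volume_path(path: Path):
    name = path.name.lower()
    if not any(name.endswith(e) for e in _VOLUME_EXT):
        raise FormatError(
            f"unsupported volume format for '{path}' (expected one of {_VOLUME_EXT})"
        )


def _from_sitk(img: sitk.Image) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    # sitk arrays are (z, y, x); transpose to index order (x, y, z)
    arr = sitk.GetArrayFromImage(img).T
    spacing = np.asarray(img.GetSpacing(), dtype=float)
    origin = np.asarray(img.GetOrigin(), dtype=float)
    direction = np.asarray(img.GetDirection(), dtype=float).reshape(3, 3)
    return arr, spacing, origin, direction


def _to_sitk(data: np.ndarray, spacing, origin, direction, is_vector=False) -> sitk.Image:
    if is_vector:
        img = sitk.GetImageFromArray(np.ascontiguousarray(data.transpose(2, 1, 0, 3)), isVector=True)
    else:
        img = sitk.GetImageFromArray(np.ascontiguousarray(data.T))
    img.SetSpacing(tuple(float(s) for s in spacing))
    img.SetOrigin(tuple(float(o) for o in origin))
    img.SetDirection(tuple(float(d) for d in np.asarray(direction).reshape(9)))
    return img


def read_volume(path) -> Volume3D:
    """Read a NIfTI or MetaImage volume, geometry taken from the header."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"volume file not found: '{path}'")
    _check_volume_path(path)
    try:
        img = sitk.ReadImage(os.fspath(path))
    except RuntimeError as exc:
        raise FormatError(f"cannot read volume '{path}': {exc}") from exc
    arr, spacing, origin, direction = _from_sitk(img)
    if np.any(np.asarray(spacing) <= 0):
        raise GeometryError(f"non-positive voxel spacing in '{path}'")
    return Volume3D(data=arr, spacing=spacing, origin=origin, direction=direction)


def read_mask(path, kind: str = "binary", threshold: float = 0.5) -> Mask3D:
    """Read a mask volume; binary kind is re-thresholded at ``threshold``."""
    v = read_volume(path)
    data = np.asarray(v.data)
    if kind == "binary":
        data = (data >= threshold).astype(np.uint8)
    return Mask3D(data=data, spacing=v.spacing, origin=v.origin, direction=v.direction, kind=kind)


def write_volume(v: Volume3D, path) -> None:
    """Write a volume; round-trips are exact for integers, float32 for floats."""
    path = Path(path)
    _check_volume_path(path)
    if not path.parent.is_dir():
        raise IOError(f"directory does not exist: '{path.parent}'")
    data = np.asarray(v.data)
    if data.dtype.kind == "f":
        data = data.astype(np.float32)
    sitk.WriteImage(_to_sitk(data, v.spacing, v.origin, v.direction), os.fspath(path))


# ---------------------------------------------------------------------------
# Landmarks
# ---------------------------------------------------------------------------

def read_landmarks(path, dialect: str = "csv"):
    """Read landmarks in world mm.

    ``dialect='csv'`` returns one :class:`LandmarkSet`; ``dialect='mni_tag'``
    returns one set, or a pair of equally sized sets when the file declares
    two volumes.
    """
    path = Path(path)
    if dialect == "csv":
        return _read_landmarks_csv(path)
    if dialect == "mni_tag":
        return _read_landmarks_tag(path)
    raise ValueError(f"unknown landmark dialect '{dialect}'")


def _read_landmarks_csv(path: Path) -> LandmarkSet:
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise ParseError(f"cannot parse landmark CSV '{path}': {exc}") from exc
    expected = ["label", "x", "y", "z"]
    if list(df.columns[:4]) != expected:
        raise ParseError(f"landmark CSV '{path}' must have header {','.join(expected)}")
    coords = df[["x", "y", "z"]].apply(pd.to_numeric, errors="coerce")
    bad = coords.isna().any(axis=1)
    if bad.any():
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # +1 header, +1 1-based
        raise ParseError(f"non-numeric coordinate at line {line} of '{path}'")
    return LandmarkSet(points=coords.to_numpy(float), labels=df["label"].astype(str).tolist())


def write_landmarks(lm: LandmarkSet, path) -> None:
    labels = lm.labels or [f"L{i + 1}" for i in range(len(lm))]
    df = pd.DataFrame(
        {"label": labels, "x": lm.points[:, 0], "y": lm.points[:, 1], "z": lm.points[:, 2]}
    )
    df.to_csv(path, index=False, lineterminator="\n")


def _read_landmarks_tag(path: Path):
    """Minimal reader for the MNI .tag text format (1- or 2-volume files)."""
    text = path.read_text(encoding="utf-8")
    if "MNI Tag Point File" not in text.splitlines()[0]:
        raise ParseError(f"'{path}' is not an MNI tag file")
    n_vols = 1
    for ln in text.splitlines():
        s = ln.strip()
        if s.lower().startswith("volumes"):
            n_vols = int(s.rstrip(";").split("=")[1])
    if "Points" not in text:
        raise ParseError(f"no Points block in '{path}'")
    block = text.split("Points", 1)[1].split("=", 1)[1]
    block = block.split(";", 1)[0]
    rows_a, rows_b, labels = [], [], []
    for lineno, ln in enumerate(block.splitlines()):
        s = ln.strip()
        if not s:
            continue
        label = None
        if '"' in s:
            s, rest = s.split('"', 1)
            label = rest.rstrip('"')
        tokens = s.split()
        try:
            vals = [float(t) for t in tokens]
        except ValueError as exc:
            raise ParseError(f"non-numeric coordinate in Points block of '{path}': {exc}") from exc
        if len(vals) != 3 * n_vols:
            raise CorrespondenceError(
                f"tag row with {len(vals)} coordinates where {3 * n_vols} were "
                f"declared ('{path}')"
            )
        rows_a.append(vals[:3])
        if n_vols == 2:
            rows_b.append(vals[3:6])
        labels.append(label if label is not None else f"L{len(rows_a)}")
    set_a = LandmarkSet(points=np.array(rows_a), labels=labels)
    if n_vols == 2:
        return set_a, LandmarkSet(points=np.array(rows_b), labels=list(labels))
    return set_a


# ---------------------------------------------------------------------------
# Transform chains
# ---------------------------------------------------------------------------

def save_chain(chain: TransformChain, path) -> None:
    """Serialize a chain to YAML; displacement fields land in sibling NIfTIs."""
    path = Path(path)
    steps = []
    n_fields = 0
    for step in chain:
        if isinstance(step, RigidTransform):
            steps.append(
                {
                    "type": "rigid",
                    "frame": "world-lps",
                    "translation_mm": [float(x) for x in step.translation],
                    "rotation_rad": [float(x) for x in step.rotation],
                    "center_mm": [float(x) for x in step.center],
                }
            )
        elif isinstance(step, DeformationField):
            fname = f"{path.stem}_field{n_fields}.nii.gz"
            n_fields += 1
            arr = np.moveaxis(step.displacements, 0, -1).astype(np.float32)
            img = _to_sitk(arr, step.spacing, step.origin, step.direction, is_vector=True)
            sitk.WriteImage(img, os.fspath(path.parent / fname))
            steps.append({"type": "field", "frame": "world-lps", "displacement": fname})
        else:
            raise TypeError(f"cannot serialize chain step of type {type(step)}")
    path.write_text(yaml.safe_dump({"steps": steps}, sort_keys=False), encoding="utf-8")


def load_chain(path) -> TransformChain:
    path = Path(path)
    doc = yaml.safe_load(path.read_text(encoding="utf-8"))
    chain = TransformChain()
    for step in doc.get("steps", []):
        if step["type"] == "rigid":
            chain.append(
                RigidTransform(
                    translation=step["translation_mm"],
                    rotation=step["rotation_rad"],
                    center=step["center_mm"],
                )
            )
        elif step["type"] == "field":
            img = sitk.ReadImage(os.fspath(path.parent / step["displacement"]))
            arr = sitk.GetArrayFromImage(img)  # (z, y, x, 3)
            disp = np.moveaxis(arr.transpose(2, 1, 0, 3), -1, 0)
            chain.append(
                DeformationField(
                    displacements=disp,
                    spacing=np.asarray(img.GetSpacing()),
                    origin=np.asarray(img.GetOrigin()),
                    direction=np.asarray(img.GetDirection()).reshape(3, 3),
                )
            )
        else:
            raise FormatError(f"unknown chain step type '{step['type']}' in '{path}'")
    return chain
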