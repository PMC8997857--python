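"""Image, mask and feature-table I/O with the package's coordinate conventions.

Conventions
-----------
* all pixel indexing is 0-based in array order ``(row, column[, slice])``;
* masks are strictly binary (``bool``) after load, obtained as ``raw > 0``;
* volumes and masks travel as NIfTI (via nibabel) or single-slice PNG/TIFF;
* feature tables are CSV, one row per nodule.

Two contrast phases are handled: ``arterial`` (A) and ``venous`` (V).  The
second enhancement phase of an acquisition protocol (venous/delayed) is
treated generically under the venous label.
"""

from __future__ import annotations

import pathlib
from dataclasses import dataclass, field

import imageio.v3 as iio
import nibabel as nib
import numpy as np
import pandas as pd

PHASES = ("arterial", "venous")


class ImagingIOError(Exception):
    """Base class for case-loading failures; carries a short error code."""

    code = "io-error"


class UnreadableFileError(ImagingIOError):
    code = "unreadable-file"


class ShapeMismatchError(ImagingIOError):
    code = "shape-mismatch"


class EmptyMaskError(ImagingIOError):
    code = "empty-mask"


@dataclass
class PhaseImage:
    """One contrast-phase CT image (HU-like values) with pixel spacing."""

    voxels: np.ndarray
    spacing: tuple[float, ...] = (1.0, 1.0)
    phase: str = "arterial"
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=float)
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("image contains non-finite values")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")
        if self.phase not in PHASES:
            raise ValueError(f"phase must be one of {PHASES}, got {self.phase!r}")


@dataclass
class RoiMask:
    """Binary region of interest aligned with a :class:`PhaseImage`.

    ``kind`` records provenance: ``manual`` (radiologist-style input),
    ``refined`` (gradient-refined tumour border) or ``zot``.
    """

    support: np.ndarray
    kind: str = "manual"

    def __post_init__(self) -> None:
        self.support = np.asarray(self.support) > 0
        if self.kind not in ("manual", "refined", "zot"):
            raise ValueError(f"unknown mask kind {self.kind!r}")
        if self.kind in ("manual", "refined") and not self.support.any():
            raise EmptyMaskError(f"{self.kind} mask is empty")

    @property
    def area(self) -> int:
        return int(self.support.sum())


# ---------------------------------------------------------------------------
# raw array readers/writers
# ---------------------------------------------------------------------------

_NIFTI_SUFFIXES = (".nii", ".nii.gz")


def _is_nifti(path: pathlib.Path) -> bool:
    name = path.name.lower()
    return name.endswith(".nii") or name.endswith(".nii.gz")


def read_array(path) -> np.ndarray:
    """Read a NIfTI / PNG / TIFF image into a float array (row, col[, slice])."""
    path = pathlib.Path(path)
    if not path.exists():
        raise UnreadableFileError(f"no such file: {path}")
    try:
        if _is_nifti(path):
            return np.asarray(nib.load(str(path)).get_fdata(), dtype=float)
        return np.asarray(iio.imread(path), dtype=float)
    except ImagingIOError:
        raise
    except Exception as exc:  # pragma: no cover - backend-specific messages
        raise UnreadableFileError(f"cannot read {path}: {exc}") from exc


def write_array(array: np.ndarray, path) -> pathlib.Path:
    """Write an array as NIfTI (any dtype) or PNG/TIFF (2-D, cast to uint16)."""
    path = pathlib.Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    array = np.asarray(array)
    if _is_nifti(path):
        nib.save(nib.Nifti1Image(array.astype(np.float64), np.eye(4)), str(path))
    else:
        if array.ndim != 2:
            raise ValueError("PNG/TIFF output supports 2-D arrays only")
        if array.dtype == bool:
            iio.imwrite(path, (array * 255).astype(np.uint8))
        else:
            lo, hi = float(array.min()), float(array.max())
            scale = 65535.0 / (hi - lo) if hi > lo else 0.0
            iio.imwrite(path, ((array - lo) * scale).astype(np.uint16))
    return path


# ---------------------------------------------------------------------------
# case loading
# ---------------------------------------------------------------------------

def read_case(paths: dict, config: dict | None = None):
    """Load a two-phase case with per-phase manual masks.

    Parameters
    ----------
    paths
        Mapping with keys ``arterial``, ``venous``, ``arterial_mask``,
        ``venous_mask``.
    config
        Optional dict; honours ``spacing`` (sequence of mm/pixel) and
        ``subject_id``.

    Returns
    -------
    (images, masks)
        Two dicts keyed by phase: ``PhaseImage`` and manual ``RoiMask``.

    Raises
    ------
    UnreadableFileError, ShapeMismatchError, EmptyMaskError
        Distinct error codes for the three failure modes.
    """
    config = config or {}
    spacing = tuple(config.get("spacing", (1.0, 1.0)))
    subject_id = str(config.get("subject_id", ""))
    images, masks = {}, {}
    for phase in PHASES:
        img = read_array(paths[phase])
        raw_mask = read_array(paths[f"{phase}_mask"])
        if raw_mask.shape != img.shape:
            raise ShapeMismatchError(
                f"{phase}: mask shape {raw_mask.shape} != image shape {img.shape}"
            )
        if not (raw_mask > 0).any():
            raise EmptyMaskError(f"{phase}: manual mask is empty")
        sp = spacing if len(spacing) == img.ndim else (1.0,) * img.ndim
        images[phase] = PhaseImage(img, sp, phase, subject_id)
        masks[phase] = RoiMask(raw_mask > 0, kind="manual")
    return images, masks


def write_case(images: dict, masks: dict, out_dir, fmt: str = "nii.gz") -> dict:
    """Persist a two-phase case; returns the path mapping read_case accepts."""
    out_dir = pathlib.Path(out_dir)
    paths = {}
    for phase in PHASES:
        paths[phase] = write_array(
            images[phase].voxels, out_dir / f"{phase}.{fmt}")
        paths[f"{phase}_mask"] = write_array(
            masks[phase].support.astype(np.uint8), out_dir / f"{phase}_mask.{fmt}")
    return paths


# ---------------------------------------------------------------------------
# feature tables
# ---------------------------------------------------------------------------

def write_feature_table(vectors, path) -> pathlib.Path:
    """Write FeatureVectors as CSV: subject_id, label, then the named features.

    All vectors must share the same feature-name schema (same names, same
    order); otherwise the write is rejected.
    """
    path = pathlib.Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    vectors = list(vectors)
    if vectors:
        schema = list(vectors[0].values.keys())
        for v in vectors[1:]:
            if list(v.values.keys()) != schema:
                raise ValueError("inconsistent feature schemas across vectors")
        rows = [
            {"subject_id": v.subject_id, "label": v.label, **v.values}
            for v in vectors
        ]
        frame = pd.DataFrame(rows, columns=["subject_id", "label"] + schema)
    else:
        frame = pd.DataFrame(columns=["subject_id", "label"])
    frame.to_csv(path, index=False)
    return path


def read_feature_table(path) -> pd.DataFrame:
    return pd.read_csv(path)
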