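"""Scan bags: ordered slice instances with scan-level labels.

A *bag* is one volumetric scan; its *instances* are the axial slices, ordered
from lung top to lung bottom. Bag labels follow the standard MIL decision
rule: a scan is negative iff every one of its slices is negative.

Axial position is reported as a normalized depth in [0, 1] with 0 at the lung
top and 1 at the lung bottom, so that scans with different slice counts and
thicknesses are comparable.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = [
    "ScanBag",
    "Manifest",
    "bag_label_from_instances",
    "normalized_depths",
    "load_bags",
    "load_volume",
    "preprocess_slices",
]


def normalized_depths(n_slices: int) -> np.ndarray:
    """Normalized axial depth of each of ``n_slices`` ordered slices.

    Slice j of N (1-based) sits at (j-1)/(N-1); a single-slice scan gets
    depth 0 by convention. Depth 0 is the lung top, 1 the lung bottom.
    """
    if n_slices < 1:
        raise ValidationError("a bag needs at least one slice")
    if n_slices == 1:
        return np.zeros(1)
    return np.arange(n_slices) / (n_slices - 1)


def bag_label_from_instances(instance_labels: Sequence[int]) -> int:
    """Bag label from instance labels: 0 iff all instances are 0, else 1."""
    labels = np.asarray(instance_labels)
    if labels.size == 0:
        raise ValidationError("cannot derive a bag label from an empty bag")
    return int((labels != 0).any())


@dataclass
class ScanBag:
    """One scan: an ordered stack of 2D slices plus an optional scan label.

    Attributes
    ----------
    scan_id : str
        Unique identifier.
    slices : ndarray, shape (N, H, W)
        Axial slices ordered top -> bottom.
    label : int or None
        Scan-level label in {0, 1}; None at inference time.
    depths : ndarray, shape (N,)
        Normalized axial depths, 0 = lung top, 1 = lung bottom.
    metadata : dict
        Free-form (phenotype tag, slice thickness, ...).
    """

    scan_id: str
    slices: np.ndarray
    label: Optional[int] = None
    depths: Optional[np.ndarray] = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.slices = np.asarray(self.slices, dtype=np.float32)
        if self.slices.ndim != 3 or self.slices.shape[0] < 1:
            raise ValidationError(
                f"scan {self.scan_id}: slices must be a (N>=1, H, W) array, "
                f"got shape {self.slices.shape}"
            )
        if self.label is not None and self.label not in (0, 1):
            raise ValidationError(
                f"scan {self.scan_id}: label must be 0 or 1, got {self.label!r}"
            )
        if self.depths is None:
            self.depths = normalized_depths(self.n_slices)
        else:
            self.depths = np.asarray(self.depths, dtype=float)
            if self.depths.shape != (self.n_slices,):
                raise ValidationError(
                    f"scan {self.scan_id}: depths must have one entry per slice"
                )
            if self.n_slices > 1 and not np.all(np.diff(self.depths) > 0):
                raise ValidationError(
                    f"scan {self.scan_id}: depths must be strictly increasing"
                )

    @property
    def n_slices(self) -> int:
        return int(self.slices.shape[0])


@dataclass
class Manifest:
    """Table of scans: id, volume path, label, optional phenotype/annotations."""

    table: pd.DataFrame

    REQUIRED = ("scan_id", "path", "label")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValidationError(f"manifest missing columns: {missing}")
        if self.table["scan_id"].duplicated().any():
            dupes = self.table.loc[self.table["scan_id"].duplicated(), "scan_id"]
            raise ValidationError(f"duplicate scan_ids in manifest: {list(dupes)}")
        bad = ~self.table["label"].isin([0, 1])
        if bad.any():
            raise ValidationError(
                f"labels must be 0 or 1; offending rows: "
                f"{self.table.loc[bad, 'scan_id'].tolist()}"
            )

    @classmethod
    def read_csv(cls, path: str | os.PathLike) -> "Manifest":
        return cls(pd.read_csv(path))

    def __len__(self) -> int:
        return len(self.table)


def _order_slices_nifti(img) -> np.ndarray:
    """Slices of a NIfTI image ordered lung top -> bottom.

    The volume is reoriented to RAS from its affine, then read along the
    third (superior-inferior) axis from the highest physical z downwards, so
    volumes that store slices in either axial direction load identically.
    """
    import nibabel as nib

    canonical = nib.as_closest_canonical(img)
    data = np.asanyarray(canonical.dataobj).astype(np.float32)
    if data.ndim != 3:
        raise ValidationError(f"expected a 3D volume, got shape {data.shape}")
    # canonical = ascending z (inferior -> superior); top-first = reversed
    return np.transpose(data[:, :, ::-1], (2, 0, 1))


def _order_slices_dicom(series_dir: str) -> np.ndarray:
    """Read a DICOM series directory, ordered by ImagePositionPatient z descending."""
    import pydicom

    files = sorted(
        os.path.join(series_dir, f)
        for f in os.listdir(series_dir)
        if not f.startswith(".")
    )
    if not files:
        raise ValidationError(f"no DICOM files in {series_dir}")
    frames = []
    for f in files:
        ds = pydicom.dcmread(f)
        z = float(getattr(ds, "ImagePositionPatient", [0, 0, len(frames)])[2])
        frames.append((z, ds.pixel_array.astype(np.float32)))
    frames.sort(key=lambda t: -t[0])
    return np.stack([arr for _, arr in frames])


def load_volume(path: str | os.PathLike) -> np.ndarray:
    """Load a NIfTI file or DICOM series directory as (N, H, W) slices, top-first."""
    path = os.fspath(path)
    if not os.path.exists(path):
        raise ValidationError(f"volume not found: {path}")
    if os.path.isdir(path):
        return _order_slices_dicom(path)
    if path.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        try:
            img = nib.load(path)
        except Exception as exc:  # pragma: no cover - nibabel message passthrough
            raise ValidationError(f"unreadable volume {path}: {exc}") from exc
        return _order_slices_nifti(img)
    raise ValidationError(f"unsupported volume format: {path}")


def preprocess_slices(
    slices: np.ndarray,
    target_size: Optional[tuple[int, int]] = None,
    window: Optional[tuple[float, float] | str] = None,
) -> np.ndarray:
    """Optionally resample slices in-plane and window intensities to [0, 1].

    ``window`` may be a (lo, hi) pair (values clipped then affinely mapped to
    [0, 1]) or ``"minmax"`` (per-volume min-max). ``None`` leaves intensities
    untouched — the built-in phantoms already live in [0, 1].
    """
    out = np.asarray(slices, dtype=np.float32)
    if window == "minmax":
        lo, hi = float(out.min()), float(out.max())
        out = (out - lo) / (hi - lo) if hi > lo else np.zeros_like(out)
    elif window is not None:
        lo, hi = window
        if hi <= lo:
            raise ValidationError(f"invalid intensity window {window}")
        out = np.clip((out - lo) / (hi - lo), 0.0, 1.0)
    if target_size is not None and out.shape[1:] != tuple(target_size):
        from skimage.transform import resize

        out = np.stack(
            [
                resize(s, target_size, order=1, anti_aliasing=True).astype(np.float32)
                for s in out
            ]
        )
    return out.astype(np.float32)


def load_bags(
    manifest: Manifest | str | os.PathLike,
    root: Optional[str | os.PathLike] = None,
    target_size: Optional[tuple[int, int]] = None,
    window: Optional[tuple[float, float] | str] = None,
) -> list[ScanBag]:
    """Assemble one :class:`ScanBag` per manifest row.

    Paths in the manifest are resolved relative to ``root`` (default: the
    manifest's own directory when a path is given, else the cwd).
    """
    if not isinstance(manifest, Manifest):
        manifest_path = os.fspath(manifest)
        if root is None:
            root = os.path.dirname(os.path.abspath(manifest_path))
        manifest = Manifest.read_csv(manifest_path)
    root = os.fspath(root) if root is not None else "."
    bags = []
    for row in manifest.table.itertuples(index=False):
        path = row.path
        if not os.path.isabs(path):
            path = os.path.join(root, path)
        slices = preprocess_slices(load_volume(path), target_size, window)
        meta = {}
        if hasattr(row, "phenotype") and pd.notna(row.phenotype):
            meta["phenotype"] = row.phenotype
        bags.append(
            ScanBag(
                scan_id=str(row.scan_id),
                slices=slices,
                label=int(row.label),
                metadata=meta,
            )
        )
    return bags
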