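"""Labeled voxel volumes.

The central container is :class:`LabelVolume`: a 3-D integer label grid with
physical spacing (mm), world origin (mm) and a label -> tissue-name map.
Label 0 is reserved for exterior air.  World coordinates follow the
convention ``world = origin + index * spacing`` with 0-based voxel indices
and axis order (x, y, z).

Volumes are read and written as NIfTI-1 (spacing and origin live in the
affine); the label map travels as a two-column CSV (``label``, ``tissue``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = ["LabelVolume", "RaterMaskSet"]


@dataclass
class LabelVolume:
    """Integer-labeled voxel grid with physical geometry.

    Parameters
    ----------
    data:
        3-D integer array of tissue labels; 0 means exterior air.
    spacing:
        Voxel size in mm per axis (x, y, z); strictly positive.
    origin:
        World coordinates (mm) of the center of voxel (0, 0, 0).
    labels:
        Map from label integer to tissue name.  Every nonzero label present
        in ``data`` must appear here.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    labels: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or self.data.size == 0:
            raise ValueError("label grid must be a non-empty 3-D array")
        if not np.issubdtype(self.data.dtype, np.integer):
            raise TypeError("label grid must be integer-typed")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be three strictly positive mm values")
        self.origin = tuple(float(o) for o in self.origin)
        present = set(np.unique(self.data).tolist()) - {0}
        missing = present - set(self.labels)
        if missing:
            raise ValueError(f"labels present in grid but not in label map: {sorted(missing)}")

    # ------------------------------------------------------------------ geometry
    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def index_to_world(self, index: np.ndarray) -> np.ndarray:
        """World mm coordinates of voxel centers for (N, 3) index array."""
        idx = np.atleast_2d(np.asarray(index, dtype=float))
        return np.asarray(self.origin) + idx * np.asarray(self.spacing)

    def mask(self, label: int) -> np.ndarray:
        return self.data == label

    def body_mask(self) -> np.ndarray:
        """All voxels carrying a nonzero label."""
        return self.data != 0

    # ------------------------------------------------------------------ I/O
    def to_nifti(self, path: str | Path, label_csv: str | Path | None = None) -> None:
        affine = np.diag(list(self.spacing) + [1.0])
        affine[:3, 3] = self.origin
        img = nib.Nifti1Image(self.data.astype(np.int32), affine)
        nib.save(img, str(path))
        if label_csv is not None:
            pd.DataFrame(
                {"label": list(self.labels), "tissue": list(self.labels.values())}
            ).to_csv(label_csv, index=False)

    @classmethod
    def from_nifti(cls, path: str | Path, label_csv: str | Path | None = None) -> "LabelVolume":
        img = nib.load(str(path))
        affine = img.affine
        spacing = tuple(float(s) for s in np.abs(np.diag(affine)[:3]))
        origin = tuple(float(o) for o in affine[:3, 3])
        labels: dict[int, str] = {}
        if label_csv is not None:
            tab = pd.read_csv(label_csv)
            labels = dict(zip(tab["label"].astype(int), tab["tissue"].astype(str)))
        data = np.asanyarray(img.dataobj).astype(np.int32)
        if not labels:
            labels = {int(v): f"label_{int(v)}" for v in np.unique(data) if v != 0}
        return cls(data=data, spacing=spacing, origin=origin, labels=labels)


@dataclass
class RaterMaskSet:
    """A gold-standard mask plus per-rater segmentations of one tissue."""

    gold: np.ndarray
    raters: list[tuple[str, np.ndarray]]
    tissue: str
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.gold = np.asarray(self.gold, dtype=bool)
        self.raters = [(str(rid), np.asarray(m, dtype=bool)) for rid, m in self.raters]
        for rid, m in self.raters:
            if m.shape != self.gold.shape:
                raise ValueError(f"rater {rid!r} mask shape {m.shape} != gold {self.gold.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be strictly positive")
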