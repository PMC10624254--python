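"""Multi-rater segmentation validation metrics.

Implements the internal/external validity checks used when qualifying a
manually segmented voxel anatomy:

* Dice similarity coefficient, DSC = 2|X n Y| / (|X| + |Y|);
* average Hausdorff distance in mm — the symmetric mean boundary-to-boundary
  surface distance (the classical Hausdorff is a max; multi-rater QC tables
  report the average variant);
* organ weight = tissue density x segmented volume;
* pass/fail comparison of a measured organ weight/volume/length against a
  literature range, with the signed percent deviation from the nearest
  bound;
* per-rater and overall summary statistics over a score table.

A packaged fixture (``data/rater_scores.csv``) carries a 17-tissue x
3-segmentor DSC / average-Hausdorff reference table used by the test suite
and the summary-statistics reproduction.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

__all__ = [
    "dice",
    "hausdorff_average",
    "boundary_voxels",
    "organ_weight",
    "LiteratureRange",
    "literature_check",
    "summarize_scores",
    "bone_length_ratio",
    "load_score_table",
    "default_score_table",
    "load_literature_ranges",
    "validation_report",
    "score_rater_set",
]


def _as_mask(x: np.ndarray) -> np.ndarray:
    return np.asarray(x, dtype=bool)


def dice(x: np.ndarray, y: np.ndarray) -> float:
    """Dice similarity coefficient 2|X n Y|/(|X|+|Y|).

    Two empty masks agree perfectly (1.0); empty vs nonempty is 0.0.
    """
    x, y = _as_mask(x), _as_mask(y)
    if x.shape != y.shape:
        raise ValueError(f"mask shapes differ: {x.shape} vs {y.shape}")
    nx, ny = int(x.sum()), int(y.sum())
    if nx + ny == 0:
        return 1.0
    return 2.0 * int((x & y).sum()) / (nx + ny)


def boundary_voxels(mask: np.ndarray) -> np.ndarray:
    """Mask voxels with at least one face-adjacent background neighbor.

    Voxels on the array edge count as boundary (the outside is background).
    """
    m = _as_mask(mask)
    struct = ndimage.generate_binary_structure(m.ndim, 1)
    interior = ndimage.binary_erosion(m, structure=struct, border_value=0)
    return m & ~interior


def hausdorff_average(x: np.ndarray, y: np.ndarray,
                      spacing: float | Sequence[float] = 1.0) -> float:
    """Symmetric average surface distance between two masks, in mm.

    The mean over boundary voxels of X of the distance (between voxel
    centers, in physical mm) to the nearest boundary voxel of Y, averaged
    with the reverse direction.  Undefined (rejected) for empty masks.
    """
    x, y = _as_mask(x), _as_mask(y)
    if x.shape != y.shape:
        raise ValueError(f"mask shapes differ: {x.shape} vs {y.shape}")
    if not x.any() or not y.any():
        raise ValueError("average Hausdorff distance is undefined for an empty mask")
    sp = np.broadcast_to(np.asarray(spacing, dtype=float), (x.ndim,))
    bx = np.argwhere(boundary_voxels(x)) * sp
    by = np.argwhere(boundary_voxels(y)) * sp
    d_xy = cKDTree(by).query(bx)[0].mean()
    d_yx = cKDTree(bx).query(by)[0].mean()
    return float(0.5 * (d_xy + d_yx))


def organ_weight(mask: np.ndarray, spacing: float | Sequence[float],
                 density: float) -> float:
    """Segmented organ weight in grams: voxel count x voxel volume x density."""
    if density <= 0:
        raise ValueError("density must be positive")
    m = _as_mask(mask)
    sp = np.broadcast_to(np.asarray(spacing, dtype=float), (m.ndim,))
    voxel_m3 = float(np.prod(sp)) * 1e-9  # mm^3 -> m^3
    return float(m.sum()) * voxel_m3 * density * 1e3  # kg -> g


@dataclass(frozen=True)
class LiteratureRange:
    """A published reference interval for one organ measurement."""

    tissue: str
    measurement: str  # weight_g | volume_cm3 | length_cm | ratio
    low: float
    high: float
    source: str = ""

    def __post_init__(self) -> None:
        if self.low > self.high:
            raise ValueError(f"{self.tissue}: low bound exceeds high bound")


def literature_check(value: float, ref: LiteratureRange) -> tuple[str, float]:
    """Pass/fail against a literature range.

    Returns ``("pass", 0.0)`` inside the range, else ``("fail", dev)`` where
    ``dev`` is the signed percent deviation from the nearest bound,
    ``100 * (value - bound) / bound`` (negative below the low bound).
    """
    if ref.low <= value <= ref.high:
        return "pass", 0.0
    bound = ref.low if value < ref.low else ref.high
    if bound == 0:
        raise ValueError("cannot express deviation relative to a zero bound")
    return "fail", 100.0 * (value - bound) / bound


def bone_length_ratio(length_a: float, length_b: float) -> float:
    """Dimensionless bone length ratio a/b (e.g. radius/humerus)."""
    if length_a <= 0 or length_b <= 0:
        raise ValueError("bone lengths must be positive")
    return length_a / length_b


# --------------------------------------------------------------------------- score tables

def load_score_table(path: str | Path) -> pd.DataFrame:
    """Load a (tissue, rater, dsc, hausdorff_mm) score table CSV."""
    tab = pd.read_csv(path)
    required = {"tissue", "rater", "dsc", "hausdorff_mm"}
    if missing := required - set(tab.columns):
        raise ValueError(f"score table missing columns: {sorted(missing)}")
    if tab.duplicated(["tissue", "rater"]).any():
        raise ValueError("duplicate (tissue, rater) rows in score table")
    if ((tab["dsc"] < 0) | (tab["dsc"] > 1)).any():
        raise ValueError("DSC values must lie in [0, 1]")
    if (tab["hausdorff_mm"] < 0).any():
        raise ValueError("Hausdorff distances must be >= 0")
    return tab


def default_score_table() -> pd.DataFrame:
    """The packaged 17-tissue x 3-segmentor reference score table."""
    with resources.as_file(resources.files("voxdosim.data") / "rater_scores.csv") as p:
        return load_score_table(p)


def summarize_scores(table: pd.DataFrame, metric: str = "dsc",
                     ddof: int = 1) -> pd.DataFrame:
    """Per-rater and overall (min, max, mean, SD) of one score column.

    SD defaults to the sample standard deviation (``ddof=1``), which matches
    reference QC tables at their printed precision; pass ``ddof=0`` for the
    population SD.  The "overall" row pools all (tissue, rater) cells.
    """
    if len(table) == 0:
        raise ValueError("empty score table")
    if metric not in table.columns:
        raise ValueError(f"no column {metric!r} in score table")

    def stats(v: pd.Series) -> dict[str, float]:
        return {
            "min": float(v.min()), "max": float(v.max()),
            "mean": float(v.mean()), "sd": float(v.std(ddof=ddof)),
            "n": int(v.size),
        }

    rows = {str(r): stats(g[metric]) for r, g in table.groupby("rater")}
    rows["overall"] = stats(table[metric])
    return pd.DataFrame(rows).T[["min", "max", "mean", "sd", "n"]]


def load_literature_ranges(path: str | Path | None = None) -> list[LiteratureRange]:
    """Load literature reference ranges (packaged table by default)."""
    if path is None:
        with resources.as_file(
            resources.files("voxdosim.data") / "literature_ranges.csv"
        ) as p:
            tab = pd.read_csv(p)
    else:
        tab = pd.read_csv(path)
    return [
        LiteratureRange(r.tissue, r.measurement, float(r.low), float(r.high),
                        str(r.source))
        for r in tab.itertuples()
    ]


def validation_report(
    measurements: dict[str, float],
    ranges: list[LiteratureRange],
) -> tuple[dict, str]:
    """Pass/fail every measured organ value against its literature ranges.

    A tissue passes if it passes at least one of its reference ranges (QC
    tables often cite several sources).  Returns a JSON-serializable dict
    plus a human-readable text rendering.
    """
    by_tissue: dict[str, list[LiteratureRange]] = {}
    for r in ranges:
        by_tissue.setdefault(r.tissue, []).append(r)
    report: dict = {}
    lines = []
    for tissue, value in measurements.items():
        refs = by_tissue.get(tissue)
        if not refs:
            raise KeyError(f"no literature range for {tissue!r}")
        checks = [literature_check(value, r) for r in refs]
        verdict = "pass" if any(v == "pass" for v, _ in checks) else "fail"
        # deviation from the closest-passing (smallest-|dev|) reference
        deviation = min((d for _, d in checks), key=abs)
        report[tissue] = {
            "value": value,
            "measurement": refs[0].measurement,
            "verdict": verdict,
            "deviation_pct": round(deviation, 2),
            "ranges": [[r.low, r.high, r.source] for r in refs],
        }
        lines.append(f"{tissue:24s} {value:>8.1f} {refs[0].measurement:<10s} "
                     f"{verdict.upper():4s} ({deviation:+.1f}%)")
    return report, "\n".join(lines) + "\n"


def score_rater_set(rater_set, gold: np.ndarray | None = None) -> pd.DataFrame:
    """DSC / average-Hausdorff score table for a multi-rater mask set."""
    gold = rater_set.gold if gold is None else _as_mask(gold)
    rows = [
        {
            "tissue": rater_set.tissue,
            "rater": rid,
            "dsc": dice(m, gold),
            "hausdorff_mm": hausdorff_average(m, gold, rater_set.spacing),
        }
        for rid, m in rater_set.raters
    ]
    return pd.DataFrame(rows)
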