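"""Synthetic phantom generation and voxel-volume assembly rules.

This module provides (a) generators for simple multi-tissue layered head
phantoms and multi-rater mask sets used throughout the package in place of
non-distributable anatomical models, and (b) the assembly operations used
when building a labeled voxel anatomy from per-tissue segmentations:

* priority merge — overlapping labels resolved in favor of the higher
  label number (small/detailed compartments get high labels);
* supplant — unassigned in-body voxels adopt the label of the nearest
  labeled voxel (Euclidean distance in mm, smallest label on ties);
* a skin shell of 1.0 mm default thickness as the outermost layer;
* resampling — Lanczos (a = 3) for scalar images, nearest-neighbor for
  label grids.

All generators are bit-reproducible under a fixed seed.
"""

from __future__ import annotations

import logging
import math
from typing import Sequence

import numpy as np
from scipy import ndimage

from .volume import LabelVolume, RaterMaskSet

__all__ = [
    "make_layered_head",
    "merge_with_priority",
    "supplant_unassigned",
    "resample_volume",
    "resample_scalar",
    "perturb_mask",
    "make_rater_set",
    "DEFAULT_HEAD_TISSUES",
    "default_head_radii",
]

logger = logging.getLogger(__name__)

#: Canonical 5-layer head composition, outermost first.
DEFAULT_HEAD_TISSUES = (
    "Skin",
    "Bone (Cortical)",
    "Cerebrospinal fluid",
    "Brain (grey matter)",
    "Brain (white matter)",
)

#: Default skin thickness in mm (ICRP-style outermost shell).
SKIN_THICKNESS_MM = 1.0

_FACE_STRUCT = ndimage.generate_binary_structure(3, 1)  # 6-connectivity


def default_head_radii(outer_radius_mm: float = 80.0) -> tuple[float, ...]:
    """Outer radii (mm) for the 5-layer head: 1.0 mm skin, 7 mm skull,
    5 mm CSF, 14 mm grey-matter cortex, white-matter core.

    Shell thicknesses are kept >= 4 mm (except the skin, which snaps to the
    grid) so the phantom voxelizes on the desk-scale solver grid.
    """
    r0 = float(outer_radius_mm)
    return (r0, r0 - SKIN_THICKNESS_MM, r0 - 8.0, r0 - 13.0, r0 - 27.0)


def make_layered_head(
    layer_radii: Sequence[float],
    layer_tissues: Sequence[str] = DEFAULT_HEAD_TISSUES,
    spacing: float | Sequence[float] = 1.0,
    air_cavity: tuple[Sequence[float], float] | None = None,
) -> LabelVolume:
    """Build a concentric-shell head phantom.

    Parameters
    ----------
    layer_radii:
        Outer radius (mm) of each layer, strictly decreasing, outermost
        first.  Layer ``i`` occupies ``layer_radii[i+1] < r <= layer_radii[i]``;
        the last entry is a solid core.  The outermost layer is the skin and
        defaults to 1.0 mm thickness via :func:`default_head_radii`.
    layer_tissues:
        Tissue name per layer (same length as ``layer_radii``).
    spacing:
        Isotropic (scalar) or per-axis voxel size in mm.
    air_cavity:
        Optional internal air sphere ``((cx, cy, cz) mm relative to the head
        center, radius mm)``, labeled as internal air ("Air").

    Labels are assigned 1..n outer -> inner (the cavity, if any, gets the
    highest label), so the priority-merge convention "higher label wins"
    keeps inner structures on re-merge.  If the grid is coarser than the
    requested skin thickness the skin shell is snapped outward to one voxel
    and the achieved thickness is logged.
    """
    radii = [float(r) for r in layer_radii]
    if len(radii) < 1:
        raise ValueError("need at least one layer")
    if len(radii) != len(layer_tissues):
        raise ValueError("layer_radii and layer_tissues must have equal length")
    if any(b >= a for a, b in zip(radii, radii[1:])):
        raise ValueError("layer radii must be strictly decreasing (outer to inner)")
    sp = np.broadcast_to(np.asarray(spacing, dtype=float), (3,)).copy()
    if np.any(sp <= 0):
        raise ValueError("spacing must be strictly positive")

    thicknesses = [a - b for a, b in zip(radii, radii[1:])]
    max_sp = float(sp.max())
    if thicknesses:
        skin_thickness = thicknesses[0]
        if max_sp > skin_thickness:
            # snap the skin shell to the nearest achievable (one-voxel) thickness
            achieved = max_sp
            radii[0] = radii[1] + achieved
            logger.info(
                "skin shell thickness snapped from %.2f mm to achievable %.2f mm "
                "(spacing %.2f mm)", skin_thickness, achieved, max_sp
            )
        for t, name in zip(thicknesses[1:], layer_tissues[1:]):
            if max_sp > t:
                raise ValueError(
                    f"spacing {max_sp:g} mm exceeds the {t:g} mm thickness of "
                    f"layer {name!r}; refine the grid or thicken the shell"
                )

    r_out = radii[0]
    nhalf = np.ceil((r_out + sp) / sp).astype(int)
    shape = tuple(2 * nhalf + 1)
    origin = tuple(-nhalf * sp)
    coords = [
        (np.arange(n) - h) * s for n, h, s in zip(shape, nhalf, sp)
    ]
    xx, yy, zz = np.meshgrid(*coords, indexing="ij")
    r = np.sqrt(xx * xx + yy * yy + zz * zz)

    data = np.zeros(shape, dtype=np.int32)
    labels: dict[int, str] = {}
    # innermost first so that outer shells do not overwrite inner ones
    for i in reversed(range(len(layer_tissues))):
        lab = i + 1
        layer = (r <= radii[i]) & (data == 0)
        data[layer] = lab
        labels[lab] = str(layer_tissues[i])

    if air_cavity is not None:
        (cx, cy, cz), cav_r = air_cavity
        if cav_r <= 0:
            raise ValueError("air cavity radius must be positive")
        rc = np.sqrt((xx - cx) ** 2 + (yy - cy) ** 2 + (zz - cz) ** 2)
        cav_lab = len(layer_tissues) + 1
        inside = (rc <= cav_r) & (data > 0)
        data[inside] = cav_lab
        labels[cav_lab] = "Air"

    return LabelVolume(data=data, spacing=tuple(sp), origin=origin, labels=labels)


def merge_with_priority(
    masks: Sequence[tuple[int, np.ndarray]],
    spacing: Sequence[float] = (1.0, 1.0, 1.0),
    origin: Sequence[float] = (0.0, 0.0, 0.0),
    labels: dict[int, str] | None = None,
) -> LabelVolume:
    """Merge binary per-tissue masks; on overlap the higher label wins.

    Voxels covered by no mask are 0 (exterior air).
    """
    if not masks:
        raise ValueError("no masks to merge")
    shape = np.asarray(masks[0][1]).shape
    out = np.zeros(shape, dtype=np.int32)
    for lab, m in sorted(masks, key=lambda lm: lm[0]):
        m = np.asarray(m, dtype=bool)
        if m.shape != shape:
            raise ValueError(f"mask for label {lab} has shape {m.shape}, expected {shape}")
        if lab <= 0:
            raise ValueError("mask labels must be positive integers")
        out[m] = lab
    lmap = labels or {int(lab): f"label_{int(lab)}" for lab, _ in masks}
    return LabelVolume(data=out, spacing=tuple(spacing), origin=tuple(origin), labels=lmap)


def supplant_unassigned(vol: LabelVolume, body_mask: np.ndarray) -> LabelVolume:
    """Assign every unlabeled in-body voxel to its nearest labeled tissue.

    Distance is Euclidean between voxel centers in mm.  Among equidistant
    donor labels the smallest label wins (deterministic tie-break).
    Already-labeled voxels are never changed.
    """
    body = np.asarray(body_mask, dtype=bool)
    if body.shape != vol.shape:
        raise ValueError("body mask shape does not match the volume")
    labeled = vol.data != 0
    if not labeled.any():
        raise ValueError("volume contains no labeled voxel to supplant from")
    if np.any(labeled & ~body):
        raise ValueError("body mask must contain every labeled voxel")

    holes = body & ~labeled
    out = vol.data.copy()
    if not holes.any():
        return LabelVolume(out, vol.spacing, vol.origin, dict(vol.labels))

    sampling = vol.spacing
    d_any = ndimage.distance_transform_edt(~labeled, sampling=sampling)
    assigned = ~holes
    # ascending label order => smallest label claims equidistant holes
    for lab in sorted(int(v) for v in np.unique(vol.data) if v != 0):
        d_lab = ndimage.distance_transform_edt(vol.data != lab, sampling=sampling)
        take = ~assigned & np.isclose(d_lab, d_any, rtol=1e-12, atol=1e-9)
        out[take] = lab
        assigned |= take
        if assigned.all():
            break
    return LabelVolume(out, vol.spacing, vol.origin, dict(vol.labels))


# --------------------------------------------------------------------------- resampling

def _lanczos_kernel(x: np.ndarray, a: int) -> np.ndarray:
    out = np.sinc(x) * np.sinc(x / a)
    out[np.abs(x) >= a] = 0.0
    return out


def _axis_weights(n_in: int, n_out: int, ratio: float, a: int) -> np.ndarray:
    """(n_out, n_in) row-normalized Lanczos-a weight matrix for one axis.

    Output sample j sits at input coordinate ``j * ratio``; taps outside the
    grid are dropped and the remaining weights renormalized (edge handling).
    """
    W = np.zeros((n_out, n_in))
    for j in range(n_out):
        x = j * ratio
        lo = max(0, int(math.ceil(x - a)))
        hi = min(n_in - 1, int(math.floor(x + a)))
        taps = np.arange(lo, hi + 1)
        w = _lanczos_kernel(x - taps, a)
        s = w.sum()
        if s == 0:
            W[j, int(round(min(max(x, 0), n_in - 1)))] = 1.0
        else:
            W[j, lo : hi + 1] = w / s
    return W


def resample_scalar(
    data: np.ndarray,
    spacing: Sequence[float],
    target_spacing: float | Sequence[float],
    a: int = 3,
) -> tuple[np.ndarray, tuple[float, ...]]:
    """Resample a scalar grid with a separable Lanczos-``a`` kernel.

    Returns the resampled array and the target spacing.  The physical extent
    is preserved within one voxel; at identical spacing the data are returned
    unchanged (interpolating kernel).
    """
    data = np.asarray(data, dtype=float)
    sp_in = np.broadcast_to(np.asarray(spacing, dtype=float), (data.ndim,))
    sp_out = np.broadcast_to(np.asarray(target_spacing, dtype=float), (data.ndim,)).copy()
    if np.any(sp_out <= 0) or np.any(sp_in <= 0):
        raise ValueError("spacing must be strictly positive")
    out = data
    for axis in range(data.ndim):
        ratio = sp_out[axis] / sp_in[axis]
        n_in = out.shape[axis]
        n_out = int(math.floor((n_in - 1) / ratio)) + 1
        W = _axis_weights(n_in, n_out, ratio, a)
        out = np.moveaxis(np.tensordot(W, np.moveaxis(out, axis, 0), axes=(1, 0)), 0, axis)
    return out, tuple(sp_out)


def _resample_nearest(data: np.ndarray, sp_in: np.ndarray, sp_out: np.ndarray) -> np.ndarray:
    idx = []
    for axis in range(data.ndim):
        ratio = sp_out[axis] / sp_in[axis]
        n_out = int(math.floor((data.shape[axis] - 1) / ratio)) + 1
        src = np.clip(np.rint(np.arange(n_out) * ratio).astype(int), 0, data.shape[axis] - 1)
        idx.append(src)
    return data[np.ix_(*idx)]


def resample_volume(
    vol: "LabelVolume | np.ndarray",
    target_spacing: float | Sequence[float],
    spacing: Sequence[float] | None = None,
):
    """Resample a volume to a new voxel size.

    Label volumes (``LabelVolume`` or integer arrays) are resampled with
    nearest-neighbor so labels stay integral; scalar arrays with the
    Lanczos-3 kernel.  For a raw array, ``spacing`` gives the current voxel
    size.  Returns a ``LabelVolume`` or ``(array, new_spacing)`` accordingly.
    """
    sp_t = np.atleast_1d(np.asarray(target_spacing, dtype=float))
    if np.any(sp_t <= 0):
        raise ValueError("target spacing must be strictly positive")
    if isinstance(vol, LabelVolume):
        sp_in = np.asarray(vol.spacing)
        sp_out = np.broadcast_to(sp_t, (3,))
        data = _resample_nearest(vol.data, sp_in, sp_out)
        return LabelVolume(data, tuple(sp_out), vol.origin, dict(vol.labels))
    data = np.asarray(vol)
    if spacing is None:
        spacing = (1.0,) * data.ndim
    sp_in = np.broadcast_to(np.asarray(spacing, dtype=float), (data.ndim,))
    sp_out = np.broadcast_to(sp_t, (data.ndim,))
    if np.issubdtype(data.dtype, np.integer) or data.dtype == bool:
        return _resample_nearest(data, sp_in, sp_out), tuple(sp_out)
    return resample_scalar(data, sp_in, sp_out)


# --------------------------------------------------------------------------- rater masks

def perturb_mask(
    mask: np.ndarray,
    mode: str,
    magnitude: int,
    seed: int = 0,
    flip_prob: float = 0.5,
) -> np.ndarray:
    """Perturb a binary mask to emulate inter-rater variability.

    Modes: ``dilate`` / ``erode`` apply ``magnitude`` exact repetitions of
    the 6-connected structuring element; ``boundary-noise`` flips voxels in
    the ``magnitude``-voxel band around the surface with probability
    ``flip_prob`` (seeded, bit-reproducible).
    """
    m = np.asarray(mask, dtype=bool)
    if magnitude < 0:
        raise ValueError("magnitude must be non-negative")
    if magnitude > max(m.shape):
        raise ValueError(f"magnitude {magnitude} exceeds mask extent {max(m.shape)}")
    if magnitude == 0:
        return m.copy()
    if mode == "dilate":
        return ndimage.binary_dilation(m, structure=_FACE_STRUCT, iterations=magnitude)
    if mode == "erode":
        out = ndimage.binary_erosion(m, structure=_FACE_STRUCT, iterations=magnitude)
        if m.any() and not out.any():
            raise ValueError(f"erosion by {magnitude} voxels annihilates the mask")
        return out
    if mode == "boundary-noise":
        inner = ndimage.binary_erosion(m, structure=_FACE_STRUCT, iterations=magnitude)
        outer = ndimage.binary_dilation(m, structure=_FACE_STRUCT, iterations=magnitude)
        band = outer & ~inner
        rng = np.random.default_rng(seed)
        flips = band & (rng.random(m.shape) < flip_prob)
        return m ^ flips
    raise ValueError(f"unknown perturbation mode {mode!r}")


def make_rater_set(
    gold: np.ndarray,
    tissue: str,
    spacing: Sequence[float],
    n_raters: int = 3,
    magnitude: int = 1,
    flip_prob: float = 0.3,
    seed: int = 0,
) -> RaterMaskSet:
    """Simulated multi-rater segmentations: boundary-noise copies of a gold mask."""
    seeds = np.random.SeedSequence(seed).generate_state(n_raters)
    raters = [
        (f"rater{i + 1}", perturb_mask(gold, "boundary-noise", magnitude,
                                       seed=int(seeds[i]), flip_prob=flip_prob))
        for i in range(n_raters)
    ]
    return RaterMaskSet(gold=np.asarray(gold, dtype=bool), raters=raters,
                        tissue=tissue, spacing=tuple(np.broadcast_to(np.asarray(spacing, float), (3,))))
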