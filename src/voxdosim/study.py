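"""End-to-end RF exposure study on synthetic phantoms.

Reproduces the shape of a 7 T head-coil dosimetry experiment: phantom ->
age-scaled tissue properties -> birdcage FDTD -> B1+ normalization to the
flip-angle target -> pointwise / head-average / 10 g SAR -> room-temperature
steady state -> 15 min exposure transient -> report, including the
cross-phantom percent-difference arithmetic used when comparing two models.

All physical defaults (297.2 MHz, 2 uT target, 23 C room, 6 / 10 W m^-2 C^-1
convective coefficients, 900 s scan) live in :data:`DEFAULT_CONFIG`, never in
the pipeline code; every reported number is recomputed from the stored
per-phantom results, and runs are deterministic under a fixed seed.
"""

from __future__ import annotations

import hashlib
import json
from contextlib import contextmanager
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from . import bioheat, em
from .phantom import default_head_radii, make_layered_head, DEFAULT_HEAD_TISSUES
from .tissues import BloodConstants, default_tissue_table, load_tissue_table
from .volume import LabelVolume

__all__ = ["DEFAULT_CONFIG", "run_exposure_study", "percent_difference",
           "line_profile", "load_config"]

DEFAULT_CONFIG: dict = {
    "schema_version": 1,
    "frequency_hz": 297.2e6,
    "target_b1_T": 2.0e-6,       # |B1+| amplitude at the coil center
    "spacing_mm": 4.0,
    "ambient_C": 23.0,
    "h_external": 6.0,           # W/(m^2 C)
    "h_internal": 10.0,          # W/(m^2 C)
    "blood_temperature_C": 37.0,
    "scan_duration_s": 900.0,
    "thermal_dt_s": 10.0,
    "seed": 0,
    "coil": {},                  # CoilModel overrides
    "fdtd": {},                  # FDTDSettings overrides
    "tissue_table": None,        # path; packaged table when None
    "phantoms": [
        {"name": "head_small", "outer_radius_mm": 70.0},
        {"name": "head_large", "outer_radius_mm": 80.0},
    ],
}


def load_config(path: str | Path | None = None, **overrides) -> dict:
    """Merge a YAML config file and keyword overrides over the defaults."""
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        cfg.update(user)
    cfg.update(overrides)
    return cfg


def percent_difference(reference: float, other: float,
                       ndigits: int | None = None) -> float:
    """Signed percent difference 100 * (other - reference) / reference.

    ``ndigits=0`` rounds to the nearest integer percent (report convention
    for SAR comparisons).
    """
    if reference == 0:
        raise ValueError("reference value must be nonzero")
    pct = 100.0 * (other - reference) / reference
    if ndigits is not None:
        pct = round(pct, ndigits)
        if ndigits == 0:
            pct = int(pct)
    return pct


def line_profile(map3d: np.ndarray, axis: int,
                 through_world_mm: Sequence[float],
                 spacing_mm: float | Sequence[float],
                 origin_mm: Sequence[float] = (0.0, 0.0, 0.0)) -> np.ndarray:
    """Values sampled along the grid line through a world point.

    The line runs along ``axis``; the other two indices are those of the
    voxel nearest to the given point, which must lie inside the grid.
    """
    sp = np.broadcast_to(np.asarray(spacing_mm, dtype=float), (3,))
    idx = np.rint((np.asarray(through_world_mm, dtype=float)
                   - np.asarray(origin_mm, dtype=float)) / sp).astype(int)
    if np.any(idx < 0) or np.any(idx >= np.asarray(map3d.shape)):
        raise ValueError(f"point {tuple(through_world_mm)} lies outside the grid")
    sl = [idx[0], idx[1], idx[2]]
    sl[axis] = slice(None)
    return np.asarray(map3d[tuple(sl)])


class StageError(RuntimeError):
    """A pipeline stage failed; carries phantom and stage identity."""

    def __init__(self, phantom: str, stage: str, cause: BaseException):
        super().__init__(f"[phantom {phantom!r}, stage {stage!r}] {cause}")
        self.phantom = phantom
        self.stage = stage


@contextmanager
def _stage(phantom: str, stage: str):
    try:
        yield
    except Exception as exc:
        raise StageError(phantom, stage, exc) from exc


def _sha(arr: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()[:16]


def _build_phantom(spec: dict, spacing: float) -> LabelVolume:
    if "nifti" in spec:
        return LabelVolume.from_nifti(spec["nifti"], spec.get("label_csv"))
    radii = spec.get("layer_radii") or default_head_radii(spec.get("outer_radius_mm", 80.0))
    tissues = spec.get("layer_tissues", list(DEFAULT_HEAD_TISSUES))
    cavity = spec.get("air_cavity")
    if cavity is not None:
        cavity = (tuple(cavity[0]), float(cavity[1]))
    return make_layered_head(radii, tissues, spacing=spacing, air_cavity=cavity)


def run_exposure_study(config: dict | str | Path | None = None,
                       outdir: str | Path | None = None) -> dict:
    """Run the full exposure pipeline for every configured phantom.

    Returns the study report as a plain dict (JSON-serializable); when
    ``outdir`` is given, writes ``report.json``, per-phantom NIfTI field/SAR/
    temperature maps and the B1+ line-profile CSVs there.
    """
    if config is None or isinstance(config, (str, Path)):
        cfg = load_config(config)
    else:
        cfg = load_config(None, **config)

    table = (default_tissue_table() if cfg["tissue_table"] is None
             else load_tissue_table(cfg["tissue_table"]))
    coil = em.CoilModel(frequency_hz=cfg["frequency_hz"], **cfg["coil"])
    settings = em.FDTDSettings(**cfg["fdtd"])
    boundary = bioheat.BoundarySpec(h_external=cfg["h_external"],
                                    h_internal=cfg["h_internal"],
                                    ambient=cfg["ambient_C"])
    blood = BloodConstants(temperature=cfg["blood_temperature_C"])

    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    report: dict = {
        "schema_version": cfg["schema_version"],
        "config": cfg,
        "seed": cfg["seed"],
        "phantoms": {},
        "comparisons": {},
    }

    for spec in cfg["phantoms"]:
        name = spec["name"]
        with _stage(name, "phantom"):
            phantom = _build_phantom(spec, cfg["spacing_mm"])
        stage_log = {"phantom_sha": _sha(phantom.data)}

        with _stage(name, "em_solve"):
            fields = em.fdtd_solve(phantom, table, coil, settings=settings)
        with _stage(name, "normalize"):
            fields, scale = em.normalize_fields(fields, cfg["target_b1_T"])
        stage_log["fields_sha"] = _sha(fields.E)

        eps_r, sigma, rho, tissue = em._material_maps(phantom, table)
        sl = fields.phantom_slices
        E_ph = fields.E[sl]
        with _stage(name, "pointwise_sar"):
            sar = em.pointwise_sar(E_ph, sigma, rho, tissue)
        with _stage(name, "mass_averaged_sar_10g"):
            sar10, max10 = em.mass_averaged_sar(sar, rho, phantom.spacing, tissue)
        head_avg = em.region_average_sar(sar, rho, tissue)
        stage_log["sar_sha"] = _sha(sar)

        with _stage(name, "thermal_steady_state"):
            equil = bioheat.steady_state(phantom, table, boundary, sar=None,
                                         blood=blood)
        with _stage(name, "thermal_transient"):
            run = bioheat.transient(phantom, table, equil, sar=sar,
                                    boundary=boundary, blood=blood,
                                    duration=cfg["scan_duration_s"],
                                    dt=cfg["thermal_dt_s"])
        tmax, tloc = bioheat.max_temperature(run, phantom)
        stage_log["temperature_sha"] = _sha(run.final.T)

        b1 = np.abs(em.b1_plus(fields))
        center = fields.coil_center_index
        profile = line_profile(
            b1, 0,
            np.asarray(fields.origin_mm) + np.asarray(center) * fields.spacing_mm,
            fields.spacing_mm, fields.origin_mm)

        report["phantoms"][name] = {
            "head_avg_sar_W_kg": head_avg,
            "max_10g_sar_W_kg": max10,
            "max_pointwise_sar_W_kg": float(sar.max()),
            "normalization_scale": scale,
            "b1_center_uT": float(b1[center] * 1e6),
            "b1_profile_uT": [float(v * 1e6) for v in profile],
            "equilibrium_max_C": round(float(np.nanmax(equil.T)), 2),
            "max_temperature_C": round(tmax, 2),
            "max_temperature_voxel_mm": [float(v) for v in tloc],
            "fdtd_periods": fields.convergence["periods"],
            "stage_hashes": stage_log,
        }

        if out is not None:
            phantom.to_nifti(out / f"{name}_labels.nii.gz", out / f"{name}_labels.csv")
            _save_map(out / f"{name}_sar.nii.gz", sar, phantom)
            _save_map(out / f"{name}_sar10g.nii.gz",
                      np.nan_to_num(sar10), phantom)
            _save_map(out / f"{name}_temperature.nii.gz",
                      np.nan_to_num(run.final.T, nan=cfg["ambient_C"]), phantom)
            np.savetxt(out / f"{name}_b1_profile_uT.csv",
                       np.column_stack([np.arange(profile.size), profile * 1e6]),
                       delimiter=",", header="index,b1_plus_uT", comments="")
            world = phantom.index_to_world(run.max_locations)
            np.savetxt(out / f"{name}_tmax_trace.csv",
                       np.column_stack([run.times, run.max_trace, world]),
                       delimiter=",", header="t_s,T_max_C,x_mm,y_mm,z_mm",
                       comments="")

    names = list(report["phantoms"])
    if len(names) >= 2:
        ref, oth = report["phantoms"][names[0]], report["phantoms"][names[1]]
        report["comparisons"] = {
            "reference": names[0],
            "other": names[1],
            "max_10g_sar_pct": percent_difference(
                ref["max_10g_sar_W_kg"], oth["max_10g_sar_W_kg"], ndigits=0),
            "head_avg_sar_pct": percent_difference(
                ref["head_avg_sar_W_kg"], oth["head_avg_sar_W_kg"], ndigits=0),
            "max_temperature_pct": percent_difference(
                ref["max_temperature_C"], oth["max_temperature_C"], ndigits=2),
        }

    if out is not None:
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
        with open(out / "report.txt", "w") as fh:
            fh.write(format_report(report))
    return report


def _save_map(path, arr, phantom: LabelVolume):
    import nibabel as nib
    affine = np.diag(list(phantom.spacing) + [1.0])
    affine[:3, 3] = phantom.origin
    nib.save(nib.Nifti1Image(np.asarray(arr, dtype=np.float32), affine), str(path))


def format_report(report: dict) -> str:
    lines = ["RF exposure study report", "=" * 32]
    for name, r in report["phantoms"].items():
        lines += [
            f"phantom: {name}",
            f"  head-average SAR   : {r['head_avg_sar_W_kg']:.3f} W/kg",
            f"  max 10 g SAR       : {r['max_10g_sar_W_kg']:.3f} W/kg",
            f"  B1+ at coil center : {r['b1_center_uT']:.3f} uT",
            f"  normalization scale: {r['normalization_scale']:.4g}",
            f"  max temperature    : {r['max_temperature_C']:.2f} C "
            f"(15 min scan, from {r['equilibrium_max_C']:.2f} C equilibrium)",
        ]
    cmp_ = report.get("comparisons")
    if cmp_:
        lines += [
            f"comparison ({cmp_['other']} vs {cmp_['reference']}):",
            f"  max 10 g SAR difference : {cmp_['max_10g_sar_pct']}%",
            f"  head-avg SAR difference : {cmp_['head_avg_sar_pct']}%",
            f"  max temperature diff    : {cmp_['max_temperature_pct']}%",
        ]
    return "\n".join(lines) + "\n"
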