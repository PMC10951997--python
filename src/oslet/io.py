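"""Disk formats: NRRD volumes (via SimpleITK), JSON plans, CSV readouts."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import SimpleITK as sitk

from .osl_model import OsldReadout
from .phantom import VoxelPhantom
from .planning import Plan, Prescription
from .scoring import CombinedMaps
from .transport import BeamField


def _write_nrrd(arr: np.ndarray, spacing, origin, path: Path) -> None:
    img = sitk.GetImageFromArray(np.ascontiguousarray(arr.T))  # (x,y,z) -> (z,y,x)
    img.SetSpacing(tuple(float(s) for s in spacing))
    img.SetOrigin(tuple(float(o) for o in origin))
    sitk.WriteImage(img, str(path))


def _read_nrrd(path: Path):
    img = sitk.ReadImage(str(path))
    arr = sitk.GetArrayFromImage(img).T
    return arr, np.array(img.GetSpacing()), np.array(img.GetOrigin())


def save_phantom(phantom: VoxelPhantom, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _write_nrrd(phantom.density.astype(np.float32), phantom.spacing, phantom.origin,
                out / "density.nrrd")
    for name, mask in phantom.masks.items():
        _write_nrrd(mask.astype(np.uint8), phantom.spacing, phantom.origin,
                    out / f"mask_{name}.nrrd")
    meta = {}
    if phantom.osld_layout is not None:
        lay = phantom.osld_layout
        meta["osld_layout"] = {"centers": lay.centers.tolist(),
                               "disk_radius_mm": lay.disk_radius_mm,
                               "slice_index": lay.slice_index}
    (out / "meta.json").write_text(json.dumps(meta, indent=2))


def load_phantom(in_dir: str | Path) -> VoxelPhantom:
    src = Path(in_dir)
    density, spacing, origin = _read_nrrd(src / "density.nrrd")
    masks = {}
    for p in sorted(src.glob("mask_*.nrrd")):
        arr, _, _ = _read_nrrd(p)
        masks[p.stem[len("mask_"):]] = arr.astype(bool)
    ph = VoxelPhantom(spacing=spacing, origin=origin,
                      density=density.astype(np.float32), masks=masks)
    meta = json.loads((src / "meta.json").read_text()) if (src / "meta.json").exists() else {}
    if "osld_layout" in meta:
        from .phantom import OsldLayout, _attach_area_weights

        lay = OsldLayout(centers=np.array(meta["osld_layout"]["centers"]),
                         disk_radius_mm=meta["osld_layout"]["disk_radius_mm"],
                         slice_index=meta["osld_layout"]["slice_index"])
        _attach_area_weights(ph, lay)
        ph.osld_layout = lay
    return ph


def save_maps(maps: CombinedMaps, phantom: VoxelPhantom, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _write_nrrd(maps.dose.astype(np.float32), phantom.spacing, phantom.origin,
                out / "dose.nrrd")
    _write_nrrd(maps.let_d.astype(np.float32), phantom.spacing, phantom.origin,
                out / "let_d.nrrd")
    for f in maps.per_field:
        _write_nrrd(f.dose.astype(np.float32), phantom.spacing, phantom.origin,
                    out / f"dose_field{f.field_id}.nrrd")
        _write_nrrd(f.let_d.astype(np.float32), phantom.spacing, phantom.origin,
                    out / f"let_d_field{f.field_id}.nrrd")


def save_plan(plan: Plan, path: str | Path) -> None:
    doc = {
        "prescription": {"rbe_dose": plan.prescription.rbe_dose,
                         "rbe_factor": plan.prescription.rbe_factor},
        "provenance": plan.provenance,
        "grid_shape": list(plan.grid_shape),
        "robustness": plan.robustness,
        "fields": [
            {
                "gantry_angle_deg": f.gantry_angle_deg,
                "iso_center_mm": f.iso_center.tolist(),
                "field_id": f.field_id,
                "spots": [
                    {"energy_mev": float(e), "u_mm": float(u), "v_mm": float(v),
                     "weight": float(w), "sigma_mm": float(s)}
                    for e, u, v, w, s in zip(f.spot_energy, f.spot_u, f.spot_v,
                                             f.spot_weight, f.spot_sigma)
                ],
            }
            for f in plan.fields
        ],
    }
    Path(path).write_text(json.dumps(doc))


def load_plan(path: str | Path) -> Plan:
    doc = json.loads(Path(path).read_text())
    fields = []
    for fd in doc["fields"]:
        spots = fd["spots"]
        fields.append(BeamField(
            fd["gantry_angle_deg"], np.array(fd["iso_center_mm"]),
            spot_energy=[s["energy_mev"] for s in spots],
            spot_u=[s["u_mm"] for s in spots],
            spot_v=[s["v_mm"] for s in spots],
            spot_weight=[s["weight"] for s in spots],
            spot_sigma=[s["sigma_mm"] for s in spots],
            field_id=fd["field_id"],
        ))
    return Plan(fields=fields,
                prescription=Prescription(**doc["prescription"]),
                provenance=doc["provenance"], grid_shape=tuple(doc["grid_shape"]),
                robustness=doc["robustness"])


def readouts_to_csv(readouts: list[OsldReadout], path: str | Path) -> None:
    pd.DataFrame([{"detector_id": r.detector_id, "blue": r.blue, "uv": r.uv,
                   "ref_blue": r.ref_blue, "ref_dose": r.ref_dose}
                  for r in readouts]).to_csv(path, index=False)


def readouts_from_csv(path: str | Path) -> list[OsldReadout]:
    df = pd.read_csv(path)
    return [OsldReadout(str(r.detector_id), float(r.blue), float(r.uv),
                        float(r.ref_blue), float(r.ref_dose))
            for r in df.itertuples()]


def steplog_to_csv(log, path: str | Path) -> None:
    """Persist per-step records as a flat columnar table (one row per step)."""
    nx, ny, nz = log.grid_shape
    vz = log.vox % nz
    vy = (log.vox // nz) % ny
    vx = log.vox // (ny * nz)
    pd.DataFrame({
        "history_id": log.history, "field_id": log.field_id,
        "spot_id": log.spot[log.history],
        "vx": vx, "vy": vy, "vz": vz,
        "dE_MeV": log.dE, "dx_cm": log.dx,
    }).to_csv(path, index=False)


def steplog_from_csv(path: str | Path, grid_shape, total_weight: float):
    from .transport import StepLog

    df = pd.read_csv(path)
    nx, ny, nz = grid_shape
    hist = df["history_id"].to_numpy(np.int32)
    n_hist = int(hist.max()) + 1 if len(hist) else 0
    spot = np.zeros(n_hist, dtype=np.int32)
    spot[hist] = df["spot_id"].to_numpy(np.int32)
    vox = (df["vx"].to_numpy(np.int64) * ny + df["vy"].to_numpy(np.int64)) * nz \
        + df["vz"].to_numpy(np.int64)
    dE = df["dE_MeV"].to_numpy(np.float32)
    e0 = np.zeros(n_hist)
    np.add.at(e0, hist, dE.astype(np.float64))
    return StepLog(field_id=int(df["field_id"].iloc[0]) if len(df) else 0,
                   history=hist, vox=vox.astype(np.int32), dE=dE,
                   dx=df["dx_cm"].to_numpy(np.float32), spot=spot,
                   e0=e0, e_exit=np.zeros(n_hist),
                   total_weight=total_weight, grid_shape=tuple(grid_shape))
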