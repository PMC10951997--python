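"""Dose and dose-averaged LET scoring from per-step energy-deposition records.

Per field F and voxel v the scorer evaluates

    LET_D^F(v) = (rho_water / rho_v) * sum_steps dE * (dE/dx) / sum_steps dE

with dE/dx the step-wise quotient of each record, reported water-referred in
keV/um (1 MeV/cm = 0.1 keV/um), and the physical dose

    D_F(v) = sum_steps dE * 1.602e-10 / (rho_v * V_voxel)   [Gy]

Fields combine dose-weighted:

    LET_D(v) = sum_F LET_D^F(v) * D_F(v) / sum_F D_F(v)

which is algebraically identical to scoring the pooled step records in one
pass -- the central correctness theorem of this module, exercised by the test
suite.  LET_D is NaN (undefined, never zero) wherever no dose was scored;
display cutoffs are a plotting concern only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .phantom import VoxelPhantom
from .transport import GY_PER_MEV_PER_G, MEV_PER_CM_TO_KEV_PER_UM, StepLog

RHO_WATER = 1.0  # g/cm3


@dataclass
class FieldMaps:
    """Per-voxel dose (Gy) and water-referred LET_D (keV/um) for one field."""

    dose: np.ndarray
    let_d: np.ndarray  # NaN where dose == 0
    n_histories: int
    field_id: int = 0
    rel_uncertainty: np.ndarray | None = None

    @property
    def shape(self):
        return self.dose.shape


@dataclass
class CombinedMaps:
    dose: np.ndarray
    let_d: np.ndarray
    per_field: list = field(default_factory=list)


@dataclass
class RoiStats:
    mean: float
    sd: float
    center_of_mass_mm: np.ndarray
    n_voxels: int


def _per_proton_scale(steplog: StepLog) -> float:
    return steplog.total_weight / max(steplog.n_histories, 1)


def _maps_from_sums(sum_dE, sum_dE2dx, phantom: VoxelPhantom, protons_per_history: float,
                    n_histories: int, field_id: int = 0) -> FieldMaps:
    shape = phantom.shape
    rho = np.asarray(phantom.density, dtype=np.float64)
    vol = phantom.voxel_volume_cm3
    sum_dE = sum_dE.reshape(shape)
    sum_dE2dx = sum_dE2dx.reshape(shape)

    with np.errstate(divide="ignore", invalid="ignore"):
        dose = sum_dE * protons_per_history * GY_PER_MEV_PER_G / (rho * vol)
        let = np.where(sum_dE > 0, sum_dE2dx / np.where(sum_dE > 0, sum_dE, 1.0), np.nan)
        let = let * (RHO_WATER / np.where(rho > 0, rho, np.nan)) * MEV_PER_CM_TO_KEV_PER_UM
    dose = np.where(rho > 0, dose, np.nan)  # zero-density voxel receiving dose: undefined
    return FieldMaps(dose=dose, let_d=let, n_histories=n_histories, field_id=field_id)


def score_field(steplog: StepLog, phantom: VoxelPhantom) -> FieldMaps:
    """Score one field's StepLog into dose and LET_D maps."""
    if steplog.n_steps == 0:
        raise ValueError("empty StepLog")
    nvox = int(np.prod(phantom.shape))
    if steplog.vox.max() >= nvox or steplog.vox.min() < 0:
        raise ValueError("StepLog voxel indices outside the phantom grid")
    dE = steplog.dE.astype(np.float64)
    sum_dE = np.bincount(steplog.vox, weights=dE, minlength=nvox)
    sum_dE2dx = np.bincount(steplog.vox, weights=dE * dE / steplog.dx.astype(np.float64),
                            minlength=nvox)
    return _maps_from_sums(sum_dE, sum_dE2dx, phantom, _per_proton_scale(steplog),
                           steplog.n_histories, steplog.field_id)


def score_from_accumulators(acc: dict, phantom: VoxelPhantom, total_weight: float,
                            n_histories: int, field_id: int = 0,
                            n_for_uncertainty: bool = True) -> FieldMaps:
    """Score directly from the transport kernel's per-voxel accumulators
    (identical result to score_field on the recorded StepLog)."""
    maps = _maps_from_sums(acc["sum_dE"], acc["sum_dE2_dx"], phantom,
                           total_weight / max(n_histories, 1), n_histories, field_id)
    if n_for_uncertainty and "batch_dE" in acc:
        maps.rel_uncertainty = _rel_uncertainty_from_batches(acc["batch_dE"], phantom)
    return maps


def _rel_uncertainty_from_batches(batch_dE: np.ndarray, phantom: VoxelPhantom) -> np.ndarray:
    B = batch_dE.shape[0]
    mean = batch_dE.mean(axis=0)
    sd = batch_dE.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.where(mean > 0, sd / np.sqrt(B) / np.where(mean > 0, mean, 1.0), np.nan)
    return rel.reshape(phantom.shape)


def combine_fields(fields: list[FieldMaps]) -> CombinedMaps:
    """Dose-weighted combination of per-field LET_D maps."""
    if not fields:
        raise ValueError("no fields to combine")
    shape = fields[0].shape
    for f in fields:
        if f.shape != shape:
            raise ValueError("field maps live on different grids")
    dose = np.zeros(shape)
    num = np.zeros(shape)
    for f in fields:
        d = np.nan_to_num(f.dose, nan=0.0)
        dose += d
        num += np.where(d > 0, np.nan_to_num(f.let_d, nan=0.0) * d, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        let = np.where(dose > 0, num / np.where(dose > 0, dose, 1.0), np.nan)
    return CombinedMaps(dose=dose, let_d=let, per_field=list(fields))


def estimate_uncertainty(steplog: StepLog, phantom: VoxelPhantom, n_batches: int,
                         mask: np.ndarray | None = None):
    """History-batch statistical uncertainty of the per-voxel mean dose.

    Histories are assigned round-robin to ``n_batches`` batches; the per-voxel
    relative standard error of the mean dose is returned, together with its
    mean over ``mask`` (the transport stopping criterion, threshold 1% over
    the target by default) when a mask is given.
    """
    if n_batches < 5:
        raise ValueError("need at least 5 batches")
    if steplog.n_histories < n_batches:
        raise ValueError("fewer histories than batches")
    nvox = int(np.prod(phantom.shape))
    batch_of_step = (steplog.history % n_batches).astype(np.int64)
    flat = batch_of_step * nvox + steplog.vox.astype(np.int64)
    batch_dE = np.bincount(flat, weights=steplog.dE.astype(np.float64),
                           minlength=n_batches * nvox).reshape(n_batches, nvox)
    rel = _rel_uncertainty_from_batches(batch_dE, phantom)
    if mask is None:
        return rel, None
    vals = rel[mask]
    vals = vals[np.isfinite(vals)]
    return rel, float(vals.mean()) if vals.size else float("nan")


def roi_statistics(values: np.ndarray, mask: np.ndarray, phantom: VoxelPhantom) -> RoiStats:
    """Unweighted mean and population SD (k=1) of voxel values inside a mask,
    plus the mask's center of mass in world mm."""
    if not mask.any():
        raise ValueError("empty ROI mask")
    vals = np.asarray(values, dtype=float)[mask]
    finite = vals[np.isfinite(vals)]
    idx = np.argwhere(mask)
    com = phantom.world_coords(idx.mean(axis=0))
    return RoiStats(mean=float(finite.mean()), sd=float(finite.std(ddof=0)),
                    center_of_mass_mm=com, n_voxels=int(mask.sum()))


def total_deposited_energy_mev(maps: FieldMaps | CombinedMaps, phantom: VoxelPhantom) -> float:
    """Invert the dose map back to total scored energy (bookkeeping checks)."""
    rho = np.asarray(phantom.density, dtype=np.float64)
    d = np.nan_to_num(maps.dose, nan=0.0)
    return float((d * rho * phantom.voxel_volume_cm3).sum() / GY_PER_MEV_PER_G)
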