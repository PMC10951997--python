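"""Three-field IMPT planning: spot placement, weight optimization, delivery.

The reference plan mirrors a clinical spot-scanning plan at desk scale: a
lateral spot grid covers the PTV's beam's-eye-view projection, energy layers
span the PTV's water-equivalent depth extent widened by the range-robustness
margin, and spot weights are found by non-negative least squares driving a
uniform physical dose over the PTV.  The influence matrix used for
optimization comes from an analytic pencil kernel (Bragg-Kleeman depth dose
with Gauss-Hermite range-straggling smear and Fermi-Eyges lateral spread);
delivered dose and LET_D are always re-computed with the Monte Carlo
transport, mirroring the analytic-plan / MC-recompute split of daily
adaptive workflows.

Delivery modes:

* ``NA``   -- the reference plan's spots are transported through the daily
             phantom unchanged;
* ``DAPT`` -- spot placement and weight optimization are re-run on the daily
             geometry (same objectives), then transported.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass

import numpy as np
from numba import njit

from .phantom import VoxelPhantom
from .scoring import CombinedMaps, FieldMaps, combine_fields, score_from_accumulators
from .transport import (
    PROTON_MASS_MEV,
    BeamField,
    StoppingModel,
    csda_range,
    energy_from_range,
    transport_field,
)

logger = logging.getLogger(__name__)

DEFAULT_GANTRY_ANGLES = (-20.0, 0.0, 20.0)


@dataclass
class Prescription:
    """Per-fraction prescription; physical dose = RBE dose / RBE factor."""

    rbe_dose: float = 2.0  # Gy(RBE)
    rbe_factor: float = 1.1

    def __post_init__(self):
        if self.rbe_factor <= 0:
            raise ValueError("RBE factor must be positive")

    @property
    def physical_dose(self) -> float:
        return self.rbe_dose / self.rbe_factor


@dataclass
class SpotPlacementConfig:
    lateral_pitch_mm: float = 4.0
    lateral_margin_mm: float = 4.0
    layer_pitch_we_mm: float = 4.0
    spot_sigma_mm: float = 4.0


@dataclass
class Plan:
    fields: list[BeamField]
    prescription: Prescription
    provenance: str  # hash of the phantom the plan was optimized on
    grid_shape: tuple[int, int, int]
    robustness: float = 0.03

    @property
    def n_spots(self) -> int:
        return sum(f.n_spots for f in self.fields)


def phantom_fingerprint(phantom: VoxelPhantom) -> str:
    h = hashlib.sha1()
    h.update(np.ascontiguousarray(phantom.density).tobytes())
    return h.hexdigest()[:16]


# ---------------------------------------------------------------------------
# WEPL coordinates of voxels in a field's beam's-eye view


@njit(cache=True)
def _wepl_points_kernel(density, sp, o, nx, ny, nz, pts, d, out):
    for n in range(pts.shape[0]):
        px, py, pz = pts[n, 0], pts[n, 1], pts[n, 2]
        # start well upstream of the grid along -d
        sx, sy, sz = px - 400.0 * d[0], py - 400.0 * d[1], pz - 400.0 * d[2]
        tlo = -1e30
        thi = 1e30
        miss = False
        for a in range(3):
            pa = (sx, sy, sz)[a]
            gmin = o[a] - 0.5 * sp[a]
            gmax = o[a] + ((nx, ny, nz)[a] - 0.5) * sp[a]
            if abs(d[a]) > 1e-12:
                t1 = (gmin - pa) / d[a]
                t2 = (gmax - pa) / d[a]
                if t1 > t2:
                    t1, t2 = t2, t1
                if t1 > tlo:
                    tlo = t1
                if t2 < thi:
                    thi = t2
            elif pa < gmin or pa > gmax:
                miss = True
        if miss or thi <= tlo:
            out[n] = 0.0
            continue
        t = max(tlo, 0.0) + 1e-6
        t_stop = 400.0  # the target point sits exactly 400 mm downstream
        x, y, z = sx + d[0] * t, sy + d[1] * t, sz + d[2] * t
        total = 0.0
        while t < t_stop:
            i = int(np.floor((x - o[0]) / sp[0] + 0.5))
            j = int(np.floor((y - o[1]) / sp[1] + 0.5))
            k = int(np.floor((z - o[2]) / sp[2] + 0.5))
            if i < 0 or i >= nx or j < 0 or j >= ny or k < 0 or k >= nz:
                break
            t_exit = 1e30
            for a in range(3):
                if abs(d[a]) > 1e-12:
                    if d[a] > 0:
                        b = o[a] + (((i, j, k)[a]) + 0.5) * sp[a]
                    else:
                        b = o[a] + (((i, j, k)[a]) - 0.5) * sp[a]
                    tb = (b - (x, y, z)[a]) / d[a]
                    if tb < t_exit:
                        t_exit = tb
            s = max(t_exit, 0.0) + 1e-6
            if t + s > t_stop:
                s = t_stop - t
            total += density[i, j, k] * s * 0.1
            x += d[0] * s
            y += d[1] * s
            z += d[2] * s
            t += s
        out[n] = total


def beam_eye_coordinates(phantom: VoxelPhantom, mask: np.ndarray, gantry_angle: float,
                         iso_center: np.ndarray):
    """(u, v, wepl_cm) of each masked voxel in the field's beam's-eye view."""
    probe = BeamField(gantry_angle, iso_center)
    d = probe.direction()
    uax, vax = probe.lateral_axes()
    idx = np.argwhere(mask)
    pts = phantom.world_coords(idx)
    rel = pts - iso_center
    u = rel @ uax
    v = rel @ vax
    out = np.empty(len(pts))
    nx, ny, nz = phantom.shape
    _wepl_points_kernel(np.ascontiguousarray(phantom.density, dtype=np.float64),
                        phantom.spacing, phantom.origin, nx, ny, nz,
                        np.ascontiguousarray(pts, dtype=np.float64), d, out)
    return idx, u, v, out


def place_spots(phantom: VoxelPhantom, ptv_mask: np.ndarray, gantry_angle: float,
                robustness: float = 0.03, config: SpotPlacementConfig | None = None,
                model: StoppingModel | None = None, field_id: int = 0) -> BeamField:
    """Lay out spots for one field covering the PTV with a range margin."""
    cfg = config or SpotPlacementConfig()
    model = model or StoppingModel()
    if not ptv_mask.any():
        raise ValueError("empty PTV mask")
    iso = phantom.world_coords(np.argwhere(ptv_mask).mean(axis=0))
    _, u, v, w = beam_eye_coordinates(phantom, ptv_mask, gantry_angle, iso)

    pitch = cfg.lateral_pitch_mm
    margin = cfg.lateral_margin_mm
    us = np.arange(u.min() - margin, u.max() + margin + pitch / 2, pitch)
    vs = np.arange(v.min() - margin, v.max() + margin + pitch / 2, pitch)
    layer_pitch_cm = cfg.layer_pitch_we_mm * 0.1

    r_max_model = float(csda_range(250.0, model=model))
    energies, uu, vv = [], [], []
    for su in us:
        for sv in vs:
            near = (np.abs(u - su) <= pitch) & (np.abs(v - sv) <= pitch)
            if not near.any():
                near = (np.abs(u - su) <= 1.5 * pitch) & (np.abs(v - sv) <= 1.5 * pitch)
                if not near.any():
                    continue
            w_lo = (1.0 - robustness) * w[near].min()
            w_hi = (1.0 + robustness) * w[near].max()
            if w_lo > r_max_model:
                raise ValueError("PTV deeper than the maximum beam range")
            n_layers = max(int(np.ceil((w_hi - w_lo) / layer_pitch_cm)), 1)
            for r in w_lo + layer_pitch_cm * np.arange(n_layers + 1):
                e = float(energy_from_range(r, model=model))
                if e < 3.0:
                    continue
                if e > 250.0:
                    raise ValueError("PTV deeper than the maximum beam range")
                energies.append(e)
                uu.append(su)
                vv.append(sv)
    n = len(energies)
    return BeamField(gantry_angle, iso,
                     spot_energy=np.array(energies), spot_u=np.array(uu), spot_v=np.array(vv),
                     spot_weight=np.ones(n), spot_sigma=np.full(n, cfg.spot_sigma_mm),
                     field_id=field_id)


# ---------------------------------------------------------------------------
# Analytic pencil-beam influence


def _fermi_eyges_sigma_table(energy: float, model: StoppingModel, n: int = 120):
    """Lateral MCS spread sigma(z) (cm) in water for a proton of this energy,
    from the same Highland scattering power the transport kernel uses."""
    R = float(csda_range(energy, model=model))
    z = np.linspace(0.0, R * 0.999, n)
    rres = R - z
    E = energy_from_range(np.maximum(rres, 1e-6), model=model)
    pv = E * (E + 2 * PROTON_MASS_MEV) / (E + PROTON_MASS_MEV)
    T = (model.ms_constant / pv) ** 2 / model.x0_water_cm  # d<theta^2>/dz
    sig2 = np.empty(n)
    for i in range(n):
        sig2[i] = np.trapezoid((z[i] - z[: i + 1]) ** 2 * T[: i + 1], z[: i + 1]) if i else 0.0
    return z, np.sqrt(sig2)


_GH_NODES, _GH_WEIGHTS = np.polynomial.hermite_e.hermegauss(8)
_GH_WEIGHTS = _GH_WEIGHTS / _GH_WEIGHTS.sum()


def _bragg_depth_dose(wepl_cm: np.ndarray, range_cm: float, model: StoppingModel,
                      voxel_we_cm: float = 0.2) -> np.ndarray:
    """Straggling-smeared depth dose averaged over the voxel's water-equivalent
    thickness, MeV/cm per proton.  The voxel average is exact: the mean of
    S(E(z)) over [z-h/2, z+h/2] is the energy lost across the slab divided by
    h, which keeps the sharp Bragg peak honest on a coarse grid."""
    out = np.zeros_like(wepl_cm, dtype=float)
    sig_r = model.straggling_fraction * range_cm
    h = voxel_we_cm

    def _energy(rres):
        return np.where(rres > 0, energy_from_range(np.maximum(rres, 0.0), model=model), 0.0)

    for x, gw in zip(_GH_NODES, _GH_WEIGHTS):
        rres = (range_cm + sig_r * x) - wepl_cm
        out += gw * (_energy(rres + h / 2) - _energy(rres - h / 2)) / h
    return out


def influence_matrix(phantom: VoxelPhantom, beams: list[BeamField], ptv_mask: np.ndarray,
                     model: StoppingModel | None = None) -> np.ndarray:
    """Analytic dose (Gy) per unit spot weight at each PTV voxel.

    Columns are ordered field by field, following each field's spot order.
    """
    model = model or StoppingModel()
    n_vox = int(ptv_mask.sum())
    cols = []
    from .transport import GY_PER_MEV_PER_G

    for beam in beams:
        _, u, v, w = beam_eye_coordinates(phantom, ptv_mask, beam.gantry_angle_deg,
                                          beam.iso_center)
        d = beam.direction()
        # voxel crossing length along the beam, water-equivalent (soft tissue)
        voxel_we = 0.1 * float(np.min(phantom.spacing / np.maximum(np.abs(d), 1e-6)))
        sig_tables = {}
        for e in np.unique(beam.spot_energy):
            sig_tables[float(e)] = _fermi_eyges_sigma_table(float(e), model)
        A_f = np.zeros((n_vox, beam.n_spots))
        for s in range(beam.n_spots):
            e = float(beam.spot_energy[s])
            R = float(csda_range(e, model=model))
            zt, st = sig_tables[e]
            sig_mcs_cm = np.interp(np.clip(w, 0, zt[-1]), zt, st)
            sig_cm = np.sqrt((beam.spot_sigma[s] * 0.1) ** 2 + sig_mcs_cm**2)
            du = (u - beam.spot_u[s]) * 0.1
            dv = (v - beam.spot_v[s]) * 0.1
            r2 = du**2 + dv**2
            lateral_ok = r2 < (4.0 * sig_cm) ** 2
            depth_ok = w < R * (1 + 5 * model.straggling_fraction)
            sel = lateral_ok & depth_ok
            if not sel.any():
                continue
            gauss = np.exp(-r2[sel] / (2 * sig_cm[sel] ** 2)) / (2 * np.pi * sig_cm[sel] ** 2)
            depth = _bragg_depth_dose(w[sel], R, model, voxel_we)
            A_f[sel, s] = depth * gauss * GY_PER_MEV_PER_G
        cols.append(A_f)
    return np.hstack(cols)


def optimize_weights(influence: np.ndarray, prescription: Prescription,
                     max_iter: int = 4000, tol: float = 1e-12) -> np.ndarray:
    """Non-negative least squares for a uniform PTV physical dose.

    Minimizes sum_v (sum_s A_vs w_s - D_phys)^2 subject to w >= 0 with an
    accelerated projected-gradient (FISTA) iteration on the normal equations;
    stops when the objective stagnates to relative ``tol``.
    """
    A = np.asarray(influence, dtype=float)
    active = A.any(axis=0)
    if not active.all():
        logger.warning("dropping %d spots with an all-zero influence column",
                       int((~active).sum()))
    b = np.full(A.shape[0], prescription.physical_dose)
    w = np.zeros(A.shape[1])
    if not active.any():
        return w
    Aa = A[:, active]
    AtA = Aa.T @ Aa
    Atb = Aa.T @ b
    v = np.ones(AtA.shape[0])
    for _ in range(60):  # power iteration for the Lipschitz constant
        v = AtA @ v
        n = np.linalg.norm(v)
        if n == 0.0 or not np.isfinite(n):
            break
        v /= n
    L = float(v @ (AtA @ v)) * 1.01
    if L <= 0.0 or not np.isfinite(L):
        logger.warning("influence matrix is numerically zero; returning zero weights")
        return w
    x = np.zeros(AtA.shape[0])
    y = x.copy()
    t = 1.0
    obj_prev = np.inf
    for k in range(max_iter):
        g = AtA @ y - Atb
        xn = np.maximum(y - g / L, 0.0)
        tn = (1.0 + np.sqrt(1.0 + 4.0 * t * t)) / 2.0
        y = xn + (t - 1.0) / tn * (xn - x)
        x, t = xn, tn
        if k % 100 == 99:
            obj = float(x @ (AtA @ x)) / 2.0 - float(Atb @ x)
            if obj_prev - obj < tol * max(abs(obj), 1.0):
                break
            obj_prev = obj
    # KKT polish: re-solve unconstrained on the active support; keep it only
    # if it stays feasible and does not worsen the objective
    support = x > 1e-12 * max(x.max(), 1.0)
    if 0 < support.sum() < A.shape[0]:
        sol, *_ = np.linalg.lstsq(Aa[:, support], b, rcond=None)
        if sol.min() >= 0.0:
            x_pol = np.zeros_like(x)
            x_pol[support] = sol
            obj_x = float(x @ (AtA @ x)) / 2.0 - float(Atb @ x)
            obj_p = float(x_pol @ (AtA @ x_pol)) / 2.0 - float(Atb @ x_pol)
            if obj_p <= obj_x:
                x = x_pol
    w[active] = x
    return w


def make_reference_plan(phantom: VoxelPhantom, prescription: Prescription | None = None,
                        gantry_angles=DEFAULT_GANTRY_ANGLES, robustness: float = 0.03,
                        config: SpotPlacementConfig | None = None,
                        model: StoppingModel | None = None) -> Plan:
    """Place spots for all fields on the reference phantom and optimize."""
    prescription = prescription or Prescription()
    ptv = phantom.masks["ptv"]
    beams = [place_spots(phantom, ptv, ang, robustness, config, model, field_id=i)
             for i, ang in enumerate(gantry_angles)]
    A = influence_matrix(phantom, beams, ptv, model)
    w = optimize_weights(A, prescription)
    off = 0
    for beam in beams:
        beam.spot_weight = w[off:off + beam.n_spots]
        off += beam.n_spots
    return Plan(fields=beams, prescription=prescription,
                provenance=phantom_fingerprint(phantom), grid_shape=phantom.shape,
                robustness=robustness)


def make_daily_plan(plan: Plan, daily_phantom: VoxelPhantom,
                    model: StoppingModel | None = None) -> Plan:
    """Re-optimize the reference plan's objectives on the daily geometry."""
    return make_reference_plan(daily_phantom, plan.prescription,
                               [f.gantry_angle_deg for f in plan.fields],
                               plan.robustness, model=model)


def deliver_fraction(plan: Plan, daily_phantom: VoxelPhantom, mode: str,
                     n_histories: int, seed: int, model: StoppingModel | None = None,
                     uncertainty_target: float | None = 0.01,
                     n_rounds: int = 8, daily_plan: Plan | None = None) -> CombinedMaps:
    """Deliver one fraction to the daily phantom and score dose + LET_D.

    ``n_histories`` is the per-field cap; transport runs in rounds and stops
    early once the mean relative statistical uncertainty of the combined dose
    over the daily PTV drops below ``uncertainty_target`` (the 1% target rule).
    For DAPT a precomputed ``daily_plan`` may be passed (re-optimization is
    deterministic, so it can be shared across replicate deliveries).
    """
    model = model or StoppingModel()
    if mode not in ("NA", "DAPT"):
        raise ValueError("mode must be 'NA' or 'DAPT'")
    if mode == "NA":
        if daily_phantom.shape != plan.grid_shape:
            raise ValueError("NA delivery requires the plan's grid")
        beams = plan.fields
    else:
        beams = (daily_plan or make_daily_plan(plan, daily_phantom, model)).fields

    rng = np.random.SeedSequence(seed)
    field_seeds = rng.generate_state(len(beams) * n_rounds, dtype=np.uint32) & 0x7FFFFFFF
    ptv = daily_phantom.masks["ptv"]
    nvox = int(np.prod(daily_phantom.shape))
    n_round = max(n_histories // n_rounds, 1)
    accs = [{"sum_dE": np.zeros(nvox), "sum_dE2_dx": np.zeros(nvox),
             "batch_dE": np.zeros((8, nvox))} for _ in beams]
    n_used = [0] * len(beams)
    for r in range(n_rounds):
        for fi, beam in enumerate(beams):
            _, acc = transport_field(daily_phantom, beam, n_round,
                                     int(field_seeds[r * len(beams) + fi]),
                                     model=model, record_steps=False)
            accs[fi]["sum_dE"] += acc["sum_dE"]
            accs[fi]["sum_dE2_dx"] += acc["sum_dE2_dx"]
            accs[fi]["batch_dE"] += acc["batch_dE"]
            n_used[fi] += n_round
        if uncertainty_target is not None:
            total_batch = sum(
                a["batch_dE"] * (b.spot_weight.sum() / n) for a, b, n in zip(accs, beams, n_used)
            )
            mean = total_batch.mean(axis=0)
            sd = total_batch.std(axis=0, ddof=1) / np.sqrt(total_batch.shape[0])
            sel = ptv.reshape(-1) & (mean > 0)
            if sel.any() and float((sd[sel] / mean[sel]).mean()) < uncertainty_target:
                break

    fields_maps: list[FieldMaps] = []
    for fi, beam in enumerate(beams):
        fm = score_from_accumulators(accs[fi], daily_phantom, beam.spot_weight.sum(),
                                     n_used[fi], field_id=beam.field_id)
        fields_maps.append(fm)
    return combine_fields(fields_maps)
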