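"""Forward model of the Al2O3:C OSL detector two-band response.

A readout consists of the integral intensities of the blue and UV emission
bands.  Only the blue band carries the dosimetry (linear below 5 Gy at the
240 MeV reference quality); its response is ionization-quenched at elevated
LET, described by the relative detector efficiency eta(L) normalized to 1 at
the reference quality (L_ref = 0.42 keV/um).  The UV/blue band ratio r(L)
grows monotonically with LET up to 41.3 keV/um in water, which makes the
ratio invertible into a dose-averaged LET estimate; sensitivity differences
between detector chips cancel in the ratio and are removed from the blue
signal by a known-dose reference irradiation.

Parametric forms (the underlying calibration data are not public; the
parameters are pinned to the stated operating constraints: quenching
corrections < 10% across proton SOBP LET values, eta(6.0) ~ 0.93, validity
to 41.3 keV/um):

    eta(L) = (1 + a*L_ref) / (1 + a*L)
    r(L)   = r0 * (1 + c*L / (1 + L/L_sat))

Noise model per readout: a per-detector sensitivity factor s_d ~ N(1, 3%)
shared by both bands, and independent multiplicative N(0, 0.3%) band noise.
Calibration exposures at varying LET additionally carry a per-exposure
delivery factor common to both bands (it cancels in the ratio) and a small
ratio-specific scatter representing the uncertainty of the LET reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq, curve_fit
from scipy.stats import linregress

LET_MAX_KEV_UM = 41.3
L_REF_DEFAULT = 0.42  # keV/um, 240 MeV protons


class SaturationError(ValueError):
    """Raised when a value lies outside the calibrated LET/ratio domain."""


@dataclass
class EfficiencyCurve:
    """Relative blue-band detection efficiency vs LET; eta(l_ref) = 1."""

    a: float = 0.01357  # (keV/um)^-1, gives eta(6.0) ~ 0.93
    l_ref: float = L_REF_DEFAULT

    def __call__(self, let):
        return efficiency(self, let)


@dataclass
class RatioCurve:
    """UV/blue emission ratio vs LET, strictly increasing on (0, 41.3]."""

    r0: float = 0.30
    c: float = 2.0  # (keV/um)^-1
    l_sat: float = 50.0  # keV/um

    def __call__(self, let):
        return uv_blue_ratio(self, let)

    def log_slope(self, let: float) -> float:
        """d ln r / d ln L at the given LET."""
        let = float(let)
        denom = 1.0 + let / self.l_sat
        drdl = self.r0 * self.c / denom**2
        return drdl * let / uv_blue_ratio(self, let)


@dataclass
class DoseCal:
    """Linear blue-intensity vs dose calibration (validity 0-5 Gy)."""

    slope: float = 1000.0  # intensity per Gy
    intercept: float = 20.0  # intensity

    def signal(self, dose):
        return self.slope * np.asarray(dose, dtype=float) + self.intercept

    def dose(self, signal):
        return (np.asarray(signal, dtype=float) - self.intercept) / self.slope


@dataclass
class OsldReadout:
    detector_id: str
    blue: float
    uv: float
    ref_blue: float
    ref_dose: float = 1.0

    def __post_init__(self):
        if min(self.blue, self.uv, self.ref_blue) <= 0:
            raise ValueError("emission intensities must be positive")


@dataclass
class NoiseConfig:
    sensitivity_sd: float = 0.03  # inter-detector spread of s_d
    band_sd: float = 0.003  # independent per-band readout noise
    delivery_sd: float = 0.037  # per-exposure dose-delivery factor (cal at varying LET)
    ratio_scatter_sd: float = 0.017  # LET-reference scatter of the ratio calibration
    enabled: bool = True

    def off(self) -> "NoiseConfig":
        return replace(self, enabled=False)


@dataclass
class ResponseModel:
    """Ground-truth detector response used by the synthetic generator."""

    dose_cal: DoseCal = field(default_factory=DoseCal)
    efficiency: EfficiencyCurve = field(default_factory=EfficiencyCurve)
    ratio: RatioCurve = field(default_factory=RatioCurve)


@dataclass
class CalibrationSet:
    """Fitted calibration curves with parameter uncertainties.

    ``dose_cal`` lives on the reference-normalized intensity scale (signal
    per unit reference-normalization factor), matching how it is applied.
    """

    dose_cal: DoseCal
    efficiency: EfficiencyCurve
    ratio: RatioCurve
    param_se: dict = field(default_factory=dict)
    residual_sd_pct: dict = field(default_factory=dict)


def _check_let_domain(let) -> np.ndarray:
    let = np.asarray(let, dtype=float)
    if np.any(let <= 0) or np.any(let > LET_MAX_KEV_UM):
        raise SaturationError(
            f"LET outside the calibrated domain (0, {LET_MAX_KEV_UM}] keV/um")
    return let


def efficiency(curve: EfficiencyCurve, let):
    """Relative detector efficiency eta(L); 1/eta is the quenching correction."""
    let = _check_let_domain(let)
    return (1.0 + curve.a * curve.l_ref) / (1.0 + curve.a * let)


def uv_blue_ratio(curve: RatioCurve, let):
    let = _check_let_domain(let)
    return curve.r0 * (1.0 + curve.c * let / (1.0 + let / curve.l_sat))


def invert_ratio(curve: RatioCurve, ratio: float, l_min: float = 1e-6) -> float:
    """LET (keV/um) whose UV/blue ratio equals ``ratio``.

    Bracketed root finding on the strictly increasing ratio curve; rejects
    ratios outside the curve's image over (0, 41.3] keV/um.
    """
    lo, hi = l_min, LET_MAX_KEV_UM
    r_lo = uv_blue_ratio(curve, lo)
    r_hi = uv_blue_ratio(curve, hi)
    if not (r_lo <= ratio <= r_hi):
        raise SaturationError(
            f"ratio {ratio:.4g} outside the calibrated image [{r_lo:.4g}, {r_hi:.4g}]")
    return float(brentq(lambda L: uv_blue_ratio(curve, L) - ratio, lo, hi,
                        xtol=1e-12, rtol=1e-12))


def forward_readout_point(detector_id: str, dose: float, let: float,
                          model: ResponseModel, noise: NoiseConfig,
                          rng: np.random.Generator, ref_dose: float = 1.0,
                          sensitivity: float | None = None,
                          delivery_factor: float = 1.0) -> OsldReadout:
    """Simulate one readout for a detector that absorbed ``dose`` at
    detector-averaged LET ``let``; both bands share the detector sensitivity,
    band noises are independent, and the reference irradiation is a separate
    known-dose exposure."""
    eta = float(efficiency(model.efficiency, let))
    r = float(uv_blue_ratio(model.ratio, let))
    if sensitivity is not None:
        s_d = sensitivity
    elif noise.enabled:
        s_d = 1.0 + noise.sensitivity_sd * rng.normal()
    else:
        s_d = 1.0
    if noise.enabled:
        eps_b, eps_u, eps_r = noise.band_sd * rng.normal(size=3)
    else:
        eps_b, eps_u, eps_r = 0.0, 0.0, 0.0
    base = model.dose_cal.signal(dose) - model.dose_cal.intercept  # slope*D
    quenched = (base * eta + model.dose_cal.intercept) * delivery_factor
    blue = s_d * quenched * (1.0 + eps_b)
    uv = s_d * quenched * r * (1.0 + eps_u)
    ref_blue = s_d * model.dose_cal.signal(ref_dose) * (1.0 + eps_r)
    return OsldReadout(detector_id=detector_id, blue=blue, uv=uv,
                       ref_blue=ref_blue, ref_dose=ref_dose)


def detector_disk_averages(dose_map: np.ndarray, let_map: np.ndarray,
                           area_weights, slice_index: int) -> tuple[float, float]:
    """(area-mean dose, dose-weighted mean LET_D) over one detector disk."""
    ix, iy, frac = area_weights
    d = dose_map[ix, iy, slice_index]
    l = let_map[ix, iy, slice_index]
    ok = np.isfinite(d)
    d = np.where(ok, d, 0.0)
    dose_mean = float((frac * d).sum() / frac.sum())
    wl = frac * d * np.where(np.isfinite(l), l, 0.0)
    wd = frac * d
    let_mean = float(wl.sum() / wd.sum()) if wd.sum() > 0 else float("nan")
    return dose_mean, let_mean


def forward_readout(detector_id: str, dose_map: np.ndarray, let_map: np.ndarray,
                    area_weights, slice_index: int, model: ResponseModel,
                    noise: NoiseConfig, rng: np.random.Generator,
                    ref_dose: float = 1.0, sensitivity: float | None = None) -> OsldReadout:
    """Simulate the readout of one physical disk placed in the scored maps."""
    dose_d, let_d = detector_disk_averages(dose_map, let_map, area_weights, slice_index)
    return forward_readout_point(detector_id, dose_d, let_d, model, noise, rng,
                                 ref_dose=ref_dose, sensitivity=sensitivity)


def reference_normalize(readout: OsldReadout) -> float:
    """Blue intensity rescaled by the reference irradiation (per-unit-dose
    reference signal), cancelling the detector sensitivity."""
    if readout.ref_blue <= 0:
        raise ValueError("readout has no reference irradiation")
    return readout.blue / (readout.ref_blue / readout.ref_dose)


# ---------------------------------------------------------------------------
# Synthetic calibration exposures + fitting


@dataclass
class CalIrradiation:
    """One calibration exposure: known dose, known reference LET, readout.

    ``series`` tags which calibration the exposure belongs to: "dose"
    (reference quality, varying dose) or "let" (fixed dose, varying LET).
    """

    dose: float
    let: float
    readout: OsldReadout
    series: str = "let"


def simulate_calibration_irradiations(model: ResponseModel, noise: NoiseConfig,
                                      rng: np.random.Generator,
                                      doses=None, lets=None,
                                      let_series_dose: float = 2.0) -> list[CalIrradiation]:
    """Dose series at reference quality plus a LET series at fixed dose.

    Each exposure uses a fresh detector chip (own sensitivity).  LET-series
    exposures additionally carry a shared-band delivery factor and a
    ratio-specific scatter emulating the uncertainty of the LET reference.
    """
    if doses is None:
        doses = np.linspace(0.5, 5.0, 20)
    if lets is None:
        lets = np.geomspace(L_REF_DEFAULT, 10.0, 15)
    out = []
    for i, d in enumerate(doses):
        ro = forward_readout_point(f"cal_dose_{i}", float(d), model.efficiency.l_ref,
                                   model, noise, rng)
        out.append(CalIrradiation(dose=float(d), let=model.efficiency.l_ref,
                                  readout=ro, series="dose"))
    for i, L in enumerate(lets):
        df = 1.0 + noise.delivery_sd * rng.normal() if noise.enabled else 1.0
        ro = forward_readout_point(f"cal_let_{i}", let_series_dose, float(L),
                                   model, noise, rng, delivery_factor=df)
        if noise.enabled and noise.ratio_scatter_sd > 0:
            ro.uv *= 1.0 + noise.ratio_scatter_sd * rng.normal()
        out.append(CalIrradiation(dose=let_series_dose, let=float(L),
                                  readout=ro, series="let"))
    return out


def fit_calibrations(cal_irradiations: list[CalIrradiation],
                     l_ref: float = L_REF_DEFAULT) -> CalibrationSet:
    """Least-squares fits of the dose line, efficiency curve and ratio curve.

    The dose line is fitted on reference-normalized blue signal vs delivered
    dose at reference quality; the ratio curve on uv/blue vs the known LET;
    the efficiency curve on calibrated-dose / true-dose vs LET.  Residual
    standard deviations (percent, relative to the fit) are reported per curve.
    """
    dose_pts = [c for c in cal_irradiations if c.series == "dose"]
    let_pts = [c for c in cal_irradiations if c.series == "let"]
    if len(dose_pts) < 5:
        raise ValueError("need at least 5 dose-calibration points in 0-5 Gy")
    if len(let_pts) < 5:
        raise ValueError("need at least 5 LET-calibration points")

    d = np.array([c.dose for c in dose_pts])
    if d.max() > 5.0 + 1e-9:
        raise ValueError("dose calibration points must stay in the linear 0-5 Gy domain")
    y = np.array([reference_normalize(c.readout) for c in dose_pts])
    lin = linregress(d, y)
    dose_cal = DoseCal(slope=float(lin.slope), intercept=float(lin.intercept))
    res_d = (y - dose_cal.signal(d)) / dose_cal.signal(d)

    L = np.array([c.let for c in let_pts])
    rr = np.array([c.readout.uv / c.readout.blue for c in let_pts])

    def r_model(x, r0, c, l_sat):
        return r0 * (1.0 + c * x / (1.0 + x / l_sat))

    p0 = (max(rr.min(), 1e-3), 1.0, 30.0)
    popt, pcov = curve_fit(r_model, L, rr, p0=p0, maxfev=20000)
    ratio = RatioCurve(*[float(v) for v in popt])
    res_r = (rr - r_model(L, *popt)) / r_model(L, *popt)

    eta_obs = np.array([dose_cal.dose(reference_normalize(c.readout)) / c.dose
                        for c in let_pts])

    def eta_model(x, a):
        return (1.0 + a * l_ref) / (1.0 + a * x)

    popt_e, pcov_e = curve_fit(eta_model, L, eta_obs, p0=(0.01,), maxfev=20000)
    eff = EfficiencyCurve(a=float(popt_e[0]), l_ref=l_ref)
    res_e = (eta_obs - eta_model(L, *popt_e)) / eta_model(L, *popt_e)

    se = {
        "dose_slope": float(lin.stderr), "dose_intercept": float(lin.intercept_stderr),
        "ratio": [float(v) for v in np.sqrt(np.diag(pcov))],
        "efficiency_a": float(np.sqrt(pcov_e[0, 0])),
    }
    resid = {
        "dose_pct": float(res_d.std(ddof=2) * 100.0),
        "efficiency_pct": float(res_e.std(ddof=1) * 100.0),
        "ratio_pct": float(res_r.std(ddof=3) * 100.0),
    }
    return CalibrationSet(dose_cal=dose_cal, efficiency=eff, ratio=ratio,
                          param_se=se, residual_sd_pct=resid)
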