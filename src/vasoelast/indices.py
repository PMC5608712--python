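"""Doppler- and diameter-derived carotid physiology.

Scalar hemodynamic indices computed from spectral-Doppler velocities and
B-mode lumen diameters: volume blood flow, Poiseuille wall shear stress,
resistive and pulsatility indices, and carotid (diameter) strain.  All
formulas operate on per-artery scalars and are applied row-wise over
cohort tables.

Units follow the source conventions: velocities mm/s, diameters mm, VTI
mm (per beat), flow mL/min, shear stress dynes/cm^2, viscosity poise.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

#: Assumed whole-blood dynamic viscosity, poise.
DEFAULT_VISCOSITY_POISE = 0.035


def blood_flow_volume(heart_rate: float, lumen_diameter_mm: float, vti_mm: float) -> float:
    """Volume blood flow rate, mL/min.

    ``flow = heart_rate * lumen_area * VTI / 1000`` with a circular lumen
    of the given diameter (area in mm^2, VTI in mm per beat, HR in
    beats/min; mm^3/min -> mL/min via the /1000).
    """
    if heart_rate <= 0 or lumen_diameter_mm <= 0 or vti_mm < 0:
        raise ValueError("heart rate and diameter must be positive, VTI non-negative")
    area_mm2 = math.pi * (lumen_diameter_mm / 2.0) ** 2
    return heart_rate * area_mm2 * vti_mm / 1000.0


def mean_shear_stress(
    flow_ml_min: float,
    lumen_radius_cm: float,
    viscosity_poise: float = DEFAULT_VISCOSITY_POISE,
) -> float:
    """Poiseuille wall shear stress ``tau = 4 mu Q / (pi r^3)``, dynes/cm^2.

    ``Q`` is converted to cm^3/s internally.  Valid only for parabolic
    (fully developed laminar) flow — callers should carry that assumption
    flag alongside the value.
    """
    if lumen_radius_cm <= 0:
        raise ValueError("lumen radius must be positive")
    if flow_ml_min < 0 or viscosity_poise <= 0:
        raise ValueError("flow must be >= 0 and viscosity > 0")
    q_cm3_s = flow_ml_min / 60.0
    return 4.0 * viscosity_poise * q_cm3_s / (math.pi * lumen_radius_cm**3)


def resistive_index(psv: float, edv: float) -> float:
    """Resistive index ``(PSV - EDV) / PSV``; dimensionless, in [0, 1]."""
    if psv <= 0:
        raise ValueError("peak systolic velocity must be positive")
    if not 0 <= edv <= psv:
        raise ValueError("need 0 <= EDV <= PSV")
    return (psv - edv) / psv


def pulsatility_index(psv: float, edv: float, ta_mean_velocity: float) -> float:
    """Pulsatility index ``(PSV - EDV) / TAmean``.

    The denominator is the time-averaged mean velocity over the cardiac
    cycle (the conventional reading of "velocity time integral of mean
    velocity"); pass the literal per-beat VTI instead to obtain the
    alternative literal form.
    """
    if ta_mean_velocity <= 0:
        raise ValueError("time-averaged mean velocity must be positive")
    if psv < edv:
        raise ValueError("need PSV >= EDV")
    return (psv - edv) / ta_mean_velocity


def carotid_strain(
    systolic_diameter_mm: float,
    diastolic_diameter_mm: float,
    magnitude_mode: bool = True,
) -> float:
    """Carotid diameter strain, percent.

    ``(systolic - diastolic) / systolic * 100`` as printed; with murine
    diastolic diameters exceeding systolic ones this is negative, so the
    default returns the magnitude (the signed value is a one-liner away
    with ``magnitude_mode=False``).
    """
    if systolic_diameter_mm <= 0:
        raise ValueError("systolic diameter must be positive")
    if diastolic_diameter_mm <= 0:
        raise ValueError("diastolic diameter must be positive")
    signed = (systolic_diameter_mm - diastolic_diameter_mm) / systolic_diameter_mm * 100.0
    return abs(signed) if magnitude_mode else signed


def augment_cohort(
    table: pd.DataFrame,
    viscosity_poise: float = DEFAULT_VISCOSITY_POISE,
    flow_diameter: str = "diastolic_diameter",
) -> pd.DataFrame:
    """Append index columns to a cohort table (one artery per row).

    Adds ``flow_ml_min``, ``shear_dyn_cm2``, ``resistive_index``,
    ``pulsatility_index``, ``strain_pct`` and ``strain_signed_pct``.
    The lumen area for flow uses ``flow_diameter`` (diastolic by
    default).  The Poiseuille parabolic-flow assumption is recorded in
    ``table.attrs``.
    """
    out = table.copy()
    d = out[flow_diameter]
    out["flow_ml_min"] = [
        blood_flow_volume(h, dd, v)
        for h, dd, v in zip(out["heart_rate"], d, out["vti"])
    ]
    out["shear_dyn_cm2"] = [
        mean_shear_stress(q, dd / 2.0 / 10.0, viscosity_poise)
        for q, dd in zip(out["flow_ml_min"], d)
    ]
    out["resistive_index"] = [
        resistive_index(p, min(e, p)) for p, e in zip(out["psv"], out["edv"])
    ]
    if "ta_mean_velocity" in out:
        tam = out["ta_mean_velocity"]
    else:
        tam = out["vti"] * out["heart_rate"] / 60.0
    out["pulsatility_index"] = [
        pulsatility_index(p, min(e, p), t)
        for p, e, t in zip(out["psv"], out["edv"], tam)
    ]
    out["strain_pct"] = [
        carotid_strain(s, dd)
        for s, dd in zip(out["systolic_diameter"], out["diastolic_diameter"])
    ]
    out["strain_signed_pct"] = [
        carotid_strain(s, dd, magnitude_mode=False)
        for s, dd in zip(out["systolic_diameter"], out["diastolic_diameter"])
    ]
    out.attrs["shear_formula"] = "poiseuille_4muQ_over_pi_r3"
    out.attrs["shear_assumes_parabolic_flow"] = True
    out.attrs["viscosity_poise"] = viscosity_poise
    out.attrs["flow_diameter"] = flow_diameter
    return out
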