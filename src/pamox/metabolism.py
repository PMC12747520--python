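"""Regional oxygen metabolism from per-vessel measurements.

Three formulas connect the microvascular measurements to the regional
read-outs, in the field's standard notation:

* per-vessel volumetric flux ``CBF = pi * v * d^2 / 8`` — the flux of a
  parabolic velocity profile with peak speed v through a circular lumen of
  diameter d (mean speed v/2 times area pi d^2/4; the 8 is not a typo),
* ``OEF = (s_aO2 - s_vO2) / s_aO2`` over the feeding arteries and draining
  veins of a region,
* ``CMRO2 = xi * C_Hb * s_aO2 * OEF * CBF`` with xi the oxygen-binding
  capacity of hemoglobin (0.014 L O2 per gram).

Regional CBF is the summed feeding-artery flux normalized by a configurable
region mass and expressed per 100 g.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Optional

import numpy as np

from .types import MetabolismConfig, RegionHemodynamics, VesselMeasure


def vessel_flow(v_mm_s: float, d_um: float) -> float:
    """Volumetric flow pi*v*d^2/8 of one vessel, in uL/min.

    v is the peak flow speed along the vascular axis (mm/s) and d the
    vascular diameter (um).  Unit audit:
    (um/s) * um^2 = um^3/s; x60 / 1e9 -> uL/min.
    """
    if v_mm_s < 0 or d_um <= 0:
        raise ValueError("need v >= 0 and d > 0")
    v_um_s = v_mm_s * 1000.0
    flux_um3_s = np.pi * v_um_s * d_um ** 2 / 8.0
    return flux_um3_s * 60.0 / 1e9


def _measure_flow(vm: VesselMeasure) -> float:
    return vessel_flow(vm.peak_speed_mm_s, vm.diameter_um)


def region_cbf(arteries: list[VesselMeasure],
               cfg: MetabolismConfig = MetabolismConfig()) -> float:
    """Regional perfusion (mL/100 g/min): summed feeding-artery flux over
    the region mass."""
    if not arteries:
        raise ValueError("need at least one feeding artery")
    total_ul_min = sum(_measure_flow(a) for a in arteries)
    return total_ul_min / 1000.0 / cfg.region_mass_g * 100.0


@dataclass
class OefResult:
    """Regional oxygen extraction with its input saturations."""

    oef: float
    sa_o2: float
    sv_o2: float
    flags: tuple[str, ...] = ()

    def __iter__(self):
        return iter((self.oef, self.sa_o2, self.sv_o2))


def region_oef(arteries: list[VesselMeasure], veins: list[VesselMeasure],
               weighting: str = "flow") -> OefResult:
    """OEF = (s_aO2 - s_vO2) / s_aO2 from per-vessel saturations.

    s_aO2 and s_vO2 are flow-weighted means by default (mass balance);
    ``weighting="uniform"`` averages vessels equally.  A venous saturation
    above the arterial one yields a flagged, unclipped negative OEF.
    """
    if not arteries or not veins:
        raise ValueError("need at least one artery and one vein with sO2 set")
    for vm in arteries + veins:
        if not np.isfinite(vm.so2):
            raise ValueError(f"vessel {vm.id!r} has no sO2")
    if weighting == "flow":
        wa = np.array([_measure_flow(a) for a in arteries])
        wv = np.array([_measure_flow(v) for v in veins])
        if wa.sum() == 0:
            wa = np.ones_like(wa)
        if wv.sum() == 0:
            wv = np.ones_like(wv)
    elif weighting == "uniform":
        wa = np.ones(len(arteries))
        wv = np.ones(len(veins))
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    sa = float(np.average([a.so2 for a in arteries], weights=wa))
    sv = float(np.average([v.so2 for v in veins], weights=wv))
    if sa == 0:
        raise ValueError("arterial saturation is zero")
    oef = (sa - sv) / sa
    flags = ("negative OEF",) if sv > sa else ()
    return OefResult(oef=oef, sa_o2=sa, sv_o2=sv, flags=flags)


def region_cmro2(cbf_ml_100g_min: float, oef: float, sa_o2: float,
                 chb_g_per_L: float,
                 cfg: MetabolismConfig = MetabolismConfig()) -> float:
    """CMRO2 = xi * C_Hb * s_aO2 * OEF * CBF, in mL O2/100 g/min.

    With xi in L O2 per g and C_Hb in g/L, ``xi * C_Hb`` is dimensionless
    in (L O2 per L blood) = (mL O2 per mL blood), so the product carries
    CBF's per-100-g-per-minute units.
    """
    for name, val in (("cbf", cbf_ml_100g_min), ("oef", oef),
                      ("sa_o2", sa_o2), ("chb", chb_g_per_L)):
        if val < 0:
            raise ValueError(f"{name} must be nonnegative")
    ml_o2_per_ml_blood = cfg.xi_L_O2_per_g * chb_g_per_L
    return ml_o2_per_ml_blood * sa_o2 * oef * cbf_ml_100g_min


def baseline_percent(value: float, baseline: float,
                     cfg: MetabolismConfig = MetabolismConfig()) -> int:
    """Percentage of baseline, rounded half-up to an integer."""
    if baseline <= 0:
        raise ValueError("baseline must be positive")
    pct = Decimal(100 * value / baseline)
    return int(pct.quantize(Decimal("1"), rounding=ROUND_HALF_UP))


def region_hemodynamics(region: str, vessels: Iterable[VesselMeasure],
                        cfg: MetabolismConfig = MetabolismConfig(),
                        chb_g_per_L: Optional[float] = None,
                        weighting: str = "flow") -> RegionHemodynamics:
    """Combine classified per-vessel measurements into the regional summary.

    ``chb_g_per_L`` defaults to the flow-weighted mean of the arterial
    per-vessel concentrations when those are set.
    """
    vs = [v for v in vessels if v.region in (None, region)]
    arteries = [v for v in vs if v.vessel_class == "artery"]
    veins = [v for v in vs if v.vessel_class == "vein"]
    cbf = region_cbf(arteries, cfg)
    oef_res = region_oef(arteries, veins, weighting=weighting)
    if chb_g_per_L is None:
        chbs = [a.chb_g_per_L for a in arteries if np.isfinite(a.chb_g_per_L)]
        if not chbs:
            raise ValueError("no hemoglobin concentration available")
        w = [_measure_flow(a) for a in arteries
             if np.isfinite(a.chb_g_per_L)]
        chb_g_per_L = float(np.average(chbs, weights=w if sum(w) else None))
    cmro2 = region_cmro2(cbf, max(oef_res.oef, 0.0), oef_res.sa_o2,
                         chb_g_per_L, cfg) if oef_res.oef >= 0 else float("nan")
    return RegionHemodynamics(
        region=region, cbf_ml_100g_min=cbf, oef=oef_res.oef,
        cmro2_ml_100g_min=cmro2, sa_o2=oef_res.sa_o2, sv_o2=oef_res.sv_o2,
        chb_g_per_L=chb_g_per_L, n_arteries=len(arteries),
        n_veins=len(veins), flags=oef_res.flags,
    )
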