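"""Spectroscopic sO2: dual-wavelength linear unmixing of oxy- and
deoxy-hemoglobin, per-vessel aggregation, artery/vein classification.

The model is amplitude(lambda) proportional to
``C_HbO2 * eps_HbO2(lambda) + C_Hb,deoxy * eps_Hb(lambda)``; with two
wavelengths this is a 2x2 linear system per pixel.  Negative unmixed
concentrations (noise) are clipped to zero before forming sO2, which keeps
sO2 in [0, 1] even for physically inconsistent amplitude pairs.
"""

from __future__ import annotations

import numpy as np

from .types import (
    DEFAULT_EXTINCTION,
    DualWavelengthImage,
    ExtinctionTable,
    VesselMask,
    VesselMeasure,
)


def unmix(a532, a558, ext: ExtinctionTable = DEFAULT_EXTINCTION):
    """Per-pixel sO2 and relative total hemoglobin from two amplitudes.

    Accepts scalars or broadcastable arrays.  Returns ``(so2, rel_chb)``
    with sO2 clipped to [0, 1] and rel_chb clipped at 0.  For scalar inputs
    a zero amplitude pair raises ``ValueError("no signal")``; in arrays such
    pixels become NaN.
    """
    m = ext.matrix(532, 558)
    minv = np.linalg.inv(m)
    a532 = np.asarray(a532, dtype=float)
    a558 = np.asarray(a558, dtype=float)
    scalar = a532.ndim == 0 and a558.ndim == 0
    if (a532 < 0).any() or (a558 < 0).any():
        raise ValueError("amplitudes must be nonnegative")
    no_signal = (a532 == 0) & (a558 == 0)
    if scalar and no_signal:
        raise ValueError("no signal")
    c_oxy = np.clip(minv[0, 0] * a532 + minv[0, 1] * a558, 0.0, None)
    c_deoxy = np.clip(minv[1, 0] * a532 + minv[1, 1] * a558, 0.0, None)
    total = c_oxy + c_deoxy
    with np.errstate(invalid="ignore", divide="ignore"):
        so2 = np.where(total > 0, c_oxy / np.where(total > 0, total, 1.0), np.nan)
    so2 = np.clip(so2, 0.0, 1.0)
    so2 = np.where(no_signal, np.nan, so2)
    rel_chb = np.where(no_signal, np.nan, total)
    if scalar:
        return float(so2), float(rel_chb)
    return so2, rel_chb


def vessel_so2(img: DualWavelengthImage, mask: VesselMask,
               ext: ExtinctionTable = DEFAULT_EXTINCTION) -> float:
    """Amplitude-weighted mean sO2 over the mask pixels.

    Weights are the 532 nm amplitudes; pixels with no signal are dropped,
    and a mask with no usable pixel is an error.  The result lies in [0, 1].
    """
    sel = mask.mask
    a532 = img.a532[sel]
    a558 = img.a558[sel]
    so2, _ = unmix(a532, a558, ext)
    ok = np.isfinite(so2)
    if not ok.any():
        raise ValueError("all mask pixels have no signal")
    w = a532[ok]
    if w.sum() == 0:
        return float(np.mean(so2[ok]))
    return float(np.average(so2[ok], weights=w))


def classify_vessels(vessels: list[VesselMeasure], method: str = "threshold",
                     artery_so2_min: float = 0.8,
                     labels: dict[str, str] | None = None,
                     ) -> list[VesselMeasure]:
    """Label vessels as arteries or veins.

    ``method="threshold"``: artery iff sO2 >= ``artery_so2_min`` (a
    placeholder heuristic; the default 0.8 separates well-oxygenated feeding
    arteries from draining veins on phantoms).  ``method="labels"``: apply
    user-provided labels keyed by vessel id.  Vessels are modified in place
    and the list returned for chaining.
    """
    if method == "threshold":
        if not 0.0 < artery_so2_min < 1.0:
            raise ValueError("artery_so2_min must lie in (0, 1)")
        for v in vessels:
            if not np.isfinite(v.so2):
                raise ValueError(f"vessel {v.id!r} has no sO2")
            v.vessel_class = "artery" if v.so2 >= artery_so2_min else "vein"
    elif method == "labels":
        if labels is None:
            raise ValueError("labels mode requires user labels")
        for v in vessels:
            v.vessel_class = labels[v.id]
    else:
        raise ValueError(f"unknown method {method!r}")
    return vessels
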