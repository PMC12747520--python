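"""Mitochondrial function from instrument traces.

Oxygen consumption rates (OCR) come from least-squares slopes of the
Clark-electrode O2 trace over protocol-defined state windows, scaled to
nmol O2 per mg mitochondrial protein per minute; the respiratory control
ratio (RCR) is State 3 over State 4.  Hydrogen peroxide emission is the
pre-rotenone Amplex UltraRed fluorescence slope converted through a linear
calibration of known H2O2 additions.  Superoxide is the initial linear rate
of the MitoSOX Red fluorescence (the kinetics saturate after ~25 min, so
only the first window is used).  Membrane potential is indexed by the
RH-123 quench depth: baseline fluorescence (300 s) minus the post-substrate
plateau, with the CCCP-released amplitude reported alongside since figure
conventions differ on which of the two is "the" delta.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.stats import linregress

from .types import CalibrationCurve, FluoroTrace, OcrResult, RespiroTrace

STATE_ORDER = ("basal", "state2", "state3", "state4", "uncoupled")


def _window_slope(t: np.ndarray, y: np.ndarray,
                  window: tuple[float, float]) -> float:
    """Least-squares slope of y vs t (per second) over [t0, t1)."""
    t0, t1 = window
    sel = (t >= t0) & (t < t1)
    if sel.sum() < 3:
        raise ValueError("window shorter than 3 samples")
    res = linregress(t[sel], y[sel])
    return float(res.slope)


def detect_state4_onset(trace: RespiroTrace, t_start: float, t_end: float,
                        window_s: float = 60.0) -> float:
    """Changepoint after ADP: the time with the largest decrease in slope
    magnitude between consecutive regression windows."""
    t = trace.time_s
    candidates = t[(t >= t_start + window_s) & (t <= t_end - window_s)]
    if candidates.size == 0:
        raise ValueError("ADP window too short for changepoint detection")
    best_t, best_drop = None, -np.inf
    for tc in candidates:
        s_before = _window_slope(t, trace.o2_nmol_per_ml, (tc - window_s, tc))
        s_after = _window_slope(t, trace.o2_nmol_per_ml, (tc, tc + window_s))
        drop = abs(s_before) - abs(s_after)
        if drop > best_drop:
            best_drop, best_t = drop, float(tc)
    return best_t


def segment_states(trace: RespiroTrace, buffer_s: float = 10.0,
                   ) -> dict[str, tuple[float, float]]:
    """Label respiration-state windows from the trace's event annotations.

    Windows start ``buffer_s`` after their triggering event (settling time)
    and end at the next event.  The State3 -> State4 boundary uses an
    explicit ``adp_exhausted`` annotation when present, otherwise the
    detected slope changepoint.  Without an ADP event only the basal (and
    State 2) windows are returned.
    """
    if buffer_s < 0:
        raise ValueError("buffer_s must be nonnegative")
    t = trace.time_s
    t_sub = trace.event_time("substrate")
    t_adp = trace.event_time("ADP")
    t_dnp = trace.event_time("DNP")
    t_end = float(t[-1])

    windows: dict[str, tuple[float, float]] = {}
    if t_sub is not None and t_sub > 0:
        windows["basal"] = (0.0, t_sub)
    first_after_sub = min([x for x in (t_adp, t_dnp, t_end) if x is not None])
    if t_sub is not None:
        windows["state2"] = (t_sub + buffer_s, first_after_sub)
    if t_adp is not None:
        seg_end = t_dnp if t_dnp is not None else t_end
        t_s4 = trace.event_time("adp_exhausted")
        if t_s4 is None:
            t_s4 = detect_state4_onset(trace, t_adp + buffer_s, seg_end)
        windows["state3"] = (t_adp + buffer_s, t_s4)
        windows["state4"] = (t_s4 + buffer_s, seg_end)
    if t_dnp is not None:
        windows["uncoupled"] = (t_dnp + buffer_s, t_end + trace.time_s[1] - trace.time_s[0])

    dt = float(np.median(np.diff(t)))
    for name, (t0, t1) in windows.items():
        if (t1 - t0) < 3 * dt:
            raise ValueError(f"window {name!r} shorter than 3 samples")
    return windows


def ocr(trace: RespiroTrace, window: tuple[float, float]) -> float:
    """Oxygen consumption rate over a window, nmol O2/mg protein/min.

    OCR = -(slope of O2 vs time in nmol/mL/min) * chamber_ml / protein_mg.
    A rising O2 trace (negative consumption) is reported as 0 with a
    warning.
    """
    slope_per_min = _window_slope(trace.time_s, trace.o2_nmol_per_ml, window) * 60.0
    val = -slope_per_min * trace.chamber_ml / trace.protein_mg
    if val < 0:
        warnings.warn("O2 rising over window; OCR clipped to 0", stacklevel=2)
        return 0.0
    return val


def rcr(state3_ocr: float, state4_ocr: float) -> float:
    """Respiratory control ratio: State 3 over State 4 respiration."""
    if state4_ocr <= 0:
        raise ValueError("State-4 OCR must be positive")
    return state3_ocr / state4_ocr


def analyze_respiro(trace: RespiroTrace, buffer_s: float = 10.0) -> OcrResult:
    """Full respirometry read-out: per-state OCR and the RCR."""
    windows = segment_states(trace, buffer_s=buffer_s)
    if "state3" not in windows:
        raise ValueError("trace lacks an ADP event; no State 3/4 to quantify")
    s3 = ocr(trace, windows["state3"])
    s4 = ocr(trace, windows["state4"])
    return OcrResult(
        state3_ocr=s3, state4_ocr=s4, rcr=rcr(s3, s4),
        uncoupled_ocr=ocr(trace, windows["uncoupled"]) if "uncoupled" in windows else None,
        basal_ocr=ocr(trace, windows["basal"]) if "basal" in windows else None,
    )


def h2o2_calibration(additions_nmol, responses_au) -> CalibrationCurve:
    """Ordinary least-squares line (with intercept) of fluorescence response
    vs known H2O2 amount.

    The intercept absorbs the dye background.  Needs at least three
    distinct addition amounts.
    """
    x = np.asarray(additions_nmol, dtype=float)
    y = np.asarray(responses_au, dtype=float)
    if x.size < 3 or x.size != y.size:
        raise ValueError("need at least 3 paired calibration points")
    if np.ptp(x) == 0:
        raise ValueError("calibration additions have zero variance")
    res = linregress(x, y)
    return CalibrationCurve(
        additions_nmol=x, responses_au=y,
        slope_au_per_nmol=float(res.slope), intercept_au=float(res.intercept),
        r2=float(res.rvalue ** 2),
    )


def h2o2_rate(trace: FluoroTrace, cal: CalibrationCurve,
              protein_mg: float) -> float:
    """H2O2 emission rate from the pre-rotenone Amplex segment,
    nmol H2O2/mg protein/min."""
    if trace.kind != "amplex":
        raise ValueError("H2O2 rate requires an Amplex trace")
    if cal.slope_au_per_nmol <= 0:
        raise ValueError("invalid calibration (non-positive slope)")
    if protein_mg <= 0:
        raise ValueError("protein_mg must be positive")
    t_rot = trace.event_time("rotenone")
    if t_rot is None:
        raise ValueError("missing rotenone event")
    slope_au_min = _window_slope(trace.time_s, trace.fluorescence_au,
                                 (0.0, t_rot)) * 60.0
    return slope_au_min / cal.slope_au_per_nmol / protein_mg


def mitosox_rate(trace: FluoroTrace, window_s: float = 300.0) -> float:
    """Initial linear increase rate of the MitoSOX fluorescence, a.u./min.

    The default 300 s window sits well inside the ~25 min saturation of the
    kinetics.
    """
    if trace.kind != "mitosox":
        raise ValueError("requires a MitoSOX trace")
    t0 = float(trace.time_s[0])
    if t0 + window_s > trace.time_s[-1]:
        raise ValueError("window longer than trace")
    slope = _window_slope(trace.time_s, trace.fluorescence_au,
                          (t0, t0 + window_s + 1e-9))
    return slope * 60.0


def rh123_delta(trace: FluoroTrace, baseline_s: float = 300.0,
                ) -> tuple[float, float | None]:
    """RH-123 quench depth and CCCP-released amplitude.

    delta_F = mean baseline (first 300 s) minus the post-substrate plateau
    (mean of the last third of the segment before CCCP or trace end);
    the release is the post-CCCP plateau minus the post-substrate plateau
    when a CCCP event is present.  Plateau means over the last third are
    robust to the settling transient after each addition.
    """
    if trace.kind != "rh123":
        raise ValueError("requires an RH-123 trace")
    t = trace.time_s
    f = trace.fluorescence_au
    t_sub = trace.event_time("substrate")
    if t_sub is None or t_sub < baseline_s or t[0] > 0:
        raise ValueError("baseline shorter than 300 s before substrate")
    baseline = float(f[(t >= 0) & (t < baseline_s)].mean())

    t_cccp = trace.event_time("cccp")
    seg_end = t_cccp if t_cccp is not None else float(t[-1])

    def plateau(t0: float, t1: float) -> float:
        lo = t1 - (t1 - t0) / 3.0
        sel = (t >= lo) & (t <= t1)
        if sel.sum() < 3:
            raise ValueError("plateau segment shorter than 3 samples")
        return float(f[sel].mean())

    quenched = plateau(t_sub, seg_end)
    delta_f = baseline - quenched
    release = None
    if t_cccp is not None:
        release = plateau(t_cccp, float(t[-1])) - quenched
    return delta_f, release
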