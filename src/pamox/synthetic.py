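"""Synthetic-data generators: every input the pipeline consumes, with known
ground truth.

The phantom emulates the multi-parametric photoacoustic acquisition at a
configurable scale: a vessel network with known diameter, peak speed, sO2
and hemoglobin concentration is rendered into co-registered 532/558 nm
amplitude maps (forward optical model: amplitude proportional to total
hemoglobin times the wavelength-dependent extinction mixture, blurred by a
Gaussian point-spread function, plus additive Gaussian noise parameterized
by an SNR in dB).  A-line ensembles carry the flow information in their
inter-line decorrelation, and Clark-electrode / fluorometer traces follow
the respirometry and fluorometry protocols with piecewise structure.

Every generator is a pure function of its parameters and an integer seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.linalg import cholesky
from scipy.ndimage import gaussian_filter

from .types import (
    AlineEnsemble,
    DualWavelengthImage,
    ExtinctionTable,
    FlowCalibration,
    FluoroTrace,
    PhantomScene,
    RespiroTrace,
    VesselSpec,
    _densify,
    DEFAULT_EXTINCTION,
)

# Instrument gain of the forward optical model: amplitude (a.u.) per
# (g/L of hemoglobin x M^-1 cm^-1 of extinction).  Arbitrary but fixed, so
# relative-concentration recovery is well defined.
RENDER_GAIN = 1e-5


# ---------------------------------------------------------------------------
# Phantom scenes
# ---------------------------------------------------------------------------

def default_scene_config() -> dict:
    """Default six-vessel, two-hemicortex phantom configuration.

    A scaled-down version of the 5 x 3 mm^2 imaging field covering both
    hemicortices: 2.5 x 1.5 mm at 5 um pixels.  Each hemicortex holds two
    feeding arteries and one draining vein with physiological sO2
    (arteries ~0.95, veins ~0.65), diameters 80-150 um, peak speeds
    0.8-1.6 mm/s and a hemoglobin concentration of 120 g/L, chosen so the
    ground-truth regional CBF lands in the tens of mL/100 g/min.
    """
    vessels = []
    for region, x0 in (("contralateral", 0.0), ("ipsilateral", 1250.0)):
        tag = region[:2]
        vessels += [
            dict(id=f"{tag}_artery1", x_um=x0 + 300.0, diameter_um=100.0,
                 peak_speed_mm_s=1.6, so2=0.95, vessel_class="artery",
                 region=region, chb_g_per_L=120.0),
            dict(id=f"{tag}_artery2", x_um=x0 + 600.0, diameter_um=80.0,
                 peak_speed_mm_s=1.2, so2=0.93, vessel_class="artery",
                 region=region, chb_g_per_L=120.0),
            dict(id=f"{tag}_vein1", x_um=x0 + 950.0, diameter_um=150.0,
                 peak_speed_mm_s=0.8, so2=0.65, vessel_class="vein",
                 region=region, chb_g_per_L=120.0),
        ]
    return dict(
        field_size_um=(2500.0, 1500.0),
        pixel_spacing_um=(5.0, 5.0),
        psf_fwhm_um=8.0,
        noise_snr_db=25.0,
        margin_um=100.0,
        jitter=dict(x_um=80.0, diameter_frac=0.08, speed_frac=0.15, so2=0.015),
        vessels=vessels,
    )


def compact_scene_config() -> dict:
    """Two-vessel (one artery, one vein) phantom on a small field.

    Same optics and noise defaults as :func:`default_scene_config`; used for
    Monte-Carlo sweeps where rendering the full two-hemicortex field per
    seed would be wasteful.
    """
    cfg = default_scene_config()
    cfg["field_size_um"] = (700.0, 700.0)
    cfg["jitter"]["x_um"] = 30.0
    cfg["vessels"] = [
        dict(id="artery", x_um=220.0, diameter_um=80.0, peak_speed_mm_s=1.5,
             so2=0.95, vessel_class="artery", region="ipsilateral",
             chb_g_per_L=120.0),
        dict(id="vein", x_um=480.0, diameter_um=100.0, peak_speed_mm_s=0.9,
             so2=0.65, vessel_class="vein", region="ipsilateral",
             chb_g_per_L=120.0),
    ]
    return cfg


def make_scene(config: Optional[dict] = None, seed: int = 0) -> PhantomScene:
    """Build a :class:`PhantomScene` from a config dict and a seed.

    Vessels are near-vertical tubes whose lateral position, diameter, speed
    and sO2 are jittered deterministically by ``seed`` within the configured
    ranges (clamped so every vessel stays inside the field).  The same
    (config, seed) pair always produces an identical scene.
    """
    cfg = default_scene_config() if config is None else config
    rng = np.random.default_rng(seed)
    fx, fy = cfg["field_size_um"]
    margin = float(cfg.get("margin_um", 100.0))
    jit = cfg.get("jitter") or {}

    vessels = []
    for vc in cfg["vessels"]:
        d = float(vc["diameter_um"])
        v = float(vc["peak_speed_mm_s"])
        s = float(vc["so2"])
        x = float(vc["x_um"])
        if jit:
            x = x + rng.uniform(-1, 1) * float(jit.get("x_um", 0.0))
            d = d * (1.0 + rng.uniform(-1, 1) * float(jit.get("diameter_frac", 0.0)))
            v = v * (1.0 + rng.uniform(-1, 1) * float(jit.get("speed_frac", 0.0)))
            s = float(np.clip(s + rng.uniform(-1, 1) * float(jit.get("so2", 0.0)),
                              0.0, 1.0))
        x = float(np.clip(x, d / 2 + 1.0, fx - d / 2 - 1.0))
        y0, y1 = margin + d / 2, fy - margin - d / 2
        if "centerline_um" in vc:
            centerline = np.asarray(vc["centerline_um"], dtype=float)
        else:
            centerline = np.array([[x, y0], [x, y1]])
        vessels.append(VesselSpec(
            id=vc["id"], centerline_um=centerline, diameter_um=d,
            peak_speed_mm_s=v, so2=s, vessel_class=vc["vessel_class"],
            region=vc["region"], chb_g_per_L=float(vc["chb_g_per_L"]),
        ))
    return PhantomScene(
        field_size_um=(fx, fy),
        pixel_spacing_um=tuple(cfg["pixel_spacing_um"]),
        vessels=vessels,
        noise_snr_db=cfg.get("noise_snr_db", 25.0),
        psf_fwhm_um=float(cfg.get("psf_fwhm_um", 8.0)),
        seed=seed,
    )


def _pixel_centers_um(scene: PhantomScene) -> tuple[np.ndarray, np.ndarray]:
    ny, nx = scene.grid_shape
    sx, sy = scene.pixel_spacing_um
    x = (np.arange(nx) + 0.5) * sx
    y = (np.arange(ny) + 0.5) * sy
    return np.meshgrid(x, y)


def _distance_to_polyline(px: np.ndarray, py: np.ndarray,
                          polyline: np.ndarray) -> np.ndarray:
    """Pointwise distance from pixel centers to a polyline (um)."""
    d2 = np.full(px.shape, np.inf)
    for a, b in zip(polyline[:-1], polyline[1:]):
        ab = b - a
        den = float(ab @ ab)
        if den == 0.0:
            t = np.zeros_like(px)
        else:
            t = ((px - a[0]) * ab[0] + (py - a[1]) * ab[1]) / den
            t = np.clip(t, 0.0, 1.0)
        qx = a[0] + t * ab[0]
        qy = a[1] + t * ab[1]
        d2 = np.minimum(d2, (px - qx) ** 2 + (py - qy) ** 2)
    return np.sqrt(d2)


def vessel_mask(scene: PhantomScene, vessel: VesselSpec) -> np.ndarray:
    """Ground-truth boolean mask of one vessel on the scene raster."""
    px, py = _pixel_centers_um(scene)
    return _distance_to_polyline(px, py, vessel.centerline_um) <= vessel.radius_um


def vessel_bbox_roi(scene: PhantomScene, vessel: VesselSpec,
                    pad_factor: float = 1.2) -> tuple[int, int, int, int]:
    """Bounding-box ROI of a vessel padded by ``pad_factor`` ("slightly
    larger than the vessel of interest")."""
    ny, nx = scene.grid_shape
    sx, sy = scene.pixel_spacing_um
    pts = vessel.centerline_um
    r = vessel.radius_um
    x0, x1 = pts[:, 0].min() - r, pts[:, 0].max() + r
    y0, y1 = pts[:, 1].min() - r, pts[:, 1].max() + r
    cx, cy = (x0 + x1) / 2, (y0 + y1) / 2
    hx, hy = (x1 - x0) / 2 * pad_factor, (y1 - y0) / 2 * pad_factor
    c0 = max(int(np.floor((cx - hx) / sx)), 0)
    c1 = min(int(np.ceil((cx + hx) / sx)), nx)
    r0 = max(int(np.floor((cy - hy) / sy)), 0)
    r1 = min(int(np.ceil((cy + hy) / sy)), ny)
    return r0, r1, c0, c1


def render_dual_wavelength(scene: PhantomScene,
                           ext: ExtinctionTable = DEFAULT_EXTINCTION,
                           ) -> DualWavelengthImage:
    """Render the spectroscopic channels of a phantom scene.

    Amplitude at pixel p and wavelength lambda is
    ``gain * C_Hb(p) * [sO2(p) * eps_HbO2 + (1 - sO2(p)) * eps_Hb]``,
    blurred by a Gaussian of FWHM ``scene.psf_fwhm_um`` and, when
    ``scene.noise_snr_db`` is set, perturbed by additive Gaussian noise whose
    standard deviation is the vessel-pixel RMS amplitude divided by
    ``10^(SNR/20)``.  Channels are clipped at zero.  The noiseless render is
    exactly invertible by :func:`pamox.oximetry.unmix` with the same table.
    """
    for wl in (532, 558):
        if wl not in ext.wavelengths_nm:
            raise KeyError(f"extinction table lacks {wl} nm")
    px, py = _pixel_centers_um(scene)
    channels = {532: np.zeros(px.shape), 558: np.zeros(px.shape)}
    occupied = np.zeros(px.shape, dtype=bool)
    for v in scene.vessels:
        m = _distance_to_polyline(px, py, v.centerline_um) <= v.radius_um
        m &= ~occupied            # first vessel wins where tubes touch
        occupied |= m
        for wl in (532, 558):
            mix = v.so2 * ext.eps_oxy[wl] + (1.0 - v.so2) * ext.eps_deoxy[wl]
            channels[wl][m] = RENDER_GAIN * v.chb_g_per_L * mix

    sx, sy = scene.pixel_spacing_um
    if scene.psf_fwhm_um > 0:
        sigma = scene.psf_fwhm_um / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        for wl in (532, 558):
            channels[wl] = gaussian_filter(channels[wl],
                                           sigma=(sigma / sy, sigma / sx))
    if scene.noise_snr_db is not None:
        rng = np.random.default_rng(scene.seed)
        signal = channels[532][occupied]
        rms = float(np.sqrt(np.mean(signal ** 2))) if occupied.any() else 1.0
        sd = rms / 10.0 ** (scene.noise_snr_db / 20.0)
        for wl in (532, 558):
            channels[wl] = channels[wl] + rng.normal(0.0, sd, channels[wl].shape)
    for wl in (532, 558):
        channels[wl] = np.clip(channels[wl], 0.0, None)
    return DualWavelengthImage(a532=channels[532], a558=channels[558],
                               pixel_spacing_um=scene.pixel_spacing_um)


def render_aline_raster(scene: PhantomScene,
                        ext: ExtinctionTable = DEFAULT_EXTINCTION,
                        wavelength_nm: int = 532,
                        n_samples: int = 64,
                        carrier_period_samples: int = 8) -> np.ndarray:
    """Raw A-line raster whose per-line envelope peak equals the rendered
    amplitude map: a Gaussian-modulated carrier scaled per pixel.

    Returns an (n_rows, n_cols, n_samples) array; the envelope/projection
    chain in :mod:`pamox.pam_signal` recovers the amplitude map from it.
    """
    img = render_dual_wavelength(scene, ext)
    amp = img.channel(wavelength_nm)
    t = np.arange(n_samples, dtype=float)
    t0 = n_samples / 2.0
    sigma = n_samples / 6.0
    env = np.exp(-((t - t0) ** 2) / (2.0 * sigma ** 2))
    carrier = np.cos(2.0 * np.pi * t / carrier_period_samples)
    return amp[:, :, None] * (env * carrier)[None, None, :]


# ---------------------------------------------------------------------------
# A-line ensembles (correlation channel)
# ---------------------------------------------------------------------------

def render_aline_ensemble(vessel: VesselSpec | float,
                          dt_s: float = 1e-4,
                          n_lines: int = 64,
                          cal: FlowCalibration = FlowCalibration(),
                          seed: int = 0,
                          n_samples: int = 256,
                          noise_snr_db: Optional[float] = None,
                          ) -> AlineEnsemble:
    """Generate an A-line ensemble whose inter-line correlation decays as
    ``exp(-(tau / tau_c)^2)`` with ``tau_c = cal.k_flow_mm / peak_speed``.

    ``vessel`` may be a :class:`VesselSpec` or a bare peak speed in mm/s.
    The ensemble is built from an orthonormal zero-mean signal basis combined
    through the Cholesky factor of the target lag-correlation matrix, so the
    noiseless empirical correlation matches the model at machine precision;
    zero speed produces identical lines (no decorrelation beyond noise).
    """
    if dt_s <= 0:
        raise ValueError("dt_s must be positive")
    if n_lines < 16:
        raise ValueError("need at least 16 lines")
    if n_samples < n_lines + 1:
        raise ValueError("n_samples must exceed n_lines")
    speed = vessel.peak_speed_mm_s if isinstance(vessel, VesselSpec) else float(vessel)
    if speed < 0:
        raise ValueError("speed must be nonnegative")

    rng = np.random.default_rng(seed)
    # orthonormal zero-mean basis: QR of a Gaussian block with the constant
    # direction projected out, so Pearson correlations are exact.
    g = rng.standard_normal((n_samples, n_lines))
    g -= g.mean(axis=0, keepdims=True)
    q, _ = np.linalg.qr(g)
    basis = q.T                                   # (n_lines, n_samples)

    if speed == 0.0:
        lines = np.tile(basis[0], (n_lines, 1))
    else:
        tau_c = cal.k_flow_mm / speed
        lag = np.abs(np.subtract.outer(np.arange(n_lines), np.arange(n_lines)))
        corr = np.exp(-((lag * dt_s) / tau_c) ** 2)
        corr[np.diag_indices(n_lines)] += 1e-9    # regularize Gaussian kernel
        chol = cholesky(corr, lower=True)
        lines = chol @ basis

    if noise_snr_db is not None:
        rms = float(np.sqrt(np.mean(lines ** 2)))
        sd = rms / 10.0 ** (noise_snr_db / 20.0)
        lines = lines + rng.normal(0.0, sd, lines.shape)
    return AlineEnsemble(lines=lines, dt_s=dt_s)


# ---------------------------------------------------------------------------
# Respirometry traces (Clark electrode)
# ---------------------------------------------------------------------------

@dataclass
class RespiroParams:
    """Parameters of a synthetic Clark-electrode O2 trace.

    Defaults mirror the respirometry protocol: 0.05 mg mitochondrial protein
    in 0.5 mL buffer, substrate-triggered respiration, 100 nmol ADP starting
    State 3, State 4 after ADP exhaustion, DNP-uncoupled respiration.  Slopes
    are in nmol O2/mL/min; the generated State-3 slope magnitude exceeds the
    State-4 magnitude.
    """

    protein_mg: float = 0.05
    chamber_ml: float = 0.5
    o2_start_nmol_per_ml: float = 200.0
    segment_slopes: dict = field(default_factory=lambda: {
        "basal": -1.0, "state2": -3.0, "state3": -12.0,
        "state4": -3.0, "uncoupled": -10.0,
    })
    event_times_s: dict = field(default_factory=lambda: {
        "substrate": 60.0, "ADP": 180.0, "DNP": 700.0,
    })
    adp_exhaustion_s: float = 400.0
    duration_s: float = 900.0
    dt_s: float = 1.0
    noise_sd: float = 0.0
    seed: int = 0
    annotate_exhaustion: bool = False

    def __post_init__(self) -> None:
        times = [self.event_times_s[k] for k in ("substrate", "ADP", "DNP")
                 if k in self.event_times_s]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("event times must be strictly increasing")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if "ADP" in self.event_times_s and not (
                self.event_times_s["ADP"] < self.adp_exhaustion_s):
            raise ValueError("ADP exhaustion must follow the ADP addition")
        if abs(self.segment_slopes.get("state3", -1)) < abs(
                self.segment_slopes.get("state4", 0)):
            raise ValueError("State-3 slope magnitude must be >= State 4")


def synth_respiro_trace(params: RespiroParams | None = None) -> RespiroTrace:
    """Piecewise-linear O2(t) with slope changes exactly at event times.

    Raises ``ValueError("chamber anoxia")`` if the parameters would drive the
    chamber O2 below zero before the trace ends.  Ground-truth slopes and the
    ADP-exhaustion time are recorded in ``trace.meta``.
    """
    p = params or RespiroParams()
    t = np.arange(0.0, p.duration_s + p.dt_s / 2, p.dt_s)
    # breakpoints: (time, state) in chronological order
    breaks: list[tuple[float, str]] = [(0.0, "basal")]
    if "substrate" in p.event_times_s:
        breaks.append((p.event_times_s["substrate"], "state2"))
    if "ADP" in p.event_times_s:
        breaks.append((p.event_times_s["ADP"], "state3"))
        breaks.append((p.adp_exhaustion_s, "state4"))
    if "DNP" in p.event_times_s:
        breaks.append((p.event_times_s["DNP"], "uncoupled"))
    breaks.sort(key=lambda b: b[0])

    o2 = np.empty_like(t)
    level = p.o2_start_nmol_per_ml
    for i, (t0, state) in enumerate(breaks):
        t1 = breaks[i + 1][0] if i + 1 < len(breaks) else t[-1] + p.dt_s
        sel = (t >= t0) & (t < t1) if i + 1 < len(breaks) else (t >= t0)
        slope_per_s = p.segment_slopes[state] / 60.0
        o2[sel] = level + slope_per_s * (t[sel] - t0)
        level = level + slope_per_s * (t1 - t0)
    if o2.min() < 0:
        raise ValueError("chamber anoxia")

    if p.noise_sd > 0:
        rng = np.random.default_rng(p.seed)
        o2 = o2 + rng.normal(0.0, p.noise_sd, o2.shape)

    events = [(p.event_times_s[k], k) for k in ("substrate", "ADP", "DNP")
              if k in p.event_times_s]
    if p.annotate_exhaustion and "ADP" in p.event_times_s:
        events.append((p.adp_exhaustion_s, "adp_exhausted"))
    events.sort()
    return RespiroTrace(
        time_s=t, o2_nmol_per_ml=o2, events=events,
        protein_mg=p.protein_mg, chamber_ml=p.chamber_ml,
        meta={"segment_slopes": dict(p.segment_slopes),
              "adp_exhaustion_s": p.adp_exhaustion_s},
    )


# ---------------------------------------------------------------------------
# Fluorometry traces
# ---------------------------------------------------------------------------

@dataclass
class FluoroParams:
    """Parameters of a synthetic fluorometer trace.

    kind="amplex": linear rise at ``rates_au_per_s[i]`` over the segments
    [start, rotenone), [rotenone, antimycin), [antimycin, end) — fluorescence
    recorded 400 s before rotenone, antimycin after another 200 s by default.
    kind="mitosox": linear rise at ``initial_rate_au_per_s`` until
    ``saturation_time_s`` (25 min default) then a smooth C1 exponential
    saturation.  kind="rh123": baseline plateau for 300 s, quenched plateau
    after the substrate addition, partial recovery after CCCP.
    """

    kind: str = "amplex"
    baseline_level_au: float | None = None   # per-kind default when None
    rates_au_per_s: tuple[float, ...] = (0.8, 0.3, 0.05)
    event_times_s: dict = field(default_factory=dict)
    initial_rate_au_per_s: float = 5.0
    saturation_time_s: float = 1500.0
    saturation_tau_s: float = 300.0
    quenched_level_au: float = 60.0
    release_level_au: float = 95.0
    settle_tau_s: float = 15.0
    duration_s: float = 0.0
    dt_s: float = 1.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        defaults = {
            "amplex": {"rotenone": 400.0, "antimycin": 600.0},
            "mitosox": {},
            "rh123": {"substrate": 300.0, "cccp": 800.0},
        }
        if self.kind not in defaults:
            raise ValueError(f"unknown fluorometry kind {self.kind!r}")
        if self.baseline_level_au is None:
            self.baseline_level_au = {"amplex": 50.0, "mitosox": 20.0,
                                      "rh123": 100.0}[self.kind]
        if self.kind == "rh123" and self.quenched_level_au >= self.baseline_level_au:
            raise ValueError("RH-123 quenched plateau must sit below baseline")
        if not self.event_times_s:
            self.event_times_s = dict(defaults[self.kind])
        required = set(defaults[self.kind])
        if self.kind == "rh123":
            required = {"substrate"}            # CCCP optional
        missing = required - set(self.event_times_s)
        extra = set(self.event_times_s) - set(defaults[self.kind])
        if missing or extra:
            raise ValueError(
                f"event set {sorted(self.event_times_s)} does not match kind "
                f"{self.kind!r}")
        if self.duration_s <= 0:
            self.duration_s = {"amplex": 800.0, "mitosox": 2400.0,
                               "rh123": 1000.0}[self.kind]
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


def synth_fluoro_trace(params: FluoroParams | None = None) -> FluoroTrace:
    """Generate a fluorometer trace with the kind-specific event structure.

    Ground-truth read-outs (segment rates, plateau levels, quench depth) are
    recorded in ``trace.meta``.
    """
    p = params or FluoroParams()
    t = np.arange(0.0, p.duration_s + p.dt_s / 2, p.dt_s)
    meta: dict = {}

    if p.kind == "amplex":
        t_rot = p.event_times_s["rotenone"]
        t_ant = p.event_times_s["antimycin"]
        if not 0 < t_rot < t_ant:
            raise ValueError("rotenone must precede antimycin A")
        f = np.empty_like(t)
        bounds = [0.0, t_rot, t_ant, t[-1] + p.dt_s]
        level = p.baseline_level_au
        for rate, (t0, t1) in zip(p.rates_au_per_s, zip(bounds, bounds[1:])):
            sel = (t >= t0) & (t < t1)
            f[sel] = level + rate * (t[sel] - t0)
            level = level + rate * (t1 - t0)
        meta["rates_au_per_s"] = tuple(p.rates_au_per_s)
        events = [(t_rot, "rotenone"), (t_ant, "antimycin")]

    elif p.kind == "mitosox":
        s = p.initial_rate_au_per_s
        ts = p.saturation_time_s
        f = np.where(
            t <= ts,
            p.baseline_level_au + s * t,
            p.baseline_level_au + s * ts
            + s * p.saturation_tau_s * (1.0 - np.exp(-(t - ts) / p.saturation_tau_s)),
        )
        meta["initial_rate_au_per_s"] = s
        meta["saturation_time_s"] = ts
        events = []

    else:  # rh123
        t_sub = p.event_times_s["substrate"]
        if t_sub < 300.0:
            raise ValueError("RH-123 baseline must be at least 300 s")
        t_cccp = p.event_times_s.get("cccp")
        f = np.full_like(t, p.baseline_level_au)
        settle = lambda tt, t0, lo, hi: hi + (lo - hi) * np.exp(-(tt - t0) / p.settle_tau_s)
        sel = t >= t_sub
        f[sel] = settle(t[sel], t_sub, p.baseline_level_au, p.quenched_level_au)
        events = [(t_sub, "substrate")]
        if t_cccp is not None:
            sel = t >= t_cccp
            f[sel] = settle(t[sel], t_cccp, p.quenched_level_au, p.release_level_au)
            events.append((t_cccp, "cccp"))
        meta["delta_f_au"] = p.baseline_level_au - p.quenched_level_au
        if t_cccp is not None:
            meta["cccp_release_au"] = p.release_level_au - p.quenched_level_au

    if p.noise_sd > 0:
        rng = np.random.default_rng(p.seed)
        f = f + rng.normal(0.0, p.noise_sd, f.shape)
    return FluoroTrace(kind=p.kind, time_s=t, fluorescence_au=f,
                       events=events, meta=meta)
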