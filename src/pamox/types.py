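"""Shared domain containers for the PAM metabolic-quantification pipeline.

Conventions used throughout the package:

* Image grids are row-major 2-D arrays indexed ``[row, col]`` with 0-based
  indices; physical coordinates are micrometres with ``x`` along columns and
  ``y`` along rows.  Regions of interest are half-open rectangles
  ``(r0, r1, c0, c1)``.
* All physical quantities carry their unit in the field name
  (``diameter_um``, ``peak_speed_mm_s``, ``chb_g_per_L``, ``dt_s`` ...).
* Oxygen saturation (sO2) is a fraction in [0, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

VESSEL_CLASSES = ("artery", "vein", "unknown")
REGIONS = ("ipsilateral", "contralateral")


class SceneGeometryError(ValueError):
    """Raised when a phantom scene is geometrically inconsistent."""


@dataclass
class VesselSpec:
    """Ground-truth description of one vessel in a phantom scene.

    The centerline is a polyline of (x, y) points in micrometres in scene
    coordinates; the vessel is the set of points within ``diameter_um / 2``
    of the polyline.
    """

    id: str
    centerline_um: np.ndarray            # (N, 2) columns (x_um, y_um)
    diameter_um: float
    peak_speed_mm_s: float
    so2: float
    vessel_class: str                    # "artery" | "vein"
    region: str                          # "ipsilateral" | "contralateral"
    chb_g_per_L: float

    def __post_init__(self) -> None:
        self.centerline_um = np.asarray(self.centerline_um, dtype=float)
        if self.centerline_um.ndim != 2 or self.centerline_um.shape[1] != 2:
            raise SceneGeometryError("centerline must be an (N, 2) polyline")
        if self.centerline_um.shape[0] < 2:
            raise SceneGeometryError("centerline needs at least two points")
        if not self.diameter_um > 0:
            raise ValueError("diameter_um must be positive")
        if self.peak_speed_mm_s < 0:
            raise ValueError("peak_speed_mm_s must be nonnegative")
        if not 0.0 <= self.so2 <= 1.0:
            raise ValueError("so2 must lie in [0, 1]")
        if self.vessel_class not in ("artery", "vein"):
            raise ValueError(f"unknown vessel_class {self.vessel_class!r}")
        if self.region not in REGIONS:
            raise ValueError(f"unknown region {self.region!r}")
        if not self.chb_g_per_L > 0:
            raise ValueError("chb_g_per_L must be positive")

    @property
    def radius_um(self) -> float:
        return self.diameter_um / 2.0


@dataclass
class PhantomScene:
    """A fully specified synthetic imaging field with known ground truth.

    ``seed`` determines every stochastic aspect of any rendering derived
    from the scene; two scenes with equal fields render identically.
    """

    field_size_um: tuple[float, float]       # (x extent, y extent)
    pixel_spacing_um: tuple[float, float]    # (x spacing, y spacing)
    vessels: list[VesselSpec]
    noise_snr_db: Optional[float] = 25.0     # None => noiseless
    psf_fwhm_um: float = 8.0
    seed: int = 0
    overlap_warning: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        fx, fy = self.field_size_um
        sx, sy = self.pixel_spacing_um
        if fx <= 0 or fy <= 0 or sx <= 0 or sy <= 0:
            raise SceneGeometryError("field size and pixel spacing must be positive")
        if self.psf_fwhm_um < 0:
            raise SceneGeometryError("psf_fwhm_um must be nonnegative")
        for v in self.vessels:
            pts = v.centerline_um
            r = v.radius_um
            if (pts[:, 0] - r < 0).any() or (pts[:, 0] + r > fx).any() \
                    or (pts[:, 1] - r < 0).any() or (pts[:, 1] + r > fy).any():
                raise SceneGeometryError(
                    f"vessel {v.id!r} extends outside the {fx}x{fy} um field")
        if self._vessels_overlap():
            self.overlap_warning = True
            warnings.warn("vessel centerlines closer than the sum of radii",
                          stacklevel=2)

    def _vessels_overlap(self) -> bool:
        samples = [_densify(v.centerline_um, step_um=2.0) for v in self.vessels]
        for i in range(len(self.vessels)):
            for j in range(i + 1, len(self.vessels)):
                limit = self.vessels[i].radius_um + self.vessels[j].radius_um
                d2 = np.min(
                    ((samples[i][:, None, :] - samples[j][None, :, :]) ** 2).sum(-1))
                if d2 < limit ** 2:
                    return True
        return False

    @property
    def grid_shape(self) -> tuple[int, int]:
        """(n_rows, n_cols) of the rendered raster."""
        fx, fy = self.field_size_um
        sx, sy = self.pixel_spacing_um
        return int(round(fy / sy)), int(round(fx / sx))


def _densify(polyline: np.ndarray, step_um: float) -> np.ndarray:
    """Resample a polyline at roughly ``step_um`` spacing (keeps vertices)."""
    out = []
    for a, b in zip(polyline[:-1], polyline[1:]):
        n = max(int(np.ceil(np.linalg.norm(b - a) / step_um)), 1)
        t = np.linspace(0.0, 1.0, n, endpoint=False)[:, None]
        out.append(a[None, :] * (1 - t) + b[None, :] * t)
    out.append(polyline[-1:])
    return np.vstack(out)


@dataclass
class Aline:
    """One depth-resolved photoacoustic record (single laser pulse)."""

    samples: np.ndarray
    sample_interval_s: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size < 8:
            raise ValueError("A-line must be 1-D with at least 8 samples")
        if not np.isfinite(self.samples).all():
            raise ValueError("A-line contains non-finite samples")
        if self.sample_interval_s <= 0:
            raise ValueError("sample_interval_s must be positive")


@dataclass
class AmplitudeMap:
    """2-D projected envelope-amplitude image at one wavelength."""

    values: np.ndarray
    pixel_spacing_um: tuple[float, float]
    wavelength_nm: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("amplitude map must be 2-D")
        if (self.values < 0).any():
            raise ValueError("amplitude map must be nonnegative")


@dataclass
class DualWavelengthImage:
    """Co-registered nonnegative amplitude maps at 532 and 558 nm."""

    a532: np.ndarray
    a558: np.ndarray
    pixel_spacing_um: tuple[float, float]

    def __post_init__(self) -> None:
        self.a532 = np.asarray(self.a532, dtype=float)
        self.a558 = np.asarray(self.a558, dtype=float)
        if self.a532.shape != self.a558.shape:
            raise ValueError("the two channels must share one raster shape")
        if (self.a532 < 0).any() or (self.a558 < 0).any():
            raise ValueError("amplitudes must be nonnegative")

    def channel(self, wavelength_nm: int) -> np.ndarray:
        if wavelength_nm == 532:
            return self.a532
        if wavelength_nm == 558:
            return self.a558
        raise KeyError(f"no channel at {wavelength_nm} nm")


@dataclass
class ExtinctionTable:
    """Molar extinction coefficients of oxy-/deoxy-hemoglobin per wavelength.

    Any two listed wavelengths must form an invertible 2x2 unmixing system.
    """

    wavelengths_nm: tuple[int, ...]
    eps_oxy: dict[int, float]
    eps_deoxy: dict[int, float]

    def __post_init__(self) -> None:
        for wl in self.wavelengths_nm:
            if self.eps_oxy[wl] <= 0 or self.eps_deoxy[wl] <= 0:
                raise ValueError("extinction coefficients must be positive")

    def matrix(self, wl_a: int, wl_b: int) -> np.ndarray:
        """2x2 system matrix [[eps_oxy(a), eps_deoxy(a)], [eps_oxy(b), eps_deoxy(b)]]."""
        for wl in (wl_a, wl_b):
            if wl not in self.wavelengths_nm:
                raise KeyError(f"wavelength {wl} nm not in extinction table")
        m = np.array([[self.eps_oxy[wl_a], self.eps_deoxy[wl_a]],
                      [self.eps_oxy[wl_b], self.eps_deoxy[wl_b]]], dtype=float)
        if abs(np.linalg.det(m)) < 1e-12 * abs(m).max() ** 2:
            raise ValueError("extinction system is singular for these wavelengths")
        return m


# Default table: tabulated hemoglobin molar extinction (M^-1 cm^-1) at the
# two excitation lines, from the standard published compilation.  532 nm is
# near-isosbestic (concentration-bearing channel); 558 nm separates the two
# species.  All phantom closure tests use this same table for generation and
# inversion, so results do not depend on the compilation chosen.
DEFAULT_EXTINCTION = ExtinctionTable(
    wavelengths_nm=(532, 558),
    eps_oxy={532: 44480.0, 558: 32620.0},
    eps_deoxy={532: 40584.0, 558: 53412.0},
)


@dataclass
class FlowCalibration:
    """Calibration of the correlation flowmeter.

    ``k_flow_mm`` relates peak speed to the decorrelation time of the
    A-line ensemble, ``v = k_flow / tau_c`` (units mm/s * s = mm); it is of
    the order of the optical focal-spot size.  ``max_lag_s`` bounds the lags
    used in fitting.
    """

    k_flow_mm: float = 0.002
    max_lag_s: float = 0.002

    def __post_init__(self) -> None:
        if self.k_flow_mm <= 0:
            raise ValueError("k_flow_mm must be positive")
        if self.max_lag_s <= 0:
            raise ValueError("max_lag_s must be positive")


@dataclass
class AlineEnsemble:
    """Repeated A-lines at one scan position; inter-line decorrelation
    encodes the flow speed."""

    lines: np.ndarray        # (n_lines, n_samples)
    dt_s: float              # repetition interval

    def __post_init__(self) -> None:
        self.lines = np.asarray(self.lines, dtype=float)
        if self.lines.ndim != 2 or self.lines.shape[0] < 16:
            raise ValueError("ensemble needs at least 16 lines")
        if self.dt_s <= 0:
            raise ValueError("dt_s must be positive")


@dataclass
class VesselMask:
    """Binary segmentation of one vessel inside a rectangular ROI."""

    mask: np.ndarray                         # bool, full map shape
    roi: tuple[int, int, int, int]           # half-open (r0, r1, c0, c1)
    source: Optional[AmplitudeMap] = None

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        r0, r1, c0, c1 = self.roi
        outside = self.mask.copy()
        outside[r0:r1, c0:c1] = False
        if outside.any():
            raise ValueError("mask pixels fall outside the ROI")
        if not self.mask.any():
            raise ValueError("mask is empty")

    @property
    def pixels(self) -> np.ndarray:
        """(K, 2) array of (row, col) foreground indices."""
        return np.argwhere(self.mask)

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())


@dataclass
class VesselMeasure:
    """Per-vessel hemodynamic measurements."""

    id: str
    mask: Optional[VesselMask] = None
    centerline_px: Optional[np.ndarray] = None     # ordered (row, col) path
    diameter_um: float = float("nan")
    so2: float = float("nan")
    peak_speed_mm_s: float = float("nan")
    vessel_class: str = "unknown"
    chb_g_per_L: float = float("nan")
    region: Optional[str] = None

    def __post_init__(self) -> None:
        if self.vessel_class not in VESSEL_CLASSES:
            raise ValueError(f"unknown vessel_class {self.vessel_class!r}")
        if np.isfinite(self.so2) and not 0.0 <= self.so2 <= 1.0:
            raise ValueError("so2 must lie in [0, 1] when set")


@dataclass
class RegionHemodynamics:
    """Per-hemicortex CBF / OEF / CMRO2 summary."""

    region: str
    cbf_ml_100g_min: float
    oef: float
    cmro2_ml_100g_min: float
    sa_o2: float
    sv_o2: float
    chb_g_per_L: float
    n_arteries: int
    n_veins: int
    flags: tuple[str, ...] = ()


@dataclass
class MetabolismConfig:
    """Constants for the regional metabolism formulas.

    xi is the oxygen-binding capacity of hemoglobin, 0.014 L O2 per gram of
    hemoglobin.  ``region_mass_g`` converts the summed arterial flux into a
    per-100-g perfusion rate (default 0.002 g for one hemicortical imaging
    region of a neonatal mouse).  Percentages are rounded half-up to
    integers.
    """

    xi_L_O2_per_g: float = 0.014
    region_mass_g: float = 0.002
    rounding: str = "half_up"

    def __post_init__(self) -> None:
        if self.xi_L_O2_per_g <= 0:
            raise ValueError("xi must be positive")
        if self.region_mass_g <= 0:
            raise ValueError("region_mass_g must be positive")


@dataclass
class RespiroTrace:
    """Clark-electrode oxygen trace with event annotations."""

    time_s: np.ndarray
    o2_nmol_per_ml: np.ndarray
    events: list[tuple[float, str]]          # (time_s, label)
    protein_mg: float
    chamber_ml: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.o2_nmol_per_ml = np.asarray(self.o2_nmol_per_ml, dtype=float)
        if self.time_s.ndim != 1 or self.time_s.shape != self.o2_nmol_per_ml.shape:
            raise ValueError("time and O2 arrays must be 1-D and equal length")
        if not (np.diff(self.time_s) > 0).all():
            raise ValueError("time must be strictly increasing")
        if self.protein_mg <= 0 or self.chamber_ml <= 0:
            raise ValueError("protein_mg and chamber_ml must be positive")

    def event_time(self, label: str) -> Optional[float]:
        for t, lab in self.events:
            if lab == label:
                return t
        return None


FLUORO_KINDS = ("amplex", "mitosox", "rh123")


@dataclass
class FluoroTrace:
    """Fluorometer trace (Amplex UltraRed / MitoSOX Red / RH-123)."""

    kind: str
    time_s: np.ndarray
    fluorescence_au: np.ndarray
    events: list[tuple[float, str]]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in FLUORO_KINDS:
            raise ValueError(f"unknown fluorometry kind {self.kind!r}")
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.fluorescence_au = np.asarray(self.fluorescence_au, dtype=float)
        if self.time_s.shape != self.fluorescence_au.shape:
            raise ValueError("time and fluorescence must be equal length")
        if not (np.diff(self.time_s) > 0).all():
            raise ValueError("time must be strictly increasing")

    def event_time(self, label: str) -> Optional[float]:
        for t, lab in self.events:
            if lab == label:
                return t
        return None


@dataclass
class OcrResult:
    """Per-sample respirometry read-outs (nmol O2 / mg protein / min)."""

    state3_ocr: float
    state4_ocr: float
    rcr: float
    uncoupled_ocr: Optional[float] = None
    basal_ocr: Optional[float] = None


@dataclass
class CalibrationCurve:
    """Linear fluorescence-vs-amount calibration (with intercept)."""

    additions_nmol: np.ndarray
    responses_au: np.ndarray
    slope_au_per_nmol: float
    intercept_au: float
    r2: float
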