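"""Raw A-line processing: analytic-signal envelope, amplitude projection,
and the relative hemoglobin-concentration map.

The vascular map is the per-pixel maximum of the Hilbert-transform envelope
of each A-line.  Relative total hemoglobin (C_Hb) is taken proportional to
the envelope amplitude at the near-isosbestic 532 nm line, with a single
user-supplied calibration constant; absolute calibration is a config input,
not computed here.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import hilbert

from .types import Aline, AmplitudeMap


def envelope(a: Aline | np.ndarray) -> np.ndarray:
    """Magnitude of the analytic signal of an A-line.

    Same length as the input and nonnegative everywhere; an all-zero input
    yields an all-zero envelope.  Values within about one carrier period of
    either end carry the usual analytic-signal edge artifact.
    """
    samples = a.samples if isinstance(a, Aline) else np.asarray(a, dtype=float)
    if samples.ndim != 1:
        raise ValueError("envelope expects a 1-D signal")
    if not np.isfinite(samples).all():
        raise ValueError("signal contains non-finite samples")
    return np.abs(hilbert(samples))


def amplitude_map(scan, wavelength_nm: int,
                  pixel_spacing_um: tuple[float, float] = (1.0, 1.0),
                  ) -> AmplitudeMap:
    """Project a rectangular raster of A-lines to a 2-D amplitude map.

    ``scan`` is either an (n_rows, n_cols, n_samples) array or a nested
    sequence of equal-length A-lines; each pixel becomes the maximum of that
    A-line's envelope.  A ragged raster is an error.
    """
    if isinstance(scan, np.ndarray):
        if scan.ndim != 3:
            raise ValueError("raster array must be (rows, cols, samples)")
        cube = np.asarray(scan, dtype=float)
    else:
        rows = []
        width = None
        for row in scan:
            lines = [l.samples if isinstance(l, Aline) else np.asarray(l, float)
                     for l in row]
            if width is None:
                width = len(lines)
            if len(lines) != width or len({l.size for l in lines}) > 1:
                raise ValueError("ragged raster")
            rows.append(np.stack(lines))
        if len({r.shape for r in rows}) > 1:
            raise ValueError("ragged raster")
        cube = np.stack(rows)
    env = np.abs(hilbert(cube, axis=-1))
    return AmplitudeMap(values=env.max(axis=-1),
                        pixel_spacing_um=pixel_spacing_um,
                        wavelength_nm=wavelength_nm)


def chb_map(iso_map: AmplitudeMap, k_chb: float) -> np.ndarray:
    """Relative hemoglobin-concentration map (g/L) from the 532 nm channel.

    C_Hb = k_chb * amplitude, clipped at zero.  ``k_chb`` is the
    instrument calibration in g/L per a.u. and must be positive.
    """
    if iso_map.wavelength_nm != 532:
        raise ValueError("C_Hb is derived from the 532 nm (near-isosbestic) map")
    if not k_chb > 0:
        raise ValueError("k_chb must be positive")
    return np.clip(k_chb * iso_map.values, 0.0, None)
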