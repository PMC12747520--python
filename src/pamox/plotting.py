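"""Quick-look plots for phantoms and instrument traces."""

from __future__ import annotations

import numpy as np

from .types import DualWavelengthImage, FluoroTrace, RespiroTrace


def plot_dual_wavelength(img: DualWavelengthImage, axes=None):
    """Side-by-side 532/558 nm amplitude maps."""
    import matplotlib.pyplot as plt

    if axes is None:
        _, axes = plt.subplots(1, 2, figsize=(10, 4))
    for ax, wl in zip(axes, (532, 558)):
        im = ax.imshow(img.channel(wl), cmap="magma")
        ax.set_title(f"{wl} nm amplitude")
        ax.figure.colorbar(im, ax=ax, shrink=0.8)
    return axes


def plot_trace(trace: RespiroTrace | FluoroTrace, ax=None):
    """Trace with event markers; works for O2 and fluorescence traces."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    if isinstance(trace, RespiroTrace):
        y, label = trace.o2_nmol_per_ml, "O2 (nmol/mL)"
    else:
        y, label = trace.fluorescence_au, "fluorescence (a.u.)"
    ax.plot(trace.time_s, y, lw=1)
    for t, name in trace.events:
        ax.axvline(t, color="0.6", ls="--", lw=0.8)
        ax.text(t, float(np.max(y)), name, rotation=90, va="top", fontsize=8)
    ax.set_xlabel("time (s)")
    ax.set_ylabel(label)
    return ax
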