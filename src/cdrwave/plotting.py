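"""Quick-look figures for kymographs, correlation maps and the collapse."""
from __future__ import annotations

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt
import numpy as np

from .containers import CorrelationMap, Kymograph
from .kinematics import VelocityAreaCurve, _collapse_model

__all__ = ["plot_kymograph", "plot_correlation_map", "plot_collapse"]


def plot_kymograph(kymo: Kymograph, ax=None, cmap: str = "gray"):
    """Render a kymograph with physical axes (time in min, space in µm)."""
    if ax is None:
        _, ax = plt.subplots()
    extent = [0, kymo.n_time * kymo.spacing_s / 60.0, 0, kymo.length_um]
    ax.imshow(kymo.values, origin="lower", aspect="auto", cmap=cmap,
              extent=extent)
    ax.set_xlabel("time (min)")
    ax.set_ylabel("arc length s (µm)" if kymo.periodic else "position (µm)")
    return ax


def plot_correlation_map(cm: CorrelationMap, ax=None):
    """Render c(Δs, Δt) symmetric about zero lag, diverging colormap."""
    if ax is None:
        _, ax = plt.subplots()
    extent = [cm.lags_s[0] / 60.0, cm.lags_s[-1] / 60.0,
              cm.lags_um[0], cm.lags_um[-1]]
    vmax = np.abs(cm.values).max()
    im = ax.imshow(cm.values, origin="lower", aspect="auto", cmap="RdBu_r",
                   vmin=-vmax, vmax=vmax, extent=extent)
    ax.set_xlabel(r"$\Delta t$ (min)")
    ax.set_ylabel(r"$\Delta s$ (µm)")
    plt.colorbar(im, ax=ax, label=r"$c(\Delta s, \Delta t)$")
    return ax


def plot_collapse(curve: VelocityAreaCurve, v0: float | None = None, ax=None):
    """Raw (a, v̄) points, box medians, and optionally the fitted law."""
    if ax is None:
        _, ax = plt.subplots()
    ax.plot(curve.raw_a, curve.raw_v, "k.", ms=3, alpha=0.4, label="raw")
    ok = np.isfinite(curve.bin_median)
    ax.plot(curve.bin_centers[ok], curve.bin_median[ok], "ro",
            label="box median (width 0.05)")
    if v0 is not None:
        a = np.linspace(0, 1, 200)
        ax.plot(a, _collapse_model(a, v0), "r-",
                label=rf"$v_0\sqrt{{1-\sqrt{{a}}}}$, $v_0$={v0:.3f}")
    ax.set_xlabel("normalized area a")
    ax.set_ylabel(r"mean velocity $\bar{v}$ (µm/s)")
    ax.legend(frameon=False)
    return ax
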