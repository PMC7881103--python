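"""Small plotting helpers (matplotlib) for state series and P-V cycles."""

from __future__ import annotations

import numpy as np

__all__ = ["plot_state_series", "plot_pv_loop", "plot_energy_ratio"]


def plot_state_series(series, columns=("N", "V", "P", "T"), axes=None):
    """Stacked time-series panels of selected state variables."""
    import matplotlib.pyplot as plt

    if axes is None:
        _, axes = plt.subplots(len(columns), 1, sharex=True, figsize=(8, 2 * len(columns)))
    for ax, col in zip(np.atleast_1d(axes), columns):
        ax.plot(series["time"], series[col], lw=0.7)
        ax.set_ylabel(col)
    np.atleast_1d(axes)[-1].set_xlabel("time (s)")
    return axes


def plot_pv_loop(loop, ax=None, **kwargs):
    """Closed loop in the pressure-volume phase plane."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    v = np.append(loop.V, loop.V[0])
    p = np.append(loop.P, loop.P[0])
    ax.plot(v, p, **kwargs)
    ax.set_xlabel(r"$\langle V\rangle_\phi$ (mm$^3$)")
    ax.set_ylabel(r"$\langle P\rangle_\phi$ (mm$^{-1}$ s$^{-2}$)")
    return ax


def plot_energy_ratio(curve, result=None, ax=None):
    """E/(kB*T) vs N with the fitted through-origin line."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.errorbar(curve["N"], curve["ratio"], yerr=curve.get("se"), fmt="o", ms=3)
    if result is not None:
        n = np.linspace(0, curve["N"].max() * 1.05, 50)
        ax.plot(n, result.slope * n, "k--",
                label=f"slope {result.slope:.2f} ({result.dof:.1f} d.o.f.)")
        ax.legend()
    ax.set_xlabel("N")
    ax.set_ylabel(r"$E/(k_B^* T)$")
    return ax
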