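"""Quick-look figures: cotyledon maps and correlation curves."""

from __future__ import annotations

import numpy as np

from .correlation import CorrelationFunction
from .io_formats import CotyledonMap

__all__ = ["plot_map", "plot_correlation"]


def plot_map(m: CotyledonMap, ax=None):
    """Blade outline, sector outlines and stomata on one axes (µm)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    cv = np.vstack([m.cotyledon.vertices, m.cotyledon.vertices[:1]])
    ax.plot(cv[:, 0], cv[:, 1], color="m", lw=1.2, label="cotyledon")
    for k, sec in enumerate(m.sectors):
        sv = np.vstack([sec.vertices, sec.vertices[:1]])
        ax.plot(sv[:, 0], sv[:, 1], color="g", lw=1.0, label="sector" if k == 0 else None)
    if m.n_stomata:
        ax.scatter(m.stomata[:, 0], m.stomata[:, 1], s=6, color="tab:blue", label="stomata")
    ax.set_aspect("equal")
    ax.set_xlabel("x (µm)")
    ax.set_ylabel("y (µm)")
    if m.label:
        ax.set_title(m.label)
    ax.legend(loc="upper right", fontsize=8)
    return ax


def plot_correlation(cf: CorrelationFunction, ax=None, label: str | None = None):
    """zeta(r) on a log distance axis, with the confidence band if present."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    ok = cf.defined
    r = cf.r_mid
    ax.axhline(0.0, color="0.6", lw=0.8)
    ax.plot(r[ok], cf.zeta[ok], marker="o", ms=3, lw=1.2, label=label)
    if cf.ci_lo is not None and cf.ci_hi is not None:
        band = ok & ~np.isnan(cf.ci_lo)
        ax.fill_between(r[band], cf.ci_lo[band], cf.ci_hi[band], alpha=0.25, lw=0)
    ax.set_xscale("log")
    ax.set_xlabel("distance r (µm)")
    ax.set_ylabel("spatial correlation ζ(r)")
    if label:
        ax.legend(fontsize=8)
    return ax
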