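"""Optional quick-look figures for patterns and envelope tests."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt

from .nullmodels import EnvelopeResult
from .ppcore import PointPattern

__all__ = ["plot_pattern", "plot_envelope"]


def plot_pattern(p: PointPattern, ax=None, **scatter_kw):
    """Scatter the pattern inside its window frame."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    w = p.window
    scatter_kw.setdefault("s", 8)
    scatter_kw.setdefault("color", "k")
    ax.scatter(p.points[:, 0], p.points[:, 1], **scatter_kw)
    ax.set_xlim(w.x_min, w.x_max)
    ax.set_ylim(w.y_min, w.y_max)
    ax.set_aspect("equal")
    ax.set_xlabel("x (m)")
    ax.set_ylabel("y (m)")
    if p.label:
        ax.set_title(p.label)
    return ax


def plot_envelope(e: EnvelopeResult, ax=None):
    """Observed g(r) over the shaded min-max null envelope."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    r = e.rgrid.values
    ax.fill_between(r, e.lower, e.upper, color="0.8", label=f"null ({e.nsim} sims)")
    ax.plot(r, e.observed, "k-", lw=1.5, label="observed")
    ax.axhline(1.0, color="0.5", ls=":", lw=0.8)
    ax.set_xlabel("r (m)")
    ax.set_ylabel("g(r)")
    ax.legend(frameon=False)
    return ax
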