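"""Optional matplotlib figures for the standard analytics outputs."""

from __future__ import annotations

import numpy as np

from .analytics import ClimbingCurve, SpeedAngleSeries


def plot_climbing_curve(curve: ClimbingCurve, ax=None, color="C0", label=None):
    """Across-trial mean climbing staircase with its s.e.m. band."""
    import matplotlib.pyplot as plt

    ax = ax or plt.gca()
    if curve.times.size:
        t = np.concatenate([[0], curve.times])
        m = np.concatenate([[0], curve.mean_counts])
        s = np.concatenate([[0], curve.sem_counts])
        ax.step(t, m, where="post", color=color, label=label)
        ax.fill_between(t, m - s, m + s, step="post", alpha=0.25, color=color, lw=0)
    ax.set_xlabel("time (s)")
    ax.set_ylabel(f"flies above {curve.target_height_mm:.0f} mm")
    ax.set_ylim(0, curve.n_flies + 0.5)
    return ax


def plot_speed_angle(series_list: list[SpeedAngleSeries], ax=None):
    """Scatter of frame-pair speed vs movement angle, split by direction."""
    import matplotlib.pyplot as plt

    ax = ax or plt.gca()
    speed = np.concatenate([s.valid_pairs[0] for s in series_list])
    theta = np.concatenate([s.valid_pairs[1] for s in series_list])
    up = theta > 0
    ax.scatter(theta[up], speed[up], s=6, alpha=0.4, color="tab:orange", label="θ > 0")
    ax.scatter(theta[~up], speed[~up], s=6, alpha=0.4, color="tab:gray", label="θ < 0")
    ax.set_xlabel("movement angle θ (deg)")
    ax.set_ylabel("speed (mm/s)")
    ax.legend(frameon=False)
    return ax


def plot_drop_scatter(drops, ax=None):
    """Pre-drop height vs drop size, with the maximum-possible-drop curve."""
    import matplotlib.pyplot as plt

    ax = ax or plt.gca()
    if drops:
        h = [d.pre_drop_height_mm for d in drops]
        s = [d.drop_mm for d in drops]
        ax.scatter(h, s, s=12, color="C3")
        lim = max(h) * 1.05
        grid = np.linspace(0, lim, 50)
        ax.plot(grid, grid, ls="--", color="k", lw=0.8)  # ratio = 1 boundary
    ax.set_xlabel("height before drop (mm)")
    ax.set_ylabel("drop size −Δy (mm)")
    return ax
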