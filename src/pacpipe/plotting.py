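"""Plotting helpers: comodulograms, circular phase histograms, MI-age trends."""

from __future__ import annotations

import numpy as np

from .metrics import BIN_CENTERS_DEG, PacMap


def plot_comodulogram(pac_map: PacMap, channel: str, metric: str = "mi_norm", ax=None):
    """Heatmap of a PAC metric over the (LF, HF) grid for one channel.

    Invalid pairs are blanked.  Returns the matplotlib Axes.
    """
    import matplotlib.pyplot as plt

    c = pac_map.ch_names.index(channel)
    grid = getattr(pac_map, metric)[c].T.copy()  # HF rows, LF columns
    grid[~pac_map.spec.valid_pair_mask.T] = np.nan
    if ax is None:
        _, ax = plt.subplots()
    spec = pac_map.spec
    mesh = ax.pcolormesh(spec.lf_centers, spec.hf_centers, grid, shading="nearest")
    ax.set_xlabel("phase frequency (Hz)")
    ax.set_ylabel("amplitude frequency (Hz)")
    ax.set_title(f"{channel} {metric}")
    plt.colorbar(mesh, ax=ax)
    return ax


def plot_phase_proportions(proportions: np.ndarray, ax=None, **polar_kwargs):
    """Circular bar plot of the 18-bin phase-max proportion vector."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(subplot_kw={"projection": "polar"})
    theta = np.deg2rad(BIN_CENTERS_DEG)
    ax.bar(theta, np.asarray(proportions), width=np.deg2rad(20.0), **polar_kwargs)
    return ax


def plot_mi_age(mean_minorm: np.ndarray, ages_months: np.ndarray, ax=None):
    """Median MI_norm in PAC+ cells per age, with interquartile shading."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ages = np.asarray(ages_months, dtype=float)
    vals = np.asarray(mean_minorm, dtype=float)
    uniq = np.unique(ages)
    med = [np.median(vals[ages == a]) for a in uniq]
    q25 = [np.percentile(vals[ages == a], 25) for a in uniq]
    q75 = [np.percentile(vals[ages == a], 75) for a in uniq]
    ax.plot(uniq, med, marker="o")
    ax.fill_between(uniq, q25, q75, alpha=0.3)
    ax.set_xlabel("age (months)")
    ax.set_ylabel("MI$_{norm}$ in PAC+ cells")
    return ax
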