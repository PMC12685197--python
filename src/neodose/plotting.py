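"""Step-function plots of dosing trajectories by cluster."""

from __future__ import annotations

import numpy as np


def plot_cluster_trajectories(results, drug: str, k: int, ax=None):
    """Draw each course's step curve colored by cluster assignment.

    ``results`` is a fitted :class:`neodose.study.StudyResults`.
    Returns the matplotlib Axes.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 4))
    data = results.stepplot_frame(drug, k)
    clusters = sorted(data["cluster"].unique())
    cmap = plt.get_cmap("tab10")
    colors = {c: cmap(i % 10) for i, c in enumerate(clusters)}
    for cid, grp in data.groupby("course_id", sort=True):
        lab = grp["cluster"].iloc[0]
        ax.step(grp["hour"], grp["dose"], where="post", color=colors[lab],
                alpha=0.6, linewidth=1)
    for c in clusters:
        ax.plot([], [], color=colors[c], label=f"cluster {c}")
    route = results.trajectories[drug][0].route if results.trajectories[drug] else "oral"
    unit = "mg/kg" if route == "oral" else "mg/kg/min"
    ax.set_xlabel("hours since first administration")
    ax.set_ylabel(f"standardized dose ({unit})")
    ax.set_title(f"{drug}, k={k}")
    ax.legend(loc="upper right", fontsize=8)
    return ax


def plot_window_profile(results, drug: str, ax=None):
    """SD-of-pairwise-distances profile with the chosen window marked."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3))
    sel = results.windows[drug]
    ax.plot(sel.profile["window"], sel.profile["sd_distance"], lw=1)
    ax.axvline(sel.chosen, color="red", ls="--",
               label=f"chosen {sel.chosen} h" + (" (override)" if sel.overridden else ""))
    if sel.overridden:
        ax.axvline(sel.argmax, color="gray", ls=":", label=f"argmax {sel.argmax} h")
    ax.set_xlabel("window (h)")
    ax.set_ylabel("SD of pairwise distances")
    ax.set_title(drug)
    ax.legend(fontsize=8)
    return ax
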