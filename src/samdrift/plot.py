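"""Plotting helpers: tissue diagrams, expression heatmaps on the tissue,
fitness trajectories and CNS pair scatters."""

from __future__ import annotations

import numpy as np

from .develop import Trajectory
from .tissue import Tissue

ZONE_COLORS = {"CZ": "#e5737f", "CZ_OC": "#b38cc9", "OC": "#7393e5",
               "other": "#e8e4da"}


def _poly_collection(tissue: Tissue, values=None, cmap="viridis"):
    from matplotlib.collections import PolyCollection
    polys = [np.asarray(c.polygon) for c in tissue.cells]
    pc = PolyCollection(polys, edgecolors="k", linewidths=0.5)
    if values is not None:
        pc.set_array(np.asarray(values))
        pc.set_cmap(cmap)
    return pc


def plot_tissue(tissue: Tissue, ax=None):
    """Zone map of a tissue with the L1 layer outlined in red."""
    import matplotlib.pyplot as plt
    if ax is None:
        _, ax = plt.subplots()
    pc = _poly_collection(tissue)
    pc.set_facecolor([ZONE_COLORS[c.zone] for c in tissue.cells])
    pc.set_edgecolor(["red" if c.is_l1 else "black" for c in tissue.cells])
    ax.add_collection(pc)
    ax.autoscale_view()
    ax.set_aspect("equal")
    return ax


def plot_expression(tissue: Tissue, trajectory: Trajectory, tf_type: int,
                    sample: int = -1, ax=None):
    """Protein concentration of one TF species painted on the tissue."""
    import matplotlib.pyplot as plt
    if ax is None:
        _, ax = plt.subplots()
    values = trajectory.P[sample, tf_type, :]
    pc = _poly_collection(tissue, values)
    ax.add_collection(pc)
    ax.autoscale_view()
    ax.set_aspect("equal")
    plt.colorbar(pc, ax=ax, label=f"P[{tf_type}]")
    return ax


def plot_fitness_history(fitness_matrix: np.ndarray, ax=None):
    """Max / median / IQR of population fitness per generation."""
    import matplotlib.pyplot as plt
    if ax is None:
        _, ax = plt.subplots()
    gens = np.arange(fitness_matrix.shape[0])
    ax.plot(gens, np.nanmax(fitness_matrix, axis=1), label="max")
    ax.plot(gens, np.nanmedian(fitness_matrix, axis=1), label="median")
    q25 = np.nanpercentile(fitness_matrix, 25, axis=1)
    q75 = np.nanpercentile(fitness_matrix, 75, axis=1)
    ax.fill_between(gens, q25, q75, alpha=0.3, label="IQR")
    ax.set_xlabel("generation")
    ax.set_ylabel("fitness")
    ax.legend()
    return ax


def plot_cns_pairs(pairs, ax=None):
    """CNS-set similarity vs expression Pearson distance per gene pair."""
    import matplotlib.pyplot as plt
    if ax is None:
        _, ax = plt.subplots()
    for rel, grp in pairs.groupby("relation"):
        ax.scatter(grp["cns_similarity"], grp["pearson_distance"],
                   label=rel or "unlabelled", alpha=0.7)
    ax.set_xlabel("CNS set similarity")
    ax.set_ylabel("Pearson distance of expression")
    ax.legend()
    return ax
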