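"""k-shell decomposition and group occupancy statistics.

A node's shell index k_s is the largest k such that it belongs to the
k-core (the maximal subgraph with all degrees >= k); the decomposition is
computed by iterative pruning on the binarized voxel network.  Per subject,
shell indices are normalized by that subject's maximum shell so nodes from
networks of different depth can be pooled.  Nodes are then pooled across
the subjects of a group, split by module (region name), binned into 15
normalized-shell bins, and the binned distributions of two groups are
compared per module by the sum of squared bin differences (SSE).

Histograms are normalized to fractions per (module, group) before the SSE:
group pools differ in node count, so raw counts would make the SSE
scale-dependent.  A raw-count mode is exposed for sensitivity checks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Hashable, Mapping, Sequence

import networkx as nx
import numpy as np

from .config import ValidationError

__all__ = [
    "ShellAssignment",
    "OccupancyHistogram",
    "kshell_decomposition",
    "normalize_shells",
    "occupancy_histogram",
    "pooled_group_histograms",
    "sse_between_groups",
    "plot_occupancy",
]

log = logging.getLogger(__name__)


@dataclass
class ShellAssignment:
    """Shell index per node and the network's maximum shell."""

    shells: dict[Hashable, int]
    k_max: int

    def normalized(self) -> dict[Hashable, float]:
        return normalize_shells(self)


def kshell_decomposition(G: nx.Graph) -> ShellAssignment:
    """Standard k-shell decomposition by iterative pruning.

    Repeatedly removes all nodes of degree <= k (cascading) to peel shell k
    for k = 0, 1, 2, ...; isolated nodes land in shell 0.  Runs on the whole
    (possibly disconnected) graph; the k_max-core is the innermost, most
    connected subgraph.
    """
    if G.number_of_nodes() == 0:
        raise ValidationError("cannot decompose an empty network")
    if any(u == v for u, v in G.edges()):
        raise ValidationError("self-loops are not allowed in the voxel network")
    degrees = dict(G.degree())
    remaining = set(G.nodes())
    shells: dict[Hashable, int] = {}
    k = 0
    while remaining:
        peel = [n for n in remaining if degrees[n] <= k]
        if not peel:
            k += 1
            continue
        while peel:
            n = peel.pop()
            if n not in remaining:
                continue
            remaining.discard(n)
            shells[n] = k
            for nb in G[n]:
                if nb in remaining:
                    degrees[nb] -= 1
                    if degrees[nb] <= k:
                        peel.append(nb)
    return ShellAssignment(shells, max(shells.values()))


def normalize_shells(assign: ShellAssignment) -> dict[Hashable, float]:
    """Map each node to k_s / k_max in (0, 1]; shell-0 nodes map to 0, flagged."""
    if assign.k_max < 1:
        raise ValidationError(
            "k_max = 0 (edgeless network); normalized shells are undefined"
        )
    n_isolated = sum(1 for v in assign.shells.values() if v == 0)
    if n_isolated:
        log.warning("%d isolated (shell-0) nodes map to normalized shell 0", n_isolated)
    return {n: k / assign.k_max for n, k in assign.shells.items()}


@dataclass
class OccupancyHistogram:
    """Binned normalized-shell occupancy for one (module, group) pool.

    Bin b (1-based) covers [(b-1)/n_bins, b/n_bins), the last bin closing
    at 1 inclusive.  ``masses`` sum to 1; ``counts`` are the raw node
    counts.
    """

    module: str
    group: str
    counts: np.ndarray
    n_bins: int

    @property
    def n_nodes(self) -> int:
        return int(self.counts.sum())

    @property
    def masses(self) -> np.ndarray:
        return self.counts / self.counts.sum()

    @property
    def modal_bin(self) -> int:
        """1-based index of the heaviest bin (first on ties)."""
        return int(np.argmax(self.counts)) + 1

    @property
    def bin_edges(self) -> np.ndarray:
        return np.linspace(0.0, 1.0, self.n_bins + 1)


def _bin_values(values: np.ndarray, n_bins: int) -> np.ndarray:
    idx = np.minimum((np.asarray(values) * n_bins).astype(int), n_bins - 1)
    return np.bincount(idx, minlength=n_bins)


def occupancy_histogram(
    assignments: Sequence[tuple[ShellAssignment, Mapping[Hashable, str]]],
    group: str,
    n_bins: int = 15,
) -> dict[str, OccupancyHistogram]:
    """Pool subjects' nodes, split by module, bin by normalized shell.

    ``assignments`` holds per subject the shell assignment and a node ->
    module-name mapping.  Modules with an empty pool are simply absent from
    the result (missing, not zero).
    """
    if n_bins < 1:
        raise ValidationError("n_bins must be >= 1")
    if not assignments:
        raise ValidationError("need at least one subject assignment")
    pooled: dict[str, list[float]] = {}
    for assign, modules in assignments:
        norm = normalize_shells(assign)
        for node, value in norm.items():
            if node not in modules:
                raise ValidationError(f"node {node!r} has no module label")
            pooled.setdefault(modules[node], []).append(value)
    return {
        module: OccupancyHistogram(module, group, _bin_values(np.array(vals), n_bins), n_bins)
        for module, vals in pooled.items()
    }


def pooled_group_histograms(
    per_group: Mapping[str, Sequence[tuple[ShellAssignment, Mapping[Hashable, str]]]],
    n_bins: int = 15,
) -> dict[str, dict[str, OccupancyHistogram]]:
    """Occupancy histograms for several groups at once: group -> module -> hist."""
    return {g: occupancy_histogram(assigns, g, n_bins) for g, assigns in per_group.items()}


def sse_between_groups(
    hists: Mapping[str, Mapping[str, OccupancyHistogram]],
    normalized: bool = True,
) -> dict[tuple[str, tuple[str, str]], float]:
    """SSE of occupancy distributions per module for every group pair.

    Keys are (module, (group1, group2)) with the group pair sorted.  A
    module missing from either group's pool is skipped and logged.  With
    ``normalized=False`` the raw counts are compared instead (sensitivity
    mode).
    """
    out: dict[tuple[str, tuple[str, str]], float] = {}
    for g1, g2 in combinations(sorted(hists), 2):
        modules = set(hists[g1]) | set(hists[g2])
        for module in sorted(modules):
            h1 = hists[g1].get(module)
            h2 = hists[g2].get(module)
            if h1 is None or h2 is None:
                log.info("module %s missing in group %s; SSE pair skipped", module, g1 if h1 is None else g2)
                continue
            if h1.n_bins != h2.n_bins:
                raise ValidationError("histograms must share n_bins for an SSE comparison")
            a = h1.masses if normalized else h1.counts.astype(float)
            b = h2.masses if normalized else h2.counts.astype(float)
            out[(module, (g1, g2))] = float(np.sum((a - b) ** 2))
    return out


def plot_occupancy(
    hists: Mapping[str, Mapping[str, OccupancyHistogram]],
    modules: Sequence[str] | None = None,
    path: str | None = None,
):
    """Bar plots of per-module occupancy, one panel per group (optional)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    groups = sorted(hists)
    fig, axes = plt.subplots(1, len(groups), figsize=(4 * len(groups), 3), squeeze=False)
    for ax, g in zip(axes[0], groups):
        mods = modules or sorted(hists[g])
        n_mod = len(mods)
        for i, module in enumerate(mods):
            h = hists[g].get(module)
            if h is None:
                continue
            centres = (np.arange(h.n_bins) + 0.5) / h.n_bins
            width = 0.9 / (h.n_bins * n_mod)
            ax.bar(centres + (i - n_mod / 2) * width, h.masses, width=width, label=module)
        ax.set_title(g)
        ax.set_xlabel("normalized shell $k_s/k_{max}$")
        ax.set_ylabel("occupancy")
        ax.legend(fontsize=6)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
        return None
    return fig
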