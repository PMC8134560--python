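"""Subject-level network construction at the voxel and fROI scales.

Active voxels are partitioned into functional regions of interest (fROIs):
connected components of the active mask restricted to a single anatomical
label.  Voxels in excluded labels (visual cortex) are dropped; active voxels
with background label are kept in flagged "unlabeled" fROIs so no active
signal silently disappears.

The voxel network places a binary link between voxels i, j whenever the
absolute Pearson correlation of their BOLD series reaches theta.  The fROI
network aggregates cross-fROI voxel links::

    W_ij = (# voxel links between fROI i and fROI j) / (S_i + S_j)

with S the fROI sizes in voxels; intra-fROI links never contribute.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import ndimage

from .config import ValidationError

__all__ = [
    "LabelMap",
    "FroiNodes",
    "VoxelNetwork",
    "label_frois",
    "voxel_correlations",
    "build_voxel_network",
    "froi_weights",
    "region_network",
]

log = logging.getLogger(__name__)

UNLABELED = "unlabeled"


@dataclass
class LabelMap:
    """3D integer anatomical label volume; label 0 is background."""

    labels: np.ndarray
    names: dict[int, str]
    excluded: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValidationError("label volume must be 3D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValidationError("label volume must be integer-valued")
        present = set(np.unique(self.labels)) - {0}
        missing = present - set(self.names)
        if missing:
            raise ValidationError(f"label ids {sorted(missing)} have no name table entry")
        self.excluded = frozenset(self.excluded)

    def name_of(self, label_id: int) -> str:
        return UNLABELED if label_id == 0 else self.names[label_id]


@dataclass(frozen=True)
class Froi:
    froi_id: int
    region: str
    size: int
    flagged: bool = False  # True for unlabeled (background) fROIs


@dataclass
class FroiNodes:
    """Active voxels with their fROI assignment."""

    coords: np.ndarray  # (n, 3) int voxel coordinates
    froi_id: np.ndarray  # (n,) int
    frois: dict[int, Froi]

    @property
    def n_nodes(self) -> int:
        return len(self.coords)

    def region_of(self, node: int) -> str:
        return self.frois[int(self.froi_id[node])].region


@dataclass
class VoxelNetwork:
    """Binary graph on active voxels; nodes carry coordinates and fROI labels."""

    graph: nx.Graph
    nodes: FroiNodes
    theta: float
    frac_negative: float = 0.0  # fraction of retained links with C_ij < 0


def _structure(connectivity: int) -> np.ndarray:
    order = {6: 1, 18: 2, 26: 3}
    if connectivity not in order:
        raise ValidationError(f"connectivity must be 6, 18 or 26, got {connectivity}")
    return ndimage.generate_binary_structure(3, order[connectivity])


def label_frois(active: np.ndarray, label_map: LabelMap, connectivity: int = 6) -> FroiNodes:
    """Partition active voxels into fROIs by (connected component, label).

    ``active`` is the activation-map mask (or an :class:`ActivationMap`'s
    ``active`` attribute).  Voxels in excluded labels are discarded; an
    active component spanning two labels is split into one fROI per label.
    """
    active = np.asarray(active, bool)
    if active.shape != label_map.labels.shape:
        raise ValidationError(
            f"activation grid {active.shape} does not match label grid {label_map.labels.shape}"
        )
    structure = _structure(connectivity)
    coords_list: list[np.ndarray] = []
    froi_ids: list[np.ndarray] = []
    frois: dict[int, Froi] = {}
    next_id = 0
    labels_present = [int(v) for v in np.unique(label_map.labels[active])]
    for lab in labels_present:
        if lab in label_map.excluded:
            continue
        mask = active & (label_map.labels == lab)
        comp, n = ndimage.label(mask, structure=structure)
        for i in range(1, n + 1):
            coords = np.argwhere(comp == i)
            flagged = lab == 0
            if flagged:
                log.warning(
                    "%d active voxels with background label kept as flagged '%s' fROI",
                    len(coords),
                    UNLABELED,
                )
            frois[next_id] = Froi(next_id, label_map.name_of(lab), len(coords), flagged)
            coords_list.append(coords)
            froi_ids.append(np.full(len(coords), next_id))
            next_id += 1
    if not coords_list:
        return FroiNodes(np.zeros((0, 3), dtype=int), np.zeros(0, dtype=int), {})
    return FroiNodes(np.concatenate(coords_list), np.concatenate(froi_ids), frois)


def voxel_correlations(scan_or_data, coords: np.ndarray) -> np.ndarray:
    """Pairwise Pearson correlation matrix of the voxel series at ``coords``.

    Accepts a :class:`~flnet.activation.SubjectScan` or a raw 4D array.
    Constant series are flagged and their correlations set to 0; the
    diagonal is always 1.
    """
    data = scan_or_data.data if hasattr(scan_or_data, "paradigm") else np.asarray(scan_or_data)
    coords = np.asarray(coords, int)
    if len(coords) < 2:
        raise ValidationError("need at least 2 voxels for a correlation matrix")
    series = data[tuple(coords.T)]  # (n, T)
    sd = series.std(axis=1)
    constant = sd == 0
    if constant.any():
        log.warning("%d constant voxel series; their correlations set to 0", int(constant.sum()))
        series = series.copy()
        series[constant] += np.arange(series.shape[1])  # placeholder, zeroed below
    C = np.corrcoef(series)
    C[constant, :] = 0.0
    C[:, constant] = 0.0
    np.fill_diagonal(C, 1.0)
    np.clip(C, -1.0, 1.0, out=C)
    return C


def build_voxel_network(C: np.ndarray, nodes: FroiNodes, theta: float) -> VoxelNetwork:
    """Binary voxel graph: link (i, j) present iff \\|C_ij\\| >= theta."""
    if not (0.0 < theta <= 1.0):
        raise ValidationError(f"theta must lie in (0, 1], got {theta}")
    C = np.asarray(C, float)
    n = nodes.n_nodes
    if C.shape != (n, n):
        raise ValidationError(f"correlation matrix shape {C.shape} does not match {n} nodes")
    G = nx.Graph()
    for i in range(n):
        froi = nodes.frois[int(nodes.froi_id[i])]
        G.add_node(i, coord=tuple(int(v) for v in nodes.coords[i]), froi=froi.froi_id, region=froi.region)
    iu, ju = np.triu_indices(n, k=1)
    keep = np.abs(C[iu, ju]) >= theta
    iu, ju = iu[keep], ju[keep]
    cvals = C[iu, ju]
    G.add_edges_from(
        (int(i), int(j), {"C": float(c)}) for i, j, c in zip(iu, ju, cvals)
    )
    frac_neg = float(np.mean(cvals < 0)) if len(cvals) else 0.0
    if frac_neg:
        log.info("%.1f%% of retained voxel links have negative correlation", 100 * frac_neg)
    return VoxelNetwork(G, nodes, float(theta), frac_neg)


def _grouped_weights(net: VoxelNetwork, group_of: dict[int, str]) -> nx.Graph:
    """Aggregate voxel links into a weighted graph over node groups."""
    sizes: dict[str, int] = {}
    for i in range(net.nodes.n_nodes):
        g = group_of[int(net.nodes.froi_id[i])]
        sizes[g] = sizes.get(g, 0) + 1
    cross: dict[tuple[str, str], int] = {}
    for u, v in net.graph.edges():
        gu = group_of[int(net.nodes.froi_id[u])]
        gv = group_of[int(net.nodes.froi_id[v])]
        if gu == gv:
            continue
        key = (gu, gv) if gu < gv else (gv, gu)
        cross[key] = cross.get(key, 0) + 1
    G = nx.Graph()
    for g, s in sizes.items():
        G.add_node(g, size=s)
    for (gu, gv), n_edges in cross.items():
        w = n_edges / (sizes[gu] + sizes[gv])
        G.add_edge(gu, gv, W=w, cross_edges=n_edges)
    return G


def froi_weights(net: VoxelNetwork) -> nx.Graph:
    """fROI-scale weighted graph (nodes = fROI ids, edge attr ``W``).

    ``W_ij = cross_edges / (S_i + S_j)``; node attributes carry ``region``
    and ``size``.
    """
    G = _grouped_weights(net, {fid: str(fid) for fid in net.nodes.frois})
    H = nx.Graph()
    for fid, froi in net.nodes.frois.items():
        H.add_node(fid, region=froi.region, size=froi.size, flagged=froi.flagged)
    for u, v, d in G.edges(data=True):
        H.add_edge(int(u), int(v), **d)
    return H


def region_network(net: VoxelNetwork) -> nx.Graph:
    """Region-scale weighted graph (nodes = region names).

    Same aggregation rule as :func:`froi_weights` but pooling all fROIs of
    one named region; this is the representation consumed by the group-level
    common-network analysis, where subjects are matched by region name.
    """
    return _grouped_weights(net, {fid: froi.region for fid, froi in net.nodes.frois.items()})
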