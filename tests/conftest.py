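"""Shared fixtures and brute-force oracles for the test suite."""

from __future__ import annotations

import networkx as nx
import numpy as np
import pytest

from flnet.config import RegionSpec, SyntheticConfig, TaskParadigm
from flnet.networks import Froi, FroiNodes


@pytest.fixture
def paradigm() -> TaskParadigm:
    return TaskParadigm()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def two_region_config(
    c: float = 0.5,
    beta: float = 0.0,
    within: float = 0.5,
    noise_sd: float = 1.0,
    voxel_jitter_sd: float = 0.0,
    seed: int = 0,
) -> SyntheticConfig:
    """Minimal two-region geometry on a small grid for generator tests."""
    return SyntheticConfig(
        grid_shape=(12, 6, 6),
        voxel_size_mm=4.0,
        regions=(
            RegionSpec("left", 1, "cuboid", (1, 1, 1), (3, 3, 3), beta=beta, within_coupling=within),
            RegionSpec("right", 2, "cuboid", (7, 1, 1), (3, 3, 3), beta=beta, within_coupling=within),
        ),
        between_coupling={("left", "right"): c},
        noise_sd=noise_sd,
        subject_jitter_sd=0.0,
        voxel_jitter_sd=voxel_jitter_sd,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# independent oracles (deliberately naive implementations)
# ---------------------------------------------------------------------------

def kcore_members_oracle(G: nx.Graph, k: int) -> set:
    """Nodes of the k-core by exhaustive iterative deletion."""
    H = G.copy()
    while True:
        low = [n for n in H if H.degree(n) < k]
        if not low:
            return set(H)
        H.remove_nodes_from(low)


def shells_oracle(G: nx.Graph) -> dict:
    """Shell index per node: in the k-core but not the (k+1)-core."""
    shells = {}
    k = 0
    core = set(G)
    while core:
        nxt = kcore_members_oracle(G, k + 1)
        for n in core - nxt:
            shells[n] = k
        core = nxt
        k += 1
    return shells


def froi_weight_oracle(edges: set[tuple[int, int]], membership: dict[int, int]) -> dict:
    """Eq-style fROI weights by a double loop over all cross voxel pairs."""
    sizes: dict[int, int] = {}
    for node, froi in membership.items():
        sizes[froi] = sizes.get(froi, 0) + 1
    nodes = sorted(membership)
    weights: dict[tuple[int, int], float] = {}
    for a_idx in range(len(nodes)):
        for b_idx in range(a_idx + 1, len(nodes)):
            a, b = nodes[a_idx], nodes[b_idx]
            fa, fb = membership[a], membership[b]
            if fa == fb:
                continue
            if (min(a, b), max(a, b)) in edges:
                key = (min(fa, fb), max(fa, fb))
                weights[key] = weights.get(key, 0.0) + 1.0
    return {k: v / (sizes[k[0]] + sizes[k[1]]) for k, v in weights.items()}


def flood_fill_components(mask: np.ndarray, offsets: np.ndarray) -> list[frozenset]:
    """Connected components by breadth-first flood fill over given offsets."""
    coords = {tuple(c) for c in np.argwhere(mask)}
    comps = []
    while coords:
        seed = coords.pop()
        comp = {seed}
        frontier = [seed]
        while frontier:
            cur = frontier.pop()
            for off in offsets:
                nb = tuple(np.array(cur) + off)
                if nb in coords:
                    coords.remove(nb)
                    comp.add(nb)
                    frontier.append(nb)
        comps.append(frozenset(comp))
    return comps


def neighbourhood_offsets(connectivity: int) -> np.ndarray:
    offs = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                if (dx, dy, dz) == (0, 0, 0):
                    continue
                order = abs(dx) + abs(dy) + abs(dz)
                if connectivity == 6 and order > 1:
                    continue
                if connectivity == 18 and order > 2:
                    continue
                offs.append((dx, dy, dz))
    return np.array(offs)


def make_froi_nodes(sizes: dict[int, int], regions: dict[int, str] | None = None) -> FroiNodes:
    """Synthetic FroiNodes with arbitrary coordinates, one fROI per entry."""
    coords = []
    froi_id = []
    frois = {}
    i = 0
    for fid, size in sizes.items():
        for _ in range(size):
            coords.append((i, 0, 0))
            froi_id.append(fid)
            i += 1
        frois[fid] = Froi(fid, (regions or {}).get(fid, f"R{fid}"), size)
    return FroiNodes(np.array(coords), np.array(froi_id), frois)
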