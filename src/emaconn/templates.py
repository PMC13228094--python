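"""Network templates and individual topography.

A network template set is a collection of binary vertex maps, one per a-priori
network.  The default synthetic set partitions the surface into K contiguous
patches grown from random seed vertices (a randomized graph-Voronoi
tessellation), standing in for group-average network membership maps.
Individual participants get their own "true" topography by relabeling a
fraction of boundary vertices, emulating inter-individual variability in the
location and extent of functional networks.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass

import numpy as np

from emaconn.surface import SurfaceModel

#: Label used for vertices not assigned to any network.
UNASSIGNED: int = -1

#: The eight a-priori networks analyzed by default: default mode,
#: cingulo-opercular, dorsal attention, ventral attention, salience,
#: fronto-parietal, dorsal somato-motor, ventral somato-motor.
DEFAULT_NETWORKS: tuple[str, ...] = (
    "DMN",
    "CON",
    "DAN",
    "VAN",
    "SAL",
    "FPN",
    "DSM",
    "VSM",
)


@dataclass(frozen=True)
class NetworkTemplateSet:
    """Per-network binary vertex maps over a shared surface.

    ``maps`` is a (K, n_vertices) boolean array; ``network_ids`` gives the
    K network labels in row order.
    """

    network_ids: tuple[str, ...]
    maps: np.ndarray

    def __post_init__(self) -> None:
        if len(self.network_ids) < 2:
            raise ValueError("a template set needs at least 2 networks")
        if self.maps.ndim != 2 or self.maps.shape[0] != len(self.network_ids):
            raise ValueError("maps must be (K, n_vertices)")
        if self.maps.dtype != bool:
            raise ValueError("maps must be boolean")
        if not self.maps.any(axis=1).all():
            raise ValueError("every template map must be nonempty")

    @property
    def n_networks(self) -> int:
        return len(self.network_ids)

    @property
    def n_vertices(self) -> int:
        return self.maps.shape[1]

    def is_partition(self) -> bool:
        """True when the maps tile the surface with no overlap."""
        return bool((self.maps.sum(axis=0) == 1).all())


def make_templates(
    surface: SurfaceModel, K: int = 8, seed: int = 0
) -> tuple[NetworkTemplateSet, np.ndarray]:
    """Partition the surface into K contiguous patches.

    Patches are grown simultaneously from K seed vertices: each frontier
    vertex is claimed by a neighboring patch in an order randomized by the
    seeded generator, which yields irregular but contiguous patches covering
    every vertex.  Seeds are placed by farthest-point sampling (first seed
    random, each next seed maximizes its graph distance to the chosen set),
    so every template is a sizeable patch rather than a sliver — matching
    the character of group-level network templates.  Returns the template
    set and the ground-truth label array (values ``0..K-1``).
    """
    n = surface.n_vertices
    if K < 1 or K > n:
        raise ValueError(f"K must be in 1..{n}, got {K}")
    rng = np.random.default_rng(seed)
    labels = np.full(n, UNASSIGNED, dtype=np.int64)
    seeds = _farthest_point_seeds(surface, K, rng)
    # first-passage growth: patches advance by randomized graph distance,
    # giving balanced cells with irregular boundaries
    heap: list[tuple[float, int, int]] = []
    for k, v in enumerate(seeds):
        labels[v] = k
        heap.append((0.0, int(v), k))
    heapq.heapify(heap)
    while heap:
        d, v, k = heapq.heappop(heap)
        for w in surface.neighbors(v):
            if labels[w] == UNASSIGNED:
                labels[w] = k
                heapq.heappush(heap, (d + rng.exponential(), int(w), k))
    if K == 1:
        return _single_network_set(n), labels
    if K <= len(DEFAULT_NETWORKS):
        ids: tuple[str, ...] = DEFAULT_NETWORKS[:K]
    else:
        ids = tuple(f"NET{k}" for k in range(K))
    maps = np.zeros((K, n), dtype=bool)
    maps[labels, np.arange(n)] = True
    return NetworkTemplateSet(network_ids=ids, maps=maps), labels


def _bfs_distances(surface: SurfaceModel, start: int) -> np.ndarray:
    dist = np.full(surface.n_vertices, -1, dtype=np.int64)
    dist[start] = 0
    frontier = [start]
    d = 0
    while frontier:
        d += 1
        nxt = []
        for v in frontier:
            for w in surface.neighbors(v):
                if dist[w] < 0:
                    dist[w] = d
                    nxt.append(int(w))
        frontier = nxt
    return dist


def _farthest_point_seeds(
    surface: SurfaceModel, K: int, rng: np.random.Generator
) -> np.ndarray:
    seeds = [int(rng.integers(surface.n_vertices))]
    mindist = _bfs_distances(surface, seeds[0])
    for _ in range(1, K):
        best = np.flatnonzero(mindist == mindist.max())
        nxt = int(best[rng.integers(best.size)])
        seeds.append(nxt)
        mindist = np.minimum(mindist, _bfs_distances(surface, nxt))
    return np.asarray(seeds)


def _single_network_set(n: int) -> NetworkTemplateSet:
    """Degenerate one-network 'set' bypassing the K>=2 container check."""
    obj = object.__new__(NetworkTemplateSet)
    object.__setattr__(obj, "network_ids", ("NET0",))
    object.__setattr__(obj, "maps", np.ones((1, n), dtype=bool))
    return obj


def perturb_individual(
    truth: np.ndarray,
    surface: SurfaceModel,
    swap_frac: float,
    seed: int = 0,
) -> np.ndarray:
    """Relabel ~``swap_frac`` of boundary vertices to a neighboring label.

    A boundary vertex is one with at least one differently-labeled neighbor.
    ``round(swap_frac * n_boundary)`` boundary vertices are sampled without
    replacement and each takes the label of a randomly chosen
    differently-labeled neighbor, producing an individual-specific variant of
    the group topography.  ``swap_frac`` must lie in [0, 0.5).
    """
    if not 0 <= swap_frac < 0.5:
        raise ValueError(f"swap_frac must be in [0, 0.5), got {swap_frac}")
    out = truth.copy()
    if swap_frac == 0:
        return out
    rng = np.random.default_rng(seed)
    boundary = [
        v
        for v in range(surface.n_vertices)
        if any(truth[w] != truth[v] for w in surface.neighbors(v))
    ]
    n_swap = int(round(swap_frac * len(boundary)))
    if n_swap == 0:
        return out
    chosen = rng.choice(len(boundary), size=n_swap, replace=False)
    for i in chosen:
        v = boundary[i]
        others = [w for w in surface.neighbors(v) if truth[w] != truth[v]]
        out[v] = truth[others[rng.integers(len(others))]]
    return out
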