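"""Road-network container used by the competition covariate and accessibility surfaces.

The network is an undirected :class:`networkx.Graph` whose nodes carry planar
coordinates (km) and whose edges carry a strictly positive car travel time in
minutes (edge attribute ``"time"``). Synthetic regions use planar coordinates;
nothing here assumes a geographic CRS.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

TIME_ATTR = "time"


@dataclass
class RoadNetwork:
    """Weighted undirected road graph.

    Parameters
    ----------
    graph
        ``networkx.Graph`` with node attributes ``x``, ``y`` (km) and edge
        attribute ``time`` (minutes, > 0).
    """

    graph: nx.Graph
    _kdtree: cKDTree | None = field(default=None, repr=False, compare=False)
    _node_order: list | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        for u, v, t in self.graph.edges(data=TIME_ATTR):
            if t is None or not np.isfinite(t) or t <= 0:
                raise ValueError(
                    f"edge ({u}, {v}) has non-positive or missing travel time: {t!r}"
                )

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def coords(self) -> tuple[list, np.ndarray]:
        """Node ids and their (n, 2) coordinate array, in a stable order."""
        if self._node_order is None:
            self._node_order = list(self.graph.nodes)
        xy = np.array(
            [[self.graph.nodes[n]["x"], self.graph.nodes[n]["y"]] for n in self._node_order]
        )
        return self._node_order, xy

    def is_connected(self) -> bool:
        return self.n_nodes > 0 and nx.is_connected(self.graph)

    def nearest_node(self, x: float, y: float) -> tuple[object, float]:
        """Nearest node to a planar point; returns (node id, Euclidean km distance)."""
        if self._kdtree is None:
            order, xy = self.coords()
            self._kdtree = cKDTree(xy)
        dist, idx = self._kdtree.query([x, y])
        return self._node_order[idx], float(dist)

    def nearest_nodes(self, points: np.ndarray) -> tuple[list, np.ndarray]:
        """Vectorized nearest-node snap for an (n, 2) point array."""
        if self._kdtree is None:
            order, xy = self.coords()
            self._kdtree = cKDTree(xy)
        dist, idx = self._kdtree.query(points)
        nodes = [self._node_order[i] for i in np.atleast_1d(idx)]
        return nodes, np.atleast_1d(dist)
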