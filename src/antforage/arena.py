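"""Hexagonal channel arena: lattice geometry, decision nodes, and food placement.

The physical arena is a box tiled with regular pointy-top hexagons whose edges
are narrow channels; every hexagon vertex is a decision node where an ant can
choose among at most three directions (a Y-maze crossing in the interior, a
binary forward/backward choice on the perimeter).  Food is introduced at the
12 vertices of two chosen hexagon faces.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

__all__ = [
    "HexArena",
    "FoodScenario",
    "build_arena",
    "node_neighbors",
    "distances",
    "place_food",
    "FULL_ARENA_FACES",
    "HALF_ARENA_FACES",
    "FULL_ARENA_Y_NODES",
    "FULL_ARENA_ALL_NODES",
    "HALF_ARENA_Y_NODES",
    "HALF_ARENA_OCCUPANCY_NODES",
]

# Reference constants of the physical experimental arena (used when ingesting
# tracking data from that setup; the constructed geometry is validated through
# internal consistency, not against these).
FULL_ARENA_FACES = 572
HALF_ARENA_FACES = 286
FULL_ARENA_Y_NODES = 1192
FULL_ARENA_ALL_NODES = 1240
HALF_ARENA_Y_NODES = 596
HALF_ARENA_OCCUPANCY_NODES = 620

_SQRT3 = np.sqrt(3.0)

FOOD_CONDITIONS = ("deterministic", "stochastic", "no_food", "p_mixture", "radial")


@dataclass(frozen=True)
class FoodScenario:
    """A placement of food items on the arena.

    ``food_nodes`` is the set of node ids holding food (the 12 vertices of two
    vertex-disjoint hexagon faces, or empty for the no-food control).
    """

    food_nodes: frozenset[int]
    condition: str
    faces: tuple[int, ...] = ()
    p: float | None = None
    R_mm: float | None = None
    items_per_node: int = 1
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.condition not in FOOD_CONDITIONS:
            raise ValueError(f"unknown food condition {self.condition!r}")
        if self.condition == "no_food":
            if self.food_nodes:
                raise ValueError("no_food scenario must have an empty food set")
        elif len(self.food_nodes) != 12:
            raise ValueError(
                f"two-hexagon placement requires 12 food nodes, got {len(self.food_nodes)}"
            )

    @property
    def total_items(self) -> int:
        return len(self.food_nodes) * self.items_per_node


class HexArena:
    """Maximal tiling of a rectangular box with regular pointy-top hexagons.

    Rows are offset by half a hexagon width and all rows have the same number
    of columns; only whole hexagons that fit the box are kept.  Node ids are
    0-based and stable under identical build parameters.  Coordinates are in
    mm with the origin at the lower-left corner, y increasing upward.
    """

    def __init__(
        self,
        width_mm: float,
        height_mm: float,
        edge_mm: float,
        nest_node: int | None = None,
    ) -> None:
        if width_mm <= 0 or height_mm <= 0 or edge_mm <= 0:
            raise ValueError("arena dimensions and edge length must be positive")
        a = float(edge_mm)
        hex_w = _SQRT3 * a  # horizontal pitch (pointy-top)
        # rows offset half a width -> usable width is (n_cols + 1/2) * hex_w
        n_cols = int(np.floor(width_mm / hex_w - 0.5 + 1e-9))
        # vertical extent of r rows: 2a + 1.5a(r-1)
        n_rows = int(np.floor((height_mm - 2.0 * a) / (1.5 * a) + 1e-9)) + 1
        if n_cols < 1 or n_rows < 1:
            raise ValueError(
                f"box {width_mm}x{height_mm} mm too small for one {edge_mm} mm hexagon"
            )
        self.width_mm = float(width_mm)
        self.height_mm = float(height_mm)
        self.edge_mm = a
        self.n_cols = n_cols
        self.n_rows = n_rows

        # vertex angles of a pointy-top hexagon
        ang = np.deg2rad([30, 90, 150, 210, 270, 330])
        vx, vy = a * np.cos(ang), a * np.sin(ang)

        node_index: dict[tuple[int, int], int] = {}
        coords: list[tuple[float, float]] = []
        faces: list[tuple[int, ...]] = []
        face_centers: list[tuple[float, float]] = []
        edges: set[tuple[int, int]] = set()
        # snap key resolution: half an edge is safely coarser than float noise
        scale = 1e6

        def node_id(x: float, y: float) -> int:
            key = (round(x * scale), round(y * scale))
            idx = node_index.get(key)
            if idx is None:
                idx = len(coords)
                node_index[key] = idx
                coords.append((x, y))
            return idx

        for row in range(n_rows):
            cy = a + 1.5 * a * row
            x0 = hex_w / 2.0 + (hex_w / 2.0 if row % 2 else 0.0)
            for col in range(n_cols):
                cx = x0 + hex_w * col
                ids = tuple(node_id(cx + vx[k], cy + vy[k]) for k in range(6))
                faces.append(ids)
                face_centers.append((cx, cy))
                for k in range(6):
                    i, j = ids[k], ids[(k + 1) % 6]
                    edges.add((min(i, j), max(i, j)))

        self.faces = faces
        self.face_centers = np.asarray(face_centers)
        self.node_xy = np.asarray(coords)
        self.edges = frozenset(edges)

        g = nx.Graph()
        g.add_nodes_from(range(len(coords)))
        g.add_edges_from(edges)
        self.graph = g
        self.degree = np.array([g.degree(i) for i in range(len(coords))])
        self.is_peripheral = self.degree < 3
        self.active_nodes = list(range(len(coords)))

        if nest_node is None:
            # nearest node to the midpoint of the lower long boundary
            mid = np.array([self.width_mm / 2.0, 0.0])
            nest_node = int(np.argmin(np.hypot(*(self.node_xy - mid).T)))
        if nest_node not in g:
            raise KeyError(f"nest node {nest_node} not in arena")
        self.nest_node = int(nest_node)

    # -- queries ---------------------------------------------------------

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    @property
    def n_nodes(self) -> int:
        return len(self.node_xy)

    def neighbors(self, node_id: int) -> set[int]:
        if node_id not in self.graph:
            raise KeyError(f"unknown node id {node_id}")
        return set(self.graph.neighbors(node_id))

    def face_nodes(self, face_id: int) -> tuple[int, ...]:
        return self.faces[face_id]

    def shortest_path(self, a: int, b: int) -> list[int]:
        return nx.shortest_path(self.graph, a, b)

    # -- serialization ---------------------------------------------------

    def to_json(self, path) -> None:
        obj = {
            "width_mm": self.width_mm,
            "height_mm": self.height_mm,
            "edge_mm": self.edge_mm,
            "nodes": [
                {
                    "id": i,
                    "x": float(x),
                    "y": float(y),
                    "degree": int(self.degree[i]),
                    "peripheral": bool(self.is_peripheral[i]),
                }
                for i, (x, y) in enumerate(self.node_xy)
            ],
            "edges": sorted([list(e) for e in self.edges]),
            "faces": [list(f) for f in self.faces],
            "nest_node": self.nest_node,
        }
        with open(path, "w") as fh:
            json.dump(obj, fh)

    @classmethod
    def from_json(cls, path) -> "HexArena":
        with open(path) as fh:
            obj = json.load(fh)
        arena = cls(obj["width_mm"], obj["height_mm"], obj["edge_mm"], obj["nest_node"])
        # geometry is reconstructed from parameters; verify identity
        if arena.n_nodes != len(obj["nodes"]) or arena.n_faces != len(obj["faces"]):
            raise ValueError("serialized arena inconsistent with its parameters")
        return arena


def build_arena(
    width_mm: float, height_mm: float, edge_mm: float, nest_node: int | None = None
) -> HexArena:
    """Tile a ``width_mm`` x ``height_mm`` box with regular hexagons of edge
    ``edge_mm`` and return the resulting channel arena."""
    return HexArena(width_mm, height_mm, edge_mm, nest_node)


def node_neighbors(arena: HexArena, node_id: int) -> set[int]:
    """Channel-adjacent nodes of ``node_id`` (3 at interior Y-crossings, <=2
    on the perimeter)."""
    return arena.neighbors(node_id)


def distances(arena: HexArena, a: int, b: int) -> tuple[float, float]:
    """Euclidean distance (mm) and minimal channel-hop count between nodes.

    Disconnected nodes get ``inf`` hops.
    """
    if a not in arena.graph or b not in arena.graph:
        raise KeyError(f"unknown node id {a if a not in arena.graph else b}")
    eu = float(np.hypot(*(arena.node_xy[a] - arena.node_xy[b])))
    try:
        hops = float(nx.shortest_path_length(arena.graph, a, b))
    except nx.NetworkXNoPath:
        hops = float("inf")
    return eu, hops


def _faces_vertex_disjoint(arena: HexArena, f1: int, f2: int) -> bool:
    return not (set(arena.faces[f1]) & set(arena.faces[f2]))


def _nest_face_distances(arena: HexArena) -> np.ndarray:
    nest_xy = arena.node_xy[arena.nest_node]
    return np.hypot(*(arena.face_centers - nest_xy).T)


def default_deterministic_faces(arena: HexArena, target_mm: float = 500.0) -> tuple[int, int]:
    """Two vertex-disjoint faces with centers nearest ``target_mm`` from the
    nest, on symmetric sides of the nest axis."""
    d = _nest_face_distances(arena)
    nest_x = arena.node_xy[arena.nest_node, 0]
    cx = arena.face_centers[:, 0]
    score = np.abs(d - target_mm)
    left = np.where(cx < nest_x)[0]
    right = np.where(cx >= nest_x)[0]
    if len(left) == 0 or len(right) == 0:
        order = np.argsort(score)
        f1 = int(order[0])
        for f2 in order[1:]:
            if _faces_vertex_disjoint(arena, f1, int(f2)):
                return f1, int(f2)
        raise ValueError("no vertex-disjoint face pair available")
    f1 = int(left[np.argmin(score[left])])
    # mirror of f1 about the nest axis
    mirror = np.array([2 * nest_x - arena.face_centers[f1, 0], arena.face_centers[f1, 1]])
    m_dist = np.hypot(*(arena.face_centers[right] - mirror).T)
    for f2 in right[np.argsort(m_dist)]:
        if _faces_vertex_disjoint(arena, f1, int(f2)):
            return f1, int(f2)
    raise ValueError("no vertex-disjoint face pair available")


def _draw_disjoint_pair(
    rng: np.random.Generator, arena: HexArena, eligible: np.ndarray
) -> tuple[int, int]:
    if len(eligible) < 2:
        raise ValueError("fewer than two eligible faces for a food placement")
    f1 = int(rng.choice(eligible))
    partners = [f for f in eligible if f != f1 and _faces_vertex_disjoint(arena, f1, int(f))]
    if not partners:
        raise ValueError("no vertex-disjoint partner face among eligible faces")
    f2 = int(rng.choice(partners))
    return f1, f2


def place_food(
    arena: HexArena,
    condition: str,
    seed: int | None = None,
    p: float | None = None,
    R_mm: float | None = None,
    fixed_faces: tuple[int, int] | None = None,
    items_per_node: int = 1,
) -> FoodScenario:
    """Place food at the 12 vertices of two vertex-disjoint hexagon faces.

    ``deterministic`` uses the configured fixed faces (default: centers nearest
    500 mm from the nest on symmetric sides); ``stochastic`` draws two
    vertex-disjoint faces uniformly; ``p_mixture`` uses the deterministic
    faces with probability ``p`` and a stochastic draw otherwise; ``radial``
    restricts the stochastic draw to faces within ``R_mm`` of the nest.
    """
    if condition not in FOOD_CONDITIONS:
        raise ValueError(f"unknown food condition {condition!r}")
    if condition == "no_food":
        return FoodScenario(frozenset(), "no_food", seed=seed)
    rng = np.random.default_rng(seed)
    det = fixed_faces if fixed_faces is not None else default_deterministic_faces(arena)
    if not _faces_vertex_disjoint(arena, det[0], det[1]):
        raise ValueError("fixed deterministic faces share a vertex")

    if condition == "deterministic":
        pair = det
    elif condition == "stochastic":
        pair = _draw_disjoint_pair(rng, arena, np.arange(arena.n_faces))
    elif condition == "p_mixture":
        if p is None or not 0.0 <= p <= 1.0:
            raise ValueError("p_mixture requires p in [0, 1]")
        if rng.random() < p:
            pair = det
        else:
            pair = _draw_disjoint_pair(rng, arena, np.arange(arena.n_faces))
    else:  # radial
        if R_mm is None or R_mm <= 0:
            raise ValueError("radial placement requires R_mm > 0")
        eligible = np.where(_nest_face_distances(arena) <= R_mm)[0]
        if len(eligible) < 2:
            raise ValueError(f"radius {R_mm} mm contains fewer than two faces")
        pair = _draw_disjoint_pair(rng, arena, eligible)

    nodes = frozenset(arena.faces[pair[0]]) | frozenset(arena.faces[pair[1]])
    return FoodScenario(
        frozenset(nodes),
        condition,
        faces=(int(pair[0]), int(pair[1])),
        p=p,
        R_mm=R_mm,
        items_per_node=items_per_node,
        seed=seed,
    )
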