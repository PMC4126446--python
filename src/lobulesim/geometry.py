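"""Hexagonal-lobule honeycomb construction and cell-placement geometry.

The tissue patch is a honeycomb of flat-top regular hexagons ("lobules").
Hexagon vertices carry portal-triad node agents; every hexagon edge carries a
septum made of two parallel boundary sub-segments joined by a prismatic joint,
each end tied to its triad node by a revolute joint.

Hepatocyte-sized agents are placed on a global triangular packing lattice of
spacing ``cell_diameter``, clipped to the interior of each lobule with a
clearance margin to the septa.  Placement sites are precomputed once per
lattice; the spiral fill and the replication rules operate on this site graph,
which makes the emergent fill count a deterministic function of the geometry.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "Node",
    "Septum",
    "Joint",
    "Lobule",
    "LobuleLattice",
    "SiteLattice",
    "build_lattice",
    "classify_nodes",
    "build_site_lattice",
    "spiral_fill",
    "spiral_fill_sites",
    "InfeasiblePackingError",
    "LatticeSizeError",
]

_DEDUP_REL_TOL = 1e-6

#: rotation of the cell-packing lattice relative to the hexagon frame (rad)
_LATTICE_ROTATION = 0.18

SQRT3 = math.sqrt(3.0)


class LatticeSizeError(ValueError):
    """Raised for non-positive honeycomb dimensions."""


class InfeasiblePackingError(ValueError):
    """Raised when the cell diameter cannot fit inside a lobule."""


@dataclass(frozen=True)
class Node:
    """A portal-triad vertex of the honeycomb."""

    id: int
    position: tuple[float, float]
    degree: int
    is_outer: bool


@dataclass(frozen=True)
class Septum:
    """A lobule edge: two parallel boundary sub-segments sharing an axis."""

    id: int
    node_a: int
    node_b: int
    #: two (p, q) endpoint pairs, offset +/- thickness/2 off the axis
    segments: tuple[tuple[tuple[float, float], tuple[float, float]], ...]
    prismatic_axis: tuple[float, float]
    is_boundary: bool


@dataclass(frozen=True)
class Joint:
    kind: str  # "prismatic" | "revolute"
    members: tuple[int, ...]
    anchor: tuple[float, float] | None = None
    axis: tuple[float, float] | None = None


@dataclass(frozen=True)
class Lobule:
    id: int
    center: tuple[float, float]
    node_ids: tuple[int, ...]
    septum_ids: tuple[int, ...]


@dataclass
class LobuleLattice:
    """The honeycomb skeleton: nodes, septa, joints and hexagon descriptors."""

    nodes: list[Node]
    septa: list[Septum]
    joints: list[Joint]
    lobules: list[Lobule]
    hex_side: float
    septum_thickness: float
    patch_extent: tuple[float, float, float, float]  # xmin, ymin, xmax, ymax

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_septa(self) -> int:
        return len(self.septa)

    @property
    def n_lobules(self) -> int:
        return len(self.lobules)

    def node_positions(self) -> np.ndarray:
        return np.array([n.position for n in self.nodes], dtype=float)

    def lobule_centers(self) -> np.ndarray:
        return np.array([l.center for l in self.lobules], dtype=float)

    @property
    def centroid(self) -> tuple[float, float]:
        c = self.lobule_centers().mean(axis=0)
        return (float(c[0]), float(c[1]))

    @property
    def inradius(self) -> float:
        return self.hex_side * SQRT3 / 2.0

    def euler_characteristic(self) -> int:
        """V - E + F for the planar graph, F counting hexagons + outer face."""
        return self.n_nodes - self.n_septa + (self.n_lobules + 1)

    # -- serialization -----------------------------------------------------

    SCHEMA_VERSION = 1

    def to_dict(self) -> dict:
        return {
            "schema_version": self.SCHEMA_VERSION,
            "hex_side": self.hex_side,
            "septum_thickness": self.septum_thickness,
            "patch_extent": list(self.patch_extent),
            "nodes": [
                {"id": n.id, "position": list(n.position), "degree": n.degree,
                 "is_outer": n.is_outer}
                for n in self.nodes
            ],
            "septa": [
                {"id": s.id, "node_a": s.node_a, "node_b": s.node_b,
                 "segments": [[list(p), list(q)] for p, q in s.segments],
                 "prismatic_axis": list(s.prismatic_axis),
                 "is_boundary": s.is_boundary}
                for s in self.septa
            ],
            "joints": [
                {"kind": j.kind, "members": list(j.members),
                 "anchor": list(j.anchor) if j.anchor is not None else None,
                 "axis": list(j.axis) if j.axis is not None else None}
                for j in self.joints
            ],
            "lobules": [
                {"id": l.id, "center": list(l.center),
                 "node_ids": list(l.node_ids), "septum_ids": list(l.septum_ids)}
                for l in self.lobules
            ],
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    @classmethod
    def from_dict(cls, d: dict) -> "LobuleLattice":
        if d.get("schema_version") != cls.SCHEMA_VERSION:
            raise ValueError(
                f"unsupported lattice schema version: {d.get('schema_version')!r}")
        nodes = [Node(n["id"], tuple(n["position"]), n["degree"], n["is_outer"])
                 for n in d["nodes"]]
        septa = [
            Septum(s["id"], s["node_a"], s["node_b"],
                   tuple((tuple(p), tuple(q)) for p, q in s["segments"]),
                   tuple(s["prismatic_axis"]), s["is_boundary"])
            for s in d["septa"]
        ]
        joints = [
            Joint(j["kind"], tuple(j["members"]),
                  tuple(j["anchor"]) if j["anchor"] is not None else None,
                  tuple(j["axis"]) if j["axis"] is not None else None)
            for j in d["joints"]
        ]
        lobules = [Lobule(l["id"], tuple(l["center"]), tuple(l["node_ids"]),
                          tuple(l["septum_ids"])) for l in d["lobules"]]
        return cls(nodes, septa, joints, lobules, d["hex_side"],
                   d["septum_thickness"], tuple(d["patch_extent"]))

    @classmethod
    def from_json(cls, s: str) -> "LobuleLattice":
        return cls.from_dict(json.loads(s))


def _hexagon_vertices(cx: float, cy: float, side: float) -> list[tuple[float, float]]:
    # flat-top hexagon: vertices at 0, 60, ..., 300 degrees
    return [(cx + side * math.cos(math.radians(60 * k)),
             cy + side * math.sin(math.radians(60 * k))) for k in range(6)]


def build_lattice(n_rows: int, n_cols: int, hex_side: float,
                  septum_thickness: float = 0.3) -> LobuleLattice:
    """Construct an ``n_rows x n_cols`` honeycomb of flat-top hexagons.

    Deterministic for fixed inputs.  Shared edges appear as a single septum;
    each septum carries two parallel sub-segments (offset by half the septum
    thickness on either side of the edge axis), one prismatic joint and two
    revolute joints.
    """
    if n_rows < 1 or n_cols < 1:
        raise LatticeSizeError(
            f"honeycomb dimensions must be >= 1, got ({n_rows}, {n_cols})")
    cells = [(col, row) for col in range(n_cols) for row in range(n_rows)]
    return build_lattice_from_cells(cells, hex_side, septum_thickness)


def build_lattice_from_cells(cells: Sequence[tuple[int, int]], hex_side: float,
                             septum_thickness: float = 0.3) -> LobuleLattice:
    """Construct a honeycomb from explicit offset ``(col, row)`` hex cells.

    Odd columns are shifted up by half a hexagon height; ``build_lattice``
    uses this with a full rectangular block, fixtures may pass e.g. a ring.
    """
    if not cells:
        raise LatticeSizeError("at least one hexagon cell is required")
    if hex_side <= 0:
        raise LatticeSizeError(f"hex_side must be > 0, got {hex_side}")

    s = float(hex_side)
    tol = _DEDUP_REL_TOL * s

    def key(p: tuple[float, float]) -> tuple[int, int]:
        return (round(p[0] / tol), round(p[1] / tol))

    vert_ids: dict[tuple[int, int], int] = {}
    vert_pos: list[tuple[float, float]] = []
    edge_ids: dict[tuple[int, int], int] = {}
    edge_nodes: list[tuple[int, int]] = []
    edge_hex_count: list[int] = []
    lobule_raw: list[tuple[tuple[float, float], list[int], list[int]]] = []

    for col, row in cells:
        cx = 1.5 * s * col
        cy = SQRT3 * s * (row + 0.5 * (col % 2))
        verts = _hexagon_vertices(cx, cy, s)
        vids = []
        for p in verts:
            k = key(p)
            if k not in vert_ids:
                vert_ids[k] = len(vert_pos)
                vert_pos.append(p)
            vids.append(vert_ids[k])
        eids = []
        for i in range(6):
            a, b = vids[i], vids[(i + 1) % 6]
            ek = (min(a, b), max(a, b))
            if ek not in edge_ids:
                edge_ids[ek] = len(edge_nodes)
                edge_nodes.append(ek)
                edge_hex_count.append(0)
            eid = edge_ids[ek]
            edge_hex_count[eid] += 1
            eids.append(eid)
        lobule_raw.append(((cx, cy), vids, eids))

    # translate so the patch lower-left corner sits at the origin
    xs = [p[0] for p in vert_pos]
    ys = [p[1] for p in vert_pos]
    x0, y0 = min(xs), min(ys)
    vert_pos = [(p[0] - x0, p[1] - y0) for p in vert_pos]
    extent = (0.0, 0.0, max(xs) - x0, max(ys) - y0)

    degree = [0] * len(vert_pos)
    outer = [False] * len(vert_pos)
    for eid, (a, b) in enumerate(edge_nodes):
        degree[a] += 1
        degree[b] += 1
        if edge_hex_count[eid] == 1:
            outer[a] = True
            outer[b] = True

    nodes = [Node(i, vert_pos[i], degree[i], outer[i])
             for i in range(len(vert_pos))]

    half_t = septum_thickness / 2.0
    septa: list[Septum] = []
    joints: list[Joint] = []
    for eid, (a, b) in enumerate(edge_nodes):
        pa = np.array(vert_pos[a])
        pb = np.array(vert_pos[b])
        axis = pb - pa
        axis = axis / np.linalg.norm(axis)
        normal = np.array([-axis[1], axis[0]])
        segs = []
        for sign in (+1.0, -1.0):
            off = sign * half_t * normal
            segs.append((tuple(pa + off), tuple(pb + off)))
        septa.append(Septum(eid, a, b, tuple(segs), tuple(axis),
                            edge_hex_count[eid] == 1))
        joints.append(Joint("prismatic", (eid, 0, 1), axis=tuple(axis)))
        joints.append(Joint("revolute", (eid, a), anchor=vert_pos[a]))
        joints.append(Joint("revolute", (eid, b), anchor=vert_pos[b]))

    lobules = [
        Lobule(i, (c[0] - x0, c[1] - y0), tuple(vids), tuple(eids))
        for i, (c, vids, eids) in enumerate(lobule_raw)
    ]
    return LobuleLattice(nodes, septa, joints, lobules, s,
                         septum_thickness, extent)


def classify_nodes(lattice: LobuleLattice) -> tuple[list[int], list[int]]:
    """Partition nodes for elastography.

    Returns ``(internal_ids, outer_ids)``: internal nodes have three adjoining
    septa and do not lie on the outer border of the patch; outer nodes lie on
    the border.  (Degree-2 interior nodes do not occur on a honeycomb but
    would fall in neither class.)
    """
    internal = [n.id for n in lattice.nodes if n.degree == 3 and not n.is_outer]
    outer = [n.id for n in lattice.nodes if n.is_outer]
    return internal, outer


# ---------------------------------------------------------------------------
# cell-placement sites


def _point_segment_distance(p: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Distances from points p (N,2) to segment a-b."""
    ab = b - a
    denom = float(ab @ ab)
    t = np.clip((p - a) @ ab / denom, 0.0, 1.0)
    proj = a + t[:, None] * ab
    return np.linalg.norm(p - proj, axis=1)


@dataclass
class SiteLattice:
    """Triangular packing sites clipped into the lobule interiors.

    ``neighbors`` is the within-lobule adjacency used by replication and
    collagen growth; septa are exclusion zones, so the site graph never
    crosses a lobule boundary.
    """

    positions: np.ndarray          # (N, 2)
    lobule_of: np.ndarray          # (N,) int
    neighbors: list[np.ndarray]    # per-site int arrays
    dist_to_septum: np.ndarray     # (N,) distance to nearest lobule edge
    dist_to_triad: np.ndarray      # (N,) distance to nearest lobule vertex
    nearest_septum: np.ndarray     # (N,) septum id of the nearest lobule edge
    nearest_triad: np.ndarray      # (N,) node id of the nearest lobule vertex
    cell_diameter: float

    @property
    def n_sites(self) -> int:
        return len(self.positions)

    def sites_in_lobule(self, lobule_id: int) -> np.ndarray:
        return np.flatnonzero(self.lobule_of == lobule_id)

    def anchored_mask(self, reach: float) -> np.ndarray:
        """Sites close enough to a septum or triad to anchor collagen."""
        return (self.dist_to_septum <= reach) | (self.dist_to_triad <= reach)


def build_site_lattice(lattice: LobuleLattice, cell_diameter: float) -> SiteLattice:
    """Generate the deterministic cell-placement site graph for a lattice."""
    if cell_diameter >= lattice.hex_side:
        raise InfeasiblePackingError(
            f"cell_diameter {cell_diameter} must be smaller than hex_side "
            f"{lattice.hex_side}")
    d = float(cell_diameter)
    margin = d / 2.0 + lattice.septum_thickness / 2.0

    xmin, ymin, xmax, ymax = lattice.patch_extent
    row_h = SQRT3 / 2.0 * d
    # The packing lattice is rotated by a fixed angle incommensurate with the
    # hexagon axes (plus a sub-cell phase shift).  With an axis-aligned
    # lattice every hexagon edge is parallel to a lattice row, so whole rows
    # of sites cross the septum clearance margin simultaneously as the
    # geometry is scaled; the rotation removes that degeneracy.
    theta = _LATTICE_ROTATION
    cos_t, sin_t = math.cos(theta), math.sin(theta)
    cx = 0.5 * (xmin + xmax)
    cy = 0.5 * (ymin + ymax)
    half_diag = 0.5 * math.hypot(xmax - xmin, ymax - ymin) + 2.0 * d
    phase_x, phase_y = 0.1234 * d, 0.2468 * d
    n_half = int(math.ceil(half_diag / min(d, row_h))) + 1
    pts = []
    for r in range(-n_half, n_half + 1):
        v = phase_y + r * row_h
        u_off = 0.5 * d if (r % 2) else 0.0
        us = phase_x + u_off + d * np.arange(-n_half, n_half + 1)
        x = cx + cos_t * us - sin_t * v
        y = cy + sin_t * us + cos_t * v
        pts.append(np.column_stack([x, y]))
    pts = np.vstack(pts)
    in_box = ((pts[:, 0] >= xmin) & (pts[:, 0] <= xmax)
              & (pts[:, 1] >= ymin) & (pts[:, 1] <= ymax))
    pts = pts[in_box]

    centers = lattice.lobule_centers()
    # hexagons tile as the Voronoi cells of their centers ...
    tree = cKDTree(centers)
    _, owner = tree.query(pts)
    # ... but the patch border is not: drop points outside their hexagon
    s = lattice.hex_side
    rel = np.abs(pts - centers[owner])
    inside = ((rel[:, 1] <= SQRT3 / 2.0 * s + 1e-12)
              & (SQRT3 * rel[:, 0] + rel[:, 1] <= SQRT3 * s + 1e-12))
    pts = pts[inside]
    owner = owner[inside]

    keep_pos = []
    keep_lob = []
    keep_dsep = []
    keep_dtri = []
    keep_nsep = []
    keep_ntri = []
    npos = lattice.node_positions()
    for lob in lattice.lobules:
        mask = owner == lob.id
        if not mask.any():
            continue
        p = pts[mask]
        verts = npos[list(lob.node_ids)]
        edge_d = np.empty((len(p), 6))
        for i in range(6):
            a = verts[i]
            b = verts[(i + 1) % 6]
            edge_d[:, i] = _point_segment_distance(p, a, b)
        e_arg = np.argmin(edge_d, axis=1)
        dsep = edge_d[np.arange(len(p)), e_arg]
        nsep = np.array(lob.septum_ids)[e_arg]
        vert_d = np.linalg.norm(p[:, None, :] - verts[None, :, :], axis=2)
        v_arg = np.argmin(vert_d, axis=1)
        dtri = vert_d[np.arange(len(p)), v_arg]
        ntri = np.array(lob.node_ids)[v_arg]
        ok = dsep >= margin
        keep_pos.append(p[ok])
        keep_lob.append(np.full(ok.sum(), lob.id, dtype=int))
        keep_dsep.append(dsep[ok])
        keep_dtri.append(dtri[ok])
        keep_nsep.append(nsep[ok])
        keep_ntri.append(ntri[ok])

    positions = np.vstack(keep_pos)
    lobule_of = np.concatenate(keep_lob)
    dist_sep = np.concatenate(keep_dsep)
    dist_tri = np.concatenate(keep_dtri)
    near_sep = np.concatenate(keep_nsep)
    near_tri = np.concatenate(keep_ntri)

    # stable ordering: by lobule, then y, then x
    order = np.lexsort((positions[:, 0], positions[:, 1], lobule_of))
    positions = positions[order]
    lobule_of = lobule_of[order]
    dist_sep = dist_sep[order]
    dist_tri = dist_tri[order]
    near_sep = near_sep[order]
    near_tri = near_tri[order]

    stree = cKDTree(positions)
    pairs = stree.query_pairs(1.1 * d, output_type="ndarray")
    if len(pairs):
        same = lobule_of[pairs[:, 0]] == lobule_of[pairs[:, 1]]
        pairs = pairs[same]
    nbr: list[list[int]] = [[] for _ in range(len(positions))]
    for i, j in pairs:
        nbr[i].append(j)
        nbr[j].append(i)
    neighbors = [np.array(sorted(v), dtype=np.int64) for v in nbr]

    return SiteLattice(positions, lobule_of, neighbors, dist_sep, dist_tri,
                       near_sep, near_tri, d)


def spiral_fill_sites(lattice: LobuleLattice, cell_diameter: float,
                      rng: np.random.Generator,
                      sites: SiteLattice | None = None) -> np.ndarray:
    """Seed each lobule along an Archimedean spiral, then let replication fill.

    Returns the sorted indices of occupied sites.  The spiral (arc step =
    one cell diameter, pitch = one cell diameter) seeds free sites outward
    from each lobule center; the replication loop then repeatedly lets every
    placed cell claim one uniformly chosen empty neighboring site until no
    cell borders empty space.  The emergent count equals the number of
    reachable sites and is independent of the seed.
    """
    if sites is None:
        sites = build_site_lattice(lattice, cell_diameter)
    d = sites.cell_diameter
    occupied = np.zeros(sites.n_sites, dtype=bool)

    for lob in lattice.lobules:
        idx = sites.sites_in_lobule(lob.id)
        if len(idx) == 0:
            continue
        lp = sites.positions[idx]
        ltree = cKDTree(lp)
        center = np.array(lob.center)
        a = d / (2.0 * math.pi)  # pitch d per turn
        theta = 0.0
        r_max = lattice.hex_side
        while True:
            r = a * theta
            p = center + r * np.array([math.cos(theta), math.sin(theta)])
            hits = ltree.query_ball_point(p, d)
            if hits:
                free = [h for h in hits if not occupied[idx[h]]]
                if free:
                    dists = np.linalg.norm(lp[free] - p, axis=1)
                    occupied[idx[free[int(np.argmin(dists))]]] = True
            if r > r_max:
                break
            theta += d / max(r, d / 2.0)

    # replication: each placed cell fills one empty neighbor per sweep
    while True:
        frontier = [i for i in np.flatnonzero(occupied)
                    if any(not occupied[j] for j in sites.neighbors[i])]
        if not frontier:
            break
        order = rng.permutation(len(frontier))
        placed = False
        for k in order:
            i = frontier[k]
            empties = [j for j in sites.neighbors[i] if not occupied[j]]
            if empties:
                occupied[empties[int(rng.integers(len(empties)))]] = True
                placed = True
        if not placed:  # pragma: no cover - defensive
            break
    return np.flatnonzero(occupied)


def spiral_fill(lattice: LobuleLattice, cell_diameter: float,
                rng: np.random.Generator) -> np.ndarray:
    """Return the (N, 2) positions of hepatocytes placed by the spiral fill."""
    if cell_diameter >= lattice.hex_side:
        raise InfeasiblePackingError(
            f"cell_diameter {cell_diameter} must be smaller than hex_side "
            f"{lattice.hex_side}")
    sites = build_site_lattice(lattice, cell_diameter)
    filled = spiral_fill_sites(lattice, cell_diameter, rng, sites)
    return sites.positions[filled]
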