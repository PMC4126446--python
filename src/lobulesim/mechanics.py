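"""Septal-skeleton mechanics and the virtual elastography measurement.

Position-based, overdamped dynamics: displacements are proportional to
impulses and constraints are enforced by iterative projection.  Only the
structural roster collides: hepatocytes, dead hepatocytes, collagen deposits
(disks on placement sites), portal-triad nodes (small disks) and septum
sub-segments (line segments following their end nodes).  Collagen is treated
as rigidly anchored to the skeleton (zero mobility); inflammatory and
fibrogenic cells never appear here at all.

The elastography probe operates on a deep copy of the mechanical state:
hepatocyte/dead diameters are shrunk by a small fraction (restoring the
compressibility a packed monolayer otherwise lacks), outer nodes are pinned,
every internal node receives an inward impulse, one constrained step is
taken, and the mean internal-node displacement is returned.  The copy is then
discarded, leaving the simulation state bit-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "MechanicalState",
    "ElastographyResult",
    "resolve_collisions",
    "apply_joints",
    "measure_elasticity",
    "UnmeasurableLatticeError",
    "DISK_HEPATOCYTE",
    "DISK_DEAD",
    "DISK_COLLAGEN",
]

logger = logging.getLogger(__name__)

DISK_HEPATOCYTE = 1
DISK_DEAD = 2
DISK_COLLAGEN = 3


class UnmeasurableLatticeError(ValueError):
    """Raised when a lattice has no internal nodes to probe."""


@dataclass
class ElastographyResult:
    """Mean internal-node displacement (simulation length units)."""

    displacement: float
    step_index: int


class MechanicalState:
    """Positions, radii and constraints of all colliding entities.

    Septum sub-segments are reduced-coordinate: each is parameterized by its
    parent nodes, a signed normal offset (half the septum thickness) and two
    axial slide values (the prismatic degree of freedom), so the prismatic
    and revolute constraints are maintained by construction whenever
    :func:`apply_joints` re-projects the cached endpoints.
    """

    def __init__(self, node_pos: np.ndarray, node_pinned: np.ndarray,
                 node_mobility: np.ndarray, node_radius: float,
                 septum_nodes: np.ndarray, septum_half_thickness: float,
                 disk_pos: np.ndarray, disk_radius: np.ndarray,
                 disk_mobility: np.ndarray, disk_kind: np.ndarray,
                 cell_diameter: float = 1.0):
        self.node_pos = np.asarray(node_pos, dtype=float).reshape(-1, 2).copy()
        self.node_pinned = np.asarray(node_pinned, dtype=bool).copy()
        self.node_mobility = np.asarray(node_mobility, dtype=float).copy()
        self.node_radius = float(node_radius)
        self.septum_nodes = np.asarray(septum_nodes, dtype=int).reshape(-1, 2).copy()
        self.septum_half_thickness = float(septum_half_thickness)
        # prismatic slides: (n_septa, 2 sub-segments, 2 ends)
        self.slides = np.zeros((len(self.septum_nodes), 2, 2), dtype=float)
        self.disk_pos = np.asarray(disk_pos, dtype=float).reshape(-1, 2).copy()
        self.disk_radius = np.asarray(disk_radius, dtype=float).copy()
        self.disk_mobility = np.asarray(disk_mobility, dtype=float).copy()
        self.disk_kind = np.asarray(disk_kind, dtype=int).copy()
        self.cell_diameter = float(cell_diameter)
        # cached world-space endpoints, (n_septa, 2 segs, 2 ends, 2 xy)
        self.seg_pos = self._project_segments()

    # -- helpers -----------------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.node_pos)

    @property
    def n_disks(self) -> int:
        return len(self.disk_pos)

    def _septum_frames(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        a = self.node_pos[self.septum_nodes[:, 0]]
        b = self.node_pos[self.septum_nodes[:, 1]]
        axis = b - a
        norms = np.linalg.norm(axis, axis=1, keepdims=True)
        norms[norms == 0] = 1.0
        axis = axis / norms
        normal = np.column_stack([-axis[:, 1], axis[:, 0]])
        return a, b, axis, normal

    def _project_segments(self) -> np.ndarray:
        """Endpoints satisfying all joint constraints for current nodes/slides."""
        a, b, axis, normal = self._septum_frames()
        ht = self.septum_half_thickness
        seg = np.empty((len(self.septum_nodes), 2, 2, 2), dtype=float)
        for si, sign in enumerate((+1.0, -1.0)):
            off = sign * ht * normal
            seg[:, si, 0, :] = a + off + self.slides[:, si, 0, None] * axis
            seg[:, si, 1, :] = b + off + self.slides[:, si, 1, None] * axis
        return seg

    def copy(self) -> "MechanicalState":
        st = MechanicalState(self.node_pos, self.node_pinned,
                             self.node_mobility, self.node_radius,
                             self.septum_nodes, self.septum_half_thickness,
                             self.disk_pos, self.disk_radius,
                             self.disk_mobility, self.disk_kind,
                             self.cell_diameter)
        st.slides = self.slides.copy()
        st.seg_pos = self.seg_pos.copy()
        return st

    def to_dict(self) -> dict:
        return {
            "node_pos": self.node_pos.tolist(),
            "node_pinned": self.node_pinned.tolist(),
            "node_mobility": self.node_mobility.tolist(),
            "node_radius": self.node_radius,
            "septum_nodes": self.septum_nodes.tolist(),
            "septum_half_thickness": self.septum_half_thickness,
            "slides": self.slides.tolist(),
            "disk_pos": self.disk_pos.tolist(),
            "disk_radius": self.disk_radius.tolist(),
            "disk_mobility": self.disk_mobility.tolist(),
            "disk_kind": self.disk_kind.tolist(),
            "cell_diameter": self.cell_diameter,
        }

    def max_overlap(self) -> float:
        """Exhaustive residual penetration depth over all colliding pairs."""
        worst = 0.0
        n = self.n_disks
        if n > 1:
            tree = cKDTree(self.disk_pos)
            rmax = float(self.disk_radius.max())
            pairs = tree.query_pairs(2.0 * rmax, output_type="ndarray")
            if len(pairs):
                d = np.linalg.norm(self.disk_pos[pairs[:, 0]]
                                   - self.disk_pos[pairs[:, 1]], axis=1)
                o = (self.disk_radius[pairs[:, 0]]
                     + self.disk_radius[pairs[:, 1]]) - d
                if len(o):
                    worst = max(worst, float(o.max()))
        if n and self.n_nodes:
            dn = np.linalg.norm(self.disk_pos[:, None, :]
                                - self.node_pos[None, :, :], axis=2)
            o = (self.disk_radius[:, None] + self.node_radius) - dn
            worst = max(worst, float(o.max(initial=0.0)))
        if n:
            for k in range(len(self.septum_nodes)):
                for si in range(2):
                    p, q = self.seg_pos[k, si]
                    dist = _point_segment_dist(self.disk_pos, p, q)
                    o = self.disk_radius - dist
                    worst = max(worst, float(o.max(initial=0.0)))
        return worst


def _point_segment_dist(pts: np.ndarray, a: np.ndarray, b: np.ndarray
                        ) -> np.ndarray:
    ab = b - a
    denom = float(ab @ ab)
    if denom == 0.0:
        return np.linalg.norm(pts - a, axis=1)
    t = np.clip((pts - a) @ ab / denom, 0.0, 1.0)
    proj = a + t[:, None] * ab
    return np.linalg.norm(pts - proj, axis=1)


def apply_joints(state: MechanicalState) -> MechanicalState:
    """Re-project septum sub-segments onto the joint constraint manifold.

    Any tentative endpoint motion stored in ``state.seg_pos`` is decomposed:
    the component along the prismatic axis updates the slide coordinates, the
    rest is discarded, and endpoints are rebuilt from the node positions.
    After this call the sub-segments are parallel to their axis at the fixed
    normal offset, with ends anchored to the (possibly moved) triad nodes.
    """
    a, b, axis, _ = state._septum_frames()
    anchors = np.stack([a, b], axis=1)          # (S, 2 ends, 2)
    for si in range(2):
        for e in range(2):
            delta = state.seg_pos[:, si, e, :] - anchors[:, e, :]
            state.slides[:, si, e] = np.einsum("ij,ij->i", delta, axis)
    state.seg_pos = state._project_segments()
    return state


def resolve_collisions(state: MechanicalState, iterations: int = 10,
                       tolerance: float | None = None,
                       project_joints: bool = True,
                       warn: bool = True) -> MechanicalState:
    """Iteratively separate overlapping colliding pairs (in place).

    Each sweep resolves disk-disk, disk-node and disk-segment contacts by
    displacing the participants along the contact normal, weighted by their
    mobilities (pinned or zero-mobility entities stay put; segment reactions
    are routed to their parent nodes).  Stops early once the worst residual
    penetration drops below the tolerance; if ``iterations`` sweeps are
    exhausted first, a warning is logged and the state returned as-is.
    """
    if tolerance is None:
        tolerance = 1e-3 * state.cell_diameter
    node_w = state.node_mobility * (~state.node_pinned)
    rmax_d = float(state.disk_radius.max()) if state.n_disks else 0.0

    converged = False
    last_worst = float("inf")
    for _ in range(iterations):
        worst = 0.0
        if project_joints:
            state.seg_pos = state._project_segments()

        disk_delta = np.zeros_like(state.disk_pos)
        disk_cnt = np.zeros(state.n_disks)
        node_delta = np.zeros_like(state.node_pos)
        node_cnt = np.zeros(state.n_nodes)

        # disk-disk
        if state.n_disks > 1:
            tree = cKDTree(state.disk_pos)
            pairs = tree.query_pairs(2.0 * rmax_d, output_type="ndarray")
            if len(pairs):
                i, j = pairs[:, 0], pairs[:, 1]
                dvec = state.disk_pos[i] - state.disk_pos[j]
                dist = np.linalg.norm(dvec, axis=1)
                overlap = (state.disk_radius[i] + state.disk_radius[j]) - dist
                hit = overlap > tolerance * 0.5
                if hit.any():
                    i, j = i[hit], j[hit]
                    dvec = dvec[hit]
                    dist = dist[hit]
                    overlap = overlap[hit]
                    worst = max(worst, float(overlap.max()))
                    dist[dist == 0] = 1.0
                    n = dvec / dist[:, None]
                    wi = state.disk_mobility[i]
                    wj = state.disk_mobility[j]
                    wsum = wi + wj
                    wsum[wsum == 0] = 1.0
                    corr = overlap / wsum
                    np.add.at(disk_delta, i, (wi * corr)[:, None] * n)
                    np.add.at(disk_delta, j, -(wj * corr)[:, None] * n)
                    np.add.at(disk_cnt, i, 1.0)
                    np.add.at(disk_cnt, j, 1.0)

        # disk-node (triad disks)
        if state.n_disks and state.n_nodes:
            tree = cKDTree(state.disk_pos)
            groups = tree.query_ball_point(state.node_pos,
                                           state.node_radius + rmax_d)
            for k, ids in enumerate(groups):
                if not ids:
                    continue
                ids = np.asarray(ids)
                dvec = state.disk_pos[ids] - state.node_pos[k]
                dist = np.linalg.norm(dvec, axis=1)
                overlap = (state.disk_radius[ids] + state.node_radius) - dist
                hit = overlap > tolerance * 0.5
                if not hit.any():
                    continue
                ids, dvec, dist, overlap = (ids[hit], dvec[hit], dist[hit],
                                            overlap[hit])
                worst = max(worst, float(overlap.max()))
                dist[dist == 0] = 1.0
                n = dvec / dist[:, None]
                wd = state.disk_mobility[ids]
                wn = node_w[k]
                wsum = wd + wn
                wsum[wsum == 0] = 1.0
                corr = overlap / wsum
                disk_delta[ids] += (wd * corr)[:, None] * n
                disk_cnt[ids] += 1.0
                if wn > 0:
                    node_delta[k] -= wn * (corr[:, None] * n).sum(axis=0)
                    node_cnt[k] += len(ids)

        # disk-segment
        if state.n_disks and len(state.septum_nodes):
            tree = cKDTree(state.disk_pos)
            for k in range(len(state.septum_nodes)):
                na, nb = state.septum_nodes[k]
                for si in range(2):
                    p, q = state.seg_pos[k, si]
                    mid = 0.5 * (p + q)
                    half_len = 0.5 * float(np.linalg.norm(q - p))
                    ids = tree.query_ball_point(mid, half_len + rmax_d)
                    if not ids:
                        continue
                    ids = np.asarray(ids)
                    ab = q - p
                    denom = float(ab @ ab) or 1.0
                    t = np.clip((state.disk_pos[ids] - p) @ ab / denom, 0.0, 1.0)
                    proj = p + t[:, None] * ab
                    dvec = state.disk_pos[ids] - proj
                    dist = np.linalg.norm(dvec, axis=1)
                    overlap = state.disk_radius[ids] - dist
                    hit = overlap > tolerance * 0.5
                    if not hit.any():
                        continue
                    ids, dvec, dist, overlap, t = (ids[hit], dvec[hit],
                                                   dist[hit], overlap[hit],
                                                   t[hit])
                    worst = max(worst, float(overlap.max()))
                    dist[dist == 0] = 1.0
                    n = dvec / dist[:, None]
                    wd = state.disk_mobility[ids]
                    # reaction distributed to the two parent nodes
                    wa, wb = node_w[na], node_w[nb]
                    wseg = 0.5 * (wa + wb)
                    wsum = wd + wseg
                    wsum[wsum == 0] = 1.0
                    corr = overlap / wsum
                    disk_delta[ids] += (wd * corr)[:, None] * n
                    disk_cnt[ids] += 1.0
                    if wseg > 0:
                        react = -(wseg * corr)[:, None] * n
                        if wa > 0:
                            node_delta[na] += ((1.0 - t)[:, None]
                                               * react).sum(axis=0)
                            node_cnt[na] += float(((1.0 - t) > 0).sum())
                        if wb > 0:
                            node_delta[nb] += (t[:, None] * react).sum(axis=0)
                            node_cnt[nb] += float((t > 0).sum())

        # Jacobi averaging: contacts vote, entities move by the mean
        moved_d = disk_cnt > 0
        if moved_d.any():
            state.disk_pos[moved_d] += (disk_delta[moved_d]
                                        / disk_cnt[moved_d, None])
        moved_n = node_cnt > 0
        if moved_n.any():
            state.node_pos[moved_n] += (node_delta[moved_n]
                                        / node_cnt[moved_n, None])

        last_worst = worst
        if worst < tolerance:
            converged = True
            break

    if project_joints:
        state.seg_pos = state._project_segments()
    if not converged:
        logger.log(logging.WARNING if warn else logging.DEBUG,
                   "collision relaxation did not converge in %d sweeps "
                   "(last residual %.3g)", iterations, last_worst)
    return state


def measure_elasticity(state: MechanicalState, internal_nodes, outer_nodes,
                       impulse_magnitude: float, shrink_fraction: float,
                       step_index: int = 0, iterations: int = 10,
                       substeps: int = 8,
                       target: np.ndarray | None = None) -> ElastographyResult:
    """Probe tissue pliability without perturbing the simulation.

    On a deep copy: hepatocyte and dead-agent radii are shrunk by
    ``shrink_fraction``, outer nodes are pinned, every internal node receives
    an inward impulse (toward ``target``, by default the node centroid) and
    one constrained mechanical step is taken.  Returns the mean displacement
    magnitude of the internal nodes; the copy is discarded.
    """
    if impulse_magnitude <= 0:
        raise ValueError("impulse_magnitude must be > 0")
    if not (0.0 < shrink_fraction < 1.0):
        raise ValueError("shrink_fraction must be in (0, 1)")
    internal = np.asarray(list(internal_nodes), dtype=int)
    outer = np.asarray(list(outer_nodes), dtype=int)
    if len(internal) == 0:
        raise UnmeasurableLatticeError(
            "unmeasurable lattice: no internal (degree-3, non-border) nodes")

    work = state.copy()
    shrink = work.disk_kind != DISK_COLLAGEN
    work.disk_radius[shrink] *= (1.0 - shrink_fraction)
    work.node_pinned[outer] = True

    if target is None:
        target = work.node_pos.mean(axis=0)
    origin = work.node_pos[internal].copy()
    direction = np.asarray(target, dtype=float)[None, :] - origin
    norms = np.linalg.norm(direction, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    direction = direction / norms
    mobility = (work.node_mobility[internal]
                * (~work.node_pinned[internal]))[:, None]
    # the impulse is integrated in substeps so that fast-moving septa cannot
    # tunnel through a cell layer between contact checks
    substeps = max(1, int(substeps))
    for _ in range(substeps):
        work.node_pos[internal] += (impulse_magnitude / substeps
                                    * mobility * direction)
        apply_joints(work)
        resolve_collisions(work, iterations=iterations, warn=False)

    disp = float(np.linalg.norm(work.node_pos[internal] - origin,
                                axis=1).mean())
    return ElastographyResult(displacement=disp, step_index=step_index)
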