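"""Simulation orchestration: configuration, state, the step loop and runs.

One tick applies a fixed sub-phase order: scheduled injury pulse, agent rules
(hepatocytes, then Kupffer cells, then fibrogenic cells, each in a freshly
shuffled order), monocyte recruitment, field diffusion/degradation, a
mechanical audit, and bookkeeping.  Randomness flows through named
substreams (placement / agents / injury / recruitment) spawned from the
replicate seed, so a given config + seed determines every output exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field as dc_field, replace

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from . import agents as ag
from . import geometry as geo
from . import mechanics as mech
from .fields import CytokineField

__all__ = [
    "GeometryConfig",
    "FieldParams",
    "InjuryConfig",
    "TherapyConfig",
    "MechanicsConfig",
    "RunConfig",
    "SimulationConfig",
    "SimulationState",
    "ScenarioResult",
    "ConfigError",
    "initialize",
    "injury_pulse",
    "step",
    "apply_therapy",
    "run",
    "run_scenarios",
    "measure_state_elasticity",
    "serialize_state",
    "deserialize_state",
    "state_hash",
]

THERAPY_KINDS = ("none", "anti_tnf", "m2_enhance")

OCC_EMPTY = 0
OCC_HEPATOCYTE = 1
OCC_DEAD = 2
OCC_COLLAGEN = 3

CENSUS_COLUMNS = [
    "step", "hepatocytes", "dead", "kc_quiescent", "kc_activated", "hsc",
    "pf", "mf", "collagen", "tnf_total", "tgf_total", "hmgb1_total",
    "elastic_displacement",
]


class ConfigError(ValueError):
    """Raised with the full list of offending configuration keys."""

    def __init__(self, errors):
        self.errors = list(errors)
        super().__init__("invalid configuration:\n  " + "\n  ".join(self.errors))


# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class GeometryConfig:
    n_rows: int = 2
    n_cols: int = 2
    hex_side: float = 8.0
    cell_diameter: float = 1.0
    septum_thickness: float = 0.3
    #: explicit offset (col, row) hexagon cells; overrides n_rows/n_cols
    cells: tuple[tuple[int, int], ...] | None = None


@dataclass(frozen=True)
class FieldParams:
    diffusion_coeff: float = 0.2
    degradation_rate: float = 0.05
    threshold: float = 1.0


@dataclass(frozen=True)
class InjuryConfig:
    enabled: bool = True
    start_step: int = 0
    period: int = 20
    radius: float = 3.0
    kill_prob: float = 0.07


@dataclass(frozen=True)
class TherapyConfig:
    kind: str = "none"
    anti_tnf_factor: float = 2.0
    m2_factor: float = 2.0
    applied: bool = False


@dataclass(frozen=True)
class MechanicsConfig:
    impulse_magnitude: float = 1.0
    shrink_fraction: float = 0.02
    relax_iterations: int = 10
    #: impulse integration substeps (prevents septa tunneling through cells)
    impulse_substeps: int = 8
    #: collision tolerance as a fraction of the cell diameter
    tolerance_factor: float = 1e-3
    #: impulse direction: toward the patch centroid or the nearest lobule center
    impulse_target: str = "patch"
    #: how close a site must be to a septum/triad to anchor collagen
    anchor_reach: float = 1.1
    audit_interval: int = 50


@dataclass(frozen=True)
class RunConfig:
    n_steps: int = 200
    seed: int = 0
    replicates: int = 1
    elastography_interval: int = 20
    portal_fibroblasts_per_triad: int = 3
    measure_elastography: bool = True


@dataclass(frozen=True)
class SimulationConfig:
    geometry: GeometryConfig = GeometryConfig()
    hepatocyte: ag.HepatocyteParams = ag.HepatocyteParams()
    kupffer: ag.KupfferParams = ag.KupfferParams()
    fibrogenic: ag.FibrogenicParams = ag.FibrogenicParams()
    dead_cell: ag.DeadCellParams = ag.DeadCellParams()
    field_tnf: FieldParams = FieldParams(threshold=1.2)
    field_tgf: FieldParams = FieldParams()
    field_hmgb1: FieldParams = FieldParams(degradation_rate=0.1,
                                           threshold=0.5)
    injury: InjuryConfig = InjuryConfig()
    therapy: TherapyConfig = TherapyConfig()
    mechanics: MechanicsConfig = MechanicsConfig()
    run: RunConfig = RunConfig()

    def field_params(self, name: str) -> FieldParams:
        return getattr(self, f"field_{name}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        cells = d["geometry"]["cells"]
        if cells is not None:
            d["geometry"]["cells"] = [list(c) for c in cells]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        sections = {
            "geometry": GeometryConfig, "hepatocyte": ag.HepatocyteParams,
            "kupffer": ag.KupfferParams, "fibrogenic": ag.FibrogenicParams,
            "dead_cell": ag.DeadCellParams, "field_tnf": FieldParams,
            "field_tgf": FieldParams, "field_hmgb1": FieldParams,
            "injury": InjuryConfig, "therapy": TherapyConfig,
            "mechanics": MechanicsConfig, "run": RunConfig,
        }
        unknown = set(d) - set(sections)
        if unknown:
            raise ConfigError([f"unknown section {k!r}" for k in sorted(unknown)])
        kwargs = {}
        errors = []
        for name, typ in sections.items():
            sub = d.get(name, {})
            if sub is None:
                sub = {}
            valid = {f.name for f in dataclasses.fields(typ)}
            bad = set(sub) - valid
            if bad:
                errors.extend(f"unknown key {name}.{k}" for k in sorted(bad))
                continue
            sub = dict(sub)
            for key in ("lifespan_range", "activated_lifespan_range",
                        "tnf_production", "tgf_production", "hmgb1_amount"):
                if key in sub and sub[key] is not None:
                    sub[key] = tuple(sub[key])
            if name == "geometry" and sub.get("cells") is not None:
                sub["cells"] = tuple(tuple(c) for c in sub["cells"])
            kwargs[name] = typ(**sub)
        if errors:
            raise ConfigError(errors)
        return cls(**kwargs)

    def validated(self) -> "SimulationConfig":
        validate_config(self)
        return self


def _check_prob(errors, key, value):
    if not (0.0 <= value <= 1.0):
        errors.append(f"{key} must be in [0, 1], got {value}")


def _check_nonneg(errors, key, value):
    if value < 0:
        errors.append(f"{key} must be >= 0, got {value}")


def validate_config(cfg: SimulationConfig) -> None:
    """Schema-validate a config, raising :class:`ConfigError` listing every
    offending key."""
    errors: list[str] = []
    g = cfg.geometry
    if g.cells is None and (g.n_rows < 1 or g.n_cols < 1):
        errors.append(f"geometry.n_rows/n_cols must be >= 1, got "
                      f"({g.n_rows}, {g.n_cols})")
    if g.hex_side <= 0:
        errors.append(f"geometry.hex_side must be > 0, got {g.hex_side}")
    if g.cell_diameter <= 0 or g.cell_diameter >= g.hex_side:
        errors.append(
            f"geometry.cell_diameter must be in (0, hex_side), got "
            f"{g.cell_diameter}")
    if g.septum_thickness <= 0:
        errors.append("geometry.septum_thickness must be > 0")

    _check_prob(errors, "hepatocyte.tnf_death_prob", cfg.hepatocyte.tnf_death_prob)
    _check_prob(errors, "kupffer.polarization_increment",
                cfg.kupffer.polarization_increment)
    _check_prob(errors, "kupffer.recruit_prob", cfg.kupffer.recruit_prob)
    _check_nonneg(errors, "kupffer.tnf_suppression_factor",
                  cfg.kupffer.tnf_suppression_factor)
    _check_prob(errors, "fibrogenic.proliferation_prob",
                cfg.fibrogenic.proliferation_prob)
    _check_prob(errors, "fibrogenic.deposit_prob", cfg.fibrogenic.deposit_prob)
    _check_prob(errors, "injury.kill_prob", cfg.injury.kill_prob)
    if cfg.injury.period < 1:
        errors.append(f"injury.period must be >= 1, got {cfg.injury.period}")
    inradius = g.hex_side * geo.SQRT3 / 2.0
    if cfg.injury.radius > inradius:
        errors.append(f"injury.radius {cfg.injury.radius} exceeds the lobule "
                      f"inradius {inradius:.3f}")
    for fname in ("tnf", "tgf", "hmgb1"):
        fp = cfg.field_params(fname)
        if not (0.0 <= fp.diffusion_coeff <= 0.25):
            errors.append(f"field_{fname}.diffusion_coeff must be in "
                          f"[0, 0.25], got {fp.diffusion_coeff}")
        _check_prob(errors, f"field_{fname}.degradation_rate",
                    fp.degradation_rate)
        if fp.threshold <= 0:
            errors.append(f"field_{fname}.threshold must be > 0")
    if cfg.therapy.kind not in THERAPY_KINDS:
        errors.append(f"therapy.kind must be one of {THERAPY_KINDS}, got "
                      f"{cfg.therapy.kind!r}")
    if cfg.therapy.kind != "none":
        factor = (cfg.therapy.anti_tnf_factor if cfg.therapy.kind == "anti_tnf"
                  else cfg.therapy.m2_factor)
        if factor <= 1.0:
            errors.append(f"therapy factor for {cfg.therapy.kind} must be > 1, "
                          f"got {factor}")
    m = cfg.mechanics
    if m.impulse_magnitude <= 0:
        errors.append("mechanics.impulse_magnitude must be > 0")
    if not (0.0 < m.shrink_fraction < 1.0):
        errors.append("mechanics.shrink_fraction must be in (0, 1)")
    if m.impulse_target not in ("patch", "lobule"):
        errors.append("mechanics.impulse_target must be 'patch' or 'lobule'")
    if cfg.run.n_steps < 0 or cfg.run.replicates < 1:
        errors.append("run.n_steps must be >= 0 and run.replicates >= 1")
    if cfg.run.elastography_interval < 1:
        errors.append("run.elastography_interval must be >= 1")
    if errors:
        raise ConfigError(errors)


def apply_therapy(cfg: SimulationConfig) -> SimulationConfig:
    """Fold the configured therapy into the relevant parameters.

    ``anti_tnf`` multiplies the TNF field degradation rate; ``m2_enhance``
    multiplies Kupffer TGF production.  Nothing else changes; applying a
    second time is rejected to avoid compounding factors.
    """
    t = cfg.therapy
    if t.kind == "none":
        return cfg
    if t.kind not in THERAPY_KINDS:
        raise ConfigError([f"therapy.kind must be one of {THERAPY_KINDS}"])
    if t.applied:
        return cfg
    if t.kind == "anti_tnf":
        if t.anti_tnf_factor <= 1.0:
            raise ConfigError(["therapy.anti_tnf_factor must be > 1"])
        new_rate = min(1.0, cfg.field_tnf.degradation_rate * t.anti_tnf_factor)
        return replace(cfg,
                       field_tnf=replace(cfg.field_tnf,
                                         degradation_rate=new_rate),
                       therapy=replace(t, applied=True))
    if t.m2_factor <= 1.0:
        raise ConfigError(["therapy.m2_factor must be > 1"])
    new_kupffer = replace(
        cfg.kupffer,
        tgf_production_factor=cfg.kupffer.tgf_production_factor * t.m2_factor)
    return replace(cfg, kupffer=new_kupffer, therapy=replace(t, applied=True))


# ---------------------------------------------------------------------------
# state


RNG_STREAMS = ("placement", "agents", "injury", "recruitment")


def _spawn_streams(seed: int) -> dict[str, np.random.Generator]:
    root = np.random.SeedSequence(seed)
    children = root.spawn(len(RNG_STREAMS))
    return {name: np.random.Generator(np.random.PCG64(child))
            for name, child in zip(RNG_STREAMS, children)}


class SimulationState:
    """Complete simulation snapshot: lattice, sites, agents, fields, RNG."""

    SCHEMA_VERSION = 1

    def __init__(self, config: SimulationConfig, seed: int):
        self.config = config
        self.seed = seed
        self.step_index = 0
        g = config.geometry
        if g.cells is not None:
            self.lattice = geo.build_lattice_from_cells(
                [tuple(c) for c in g.cells], g.hex_side, g.septum_thickness)
        else:
            self.lattice = geo.build_lattice(g.n_rows, g.n_cols, g.hex_side,
                                             g.septum_thickness)
        self.sites = geo.build_site_lattice(self.lattice, g.cell_diameter)
        self.rng = _spawn_streams(seed)

        self.occupancy = np.zeros(self.sites.n_sites, dtype=np.int8)
        self.hepatocytes: dict[int, ag.Hepatocyte] = {}
        self.dead: dict[int, ag.DeadHepatocyte] = {}
        self.collagen: dict[int, ag.CollagenDeposit] = {}
        self.kupffer: list[ag.KupfferCell] = []
        self.fibrogenic: list[ag.FibrogenicCell] = []
        self.cumulative_deaths = 0
        self.cumulative_replications = 0

        extent = self.lattice.patch_extent
        self.fields: dict[str, CytokineField] = {}
        for name in ("tnf", "tgf", "hmgb1"):
            fp = config.field_params(name)
            self.fields[name] = CytokineField(
                name, extent, g.cell_diameter, fp.diffusion_coeff,
                fp.degradation_rate, fp.threshold)

        self._build_caches()

    # -- derived caches (deterministic functions of lattice/config) --------

    def _build_caches(self) -> None:
        sites = self.sites
        centers = self.lattice.lobule_centers()
        self.site_center_dist = np.linalg.norm(
            sites.positions - centers[sites.lobule_of], axis=1)
        any_field = self.fields["tnf"]
        self.site_iy, self.site_ix = any_field.cell_indices(sites.positions)
        reach = self.config.mechanics.anchor_reach
        self.anchorable = sites.anchored_mask(reach).copy()
        self.site_tree = cKDTree(sites.positions)
        self.internal_nodes, self.outer_nodes = geo.classify_nodes(self.lattice)

    # -- census ------------------------------------------------------------

    def counts(self) -> dict[str, int]:
        kc_act = sum(1 for k in self.kupffer if k.state == ag.ACTIVATED)
        fib = {"hsc": 0, "portal_fibroblast": 0, "myofibroblast": 0}
        for f in self.fibrogenic:
            fib[f.kind] += 1
        return {
            "hepatocytes": len(self.hepatocytes),
            "dead": len(self.dead),
            "kc_quiescent": len(self.kupffer) - kc_act,
            "kc_activated": kc_act,
            "hsc": fib["hsc"],
            "pf": fib["portal_fibroblast"],
            "mf": fib["myofibroblast"],
            "collagen": len(self.collagen),
        }

    def census_row(self, displacement: float = math.nan) -> dict:
        row = {"step": self.step_index}
        row.update(self.counts())
        row["tnf_total"] = self.fields["tnf"].total_mass()
        row["tgf_total"] = self.fields["tgf"].total_mass()
        row["hmgb1_total"] = self.fields["hmgb1"].total_mass()
        row["elastic_displacement"] = displacement
        return row

    # -- occupancy helpers -------------------------------------------------

    def add_hepatocyte(self, cell: ag.Hepatocyte) -> None:
        assert self.occupancy[cell.site] == OCC_EMPTY
        self.occupancy[cell.site] = OCC_HEPATOCYTE
        self.hepatocytes[cell.site] = cell

    def kill_hepatocyte(self, site: int) -> None:
        del self.hepatocytes[site]
        self.occupancy[site] = OCC_DEAD
        self.dead[site] = ag.DeadHepatocyte(site)
        self.cumulative_deaths += 1

    def clear_dead(self, site: int) -> None:
        if site not in self.dead:
            raise RuntimeError(
                f"phagocytosis of already-removed dead agent at site {site}")
        del self.dead[site]
        self.occupancy[site] = OCC_EMPTY

    def add_collagen(self, site: int) -> None:
        assert self.occupancy[site] == OCC_EMPTY
        sl = self.sites
        reach = self.config.mechanics.anchor_reach
        if sl.dist_to_septum[site] <= reach:
            anchor = ("septum", int(sl.nearest_septum[site]))
        elif sl.dist_to_triad[site] <= reach:
            anchor = ("triad", int(sl.nearest_triad[site]))
        else:
            neigh = [j for j in sl.neighbors[site]
                     if self.occupancy[j] == OCC_COLLAGEN]
            anchor = ("collagen", int(neigh[0]) if neigh else -1)
        self.occupancy[site] = OCC_COLLAGEN
        self.collagen[site] = ag.CollagenDeposit(site, anchor)
        for j in sl.neighbors[site]:
            self.anchorable[j] = True

    def find_deposit_site(self, position) -> int | None:
        """Nearest empty, structure-anchored site within fibrogenic reach."""
        reach = self.config.fibrogenic.reach
        ids = self.site_tree.query_ball_point(position, reach)
        best = None
        best_d = math.inf
        for i in ids:
            if self.occupancy[i] == OCC_EMPTY and self.anchorable[i]:
                d = math.hypot(self.sites.positions[i, 0] - position[0],
                               self.sites.positions[i, 1] - position[1])
                if d < best_d:
                    best, best_d = int(i), d
        return best

    # -- mechanics view ----------------------------------------------------

    def mechanical_view(self) -> mech.MechanicalState:
        occ_sites = np.flatnonzero(self.occupancy != OCC_EMPTY)
        kinds = np.empty(len(occ_sites), dtype=int)
        occ = self.occupancy[occ_sites]
        kinds[occ == OCC_HEPATOCYTE] = mech.DISK_HEPATOCYTE
        kinds[occ == OCC_DEAD] = mech.DISK_DEAD
        kinds[occ == OCC_COLLAGEN] = mech.DISK_COLLAGEN
        d = self.config.geometry.cell_diameter
        radius = np.full(len(occ_sites), d / 2.0)
        mobility = np.where(kinds == mech.DISK_COLLAGEN, 0.0, 1.0)
        lat = self.lattice
        septum_nodes = np.array([[s.node_a, s.node_b] for s in lat.septa],
                                dtype=int)
        return mech.MechanicalState(
            node_pos=lat.node_positions(),
            node_pinned=np.zeros(lat.n_nodes, dtype=bool),
            node_mobility=np.ones(lat.n_nodes),
            node_radius=lat.septum_thickness / 2.0,
            septum_nodes=septum_nodes,
            septum_half_thickness=lat.septum_thickness / 2.0,
            disk_pos=self.sites.positions[occ_sites],
            disk_radius=radius,
            disk_mobility=mobility,
            disk_kind=kinds,
            cell_diameter=d,
        )


def initialize(config: SimulationConfig, seed: int | None = None
               ) -> SimulationState:
    """Build the lattice, spiral-fill hepatocytes and seed all populations."""
    validate_config(config)
    if seed is None:
        seed = config.run.seed
    state = SimulationState(config, seed)
    rng = state.rng["placement"]
    g = config.geometry

    filled = geo.spiral_fill_sites(state.lattice, g.cell_diameter, rng,
                                   state.sites)
    for site in filled:
        lifespan = int(round(ag.sample_range(
            rng, config.hepatocyte.lifespan_range)))
        state.add_hepatocyte(ag.Hepatocyte(int(site), age=0, lifespan=lifespan))

    n_kupffer, n_hsc = ag.initialize_populations(len(filled))
    xmin, ymin, xmax, ymax = state.lattice.patch_extent
    for _ in range(n_kupffer):
        state.kupffer.append(ag.KupfferCell(
            x=float(rng.uniform(xmin, xmax)), y=float(rng.uniform(ymin, ymax))))

    centers = state.lattice.lobule_centers()
    s = state.lattice.hex_side
    placed = 0
    while placed < n_hsc:
        x = float(rng.uniform(xmin, xmax))
        y = float(rng.uniform(ymin, ymax))
        if _in_any_lobule(x, y, centers, s):
            state.fibrogenic.append(ag.FibrogenicCell(x, y, ag.HSC))
            placed += 1

    for node in state.lattice.nodes:
        for _ in range(config.run.portal_fibroblasts_per_triad):
            state.fibrogenic.append(ag.FibrogenicCell(
                node.position[0], node.position[1], ag.PORTAL_FIBROBLAST))
    return state


def _in_any_lobule(x: float, y: float, centers: np.ndarray, side: float) -> bool:
    # flat-top regular hexagon containment around the nearest center
    d = np.abs(np.array([x, y]) - centers)
    q, r = d[:, 0], d[:, 1]
    inside = (r <= geo.SQRT3 / 2.0 * side) & (geo.SQRT3 * q + r
                                              <= geo.SQRT3 * side)
    return bool(inside.any())


def injury_pulse(state: SimulationState, radius: float, kill_prob: float,
                 rng: np.random.Generator) -> SimulationState:
    """One pulse of centrilobular toxicity: hepatocytes within ``radius`` of
    their lobule center die with probability ``kill_prob``."""
    candidates = np.flatnonzero(
        (state.occupancy == OCC_HEPATOCYTE)
        & (state.site_center_dist <= radius))
    if len(candidates) == 0 or kill_prob <= 0:
        return state
    draws = rng.random(len(candidates))
    for site, u in zip(candidates, draws):
        if u < kill_prob:
            state.kill_hepatocyte(int(site))
    return state


# ---------------------------------------------------------------------------
# the step loop


def _hepatocyte_phase(state: SimulationState) -> None:
    cfg = state.config
    rng = state.rng["agents"]
    occ = state.occupancy
    hot = state.fields["tnf"].above_threshold_mask()
    site_hot = hot[state.site_iy, state.site_ix]

    # only cells that can possibly act: TNF-exposed, or next to empty space
    empty_sites = np.flatnonzero(occ == OCC_EMPTY)
    cand = set(np.flatnonzero(
        site_hot & (occ == OCC_HEPATOCYTE)).tolist())
    for e in empty_sites:
        for j in state.sites.neighbors[e]:
            if occ[j] == OCC_HEPATOCYTE:
                cand.add(int(j))
    cand = sorted(cand)
    order = rng.permutation(len(cand))
    nbrs = state.sites.neighbors
    for k in order:
        site = cand[k]
        cell = state.hepatocytes.get(site)
        if cell is None:  # died earlier this phase
            continue
        empty_neighbors = [int(j) for j in nbrs[site] if occ[j] == OCC_EMPTY]
        collagen_adjacent = any(occ[j] == OCC_COLLAGEN for j in nbrs[site])
        event = ag.hepatocyte_step(cell, bool(site_hot[site]), empty_neighbors,
                                   collagen_adjacent, rng, cfg.hepatocyte)
        if event[0] == "die":
            state.kill_hepatocyte(site)
        elif event[0] == "replicate":
            target = event[1]
            lifespan = int(round(ag.sample_range(
                rng, cfg.hepatocyte.lifespan_range)))
            state.add_hepatocyte(ag.Hepatocyte(target, age=0,
                                               lifespan=lifespan))
            state.cumulative_replications += 1
    # remaining hepatocytes: plain aging (no possible event, no rng draws)
    cand_set = set(cand)
    expired = []
    for site, cell in state.hepatocytes.items():
        if site in cand_set:
            continue
        cell.age += 1
        if cell.age > cell.lifespan:
            expired.append(site)
    for site in expired:
        state.kill_hepatocyte(site)


def _kupffer_phase(state: SimulationState) -> None:
    cfg = state.config
    rng = state.rng["agents"]
    kcs = state.kupffer
    if not kcs:
        return
    xmin, ymin, xmax, ymax = state.lattice.patch_extent
    n = len(kcs)
    # random walk
    angles = rng.random(n) * 2.0 * math.pi
    steps = cfg.kupffer.speed
    for kc, a in zip(kcs, angles):
        kc.x = min(max(kc.x + steps * math.cos(a), xmin), xmax)
        kc.y = min(max(kc.y + steps * math.sin(a), ymin), ymax)

    dead_sites = list(state.dead.keys())
    dead_tree = None
    if dead_sites:
        dead_pos = state.sites.positions[dead_sites]
        dead_tree = cKDTree(dead_pos)

    order = rng.permutation(n)
    claimed: set[int] = set()
    survivors: list[ag.KupfferCell] = [None] * n  # type: ignore[list-item]
    for k in order:
        kc = kcs[k]
        adjacent: list[int] = []
        if dead_tree is not None:
            ids = dead_tree.query_ball_point((kc.x, kc.y),
                                             cfg.kupffer.sense_radius)
            free = [dead_sites[i] for i in ids if dead_sites[i] not in claimed]
            if free:
                free.sort(key=lambda s: (
                    (state.sites.positions[s, 0] - kc.x) ** 2
                    + (state.sites.positions[s, 1] - kc.y) ** 2))
                adjacent = [free[0]]
        events = ag.kupffer_step(kc, adjacent, state.fields, rng, cfg.kupffer)
        for ev in events:
            if ev[0] == "phagocytize":
                claimed.add(ev[1])
                state.clear_dead(ev[1])
        if kc.state == ag.ACTIVATED:
            kc.age_activated += 1
            if kc.age_activated > kc.lifespan:
                continue  # activated Kupffer cell dies
        survivors[k] = kc
    state.kupffer = [kc for kc in survivors if kc is not None]


def _fibrogenic_phase(state: SimulationState) -> None:
    cfg = state.config
    rng = state.rng["agents"]
    cells = state.fibrogenic
    if not cells:
        return
    xmin, ymin, xmax, ymax = state.lattice.patch_extent
    tnf_mask = state.fields["tnf"].above_threshold_mask()
    tgf_mask = state.fields["tgf"].above_threshold_mask()
    hmgb1_mask = state.fields["hmgb1"].above_threshold_mask()
    fld = state.fields["tnf"]

    n = len(cells)
    angles = rng.random(n) * 2.0 * math.pi
    order = rng.permutation(n)
    born: list[ag.FibrogenicCell] = []
    for k in order:
        cell = cells[k]
        if cell.kind != ag.PORTAL_FIBROBLAST:
            speed = cfg.fibrogenic.speed
            cell.x = min(max(cell.x + speed * math.cos(angles[k]), xmin), xmax)
            cell.y = min(max(cell.y + speed * math.sin(angles[k]), ymin), ymax)
        iy, ix = fld.cell_index((cell.x, cell.y))
        events = ag.fibrogenic_step(
            cell, bool(tnf_mask[iy, ix]), bool(hmgb1_mask[iy, ix]),
            bool(tgf_mask[iy, ix]), rng, cfg.fibrogenic,
            find_deposit_site=lambda c=cell: state.find_deposit_site((c.x, c.y)))
        for ev in events:
            if ev[0] == "proliferate":
                born.append(ag.FibrogenicCell(cell.x, cell.y,
                                              ag.MYOFIBROBLAST))
            elif ev[0] == "deposit":
                state.add_collagen(ev[1])
    cells.extend(born)


def _dead_cell_phase(state: SimulationState) -> None:
    cfg = state.config.dead_cell
    rng = state.rng["agents"]
    if not state.dead:
        return
    emitters = []
    for site, dcell in state.dead.items():
        dcell.steps_since_death += 1
        if dcell.steps_since_death > cfg.hmgb1_delay:
            emitters.append(site)
    if emitters:
        emitters = np.asarray(emitters)
        lo, hi = cfg.hmgb1_amount
        amounts = rng.uniform(lo, hi, size=len(emitters)) if hi > lo \
            else np.full(len(emitters), lo)
        hmgb1 = state.fields["hmgb1"]
        hmgb1.deposit_many(state.site_iy[emitters], state.site_ix[emitters],
                           amounts)


def _mechanics_phase(state: SimulationState) -> None:
    interval = state.config.mechanics.audit_interval
    if interval <= 0 or state.step_index % interval:
        return
    view = state.mechanical_view()
    tol = (state.config.mechanics.tolerance_factor
           * state.config.geometry.cell_diameter)
    worst = view.max_overlap()
    if worst >= tol:
        mech.resolve_collisions(view, state.config.mechanics.relax_iterations,
                                tol)
        if view.max_overlap() >= tol:
            raise RuntimeError(
                f"collider overlap invariant breached at step "
                f"{state.step_index}: residual {worst:.4g}")


def step(state: SimulationState) -> SimulationState:
    """Advance the simulation by one tick (fixed sub-phase order)."""
    cfg = state.config
    inj = cfg.injury
    if (inj.enabled and state.step_index >= inj.start_step
            and (state.step_index - inj.start_step) % inj.period == 0):
        injury_pulse(state, inj.radius, inj.kill_prob, state.rng["injury"])

    _hepatocyte_phase(state)
    _kupffer_phase(state)
    _fibrogenic_phase(state)
    _dead_cell_phase(state)

    recruits = ag.recruit_monocytes(state.fields["hmgb1"],
                                    state.rng["recruitment"], cfg.kupffer)
    state.kupffer.extend(recruits)

    for fld in state.fields.values():
        fld.step()
        if fld.grid.min() < 0:  # pragma: no cover - defensive
            raise RuntimeError(f"negative concentration in field {fld.name}")

    _mechanics_phase(state)
    state.step_index += 1
    return state


def measure_state_elasticity(state: SimulationState) -> mech.ElastographyResult:
    """Non-perturbing elastography of the current state."""
    m = state.config.mechanics
    view = state.mechanical_view()
    target = None
    if m.impulse_target == "patch":
        target = np.asarray(state.lattice.centroid)
    else:  # per-node nearest lobule center handled inside measure via default
        target = None
    return mech.measure_elasticity(
        view, state.internal_nodes, state.outer_nodes,
        impulse_magnitude=m.impulse_magnitude,
        shrink_fraction=m.shrink_fraction,
        step_index=state.step_index,
        iterations=m.relax_iterations,
        substeps=m.impulse_substeps,
        target=target)


# ---------------------------------------------------------------------------
# runs and aggregation


@dataclass
class ScenarioResult:
    """Replicate time series plus their per-step mean and SD.

    SD uses ``ddof=0`` so a single replicate reports zero spread.
    """

    config: SimulationConfig
    replicates: list[pd.DataFrame]
    mean: pd.DataFrame = dc_field(default=None)  # type: ignore[assignment]
    sd: pd.DataFrame = dc_field(default=None)    # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.mean is None:
            stacked = pd.concat(self.replicates, keys=range(len(self.replicates)),
                                names=["replicate"])
            grouped = stacked.groupby("step")
            self.mean = grouped.mean().reset_index()
            self.sd = grouped.std(ddof=0).reset_index()

    @property
    def n_steps(self) -> int:
        return int(self.replicates[0]["step"].max())

    @property
    def n_replicates(self) -> int:
        return len(self.replicates)


def run_replicate(config: SimulationConfig, seed: int,
                  callbacks=None) -> pd.DataFrame:
    """Run one replicate, returning the per-step census frame."""
    state = initialize(config, seed)
    rows = []
    interval = config.run.elastography_interval
    measure = config.run.measure_elastography and len(state.internal_nodes) > 0

    def census():
        disp = math.nan
        if measure and state.step_index % interval == 0:
            disp = measure_state_elasticity(state).displacement
        rows.append(state.census_row(disp))

    census()
    for _ in range(config.run.n_steps):
        step(state)
        census()
        if callbacks:
            for cb in callbacks:
                cb(state)
    df = pd.DataFrame(rows, columns=CENSUS_COLUMNS)
    return df


def run(config: SimulationConfig) -> ScenarioResult:
    """Execute ``config.run.replicates`` runs (seeds = base seed + index) and
    aggregate the census series into per-step mean and SD."""
    config = apply_therapy(config.validated())
    frames = []
    for r in range(config.run.replicates):
        frames.append(run_replicate(config, config.run.seed + r))
    return ScenarioResult(config=config, replicates=frames)


def run_scenarios(config: SimulationConfig,
                  kinds=("none", "anti_tnf", "m2_enhance")
                  ) -> dict[str, ScenarioResult]:
    """Run baseline and therapy scenarios with paired seeds."""
    results = {}
    for kind in kinds:
        cfg = replace(config, therapy=replace(config.therapy, kind=kind,
                                              applied=False))
        results[kind] = run(cfg)
    return results


# ---------------------------------------------------------------------------
# serialization


def serialize_state(state: SimulationState) -> dict:
    return {
        "schema_version": SimulationState.SCHEMA_VERSION,
        "config": state.config.to_dict(),
        "seed": state.seed,
        "step": state.step_index,
        "cumulative_deaths": state.cumulative_deaths,
        "cumulative_replications": state.cumulative_replications,
        "hepatocytes": [c.to_dict() for c in state.hepatocytes.values()],
        "dead": [c.to_dict() for c in state.dead.values()],
        "collagen": [c.to_dict() for c in state.collagen.values()],
        "kupffer": [c.to_dict() for c in state.kupffer],
        "fibrogenic": [c.to_dict() for c in state.fibrogenic],
        "fields": {name: f.to_dict() for name, f in state.fields.items()},
        "rng": {name: gen.bit_generator.state
                for name, gen in state.rng.items()},
    }


def deserialize_state(data: dict) -> SimulationState:
    if data.get("schema_version") != SimulationState.SCHEMA_VERSION:
        raise ValueError(
            f"unsupported state schema version {data.get('schema_version')!r}")
    config = SimulationConfig.from_dict(data["config"])
    state = SimulationState(config, data["seed"])
    state.step_index = data["step"]
    state.cumulative_deaths = data["cumulative_deaths"]
    state.cumulative_replications = data["cumulative_replications"]
    for d in data["hepatocytes"]:
        state.add_hepatocyte(ag.Hepatocyte.from_dict(d))
    for d in data["dead"]:
        cell = ag.DeadHepatocyte.from_dict(d)
        state.occupancy[cell.site] = OCC_DEAD
        state.dead[cell.site] = cell
    for d in data["collagen"]:
        cell = ag.CollagenDeposit.from_dict(d)
        state.occupancy[cell.site] = OCC_COLLAGEN
        state.collagen[cell.site] = cell
        for j in state.sites.neighbors[cell.site]:
            state.anchorable[j] = True
    state.kupffer = [ag.KupfferCell.from_dict(d) for d in data["kupffer"]]
    state.fibrogenic = [ag.FibrogenicCell.from_dict(d)
                        for d in data["fibrogenic"]]
    for name, fd in data["fields"].items():
        state.fields[name] = CytokineField.from_dict(fd)
    for name, st in data["rng"].items():
        state.rng[name].bit_generator.state = st
    return state


def state_hash(state: SimulationState) -> str:
    """SHA-256 digest of the canonical serialized state."""
    payload = json.dumps(serialize_state(state), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()
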