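"""Per-type agent state and behavioral rules.

Agent types split into two mechanical classes: hepatocytes, dead hepatocytes
and collagen deposits occupy placement sites and collide; Kupffer cells and
fibrogenic cells (HSC / portal fibroblast / myofibroblast) carry free
continuous positions and co-occupy space with anything.

The rule functions here are the single-agent contracts used by the engine's
step loop and by the unit tests.  They mutate the agent they are given and
report the resulting event(s); all side effects on shared structures
(occupancy, fields) are carried out by the caller, except cytokine secretion
which deposits directly into the passed fields.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .fields import CytokineField

__all__ = [
    "Hepatocyte",
    "DeadHepatocyte",
    "KupfferCell",
    "FibrogenicCell",
    "CollagenDeposit",
    "HepatocyteParams",
    "KupfferParams",
    "FibrogenicParams",
    "DeadCellParams",
    "hepatocyte_step",
    "kupffer_step",
    "recruit_monocytes",
    "fibrogenic_step",
    "initialize_populations",
    "sample_range",
]

QUIESCENT = "quiescent"
ACTIVATED = "activated"

HSC = "hsc"
PORTAL_FIBROBLAST = "portal_fibroblast"
MYOFIBROBLAST = "myofibroblast"


def sample_range(rng: np.random.Generator, bounds: Sequence[float]) -> float:
    """Uniform draw from a [lo, hi] parameter range (degenerate ranges ok)."""
    lo, hi = float(bounds[0]), float(bounds[1])
    if hi <= lo:
        return lo
    return float(rng.uniform(lo, hi))


# ---------------------------------------------------------------------------
# agent state


@dataclass(slots=True)
class Hepatocyte:
    site: int
    age: int = 0
    lifespan: int = 10_000
    replication_count: int = 0

    collides = True

    def to_dict(self) -> dict:
        return {"site": self.site, "age": self.age, "lifespan": self.lifespan,
                "replication_count": self.replication_count}

    @classmethod
    def from_dict(cls, d: dict) -> "Hepatocyte":
        return cls(d["site"], d["age"], d["lifespan"], d["replication_count"])


@dataclass(slots=True)
class DeadHepatocyte:
    site: int
    steps_since_death: int = 0

    collides = True

    def to_dict(self) -> dict:
        return {"site": self.site, "steps_since_death": self.steps_since_death}

    @classmethod
    def from_dict(cls, d: dict) -> "DeadHepatocyte":
        return cls(d["site"], d["steps_since_death"])


@dataclass(slots=True)
class KupfferCell:
    x: float
    y: float
    state: str = QUIESCENT
    m: float = 0.0            # phenotype weight: 0 = pure M1, 1 = pure M2
    phagocytosis_count: int = 0
    age_activated: int = 0    # steps since activation
    lifespan: int = 0         # activated lifespan; 0 while quiescent

    collides = False

    @property
    def position(self) -> tuple[float, float]:
        return (self.x, self.y)

    def to_dict(self) -> dict:
        return {"x": self.x, "y": self.y, "state": self.state, "m": self.m,
                "phagocytosis_count": self.phagocytosis_count,
                "age_activated": self.age_activated, "lifespan": self.lifespan}

    @classmethod
    def from_dict(cls, d: dict) -> "KupfferCell":
        return cls(d["x"], d["y"], d["state"], d["m"],
                   d["phagocytosis_count"], d["age_activated"], d["lifespan"])


@dataclass(slots=True)
class FibrogenicCell:
    x: float
    y: float
    kind: str = HSC

    collides = False

    @property
    def position(self) -> tuple[float, float]:
        return (self.x, self.y)

    def to_dict(self) -> dict:
        return {"x": self.x, "y": self.y, "kind": self.kind}

    @classmethod
    def from_dict(cls, d: dict) -> "FibrogenicCell":
        return cls(d["x"], d["y"], d["kind"])


@dataclass(slots=True)
class CollagenDeposit:
    site: int
    #: ("septum" | "triad" | "collagen", nearest structural element / site id)
    anchored_to: tuple[str, int] = ("septum", -1)

    collides = True

    def to_dict(self) -> dict:
        return {"site": self.site, "anchored_to": list(self.anchored_to)}

    @classmethod
    def from_dict(cls, d: dict) -> "CollagenDeposit":
        return cls(d["site"], tuple(d["anchored_to"]))


# ---------------------------------------------------------------------------
# parameters


@dataclass(frozen=True)
class HepatocyteParams:
    lifespan_range: tuple[int, int] = (8000, 12000)
    tnf_death_prob: float = 0.015
    #: chance per step of dividing into detected empty space
    replication_prob: float = 0.05
    #: max replications when collagen is present in the neighborhood
    collagen_replication_cap: int = 2


@dataclass(frozen=True)
class KupfferParams:
    #: phenotype shift per phagocytosis event (m += increment, capped at 1)
    polarization_increment: float = 0.05
    tnf_production: tuple[float, float] = (0.8, 1.2)
    tgf_production: tuple[float, float] = (0.8, 1.2)
    #: extra multiplier on TGF production (therapy hook, M2 enhancement)
    tgf_production_factor: float = 1.0
    #: factor applied to TNF secretion while local TGF is above threshold
    #: (anti-inflammatory feedback of the M2 product)
    tnf_suppression_factor: float = 0.4
    activated_lifespan_range: tuple[int, int] = (5000, 8000)
    sense_radius: float = 1.5
    speed: float = 0.7
    recruit_prob: float = 0.1


@dataclass(frozen=True)
class FibrogenicParams:
    #: whether HMGB1 alone (without TNF) can trigger transformation
    hmgb1_transforms: bool = True
    proliferation_prob: float = 0.006
    deposit_prob: float = 0.15
    reach: float = 2.0
    speed: float = 0.5


@dataclass(frozen=True)
class DeadCellParams:
    #: steps a dead agent stays silent before it starts releasing HMGB1
    hmgb1_delay: int = 3
    hmgb1_amount: tuple[float, float] = (0.8, 1.2)


# ---------------------------------------------------------------------------
# rules


def hepatocyte_step(cell: Hepatocyte, tnf_above: bool,
                    empty_neighbor_sites: Sequence[int],
                    collagen_adjacent: bool, rng: np.random.Generator,
                    params: HepatocyteParams) -> tuple:
    """One hepatocyte tick.

    Returns ``("die",)``, ``("replicate", site)`` or ``("none",)``.  Death is
    the bystander effect of above-threshold TNF (probabilistic) or lifespan
    expiry.  Replication requires empty neighboring space and is capped at
    two divisions once collagen is detected nearby.
    """
    cell.age += 1
    if tnf_above and rng.random() < params.tnf_death_prob:
        return ("die",)
    if cell.age > cell.lifespan:
        return ("die",)
    if len(empty_neighbor_sites) > 0:
        if (not collagen_adjacent
                or cell.replication_count < params.collagen_replication_cap):
            if rng.random() < params.replication_prob:
                target = empty_neighbor_sites[
                    int(rng.integers(len(empty_neighbor_sites)))]
                cell.replication_count += 1
                return ("replicate", int(target))
    return ("none",)


def kupffer_step(cell: KupfferCell, adjacent_dead: Sequence[int],
                 flds: dict[str, CytokineField], rng: np.random.Generator,
                 params: KupfferParams) -> list[tuple]:
    """One Kupffer-cell tick.

    Phagocytizes one adjacent dead agent (activating if quiescent, shifting
    the M1->M2 phenotype weight), then, if activated, secretes TNF in
    proportion to ``1 - m`` and TGF in proportion to ``m`` at its own
    position.  Local above-threshold TGF damps the TNF output (the
    anti-inflammatory arm of the M2 product).  Returns the event list.
    """
    events: list[tuple] = []
    if len(adjacent_dead) > 0:
        target = int(adjacent_dead[0])
        if cell.state == QUIESCENT:
            cell.state = ACTIVATED
            cell.lifespan = int(round(sample_range(
                rng, params.activated_lifespan_range)))
        cell.phagocytosis_count += 1
        cell.m = min(1.0, cell.m + params.polarization_increment)
        events.append(("phagocytize", target))
    if cell.state == ACTIVATED:
        tnf_amt = sample_range(rng, params.tnf_production) * (1.0 - cell.m)
        tgf_amt = (sample_range(rng, params.tgf_production) * cell.m
                   * params.tgf_production_factor)
        if tnf_amt > 0 and flds["tgf"].above_threshold(cell.position):
            tnf_amt *= params.tnf_suppression_factor
        if tnf_amt > 0:
            flds["tnf"].deposit(cell.position, tnf_amt)
        if tgf_amt > 0:
            flds["tgf"].deposit(cell.position, tgf_amt)
        if tnf_amt > 0 or tgf_amt > 0:
            events.append(("secrete", tnf_amt, tgf_amt))
    if not events:
        events.append(("none",))
    return events


def recruit_monocytes(hmgb1: CytokineField, rng: np.random.Generator,
                      params: KupfferParams) -> list[KupfferCell]:
    """Spawn activated Kupffer cells where HMGB1 is above threshold.

    Each above-threshold grid location independently recruits one monocyte
    with the configured per-step probability; recruits enter already
    activated with a pure-M1 phenotype (m = 0).
    """
    mask = hmgb1.above_threshold_mask()
    if not mask.any():
        return []
    recruits: list[KupfferCell] = []
    xmin, ymin, _, _ = hmgb1.extent
    h = hmgb1.resolution
    iys, ixs = np.nonzero(mask)
    draws = rng.random(len(iys))
    for iy, ix, u in zip(iys, ixs, draws):
        if u < params.recruit_prob:
            kc = KupfferCell(x=xmin + (ix + 0.5) * h, y=ymin + (iy + 0.5) * h,
                             state=ACTIVATED, m=0.0)
            kc.lifespan = int(round(sample_range(
                rng, params.activated_lifespan_range)))
            recruits.append(kc)
    return recruits


def fibrogenic_step(cell: FibrogenicCell, tnf_above: bool, hmgb1_above: bool,
                    tgf_above: bool, rng: np.random.Generator,
                    params: FibrogenicParams,
                    find_deposit_site: Callable[[], int | None] | None = None,
                    ) -> list[tuple]:
    """One fibrogenic-cell tick.

    HSCs and portal fibroblasts transform (irreversibly) to myofibroblasts on
    detecting TNF (or HMGB1, if enabled).  Myofibroblasts detecting TGF may
    proliferate and may deposit one collagen unit at the nearest empty site
    anchored to existing structure; with no anchor in reach the deposition is
    skipped.
    """
    events: list[tuple] = []
    if cell.kind in (HSC, PORTAL_FIBROBLAST):
        if tnf_above or (params.hmgb1_transforms and hmgb1_above):
            cell.kind = MYOFIBROBLAST
            events.append(("transform",))
    elif cell.kind == MYOFIBROBLAST and tgf_above:
        if rng.random() < params.proliferation_prob:
            events.append(("proliferate",))
        if rng.random() < params.deposit_prob:
            site = find_deposit_site() if find_deposit_site is not None else None
            if site is not None:
                events.append(("deposit", int(site)))
    if not events:
        events.append(("none",))
    return events


def initialize_populations(n_hepatocytes: int) -> tuple[int, int]:
    """Initial Kupffer and HSC counts from the hepatocyte count.

    Hepatocytes are taken to be 60% of all liver cells, Kupffer cells 15%
    and HSCs 5%; counts are rounded to the nearest integer.
    """
    if n_hepatocytes < 0:
        raise ValueError(f"n_hepatocytes must be >= 0, got {n_hepatocytes}")
    n_kupffer = int(round(n_hepatocytes * 15.0 / 60.0))
    n_hsc = int(round(n_hepatocytes * 5.0 / 60.0))
    return n_kupffer, n_hsc
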