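"""Diffusible-factor concentration grids.

Each factor (TNF, TGF, HMGB1) lives on a regular 2-D grid covering the tissue
patch.  One field step applies an explicit 5-point diffusion stencil with
zero-flux boundaries followed by multiplicative first-order decay.  Agents
interact with fields only through :meth:`CytokineField.deposit` and the
threshold query, keeping the rule code independent of grid details.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field

import numpy as np

__all__ = [
    "CytokineField",
    "deposit",
    "step_field",
    "above_threshold",
    "FieldConfigError",
    "OutOfBoundsError",
]

FACTOR_NAMES = ("tnf", "tgf", "hmgb1")

#: explicit-scheme stability bound for the 5-point stencil
MAX_DIFFUSION_COEFF = 0.25


class FieldConfigError(ValueError):
    """Invalid field parameterization (stability bound, rates, threshold)."""


class OutOfBoundsError(ValueError):
    """Position outside the patch extent."""


@dataclass
class CytokineField:
    """A single diffusible factor on a zero-flux grid.

    Parameters
    ----------
    name
        Factor identifier (free-form; the engine uses ``tnf``/``tgf``/``hmgb1``).
    extent
        Patch bounding box ``(xmin, ymin, xmax, ymax)``.
    resolution
        Grid cell edge length ``h`` (defaults to one hepatocyte diameter).
    diffusion_coeff
        Per-step spread fraction of the explicit stencil; must lie in
        ``[0, 0.25]`` for stability.
    degradation_rate
        Per-step multiplicative decay fraction in ``[0, 1]``.
    threshold
        Detection level for :meth:`above_threshold`; must be positive.
    """

    name: str
    extent: tuple[float, float, float, float]
    resolution: float
    diffusion_coeff: float
    degradation_rate: float
    threshold: float
    grid: np.ndarray = dc_field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not (0.0 <= self.diffusion_coeff <= MAX_DIFFUSION_COEFF):
            raise FieldConfigError(
                f"field {self.name!r}: diffusion_coeff {self.diffusion_coeff} "
                f"violates the explicit-scheme bound [0, {MAX_DIFFUSION_COEFF}]")
        if not (0.0 <= self.degradation_rate <= 1.0):
            raise FieldConfigError(
                f"field {self.name!r}: degradation_rate {self.degradation_rate} "
                "must be in [0, 1]")
        if self.threshold <= 0:
            raise FieldConfigError(
                f"field {self.name!r}: threshold must be > 0, "
                f"got {self.threshold}")
        if self.resolution <= 0:
            raise FieldConfigError(
                f"field {self.name!r}: resolution must be > 0")
        xmin, ymin, xmax, ymax = self.extent
        nx = max(1, int(math.ceil((xmax - xmin) / self.resolution)))
        ny = max(1, int(math.ceil((ymax - ymin) / self.resolution)))
        if self.grid is None:
            self.grid = np.zeros((ny, nx), dtype=float)
        else:
            self.grid = np.asarray(self.grid, dtype=float)
            if self.grid.shape != (ny, nx):
                raise FieldConfigError(
                    f"field {self.name!r}: grid shape {self.grid.shape} does "
                    f"not match extent/resolution ({ny}, {nx})")

    # -- geometry ----------------------------------------------------------

    def cell_index(self, position) -> tuple[int, int]:
        """Grid (iy, ix) of the cell containing ``position``."""
        x, y = float(position[0]), float(position[1])
        xmin, ymin, xmax, ymax = self.extent
        if not (xmin <= x <= xmax and ymin <= y <= ymax):
            raise OutOfBoundsError(
                f"position ({x}, {y}) outside patch extent {self.extent}")
        ny, nx = self.grid.shape
        ix = min(int((x - xmin) / self.resolution), nx - 1)
        iy = min(int((y - ymin) / self.resolution), ny - 1)
        return iy, ix

    def cell_indices(self, positions: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Vectorized :meth:`cell_index` without bounds checking (pre-clipped)."""
        xmin, ymin, _, _ = self.extent
        ny, nx = self.grid.shape
        ix = np.minimum(((positions[:, 0] - xmin) / self.resolution).astype(int), nx - 1)
        iy = np.minimum(((positions[:, 1] - ymin) / self.resolution).astype(int), ny - 1)
        return iy, ix

    # -- dynamics ----------------------------------------------------------

    def deposit(self, position, amount: float) -> None:
        """Add ``amount`` of mass into the cell containing ``position``."""
        if amount < 0:
            raise ValueError(f"deposit amount must be >= 0, got {amount}")
        iy, ix = self.cell_index(position)
        self.grid[iy, ix] += amount / self.resolution ** 2

    def deposit_many(self, iy: np.ndarray, ix: np.ndarray,
                     amounts: np.ndarray) -> None:
        np.add.at(self.grid, (iy, ix), np.asarray(amounts) / self.resolution ** 2)

    def step(self) -> None:
        """One diffusion + degradation step (in place)."""
        u = self.grid
        if self.diffusion_coeff > 0.0 and u.size > 1:
            # zero-flux: boundary cells see themselves as their missing neighbor
            up = np.vstack([u[:1], u[:-1]])
            down = np.vstack([u[1:], u[-1:]])
            left = np.hstack([u[:, :1], u[:, :-1]])
            right = np.hstack([u[:, 1:], u[:, -1:]])
            u = u + self.diffusion_coeff * (up + down + left + right - 4.0 * u)
        if self.degradation_rate > 0.0:
            u = u * (1.0 - self.degradation_rate)
        self.grid = np.maximum(u, 0.0) if u is not self.grid else u

    def above_threshold(self, position) -> bool:
        """True iff the local concentration is at or above the threshold."""
        iy, ix = self.cell_index(position)
        return bool(self.grid[iy, ix] >= self.threshold)

    def above_threshold_mask(self) -> np.ndarray:
        return self.grid >= self.threshold

    def total_mass(self) -> float:
        return float(self.grid.sum() * self.resolution ** 2)

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "extent": list(self.extent),
            "resolution": self.resolution,
            "diffusion_coeff": self.diffusion_coeff,
            "degradation_rate": self.degradation_rate,
            "threshold": self.threshold,
            "grid": self.grid.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CytokineField":
        return cls(d["name"], tuple(d["extent"]), d["resolution"],
                   d["diffusion_coeff"], d["degradation_rate"], d["threshold"],
                   grid=np.array(d["grid"], dtype=float))

    def copy(self) -> "CytokineField":
        return CytokineField(self.name, self.extent, self.resolution,
                             self.diffusion_coeff, self.degradation_rate,
                             self.threshold, grid=self.grid.copy())


# functional aliases matching the operation-level interface


def deposit(fld: CytokineField, position, amount: float) -> CytokineField:
    fld.deposit(position, amount)
    return fld


def step_field(fld: CytokineField) -> CytokineField:
    fld.step()
    return fld


def above_threshold(fld: CytokineField, position) -> bool:
    return fld.above_threshold(position)
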