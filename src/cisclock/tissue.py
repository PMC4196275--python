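"""Lattice geometry, neighborhoods and the growing-PSM machinery.

Cells sit on a 1-, 2- or 3-D rectangular lattice without periodic wrap.
The neighborhood is either von Neumann (face-adjacent: 2/4/6 interior
neighbors in 1/2/3 dimensions) or extended (diagonals included, e.g. 8
interior neighbors in 2-D).  In presomitic-mesoderm (PSM) mode the
lattice is a slab with a fixed cross-section that elongates by cell
division in a posterior growth zone; an exponential posterior-to-anterior
gradient (FGF8-like) scales the cytoplasmic HES7 decay rate.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse

__all__ = [
    "Tissue",
    "GradientSpec",
    "GrowthOptions",
    "build_tissue",
    "neighbor_mean",
    "gradient_modifier",
    "advance_growth",
    "DivisionEvent",
]


class Tissue:
    """Rectangular cell lattice with precomputed neighbor structure.

    ``W`` is the row-normalized adjacency matrix, so ``W @ values`` is the
    per-cell arithmetic mean over each cell's neighbor list (0 for cells
    without neighbors).
    """

    def __init__(self, shape: tuple[int, ...], neighborhood_mode: str = "von_neumann"):
        shape = tuple(int(s) for s in shape)
        if len(shape) < 1 or len(shape) > 3:
            raise ValueError("lattice must be 1-, 2- or 3-dimensional")
        if any(s < 1 for s in shape):
            raise ValueError(f"every lattice dimension must be >= 1; got {shape}")
        if neighborhood_mode not in ("von_neumann", "extended"):
            raise ValueError("neighborhood_mode must be 'von_neumann' or 'extended'")
        self.shape = shape
        self.neighborhood_mode = neighborhood_mode
        self.n_cells = int(np.prod(shape))
        self.coords = np.array(list(np.ndindex(*shape)), dtype=int)
        self.neighbor_lists = _neighbor_lists(shape, neighborhood_mode)
        self.W = _mean_matrix(self.neighbor_lists, self.n_cells)

    def neighbor_counts(self) -> np.ndarray:
        return np.array([len(nb) for nb in self.neighbor_lists])

    def cell_index(self, coord: tuple[int, ...]) -> int:
        return int(np.ravel_multi_index(coord, self.shape))

    def __repr__(self) -> str:
        return f"Tissue(shape={self.shape}, mode={self.neighborhood_mode!r})"


def _neighbor_lists(shape: tuple[int, ...], mode: str) -> list[np.ndarray]:
    ndim = len(shape)
    if mode == "von_neumann":
        offsets = [o for o in itertools.product((-1, 0, 1), repeat=ndim)
                   if sum(abs(x) for x in o) == 1]
    else:
        offsets = [o for o in itertools.product((-1, 0, 1), repeat=ndim)
                   if any(o)]
    lists: list[np.ndarray] = []
    for coord in np.ndindex(*shape):
        nbs = []
        for off in offsets:
            cand = tuple(c + d for c, d in zip(coord, off))
            if all(0 <= x < s for x, s in zip(cand, shape)):
                nbs.append(np.ravel_multi_index(cand, shape))
        lists.append(np.array(sorted(nbs), dtype=int))
    return lists


def _mean_matrix(neighbor_lists: list[np.ndarray], n: int) -> sparse.csr_matrix:
    rows, cols, vals = [], [], []
    for i, nbs in enumerate(neighbor_lists):
        if len(nbs) == 0:
            continue
        w = 1.0 / len(nbs)
        rows.extend([i] * len(nbs))
        cols.extend(nbs.tolist())
        vals.extend([w] * len(nbs))
    return sparse.csr_matrix((vals, (rows, cols)), shape=(n, n))


def build_tissue(shape, neighborhood_mode: str = "von_neumann") -> Tissue:
    """Build a rectangular lattice with populated neighbor lists."""
    return Tissue(tuple(np.atleast_1d(shape).astype(int)), neighborhood_mode)


def neighbor_mean(tissue: Tissue, values: np.ndarray) -> np.ndarray:
    """Per-cell arithmetic mean of ``values`` over each neighbor list."""
    values = np.asarray(values, dtype=float)
    if values.shape != (tissue.n_cells,):
        raise ValueError(f"expected {tissue.n_cells} per-cell values; got {values.shape}")
    return tissue.W @ values


# ---------------------------------------------------------------------------
# gradients

@dataclass
class GradientSpec:
    """Posterior-to-anterior exponential gradient acting on a decay rate.

    The scaling factor at distance ``d`` (cell units) from the posterior
    end is ``1 + amplitude * exp(-d / length_scale)``: maximal at the
    posterior boundary, decaying monotonically to the baseline 1
    anteriorly.  The default target is the cytoplasmic HES7 decay rate,
    so posterior cells oscillate faster and anterior cells slow down
    (the wave-generating mechanism).
    """

    amplitude: float = 0.5
    length_scale: float = 5.0
    target: str = "hes7.dpC"

    def __post_init__(self):
        if self.amplitude < 0:
            raise ValueError("gradient amplitude must be >= 0")
        if self.length_scale <= 0:
            raise ValueError("gradient length scale must be > 0")


def gradient_modifier(distance_from_posterior, spec: GradientSpec):
    """Multiplicative decay-rate factor at a given axial distance."""
    d = np.asarray(distance_from_posterior, dtype=float)
    out = 1.0 + spec.amplitude * np.exp(-d / spec.length_scale)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# growing PSM

@dataclass
class GrowthOptions:
    """Conveyor model of the elongating PSM.

    The slab keeps a fixed cross-section; the posterior growth zone
    (``growth_zone_depth`` axial rows) divides every ``cell_cycle_min``
    minutes: the posterior-most row duplicates, daughters inherit the
    mother's concentrations and the slab elongates by one row.  Divisions
    within a round are synchronous up to a uniform per-cell jitter.  Each
    dividing cell optionally shuts down transcription of the clock genes
    for ``mitosis_shutdown_min`` and/or receives multiplicative division
    noise.
    """

    cell_cycle_min: float = 30.0
    growth_zone_depth: int = 3
    mitosis_shutdown_min: float = 0.0
    division_noise_percent: float = 0.0
    jitter_min: float = 5.0
    max_length: int = 60

    def __post_init__(self):
        if self.cell_cycle_min <= 0:
            raise ValueError("cell_cycle_min must be > 0")
        if self.growth_zone_depth < 1:
            raise ValueError("growth_zone_depth must be >= 1")
        if self.mitosis_shutdown_min < 0 or self.division_noise_percent < 0:
            raise ValueError("shutdown length and division noise must be >= 0")


@dataclass
class DivisionEvent:
    time: float
    mother_row: int
    cell_ids: list[int] = field(default_factory=list)


class PsmTissue:
    """Growing slab: axial length x fixed cross-section, posterior = last row."""

    def __init__(self, initial_length: int, cross_section: tuple[int, ...] = (7, 3),
                 neighborhood_mode: str = "extended",
                 growth: GrowthOptions | None = None,
                 gradient: GradientSpec | None = None):
        if initial_length < 2:
            raise ValueError("initial axial length must be >= 2")
        self.cross_section = tuple(int(c) for c in cross_section)
        self.neighborhood_mode = neighborhood_mode
        self.growth = growth or GrowthOptions()
        self.gradient = gradient or GradientSpec()
        self.tissue = build_tissue((initial_length, *self.cross_section),
                                   neighborhood_mode)
        self.next_division_time = self.growth.cell_cycle_min
        # per-cell transcription-shutdown window [start, end), NaN = none
        self.shutdown_windows = np.full((self.tissue.n_cells, 2), np.nan)

    @property
    def axial_length(self) -> int:
        return self.tissue.shape[0]

    def row_cells(self, row: int) -> np.ndarray:
        n_cross = int(np.prod(self.cross_section))
        return np.arange(row * n_cross, (row + 1) * n_cross)

    def decay_scale(self) -> np.ndarray:
        """Gradient factor per cell (posterior = highest axial index)."""
        d = (self.axial_length - 1) - self.tissue.coords[:, 0]
        return gradient_modifier(d.astype(float), self.gradient)

    def transcription_gate(self, clock: float) -> np.ndarray:
        w = self.shutdown_windows
        shut = (clock >= w[:, 0]) & (clock < w[:, 1])
        return np.where(shut, 0.0, 1.0)


def advance_growth(psm: PsmTissue, states: np.ndarray, clock: float,
                   rng: np.random.Generator) -> tuple[np.ndarray, list[DivisionEvent]]:
    """Execute any division round due at ``clock``; return updated states.

    The posterior-most growth-zone row divides as a group: a duplicate
    row is inserted at the posterior end, every daughter inherits the
    mother's state vector exactly, and each dividing cell gets its own
    jittered shutdown window and/or multiplicative division noise.
    Rebuilds the neighbor structure after elongation.
    """
    events: list[DivisionEvent] = []
    g = psm.growth
    while clock >= psm.next_division_time and psm.axial_length < g.max_length:
        t_div = psm.next_division_time
        psm.next_division_time += g.cell_cycle_min
        mother_row = psm.axial_length - 1
        mothers = psm.row_cells(mother_row)
        n_cross = len(mothers)

        # elongate: duplicate the posterior row, daughters inherit state
        states = np.vstack([states, states[mothers].copy()])
        psm.tissue = build_tissue((psm.axial_length + 1, *psm.cross_section),
                                  psm.neighborhood_mode)
        daughters = psm.row_cells(psm.axial_length - 1)
        psm.shutdown_windows = np.vstack(
            [psm.shutdown_windows, np.full((n_cross, 2), np.nan)])

        if g.mitosis_shutdown_min > 0:
            jit = rng.uniform(0.0, g.jitter_min, size=n_cross)
            for pair, j in zip(np.column_stack([mothers, daughters]), jit):
                start = t_div + j
                psm.shutdown_windows[pair, 0] = start
                psm.shutdown_windows[pair, 1] = start + g.mitosis_shutdown_min
        if g.division_noise_percent > 0:
            amp = g.division_noise_percent / 100.0
            for pair in np.column_stack([mothers, daughters]):
                u = rng.uniform(size=(2, states.shape[1]))
                states[pair] = states[pair] * (1.0 + amp * u)

        events.append(DivisionEvent(time=t_div, mother_row=mother_row,
                                    cell_ids=list(mothers) + list(daughters)))
    return states, events
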