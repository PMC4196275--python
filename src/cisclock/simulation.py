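"""Time integration of the whole tissue.

Synchronous explicit Euler with a fixed step (default 0.1 min): the
neighbor fields are computed from the pre-step state so the update is
independent of cell ordering.  Concentrations are clamped at zero after
each step; the clamp rate is recorded and a high rate triggers a warning
to reduce dt.  All randomness (initial noise, growth scheduling) flows
from a single root seed through independent child streams.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .grn_model import GrnModel, canonical_initial_state
from .interfaces import RunConfig, config_to_dict
from .tissue import PsmTissue, Tissue, advance_growth

__all__ = ["SimulationTrace", "apply_initial_noise", "step_euler", "run_simulation"]


class NumericalError(RuntimeError):
    pass


@dataclass
class SimulationTrace:
    """Time-indexed record of selected species across all cells.

    ``data[species]`` is a list of per-cell arrays, one per recorded
    time; in growing-tissue runs the arrays lengthen over time.  Use
    :meth:`matrix` for the dense (n_times, n_cells) view of a fixed-size
    run.
    """

    times: np.ndarray
    data: dict[str, list[np.ndarray]]
    dt: float
    seed: int
    config: dict[str, str]
    events: list[dict[str, Any]] = field(default_factory=list)
    clamp_fraction: float = 0.0
    final_tissue: Any = None

    @property
    def species(self) -> list[str]:
        return list(self.data)

    def matrix(self, species: str | None = None) -> np.ndarray:
        """Dense (n_times, n_cells) array; requires constant cell count."""
        species = species or next(iter(self.data))
        frames = self.data[species]
        sizes = {len(f) for f in frames}
        if len(sizes) != 1:
            raise ValueError("cell count changed during the run; use to_dataframe()")
        return np.vstack(frames)

    def mean_series(self, species: str | None = None) -> np.ndarray:
        species = species or next(iter(self.data))
        return np.array([frame.mean() for frame in self.data[species]])

    def to_dataframe(self) -> pd.DataFrame:
        """Long-format table: time, cell_id, species, value."""
        rows = []
        for sp, frames in self.data.items():
            for t, frame in zip(self.times, frames):
                rows.append(pd.DataFrame({
                    "time": t, "cell_id": np.arange(len(frame)),
                    "species": sp, "value": frame,
                }))
        return pd.concat(rows, ignore_index=True)

    def events_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.events)

    def save_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def apply_initial_noise(states: np.ndarray, percent: float,
                        rng: np.random.Generator) -> np.ndarray:
    """Multiplicative initial noise: c -> c * (1 + (percent/100) * u).

    ``u`` is drawn i.i.d. Uniform(0, 1) per concentration per cell, so
    e.g. 200% noise maps each concentration c into [c, 3c].
    """
    if percent < 0:
        raise ValueError("noise percent must be >= 0")
    states = np.asarray(states, dtype=float)
    if percent == 0:
        return states.copy()
    u = rng.uniform(size=states.shape)
    return states * (1.0 + percent / 100.0 * u)


def step_euler(states: np.ndarray, model: GrnModel, tissue: Tissue, dt: float,
               gate: np.ndarray | float = 1.0,
               decay_scale: np.ndarray | float = 1.0) -> tuple[np.ndarray, int]:
    """One synchronous explicit Euler step; returns (new state, clamp count).

    Neighbor membrane means are taken from the pre-step state; the update
    is clamped at zero per species per cell.
    """
    if dt < 0:
        raise ValueError("dt must be >= 0")
    i_d = model.index["dll1.pM"]
    i_n = model.index["notch1.pM"]
    nb_d = tissue.W @ states[:, i_d]
    nb_n = tissue.W @ states[:, i_n]
    dS = model.derivatives(states, nb_d, nb_n, gate=gate,
                           hes7_decay_scale=decay_scale)
    if not np.all(np.isfinite(dS)):
        cell, sp = np.argwhere(~np.isfinite(dS))[0]
        raise NumericalError(
            f"non-finite derivative for cell {cell}, species {model.species[sp]}")
    new = states + dt * dS
    n_clamped = int(np.count_nonzero(new < 0))
    np.maximum(new, 0.0, out=new)
    return new, n_clamped


def initial_states(cfg: RunConfig, model: GrnModel, n_cells: int) -> np.ndarray:
    """Pre-noise initial state matrix for a run.

    ``canonical`` tiles the burn-in limit-cycle snapshot; ``zero`` starts
    from rest; ``asymmetric`` scales the canonical vector by 1.0 / 0.5 on
    alternating cells (a deterministic desynchronized start).
    """
    if cfg.initial == "zero":
        return np.zeros((n_cells, model.n_species))
    base = canonical_initial_state(model)
    states = np.tile(base, (n_cells, 1))
    if cfg.initial == "asymmetric":
        scale = np.where(np.arange(n_cells) % 2 == 0, 1.0, 0.5)
        states *= scale[:, None]
    return states


def run_simulation(cfg: RunConfig) -> SimulationTrace:
    """Integrate a configured run and record the requested species.

    Fully reproducible from (config, seed): initial noise and growth
    scheduling use independent child streams of the root seed, so
    enabling growth does not change the noise draws.
    """
    cfg.validate()
    model = cfg.build_model()
    tis = cfg.build_tissue()
    psm: PsmTissue | None = tis if isinstance(tis, PsmTissue) else None
    tissue = psm.tissue if psm else tis

    noise_ss, growth_ss = np.random.SeedSequence(cfg.seed).spawn(2)
    noise_rng = np.random.default_rng(noise_ss)
    growth_rng = np.random.default_rng(growth_ss)

    states = initial_states(cfg, model, tissue.n_cells)
    states = apply_initial_noise(states, cfg.noise_percent, noise_rng)

    record = [model.index[s] for s in cfg.record_species]
    times: list[float] = []
    data: dict[str, list[np.ndarray]] = {s: [] for s in cfg.record_species}
    events: list[dict[str, Any]] = []

    clamped = 0
    total = 0
    gate: np.ndarray | float = 1.0
    decay: np.ndarray | float = 1.0
    for step in range(cfg.steps + 1):
        clock = step * cfg.dt
        if psm is not None:
            states, new_events = advance_growth(psm, states, clock, growth_rng)
            if new_events:
                tissue = psm.tissue
                for ev in new_events:
                    events.append({"time": ev.time, "kind": "division",
                                   "mother_row": ev.mother_row,
                                   "n_cells": tissue.n_cells})
            gate = psm.transcription_gate(clock)
            decay = psm.decay_scale()
        if step % cfg.record_stride == 0:
            times.append(clock)
            for sp, idx in zip(cfg.record_species, record):
                data[sp].append(states[:, idx].copy())
        if step == cfg.steps:
            break
        states, n_cl = step_euler(states, model, tissue, cfg.dt,
                                  gate=gate, decay_scale=decay)
        clamped += n_cl
        total += states.size

    frac = clamped / total if total else 0.0
    if frac > 1e-3:
        warnings.warn(
            f"{100 * frac:.2f}% of concentration updates were clamped at zero; "
            "consider a smaller dt", RuntimeWarning, stacklevel=2)
    return SimulationTrace(times=np.asarray(times), data=data, dt=cfg.dt,
                           seed=cfg.seed, config=config_to_dict(cfg),
                           events=events, clamp_fraction=frac,
                           final_tissue=tissue)
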