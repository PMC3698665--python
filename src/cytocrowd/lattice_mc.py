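"""Lattice Monte Carlo of reactant walkers among non-reactive obstacles.

A scalable counterpart to the continuous-space simulator: reactant random
walkers hop on a periodic simple cubic lattice (default 50^3 sites) that is
randomly interspersed with non-reactive obstacles (NRO).  NROs may be

* immobile (``p_f = 0``),
* mobile single sites or rigid cubic blocks moving with per-sweep
  probability ``p_f`` relative to the reactants (which attempt a move every
  sweep), or
* aggregated: an obstacle of size parameter ``r_nro`` occupies a
  ``(2 r_nro)^3`` block of sites (``r_nro = 1`` is the 8-site base object).

Dynamics are "blind ant": a reactant picks one of its 6 lattice neighbors
uniformly; if the target site is blocked the attempt fails and the walker
stays for that step.  (Re-drawing a random *position* for a blocked
reactant, a possible literal reading of the obstacle rule, would destroy
the subdiffusion that crowding produces and is not used.)  Optionally the
coalescence reaction A + A -> A is enabled: a reactant stepping onto
another reactant annihilates the target and takes its site.

Mean squared displacement is accumulated from unwrapped coordinates so
periodic wraps never truncate displacements.  The inner loop is compiled
with numba.

Physical units: the reference calibration maps one lattice site to
77.8 nm; MSD is reported in lattice units squared with one sweep as the
time unit, and converted only at the reporting layer.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from numba import njit

__all__ = ["LatticeConfig", "LatticeState", "LatticeRun",
           "init_lattice", "reactant_sweep", "nro_sweep", "run",
           "preset_config"]

#: Physical edge of one lattice site in the reference calibration (nm).
DEFAULT_PX_NM = 77.8

EMPTY = np.int8(0)
NRO = np.int8(1)
REACTANT = np.int8(2)

@dataclass
class LatticeConfig:
    """Configuration of a lattice Monte Carlo run.

    ``nro_radius_px = 0`` requests single-site obstacles (the mobility
    sweep); ``r >= 1`` requests rigid cubic blocks of edge ``2 r`` sites
    (the aggregation sweep; ``r = 1`` occupies 8 sites).  ``nro_fraction``
    is the target fraction of lattice sites covered by obstacles; the
    placed block count is ``floor(fraction * edge^3 / block_volume)``.
    """

    edge: int = 50
    nro_fraction: float = 0.0
    nro_radius_px: int = 0
    p_f: float = 0.0
    n_reactants: int = 1000
    reaction_on: bool = False
    n_steps: int = 100_000
    px_nm: float = DEFAULT_PX_NM
    seed: int = 0

    def __post_init__(self) -> None:
        if self.edge < 2:
            raise ValueError("edge must be >= 2")
        if not 0.0 <= self.nro_fraction < 1.0:
            raise ValueError("nro_fraction must lie in [0, 1)")
        if not 0.0 <= self.p_f <= 1.0:
            raise ValueError("p_f must lie in [0, 1]")
        if self.nro_radius_px < 0 or self.nro_radius_px > 5:
            raise ValueError("nro_radius_px must lie in 0..5")
        if self.n_reactants < 1:
            raise ValueError("need at least one reactant")

    @property
    def block_edge(self) -> int:
        return 1 if self.nro_radius_px == 0 else 2 * self.nro_radius_px

    @property
    def block_volume(self) -> int:
        return self.block_edge ** 3

    @property
    def n_blocks(self) -> int:
        return int(self.nro_fraction * self.edge ** 3 // self.block_volume)


@dataclass
class LatticeState:
    """Mutable simulation state.

    ``occupancy[z, y, x]`` holds EMPTY/NRO/REACTANT codes; reactant and
    block positions are tracked separately.  ``unwrapped`` accumulates each
    reactant's displacement in lattice units across periodic wraps.
    """

    occupancy: np.ndarray
    react_pos: np.ndarray        # (N, 3) int64 wrapped positions
    unwrapped: np.ndarray        # (N, 3) int64 cumulative displacements
    alive: np.ndarray            # (N,) bool
    block_anchor: np.ndarray     # (B, 3) int64
    block_edge: int
    step_count: int = 0

    @property
    def n_alive(self) -> int:
        return int(self.alive.sum())


@dataclass
class LatticeRun:
    """Result of :func:`run`: MSD and reactant-count series per sweep."""

    steps: np.ndarray            # (T,) sweep indices (1..n_steps)
    msd: np.ndarray              # (T,) lattice units^2, ensemble over alive
    counts: np.ndarray           # (T,) surviving reactants
    config: LatticeConfig
    final_state: LatticeState | None = None


class PlacementError(RuntimeError):
    """Raised when obstacles/reactants cannot be placed at the density asked."""


# ---------------------------------------------------------------------------
# Initialisation
# ---------------------------------------------------------------------------

def init_lattice(cfg: LatticeConfig,
                 rng: np.random.Generator | None = None) -> LatticeState:
    """Place NRO blocks and reactants uniformly at random without overlap."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    L = cfg.edge
    e = cfg.block_edge
    occ = np.zeros((L, L, L), dtype=np.int8)

    n_blocks = cfg.n_blocks
    if n_blocks * cfg.block_volume + cfg.n_reactants > L ** 3:
        raise PlacementError("requested occupancy exceeds the lattice")

    anchors = np.empty((n_blocks, 3), dtype=np.int64)
    offs = np.arange(e)
    max_attempts = 200 * max(n_blocks, 1)
    placed = 0
    attempts = 0
    while placed < n_blocks:
        attempts += 1
        if attempts > max_attempts:
            raise PlacementError(
                f"could not place {n_blocks} blocks of edge {e} "
                f"({placed} placed after {attempts} attempts)")
        a = rng.integers(0, L, size=3)
        zz = (a[0] + offs) % L
        yy = (a[1] + offs) % L
        xx = (a[2] + offs) % L
        region = occ[np.ix_(zz, yy, xx)]
        if np.any(region != EMPTY):
            continue
        occ[np.ix_(zz, yy, xx)] = NRO
        anchors[placed] = a
        placed += 1

    empty_flat = np.flatnonzero(occ.ravel() == EMPTY)
    if empty_flat.size < cfg.n_reactants:
        raise PlacementError("not enough empty sites for reactants")
    chosen = rng.choice(empty_flat, size=cfg.n_reactants, replace=False)
    pos = np.stack(np.unravel_index(chosen, occ.shape), axis=1).astype(np.int64)
    occ.ravel()[chosen] = REACTANT

    return LatticeState(
        occupancy=occ,
        react_pos=pos,
        unwrapped=np.zeros_like(pos),
        alive=np.ones(cfg.n_reactants, dtype=bool),
        block_anchor=anchors,
        block_edge=e,
    )


# ---------------------------------------------------------------------------
# Compiled kernels
# ---------------------------------------------------------------------------

@njit(cache=True)
def _shuffle_in_place(idx, n):
    for i in range(n - 1, 0, -1):
        j = np.random.randint(0, i + 1)
        tmp = idx[i]
        idx[i] = idx[j]
        idx[j] = tmp


@njit(cache=True)
def _reactant_sweep_nb(occ, pos, unw, alive, order, L, reaction_on):
    """One sweep of all surviving reactants in the given order."""
    n = order.shape[0]
    for k in range(n):
        i = order[k]
        if not alive[i]:
            continue
        d = np.random.randint(0, 6)
        dz = (1 if d == 0 else -1 if d == 1 else 0)
        dy = (1 if d == 2 else -1 if d == 3 else 0)
        dx = (1 if d == 4 else -1 if d == 5 else 0)
        z, y, x = pos[i, 0], pos[i, 1], pos[i, 2]
        nz = (z + dz) % L
        ny = (y + dy) % L
        nx = (x + dx) % L
        t = occ[nz, ny, nx]
        if t == 0:
            occ[z, y, x] = 0
            occ[nz, ny, nx] = 2
            pos[i, 0], pos[i, 1], pos[i, 2] = nz, ny, nx
            unw[i, 0] += dz
            unw[i, 1] += dy
            unw[i, 2] += dx
        elif t == 2 and reaction_on:
            # A + A -> A: find and annihilate the reactant on the target
            for m in range(alive.shape[0]):
                if alive[m] and m != i and pos[m, 0] == nz and \
                        pos[m, 1] == ny and pos[m, 2] == nx:
                    alive[m] = False
                    break
            occ[z, y, x] = 0
            occ[nz, ny, nx] = 2
            pos[i, 0], pos[i, 1], pos[i, 2] = nz, ny, nx
            unw[i, 0] += dz
            unw[i, 1] += dy
            unw[i, 2] += dx
        # blocked by NRO (or by reactant without reaction): stay


@njit(cache=True)
def _nro_sweep_nb(occ, anchors, e, L, p_f):
    """One sweep of all NRO blocks (fixed order), each moving w.p. p_f."""
    B = anchors.shape[0]
    for b in range(B):
        if p_f < 1.0 and np.random.random() >= p_f:
            continue
        d = np.random.randint(0, 6)
        dz = (1 if d == 0 else -1 if d == 1 else 0)
        dy = (1 if d == 2 else -1 if d == 3 else 0)
        dx = (1 if d == 4 else -1 if d == 5 else 0)
        az, ay, ax = anchors[b, 0], anchors[b, 1], anchors[b, 2]
        # leading face: the layer of sites newly covered by the move
        ok = True
        if dz != 0:
            lz = (az + e) % L if dz > 0 else (az - 1) % L
            for u in range(e):
                for v in range(e):
                    if occ[lz, (ay + u) % L, (ax + v) % L] != 0:
                        ok = False
                        break
                if not ok:
                    break
        elif dy != 0:
            ly = (ay + e) % L if dy > 0 else (ay - 1) % L
            for u in range(e):
                for v in range(e):
                    if occ[(az + u) % L, ly, (ax + v) % L] != 0:
                        ok = False
                        break
                if not ok:
                    break
        else:
            lx = (ax + e) % L if dx > 0 else (ax - 1) % L
            for u in range(e):
                for v in range(e):
                    if occ[(az + u) % L, (ay + v) % L, lx] != 0:
                        ok = False
                        break
                if not ok:
                    break
        if not ok:
            continue
        # move: set leading face, clear trailing face
        if dz != 0:
            lz = (az + e) % L if dz > 0 else (az - 1) % L
            tz = az if dz > 0 else (az + e - 1) % L
            for u in range(e):
                for v in range(e):
                    occ[lz, (ay + u) % L, (ax + v) % L] = 1
                    occ[tz, (ay + u) % L, (ax + v) % L] = 0
        elif dy != 0:
            ly = (ay + e) % L if dy > 0 else (ay - 1) % L
            ty = ay if dy > 0 else (ay + e - 1) % L
            for u in range(e):
                for v in range(e):
                    occ[(az + u) % L, ly, (ax + v) % L] = 1
                    occ[(az + u) % L, ty, (ax + v) % L] = 0
        else:
            lx = (ax + e) % L if dx > 0 else (ax - 1) % L
            tx = ax if dx > 0 else (ax + e - 1) % L
            for u in range(e):
                for v in range(e):
                    occ[(az + u) % L, (ay + v) % L, lx] = 1
                    occ[(az + u) % L, (ay + v) % L, tx] = 0
        anchors[b, 0] = (az + dz) % L
        anchors[b, 1] = (ay + dy) % L
        anchors[b, 2] = (ax + dx) % L


@njit(cache=True)
def _run_loop(occ, pos, unw, alive, anchors, e, L, p_f, reaction_on,
              n_steps, seed):
    """Full simulation loop: per sweep, reactants (random order) then NROs."""
    np.random.seed(seed)
    n = pos.shape[0]
    msd = np.zeros(n_steps)
    counts = np.zeros(n_steps, dtype=np.int64)
    order = np.arange(n)
    move_nro = p_f > 0.0 and anchors.shape[0] > 0
    for t in range(n_steps):
        _shuffle_in_place(order, n)
        _reactant_sweep_nb(occ, pos, unw, alive, order, L, reaction_on)
        if move_nro:
            _nro_sweep_nb(occ, anchors, e, L, p_f)
        s = 0.0
        c = 0
        for i in range(n):
            if alive[i]:
                s += unw[i, 0] ** 2 + unw[i, 1] ** 2 + unw[i, 2] ** 2
                c += 1
        msd[t] = s / c if c > 0 else np.nan
        counts[t] = c
    return msd, counts


# ---------------------------------------------------------------------------
# Python-level sweeps (thin wrappers, useful for stepping small systems)
# ---------------------------------------------------------------------------

def reactant_sweep(state: LatticeState, cfg: LatticeConfig,
                   rng: np.random.Generator) -> LatticeState:
    """Advance every surviving reactant by one attempted move (random order)."""
    order = rng.permutation(np.flatnonzero(state.alive)).astype(np.int64)
    seed = int(rng.integers(0, 2**31 - 1))
    _seed_and_reactant_sweep(state.occupancy, state.react_pos, state.unwrapped,
                             state.alive, order, cfg.edge, cfg.reaction_on,
                             seed)
    state.step_count += 1
    return state


@njit(cache=True)
def _seed_and_reactant_sweep(occ, pos, unw, alive, order, L, reaction_on, seed):
    np.random.seed(seed)
    _reactant_sweep_nb(occ, pos, unw, alive, order, L, reaction_on)


def nro_sweep(state: LatticeState, cfg: LatticeConfig,
              rng: np.random.Generator) -> LatticeState:
    """Attempt one rigid move for every NRO block with probability p_f."""
    seed = int(rng.integers(0, 2**31 - 1))
    _seed_and_nro_sweep(state.occupancy, state.block_anchor, state.block_edge,
                        cfg.edge, cfg.p_f, seed)
    return state


@njit(cache=True)
def _seed_and_nro_sweep(occ, anchors, e, L, p_f, seed):
    np.random.seed(seed)
    _nro_sweep_nb(occ, anchors, e, L, p_f)


# ---------------------------------------------------------------------------
# Full run
# ---------------------------------------------------------------------------

def run(cfg: LatticeConfig, keep_state: bool = False) -> LatticeRun:
    """Run a full simulation and return per-sweep MSD and reactant counts."""
    rng = np.random.default_rng(cfg.seed)
    state = init_lattice(cfg, rng)
    loop_seed = int(rng.integers(0, 2**31 - 1))
    msd, counts = _run_loop(
        state.occupancy, state.react_pos, state.unwrapped, state.alive,
        state.block_anchor, state.block_edge, cfg.edge, cfg.p_f,
        cfg.reaction_on, cfg.n_steps, loop_seed)
    state.step_count = cfg.n_steps
    return LatticeRun(
        steps=np.arange(1, cfg.n_steps + 1),
        msd=msd,
        counts=counts,
        config=cfg,
        final_state=state if keep_state else None,
    )


def preset_config(preset: Literal["static", "mobility", "size", "reaction"],
                  fraction: float = 0.2, p_f: float = 0.1, r_nro: int = 1,
                  n_steps: int = 100_000, seed: int = 0,
                  edge: int = 50, n_reactants: int = 1000) -> LatticeConfig:
    """Named experiment presets.

    * ``static``: immobile obstacles (single-site, p_f = 0);
    * ``mobility``: single-site obstacles moving with the given p_f;
    * ``size``: aggregated blocks of the given r_nro moving with p_f = 1;
    * ``reaction``: A + A -> A coalescence among immobile obstacles.
    """
    common = dict(edge=edge, nro_fraction=fraction, n_steps=n_steps,
                  seed=seed, n_reactants=n_reactants)
    if preset == "static":
        return LatticeConfig(nro_radius_px=0, p_f=0.0, **common)
    if preset == "mobility":
        return LatticeConfig(nro_radius_px=0, p_f=p_f, **common)
    if preset == "size":
        return LatticeConfig(nro_radius_px=r_nro, p_f=1.0, **common)
    if preset == "reaction":
        return LatticeConfig(nro_radius_px=0, p_f=0.0, reaction_on=True,
                             **common)
    raise ValueError(f"unknown preset {preset!r}")
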