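"""Cellular automaton for tumor and normal tissue.

Per-site state is held in parallel integer/float arrays. A site carries
at most one cell. Cycle phases are G1/S/G2/M; only proliferative cells
age through the cycle, and a cell completing mitosis divides into an
empty von-Neumann neighbor (normal cells additionally require the local
Moore-neighborhood occupancy to sit below a density threshold).

Death rules: a cell dies when its normalized ATP production rate
W_A/A_0 falls below the death threshold, or when the local pH drops
below its acid tolerance (tumor cells are acid-resistant down to
A_res = 6, normal cells die earlier). Dead tumor cells persist as
necrotic material; dead normal cells lyse and free their site, which is
what lets the acidified tumor margin invade.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import LatticeSpec, ParamSet, RandomStream

EMPTY, NORMAL, TUMOR = 0, 1, 2
PROLIF, QUIESC, DEAD, TREATED = 0, 1, 2, 3
G1, S, G2, M = 0, 1, 2, 3

# raster export codes
RASTER_EMPTY, RASTER_NORMAL, RASTER_TPROLIF, RASTER_TQUIESC, RASTER_DEAD, \
    RASTER_TREATED = 0, 1, 2, 3, 4, 5

_VN_OFFSETS = ((-1, 0), (1, 0), (0, -1), (0, 1))
_MOORE_OFFSETS = tuple(
    (dy, dx) for dy in (-1, 0, 1) for dx in (-1, 0, 1) if (dy, dx) != (0, 0)
)


@dataclass
class CellGrid:
    kind: np.ndarray          # uint8, EMPTY/NORMAL/TUMOR
    state: np.ndarray         # uint8, PROLIF/QUIESC/DEAD/TREATED
    phase: np.ndarray         # uint8, G1/S/G2/M
    phase_age: np.ndarray     # float, hours within current phase
    hypoxic: np.ndarray       # bool, eta_P (oxygen-quiescent tumor)
    prior_state: np.ndarray = field(default=None)  # for normal-cell repair
    treat_clock: np.ndarray = field(default=None)  # hours since treatment
    acid_tol: np.ndarray = field(default=None)     # per-site normal pH tolerance

    def __post_init__(self):
        if self.prior_state is None:
            self.prior_state = np.zeros_like(self.state)
        if self.treat_clock is None:
            self.treat_clock = np.full(self.state.shape, -1.0)
        if self.acid_tol is None:
            self.acid_tol = np.full(self.state.shape, 7.0)

    @property
    def shape(self):
        return self.kind.shape

    def copy(self) -> "CellGrid":
        return CellGrid(self.kind.copy(), self.state.copy(), self.phase.copy(),
                        self.phase_age.copy(), self.hypoxic.copy(),
                        self.prior_state.copy(), self.treat_clock.copy(),
                        self.acid_tol.copy())

    # indicator fields used by the transport equations
    def tumor_mask(self) -> np.ndarray:
        return self.kind == TUMOR

    def alive_mask(self) -> np.ndarray:
        occupied = self.kind != EMPTY
        return occupied & ((self.state == PROLIF) | (self.state == QUIESC))

    def raster(self) -> np.ndarray:
        out = np.zeros(self.shape, dtype=np.uint8)
        out[(self.kind == NORMAL) & (self.state <= QUIESC)] = RASTER_NORMAL
        out[(self.kind == TUMOR) & (self.state == PROLIF)] = RASTER_TPROLIF
        out[(self.kind == TUMOR) & (self.state == QUIESC)] = RASTER_TQUIESC
        out[self.state == DEAD] = RASTER_DEAD
        out[(self.kind != EMPTY) & (self.state == TREATED)] = RASTER_TREATED
        return out


def census(grid: CellGrid) -> dict:
    """Exact counts by kind and state."""
    out = {}
    for kname, kcode in (("tumor", TUMOR), ("normal", NORMAL)):
        kmask = grid.kind == kcode
        out[kname] = {
            "proliferative": int(np.sum(kmask & (grid.state == PROLIF))),
            "quiescent": int(np.sum(kmask & (grid.state == QUIESC))),
            "dead": int(np.sum(kmask & (grid.state == DEAD))),
            "treated": int(np.sum(kmask & (grid.state == TREATED))),
        }
        out[kname]["total"] = sum(out[kname].values())
    out["empty"] = int(np.sum(grid.kind == EMPTY))
    return out


def init_cell_grid(lattice: LatticeSpec, params: ParamSet,
                   rng: RandomStream) -> CellGrid:
    """Seed tumor cells at the domain center inside normal tissue.

    ``initial_tumor_cells`` proliferative tumor cells (a centered block,
    9 by default -> 3x3) with cycle phases drawn proportionally to phase
    duration and ages uniform within phase; every other site holds a
    normal cell with probability ``normal_density``.
    """
    ny, nx = lattice.shape
    g = rng.cells
    kind = np.where(g.random((ny, nx)) < params.normal_density, NORMAL,
                    EMPTY).astype(np.uint8)
    state = np.zeros((ny, nx), dtype=np.uint8)  # everyone proliferative a priori
    durations = params.cycle_durations()
    probs = durations / durations.sum()
    phase = g.choice(4, size=(ny, nx), p=probs).astype(np.uint8)
    phase_age = g.random((ny, nx)) * durations[phase]

    n0 = params.initial_tumor_cells
    side = max(1, int(np.ceil(np.sqrt(n0))))
    cy, cx = ny // 2, nx // 2
    placed = 0
    for dy in range(side):
        for dx in range(side):
            if placed >= n0:
                break
            y = cy - side // 2 + dy
            x = cx - side // 2 + dx
            kind[y, x] = TUMOR
            state[y, x] = PROLIF
            placed += 1
    hypoxic = np.zeros((ny, nx), dtype=bool)
    # heterogeneous acid sensitivity of the host tissue, fixed per site
    acid_tol = np.clip(
        g.normal(params.normal_pH_death, params.normal_pH_death_sd, (ny, nx)),
        6.6, 7.3)
    grid = CellGrid(kind, state, phase, phase_age, hypoxic, acid_tol=acid_tol)
    # crowded normal tissue starts at rest; the tumor seed proliferates
    crowded = (kind == NORMAL) & \
        (_moore_occupancy(kind) >= params.normal_density_threshold)
    state[crowded] = QUIESC
    return grid


def _moore_occupancy(kind: np.ndarray) -> np.ndarray:
    """Fraction of the 8 Moore neighbors that are occupied (edge sites
    treat out-of-domain neighbors as occupied)."""
    occ = (kind != EMPTY).astype(float)
    padded = np.pad(occ, 1, constant_values=1.0)
    total = np.zeros_like(occ)
    for dy, dx in _MOORE_OFFSETS:
        total += padded[1 + dy: 1 + dy + occ.shape[0],
                        1 + dx: 1 + dx + occ.shape[1]]
    return total / 8.0


def update_cells(grid: CellGrid, atp_ratio: np.ndarray, pH: np.ndarray,
                 C_O2: np.ndarray, params: ParamSet, rng: RandomStream,
                 dt: float = 1.0) -> dict:
    """One CA step (default 1 h). Mutates ``grid``; returns event counts.

    atp_ratio -- W_A/A_0 evaluated at each occupied node
    pH, C_O2  -- current chemical fields
    """
    kind, state = grid.kind, grid.state
    occupied = kind != EMPTY
    alive = occupied & ((state == PROLIF) | (state == QUIESC))

    # --- survival / quiescence classification -------------------------
    acid_limit = np.where(kind == TUMOR, params.A_res, grid.acid_tol)
    die = alive & ((atp_ratio < params.A_d) | (pH < acid_limit))
    hypox = (kind == TUMOR) & alive & ~die & \
        (C_O2 < params.hypoxia_fraction * params.CO2_ref)
    # normal cells rest (and throttle their metabolism) while the local
    # density blocks proliferation
    crowded = (kind == NORMAL) & \
        (_moore_occupancy(kind) >= params.normal_density_threshold)
    quiesce = alive & ~die & (
        ((atp_ratio >= params.A_d) & (atp_ratio < params.A_q))
        | hypox | crowded)
    prolif = alive & ~die & ~quiesce

    deaths_tumor = int(np.sum(die & (kind == TUMOR)))
    deaths_normal = int(np.sum(die & (kind == NORMAL)))

    # dead tumor cells persist (necrosis); dead normal cells lyse
    state[die & (kind == TUMOR)] = DEAD
    kind[die & (kind == NORMAL)] = EMPTY
    state[quiesce] = QUIESC
    state[prolif] = PROLIF
    grid.hypoxic = hypox & quiesce

    # --- cycle progression --------------------------------------------
    # host tissue turns over an order of magnitude more slowly than tumor
    durations = params.cycle_durations()
    grid.phase_age[prolif & (kind == TUMOR)] += dt
    grid.phase_age[prolif & (kind == NORMAL)] += dt / params.normal_cycle_slowdown
    # advance through possibly several short phases
    for _ in range(2):
        dur = durations[grid.phase]
        ready = prolif & (grid.phase_age >= dur) & (grid.phase < M)
        grid.phase_age[ready] -= dur[ready]
        grid.phase[ready] += 1

    dividing = prolif & (grid.phase == M) & (grid.phase_age >= durations[M])
    ys, xs = np.nonzero(dividing)
    births = 0
    if ys.size:
        order = rng.order.permutation(ys.size)
        moore = _moore_occupancy(kind)
        ny, nx = kind.shape
        for i in order:
            y, x = int(ys[i]), int(xs[i])
            if kind[y, x] == NORMAL and \
                    moore[y, x] >= params.normal_density_threshold:
                continue  # density rule blocks normal division
            targets = [(y + dy, x + dx) for dy, dx in _VN_OFFSETS
                       if 0 <= y + dy < ny and 0 <= x + dx < nx
                       and kind[y + dy, x + dx] == EMPTY]
            if not targets:
                continue  # deferred: stays at end of M
            ty, tx = targets[rng.division.integers(len(targets))]
            kind[ty, tx] = kind[y, x]
            state[ty, tx] = PROLIF
            grid.phase[ty, tx] = G1
            grid.phase_age[ty, tx] = 0.0
            grid.phase[y, x] = G1
            grid.phase_age[y, x] = 0.0
            births += 1

    return {"births": births, "deaths_tumor": deaths_tumor,
            "deaths_normal": deaths_normal}
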