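"""Simulation loop, checkpointing and miniature fixtures.

One cellular-automaton step corresponds to 1 h of cellular dynamics and
runs, in order: chemical transport (oxygen, glucose, acid, VEGF) ->
cell update -> angiogenesis (morphogens, sprout selection, tip
migration, branching) -> blood-flow solve and radius adaptation ->
refresh of the vascular source terms. The default durations of
interest are 41.6 days (1000 steps, end of the avascular phase in the
default run) and 141.6 days (3400 steps, the treatment snapshot).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import cells as cellmod
from .angio import AngioModel, Sprout, TipCell
from .cells import CellGrid, census, init_cell_grid
from .chemistry import (ChemicalFields, ChemistrySolver, atp_ratio_field,
                        init_chemical_fields)
from .config import LatticeSpec, ParamSet, RandomStream, load_config
from .hemo import Segment, VesselNetwork, make_parent_vessel
from .treatment import TreatmentOutcome, TreatmentPlan, apply_xpdt, repair_normal

CHECKPOINT_VERSION = 1
HOURS_PER_DAY = 24.0


class IntegrityError(RuntimeError):
    """Corrupt or foreign checkpoint file."""


@dataclass
class SimulationState:
    lattice: LatticeSpec
    params: ParamSet
    rng: RandomStream
    fields: ChemicalFields
    grid: CellGrid
    net: VesselNetwork | None
    angio: AngioModel | None
    step: int = 0
    solver: ChemistrySolver = None

    def __post_init__(self):
        if self.solver is None:
            self.solver = ChemistrySolver(self.lattice, self.params)

    @property
    def clock_days(self) -> float:
        return self.step / HOURS_PER_DAY

    def copy(self) -> "SimulationState":
        import copy as _copy
        st = SimulationState(
            lattice=self.lattice, params=self.params,
            rng=RandomStream(self.rng.seed),
            fields=self.fields.copy(), grid=self.grid.copy(),
            net=_copy.deepcopy(self.net), angio=None,
            step=self.step, solver=self.solver)
        st.rng.set_state(self.rng.state())
        if self.angio is not None:
            ang = AngioModel(self.lattice, self.params)
            ang.A = self.angio.A.copy()
            ang.I = self.angio.I.copy()
            ang.f = self.angio.f.copy()
            ang.tips = _copy.deepcopy(self.angio.tips)
            ang.sprouts = _copy.deepcopy(self.angio.sprouts)
            ang.started = self.angio.started
            ang.onset_step = self.angio.onset_step
            ang.n_anastomoses = self.angio.n_anastomoses
            ang.n_branches = self.angio.n_branches
            st.angio = ang
        return st


@dataclass
class RunReport:
    rows: list = field(default_factory=list)
    onset_step: int | None = None
    onset_sprouts: int | None = None
    outcome: TreatmentOutcome | None = None

    def record(self, state: SimulationState) -> None:
        c = census(state.grid)
        self.rows.append({
            "step": state.step,
            "days": state.clock_days,
            "tumor_proliferative": c["tumor"]["proliferative"],
            "tumor_quiescent": c["tumor"]["quiescent"],
            "tumor_dead": c["tumor"]["dead"],
            "tumor_treated": c["tumor"]["treated"],
            "tumor_total": c["tumor"]["total"],
            "normal_total": c["normal"]["total"],
            "mvn": state.net.mvn if state.net is not None else 0,
            "segments": state.net.n_segments if state.net is not None else 0,
            "tips": state.angio.alive_tips if state.angio is not None else 0,
            "sprouts": len(state.angio.sprouts) if state.angio else 0,
            "mean_C_O2": float(state.fields.C_O2.mean()),
            "min_C_O2": float(state.fields.C_O2.min()),
        })

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)

    def digest(self) -> str:
        return hashlib.sha256(
            self.to_frame().to_csv(index=False).encode()).hexdigest()


def initialize_state(lattice: LatticeSpec, params: ParamSet,
                     rng: RandomStream) -> SimulationState:
    """Default initial condition: a small proliferative tumor seed at the
    domain center, normal tissue at 80% density, uniform chemistry, and
    (vascularized scenario) the parent vessel on the left border."""
    grid = init_cell_grid(lattice, params, rng)
    fields = init_chemical_fields(lattice, params)
    net = angio = None
    if params.vascularized:
        net = make_parent_vessel(lattice, params)
        net.solve_flow(params)
        angio = AngioModel(lattice, params)
    return SimulationState(lattice=lattice, params=params, rng=rng,
                           fields=fields, grid=grid, net=net, angio=angio)


def step_once(state: SimulationState, report: RunReport | None = None) -> None:
    p = state.params
    grid = state.grid

    # 1. chemistry with current vascular sources
    if state.net is not None:
        exchange = state.net.exchange_field(state.lattice.shape,
                                            p.parent_exchange_fraction)
    else:
        exchange = np.zeros(state.lattice.shape)
    state.fields = state.solver.step(state.fields, grid, exchange)

    # 2. cellular automaton
    ratio = atp_ratio_field(grid, state.fields, p)
    cellmod.update_cells(grid, ratio, state.fields.pH, state.fields.C_O2,
                         p, state.rng)

    # 3. VEGF + angiogenesis
    if state.angio is not None:
        ang = state.angio
        ec = ang.ec_mask(state.net)
        state.fields.C_v = state.solver.step_vegf(state.fields, grid.hypoxic, ec)
        if not ang.started and np.any(grid.hypoxic):
            ang.started = True
        if ang.started:
            ang.expire_inhibitors(state.step)
            ang.step_activator(grid.hypoxic)
            parent_nodes = sorted(ang._parent_nodes(state.net))
            born = ang.select_sprouts(parent_nodes, state.net, state.rng,
                                      state.step)
            if born and ang.onset_step is None:
                ang.onset_step = state.step
            ang.migrate_tips(state.fields.C_v, state.net, state.rng)
            ang.branch_tips(state.net, state.rng, state.fields.C_v)
        # 4. perfusion + adaptation
        state.net.solve_flow(p)
        state.net.adapt_radii(p)
        state.net.solve_flow(p)

    # 5. clocks
    treated = grid.state == cellmod.TREATED
    grid.treat_clock[treated & (grid.treat_clock >= 0)] += 1.0
    if np.any(treated & (grid.kind == cellmod.NORMAL)):
        mask = (grid.kind == cellmod.NORMAL) & treated & \
            (grid.treat_clock >= p.repair_delay_days * HOURS_PER_DAY)
        grid.state[mask] = grid.prior_state[mask]
        grid.treat_clock[mask] = -1.0
    state.step += 1
    if report is not None:
        report.record(state)


def run(config=None, *, seed: int = 0, until_days: float = 41.6,
        treat_at_days: float | None = None, plan: TreatmentPlan | None = None,
        state: SimulationState | None = None,
        record_every: int = 10) -> tuple[RunReport, SimulationState]:
    """Execute the coupled loop until ``until_days`` simulated days,
    optionally applying the treatment plan at ``treat_at_days``."""
    if state is None:
        lattice, params, rng = load_config(config, seed=seed)
        state = initialize_state(lattice, params, rng)
    report = RunReport()
    report.record(state)
    n_steps = int(round(until_days * HOURS_PER_DAY))
    treat_step = (None if treat_at_days is None
                  else int(round(treat_at_days * HOURS_PER_DAY)))
    while state.step < n_steps:
        step_once(state)
        if state.step % record_every == 0 or state.step == n_steps:
            report.record(state)
        if treat_step is not None and state.step == treat_step:
            if plan is None:
                plan = TreatmentPlan.from_params(state.params, 4.0, 4.0)
            report.outcome = apply_xpdt(state.grid, state.fields.C_O2, plan,
                                        state.rng, state.params)
    if state.angio is not None and state.angio.onset_step is not None:
        report.onset_step = state.angio.onset_step
        report.onset_sprouts = onset_sprout_count(state)
    return report, state


def onset_sprout_count(state: SimulationState, window_h: float = 120.0) -> int:
    """Sprouts of the initial activation wave: those formed while the
    activator first sweeps across the parent vessel (a 5-day window
    from the first sprout)."""
    ang = state.angio
    if ang is None or ang.onset_step is None:
        return 0
    return sum(1 for s in ang.sprouts
               if s.step_formed <= ang.onset_step + window_h)


# ----------------------------------------------------------------------
# checkpointing
# ----------------------------------------------------------------------

def checkpoint(state: SimulationState, path) -> None:
    """Lossless snapshot in an HDF5 container (deterministic layout)."""
    import h5py

    def put(group, name, arr):
        group.create_dataset(name, data=arr, track_times=False)

    with h5py.File(path, "w", track_order=False) as f:
        f.attrs["version"] = CHECKPOINT_VERSION
        f.attrs["step"] = state.step
        f.attrs["seed"] = state.rng.seed
        f.attrs["lattice"] = json.dumps(dataclasses.asdict(state.lattice))
        f.attrs["params"] = json.dumps(dataclasses.asdict(state.params))
        f.attrs["rng_state"] = json.dumps(state.rng.state(), default=int)
        g = f.create_group("grid")
        for name in ("kind", "state", "phase", "phase_age", "hypoxic",
                     "prior_state", "treat_clock", "acid_tol"):
            put(g, name, getattr(state.grid, name))
        c = f.create_group("chem")
        for name in ("C_O2", "C_G", "C_H", "C_v"):
            put(c, name, getattr(state.fields, name))
        if state.net is not None:
            v = f.create_group("net")
            put(v, "coords", np.array(state.net.coords, dtype=np.int32))
            segs = np.array([(s.a, s.b, s.R, s.L, s.branch_id, int(s.parent))
                             for s in state.net.segments], dtype=float)
            put(v, "segments", segs if segs.size else np.zeros((0, 6)))
            put(v, "boundary", np.array(
                [(i, p) for i, p in sorted(state.net.boundary.items())]))
            v.attrs["next_branch_id"] = state.net.next_branch_id
        if state.angio is not None:
            a = f.create_group("angio")
            put(a, "A", state.angio.A)
            put(a, "I", state.angio.I)
            put(a, "f", state.angio.f)
            a.attrs["started"] = state.angio.started
            a.attrs["onset_step"] = -1 if state.angio.onset_step is None \
                else state.angio.onset_step
            a.attrs["n_anastomoses"] = state.angio.n_anastomoses
            a.attrs["n_branches"] = state.angio.n_branches
            a.attrs["sprouts"] = json.dumps(
                [(s.origin, s.radius, s.step_formed, s.tip_index, s.active)
                 for s in state.angio.sprouts])
            a.attrs["tips"] = json.dumps(
                [{"pos": t.pos, "psi": t.psi, "alive": t.alive,
                  "branch_id": t.branch_id, "stall": t.stall,
                  "path": t.path_list}
                 for t in state.angio.tips])


def restore(path) -> SimulationState:
    import h5py

    try:
        f = h5py.File(path, "r")
    except OSError as exc:
        raise IntegrityError(f"cannot open checkpoint: {exc}") from exc
    with f:
        try:
            version = int(f.attrs["version"])
        except KeyError as exc:
            raise IntegrityError("missing version header") from exc
        if version != CHECKPOINT_VERSION:
            raise IntegrityError(
                f"checkpoint version {version} not supported "
                f"(expected {CHECKPOINT_VERSION})")
        try:
            lattice = LatticeSpec(**json.loads(f.attrs["lattice"]))
            params = ParamSet(**json.loads(f.attrs["params"]))
            rng = RandomStream(int(f.attrs["seed"]))
            rng.set_state(json.loads(f.attrs["rng_state"]))
            g = f["grid"]
            grid = CellGrid(
                kind=g["kind"][()], state=g["state"][()], phase=g["phase"][()],
                phase_age=g["phase_age"][()], hypoxic=g["hypoxic"][()],
                prior_state=g["prior_state"][()],
                treat_clock=g["treat_clock"][()], acid_tol=g["acid_tol"][()])
            c = f["chem"]
            fields = ChemicalFields(C_O2=c["C_O2"][()], C_G=c["C_G"][()],
                                    C_H=c["C_H"][()], C_v=c["C_v"][()])
            net = angio = None
            if "net" in f:
                v = f["net"]
                net = VesselNetwork()
                for (y, x) in v["coords"][()]:
                    net.node_index((int(y), int(x)))
                for a_, b_, R, L, bid, par in v["segments"][()]:
                    net.segments.append(Segment(int(a_), int(b_), float(R),
                                                float(L), int(bid), bool(par)))
                for i, pressure in v["boundary"][()]:
                    net.boundary[int(i)] = float(pressure)
                net.next_branch_id = int(v.attrs["next_branch_id"])
            if "angio" in f:
                a = f["angio"]
                angio = AngioModel(lattice, params)
                angio.A = a["A"][()]
                angio.I = a["I"][()]
                angio.f = a["f"][()]
                angio.started = bool(a.attrs["started"])
                onset = int(a.attrs["onset_step"])
                angio.onset_step = None if onset < 0 else onset
                angio.n_anastomoses = int(a.attrs["n_anastomoses"])
                angio.n_branches = int(a.attrs["n_branches"])
                angio.sprouts = []
                for o, r, s, ti, act in json.loads(a.attrs["sprouts"]):
                    sp = Sprout(tuple(o), r, s, tip_index=ti, active=act)
                    if act:
                        sp.kernel = angio._inhibitor_kernel(tuple(o), r)
                    angio.sprouts.append(sp)
                for t in json.loads(a.attrs["tips"]):
                    tip = TipCell(pos=tuple(t["pos"]), psi=t["psi"],
                                  alive=t["alive"], branch_id=t["branch_id"],
                                  stall=t.get("stall", 0))
                    tip.path_list = [tuple(q) for q in t["path"]]
                    tip.path = set(tip.path_list)
                    angio.tips.append(tip)
            step = int(f.attrs["step"])
        except IntegrityError:
            raise
        except Exception as exc:
            raise IntegrityError(f"corrupt checkpoint: {exc}") from exc
    state = SimulationState(lattice=lattice, params=params, rng=rng,
                            fields=fields, grid=grid, net=net, angio=angio,
                            step=step)
    if net is not None:
        net.solve_flow(params)
    return state


# ----------------------------------------------------------------------
# fixtures
# ----------------------------------------------------------------------

def make_fixture(kind: str, seed: int = 0) -> SimulationState:
    """Deterministic miniature states for unit exercise of each module."""
    if kind == "tiny-tumor":
        lattice, params, rng = load_config(
            {"nx": 32, "ny": 32, "vascularized": False}, seed=seed)
        return initialize_state(lattice, params, rng)

    if kind == "two-vessel-loop":
        lattice, params, rng = load_config(
            {"nx": 16, "ny": 16, "vascularized": False}, seed=seed)
        state = initialize_state(lattice, params, rng)
        net = VesselNetwork()
        bid = net.new_branch_id()
        # two identical three-segment paths between the boundary nodes
        for path in ([(0, 0), (1, 0), (2, 0), (3, 0)],
                     [(0, 0), (0, 1), (2, 1), (3, 0)]):
            for a, b in zip(path[:-1], path[1:]):
                net.add_segment(a, b, 4.0, 25.0, bid)
        net.boundary[net.nodes[(0, 0)]] = 120.0
        net.boundary[net.nodes[(3, 0)]] = 20.0
        net.solve_flow(params)
        state.net = net
        return state

    if kind == "hypoxic-core":
        lattice, params, rng = load_config(
            {"nx": 32, "ny": 32, "vascularized": False}, seed=seed)
        state = initialize_state(lattice, params, rng)
        yy, xx = np.mgrid[0:32, 0:32]
        disk = (yy - 16) ** 2 + (xx - 16) ** 2 <= 8 ** 2
        core = (yy - 16) ** 2 + (xx - 16) ** 2 <= 4 ** 2
        state.grid.kind[disk] = cellmod.TUMOR
        state.grid.state[disk] = cellmod.PROLIF
        state.grid.state[core] = cellmod.QUIESC
        state.fields.C_O2[:] = params.CO2_ref
        state.fields.C_O2[core] = 0.0
        return state

    if kind == "uniform-oxic":
        lattice, params, rng = load_config(
            {"nx": 32, "ny": 32, "vascularized": False}, seed=seed)
        state = initialize_state(lattice, params, rng)
        state.fields.C_O2[:] = 10 * params.CO2_ref
        return state

    raise ValueError(f"unknown fixture kind: {kind}")
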