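"""Capillary network: Poiseuille flow, apparent viscosity, and
structural adaptation of vessel radii.

The network lives on lattice nodes. Segment conductance is
g = pi R^4 / (8 mu_app L); nodal mass conservation (sum Q = 0) gives a
sparse linear system with Dirichlet pressures at the parent-vessel
inlet and outlet. Dead-end branches carry (numerically) zero flow and
only loop-closing subnetworks perfuse.

Radii adapt by dR = S_total R dt with S_total the sum of a wall-shear
stimulus, an intravascular-pressure stimulus and a metabolic stimulus,
against a constant intrinsic shrinking tendency; the empirical
shear/pressure response curves follow the microvascular adaptation
literature.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.sparse.csgraph import connected_components

from .config import LatticeSpec, ParamSet

MMHG = 1333.22  # dyn/cm^2


class TopologyError(RuntimeError):
    """Flow solve attempted on a network without pressure anchoring."""


def apparent_viscosity(R_um, H_D, mu_plasma: float = 1.2):
    """Apparent blood viscosity (cP) vs capillary radius and hematocrit.

    Empirical glass-tube law: the relative viscosity at H_D = 0.45 has
    its characteristic minimum near 7 µm diameter, and the law reduces
    to the plasma viscosity as H_D -> 0.
    """
    R_um = np.asarray(R_um, dtype=float)
    if np.any(R_um <= 0):
        raise ValueError("radius must be positive")
    if np.any((np.asarray(H_D) < 0) | (np.asarray(H_D) >= 1)):
        raise ValueError("hematocrit must lie in [0, 1)")
    D = 2.0 * R_um
    mu45 = 220.0 * np.exp(-1.3 * D) + 3.2 - 2.44 * np.exp(-0.06 * D**0.645)
    Cc = (0.8 + np.exp(-0.075 * D)) * (-1.0 + 1.0 / (1.0 + 1e-11 * D**12)) \
        + 1.0 / (1.0 + 1e-11 * D**12)
    H_D = np.asarray(H_D, dtype=float)
    num = (1.0 - H_D) ** Cc - 1.0
    den = (1.0 - 0.45) ** Cc - 1.0
    mu_rel = 1.0 + (mu45 - 1.0) * num / den
    return mu_plasma * mu_rel


@dataclass
class Segment:
    a: int                 # node indices
    b: int
    R: float               # µm
    L: float               # µm
    branch_id: int         # unbranched-run identifier (MVN counting)
    parent: bool = False   # belongs to the pre-existing parent vessel


@dataclass
class VesselNetwork:
    nodes: dict = field(default_factory=dict)      # (y, x) -> index
    coords: list = field(default_factory=list)     # index -> (y, x)
    segments: list = field(default_factory=list)
    boundary: dict = field(default_factory=dict)   # node index -> pressure mmHg
    pressures: np.ndarray | None = None            # mmHg per node
    Q: np.ndarray | None = None                    # cm^3/s per segment
    tau_w: np.ndarray | None = None                # dyn/cm^2 per segment
    mu: np.ndarray | None = None                   # cP per segment
    S_prev: dict = field(default_factory=dict)     # seg idx -> last stimulus
    next_branch_id: int = 0

    def node_index(self, pos) -> int:
        pos = (int(pos[0]), int(pos[1]))
        if pos not in self.nodes:
            self.nodes[pos] = len(self.coords)
            self.coords.append(pos)
        return self.nodes[pos]

    def has_node(self, pos) -> bool:
        return (int(pos[0]), int(pos[1])) in self.nodes

    def new_branch_id(self) -> int:
        self.next_branch_id += 1
        return self.next_branch_id - 1

    def add_segment(self, pos_a, pos_b, R: float, L: float,
                    branch_id: int, parent: bool = False) -> int:
        a = self.node_index(pos_a)
        b = self.node_index(pos_b)
        self.segments.append(Segment(a, b, R, L, branch_id, parent))
        return len(self.segments) - 1

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    @property
    def mvn(self) -> int:
        """Micro-vessel number: count of unbranched vessel runs."""
        return len({s.branch_id for s in self.segments if not s.parent})

    def node_mask(self, shape) -> np.ndarray:
        mask = np.zeros(shape, dtype=bool)
        for (y, x) in self.nodes:
            mask[y, x] = True
        return mask

    # ------------------------------------------------------------------
    def solve_flow(self, params: ParamSet) -> None:
        """Nodal pressure solve; fills pressures, Q, tau_w, mu."""
        if not self.boundary:
            raise TopologyError("no fixed-pressure boundary nodes")
        n = len(self.coords)
        m = len(self.segments)
        if m == 0:
            self.pressures = np.zeros(n)
            self.Q = np.zeros(0)
            self.tau_w = np.zeros(0)
            self.mu = np.zeros(0)
            return
        R_cm = np.array([s.R for s in self.segments]) * 1e-4
        L_cm = np.array([s.L for s in self.segments]) * 1e-4
        mu_cP = apparent_viscosity(np.array([s.R for s in self.segments]),
                                   params.hematocrit, params.mu_plasma)
        g = np.pi * R_cm**4 / (8.0 * mu_cP * 1e-2 * L_cm)  # cm^3 / (s dyn/cm^2)

        ai = np.array([s.a for s in self.segments])
        bi = np.array([s.b for s in self.segments])
        A = sp.coo_matrix(
            (np.concatenate([g, g, -g, -g]),
             (np.concatenate([ai, bi, ai, bi]),
              np.concatenate([ai, bi, bi, ai]))),
            shape=(n, n)).tocsr()

        # restrict to components that contain a boundary node
        adj = sp.coo_matrix((np.ones(m), (ai, bi)), shape=(n, n))
        ncomp, labels = connected_components(adj, directed=False)
        anchored = {labels[i] for i in self.boundary}
        live = np.isin(labels, list(anchored))
        if not np.any(live):
            raise TopologyError("no network component touches a boundary node")

        P = np.zeros(n)
        fixed = np.zeros(n, dtype=bool)
        for i, p_mmHg in self.boundary.items():
            fixed[i] = True
            P[i] = p_mmHg * MMHG
        free = live & ~fixed
        if np.any(free):
            idx = np.nonzero(free)[0]
            Aff = A[idx][:, idx]
            rhs = -A[idx][:, np.nonzero(fixed)[0]] @ P[np.nonzero(fixed)[0]]
            try:
                P[idx] = spla.spsolve(Aff.tocsr(), rhs)
            except Exception as exc:
                raise TopologyError(f"singular flow system: {exc}") from exc
        P[~live] = 0.0

        dP = P[ai] - P[bi]
        Q = g * dP
        Q[~live[ai]] = 0.0
        self.pressures = P / MMHG
        self.Q = Q
        self.mu = mu_cP
        self.tau_w = 4.0 * mu_cP * 1e-2 * np.abs(Q) / (np.pi * R_cm**3)

    def perfused_mask(self) -> np.ndarray:
        """Segments that actually carry flow (loop-closing paths)."""
        if self.Q is None or self.Q.size == 0:
            return np.zeros(len(self.segments), dtype=bool)
        qmax = np.max(np.abs(self.Q))
        if qmax == 0:
            return np.zeros(len(self.segments), dtype=bool)
        return np.abs(self.Q) > 1e-6 * qmax

    def residuals(self) -> np.ndarray:
        """|sum Q| at every interior (non-boundary) node."""
        n = len(self.coords)
        r = np.zeros(n)
        for s, q in zip(self.segments, self.Q):
            r[s.a] -= q
            r[s.b] += q
        for i in self.boundary:
            r[i] = 0.0
        return np.abs(r)

    # ------------------------------------------------------------------
    def adapt_radii(self, params: ParamSet, adapt_parent: bool = False) -> None:
        """One structural-adaptation step from the current flow state."""
        if self.Q is None:
            raise RuntimeError("flow must be solved before adaptation")
        if not self.segments:
            return
        absQ = np.abs(self.Q)
        pos = absQ[absQ > 0]
        q_floor = 1e-6 * (np.median(pos) if pos.size else params.Q_ref)
        for i, s in enumerate(self.segments):
            if s.parent and not adapt_parent:
                continue
            tau = self.tau_w[i]
            Pm = max(0.5 * (self.pressures[s.a] + self.pressures[s.b]), 10.001)
            tau_e = 100.0 - 86.0 * np.exp(
                -5000.0 * (np.log10(np.log10(Pm))) ** 5.4)
            S_wss = np.log10(tau + params.tau_ref)
            S_p = -params.k_p * np.log10(tau_e)
            Qh = max(absQ[i], q_floor) * params.hematocrit
            S_m = params.k_m * np.log10(params.Q_ref / Qh + 1.0)
            S_tot = S_wss + S_p + S_m - params.shrink_tendency
            S_used = 0.5 * (S_tot + self.S_prev.get(i, S_tot))
            self.S_prev[i] = S_tot
            s.R = float(np.clip(s.R * (1.0 + S_used * params.adapt_dt),
                                params.R_min, params.R_max))

    def exchange_field(self, shape,
                       parent_fraction: float = 0.0) -> np.ndarray:
        """Per-node sum of 2/R (cm^-1) over incident perfused segments;
        multiplied by a molecule's permeability q_i this is the vascular
        exchange rate density of the transport equation.

        The pre-existing parent vessel is an arteriole whose wall
        exchanges little; its segments contribute scaled by
        ``parent_fraction`` (0 by default).
        """
        out = np.zeros(shape)
        if self.Q is None or not self.segments:
            return out
        perf = self.perfused_mask()
        for i, s in enumerate(self.segments):
            if not perf[i]:
                continue
            w = 2.0 / (s.R * 1e-4)
            if s.parent:
                w *= parent_fraction
                if w == 0.0:
                    continue
            for node in (s.a, s.b):
                y, x = self.coords[node]
                out[y, x] += 0.5 * w
        return out


def make_parent_vessel(lattice: LatticeSpec, params: ParamSet) -> VesselNetwork:
    """Pre-existing arteriole along the left border (x = 0 column) with a
    fixed end-to-end pressure drop."""
    net = VesselNetwork()
    ny = lattice.shape[0]
    bid = net.new_branch_id()
    for y in range(ny - 1):
        net.add_segment((y, 0), (y + 1, 0), params.parent_radius,
                        lattice.dx, bid, parent=True)
    p_low = params.parent_pressure_low
    net.boundary[net.nodes[(0, 0)]] = p_low + params.parent_delta_P
    net.boundary[net.nodes[(ny - 1, 0)]] = p_low
    return net
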