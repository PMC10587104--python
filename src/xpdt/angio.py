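"""Sprout initiation and tip-cell migration.

Sprouting follows an adaptive-sprout-spacing scheme: a diffusible
activator is secreted by hypoxic tumor cells and a lateral inhibitor by
every formed sprout. A parent-vessel node sprouts when the activator
reaches its trigger level while the inhibitor sits below threshold;
each new sprout immediately deposits inhibitor over a random radius,
which is what spaces sprouts irregularly along the parent vessel.

Both morphogens are fast relative to the cellular clock and are kept at
their quasi-steady profiles (diffusion balancing decay around the
current sources). Each sprout's inhibitor kernel is scaled so that its
threshold contour sits at the drawn suppression radius.

Tip migration is hybrid discrete-continuum: the endothelial-cell flux
(diffusion + VEGF chemotaxis with receptor saturation + fibronectin
haptotaxis) is discretized on the five-point stencil and the resulting
coefficients are used as movement probabilities for each discrete tip.
Tips deposit capillary segments as they move, branch once their age
exceeds the branching-age threshold, and fuse (anastomose) when they
step onto existing vasculature, closing perfusable loops.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import LatticeSpec, ParamSet, RandomStream
from .fields import SteadyOperator
from .hemo import VesselNetwork


@dataclass
class TipCell:
    pos: tuple          # (y, x)
    psi: float = 0.0    # age since sprouting/branching, h
    alive: bool = True
    path: set = field(default_factory=set)
    path_list: list = field(default_factory=list)
    branch_id: int = -1
    stall: int = 0      # consecutive steps without movement

    def visit(self, pos) -> None:
        self.pos = pos
        self.path.add(pos)
        self.path_list.append(pos)


@dataclass
class Sprout:
    origin: tuple
    radius: float       # realized suppression radius, lattice units
    step_formed: int
    tip_index: int = -1  # index into AngioModel.tips
    kernel: np.ndarray | None = None
    active: bool = True  # still depositing inhibitor


class AngioModel:
    """Morphogen fields, sprout bookkeeping and tip dynamics."""

    def __init__(self, lattice: LatticeSpec, params: ParamSet):
        self.lattice = lattice
        self.params = params
        self._opA = SteadyOperator(lattice.shape, lattice.dx_cm,
                                   params.D_a, params.lambda_a)
        self._opI = SteadyOperator(lattice.shape, lattice.dx_cm,
                                   params.D_inh, params.lambda_inh)
        self.A = np.zeros(lattice.shape)
        self.I = np.zeros(lattice.shape)
        self.f = np.full(lattice.shape, params.f_init)
        self.tips: list[TipCell] = []
        self.sprouts: list[Sprout] = []
        self.started = False
        self.onset_step: int | None = None
        self.n_anastomoses = 0
        self.n_branches = 0

    # ------------------------------------------------------------------
    def step_activator(self, hypoxic: np.ndarray) -> None:
        """Quasi-steady activator around the current hypoxic sources."""
        src = self.params.src_a * hypoxic.astype(float)
        if np.any(src):
            self.A = self._opA.solve(src)
        else:
            self.A = np.zeros(self.lattice.shape)

    def _inhibitor_kernel(self, origin, radius: float) -> np.ndarray:
        """Steady inhibitor plume of one sprout, scaled so the threshold
        contour sits ``radius`` lattice units from the origin."""
        src = np.zeros(self.lattice.shape)
        src[origin] = 1.0
        kern = self._opI.solve(src)
        y0, x0 = origin
        ny, nx = self.lattice.shape
        ref_vals = []
        r = int(round(radius))
        for yy, xx in ((y0 + r, x0), (y0 - r, x0), (y0, x0 + r)):
            if 0 <= yy < ny and 0 <= xx < nx:
                ref_vals.append(kern[yy, xx])
        ref = max(np.mean(ref_vals) if ref_vals else kern.max() * 1e-3, 1e-300)
        return kern * (self.params.I_thresh / ref)

    def select_sprouts(self, parent_nodes, net: VesselNetwork,
                       rng: RandomStream, step: int) -> list[TipCell]:
        """Apply the two sprouting conditions along the parent vessel.

        Nodes are scanned in order of descending activator; each formed
        sprout deposits its inhibitor before the next candidate is
        examined, so adjacent super-threshold nodes cannot both sprout.
        """
        p = self.params
        taken = {s.origin for s in self.sprouts}
        cand = [n for n in parent_nodes if n not in taken]
        cand.sort(key=lambda n: -self.A[n])
        born = []
        for node in cand:
            if self.A[node] < p.A_trigg or self.I[node] > p.I_thresh:
                continue
            radius = rng.inhibitor.uniform(p.inhibitor_radius_min,
                                           p.inhibitor_radius_max)
            kernel = self._inhibitor_kernel(node, radius)
            self.I = self.I + kernel
            tip = TipCell(pos=node, branch_id=net.new_branch_id())
            tip.path.add(node)
            tip.path_list.append(node)
            self.tips.append(tip)
            self.sprouts.append(Sprout(node, radius, step,
                                       tip_index=len(self.tips) - 1,
                                       kernel=kernel))
            born.append(tip)
        return born

    def expire_inhibitors(self, step: int) -> None:
        """A sprout deposits inhibitor while it is an active sprouting
        site; once its tip has fused or regressed and the deposition
        lifetime has passed, the local suppression fades and the parent
        vessel can sprout again (successive sprouting waves)."""
        lifetime = self.params.inhibitor_lifetime_h
        changed = False
        for s in self.sprouts:
            if not s.active:
                continue
            tip_dead = (0 <= s.tip_index < len(self.tips)
                        and not self.tips[s.tip_index].alive)
            if tip_dead and step - s.step_formed > lifetime:
                s.active = False
                changed = True
        if changed:
            self.I = np.zeros(self.lattice.shape)
            for s in self.sprouts:
                if s.active and s.kernel is not None:
                    self.I = self.I + s.kernel

    # ------------------------------------------------------------------
    def _move_probabilities(self, tip: TipCell, c_hat: np.ndarray,
                            parent_nodes: set) -> tuple[list, np.ndarray]:
        """Five-point stencil movement probabilities {stay, N, S, W, E}."""
        p = self.params
        h = self.lattice.h
        k = p.tip_dt
        ny, nx = self.lattice.shape
        y, x = tip.pos

        def at(arr, yy, xx):
            return arr[min(max(yy, 0), ny - 1), min(max(xx, 0), nx - 1)]

        c0 = c_hat[y, x]
        chemo = p.chi / (1.0 + p.sigma * c0)
        base = k * p.D_e / h**2
        dirs = ((-1, 0), (1, 0), (0, -1), (0, 1))
        probs = [0.0]
        targets = [None]
        for dy, dx in dirs:
            dc = at(c_hat, y + dy, x + dx) - at(c_hat, y - dy, x - dx)
            df = at(self.f, y + dy, x + dx) - at(self.f, y - dy, x - dx)
            w = base + (k / h**2) * 0.25 * (chemo * dc + p.rho * df)
            ty, tx = y + dy, x + dx
            ok = (0 <= ty < ny and 0 <= tx < nx
                  and (ty, tx) not in tip.path
                  and (ty, tx) not in parent_nodes)
            probs.append(max(w, 0.0) if ok else 0.0)
            targets.append((ty, tx) if ok else None)
        probs = np.asarray(probs)
        probs[0] = max(1.0 - probs[1:].sum(), 0.0)
        total = probs.sum()
        if total <= 0:
            probs = np.array([1.0, 0, 0, 0, 0])
            total = 1.0
        return targets, probs / total

    def migrate_tips(self, C_v: np.ndarray, net: VesselNetwork,
                     rng: RandomStream) -> None:
        """One movement attempt per alive tip; deposits segments, updates
        fibronectin, and handles anastomosis on contact."""
        p = self.params
        cmax = C_v.max()
        c_hat = C_v / cmax if cmax > 0 else np.zeros_like(C_v)
        parent_nodes = self._parent_nodes(net)
        tip_positions = {t.pos for t in self.tips if t.alive}
        for tip in self.tips:
            if not tip.alive:
                continue
            tip.psi += 1.0
            targets, probs = self._move_probabilities(tip, c_hat, parent_nodes)
            choice = rng.tips.choice(5, p=probs)
            target = targets[choice]
            # fibronectin dynamics at the occupied node (e = 1 at the tip)
            y, x = tip.pos
            self.f[y, x] += p.tip_dt * (p.beta_f - p.gamma_f * self.f[y, x])
            if target is None:
                tip.stall += 1
                if tip.stall > p.tip_stall_limit:
                    tip.alive = False  # boxed-in sprout regresses
                    tip_positions.discard(tip.pos)
                continue
            tip.stall = 0
            occupied_by_vessel = net.has_node(target)
            occupied_by_tip = target in tip_positions and target != tip.pos
            if occupied_by_vessel or occupied_by_tip:
                # contact with existing vasculature: fuse (close a loop)
                # with probability fuse_prob, otherwise the move is blocked
                if rng.tips.random() < p.fuse_prob:
                    net.add_segment(tip.pos, target, p.capillary_radius,
                                    self.lattice.dx, tip.branch_id)
                    tip.alive = False
                    self.n_anastomoses += 1
                    tip_positions.discard(tip.pos)
                else:
                    tip.stall += 1
                continue
            net.add_segment(tip.pos, target, p.capillary_radius,
                            self.lattice.dx, tip.branch_id)
            tip_positions.discard(tip.pos)
            tip.visit(target)
            tip_positions.add(target)

    @staticmethod
    def _parent_nodes(net: VesselNetwork) -> set:
        out = set()
        for s in net.segments:
            if s.parent:
                out.add(net.coords[s.a])
                out.add(net.coords[s.b])
        return out

    def branch_tips(self, net: VesselNetwork, rng: RandomStream,
                    C_v: np.ndarray | None = None) -> None:
        """Tips older than the branching-age threshold split in two.

        Splitting is VEGF-driven: a tip branches only where the
        normalized VEGF concentration is high (near the hypoxic tumor),
        so sprouts cross the host tissue as single trunks and arborize
        around their target.
        """
        p = self.params
        ny, nx = self.lattice.shape
        if C_v is not None and C_v.max() > 0:
            c_hat = C_v / C_v.max()
        else:
            c_hat = None
        new_tips = []
        for tip in self.tips:
            if not tip.alive or tip.psi < p.psi_branch:
                continue
            if c_hat is not None and \
                    c_hat[tip.pos] < p.vegf_branch_threshold:
                continue
            if rng.tips.random() > p.branch_prob:
                continue
            y, x = tip.pos
            free = [(y + dy, x + dx)
                    for dy, dx in ((-1, 0), (1, 0), (0, -1), (0, 1))
                    if 0 <= y + dy < ny and 0 <= x + dx < nx
                    and (y + dy, x + dx) not in tip.path
                    and not net.has_node((y + dy, x + dx))]
            if not free:
                continue
            tip.psi = 0.0
            tip.branch_id = net.new_branch_id()
            child = TipCell(pos=tip.pos, branch_id=net.new_branch_id())
            child.path = set(tip.path)
            child.path_list = [tip.pos]
            new_tips.append(child)
            self.n_branches += 1
        self.tips.extend(new_tips)

    def ec_mask(self, net: VesselNetwork) -> np.ndarray:
        """Endothelial occupancy (vessel nodes and active tips)."""
        mask = net.node_mask(self.lattice.shape)
        for t in self.tips:
            if t.alive:
                mask[t.pos] = True
        return mask

    @property
    def alive_tips(self) -> int:
        return sum(1 for t in self.tips if t.alive)
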