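"""Transport of oxygen, glucose, hydrogen ion and VEGF.

Each species obeys  dC/dt = D lap(C) + A + B  with cellular uptake A and
vascular exchange B = sum 2 q / R (C_b - C_w) over perfused capillary
segments at a node, under no-flux boundaries. The wall concentration
C_w is identified with the local extravascular concentration, so the
exchange acts as a relaxation toward the intravascular level C_b.

Metabolism follows Michaelis-Menten oxygen consumption with a glycolytic
(Warburg) glucose pathway: when oxygen is scarce, glucose consumption
rises to defend the ATP production rate and protons are excreted. The
classification rates returned by :func:`metabolic_rates` are the demand
rates achievable at the local concentrations; the transport sink scales
them by each cell's metabolic activity (full for proliferative cells,
``quiescent_metabolic_fraction`` for resting cells, zero for dead or
treated cells).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import cells as C
from .config import LatticeSpec, ParamSet
from .fields import (SteadyOperator, diffuse, laplacian_eigenvalues, react,
                     steady_solve)

# per-cell rate (mol/cell/s) * phi (cell/cm^3) -> mol/(L s)
_CM3_TO_L = 1.0e3


@dataclass
class MetabolicRates:
    """Per-cell metabolic demand rates, mol/(cell s)."""

    W_O2: np.ndarray   # <= 0, oxygen consumption
    W_G: np.ndarray    # <= 0, glucose consumption
    W_A: np.ndarray    # >= 0, ATP production
    W_H: np.ndarray    # >= 0, proton excretion
    A_0: float         # baseline ATP rate, (29/5) V_O2


@dataclass
class ChemicalFields:
    """Concentration fields (mol/L; VEGF in arbitrary units)."""

    C_O2: np.ndarray
    C_G: np.ndarray
    C_H: np.ndarray
    C_v: np.ndarray

    def copy(self) -> "ChemicalFields":
        return ChemicalFields(self.C_O2.copy(), self.C_G.copy(),
                              self.C_H.copy(), self.C_v.copy())

    @property
    def pH(self) -> np.ndarray:
        return -np.log10(np.maximum(self.C_H, 1e-14))


def init_chemical_fields(lattice: LatticeSpec, params: ParamSet) -> ChemicalFields:
    ny, nx = lattice.shape
    m = params.oxygen_multiplier
    return ChemicalFields(
        C_O2=np.full((ny, nx), params.C_O2_init * m),
        C_G=np.full((ny, nx), params.C_G_init),
        C_H=np.full((ny, nx), params.C_H_init),
        C_v=np.zeros((ny, nx)),
    )


def metabolic_rates(C_O2, C_G, params: ParamSet, P_G=None) -> MetabolicRates:
    """Demand rates from the local oxygen and glucose concentrations.

    Accepts scalars or fields. ``P_G`` defaults to the configured tumor
    Warburg multiplier; pass 1.0 for normal cells.
    """
    C_O2 = np.asarray(C_O2, dtype=float)
    C_G = np.asarray(C_G, dtype=float)
    if np.any(C_O2 < 0) or np.any(C_G < 0):
        raise ValueError("concentrations must be nonnegative")
    if P_G is None:
        P_G = params.P_G
    A0 = params.A_0
    W_O2 = -params.V_O2 * C_O2 / (C_O2 + params.K_O2)
    g = C_G / (C_G + params.K_G)
    W_G = -(P_G * A0 / 2.0 + 27.0 * W_O2 / 10.0) * g
    W_A = -(2.0 * W_G + 27.0 * W_O2 / 5.0)
    W_H = params.K_H * 29.0 * (P_G * params.V_O2 + W_O2) / 5.0
    return MetabolicRates(W_O2=W_O2, W_G=W_G, W_A=W_A, W_H=W_H, A_0=A0)


def activity_field(grid: C.CellGrid, params: ParamSet,
                   pathway: str = "oxidative") -> np.ndarray:
    """Metabolic activity per site in [0, 1]; scales the transport sink.

    Proliferating tumor cells consume at the full Table rates; dormant
    tumor cells throttle their *oxidative* pathway to
    ``quiescent_metabolic_fraction`` while their glycolytic pathway
    (glucose uptake, proton excretion) stays at
    ``quiescent_tumor_glycolysis`` -- hypoxia-arrested tumor cells keep
    fermenting, which is what acidifies the tumor margin. Host tissue
    runs at its low homeostatic baseline
    ``normal_metabolic_fraction`` regardless of division state.
    """
    act = np.zeros(grid.shape)
    alive = grid.alive_mask()
    tumor = grid.tumor_mask()
    act[alive & tumor & (grid.state == C.PROLIF)] = 1.0
    resting_tumor = alive & tumor & (grid.state == C.QUIESC)
    if pathway == "glycolytic":
        act[resting_tumor] = params.quiescent_tumor_glycolysis
    else:
        act[resting_tumor] = params.quiescent_metabolic_fraction
    if params.normal_uptake:
        act[alive & (grid.kind == C.NORMAL)] = params.normal_metabolic_fraction
    return act


def atp_ratio_field(grid: C.CellGrid, fields: ChemicalFields,
                    params: ParamSet) -> np.ndarray:
    """W_A/A_0 per node, evaluated with the tumor Warburg multiplier on
    tumor sites and P_G = 1 elsewhere. Unoccupied nodes report 1."""
    tumor = metabolic_rates(fields.C_O2, fields.C_G, params)
    out = np.ones(grid.shape)
    tmask = grid.tumor_mask()
    out[tmask] = (tumor.W_A / tumor.A_0)[tmask]
    if params.P_G != 1.0:
        normal = metabolic_rates(fields.C_O2, fields.C_G, params, P_G=1.0)
        nmask = grid.kind == C.NORMAL
        out[nmask] = (normal.W_A / normal.A_0)[nmask]
    else:
        nmask = grid.kind == C.NORMAL
        out[nmask] = (tumor.W_A / tumor.A_0)[nmask]
    return out


class ChemistrySolver:
    """Split-step integrator for the chemical fields on one lattice.

    Per CA step the fields advance by ``chem_seconds_per_step`` seconds
    of chemical time: exact pointwise reaction (linearized uptake and
    vascular exchange) followed by the exact diffusion semigroup.
    """

    def __init__(self, lattice: LatticeSpec, params: ParamSet):
        self.lattice = lattice
        self.params = params
        self.eig = laplacian_eigenvalues(lattice.shape, lattice.dx_cm)
        self._vegf_op = None

    def step(self, fields: ChemicalFields, grid: C.CellGrid,
             exchange: np.ndarray, tau: float | None = None) -> ChemicalFields:
        """Advance O2, glucose and H+ by ``tau`` seconds (default: the
        configured chemical time per CA step).

        ``exchange`` is the per-node vascular exchange density
        sum(2 q / R) in 1/s units per unit permeability ratio -- i.e.
        the field of 2/R sums (cm^-1); each molecule multiplies by its
        own permeability q_i.
        """
        p = self.params
        if tau is None:
            tau = p.chem_seconds_per_step
        act = activity_field(grid, p)
        act_gly = activity_field(grid, p, pathway="glycolytic")
        tumor = grid.tumor_mask()
        P_G_field = np.where(tumor, p.P_G, 1.0)
        A0 = p.A_0
        m = p.oxygen_multiplier

        # oxygen: MM uptake linearized about the current field
        k_up = act * p.V_O2 * p.phi * _CM3_TO_L / (fields.C_O2 + p.K_O2)
        k = k_up + p.q_O2 * exchange
        s = p.q_O2 * exchange * (p.C_b_O2 * p.O2_partition * m)
        C_O2 = react(fields.C_O2, k, s, tau)
        C_O2 = diffuse(C_O2, p.D_O2, tau, self.lattice.dx_cm, self.eig)

        # glucose: demand coefficient depends on the oxygen just solved
        W_O2 = -p.V_O2 * C_O2 / (C_O2 + p.K_O2)
        coef = (P_G_field * A0 / 2.0 + 27.0 * W_O2 / 10.0)  # >= 0 per-cell rate
        k_up = act_gly * coef * p.phi * _CM3_TO_L / (fields.C_G + p.K_G)
        k = k_up + p.q_G * exchange + p.lambda_G
        s = (p.q_G * exchange + p.lambda_G) * p.C_b_G
        C_G = react(fields.C_G, k, s, tau)
        C_G = diffuse(C_G, p.D_G, tau, self.lattice.dx_cm, self.eig)

        # hydrogen ion: zeroth-order excretion, vascular washout
        W_H = p.K_H * 29.0 * (P_G_field * p.V_O2 + W_O2) / 5.0
        s = act_gly * W_H * p.phi * _CM3_TO_L \
            + (p.q_H * exchange + p.lambda_H) * p.C_b_H
        k = p.q_H * exchange + p.lambda_H
        C_H = react(fields.C_H, k, s, tau)
        C_H = diffuse(C_H, p.D_H, tau, self.lattice.dx_cm, self.eig)

        return ChemicalFields(C_O2=C_O2, C_G=C_G, C_H=C_H, C_v=fields.C_v)

    def step_vegf(self, fields: ChemicalFields, hypoxic: np.ndarray,
                  ec_nodes: np.ndarray) -> np.ndarray:
        """Quasi-steady VEGF: secretion by hypoxic tumor cells balanced by
        diffusion and decay (plus endothelial uptake when enabled).

        VEGF kinetics are fast on the cellular clock, so the field sits
        at the steady profile of its current sources. With ``eps_v`` = 0
        the operator is constant and factorized once; a nonzero EC
        uptake switches to a general solve with spatially varying decay.
        """
        p = self.params
        src = p.W_v_phi * hypoxic.astype(float)
        if not np.any(src):
            return np.zeros(self.lattice.shape)
        if p.eps_v > 0 and np.any(ec_nodes):
            decay = p.lambda_v + p.eps_v * ec_nodes.astype(float)
            return steady_solve(p.D_v, decay, src, self.lattice.dx_cm)
        if self._vegf_op is None:
            self._vegf_op = SteadyOperator(self.lattice.shape,
                                           self.lattice.dx_cm,
                                           p.D_v, p.lambda_v)
        return self._vegf_op.solve(src)


def steady_chemical(lattice: LatticeSpec, params: ParamSet,
                    uptake_rate: np.ndarray, exchange: np.ndarray,
                    q: float, C_b: float, D: float,
                    iterations: int = 1, C0: np.ndarray | None = None,
                    K: float | None = None) -> np.ndarray:
    """Quasi-steady solve of one species with linear(ized) uptake.

    ``uptake_rate`` is the saturated volumetric consumption (mol/L/s);
    when ``K`` is given the Michaelis-Menten denominator is iterated by
    Picard starting from ``C0`` (or C_b). Used by fixtures and by the
    dense-oracle solver checks.
    """
    shape = uptake_rate.shape
    Cb_field = np.full(shape, C_b)
    Cprev = Cb_field.copy() if C0 is None else C0.copy()
    out = Cprev
    for _ in range(max(1, iterations)):
        if K is None:
            k = uptake_rate + q * exchange
        else:
            k = uptake_rate / (Cprev + K) + q * exchange
        src = q * exchange * C_b
        out = steady_solve(D, k, src, lattice.dx_cm)
        Cprev = out
    return out
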