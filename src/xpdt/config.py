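"""Lattice geometry, parameter set, and seeded random streams.

All concentrations are mol/L, diffusivities cm^2/s, lengths µm at the
interface (cm internally where noted), times in hours for the cellular
clock and seconds for chemical kinetics.
"""

from __future__ import annotations

import dataclasses
import io
from dataclasses import dataclass, field, fields as dc_fields

import numpy as np
import yaml


class ConfigError(ValueError):
    """Malformed configuration input."""


class ValidationError(ValueError):
    """A parameter value violates a model invariant."""


@dataclass(frozen=True)
class LatticeSpec:
    """Regular square lattice over the tissue domain.

    nx, ny   -- node counts
    dx, dy   -- grid spacing in µm (one cell diameter)
    """

    nx: int = 200
    ny: int = 200
    dx: float = 25.0
    dy: float = 25.0

    def __post_init__(self) -> None:
        if self.nx < 8 or self.ny < 8:
            raise ValidationError("lattice must be at least 8x8")
        if self.dx <= 0 or self.dy <= 0:
            raise ValidationError("grid spacing must be positive")

    @property
    def h(self) -> float:
        """Nondimensional space step on the unit square (1/nx)."""
        return 1.0 / self.nx

    @property
    def physical_extent_mm(self) -> float:
        """Domain side length in mm; dx·nx exactly."""
        return self.nx * self.dx / 1000.0

    @property
    def dx_cm(self) -> float:
        return self.dx * 1e-4

    @property
    def shape(self) -> tuple[int, int]:
        # (ny, nx): row index y, column index x; parent vessel at x = 0.
        return (self.ny, self.nx)


# Fields whose values must be strictly positive.
_POSITIVE = {
    "P_G", "alpha", "beta", "alpha_NC", "beta_NC", "Y_sc",
    "D_O2", "D_G", "D_H", "K_O2", "K_G", "V_O2", "K_H",
    "A_res", "A_d", "A_q", "b", "C_b_O2", "C_b_G", "C_b_H",
    "psi_ref", "Kp_over_Kot", "phi",
    "C_O2_init", "C_G_init", "pH_init",
    "parent_delta_P", "parent_radius", "capillary_radius", "segment_length",
    "q_O2", "q_G", "q_H",
    "chem_seconds_per_step", "N_th", "mu_rho_ratio",
}


@dataclass
class ParamSet:
    """Physiological and treatment parameters (defaults: the model's
    reference parameter table plus frozen gap-filled constants)."""

    # --- metabolism ---
    P_G: float = 1.0                 # Warburg glucose multiplier (tumor), dimensionless
    D_O2: float = 2.41e-5            # cm^2/s
    D_G: float = 9e-5                # cm^2/s
    D_H: float = 1.1e-5              # cm^2/s
    K_O2: float = 5e-6               # mol/L
    K_G: float = 4e-5                # mol/L
    V_O2: float = 2.3e-16            # mol/(cell s)
    K_H: float = 2.5e-4              # proton buffering, dimensionless
    A_res: float = 6.0               # tumor acid-death pH
    A_d: float = 0.3                 # ATP death threshold (W_A/A_0)
    A_q: float = 0.8                 # ATP quiescence threshold
    phi: float = 5e7                 # cells/cm^3
    normal_pH_death: float = 7.25    # mean normal-tissue acid tolerance
    normal_pH_death_sd: float = 0.08  # cell-to-cell tolerance spread
    lambda_H: float = 0.05           # host acid clearance/buffering, 1/s
    lambda_G: float = 0.01           # host glucose replenishment, 1/s
    hypoxia_fraction: float = 0.1    # eta_P when C_O2 < fraction * CO2_ref
    quiescent_metabolic_fraction: float = 0.01  # dormant-tumor O2 uptake scale
    quiescent_tumor_glycolysis: float = 1.0  # dormant tumor glycolytic activity
    normal_metabolic_fraction: float = 0.002  # host-tissue baseline uptake scale
    normal_uptake: bool = True       # normal cells metabolize (P_G = 1)

    # --- intravascular / initial chemistry ---
    C_b_O2: float = 5.6e-5           # mol/L
    C_b_G: float = 5e-3              # mol/L
    C_b_H: float = 3.98e-8           # mol/L
    C_O2_init: float = 5.2e-6        # mol/L == CO2_ref
    C_G_init: float = 5e-3           # mol/L
    pH_init: float = 7.4
    oxygen_multiplier: float = 1.0   # scales C_b_O2 and the initial O2 field
    q_O2: float = 3.0e-4             # capillary permeability, cm/s (calibrated, frozen)
    q_G: float = 3.0e-4
    q_H: float = 3.0e-4
    parent_exchange_fraction: float = 0.0  # arteriole wall barely exchanges
    # Blood O2 content is mostly hemoglobin-bound; transmural equilibrium is
    # set by the free plasma fraction, so tissue next to a capillary sits
    # near the reference tissue oxygenation (5.2e-6 / 5.6e-5).
    O2_partition: float = 5.2e-6 / 5.6e-5
    chem_seconds_per_step: float = 0.2  # chemical time advanced per 1 h CA step

    # --- VEGF (arbitrary concentration units) ---
    D_v: float = 1.0e-6              # cm^2/s
    W_v_phi: float = 1.0e-3          # source rate per hypoxic node, 1/s
    eps_v: float = 0.0               # EC uptake rate, 1/s (off by default)
    lambda_v: float = 1.0e-4         # decay, 1/s

    # --- cell cycle ---
    dur_G1: float = 11.0             # h
    dur_S: float = 8.0
    dur_G2: float = 4.0
    dur_M: float = 1.0
    sens_G1: float = 0.8             # radiosensitivity multipliers on alpha
    sens_S: float = 0.9
    sens_G2: float = 1.25
    sens_M: float = 1.25
    normal_density_threshold: float = 0.8  # Moore-neighborhood occupancy gate
    normal_cycle_slowdown: float = 10.0  # host cycle time / tumor cycle time

    # --- angiogenesis morphogens (activator/inhibitor, arbitrary units) ---
    D_a: float = 1.0e-6              # cm^2/s
    lambda_a: float = 1.0e-4         # 1/s
    src_a: float = 1.0               # per hypoxic node
    A_trigg: float = 340.0           # trigger level (calibrated, frozen)
    D_inh: float = 1.0e-6
    lambda_inh: float = 5.0e-3
    I_thresh: float = 1.0
    inhibitor_radius_min: float = 6.0   # lattice units
    inhibitor_radius_max: float = 16.0
    inhibitor_lifetime_h: float = 1.0e9  # deposition persists after tip death

    # --- tip migration (nondimensional, unit-square stencil) ---
    D_e: float = 0.00035
    chi: float = 0.38
    sigma: float = 0.6
    rho: float = 0.34
    beta_f: float = 0.05
    gamma_f: float = 0.1
    f_init: float = 0.75
    tip_dt: float = 0.015            # nondim stencil time step per CA step
    branch_prob: float = 0.12        # per-step branching rate once psi >= threshold
    vegf_branch_threshold: float = 0.5  # tip splits only where normalized VEGF is high
    tip_stall_limit: int = 72        # steps without movement before a tip regresses
    fuse_prob: float = 0.4           # probability a vessel contact anastomoses

    # --- vessels / hemodynamics ---
    parent_delta_P: float = 100.0    # mmHg end-to-end
    parent_pressure_low: float = 20.0  # mmHg outlet
    parent_radius: float = 14.0      # µm
    capillary_radius: float = 2.0    # µm
    segment_length: float = 25.0     # µm
    psi_ref: float = 18.0            # branching-age threshold, h
    psi_multiplier: float = 1.0
    hematocrit: float = 0.45
    mu_plasma: float = 1.2           # cP
    tau_ref: float = 0.103           # dyn/cm^2
    k_p: float = 0.5
    k_m: float = 1.0
    Q_ref: float = 4.0e-8            # cm^3/s
    shrink_tendency: float = 1.0     # intrinsic shrinking offset
    adapt_dt: float = 0.05           # adaptation step (dimensionless)
    R_min: float = 1.0               # µm
    R_max: float = 14.0              # µm
    lookahead_steps: int = 10        # stimulus smoothing horizon

    # --- treatment ---
    alpha: float = 0.002             # Gy^-1 (tumor)
    beta: float = 0.01               # Gy^-2 (tumor)
    alpha_NC: float = 0.211          # Gy^-1 (normal)
    beta_NC: float = 0.068           # Gy^-2 (normal)
    Y_sc: float = 1e5                # photons/MeV
    mu_rho_ratio: float = 1.0        # (µ/ρ)_sc / (µ/ρ)_tissue
    b: float = 0.45                  # ml/mg
    Kp_over_Kot: float = 11.9e-6     # mol/L
    N_th: float = 4e7                # lethal 1O2 molecules/cell
    normal_drug_fraction: float = 0.5
    kill_law: str = "linear"         # or "one_hit"
    repair_delay_days: float = 4.16

    # --- scenario / initial state ---
    vascularized: bool = True
    normal_density: float = 0.80
    initial_tumor_cells: int = 9

    @property
    def CO2_ref(self) -> float:
        """Reference tissue oxygen concentration (mol/L)."""
        return 5.2e-6

    @property
    def V_cell(self) -> float:
        """Cell volume, cm^3/cell (always derived from phi)."""
        return 1.0 / self.phi

    @property
    def A_0(self) -> float:
        """Baseline ATP production rate, mol/(cell s)."""
        return 29.0 / 5.0 * self.V_O2

    @property
    def C_H_init(self) -> float:
        return 10.0 ** (-self.pH_init)

    @property
    def psi_branch(self) -> float:
        return self.psi_ref * self.psi_multiplier

    def cycle_durations(self) -> np.ndarray:
        return np.array([self.dur_G1, self.dur_S, self.dur_G2, self.dur_M])

    def cycle_sensitivities(self) -> np.ndarray:
        return np.array([self.sens_G1, self.sens_S, self.sens_G2, self.sens_M])

    def validate(self) -> None:
        for f in dc_fields(self):
            if f.name in _POSITIVE:
                v = getattr(self, f.name)
                if not (isinstance(v, (int, float)) and v > 0):
                    raise ValidationError(
                        f"parameter {f.name} must be strictly positive, got {v!r}"
                    )
        if not (0.0 < self.A_d < self.A_q <= 1.0):
            raise ValidationError("require 0 < A_d < A_q <= 1")
        ratio = self.alpha_NC / self.beta_NC
        if abs(ratio - 3.1) / 3.1 > 0.02:
            raise ValidationError(
                f"normal-tissue alpha/beta = {ratio:.3g} departs from 3.1 by > 2%"
            )
        if not (0.0 <= self.normal_drug_fraction <= 1.0):
            raise ValidationError("normal_drug_fraction must lie in [0, 1]")
        if not (0.0 <= self.hematocrit < 1.0):
            raise ValidationError("hematocrit must lie in [0, 1)")
        if not (self.sens_G2 >= self.sens_M >= self.sens_S >= self.sens_G1 > 0):
            raise ValidationError(
                "cycle sensitivities must satisfy G2 >= M >= S >= G1 > 0"
            )
        if self.kill_law not in ("linear", "one_hit"):
            raise ValidationError("kill_law must be 'linear' or 'one_hit'")
        if self.inhibitor_radius_min > self.inhibitor_radius_max:
            raise ValidationError("inhibitor radius range inverted")
        if self.R_min <= 0 or self.R_min > self.R_max:
            raise ValidationError("radius clamp range invalid")


class RandomStream:
    """Seeded random source with independent substreams.

    Substreams: cell-cycle initialization, tip migration, inhibitor
    spacing, division placement, treatment draws, CA visit order.
    """

    _NAMES = ("cells", "tips", "inhibitor", "division", "treatment", "order")

    def __init__(self, seed: int):
        self.seed = int(seed)
        ss = np.random.SeedSequence(self.seed)
        children = ss.spawn(len(self._NAMES))
        self._streams = {
            name: np.random.Generator(np.random.PCG64(child))
            for name, child in zip(self._NAMES, children)
        }

    def __getattr__(self, name: str) -> np.random.Generator:
        try:
            return self.__dict__["_streams"][name]
        except KeyError:
            raise AttributeError(name) from None

    def state(self) -> dict:
        return {k: g.bit_generator.state for k, g in self._streams.items()}

    def set_state(self, state: dict) -> None:
        for k, s in state.items():
            self._streams[k].bit_generator.state = s


_LATTICE_KEYS = {"nx", "ny", "dx", "dy"}
_PARAM_KEYS = {f.name for f in dc_fields(ParamSet)}


def load_config(source=None, *, seed: int = 0, **overrides):
    """Build (LatticeSpec, ParamSet, RandomStream) from defaults plus overrides.

    ``source`` may be None, a mapping, a path to a flat key: value YAML
    file, or a file-like object. Keyword overrides win over the file.
    Unknown keys are rejected.
    """
    data: dict = {}
    if source is not None:
        if isinstance(source, dict):
            data = dict(source)
        else:
            try:
                if hasattr(source, "read"):
                    text = source.read()
                else:
                    with open(source) as fh:
                        text = fh.read()
                loaded = yaml.safe_load(text)
            except yaml.YAMLError as exc:
                raise ConfigError(f"cannot parse configuration: {exc}") from exc
            except OSError as exc:
                raise ConfigError(f"cannot read configuration: {exc}") from exc
            if loaded is None:
                loaded = {}
            if not isinstance(loaded, dict):
                raise ConfigError("configuration must be a flat key: value mapping")
            data = loaded
    data.update(overrides)

    if "seed" in data:
        seed = int(data.pop("seed"))

    unknown = set(data) - _LATTICE_KEYS - _PARAM_KEYS
    if unknown:
        raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")

    lat_kwargs = {k: data[k] for k in _LATTICE_KEYS & set(data)}
    par_kwargs = {k: data[k] for k in _PARAM_KEYS & set(data)}
    lattice = LatticeSpec(**lat_kwargs)
    params = ParamSet(**par_kwargs)
    params.validate()
    return lattice, params, RandomStream(seed)


def serialize_config(lattice: LatticeSpec, params: ParamSet, seed: int = 0) -> str:
    """YAML round-trip companion of load_config."""
    out = {"seed": seed}
    out.update(dataclasses.asdict(lattice))
    out.update(dataclasses.asdict(params))
    buf = io.StringIO()
    yaml.safe_dump(out, buf, sort_keys=True)
    return buf.getvalue()
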