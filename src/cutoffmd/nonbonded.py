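"""Reaction-field electrostatics and Lennard-Jones interactions.

The electrostatic pair energy is

    V(r) = f q_i q_j [ 1/r - (C_rf r^2) / (2 R_rf^3) - (1 - C_rf/2) / R_rf ]

with f = 1/(4 pi eps0). The quadratic term is the reaction of a homogeneous
dielectric continuum (relative permittivity ``eps_rf``) outside the cutoff
sphere of radius R_rf; the distance-independent term shifts the potential so
it vanishes exactly at r = R_rf. For zero ionic strength and unit dielectric
inside the cutoff the reaction-field constant is

    C_rf = 2 (eps_rf - 1) / (2 eps_rf + 1).

Energies are decomposed into solute-solute, solute-solvent and
solvent-solvent contributions. Under group-based cutoffs only the *list
membership* is decided by group-center distances: the distance-dependent
terms always use atomic separations, so pair energies need not vanish when a
group pair leaves the list — the physical origin of the group-scheme energy
jumps this package exists to study.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._kernels import eval_pairs, eval_single_range
from .constants import F_ELEC
from .pairlist import CutoffScheme, EntityList, PairStructure
from .system import System


def rf_constant(eps_rf: float) -> float:
    """Reaction-field constant C_rf for a continuum of relative permittivity
    ``eps_rf`` beyond the cutoff (zero ionic strength, unit internal
    dielectric)."""
    if eps_rf < 1:
        raise ValueError("eps_rf must be >= 1")
    return 2.0 * (eps_rf - 1.0) / (2.0 * eps_rf + 1.0)


@dataclass(frozen=True)
class RFParams:
    """Reaction-field parameters: dielectric, cutoff radius and the derived
    constant C_rf."""

    eps_rf: float
    r_rf: float

    def __post_init__(self) -> None:
        if self.eps_rf < 1:
            raise ValueError("eps_rf must be >= 1")
        if self.r_rf <= 0:
            raise ValueError("R_rf must be positive")

    @property
    def c_rf(self) -> float:
        return rf_constant(self.eps_rf)

    @property
    def k1(self) -> float:
        """C_rf / R_rf^3 (the force constant of the reaction-field term)."""
        return self.c_rf / self.r_rf**3

    @property
    def kshift(self) -> float:
        """(1 - C_rf/2) / R_rf (the shift that zeroes V at R_rf)."""
        return (1.0 - 0.5 * self.c_rf) / self.r_rf


def rf_pair_energy(q_i: float, q_j: float, r_ij: float, params: RFParams) -> float:
    """Electrostatic pair energy (kJ/mol) at separation ``r_ij`` (nm)."""
    if r_ij <= 0:
        raise ValueError("r_ij must be positive")
    # algebraically identical to 1/r - k1 r^2/2 - kshift, but written so the
    # value is exactly zero (in floating point too) at r = R_rf
    # (q_i * q_j) is grouped so the value is bitwise symmetric in the charges
    return (
        F_ELEC
        * (q_i * q_j)
        * ((1.0 / r_ij - 1.0 / params.r_rf) - 0.5 * params.k1 * (r_ij**2 - params.r_rf**2))
    )


def rf_pair_force(q_i: float, q_j: float, r_vec: np.ndarray, params: RFParams) -> np.ndarray:
    """Force (kJ mol^-1 nm^-1) on atom i, with ``r_vec = r_i - r_j``; the
    force on j is the negative."""
    r_vec = np.asarray(r_vec, dtype=float)
    r2 = float(r_vec @ r_vec)
    if r2 == 0.0:
        raise ValueError("zero separation")
    r = np.sqrt(r2)
    fscal = F_ELEC * (q_i * q_j) * (1.0 / (r2 * r) + params.k1)
    return fscal * r_vec


def lj_pair_energy_force(type_i, type_j, r_vec, lj) -> tuple[float, np.ndarray]:
    """Lennard-Jones V = C12/r^12 - C6/r^6 and the force on atom i."""
    r_vec = np.asarray(r_vec, dtype=float)
    r2 = float(r_vec @ r_vec)
    if r2 == 0.0:
        raise ValueError("zero separation")
    c6 = lj.c6[type_i, type_j]
    c12 = lj.c12[type_i, type_j]
    ir6 = 1.0 / r2**3
    energy = c12 * ir6 * ir6 - c6 * ir6
    fscal = (12.0 * c12 * ir6 * ir6 - 6.0 * c6 * ir6) / r2
    return float(energy), fscal * r_vec


@dataclass
class EnergyDecomposition:
    """Electrostatic and LJ energies split by subsystem pair (kJ/mol)."""

    elec: np.ndarray  # (3,) solute-solute, solute-solvent, solvent-solvent
    lj: np.ndarray    # (3,)

    @classmethod
    def zeros(cls) -> "EnergyDecomposition":
        return cls(np.zeros(3), np.zeros(3))

    @property
    def elec_total(self) -> float:
        return float(self.elec.sum())

    @property
    def lj_total(self) -> float:
        return float(self.lj.sum())

    @property
    def total(self) -> float:
        return self.elec_total + self.lj_total

    def __add__(self, other: "EnergyDecomposition") -> "EnergyDecomposition":
        return EnergyDecomposition(self.elec + other.elec, self.lj + other.lj)


def _eval(system: System, ev: dict, params: RFParams, forces: np.ndarray):
    e_el, e_lj, w = eval_pairs(
        system.positions,
        system.box,
        ev["ai"], ev["aj"], ev["qq"], ev["c6"], ev["c12"], ev["bucket"],
        params.k1, params.r_rf,
        forces,
    )
    return e_el, e_lj, w


def compute_single_range(
    system: System,
    entities: EntityList,
    params: RFParams,
    r_cut: float,
) -> tuple[EnergyDecomposition, np.ndarray, float]:
    """Single-range evaluation at the current positions without
    materializing a pairlist: entity pairs are classified by minimum-image
    center distance (strictly < ``r_cut``) and all non-excluded atom pairs
    between included entities are accumulated in one fused pass.

    Numerically equivalent to ``build_pairlist`` + :func:`compute_nonbonded`
    with ``r_short = r_long = r_cut`` (summation order may differ at the
    10^-15 relative level); used on hot paths — per-step single-range
    dynamics and per-frame trajectory re-evaluation.
    """
    forces = np.zeros_like(system.positions)
    box = system.box
    centers = entities.centers(system.positions)
    pos = system.positions - box * np.floor(system.positions / box)
    centers = np.ascontiguousarray(centers - box * np.floor(centers / box))
    e_el, e_lj, w = eval_single_range(
        pos,
        box,
        centers,
        entities.ent_ptr,
        entities.ent_atoms,
        entities.subsystem,
        system.molecule_id,
        system.charges,
        system.lj_type,
        system.lj_table.c6,
        system.lj_table.c12,
        entities.excl_keys,
        system.n_atoms,
        r_cut,
        params.k1,
        params.r_rf,
        forces,
    )
    return EnergyDecomposition(e_el, e_lj), forces, -0.5 * w


def compute_nonbonded(
    system: System,
    pairs: PairStructure,
    scheme: CutoffScheme,
    params: RFParams,
    step: int,
) -> tuple[EnergyDecomposition, np.ndarray, float]:
    """Evaluate nonbonded energies, per-atom forces and the virial over a
    pair structure.

    Short-range pairs are evaluated at the current positions every call.
    Intermediate-range pairs are evaluated once, when the pair structure is
    fresh (just after a pairlist update); the resulting forces, energy
    decomposition and virial are cached on the structure and re-added
    unchanged on subsequent steps until the next update.

    Returns ``(decomposition, forces, virial)`` with the virial
    Xi = -1/2 sum r_ij . F_ij.
    """
    forces = np.zeros_like(system.positions)
    e_el, e_lj, w = _eval(system, pairs.short_eval, params, forces)

    if len(pairs.intermediate_pairs):
        if pairs.cache is None:
            if pairs.last_update_step >= 0 and pairs.last_update_step != step:
                raise RuntimeError(
                    "stale intermediate-range cache: pairlist was built at step "
                    f"{pairs.last_update_step} but first evaluated at step {step}"
                )
            f_int = np.zeros_like(forces)
            ee, el, wi = _eval(system, pairs.inter_eval, params, f_int)
            pairs.cache = dict(forces=f_int, e_el=ee, e_lj=el, w=wi)
            pairs.last_update_step = step
        cache = pairs.cache
        forces += cache["forces"]
        e_el = e_el + cache["e_el"]
        e_lj = e_lj + cache["e_lj"]
        w += cache["w"]

    return EnergyDecomposition(e_el, e_lj), forces, -0.5 * w
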