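"""Leapfrog dynamics with SHAKE constraints and weak-coupling baths.

The step sequence is: (pairlist update when due) -> nonbonded forces
(short range + frozen intermediate-range cache) -> leapfrog -> SHAKE with
velocity correction and constraint-velocity projection -> per-bath
weak-coupling velocity scaling -> optional weak-coupling pressure scaling.
Solute and solvent couple to separate temperature baths; scaling one bath's
velocities leaves the other bath bit-identical.

Temperatures are defined per bath as T = 2 E_kin / (n_dof k_B) with
n_dof = 3 N_atoms - N_constraints of that bath (no global center-of-mass
motion removal by default). Kinetic energies entering the thermostat are the
post-constraint half-step values. Reported on-step kinetic energies average
the two adjacent half-step velocities.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from . import _kernels
from .constants import ATM, KB
from .nonbonded import RFParams, compute_nonbonded, compute_single_range
from .pairlist import (
    CutoffScheme,
    build_pairlist,
    make_entities,
    pairlist_due_for_update,
)
from .system import SOLUTE, SOLVENT, System

SHAKE_MAX_ITER = 500


@dataclass
class Protocol:
    """Integration and bath settings (defaults follow the reference setup:
    2 fs leapfrog steps, SHAKE tolerance 1e-4, weak coupling with
    tau_T = 0.1 ps and tau_P = 0.5 ps at 298.15 K and 1 atm)."""

    timestep: float = 0.002                  # ps
    n_steps: int = 1000
    t_ref_solute: float = 298.15             # K
    t_ref_solvent: float = 298.15            # K
    tau_t: float = 0.1                       # ps
    temperature_coupling: bool = True
    p_ref: float = ATM                       # kJ mol^-1 nm^-3
    tau_p: float = 0.5                       # ps
    isothermal_compressibility: float = 4.575e-4   # (kJ mol^-1 nm^-3)^-1
    pressure_coupling: bool = False
    shake_tolerance: float = 1e-4
    log_interval: int = 10                   # steps between energy-log rows
    frame_interval: int = 100                # steps between stored frames
    seed: int = 0

    def __post_init__(self) -> None:
        if self.timestep <= 0:
            raise ValueError("timestep must be positive")
        if self.temperature_coupling and self.tau_t < self.timestep:
            raise ValueError("tau_t must be >= timestep")
        if self.shake_tolerance <= 0:
            raise ValueError("shake tolerance must be positive")


@dataclass
class BathState:
    """Per-bath bookkeeping: degrees of freedom and the last scaling factor."""

    dof: int
    kinetic_energy: float = 0.0
    last_scale: float = 1.0


def leapfrog_step(system: System, forces: np.ndarray, timestep: float) -> System:
    """Advance velocities to t + dt/2 and positions to t + dt (in place); no
    constraint enforcement here."""
    system.velocities += forces / system.masses[:, None] * timestep
    system.positions += system.velocities * timestep
    return system


def shake(
    positions_new: np.ndarray,
    positions_ref: np.ndarray,
    constraint_pairs: np.ndarray,
    constraint_lengths: np.ndarray,
    tolerance: float,
    masses: np.ndarray,
) -> np.ndarray:
    """Return positions corrected to satisfy all distance constraints to the
    relative tolerance |d^2 - d0^2| / d0^2 <= tol."""
    out = np.array(positions_new, dtype=float, copy=True)
    if len(constraint_pairs) == 0:
        return out
    n_it = _kernels.shake(
        out,
        np.ascontiguousarray(positions_ref, dtype=float),
        np.ascontiguousarray(constraint_pairs[:, 0]),
        np.ascontiguousarray(constraint_pairs[:, 1]),
        np.ascontiguousarray(constraint_lengths, dtype=float) ** 2,
        1.0 / np.asarray(masses, dtype=float),
        tolerance,
        SHAKE_MAX_ITER,
    )
    if n_it < 0:
        worst = _kernels.max_constraint_violation(
            out,
            constraint_pairs[:, 0].copy(),
            constraint_pairs[:, 1].copy(),
            constraint_lengths**2,
        )
        raise RuntimeError(
            f"SHAKE did not converge within {SHAKE_MAX_ITER} iterations "
            f"(worst relative violation {worst:.3e})"
        )
    return out


def bath_temperature(kinetic_energy: float, dof: int) -> float:
    """Instantaneous temperature T = 2 E_kin / (dof k_B)."""
    if dof <= 0:
        raise ValueError("dof must be positive")
    return 2.0 * kinetic_energy / (dof * KB)


def weak_coupling_T_scale(
    t_inst: float, t_ref: float, timestep: float, tau_t: float
) -> float:
    """First-order weak-coupling velocity scaling factor
    lambda = sqrt(1 + (dt/tau)(T_ref/T - 1))."""
    if t_inst <= 0.0:
        # nothing to scale; documented skip (e.g. a cold-started bath)
        return 1.0
    return float(np.sqrt(1.0 + (timestep / tau_t) * (t_ref / t_inst - 1.0)))


def weak_coupling_P_scale(
    p_inst: float, p_ref: float, timestep: float, tau_p: float, kappa_t: float
) -> float:
    """Isotropic box/coordinate scaling factor
    mu = (1 - kappa (dt/tau)(P_ref - P_inst))^(1/3), clamped to [0.9, 1.1]."""
    mu3 = 1.0 - kappa_t * (timestep / tau_p) * (p_ref - p_inst)
    mu = float(np.cbrt(mu3))
    if not 0.9 <= mu <= 1.1:
        import warnings

        warnings.warn(
            f"pathological pressure spike: mu={mu:.4f} clamped to [0.9, 1.1]",
            stacklevel=2,
        )
        mu = min(max(mu, 0.9), 1.1)
    return mu


def compute_pressure(kinetic_energy: float, virial: float, volume: float) -> float:
    """P = (2/3)(E_kin - Xi)/V with Xi = -1/2 sum r_ij . F_ij."""
    if volume <= 0:
        raise ValueError("volume must be positive")
    return (2.0 / 3.0) * (kinetic_energy - virial) / volume


def minimize(
    system: System,
    scheme: CutoffScheme,
    params: Optional[RFParams] = None,
    n_steps: int = 300,
    max_displacement: float = 0.01,
    shake_tolerance: float = 1e-6,
) -> System:
    """Constrained steepest-descent relaxation.

    Lattice-built boxes start far above the liquid's potential energy;
    dropped straight into 2 fs dynamics they can heat faster than a weak
    coupling bath cools. A few hundred descent steps (displacement along the
    forces capped at ``max_displacement`` nm, constraints restored by SHAKE
    after every move, step size halved whenever the energy rises) remove the
    worst strain before velocities are assigned.
    """
    system = system.copy()
    if params is None:
        params = RFParams(eps_rf=78.0, r_rf=scheme.r_long)
    entities = make_entities(system, scheme)
    step_size = max_displacement
    last_energy = None
    for _ in range(n_steps):
        decomp, forces, _ = compute_single_range(
            system, entities, params, scheme.r_long
        )
        if last_energy is not None and decomp.total > last_energy:
            step_size = max(step_size * 0.5, 1e-5)
        last_energy = decomp.total
        fmax = np.abs(forces).max()
        if fmax == 0.0:
            break
        trial = system.positions + forces * (step_size / fmax)
        if len(system.constraint_pairs):
            trial = shake(
                trial,
                system.positions,
                system.constraint_pairs,
                system.constraint_lengths,
                shake_tolerance,
                system.masses,
            )
        system.positions = trial
    return system


@dataclass
class TrajectoryFrame:
    time: float
    positions: np.ndarray
    velocities: np.ndarray
    box: np.ndarray


@dataclass
class SimulationResult:
    """Output of :func:`run_simulation`: stored frames, the energy log (one
    dict per logged step, convertible to a DataFrame), run diagnostics and the
    final system state."""

    frames: list
    log: list
    diagnostics: dict
    system: System

    def log_frame(self):
        import pandas as pd

        return pd.DataFrame(self.log)


def run_simulation(
    system: System,
    scheme: CutoffScheme,
    protocol: Protocol,
    params: Optional[RFParams] = None,
    eps_rf: float = 78.0,
) -> SimulationResult:
    """Integrate ``system`` under ``scheme`` for ``protocol.n_steps`` steps.

    Frames and energy-log rows are recorded *before* integration of the step,
    so a logged row/frame pair reflects the same positions (and, whenever the
    frame interval is a multiple of the pairlist update interval, a freshly
    built pairlist — which is what makes stored frames exactly re-evaluable).
    """
    system = system.copy()
    system.validate(longest_cutoff=scheme.r_long)
    if params is None:
        params = RFParams(eps_rf=eps_rf, r_rf=scheme.r_long)
    dt = protocol.timestep
    entities = make_entities(system, scheme)

    baths = {}
    for label in (SOLUTE, SOLVENT):
        if system.mask(label).any():
            baths[label] = BathState(dof=system.dof(label))

    cp = system.constraint_pairs
    ci = np.ascontiguousarray(cp[:, 0]) if len(cp) else np.empty(0, dtype=np.int64)
    cj = np.ascontiguousarray(cp[:, 1]) if len(cp) else np.empty(0, dtype=np.int64)
    d0sq = system.constraint_lengths**2
    invm = 1.0 / system.masses

    frames: list[TrajectoryFrame] = []
    log: list[dict] = []
    diagnostics = {
        "max_constraint_violation": 0.0,
        "max_velocity_residual": 0.0,
        "scheme": scheme.describe(),
        "pairlist_updates": 0,
        "short_pair_count": 0,
        "intermediate_pair_count": 0,
    }

    # A single-range scheme rebuilt every step never caches anything, so the
    # pairlist need not be materialized at all; the fused kernel classifies
    # and evaluates in one pass.
    fused = scheme.r_short == scheme.r_long and scheme.update_interval == 1
    pairs = None
    for step in range(protocol.n_steps):
        if fused:
            decomp, forces, virial = compute_single_range(
                system, entities, params, scheme.r_long
            )
            diagnostics["pairlist_updates"] += 1
        else:
            if pairs is None or pairlist_due_for_update(step, scheme):
                pairs = build_pairlist(entities, system.positions, system.box, scheme)
                pairs.last_update_step = step
                diagnostics["pairlist_updates"] += 1
                diagnostics["short_pair_count"] = len(pairs.short_pairs)
                diagnostics["intermediate_pair_count"] = len(pairs.intermediate_pairs)
            decomp, forces, virial = compute_nonbonded(
                system, pairs, scheme, params, step
            )

        if step % protocol.frame_interval == 0:
            frames.append(
                TrajectoryFrame(
                    time=step * dt,
                    positions=system.positions.copy(),
                    velocities=system.velocities.copy(),
                    box=system.box.copy(),
                )
            )

        v_old = system.velocities.copy()
        pos_ref = system.positions.copy()
        leapfrog_step(system, forces, dt)
        if len(cp):
            unconstrained = system.positions
            corrected = shake(
                unconstrained,
                pos_ref,
                cp,
                system.constraint_lengths,
                protocol.shake_tolerance,
                system.masses,
            )
            system.velocities += (corrected - unconstrained) / dt
            system.positions = corrected
            _kernels.velocity_project(
                system.velocities, system.positions, ci, cj, invm, 1e-13, 200
            )
            res = _kernels.max_velocity_residual(
                system.velocities, system.positions, ci, cj
            )
            diagnostics["max_velocity_residual"] = max(
                diagnostics["max_velocity_residual"], float(res)
            )
            viol = _kernels.max_constraint_violation(system.positions, ci, cj, d0sq)
            diagnostics["max_constraint_violation"] = max(
                diagnostics["max_constraint_violation"], float(viol)
            )

        # --- weak-coupling thermostat (per bath, post-constraint velocities)
        t_by_bath = {}
        for label, bath in baths.items():
            bath.kinetic_energy = system.kinetic_energy(label)
            t_by_bath[label] = bath_temperature(bath.kinetic_energy, bath.dof)
        if protocol.temperature_coupling:
            for label, bath in baths.items():
                t_ref = (
                    protocol.t_ref_solute if label == SOLUTE else protocol.t_ref_solvent
                )
                lam = weak_coupling_T_scale(t_by_bath[label], t_ref, dt, protocol.tau_t)
                bath.last_scale = lam
                system.velocities[system.mask(label)] *= lam

        # --- weak-coupling barostat
        e_kin_half = sum(b.kinetic_energy for b in baths.values())
        pressure = compute_pressure(e_kin_half, virial, system.volume)
        if protocol.pressure_coupling:
            mu = weak_coupling_P_scale(
                pressure,
                protocol.p_ref,
                dt,
                protocol.tau_p,
                protocol.isothermal_compressibility,
            )
            system.box *= mu
            system.positions *= mu
            if (system.box < 2.0 * scheme.r_long).any():
                raise RuntimeError(
                    f"barostat shrank the box below 2 r_long at step {step}"
                )

        if step % protocol.log_interval == 0:
            v_on = 0.5 * (v_old + system.velocities)
            e_kin_on = float(0.5 * (system.masses * (v_on**2).sum(axis=1)).sum())
            row = {
                "step": step,
                "time": step * dt,
                "e_el_ss": decomp.elec[0],
                "e_el_sv": decomp.elec[1],
                "e_el_vv": decomp.elec[2],
                "e_el_total": decomp.elec_total,
                "e_lj_ss": decomp.lj[0],
                "e_lj_sv": decomp.lj[1],
                "e_lj_vv": decomp.lj[2],
                "e_lj_total": decomp.lj_total,
                "e_pot": decomp.total,
                "e_kin": e_kin_on,
                "e_total": decomp.total + e_kin_on,
                "virial": virial,
                "pressure": pressure,
                "volume": system.volume,
            }
            for label, name in ((SOLUTE, "solute"), (SOLVENT, "solvent")):
                if label in baths:
                    row[f"e_kin_{name}"] = baths[label].kinetic_energy
                    row[f"dof_{name}"] = baths[label].dof
                    row[f"T_{name}"] = t_by_bath[label]
            log.append(row)

    return SimulationResult(frames=frames, log=log, diagnostics=diagnostics, system=system)
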