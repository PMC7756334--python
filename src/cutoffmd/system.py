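"""In-memory representation of a simulated system.

A :class:`System` carries per-atom arrays (positions, velocities, masses,
charges, Lennard-Jones type indices), the partition of atoms into molecules,
charge groups and subsystems (solute / solvent), holonomic distance
constraints, nonbonded exclusions and the orthorhombic periodic box.

Subsystem labels are stored as small integers: ``SOLUTE = 0``, ``SOLVENT = 1``.
The sum of two labels then directly indexes the energy-decomposition buckets
(solute-solute, solute-solvent, solvent-solvent).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

SOLUTE = 0
SOLVENT = 1


@dataclass
class LJTable:
    """Symmetric per-type-pair Lennard-Jones coefficient tables.

    ``c6[i, j]`` in kJ mol^-1 nm^6 and ``c12[i, j]`` in kJ mol^-1 nm^12.
    """

    c6: np.ndarray
    c12: np.ndarray

    def __post_init__(self) -> None:
        self.c6 = np.asarray(self.c6, dtype=float)
        self.c12 = np.asarray(self.c12, dtype=float)
        if self.c6.shape != self.c12.shape or self.c6.ndim != 2:
            raise ValueError("LJ tables must be two square arrays of equal shape")
        if not (np.allclose(self.c6, self.c6.T) and np.allclose(self.c12, self.c12.T)):
            raise ValueError("LJ tables must be symmetric in the two types")
        if (self.c6 < 0).any() or (self.c12 < 0).any():
            raise ValueError("LJ coefficients must be non-negative")

    @classmethod
    def from_per_type(cls, c6_ii, c12_ii) -> "LJTable":
        """Build a combined table from per-type self coefficients by the
        geometric-mean combination rule."""
        r6 = np.sqrt(np.outer(c6_ii, c6_ii))
        r12 = np.sqrt(np.outer(c12_ii, c12_ii))
        return cls(r6, r12)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, LJTable)
            and self.c6.shape == other.c6.shape
            and np.array_equal(self.c6, other.c6)
            and np.array_equal(self.c12, other.c12)
        )


def _pair_key(i: np.ndarray, j: np.ndarray, n: int) -> np.ndarray:
    lo = np.minimum(i, j).astype(np.int64)
    hi = np.maximum(i, j).astype(np.int64)
    return lo * np.int64(n) + hi


@dataclass
class System:
    """A periodic system of point charges with rigid internal geometry."""

    names: np.ndarray            # (N,) str atom names
    positions: np.ndarray        # (N, 3) nm
    velocities: np.ndarray       # (N, 3) nm/ps
    masses: np.ndarray           # (N,) u
    charges: np.ndarray          # (N,) e
    lj_type: np.ndarray          # (N,) int index into lj_table
    molecule_id: np.ndarray      # (N,) int
    charge_group_id: np.ndarray  # (N,) int
    subsystem: np.ndarray        # (N,) int, SOLUTE or SOLVENT
    constraint_pairs: np.ndarray     # (M, 2) int
    constraint_lengths: np.ndarray   # (M,) nm
    box: np.ndarray              # (3,) nm orthorhombic edges; zeros = unset
    lj_table: LJTable
    exclusion_pairs: np.ndarray = field(default=None)  # (K, 2) int

    def __post_init__(self) -> None:
        self.names = np.asarray(self.names, dtype=object)
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        self.velocities = np.asarray(self.velocities, dtype=float).reshape(-1, 3)
        self.masses = np.asarray(self.masses, dtype=float)
        self.charges = np.asarray(self.charges, dtype=float)
        self.lj_type = np.asarray(self.lj_type, dtype=np.int64)
        self.molecule_id = np.asarray(self.molecule_id, dtype=np.int64)
        self.charge_group_id = np.asarray(self.charge_group_id, dtype=np.int64)
        self.subsystem = np.asarray(self.subsystem, dtype=np.int64)
        self.constraint_pairs = np.asarray(
            self.constraint_pairs, dtype=np.int64
        ).reshape(-1, 2)
        self.constraint_lengths = np.asarray(self.constraint_lengths, dtype=float)
        self.box = np.asarray(self.box, dtype=float).reshape(3)
        if self.exclusion_pairs is None:
            # Constrained pairs are always excluded from nonbonded interactions.
            self.exclusion_pairs = self.constraint_pairs.copy()
        self.exclusion_pairs = np.asarray(
            self.exclusion_pairs, dtype=np.int64
        ).reshape(-1, 2)

    # ------------------------------------------------------------------ sizes
    @property
    def n_atoms(self) -> int:
        return self.positions.shape[0]

    @property
    def n_molecules(self) -> int:
        return len(np.unique(self.molecule_id)) if self.n_atoms else 0

    @property
    def n_charge_groups(self) -> int:
        return len(np.unique(self.charge_group_id)) if self.n_atoms else 0

    @property
    def n_constraints(self) -> int:
        return self.constraint_pairs.shape[0]

    @property
    def volume(self) -> float:
        return float(np.prod(self.box))

    def net_charge(self) -> float:
        return float(self.charges.sum())

    def mask(self, subsystem: int) -> np.ndarray:
        return self.subsystem == subsystem

    def exclusion_keys(self) -> np.ndarray:
        """Sorted encoded keys of excluded atom pairs (for fast membership)."""
        if self.exclusion_pairs.shape[0] == 0:
            return np.empty(0, dtype=np.int64)
        keys = _pair_key(
            self.exclusion_pairs[:, 0], self.exclusion_pairs[:, 1], self.n_atoms
        )
        return np.unique(keys)

    # -------------------------------------------------------------- invariants
    def validate(self, longest_cutoff: float | None = None) -> None:
        """Check structural invariants; raise ``ValueError`` on violation."""
        n = self.n_atoms
        for arr, nm in [
            (self.masses, "masses"), (self.charges, "charges"),
            (self.lj_type, "lj_type"), (self.molecule_id, "molecule_id"),
            (self.charge_group_id, "charge_group_id"), (self.subsystem, "subsystem"),
        ]:
            if arr.shape[0] != n:
                raise ValueError(f"{nm} has wrong length")
        if not np.isin(self.subsystem, [SOLUTE, SOLVENT]).all():
            raise ValueError("subsystem labels must be SOLUTE (0) or SOLVENT (1)")
        # a charge group never spans molecules, nor subsystems
        for gid in np.unique(self.charge_group_id):
            sel = self.charge_group_id == gid
            if len(np.unique(self.molecule_id[sel])) != 1:
                raise ValueError(f"charge group {gid} spans molecules")
            if len(np.unique(self.subsystem[sel])) != 1:
                raise ValueError(f"charge group {gid} spans subsystems")
        if (self.constraint_lengths <= 0).any():
            raise ValueError("constraint target lengths must be positive")
        if self.n_constraints:
            ckeys = _pair_key(
                self.constraint_pairs[:, 0], self.constraint_pairs[:, 1], n
            )
            if not np.isin(ckeys, self.exclusion_keys()).all():
                raise ValueError("constrained pairs must also be excluded pairs")
        if longest_cutoff is not None and (self.box < 2.0 * longest_cutoff).any():
            raise ValueError(
                f"box {self.box} smaller than twice the cutoff {longest_cutoff}: "
                "minimum image would double-count interactions"
            )

    # ------------------------------------------------------------------ energy
    def kinetic_energy(self, subsystem: int | None = None) -> float:
        """Kinetic energy in kJ/mol, optionally restricted to one subsystem."""
        v2 = (self.velocities**2).sum(axis=1)
        if subsystem is None:
            return float(0.5 * (self.masses * v2).sum())
        m = self.mask(subsystem)
        return float(0.5 * (self.masses[m] * v2[m]).sum())

    def dof(self, subsystem: int | None = None) -> int:
        """Degrees of freedom: 3 N_atoms - N_constraints (per subsystem)."""
        if subsystem is None:
            return 3 * self.n_atoms - self.n_constraints
        m = self.mask(subsystem)
        ncons = int(np.sum(m[self.constraint_pairs[:, 0]])) if self.n_constraints else 0
        return 3 * int(m.sum()) - ncons

    def copy(self) -> "System":
        return replace(
            self,
            names=self.names.copy(),
            positions=self.positions.copy(),
            velocities=self.velocities.copy(),
            masses=self.masses.copy(),
            charges=self.charges.copy(),
            lj_type=self.lj_type.copy(),
            molecule_id=self.molecule_id.copy(),
            charge_group_id=self.charge_group_id.copy(),
            subsystem=self.subsystem.copy(),
            constraint_pairs=self.constraint_pairs.copy(),
            constraint_lengths=self.constraint_lengths.copy(),
            box=self.box.copy(),
            exclusion_pairs=self.exclusion_pairs.copy(),
        )

    def with_singleton_charge_groups(self) -> "System":
        """Copy in which every atom is its own charge group (used by the
        scheme-degeneracy checks: a group cutoff over singletons must behave
        exactly like an atomistic cutoff)."""
        out = self.copy()
        out.charge_group_id = np.arange(self.n_atoms, dtype=np.int64)
        return out
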