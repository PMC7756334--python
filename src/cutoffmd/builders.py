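"""Seeded builders for every input the pipeline needs.

* :func:`build_water_box` — periodic boxes of rigid 3-site (SPC) water on a
  jittered cubic lattice with random orientations.
* :func:`build_toy_solute` — a chain of neutral dipolar "residues" standing in
  for a charge-grouped solute, so solute/solvent cutoff distinctions can be
  exercised without a protein force field.
* :func:`solvate` — merge a solute into a water box, deleting overlapping
  waters whole.
* :func:`assign_maxwell_velocities` — Maxwell-Boltzmann velocities followed by
  constraint projection.

All builders are bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

from . import constants as c
from .system import SOLUTE, SOLVENT, LJTable, System

#: Uniform lattice jitter applied per coordinate, nm.
LATTICE_JITTER = 0.01
#: Smallest intermolecular O-O distance accepted in a built water box, nm.
MIN_OO_SEPARATION = 0.24

# Global LJ type convention shared by all builders so systems can be merged:
# type 0 = water oxygen, type 1 = hydrogen (no LJ), type 2 = solute bead
# (given the water-oxygen well so beads cannot overlap).
LJ_TYPES = LJTable.from_per_type(
    [c.SPC_C6_OO, 0.0, c.SPC_C6_OO], [c.SPC_C12_OO, 0.0, c.SPC_C12_OO]
)

TOY_BEAD_CHARGE = 0.4      # e, mimics peptide-dipole magnitudes
TOY_BEAD_BOND = 0.1        # nm, intra-residue +/- separation
TOY_BACKBONE_BOND = 0.38   # nm, virtual bond between consecutive residues
TOY_BEAD_MASS = 14.0       # u


def _random_rotations(rng: np.random.Generator, n: int) -> np.ndarray:
    """n uniformly random rotation matrices from normalized quaternions."""
    q = rng.normal(size=(n, 4))
    q /= np.linalg.norm(q, axis=1, keepdims=True)
    w, x, y, z = q.T
    return np.stack(
        [
            np.stack([1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)], axis=-1),
            np.stack([2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)], axis=-1),
            np.stack([2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)], axis=-1),
        ],
        axis=1,
    )


def _spc_template() -> np.ndarray:
    """Atom offsets (O, H1, H2) of one rigid SPC water, oxygen at the origin."""
    half = np.radians(109.47 / 2.0)
    s, co = np.sin(half), np.cos(half)
    return np.array(
        [
            [0.0, 0.0, 0.0],
            [c.SPC_D_OH * s, 0.0, c.SPC_D_OH * co],
            [-c.SPC_D_OH * s, 0.0, c.SPC_D_OH * co],
        ]
    )


def build_water_box(n_molecules: int, box_edge: float, seed: int) -> System:
    """Place ``n_molecules`` rigid waters on a jittered cubic lattice with
    random orientations inside a cubic box of the given edge (nm).

    Raises ``ValueError`` when the box cannot hold the molecules at the
    minimum O-O separation.
    """
    if n_molecules < 1:
        raise ValueError("n_molecules must be >= 1")
    if box_edge <= 0:
        raise ValueError("box_edge must be positive")
    n_cells = int(np.ceil(round(n_molecules ** (1.0 / 3.0), 9)))
    while n_cells**3 < n_molecules:
        n_cells += 1
    spacing = box_edge / n_cells
    worst_jitter = 2.0 * np.sqrt(3.0) * LATTICE_JITTER
    if spacing - worst_jitter < MIN_OO_SEPARATION:
        raise ValueError(
            f"box edge {box_edge} nm is too small for {n_molecules} waters: "
            f"lattice spacing {spacing:.3f} nm cannot guarantee the "
            f"{MIN_OO_SEPARATION} nm minimum O-O separation"
        )

    rng = np.random.default_rng(seed)
    grid = (np.arange(n_cells) + 0.5) * spacing
    sites = np.stack(np.meshgrid(grid, grid, grid, indexing="ij"), axis=-1).reshape(-1, 3)
    if len(sites) > n_molecules:
        chosen = np.sort(rng.choice(len(sites), size=n_molecules, replace=False))
        sites = sites[chosen]
    sites = sites + rng.uniform(-LATTICE_JITTER, LATTICE_JITTER, size=sites.shape)

    rot = _random_rotations(rng, n_molecules)
    template = _spc_template()
    pos = sites[:, None, :] + np.einsum("nij,aj->nai", rot, template)
    pos = pos.reshape(-1, 3)

    box = np.full(3, float(box_edge))
    tree = cKDTree(np.mod(sites, box_edge), boxsize=box)
    close = tree.query_pairs(MIN_OO_SEPARATION, output_type="ndarray")
    if len(close):
        raise ValueError(
            f"jittered lattice produced O-O contacts below {MIN_OO_SEPARATION} nm"
        )

    n = n_molecules
    idx = np.arange(n) * 3
    constraint_pairs = np.concatenate(
        [
            np.stack([idx, idx + 1], axis=1),
            np.stack([idx, idx + 2], axis=1),
            np.stack([idx + 1, idx + 2], axis=1),
        ]
    )
    constraint_lengths = np.concatenate(
        [np.full(n, c.SPC_D_OH), np.full(n, c.SPC_D_OH), np.full(n, c.SPC_D_HH)]
    )
    sys_ = System(
        names=np.array(["OW", "HW1", "HW2"] * n, dtype=object),
        positions=pos,
        velocities=np.zeros_like(pos),
        masses=np.tile([c.SPC_M_O, c.SPC_M_H, c.SPC_M_H], n),
        charges=np.tile([c.SPC_Q_O, c.SPC_Q_H, c.SPC_Q_H], n),
        lj_type=np.tile([0, 1, 1], n),
        molecule_id=np.repeat(np.arange(n), 3),
        charge_group_id=np.repeat(np.arange(n), 3),
        subsystem=np.full(3 * n, SOLVENT),
        constraint_pairs=constraint_pairs,
        constraint_lengths=constraint_lengths,
        box=box,
        lj_table=LJ_TYPES,
    )
    return sys_


def build_toy_solute(n_beads: int, seed: int) -> System:
    """A chain of dipolar residues: each residue is two atoms (+0.4 e / -0.4 e,
    0.1 nm apart) forming one neutral charge group; consecutive residues are
    linked by a constrained 0.38 nm virtual bond between their first atoms.

    The box is left unset (zeros); :func:`solvate` adopts the water box.
    """
    if n_beads < 1:
        raise ValueError("n_beads must be >= 1")
    rng = np.random.default_rng(seed)
    n = n_beads
    first = np.zeros((n, 3))
    first[:, 0] = np.arange(n) * TOY_BACKBONE_BOND
    # random dipole orientations, reproducible via the seed
    u = rng.normal(size=(n, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    second = first + TOY_BEAD_BOND * u
    pos = np.stack([first, second], axis=1).reshape(-1, 3)

    a1 = np.arange(n) * 2
    intra = np.stack([a1, a1 + 1], axis=1)
    inter = np.stack([a1[:-1], a1[1:]], axis=1)
    constraint_pairs = np.concatenate([intra, inter]) if n > 1 else intra
    constraint_lengths = np.concatenate(
        [np.full(n, TOY_BEAD_BOND), np.full(max(n - 1, 0), TOY_BACKBONE_BOND)]
    )
    return System(
        names=np.array(["CP", "CM"] * n, dtype=object),
        positions=pos,
        velocities=np.zeros_like(pos),
        masses=np.full(2 * n, TOY_BEAD_MASS),
        charges=np.tile([TOY_BEAD_CHARGE, -TOY_BEAD_CHARGE], n),
        lj_type=np.full(2 * n, 2, dtype=np.int64),
        molecule_id=np.zeros(2 * n, dtype=np.int64),
        charge_group_id=np.repeat(np.arange(n), 2),
        subsystem=np.full(2 * n, SOLUTE),
        constraint_pairs=constraint_pairs,
        constraint_lengths=constraint_lengths,
        box=np.zeros(3),
        lj_table=LJ_TYPES,
    )


def solvate(solute: System, water: System, overlap_cutoff: float) -> System:
    """Merge ``solute`` into ``water``; any water molecule with an atom within
    ``overlap_cutoff`` (nm, minimum image) of a solute atom is removed whole.

    A solute with an unset box (zeros) is centered in the water box first.
    """
    box = water.box
    solute = solute.copy()
    if np.allclose(solute.box, 0.0):
        span = 0.5 * (solute.positions.min(axis=0) + solute.positions.max(axis=0))
        solute.positions += 0.5 * box - span
        solute.box = box.copy()
    elif not np.allclose(solute.box, box):
        raise ValueError(f"incompatible boxes: solute {solute.box}, water {box}")

    if solute.n_atoms == 0:
        return water.copy()

    tree = cKDTree(np.mod(water.positions, box), boxsize=box)
    hits = tree.query_ball_point(np.mod(solute.positions, box), overlap_cutoff)
    removed_atoms = sorted({a for sub in hits for a in sub})
    removed_mols = np.unique(water.molecule_id[removed_atoms]) if removed_atoms else []
    keep = ~np.isin(water.molecule_id, removed_mols)

    n_solu = solute.n_atoms
    kept_idx = np.flatnonzero(keep)
    remap = -np.ones(water.n_atoms, dtype=np.int64)
    remap[kept_idx] = np.arange(len(kept_idx)) + n_solu
    wc_keep = keep[water.constraint_pairs[:, 0]]
    w_cons = remap[water.constraint_pairs[wc_keep]]
    w_lens = water.constraint_lengths[wc_keep]
    we_keep = keep[water.exclusion_pairs[:, 0]] & keep[water.exclusion_pairs[:, 1]]
    w_excl = remap[water.exclusion_pairs[we_keep]]

    def _renumber(ids):
        _, inv = np.unique(ids, return_inverse=True)
        return inv

    if solute.lj_table != water.lj_table:
        raise ValueError("solute and water use different LJ type tables")

    return System(
        names=np.concatenate([solute.names, water.names[keep]]),
        positions=np.concatenate([solute.positions, water.positions[keep]]),
        velocities=np.concatenate([solute.velocities, water.velocities[keep]]),
        masses=np.concatenate([solute.masses, water.masses[keep]]),
        charges=np.concatenate([solute.charges, water.charges[keep]]),
        lj_type=np.concatenate([solute.lj_type, water.lj_type[keep]]),
        molecule_id=np.concatenate(
            [
                _renumber(solute.molecule_id),
                _renumber(water.molecule_id[keep]) + solute.n_molecules,
            ]
        ),
        charge_group_id=np.concatenate(
            [
                _renumber(solute.charge_group_id),
                _renumber(water.charge_group_id[keep]) + solute.n_charge_groups,
            ]
        ),
        subsystem=np.concatenate([solute.subsystem, water.subsystem[keep]]),
        constraint_pairs=np.concatenate([solute.constraint_pairs, w_cons]),
        constraint_lengths=np.concatenate([solute.constraint_lengths, w_lens]),
        box=box.copy(),
        lj_table=water.lj_table,
        exclusion_pairs=np.concatenate([solute.exclusion_pairs, w_excl]),
    )


def project_constraint_velocities(
    system: System, tol: float = 1e-12, max_sweeps: int = 500
) -> float:
    """Iteratively remove relative velocity components along constrained bonds
    (mass-weighted impulses). Returns the final maximum residual (nm/ps)."""
    if system.n_constraints == 0:
        return 0.0
    from ._kernels import velocity_project

    return float(
        velocity_project(
            system.velocities,
            system.positions,
            system.constraint_pairs[:, 0],
            system.constraint_pairs[:, 1],
            1.0 / system.masses,
            tol,
            max_sweeps,
        )
    )


def assign_maxwell_velocities(system: System, temperature: float, seed: int) -> System:
    """Draw per-component Maxwell-Boltzmann velocities at the given temperature
    (K), then remove velocity components along constrained bonds."""
    if temperature < 0:
        raise ValueError("temperature must be >= 0")
    out = system.copy()
    if temperature == 0:
        out.velocities[:] = 0.0
        return out
    rng = np.random.default_rng(seed)
    sigma = np.sqrt(c.KB * temperature / out.masses)
    out.velocities = rng.normal(size=(out.n_atoms, 3)) * sigma[:, None]
    project_constraint_velocities(out)
    return out
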