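"""Interaction entities and single-/twin-range pairlists.

A cutoff scheme decides *what* the cutoff distance is measured between:

* ``atomistic`` — every atom is its own interaction entity;
* ``group`` — every charge group is one entity, located either at its center
  of geometry or at a designated atom (e.g. the water oxygen).

Solute and solvent may use different rules (the solute-atomistic scheme
combines an atomistic solute with charge-group solvent). Pairs of entities
whose minimum-image center distance is below ``r_short`` form the short-range
list (evaluated every step); pairs in ``[r_short, r_long)`` form the
intermediate list whose forces/energies are computed only at pairlist updates
and held constant in between (twin range). Distances strictly below the
cutoff are included; shells are half-open — tie handling at exactly the
cutoff is a convention of this package, not of the scheme definitions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.spatial import cKDTree

from ._kernels import classify_pairs_brute, expand_entity_pairs
from .system import SOLUTE, SOLVENT, System

ATOMISTIC = "atomistic"
GROUP = "group"
COG = "cog"
DESIGNATED_ATOM = "designated_atom"

#: Below this many entities the brute-force O(N^2) classifier is used.
CELL_LIST_THRESHOLD = 200


@dataclass(frozen=True)
class CutoffScheme:
    """Per-subsystem entity rules plus cutoff radii and pairlist cadence."""

    solute_entity_rule: str = GROUP
    solvent_entity_rule: str = GROUP
    group_center_rule: str = COG
    designated_atom_name: Optional[str] = None
    r_short: float = 0.8
    r_long: float = 1.4          # doubles as the reaction-field radius R_rf
    update_interval: int = 5     # steps; 5 x 2 fs = 10 fs

    def __post_init__(self) -> None:
        if not (0.0 < self.r_short <= self.r_long):
            raise ValueError("need 0 < r_short <= r_long")
        if self.update_interval < 1:
            raise ValueError("update interval must be >= 1")
        for rule in (self.solute_entity_rule, self.solvent_entity_rule):
            if rule not in (ATOMISTIC, GROUP):
                raise ValueError(f"unknown entity rule {rule!r}")
        if self.group_center_rule not in (COG, DESIGNATED_ATOM):
            raise ValueError(f"unknown center rule {self.group_center_rule!r}")
        if self.group_center_rule == DESIGNATED_ATOM and not self.designated_atom_name:
            raise ValueError("designated_atom rule needs designated_atom_name")

    @property
    def single_range(self) -> bool:
        return self.update_interval == 1 and self.r_short == self.r_long

    def describe(self) -> str:
        ent = {ATOMISTIC: "AT", GROUP: "CG"}
        tag = (
            "AT"
            if self.solute_entity_rule == self.solvent_entity_rule == ATOMISTIC
            else "CG"
            if self.solute_entity_rule == self.solvent_entity_rule == GROUP
            else f"S{ent[self.solute_entity_rule][0]}"  # SA mixed scheme
        )
        rng = "SR" if self.update_interval == 1 else "TR"
        center = (
            f"({self.designated_atom_name})"
            if self.group_center_rule == DESIGNATED_ATOM
            else "(cog)"
            if GROUP in (self.solute_entity_rule, self.solvent_entity_rule)
            else ""
        )
        return f"{tag}{center}/{rng} r_short={self.r_short} r_long={self.r_long}"


# Paper-settings presets --------------------------------------------------
def scheme_cg_tr(**kw) -> CutoffScheme:
    return CutoffScheme(GROUP, GROUP, COG, None, **kw)


def scheme_cg_sr(**kw) -> CutoffScheme:
    kw.setdefault("update_interval", 1)
    return CutoffScheme(GROUP, GROUP, COG, None, **kw)


def scheme_at_tr(**kw) -> CutoffScheme:
    return CutoffScheme(ATOMISTIC, ATOMISTIC, COG, None, **kw)


def scheme_sa_tr(designated_atom_name: Optional[str] = "OW", **kw) -> CutoffScheme:
    """Solute-atomistic: every solute atom its own group, solvent by groups."""
    rule = DESIGNATED_ATOM if designated_atom_name else COG
    return CutoffScheme(ATOMISTIC, GROUP, rule, designated_atom_name, **kw)


def scheme_cg_ow(**kw) -> CutoffScheme:
    """Water charge groups centered on the oxygen atom, CG(OW)."""
    return CutoffScheme(GROUP, GROUP, DESIGNATED_ATOM, "OW", **kw)


@dataclass
class Entity:
    """One interaction entity: a set of atoms with a center rule."""

    atoms: np.ndarray
    subsystem: int
    center_atom: int  # index into atoms' frame, -1 for center of geometry

    def center(self, positions: np.ndarray) -> np.ndarray:
        if self.center_atom >= 0:
            return positions[self.center_atom]
        return positions[self.atoms].mean(axis=0)


def entity_center(entity: Entity, positions: np.ndarray) -> np.ndarray:
    """Center of one entity: designated atom position, or the unweighted mean
    of member positions (center of geometry). Single-atom entities return the
    atom's own coordinates either way."""
    return entity.center(positions)


class EntityList:
    """All entities of a system under a scheme, in flat-array form.

    Also carries the per-atom data (charges, LJ coefficients, decomposition
    buckets, exclusions) needed to expand entity pairs into evaluable atom
    pairs without touching the System again.
    """

    def __init__(self, system: System, scheme: CutoffScheme):
        self.scheme = scheme
        self.n_atoms = system.n_atoms
        atoms_parts = []
        ptr = [0]
        subsys = []
        center_atom = []

        order = np.arange(system.n_atoms)
        for label, rule in (
            (SOLUTE, scheme.solute_entity_rule),
            (SOLVENT, scheme.solvent_entity_rule),
        ):
            sel = order[system.subsystem == label]
            if len(sel) == 0:
                continue
            if rule == ATOMISTIC:
                for a in sel:
                    atoms_parts.append([a])
                    ptr.append(ptr[-1] + 1)
                    subsys.append(label)
                    center_atom.append(a)
            else:
                gids = system.charge_group_id[sel]
                for g in np.unique(gids):
                    members = sel[gids == g]
                    atoms_parts.append(members)
                    ptr.append(ptr[-1] + len(members))
                    subsys.append(label)
                    if len(members) == 1:
                        center_atom.append(members[0])
                    elif scheme.group_center_rule == DESIGNATED_ATOM:
                        match = [
                            a for a in members
                            if system.names[a] == scheme.designated_atom_name
                        ]
                        if not match:
                            raise ValueError(
                                f"charge group {g} has no atom named "
                                f"{scheme.designated_atom_name!r} to act as center"
                            )
                        center_atom.append(match[0])
                    else:
                        center_atom.append(-1)

        self.ent_ptr = np.asarray(ptr, dtype=np.int64)
        self.ent_atoms = np.concatenate(atoms_parts).astype(np.int64)
        self.subsystem = np.asarray(subsys, dtype=np.int64)
        self.center_atom = np.asarray(center_atom, dtype=np.int64)
        self._cog_only = bool((self.center_atom < 0).all())
        self._atom_only = bool((self.ent_ptr[1:] - self.ent_ptr[:-1] == 1).all())

        self.charges = system.charges
        self.lj_type = system.lj_type
        self.lj_c6 = system.lj_table.c6
        self.lj_c12 = system.lj_table.c12
        self.atom_subsystem = system.subsystem
        self.excl_keys = system.exclusion_keys()

    def __len__(self) -> int:
        return len(self.subsystem)

    def __getitem__(self, k: int) -> Entity:
        return Entity(
            atoms=self.ent_atoms[self.ent_ptr[k]: self.ent_ptr[k + 1]],
            subsystem=int(self.subsystem[k]),
            center_atom=int(self.center_atom[k]),
        )

    def centers(self, positions: np.ndarray) -> np.ndarray:
        """(E, 3) array of entity centers for the given positions."""
        if self._atom_only or (self.center_atom >= 0).all():
            return positions[self.center_atom]
        sums = np.add.reduceat(positions[self.ent_atoms], self.ent_ptr[:-1], axis=0)
        sizes = (self.ent_ptr[1:] - self.ent_ptr[:-1]).astype(float)
        cog = sums / sizes[:, None]
        out = np.where((self.center_atom >= 0)[:, None],
                       positions[np.maximum(self.center_atom, 0)], cog)
        return out


def make_entities(system: System, scheme: CutoffScheme) -> EntityList:
    """Build the interaction entities of ``system`` under ``scheme``."""
    return EntityList(system, scheme)


@dataclass
class PairStructure:
    """Short-range and intermediate-range entity pair sets plus the cached
    intermediate-range results held constant between pairlist updates."""

    short_pairs: np.ndarray          # (S, 2) entity indices
    intermediate_pairs: np.ndarray   # (I, 2) entity indices
    last_update_step: int = -1
    # expanded atom-pair evaluation arrays (implementation detail)
    short_eval: dict = field(default_factory=dict)
    inter_eval: dict = field(default_factory=dict)
    # frozen intermediate-range results (set by the nonbonded module)
    cache: Optional[dict] = None


def _min_image(delta: np.ndarray, box: np.ndarray) -> np.ndarray:
    return delta - box * np.rint(delta / box)


def _classify_pairs(centers, box, r_short, r_long, use_tree):
    """Return (short, intermediate) entity pair arrays in lexicographic
    order; the same strict-< squared-distance comparisons run on either
    path, so the accelerated and brute-force classifiers agree exactly."""
    if not use_tree:
        return classify_pairs_brute(
            np.ascontiguousarray(centers, dtype=float), box, r_short, r_long
        )
    tree = cKDTree(np.mod(centers, box), boxsize=box)
    cand = tree.query_pairs(r_long * (1.0 + 1e-9), output_type="ndarray")
    if len(cand) == 0:
        empty = np.empty((0, 2), dtype=np.int64)
        return empty, empty.copy()
    d2 = (
        _min_image(centers[cand[:, 0]] - centers[cand[:, 1]], box) ** 2
    ).sum(axis=1)
    short = cand[d2 < r_short**2]
    inter = cand[(d2 >= r_short**2) & (d2 < r_long**2)]

    def _sort(p):
        if len(p) == 0:
            return p.astype(np.int64).reshape(0, 2)
        order = np.argsort(p[:, 0] * np.int64(len(centers)) + p[:, 1], kind="stable")
        return p[order].astype(np.int64)

    return _sort(short), _sort(inter)


def build_pairlist(
    entities: EntityList,
    positions: np.ndarray,
    box: np.ndarray,
    scheme: CutoffScheme,
    method: str = "auto",
) -> PairStructure:
    """Classify entity pairs into short and intermediate lists by their
    minimum-image center distance, and pre-expand them into atom-pair
    evaluation arrays (exclusions dropped).

    ``method``: "auto" picks a periodic KD-tree above
    :data:`CELL_LIST_THRESHOLD` entities when the cutoff is small against the
    box (below that, or in dense small boxes, the compiled O(N^2) classifier
    is faster); "brute" and "tree" force one path. Both paths apply identical
    distance comparisons and produce identical lists.
    """
    box = np.asarray(box, dtype=float)
    if (box < 2.0 * scheme.r_long).any():
        raise ValueError(
            f"box {box} smaller than twice r_long={scheme.r_long}: minimum image "
            "would double-count interactions"
        )
    centers = entities.centers(positions)
    if method == "auto":
        use_tree = (
            len(entities) >= CELL_LIST_THRESHOLD
            and 4.0 * scheme.r_long <= float(np.min(box))
        )
    elif method in ("brute", "tree"):
        use_tree = method == "tree"
    else:
        raise ValueError("method must be auto, brute or tree")
    short, inter = _classify_pairs(centers, box, scheme.r_short, scheme.r_long, use_tree)

    ps = PairStructure(short_pairs=short, intermediate_pairs=inter)
    ps.short_eval = _expand(entities, short)
    ps.inter_eval = _expand(entities, inter)
    return ps


def _expand(entities: EntityList, pairs: np.ndarray) -> dict:
    """Expand entity pairs to atom-pair arrays with per-pair interaction
    coefficients, ready for the evaluation kernel."""
    from .constants import F_ELEC

    if len(pairs) == 0:
        z = np.empty(0)
        return dict(
            ai=np.empty(0, dtype=np.int64), aj=np.empty(0, dtype=np.int64),
            qq=z, c6=z.copy(), c12=z.copy(), bucket=np.empty(0, dtype=np.int64),
        )
    ai, aj = expand_entity_pairs(
        np.ascontiguousarray(pairs[:, 0]),
        np.ascontiguousarray(pairs[:, 1]),
        entities.ent_ptr,
        entities.ent_atoms,
        entities.excl_keys,
        entities.n_atoms,
    )
    qq = F_ELEC * entities.charges[ai] * entities.charges[aj]
    c6 = entities.lj_c6[entities.lj_type[ai], entities.lj_type[aj]]
    c12 = entities.lj_c12[entities.lj_type[ai], entities.lj_type[aj]]
    bucket = entities.atom_subsystem[ai] + entities.atom_subsystem[aj]
    return dict(ai=ai, aj=aj, qq=qq, c6=c6, c12=c12, bucket=bucket)


def pairlist_due_for_update(step: int, scheme: CutoffScheme) -> bool:
    """True on steps where the pairlist (and the intermediate-range cache) is
    rebuilt; an interval of 1 makes every step an update (single range)."""
    if step < 0:
        raise ValueError("step must be >= 0")
    return step % scheme.update_interval == 0
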