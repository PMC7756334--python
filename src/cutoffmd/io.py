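"""File formats: GRO-dialect coordinates, topology sidecars, full-precision
columnar trajectories, TSV observable/energy logs and the run configuration.

The GRO dialect is the fixed-width, nm-native coordinate format (optional
velocities, box line). Coordinates written there are rounded to the format's
0.001 nm precision; the JSON topology sidecar additionally stores positions
and velocities at full double precision, so a write/read cycle of the
sidecar is exact. All numeric reports are tab-separated files with
'#'-prefixed metadata headers.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .dynamics import Protocol, TrajectoryFrame
from .pairlist import CutoffScheme
from .system import LJTable, System

GRO_PRECISION = 1e-3  # nm


# --------------------------------------------------------------------- GRO
def _write_gro_block(fh, system: System, title: str) -> None:
    resnames = {0: "TOY", 1: "SOL"}
    fh.write(f"{title}\n{system.n_atoms:5d}\n")
    for i in range(system.n_atoms):
        resid = int(system.molecule_id[i]) + 1
        resname = resnames.get(int(system.subsystem[i]), "MOL")
        x, y, z = system.positions[i]
        vx, vy, vz = system.velocities[i]
        fh.write(
            f"{resid % 100000:5d}{resname:<5s}{str(system.names[i]):>5s}"
            f"{(i + 1) % 100000:5d}"
            f"{x:8.3f}{y:8.3f}{z:8.3f}{vx:8.4f}{vy:8.4f}{vz:8.4f}\n"
        )
    fh.write(f"{system.box[0]:10.5f}{system.box[1]:10.5f}{system.box[2]:10.5f}\n")


def write_gro(path, system: System, title: str = "cutoffmd system") -> None:
    """Write a fixed-width GRO-dialect coordinate file (positions in nm,
    velocities in nm/ps, final box line)."""
    with open(path, "w") as fh:
        _write_gro_block(fh, system, title)


def read_gro(path) -> dict:
    """Parse a GRO-dialect file; returns a dict with names, residue ids and
    names, positions, velocities and box. Raises ``ValueError`` naming the
    offending line on malformed fixed-width content."""
    with open(path) as fh:
        lines = fh.read().splitlines()
    if len(lines) < 2:
        raise ValueError(f"{path}: truncated file (line {len(lines) + 1}: "
                         "missing header or atom count)")
    try:
        n_atoms = int(lines[1].strip())
    except ValueError as exc:
        raise ValueError(f"{path}: line 2: bad atom count {lines[1]!r}") from exc
    if len(lines) < n_atoms + 3:
        raise ValueError(
            f"{path}: truncated file (line {len(lines) + 1}: expected "
            f"{n_atoms} atom lines plus a box line)"
        )
    names, resids, resnames = [], [], []
    pos = np.zeros((n_atoms, 3))
    vel = np.zeros((n_atoms, 3))
    for k in range(n_atoms):
        line = lines[2 + k]
        lineno = 3 + k
        if len(line) < 44:
            raise ValueError(f"{path}: line {lineno}: fixed-width line too short")
        try:
            resids.append(int(line[0:5]))
            resnames.append(line[5:10].strip())
            names.append(line[10:15].strip())
            pos[k] = [float(line[20:28]), float(line[28:36]), float(line[36:44])]
            if len(line) >= 68:
                vel[k] = [float(line[44:52]), float(line[52:60]), float(line[60:68])]
        except ValueError as exc:
            raise ValueError(f"{path}: line {lineno}: malformed field ({exc})") from exc
    try:
        box = np.array([float(tok) for tok in lines[2 + n_atoms].split()[:3]])
    except (ValueError, IndexError) as exc:
        raise ValueError(f"{path}: line {3 + n_atoms}: malformed box line") from exc
    return dict(
        names=np.array(names, dtype=object),
        residue_ids=np.array(resids),
        residue_names=np.array(resnames, dtype=object),
        positions=pos,
        velocities=vel,
        box=box,
    )


# ---------------------------------------------------------------- topology
def write_topology(path, system: System) -> None:
    """JSON topology sidecar: charges, masses, LJ types and tables,
    molecule/group/subsystem ids, constraints, exclusions — plus positions,
    velocities and box at full double precision."""
    data = {
        "names": [str(s) for s in system.names],
        "positions": system.positions.tolist(),
        "velocities": system.velocities.tolist(),
        "masses": system.masses.tolist(),
        "charges": system.charges.tolist(),
        "lj_type": system.lj_type.tolist(),
        "molecule_id": system.molecule_id.tolist(),
        "charge_group_id": system.charge_group_id.tolist(),
        "subsystem": system.subsystem.tolist(),
        "constraint_pairs": system.constraint_pairs.tolist(),
        "constraint_lengths": system.constraint_lengths.tolist(),
        "exclusion_pairs": system.exclusion_pairs.tolist(),
        "box": system.box.tolist(),
        "lj_c6": system.lj_table.c6.tolist(),
        "lj_c12": system.lj_table.c12.tolist(),
    }
    Path(path).write_text(json.dumps(data))


def read_topology(path) -> System:
    data = json.loads(Path(path).read_text())
    return System(
        names=np.array(data["names"], dtype=object),
        positions=np.array(data["positions"]),
        velocities=np.array(data["velocities"]),
        masses=np.array(data["masses"]),
        charges=np.array(data["charges"]),
        lj_type=np.array(data["lj_type"]),
        molecule_id=np.array(data["molecule_id"]),
        charge_group_id=np.array(data["charge_group_id"]),
        subsystem=np.array(data["subsystem"]),
        constraint_pairs=np.array(data["constraint_pairs"]).reshape(-1, 2),
        constraint_lengths=np.array(data["constraint_lengths"]),
        box=np.array(data["box"]),
        lj_table=LJTable(np.array(data["lj_c6"]), np.array(data["lj_c12"])),
        exclusion_pairs=np.array(data["exclusion_pairs"]).reshape(-1, 2),
    )


def write_system(prefix, system: System, title: str = "cutoffmd system") -> None:
    """Write ``<prefix>.gro`` plus the ``<prefix>.top.json`` sidecar."""
    write_gro(f"{prefix}.gro", system, title)
    write_topology(f"{prefix}.top.json", system)


def read_system(prefix) -> System:
    return read_topology(f"{prefix}.top.json")


# -------------------------------------------------------------- trajectory
def write_frames_tsv(path, frames) -> None:
    """Full-precision columnar text trajectory (17 significant digits), one
    block per frame, for bit-sensitive re-analysis."""
    with open(path, "w") as fh:
        fh.write("# cutoffmd full-precision trajectory\n")
        for fr in frames:
            box = "\t".join(f"{v:.17g}" for v in fr.box)
            fh.write(f"# frame\t{fr.time:.17g}\t{fr.positions.shape[0]}\t{box}\n")
            for r, v in zip(fr.positions, fr.velocities):
                fh.write(
                    "\t".join(f"{val:.17g}" for val in (*r, *v)) + "\n"
                )


def read_frames_tsv(path) -> list:
    frames = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    k = 0
    while k < len(lines):
        line = lines[k]
        if line.startswith("# frame"):
            parts = line.split("\t")
            time = float(parts[1])
            n = int(parts[2])
            box = np.array([float(x) for x in parts[3:6]])
            block = np.array(
                [[float(v) for v in row.split("\t")] for row in lines[k + 1: k + 1 + n]]
            )
            frames.append(
                TrajectoryFrame(
                    time=time,
                    positions=block[:, :3],
                    velocities=block[:, 3:6],
                    box=box,
                )
            )
            k += n + 1
        else:
            k += 1
    return frames


def write_multiframe_gro(path, frames, system: System) -> None:
    """Multi-frame GRO-dialect trajectory for interoperability."""
    work = system.copy()
    with open(path, "w") as fh:
        for fr in frames:
            work.positions = fr.positions
            work.velocities = fr.velocities
            work.box = fr.box
            _write_gro_block(fh, work, f"t= {fr.time:.4f} ps")


# --------------------------------------------------------------- TSV logs
def write_tsv(path, df, metadata: dict | None = None) -> None:
    """Tab-separated numeric output with '#'-prefixed metadata header."""
    with open(path, "w") as fh:
        for key, val in (metadata or {}).items():
            fh.write(f"# {key}\t{val}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_tsv(path):
    import pandas as pd

    return pd.read_csv(path, sep="\t", comment="#")


# ------------------------------------------------------------- run config
@dataclass
class RunConfig:
    """Complete, serializable run configuration (scheme + protocol + reaction
    field + outputs). Defaults follow the reference setup: group-based
    twin-range cutoffs 0.8/1.4 nm updated every 10 fs, 2 fs timestep,
    298.15 K, 1 atm, eps_rf 61."""

    scheme: CutoffScheme = field(default_factory=CutoffScheme)
    protocol: Protocol = field(default_factory=Protocol)
    eps_rf: float = 61.0
    output_prefix: str = "run"
    seed: int = 1

    def to_dict(self) -> dict:
        return {
            "scheme": asdict(self.scheme),
            "protocol": asdict(self.protocol),
            "eps_rf": self.eps_rf,
            "output_prefix": self.output_prefix,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data or {})
        scheme_kw = dict(data.pop("scheme", {}) or {})
        proto_kw = dict(data.pop("protocol", {}) or {})
        for kw, ref in ((scheme_kw, CutoffScheme), (proto_kw, Protocol)):
            unknown = set(kw) - {f for f in ref.__dataclass_fields__}
            if unknown:
                raise ValueError(f"unknown {ref.__name__} keys: {sorted(unknown)}")
        top_known = {"eps_rf", "output_prefix", "seed"}
        unknown = set(data) - top_known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        try:
            scheme = CutoffScheme(**scheme_kw)
            protocol = Protocol(**proto_kw)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"invalid configuration: {exc}") from exc
        return cls(scheme=scheme, protocol=protocol, **data)

    def describe(self) -> str:
        rng = "single-range" if self.scheme.update_interval == 1 else "twin-range"
        return f"{self.scheme.describe()} [{rng}] eps_rf={self.eps_rf}"


def parse_config(path) -> RunConfig:
    """Parse a YAML run configuration; an empty file yields the full default
    configuration; unknown keys are rejected with field-specific messages."""
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: configuration must be a mapping")
    return RunConfig.from_dict(data)


def serialize_config(config: RunConfig) -> str:
    return yaml.safe_dump(config.to_dict(), sort_keys=True)


def write_config(path, config: RunConfig) -> None:
    Path(path).write_text(serialize_config(config))
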