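"""One-dimensional two-diatomic probe of cutoff energies and forces.

Two diatomic molecules lie on the x-axis: molecule A carries charges
(q1, q2) at +-b/2 around its center, molecule B carries (q3, q4) at +-b/2
around a center a distance s away. Scanning s produces energy and axial
force profiles under three cutoff schemes:

* ``atomistic`` — each of the four atom pairs interacts iff its *atomic*
  distance is below R_rf; every pair energy vanishes at R_rf, so the energy
  profile is continuous (but the *force* jumps each time a pair drops out).
* ``group`` — all four pairs interact iff the center-center distance is
  below R_rf; the four-term sum does not vanish there, producing a single
  sudden energy jump at s = R_rf.
* ``mixed`` — A's atoms are individual entities, B is one group: the pairs
  of an A atom are included iff that atom's distance to B's *center* is
  below R_rf.

Pair energies always use atomic distances (membership only is scheme
dependent), mirroring the engine's group-cutoff convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import F_ELEC
from .nonbonded import RFParams

SCHEMES = ("atomistic", "group", "mixed")


@dataclass(frozen=True)
class ProbeConfig:
    """Charges, geometry and scan grid of the two-diatomic probe."""

    charges_a: tuple = (1.0, -1.0)   # (q1, q2), e
    charges_b: tuple = (1.0, -1.0)   # (q3, q4), e
    bond_length: float = 0.1         # nm
    scheme: str = "atomistic"
    r_rf: float = 1.4                # nm
    eps_rf: float = 61.0
    grid_start: float = 0.2          # nm, center-center separation
    grid_stop: float = 1.8
    grid_step: float = 1e-3

    def __post_init__(self) -> None:
        if self.scheme not in SCHEMES:
            raise ValueError(f"scheme must be one of {SCHEMES}")
        if self.bond_length <= 0 or self.grid_step <= 0:
            raise ValueError("bond length and grid step must be positive")
        if self.grid_start <= self.bond_length:
            raise ValueError("molecules overlap: separation <= bond length")
        if self.grid_stop > self.r_rf + 0.5:
            raise ValueError("scan grid must stay within (0, R_rf + 0.5]")

    @property
    def params(self) -> RFParams:
        return RFParams(eps_rf=self.eps_rf, r_rf=self.r_rf)

    def grid(self) -> np.ndarray:
        return np.arange(self.grid_start, self.grid_stop, self.grid_step)


@dataclass
class Profile:
    """Scan result: energies (kJ/mol) and axial forces on molecule A
    (kJ mol^-1 nm^-1) over strictly increasing separations (nm)."""

    separations: np.ndarray
    energies: np.ndarray
    forces: np.ndarray
    discontinuities: list = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.separations)
        if len(self.energies) != n or len(self.forces) != n:
            raise ValueError("profile arrays must have equal length")
        if n > 1 and not (np.diff(self.separations) > 0).all():
            raise ValueError("separations must be strictly increasing")


def _pair_terms(config: ProbeConfig, s: np.ndarray):
    """Distances, charge products and membership masks of the four atom pairs
    (q1q3, q1q4, q2q3, q2q4) at center separations ``s``."""
    b = config.bond_length
    q1, q2 = config.charges_a
    q3, q4 = config.charges_b
    dists = np.stack([s, s + b, s - b, s], axis=0)
    qq = np.array([q1 * q3, q1 * q4, q2 * q3, q2 * q4])
    r = config.r_rf
    if config.scheme == "atomistic":
        member = dists < r
    elif config.scheme == "group":
        member = np.broadcast_to(s < r, dists.shape)
    else:  # mixed: per (atom of A, center of B)
        in_a1 = s + b / 2 < r          # q1 sits at -b/2, center of B at s
        in_a2 = s - b / 2 < r
        member = np.stack([in_a1, in_a1, in_a2, in_a2], axis=0)
    return dists, qq, member


def scan_profile(config: ProbeConfig) -> Profile:
    """Energy and axial-force profiles of the probe over its scan grid."""
    s = config.grid()
    p = config.params
    dists, qq, member = _pair_terms(config, s)
    v0 = (1.0 / dists - 1.0 / p.r_rf) - 0.5 * p.k1 * (dists**2 - p.r_rf**2)
    energy = F_ELEC * (qq[:, None] * v0 * member).sum(axis=0)
    # axial force on molecule A, taken positive along the direction away
    # from B (so like charges give a positive, repulsive force and the
    # profile obeys F = -dE/ds between membership changes)
    fmag = 1.0 / dists**2 + p.k1 * dists
    force = F_ELEC * (qq[:, None] * fmag * member).sum(axis=0)
    prof = Profile(separations=s, energies=energy, forces=force)
    prof.discontinuities = find_discontinuities(prof)
    return prof


def coulomb_reference_profile(config: ProbeConfig) -> Profile:
    """Bare-Coulomb, no-cutoff profile of the same geometry (a multipole
    reference: dipole-dipole decays as r^-3, charge-charge as r^-1)."""
    s = config.grid()
    dists, qq, _ = _pair_terms(config, s)
    energy = F_ELEC * (qq[:, None] / dists).sum(axis=0)
    force = F_ELEC * (qq[:, None] / dists**2).sum(axis=0)
    return Profile(separations=s, energies=energy, forces=force)


def find_discontinuities(profile: Profile, window: int = 20, on: str = "energies"):
    """Flag grid intervals whose value change exceeds 10x the median absolute
    neighboring change within ``window`` intervals on either side.

    Returns a list of ``(midpoint, signed_jump)`` tuples.
    """
    values = getattr(profile, on)
    x = profile.separations
    d = np.diff(values)
    n = len(d)
    out = []
    for k in range(n):
        lo = max(0, k - window)
        hi = min(n, k + window + 1)
        neigh = np.abs(np.delete(d[lo:hi], k - lo))
        if len(neigh) == 0:
            continue
        med = float(np.median(neigh))
        if abs(d[k]) > 10.0 * med and abs(d[k]) > 0.0:
            out.append((float(0.5 * (x[k] + x[k + 1])), float(d[k])))
    return out


def standard_configs(
    q: float = 1.0, scheme: str = "atomistic", **kw
) -> dict[str, ProbeConfig]:
    """The three canonical charge distributions: dipole-dipole, dipole-charge
    and charge-charge, with charge magnitude ``q`` (e)."""
    return {
        "dipole-dipole": ProbeConfig((q, -q), (q, -q), scheme=scheme, **kw),
        "dipole-charge": ProbeConfig((q, -q), (q, 0.0), scheme=scheme, **kw),
        "charge-charge": ProbeConfig((q, 0.0), (q, 0.0), scheme=scheme, **kw),
    }
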