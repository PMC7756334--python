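"""Trajectory observables.

Solvent-structure diagnostics (radial distribution function and the
dipole-dipole orientation correlation function), per-bath temperature series
from the energy log, and the standard structural quantities: mass-weighted
radius of gyration, RMSD normalized to a notional 100-residue protein,
geometric backbone hydrogen-bond counting, and NOE-style <r^-3>^-1/3
distance averaging.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class BinnedCurve:
    """Uniformly binned radial curve; ``values`` are flagged NaN in bins with
    no samples."""

    bin_centers: np.ndarray
    values: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        w = np.diff(self.bin_centers)
        if len(w) and not np.allclose(w, w[0]):
            raise ValueError("bins must be uniform")
        if (self.counts < 0).any():
            raise ValueError("bin counts must be non-negative")


def _min_image(delta: np.ndarray, box: np.ndarray) -> np.ndarray:
    return delta - box * np.rint(delta / box)


def _frame_arrays(trajectory):
    for fr in trajectory:
        yield fr.positions, fr.box


def _check_rmax(r_max: float, box: np.ndarray) -> None:
    if r_max > 0.5 * float(np.min(box)) * (1 + 1e-12):
        raise ValueError(
            f"r_max={r_max} exceeds half the smallest box edge {np.min(box) / 2}"
        )


def rdf(
    trajectory,
    selection_a: np.ndarray,
    selection_b: np.ndarray,
    bin_width: float,
    r_max: float,
) -> BinnedCurve:
    """Radial distribution function g(r) between two atom selections.

    Histograms minimum-image ordered-pair distances per frame and normalizes
    by the ideal-gas shell count N_a N_b (4 pi r^2 dr) / V; self pairs are
    excluded where the selections overlap.
    """
    selection_a = np.asarray(selection_a)
    selection_b = np.asarray(selection_b)
    edges = np.arange(0.0, r_max + bin_width * 0.5, bin_width)
    hist = np.zeros(len(edges) - 1)
    n_frames = 0
    norm = 0.0
    for pos, box in _frame_arrays(trajectory):
        _check_rmax(r_max, box)
        delta = _min_image(pos[selection_a][:, None, :] - pos[selection_b][None, :, :], box)
        d = np.linalg.norm(delta, axis=-1)
        same = selection_a[:, None] == selection_b[None, :]
        d = d[~same]
        hist += np.histogram(d, bins=edges)[0]
        n_frames += 1
        volume = float(np.prod(box))
        n_pairs = selection_a.size * selection_b.size - int(same.sum())
        norm += n_pairs / volume
    centers = 0.5 * (edges[:-1] + edges[1:])
    shell = 4.0 * np.pi * centers**2 * bin_width
    with np.errstate(invalid="ignore", divide="ignore"):
        g = hist / (shell * norm)
    return BinnedCurve(bin_centers=centers, values=g, counts=hist)


def molecular_dipoles(positions: np.ndarray, charges: np.ndarray, mol_ptr: np.ndarray):
    """Unit dipole directions of molecules given a flat (sorted-by-molecule)
    atom layout described by ``mol_ptr`` boundaries. Raises on apolar
    molecules."""
    sums = np.add.reduceat(positions, mol_ptr[:-1], axis=0)
    sizes = (mol_ptr[1:] - mol_ptr[:-1]).astype(float)
    cog = sums / sizes[:, None]
    mu = np.add.reduceat(
        charges[:, None] * (positions - np.repeat(cog, np.diff(mol_ptr), axis=0)),
        mol_ptr[:-1],
        axis=0,
    )
    norm = np.linalg.norm(mu, axis=1)
    if (norm < 1e-12).any():
        raise ValueError("apolar molecule in selection: zero dipole moment")
    return mu / norm[:, None]


def dipole_correlation(
    trajectory,
    system,
    bin_width: float,
    r_max: float,
    reference_atoms: np.ndarray | None = None,
) -> BinnedCurve:
    """Dipole-dipole orientation correlation C(r) = <mu_i . mu_j> binned by
    the minimum-image distance between molecular reference atoms (default:
    the first atom of each molecule, i.e. the water oxygen)."""
    mols, first = np.unique(system.molecule_id, return_index=True)
    counts_per_mol = np.bincount(
        np.searchsorted(mols, system.molecule_id), minlength=len(mols)
    )
    mol_ptr = np.concatenate([[0], np.cumsum(counts_per_mol)])
    if reference_atoms is None:
        reference_atoms = first
    reference_atoms = np.asarray(reference_atoms)

    edges = np.arange(0.0, r_max + bin_width * 0.5, bin_width)
    acc = np.zeros(len(edges) - 1)
    cnt = np.zeros(len(edges) - 1)
    iu, ju = np.triu_indices(len(mols), k=1)
    for pos, box in _frame_arrays(trajectory):
        _check_rmax(r_max, box)
        mu = molecular_dipoles(pos, system.charges, mol_ptr)
        ref = pos[reference_atoms]
        d = np.linalg.norm(_min_image(ref[iu] - ref[ju], box), axis=1)
        dots = (mu[iu] * mu[ju]).sum(axis=1)
        sel = d < r_max
        idx = np.minimum((d[sel] / bin_width).astype(int), len(acc) - 1)
        np.add.at(acc, idx, dots[sel])
        np.add.at(cnt, idx, 1.0)
    with np.errstate(invalid="ignore"):
        values = np.where(cnt > 0, acc / np.maximum(cnt, 1), np.nan)
    return BinnedCurve(
        bin_centers=0.5 * (edges[:-1] + edges[1:]), values=values, counts=cnt
    )


def radius_of_gyration(positions: np.ndarray, masses: np.ndarray) -> float:
    """Mass-weighted radius of gyration sqrt(sum m_i (r_i - r_com)^2 / M)."""
    positions = np.asarray(positions, dtype=float).reshape(-1, 3)
    masses = np.asarray(masses, dtype=float)
    if positions.shape[0] == 0:
        raise ValueError("empty selection")
    m_total = masses.sum()
    if m_total <= 0:
        raise ValueError("total mass must be positive")
    com = (masses[:, None] * positions).sum(axis=0) / m_total
    return float(np.sqrt((masses * ((positions - com) ** 2).sum(axis=1)).sum() / m_total))


def rmsd100(rmsd: float, n_residues: int) -> float:
    """Normalize an RMSD to a notional 100-residue protein:
    RMSD100 = RMSD / (1 + ln sqrt(N/100)). Below the formula's validity range
    (denominator <= 0) the result is flagged NaN rather than extrapolated."""
    if n_residues < 1:
        raise ValueError("n_residues must be >= 1")
    if rmsd < 0:
        raise ValueError("rmsd must be >= 0")
    denom = 1.0 + np.log(np.sqrt(n_residues / 100.0))
    if denom <= 0:
        return float("nan")
    return float(rmsd / denom)


def count_hbonds(
    positions: np.ndarray,
    box: np.ndarray,
    donors: np.ndarray,
    hydrogens: np.ndarray,
    acceptors: np.ndarray,
    distance_cutoff: float = 0.25,
    angle_cutoff_deg: float = 120.0,
    distance_between: str = "donor-acceptor",
) -> int:
    """Count hydrogen bonds by the geometric criterion: an acceptor-donor
    distance below ``distance_cutoff`` (nm) and an acceptor-hydrogen-donor
    angle larger than ``angle_cutoff_deg``.

    ``donors`` and ``hydrogens`` are parallel arrays (the covalent D-H
    mapping); every (D, H) is tested against every acceptor. The
    ``distance_between`` switch ("donor-acceptor" or "hydrogen-acceptor")
    selects which distance the cutoff applies to.
    """
    donors = np.asarray(donors)
    hydrogens = np.asarray(hydrogens)
    acceptors = np.asarray(acceptors)
    if distance_between not in ("donor-acceptor", "hydrogen-acceptor"):
        raise ValueError("distance_between must be donor-acceptor or hydrogen-acceptor")
    count = 0
    for d_idx, h_idx in zip(donors, hydrogens):
        for a_idx in acceptors:
            if a_idx == d_idx or a_idx == h_idx:
                continue
            ref = d_idx if distance_between == "donor-acceptor" else h_idx
            dist = np.linalg.norm(_min_image(positions[a_idx] - positions[ref], box))
            if dist >= distance_cutoff:
                continue
            v_d = _min_image(positions[d_idx] - positions[h_idx], box)
            v_a = _min_image(positions[a_idx] - positions[h_idx], box)
            cosang = (v_d @ v_a) / (np.linalg.norm(v_d) * np.linalg.norm(v_a))
            angle = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
            if angle > angle_cutoff_deg:
                count += 1
    return count


def noe_average(distance_series) -> float:
    """NOE-style distance average ( <r^-3> )^(-1/3)."""
    r = np.asarray(distance_series, dtype=float)
    if r.size == 0:
        raise ValueError("empty distance series")
    if (r <= 0).any():
        raise ValueError("all distances must be positive")
    return float(np.mean(r**-3.0) ** (-1.0 / 3.0))


def bath_temperature_series(
    energy_log, window: tuple[float, float] | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-bath temperature time series and summary (mean, SD) over an
    analysis window ``(t_start, t_end)`` in ps (default: the whole log)."""
    df = pd.DataFrame(energy_log) if not isinstance(energy_log, pd.DataFrame) else energy_log
    t_cols = [col for col in df.columns if col.startswith("T_")]
    if "time" not in df.columns or not t_cols:
        raise ValueError("energy log lacks time or per-bath temperature columns")
    series = df[["time", *t_cols]].copy()
    if window is not None:
        series = series[(series["time"] >= window[0]) & (series["time"] <= window[1])]
    summary = pd.DataFrame(
        {
            "bath": [col[2:] for col in t_cols],
            "mean": [series[col].mean() for col in t_cols],
            "sd": [series[col].std(ddof=1) for col in t_cols],
            "n": [series[col].count() for col in t_cols],
        }
    )
    return series, summary
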