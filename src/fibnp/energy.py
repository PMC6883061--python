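"""Coulomb and Lennard-Jones interaction energies between atom selections.

Only inter-group pairs are summed (an interaction-energy, not total-energy,
contract; intra-group and bonded exclusions never enter).  The electrostatic
term is

    E_C = C * sum_ij q_i q_j / (eps * r_ij),   C = 332.0636 kcal·Å/(mol·e²),

evaluated over all pairs by default — the distance cutoff applies to the
12-6 term only, matching a post-hoc energy evaluation in a uniform
dielectric.  Setting ``NonbondedParams.coulomb_cutoff`` truncates the
electrostatics too; that short-range variant is the package's proxy for the
salt-screened local field of a simulated electrolyte.  The dispersion term is

    E_LJ = sum_{r_ij <= cutoff} eps_ij [ (rmin_ij/r_ij)^12 - 2 (rmin_ij/r_ij)^6 ],

with Lorentz–Berthelot-style combining eps_ij = sqrt(eps_i eps_j) and
rmin_ij = rmin_half_i + rmin_half_j, plainly truncated (no switching).

Energies can be attributed residue-by-residue on the second selection, and a
Coulomb potential grid (volts) supports equipotential-surface analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from .model import COULOMB_VOLT, NonbondedParams, StructureModel, Trajectory

__all__ = [
    "InteractionReport",
    "PotentialGrid",
    "pair_energy",
    "trajectory_energy",
    "per_residue_decomposition",
    "coulomb_grid",
]

_BLOCK = 2048  # atoms per block in the dense Coulomb evaluation


@dataclass
class InteractionReport:
    """Coulomb/LJ/total interaction energies (kcal/mol) for a selection pair.

    ``per_residue`` maps (chain_id, residue_seq, residue_name) of the second
    selection to its (coulomb, lj) share; the shares sum to the totals.
    """

    coulomb: float
    lj: float
    total: float
    per_residue: dict[tuple[str, int, str], tuple[float, float]]
    frames_used: int
    dielectric: float
    lj_cutoff: float
    per_frame: pd.DataFrame | None = field(default=None, repr=False)

    def to_dict(self) -> dict:
        return {
            "coulomb_kcal_mol": self.coulomb,
            "lj_kcal_mol": self.lj,
            "total_kcal_mol": self.total,
            "frames_used": self.frames_used,
            "dielectric": self.dielectric,
            "lj_cutoff_A": self.lj_cutoff,
            "per_residue": {
                f"{c}/{rn}{rs}": {"coulomb": e[0], "lj": e[1]}
                for (c, rs, rn), e in sorted(self.per_residue.items())
            },
        }


def _residue_bins(model: StructureModel, indices: np.ndarray):
    keys = [
        (str(model.chain_ids[i]), int(model.res_seq[i]), str(model.res_names[i]))
        for i in indices
    ]
    uniq: list[tuple[str, int, str]] = []
    lookup: dict[tuple[str, int, str], int] = {}
    bins = np.empty(len(keys), dtype=int)
    for n, k in enumerate(keys):
        if k not in lookup:
            lookup[k] = len(uniq)
            uniq.append(k)
        bins[n] = lookup[k]
    return uniq, bins


def pair_energy(model: StructureModel, group_a: np.ndarray,
                group_b: np.ndarray, frame: np.ndarray,
                params: NonbondedParams) -> InteractionReport:
    """Single-frame Coulomb + LJ interaction energy between two selections."""
    group_a = np.asarray(group_a, dtype=int)
    group_b = np.asarray(group_b, dtype=int)
    if np.intersect1d(group_a, group_b).size:
        raise ValueError("selections overlap; interaction energy is pairwise "
                         "between disjoint groups")
    if group_a.size == 0 or group_b.size == 0:
        raise ValueError("empty selection")
    model.require_charges(group_a)
    model.require_charges(group_b)
    model.require_lj(group_a)
    model.require_lj(group_b)
    frame = np.asarray(frame, dtype=float)
    pa, pb = frame[group_a], frame[group_b]
    qa, qb = model.charges[group_a], model.charges[group_b]
    res_keys, res_bins = _residue_bins(model, group_b)
    res_coul = np.zeros(len(res_keys))
    res_lj = np.zeros(len(res_keys))

    # Coulomb: dense blocks, all pairs (optionally truncated)
    ke = params.coulomb_constant / params.dielectric
    coulomb = 0.0
    for start in range(0, len(pa), _BLOCK):
        sl = slice(start, start + _BLOCK)
        r = cdist(pa[sl], pb)
        if np.any(r == 0.0):
            raise ValueError("overlapping atoms (zero pair distance)")
        e = ke * np.outer(qa[sl], qb) / r
        if params.coulomb_cutoff is not None:
            e[r > params.coulomb_cutoff] = 0.0
        coulomb += float(e.sum())
        np.add.at(res_coul, res_bins, e.sum(axis=0))

    # LJ: tree-pruned pairs within the cutoff
    ea, eb = model.lj_epsilon[group_a], model.lj_epsilon[group_b]
    ra, rb = model.lj_rmin_half[group_a], model.lj_rmin_half[group_b]
    tree_a, tree_b = cKDTree(pa), cKDTree(pb)
    lj = 0.0
    pairs = tree_a.query_ball_tree(tree_b, params.lj_cutoff)
    for ia, nbrs in enumerate(pairs):
        if not nbrs:
            continue
        nbrs = np.asarray(nbrs, dtype=int)
        r = np.linalg.norm(pb[nbrs] - pa[ia], axis=1)
        if np.any(r == 0.0):
            raise ValueError("overlapping atoms (zero pair distance)")
        eps = np.sqrt(ea[ia] * eb[nbrs])
        rmin = ra[ia] + rb[nbrs]
        x6 = (rmin / r) ** 6
        e = eps * (x6 * x6 - 2.0 * x6)
        lj += float(e.sum())
        np.add.at(res_lj, res_bins[nbrs], e)

    per_residue = {
        k: (float(res_coul[n]), float(res_lj[n])) for n, k in enumerate(res_keys)
    }
    return InteractionReport(
        coulomb=coulomb, lj=lj, total=coulomb + lj,
        per_residue=per_residue, frames_used=1,
        dielectric=params.dielectric, lj_cutoff=params.lj_cutoff,
    )


def trajectory_energy(model: StructureModel, group_a: np.ndarray,
                      group_b: np.ndarray, traj: Trajectory,
                      params: NonbondedParams, last_n_frames: int = 500,
                      frame_stride: int = 1) -> InteractionReport:
    """Frame-averaged interaction energy over the trajectory tail.

    ``frame_stride`` evenly subsamples the last ``last_n_frames``; the
    per-frame table is attached as ``report.per_frame``.
    """
    frames = traj.last(last_n_frames)[::max(1, int(frame_stride))]
    reports = [pair_energy(model, group_a, group_b, f, params) for f in frames]
    n = len(reports)
    per_residue: dict[tuple[str, int, str], tuple[float, float]] = {}
    for k in reports[0].per_residue:
        c = sum(r.per_residue[k][0] for r in reports) / n
        l = sum(r.per_residue[k][1] for r in reports) / n
        per_residue[k] = (c, l)
    per_frame = pd.DataFrame({
        "frame": np.arange(n),
        "coulomb": [r.coulomb for r in reports],
        "lj": [r.lj for r in reports],
        "total": [r.total for r in reports],
    })
    coulomb = float(per_frame["coulomb"].mean())
    lj = float(per_frame["lj"].mean())
    return InteractionReport(
        coulomb=coulomb, lj=lj, total=coulomb + lj,
        per_residue=per_residue, frames_used=n,
        dielectric=params.dielectric, lj_cutoff=params.lj_cutoff,
        per_frame=per_frame,
    )


def per_residue_decomposition(report: InteractionReport) -> pd.DataFrame:
    """Residue-level energy table, sorted by total contribution."""
    rows = [
        {"chain": c, "residue_seq": rs, "residue": rn,
         "coulomb": e[0], "lj": e[1], "total": e[0] + e[1]}
        for (c, rs, rn), e in report.per_residue.items()
    ]
    df = pd.DataFrame(rows)
    return df.sort_values("total").reset_index(drop=True)


@dataclass
class PotentialGrid:
    """Coulomb potential (volts) on a regular grid; NaN inside atom cores."""

    origin: np.ndarray
    spacing: float
    values: np.ndarray
    dielectric: float


def coulomb_grid(model: StructureModel, bounds: np.ndarray, spacing: float,
                 params: NonbondedParams, mask_radius: float = 0.5
                 ) -> PotentialGrid:
    """Electrostatic potential phi(x) = (14.3996/eps) * sum_i q_i / r_i volts.

    ``bounds`` is ((xmin, xmax), (ymin, ymax), (zmin, zmax)) in Å.  Grid
    points closer than ``mask_radius`` to any atom center are masked NaN.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    bounds = np.asarray(bounds, dtype=float).reshape(3, 2)
    if np.any(bounds[:, 1] < bounds[:, 0]):
        raise ValueError("empty box: every axis needs max >= min")
    model.require_charges()
    axes = [np.arange(lo, hi + spacing / 2.0, spacing) for lo, hi in bounds]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    phi = np.zeros(len(pts))
    masked = np.zeros(len(pts), dtype=bool)
    kv = COULOMB_VOLT / params.dielectric
    for start in range(0, len(pts), _BLOCK):
        sl = slice(start, start + _BLOCK)
        r = cdist(pts[sl], model.positions)
        masked[sl] = np.any(r < mask_radius, axis=1)
        with np.errstate(divide="ignore"):
            phi[sl] = kv * np.sum(model.charges[None, :] / r, axis=1)
    phi[masked] = np.nan
    return PotentialGrid(
        origin=bounds[:, 0].copy(), spacing=float(spacing),
        values=phi.reshape(gx.shape), dielectric=params.dielectric,
    )
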