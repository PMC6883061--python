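"""Fibril twist-angle statistics.

Each peptide defines a vector between the Cα atoms of two marker residues
(by default pointing from residue 32 to residue 18).  The twist angle of a
consecutive peptide pair is the unsigned 3-D angle between their two vectors,
and the summary statistic is the grand mean over inner peptide pairs and
trajectory frames,

    theta_twist = (1/m) * sum_j phi_{j,j+1},

with m pairs taken from the inner peptide ordinals (4..25 by default, so a
29-peptide protofilament contributes 22 peptides and m = 21 pairs per frame;
500 frames pool 10,500 angles).  Terminal peptides are excluded to avoid
boundary effects.  Angles are unsigned and unprojected: the raw 3-D angle in
[0°, 180°] is used, so handedness is not resolved.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import StructureModel, Trajectory

__all__ = [
    "TwistReport",
    "peptide_vector",
    "pair_twist_angle",
    "compute_twist_report",
    "bin_percentages",
]


@dataclass
class TwistReport:
    """Per-pair/per-frame twist angles and their summaries (degrees)."""

    pair_angles: np.ndarray          # (frames, m)
    frame_means: np.ndarray          # (frames,)
    theta_twist: float
    histogram_edges: np.ndarray
    histogram_counts: np.ndarray
    bin_percentages: dict[str, float]
    m: int
    residue_pair: tuple[int, int]
    frames_used: int

    def to_dict(self) -> dict:
        return {
            "theta_twist_deg": self.theta_twist,
            "m_pairs": self.m,
            "frames_used": self.frames_used,
            "n_angles": int(self.pair_angles.size),
            "residue_pair": list(self.residue_pair),
            "bin_percentages": self.bin_percentages,
            "frame_means_deg": self.frame_means.tolist(),
            "histogram_edges_deg": self.histogram_edges.tolist(),
            "histogram_counts": self.histogram_counts.tolist(),
        }


def _ca_index(model: StructureModel, chain_id: str, residue: int,
              ordinal: int) -> int:
    mask = ((model.chain_ids == chain_id) & (model.res_seq == residue)
            & (model.names == "CA"))
    idx = np.nonzero(mask)[0]
    if idx.size != 1:
        raise ValueError(
            f"peptide ordinal {ordinal}: expected exactly one Cα for residue "
            f"{residue} in chain {chain_id!r}, found {idx.size}"
        )
    return int(idx[0])


def peptide_vector(model: StructureModel, coords: np.ndarray,
                   protofilament: int, peptide: int,
                   from_residue: int = 18, to_residue: int = 32) -> np.ndarray:
    """Marker vector of one peptide (1-based ordinal within a protofilament).

    Returns the displacement pointing from Cα(to_residue) to Cα(from_residue)
    — with the defaults, from residue 32 toward residue 18 — unnormalized.
    """
    pf = model.protofilaments[protofilament]
    pep = model.peptides[pf[peptide - 1]]
    i_from = _ca_index(model, pep.chain_id, from_residue, peptide)
    i_to = _ca_index(model, pep.chain_id, to_residue, peptide)
    return np.asarray(coords)[i_from] - np.asarray(coords)[i_to]


def pair_twist_angle(v1: np.ndarray, v2: np.ndarray) -> float:
    """Unsigned angle between two vectors, degrees in [0, 180]."""
    v1 = np.asarray(v1, dtype=float)
    v2 = np.asarray(v2, dtype=float)
    n1 = np.linalg.norm(v1, axis=-1)
    n2 = np.linalg.norm(v2, axis=-1)
    if np.any(n1 == 0) or np.any(n2 == 0):
        raise ValueError("zero-length vector has no direction")
    # atan2(|v1 x v2|, v1.v2) equals the arccos of the normalized dot product
    # but stays fully accurate for near-parallel vectors
    cross = np.cross(v1, v2)
    ang = np.degrees(np.arctan2(np.linalg.norm(cross, axis=-1),
                                np.sum(v1 * v2, axis=-1)))
    return float(ang) if np.ndim(ang) == 0 else ang


def bin_percentages(angles: np.ndarray) -> dict[str, float]:
    """Percentages in the [0,10), [10,20), [20,180] degree bins.

    Half-open convention: a tie on a boundary goes to the upper bin.
    """
    a = np.asarray(angles, dtype=float).ravel()
    if a.size == 0:
        raise ValueError("empty angle list")
    n = a.size
    lo = np.count_nonzero(a < 10.0)
    hi = np.count_nonzero(a >= 20.0)
    mid = n - lo - hi
    return {
        "<10": 100.0 * lo / n,
        "10-20": 100.0 * mid / n,
        ">=20": 100.0 * hi / n,
    }


def compute_twist_report(traj: Trajectory, protofilament: int = 0,
                         inner_range: tuple[int, int] = (4, 25),
                         last_n_frames: int = 500,
                         from_residue: int = 18, to_residue: int = 32,
                         bin_width: float = 1.0) -> TwistReport:
    """Twist-angle report over the final frames of a trajectory.

    ``inner_range`` is an inclusive 1-based ordinal range of peptides within
    the protofilament; consecutive ordinals form the pairs, so m =
    |inner_range| − 1.  The report pools every frame × pair angle for the
    histogram and bin percentages; ``theta_twist`` is the grand mean.
    """
    model = traj.topology
    if protofilament >= len(model.protofilaments):
        raise ValueError(f"no protofilament {protofilament}")
    pf = model.protofilaments[protofilament]
    lo, hi = inner_range
    if lo < 1 or hi > len(pf) or hi <= lo:
        raise ValueError(
            f"inner range {lo}..{hi} outside the protofilament's "
            f"{len(pf)} peptides"
        )
    ordinals = list(range(lo, hi + 1))
    frames = traj.last(last_n_frames)

    idx_from, idx_to = [], []
    for o in ordinals:
        pep = model.peptides[pf[o - 1]]
        idx_from.append(_ca_index(model, pep.chain_id, from_residue, o))
        idx_to.append(_ca_index(model, pep.chain_id, to_residue, o))
    idx_from = np.asarray(idx_from)
    idx_to = np.asarray(idx_to)

    vectors = frames[:, idx_from, :] - frames[:, idx_to, :]   # (F, P, 3)
    v1, v2 = vectors[:, :-1, :], vectors[:, 1:, :]
    pair_angles = pair_twist_angle(v1, v2)                     # (F, m)

    m = len(ordinals) - 1
    frame_means = pair_angles.mean(axis=1)
    pooled = pair_angles.ravel()
    edges = np.arange(0.0, 180.0 + bin_width, bin_width)
    counts, edges = np.histogram(pooled, bins=edges)
    return TwistReport(
        pair_angles=pair_angles,
        frame_means=frame_means,
        theta_twist=float(pooled.mean()),
        histogram_edges=edges,
        histogram_counts=counts,
        bin_percentages=bin_percentages(pooled),
        m=m,
        residue_pair=(from_residue, to_residue),
        frames_used=int(frames.shape[0]),
    )
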