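"""Stochastic solvent-accessible surface areas and contact statistics.

SASA follows the Monte-Carlo variant of the Shrake–Rupley construction: each
target atom is surrounded by a probe-expanded sphere of radius r_i + r_probe
carrying n uniformly random surface points; a point is accessible iff it lies
outside the (by default probe-expanded) sphere of every other target atom and
of every occluder atom, and the accessible fraction scales the exact sphere
area 4π(r_i + r_probe)².  The binomial standard error of the estimate is
always reported so downstream comparisons can use Monte-Carlo tolerance
bands.

A contact area is a SASA difference: the area of a structure evaluated alone
minus its area with a second structure present as occluders, both with the
identical point sets (same seed).  Heavy-atom contacts are counted with an
inclusive center-to-center distance cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .model import NonbondedParams, StructureModel, Trajectory

__all__ = [
    "SasaResult",
    "ContactAreaResult",
    "BindingProfile",
    "sphere_points",
    "compute_sasa",
    "contact_area",
    "count_contacts",
    "binding_profile",
]


@dataclass
class SasaResult:
    """Monte-Carlo SASA estimate (Ų) with its binomial standard error."""

    total_area: float
    per_atom_area: np.ndarray
    n_points: int
    probe_radius: float
    mc_se: float


@dataclass
class ContactAreaResult:
    """Frame-averaged SASA-difference contact area (Ų)."""

    sasa_alone: float
    sasa_in_context: float
    contact_area: float
    context_label: str
    mc_se: float
    frames_used: int

    def to_dict(self) -> dict:
        return {
            "context": self.context_label,
            "sasa_alone_A2": self.sasa_alone,
            "sasa_in_context_A2": self.sasa_in_context,
            "contact_area_A2": self.contact_area,
            "contact_area_nm2": self.contact_area / 100.0,
            "mc_se_A2": self.mc_se,
            "frames_used": self.frames_used,
        }


def sphere_points(n_atoms: int, n_points: int, seed: int) -> np.ndarray:
    """(n_atoms, n_points, 3) unit vectors, Marsaglia-sampled, seed-fixed.

    The point sets depend only on (n_atoms, n_points, seed), never on the
    geometry, so evaluations with and without occluders reuse identical
    points and their difference carries no extra sampling noise at the
    per-point level.
    """
    rng = np.random.default_rng(seed)
    need = n_atoms * n_points
    chunks = []
    got = 0
    while got < need:
        uv = rng.uniform(-1.0, 1.0, size=(int((need - got) * 1.4) + 16, 2))
        s = np.sum(uv * uv, axis=1)
        uv = uv[s < 1.0]
        s = np.sum(uv * uv, axis=1)
        root = np.sqrt(1.0 - s)
        pts = np.column_stack([2 * uv[:, 0] * root, 2 * uv[:, 1] * root,
                               1.0 - 2.0 * s])
        chunks.append(pts)
        got += len(pts)
    return np.concatenate(chunks)[:need].reshape(n_atoms, n_points, 3)


def compute_sasa(positions: np.ndarray, radii: np.ndarray,
                 params: NonbondedParams,
                 occluder_positions: np.ndarray | None = None,
                 occluder_radii: np.ndarray | None = None) -> SasaResult:
    """Monte-Carlo SASA of the target atoms, optionally with occluders.

    Target atoms always occlude each other; occluder atoms block points but
    contribute no area of their own.  ``params.occluder_surface`` selects
    whether blocking spheres are probe-expanded (standard, default) or bare
    vdW, a sensitivity knob only.
    """
    positions = np.asarray(positions, dtype=float).reshape(-1, 3)
    radii = np.asarray(radii, dtype=float).ravel()
    if radii.size != positions.shape[0]:
        raise ValueError("one radius per target atom required")
    if np.any(~np.isfinite(radii)) or np.any(radii <= 0):
        raise ValueError("target atoms have missing or non-positive radii")
    probe = params.probe_radius
    n_pts = params.sasa_points
    expand = probe if params.occluder_surface == "expanded" else 0.0

    target_R = radii + probe
    block_pos = [positions]
    block_R = [radii + expand]
    if occluder_positions is not None:
        occ_p = np.asarray(occluder_positions, dtype=float).reshape(-1, 3)
        occ_r = np.asarray(occluder_radii, dtype=float).ravel()
        if occ_r.size != occ_p.shape[0]:
            raise ValueError("one radius per occluder atom required")
        if np.any(~np.isfinite(occ_r)) or np.any(occ_r <= 0):
            raise ValueError("occluder atoms have missing or non-positive radii")
        block_pos.append(occ_p)
        block_R.append(occ_r + expand)
    block_pos = np.vstack(block_pos)
    block_R = np.concatenate(block_R)
    n_targets = positions.shape[0]

    unit = sphere_points(n_targets, n_pts, params.rng_seed)
    tree = cKDTree(block_pos)
    max_R = float(block_R.max())

    per_atom = np.zeros(n_targets)
    per_var = np.zeros(n_targets)
    for i in range(n_targets):
        sphere_area = 4.0 * np.pi * target_R[i] ** 2
        neigh = tree.query_ball_point(positions[i], target_R[i] + max_R)
        neigh = [j for j in neigh if j != i]
        if not neigh:
            per_atom[i] = sphere_area
            continue
        nb_pos = block_pos[neigh]
        nb_R2 = block_R[neigh] ** 2
        pts = positions[i] + target_R[i] * unit[i]
        diff = pts[:, None, :] - nb_pos[None, :, :]
        d2 = np.einsum("pjk,pjk->pj", diff, diff)
        accessible = np.all(d2 >= nb_R2[None, :], axis=1)
        p = accessible.mean()
        per_atom[i] = p * sphere_area
        per_var[i] = p * (1.0 - p) / n_pts * sphere_area ** 2
    total = float(per_atom.sum())
    return SasaResult(
        total_area=total,
        per_atom_area=per_atom,
        n_points=n_pts,
        probe_radius=probe,
        mc_se=float(np.sqrt(per_var.sum())),
    )


def contact_area(np_indices: np.ndarray, context_indices: np.ndarray,
                 traj: Trajectory, params: NonbondedParams,
                 last_n_frames: int = 500, frame_stride: int = 1,
                 context_label: str = "context") -> ContactAreaResult:
    """Frame-averaged SASA-difference contact area of a target selection.

    Per frame: SASA of the target atoms alone, and with the context atoms as
    occluders, with identical point sets; the contact area is the mean
    difference.  ``frame_stride`` subsamples the last ``last_n_frames``
    evenly (stride 1 uses every frame).
    """
    np_indices = np.asarray(np_indices, dtype=int)
    context_indices = np.asarray(context_indices, dtype=int)
    if np.intersect1d(np_indices, context_indices).size:
        raise ValueError("target and context selections overlap")
    if np_indices.size == 0 or context_indices.size == 0:
        raise ValueError("empty selection")
    model = traj.topology
    model.require_radii(np_indices)
    model.require_radii(context_indices)
    frames = traj.last(last_n_frames)[::max(1, int(frame_stride))]
    r_np = model.vdw_radii[np_indices]
    r_ctx = model.vdw_radii[context_indices]
    alone, within, var = [], [], []
    for frame in frames:
        s0 = compute_sasa(frame[np_indices], r_np, params)
        s1 = compute_sasa(frame[np_indices], r_np, params,
                          occluder_positions=frame[context_indices],
                          occluder_radii=r_ctx)
        alone.append(s0.total_area)
        within.append(s1.total_area)
        var.append(s0.mc_se ** 2 + s1.mc_se ** 2)
    n_f = len(frames)
    return ContactAreaResult(
        sasa_alone=float(np.mean(alone)),
        sasa_in_context=float(np.mean(within)),
        contact_area=float(np.mean(alone) - np.mean(within)),
        context_label=context_label,
        mc_se=float(np.sqrt(np.mean(var) / n_f)),
        frames_used=n_f,
    )


def count_contacts(model: StructureModel, group_a: np.ndarray,
                   group_b: np.ndarray, frame: np.ndarray,
                   cutoff: float = 5.0, heavy_only: bool = True) -> int:
    """Number of group-a atoms within ``cutoff`` Å of any group-b atom.

    The cutoff is inclusive and center-to-center; with ``heavy_only`` the
    counted group-a atoms are restricted to non-hydrogens.  Selections must
    be disjoint.
    """
    group_a = np.asarray(group_a, dtype=int)
    group_b = np.asarray(group_b, dtype=int)
    if np.intersect1d(group_a, group_b).size:
        raise ValueError("selections overlap")
    if group_a.size == 0 or group_b.size == 0:
        raise ValueError("empty selection")
    if heavy_only:
        group_a = group_a[model.is_heavy[group_a]]
        if group_a.size == 0:
            return 0
    frame = np.asarray(frame, dtype=float)
    tree = cKDTree(frame[group_b])
    d, _ = tree.query(frame[group_a], k=1)
    return int(np.count_nonzero(d <= cutoff))


@dataclass
class BindingProfile:
    """Per-peptide frame-averaged contact counts."""

    counts: np.ndarray   # (frames, peptides)
    means: np.ndarray
    sds: np.ndarray
    frames_used: int

    def to_dict(self) -> dict:
        return {
            "frames_used": self.frames_used,
            "mean_contacts": self.means.tolist(),
            "sd_contacts": self.sds.tolist(),
        }


def binding_profile(model: StructureModel, peptide_selections: list[np.ndarray],
                    np_selection: np.ndarray, traj: Trajectory,
                    params: NonbondedParams, last_n_frames: int = 500,
                    frame_stride: int = 1) -> BindingProfile:
    """Heavy-atom contact counts of each peptide with a reference selection,
    per frame over the trajectory tail."""
    if not peptide_selections:
        raise ValueError("empty peptide list")
    frames = traj.last(last_n_frames)[::max(1, int(frame_stride))]
    counts = np.zeros((len(frames), len(peptide_selections)))
    for fi, frame in enumerate(frames):
        for pi, pep in enumerate(peptide_selections):
            counts[fi, pi] = count_contacts(
                model, pep, np_selection, frame,
                cutoff=params.contact_cutoff, heavy_only=True,
            )
    return BindingProfile(
        counts=counts,
        means=counts.mean(axis=0),
        sds=counts.std(axis=0, ddof=0),
        frames_used=len(frames),
    )
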