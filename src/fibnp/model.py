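"""Core domain types: atoms, structures, trajectories and nonbonded parameters.

A :class:`StructureModel` is a column-oriented atom table (numpy arrays) plus
light topology annotations: the list of peptides (monomers), their grouping
into protofilaments, and — for nanoparticles — a ligand map.  Missing per-atom
physical parameters (charge, vdW radius, LJ terms) are stored as NaN and must
be resolved explicitly before any energy or surface-area computation; they are
never silently treated as zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "AtomRecord",
    "Peptide",
    "StructureModel",
    "Trajectory",
    "NonbondedParams",
    "select",
    "union",
    "intersection",
    "complement",
    "concat_models",
    "MissingParameterError",
    "SelectionError",
]

#: elements counted as hydrogen for the heavy-atom flag
_HYDROGEN = {"H", "D", "T"}

#: Bondi van der Waals radii (Å) by element, with a generic fallback.
BONDI_RADII: dict[str, float] = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "F": 1.47,
    "P": 1.80, "S": 1.80, "CL": 1.75, "BR": 1.85, "I": 1.98,
    "AU": 1.66,
}
DEFAULT_VDW_RADIUS = 1.70


class MissingParameterError(ValueError):
    """Raised when charges/radii/LJ parameters are required but absent."""


class SelectionError(ValueError):
    """Raised for malformed selection queries."""


@dataclass(frozen=True)
class AtomRecord:
    """One atom with its residue/chain context and nonbonded parameters.

    ``charge`` is in elementary charges, ``lj_epsilon`` in kcal/mol,
    ``lj_rmin_half`` (half the pair-minimum distance for a homo pair) and
    ``vdw_radius`` in Å.  Unknown parameters are NaN.
    """

    atom_id: int
    name: str
    element: str
    residue_name: str
    residue_seq: int
    chain_id: str
    position: np.ndarray
    charge: float = np.nan
    lj_epsilon: float = np.nan
    lj_rmin_half: float = np.nan
    vdw_radius: float = np.nan

    @property
    def is_heavy(self) -> bool:
        return self.element.upper() not in _HYDROGEN


@dataclass(frozen=True)
class Peptide:
    """One monomer: a chain id plus an inclusive residue_seq range."""

    chain_id: str
    residue_start: int
    residue_stop: int


@dataclass
class StructureModel:
    """Ordered atom collection with peptide/protofilament/ligand topology.

    Arrays all have length ``n_atoms``.  ``protofilaments`` holds indices into
    ``peptides``; peptides within one protofilament are ordered along the
    fibril axis.  ``ligand_map`` maps ligand id -> (ligand_type, atom index
    array); core atoms belong to no ligand.  ``atom_roles`` is only populated
    for models produced by :func:`concat_models`, where atoms of different
    roles coexist.
    """

    names: np.ndarray
    elements: np.ndarray
    res_names: np.ndarray
    res_seq: np.ndarray
    chain_ids: np.ndarray
    positions: np.ndarray
    charges: np.ndarray
    lj_epsilon: np.ndarray
    lj_rmin_half: np.ndarray
    vdw_radii: np.ndarray
    role_tag: str = "fibril"
    peptides: list[Peptide] = field(default_factory=list)
    protofilaments: list[list[int]] = field(default_factory=list)
    ligand_map: dict[int, tuple[str, np.ndarray]] = field(default_factory=dict)
    atom_roles: np.ndarray | None = None

    # ---------------------------------------------------------------- basics
    @property
    def n_atoms(self) -> int:
        return len(self.names)

    @property
    def is_heavy(self) -> np.ndarray:
        return ~np.isin(np.char.upper(self.elements.astype(str)), sorted(_HYDROGEN))

    def atom(self, i: int) -> AtomRecord:
        return AtomRecord(
            atom_id=int(i) + 1,
            name=str(self.names[i]),
            element=str(self.elements[i]),
            residue_name=str(self.res_names[i]),
            residue_seq=int(self.res_seq[i]),
            chain_id=str(self.chain_ids[i]),
            position=self.positions[i].copy(),
            charge=float(self.charges[i]),
            lj_epsilon=float(self.lj_epsilon[i]),
            lj_rmin_half=float(self.lj_rmin_half[i]),
            vdw_radius=float(self.vdw_radii[i]),
        )

    def __len__(self) -> int:
        return self.n_atoms

    def copy(self) -> "StructureModel":
        return StructureModel(
            names=self.names.copy(), elements=self.elements.copy(),
            res_names=self.res_names.copy(), res_seq=self.res_seq.copy(),
            chain_ids=self.chain_ids.copy(), positions=self.positions.copy(),
            charges=self.charges.copy(), lj_epsilon=self.lj_epsilon.copy(),
            lj_rmin_half=self.lj_rmin_half.copy(), vdw_radii=self.vdw_radii.copy(),
            role_tag=self.role_tag, peptides=list(self.peptides),
            protofilaments=[list(p) for p in self.protofilaments],
            ligand_map={k: (t, idx.copy()) for k, (t, idx) in self.ligand_map.items()},
            atom_roles=None if self.atom_roles is None else self.atom_roles.copy(),
        )

    @classmethod
    def from_arrays(
        cls,
        *,
        names: Sequence[str],
        elements: Sequence[str],
        res_names: Sequence[str],
        res_seq: Sequence[int],
        chain_ids: Sequence[str],
        positions: np.ndarray,
        charges: Sequence[float] | None = None,
        vdw_radii: Sequence[float] | None = None,
        lj_epsilon: Sequence[float] | None = None,
        lj_rmin_half: Sequence[float] | None = None,
        role_tag: str = "fibril",
        **kwargs,
    ) -> "StructureModel":
        n = len(names)
        positions = np.asarray(positions, dtype=float).reshape(n, 3)
        if not np.all(np.isfinite(positions)):
            raise ValueError("atom positions must be finite")

        def _f(x):
            return np.full(n, np.nan) if x is None else np.asarray(x, dtype=float)

        return cls(
            names=np.asarray(names, dtype="U6"),
            elements=np.asarray(elements, dtype="U2"),
            res_names=np.asarray(res_names, dtype="U4"),
            res_seq=np.asarray(res_seq, dtype=int),
            chain_ids=np.asarray(chain_ids, dtype="U4"),
            positions=positions,
            charges=_f(charges),
            lj_epsilon=_f(lj_epsilon),
            lj_rmin_half=_f(lj_rmin_half),
            vdw_radii=_f(vdw_radii),
            role_tag=role_tag,
            **kwargs,
        )

    # ------------------------------------------------------------ parameters
    def assign_default_radii(self, table: Mapping[str, float] | None = None) -> None:
        """Fill missing vdW radii from an element table (Bondi by default)."""
        table = dict(BONDI_RADII if table is None else table)
        missing = np.isnan(self.vdw_radii)
        for i in np.nonzero(missing)[0]:
            el = str(self.elements[i]).upper()
            self.vdw_radii[i] = table.get(el, DEFAULT_VDW_RADIUS)

    def require_charges(self, indices: np.ndarray | None = None) -> None:
        self._require(self.charges, indices, "charge")

    def require_radii(self, indices: np.ndarray | None = None) -> None:
        self._require(self.vdw_radii, indices, "vdw_radius")
        sel = slice(None) if indices is None else indices
        if np.any(self.vdw_radii[sel] <= 0):
            raise MissingParameterError("non-positive vdW radius encountered")

    def require_lj(self, indices: np.ndarray | None = None) -> None:
        self._require(self.lj_epsilon, indices, "lj_epsilon")
        self._require(self.lj_rmin_half, indices, "lj_rmin_half")

    def _require(self, arr: np.ndarray, indices: np.ndarray | None, what: str) -> None:
        sel = np.arange(self.n_atoms) if indices is None else np.asarray(indices)
        bad = sel[np.isnan(arr[sel])]
        if bad.size:
            examples = ", ".join(
                f"{self.chain_ids[i]}/{self.res_names[i]}{self.res_seq[i]}:{self.names[i]}"
                for i in bad[:5]
            )
            raise MissingParameterError(
                f"{what} missing for {bad.size} atom(s), e.g. {examples}; "
                "assign parameters before energy/SASA analysis"
            )

    # -------------------------------------------------------------- peptides
    def peptide_atom_indices(self, peptide: Peptide) -> np.ndarray:
        mask = (
            (self.chain_ids == peptide.chain_id)
            & (self.res_seq >= peptide.residue_start)
            & (self.res_seq <= peptide.residue_stop)
        )
        return np.nonzero(mask)[0]

    def validate(self) -> None:
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions contain non-finite values")
        claimed = np.zeros(self.n_atoms, dtype=int)
        for _, idx in self.ligand_map.values():
            claimed[idx] += 1
        if np.any(claimed > 1):
            raise ValueError("an atom belongs to more than one ligand")
        au = np.char.upper(self.elements.astype(str)) == "AU"
        if np.any(au & (claimed > 0)):
            raise ValueError("gold core atoms may not belong to a ligand")
        if np.any(np.nan_to_num(self.charges[au], nan=0.0) != 0.0):
            raise ValueError("gold core atoms must carry zero charge")


# --------------------------------------------------------------------------
# selections
# --------------------------------------------------------------------------

_SELECT_FIELDS = {"chain", "residue_seq", "element", "heavy", "ligand_type", "role_tag"}


def select(model: StructureModel, **query) -> np.ndarray:
    """Return sorted atom indices matching all given criteria.

    Supported keys: ``chain`` (str or list), ``residue_seq`` (int or inclusive
    ``(lo, hi)`` tuple), ``element``, ``heavy`` (bool), ``ligand_type``,
    ``role_tag``.  Criteria combine by intersection; compose further with
    :func:`union` / :func:`intersection` / :func:`complement`.
    """
    unknown = set(query) - _SELECT_FIELDS
    if unknown:
        raise SelectionError(f"unknown selection field(s): {sorted(unknown)}")
    mask = np.ones(model.n_atoms, dtype=bool)
    if "chain" in query:
        chains = query["chain"]
        if isinstance(chains, str):
            chains = [chains]
        mask &= np.isin(model.chain_ids, list(chains))
    if "residue_seq" in query:
        rs = query["residue_seq"]
        if np.isscalar(rs):
            mask &= model.res_seq == int(rs)
        else:
            lo, hi = rs
            mask &= (model.res_seq >= int(lo)) & (model.res_seq <= int(hi))
    if "element" in query:
        mask &= np.char.upper(model.elements.astype(str)) == str(query["element"]).upper()
    if "heavy" in query:
        mask &= model.is_heavy == bool(query["heavy"])
    if "ligand_type" in query:
        lig_mask = np.zeros(model.n_atoms, dtype=bool)
        for _, (ltype, idx) in model.ligand_map.items():
            if ltype == query["ligand_type"]:
                lig_mask[idx] = True
        mask &= lig_mask
    if "role_tag" in query:
        if model.atom_roles is not None:
            mask &= model.atom_roles == str(query["role_tag"])
        elif model.role_tag != query["role_tag"]:
            mask &= False
    return np.nonzero(mask)[0]


def union(*index_sets: np.ndarray) -> np.ndarray:
    if not index_sets:
        return np.empty(0, dtype=int)
    return np.unique(np.concatenate([np.asarray(s, dtype=int) for s in index_sets]))


def intersection(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return np.intersect1d(np.asarray(a, dtype=int), np.asarray(b, dtype=int))


def complement(model: StructureModel, indices: np.ndarray) -> np.ndarray:
    return np.setdiff1d(np.arange(model.n_atoms), np.asarray(indices, dtype=int))


def concat_models(models: Sequence[StructureModel], role_tag: str = "complex") -> StructureModel:
    """Concatenate models into one system, preserving per-atom role tags.

    Ligand-map atom indices and protofilament peptide indices are offset so
    that selections keep working on the combined model.
    """
    if not models:
        raise ValueError("need at least one model")
    offset = 0
    pep_offset = 0
    peptides: list[Peptide] = []
    protofilaments: list[list[int]] = []
    ligand_map: dict[int, tuple[str, np.ndarray]] = {}
    roles: list[np.ndarray] = []
    lig_id = 0
    for m in models:
        peptides.extend(m.peptides)
        protofilaments.extend([[p + pep_offset for p in pf] for pf in m.protofilaments])
        for _, (ltype, idx) in sorted(m.ligand_map.items()):
            ligand_map[lig_id] = (ltype, np.asarray(idx) + offset)
            lig_id += 1
        if m.atom_roles is not None:
            roles.append(m.atom_roles)
        else:
            roles.append(np.full(m.n_atoms, m.role_tag, dtype="U16"))
        offset += m.n_atoms
        pep_offset += len(m.peptides)
    cat = lambda key: np.concatenate([getattr(m, key) for m in models])
    return StructureModel(
        names=cat("names"), elements=cat("elements"), res_names=cat("res_names"),
        res_seq=cat("res_seq"), chain_ids=cat("chain_ids"),
        positions=np.vstack([m.positions for m in models]),
        charges=cat("charges"), lj_epsilon=cat("lj_epsilon"),
        lj_rmin_half=cat("lj_rmin_half"), vdw_radii=cat("vdw_radii"),
        role_tag=role_tag, peptides=peptides, protofilaments=protofilaments,
        ligand_map=ligand_map, atom_roles=np.concatenate(roles),
    )


# --------------------------------------------------------------------------
# trajectory
# --------------------------------------------------------------------------

@dataclass
class Trajectory:
    """Ordered coordinate frames sharing one topology.

    ``frames`` has shape (n_frames, n_atoms, 3) in Å; ``frame_dt`` is the
    frame spacing in ps (default 10 ps, so 500 frames span 5 ns).
    """

    topology: StructureModel
    frames: np.ndarray
    frame_dt: float = 10.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must have shape (n_frames, n_atoms, 3)")
        if self.frames.shape[1] != self.topology.n_atoms:
            raise ValueError(
                f"frames carry {self.frames.shape[1]} atoms but topology has "
                f"{self.topology.n_atoms}"
            )

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def duration_ps(self) -> float:
        return self.n_frames * self.frame_dt

    def last(self, n: int) -> np.ndarray:
        """The final ``n`` frames; errors rather than silently rescaling."""
        if n < 1 or n > self.n_frames:
            raise ValueError(
                f"requested last {n} frames but trajectory has {self.n_frames}"
            )
        return self.frames[self.n_frames - n:]


# --------------------------------------------------------------------------
# nonbonded parameters
# --------------------------------------------------------------------------

#: Coulomb conversion constant, kcal·Å/(mol·e²)
COULOMB_KCAL = 332.0636
#: Coulomb potential constant, V·Å/e
COULOMB_VOLT = 14.3996


@dataclass
class NonbondedParams:
    """Knobs shared by the energy, SASA and contact analyses.

    ``dielectric`` is the uniform relative permittivity dividing Coulomb terms
    (78.5 mimics water); ``lj_cutoff`` truncates only the 12-6 term unless
    ``coulomb_cutoff`` is set (short-range electrostatics, a proxy for ionic
    screening); ``contact_cutoff`` is the inclusive heavy-atom contact
    distance; ``probe_radius`` and ``sasa_points`` parameterize the stochastic
    surface-area estimate.
    """

    dielectric: float = 78.5
    coulomb_constant: float = COULOMB_KCAL
    lj_cutoff: float = 10.0
    contact_cutoff: float = 5.0
    probe_radius: float = 1.4
    sasa_points: int = 500
    rng_seed: int = 0
    coulomb_cutoff: float | None = None
    occluder_surface: str = "expanded"  # or "bare"

    def __post_init__(self) -> None:
        if self.lj_cutoff <= 0 or self.contact_cutoff <= 0:
            raise ValueError("cutoffs must be positive")
        if self.coulomb_cutoff is not None and self.coulomb_cutoff <= 0:
            raise ValueError("coulomb_cutoff must be positive when set")
        if self.sasa_points < 1:
            raise ValueError("sasa_points must be >= 1")
        if self.dielectric <= 0:
            raise ValueError("dielectric must be positive")
        if self.occluder_surface not in ("expanded", "bare"):
            raise ValueError("occluder_surface must be 'expanded' or 'bare'")

    def with_seed(self, seed: int) -> "NonbondedParams":
        return replace(self, rng_seed=int(seed))
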