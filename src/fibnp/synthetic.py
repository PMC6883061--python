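"""Synthetic inputs with known ground truth.

Three generators cover the systems under study:

* :func:`build_fibril` — an idealized two-protofilament cross-beta fibril of
  Cα-trace peptides (one Cα plus one pseudo-sidechain bead per residue) with a
  controllable per-peptide axial twist, so the twist estimator can be checked
  against the value that was imposed.
* :func:`build_nanoparticle` — a ligated gold-core nanoparticle: an
  icosahedral Au shell with uniform nearest-neighbour bond length and a shell
  of schematic ligands (PEG-ammonium, PEG-sulfonate, PEG-NQTrp, or a
  charge-inverted peptide) on a deterministic spherical Fibonacci lattice.
* :func:`synthesize_trajectory` — frames of i.i.d. Gaussian coordinate noise
  around a reference structure, optionally with a rigid drift of a tagged
  sub-structure.

The geometry is schematic by design: charges, sizes and topology tags are
faithful, torsional realism is not.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .model import Peptide, StructureModel, Trajectory

__all__ = [
    "FibrilSpec",
    "NPSpec",
    "DriftSpec",
    "AB40_SEQUENCE",
    "RESIDUE_CHARGES",
    "NP_RECIPES",
    "build_fibril",
    "build_nanoparticle",
    "synthesize_trajectory",
    "invert_charge_sequence",
    "icosahedral_gold_shell",
    "fibonacci_sphere",
    "place_near",
]

# ---------------------------------------------------------------------------
# residue bookkeeping
# ---------------------------------------------------------------------------

_ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}
_STANDARD = set(_ONE_TO_THREE.values())

#: Aβ40 primary sequence (three-letter codes, residues 1..40)
AB40_SEQUENCE: tuple[str, ...] = tuple(
    _ONE_TO_THREE[c] for c in "DAEFRHDSGYEVHHQKLVFFAEDVGSNKGAIIGLMVGGVV"
)

#: integer side-chain charges at neutral pH (His neutral)
RESIDUE_CHARGES: dict[str, int] = {
    **{r: 0 for r in _STANDARD},
    "ASP": -1, "GLU": -1, "LYS": +1, "ARG": +1, "HIS": 0,
}

#: schematic element-level LJ parameters (epsilon kcal/mol, rmin/2 Å)
DEFAULT_LJ: dict[str, tuple[float, float]] = {
    "H": (0.030, 1.34), "C": (0.070, 2.00), "N": (0.170, 1.85),
    "O": (0.120, 1.70), "S": (0.450, 2.00), "AU": (0.200, 1.66),
}

#: ligand compositions of the five standard nanoparticle recipes
NP_RECIPES: dict[str, dict] = {
    "Pos": {"composition": {"Pos-lig": 90}, "placement": "homogeneous"},
    "PosNQ": {"composition": {"Pos-lig": 80, "Neu-lig": 10}, "placement": "homogeneous"},
    "Pep": {"composition": {"Pep-lig": 90}, "placement": "homogeneous"},
    "Janus": {"composition": {"Pos-lig": 45, "Neg-lig": 45}, "placement": "janus"},
    "NegNQ": {"composition": {"Neg-lig": 80, "Neu-lig": 10}, "placement": "homogeneous"},
}

#: single-character chain alphabet for PDB-compatible chain ids
CHAIN_ALPHABET = (
    "ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz0123456789"
)


def invert_charge_sequence(seq: Sequence[str]) -> list[str]:
    """Swap charge classes: Lys/Arg -> Glu, Glu/Asp -> Lys, others unchanged.

    This is the design rule behind the peptide ligand: the fibril's exposed
    Lys-Leu-Val-Phe-Phe-Ala-Glu-Asp stretch maps to
    Glu-Leu-Val-Phe-Phe-Ala-Lys-Lys.
    """
    out = []
    for res in seq:
        r = res.upper()
        if r not in _STANDARD:
            raise ValueError(f"unknown residue {res!r}")
        if r in ("LYS", "ARG"):
            out.append("GLU")
        elif r in ("GLU", "ASP"):
            out.append("LYS")
        else:
            out.append(r)
    return out


#: peptide-ligand sequence: Cys anchor + charge-inverted fibril surface motif
PEP_LIG_SEQUENCE: tuple[str, ...] = ("CYS",) + tuple(
    invert_charge_sequence(["LYS", "LEU", "VAL", "PHE", "PHE", "ALA", "GLU", "ASP"])
)


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------

@dataclass
class FibrilSpec:
    """Parameters of the idealized two-protofilament fibril.

    29 peptides per protofilament at a 4.8 Å cross-beta rise give a
    28 x 4.8 = 134.4 Å (13.44 nm) axial span.  ``imposed_twist`` is the
    rotation (degrees) relating consecutive peptides about the fibril axis —
    the ground truth the twist estimator must recover.
    """

    n_peptides_per_protofilament: int = 29
    rise: float = 4.8
    imposed_twist: float = 0.0
    n_residues: int = 40
    noise_sigma: float = 0.0
    include_disordered_stub: bool = False
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_peptides_per_protofilament < 2:
            raise ValueError("need at least 2 peptides per protofilament")
        if self.rise <= 0:
            raise ValueError("rise must be positive")
        if not (0.0 <= self.imposed_twist < 180.0):
            raise ValueError("imposed_twist must lie in [0, 180)")
        if self.n_residues < 2:
            raise ValueError("need at least 2 residues")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")


@dataclass
class NPSpec:
    """Parameters of the ligated gold-core nanoparticle."""

    core_diameter: float = 22.0
    n_ligands: int = 90
    composition: dict[str, int] = field(
        default_factory=lambda: {"Pos-lig": 90})
    placement: str = "homogeneous"
    au_bond_length: float = 2.74
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.core_diameter <= 0 or self.au_bond_length <= 0:
            raise ValueError("core_diameter and au_bond_length must be positive")
        if sum(self.composition.values()) != self.n_ligands:
            raise ValueError(
                f"ligand composition sums to {sum(self.composition.values())}, "
                f"expected n_ligands={self.n_ligands}"
            )
        unknown = set(self.composition) - {"Pos-lig", "Neg-lig", "Neu-lig", "Pep-lig"}
        if unknown:
            raise ValueError(f"unknown ligand type(s): {sorted(unknown)}")
        if self.placement not in ("homogeneous", "janus"):
            raise ValueError("placement must be 'homogeneous' or 'janus'")
        if self.placement == "janus" and len(self.composition) != 2:
            raise ValueError("janus placement requires exactly two ligand types")

    @classmethod
    def from_recipe(cls, name: str, **overrides) -> "NPSpec":
        if name not in NP_RECIPES:
            raise ValueError(f"unknown recipe {name!r}; choose from {sorted(NP_RECIPES)}")
        recipe = NP_RECIPES[name]
        kwargs = dict(composition=dict(recipe["composition"]),
                      placement=recipe["placement"],
                      n_ligands=sum(recipe["composition"].values()))
        kwargs.update(overrides)
        return cls(**kwargs)


# ---------------------------------------------------------------------------
# fibril builder
# ---------------------------------------------------------------------------

_CA_STEP = 3.47       # Å between consecutive Cα along a beta strand
_U_WIDTH = 9.6        # Å between the two strands of the U-shaped monomer
_SC_OFFSET = 1.5      # Å pseudo-sidechain bead offset
_PF_OFFSET = 7.5      # Å lateral offset of each protofilament from the axis


def _peptide_template(n_residues: int) -> tuple[np.ndarray, np.ndarray]:
    """Cα and sidechain-bead coordinates of one U-shaped monomer.

    The monomer lies in the z = 0 plane (so every inter-residue Cα vector is
    perpendicular to the +z fibril axis), strands run along x, and the
    template is centered on the origin before the protofilament offset.
    """
    half = (n_residues + 1) // 2
    ca = np.zeros((n_residues, 3))
    sc = np.zeros((n_residues, 3))
    for i in range(n_residues):
        r = i + 1
        if r <= half:
            ca[i] = ((r - 1) * _CA_STEP, 0.0, 0.0)
            side = -1.0 if r % 2 == 0 else 1.0
            sc[i] = ca[i] + (0.0, side * _SC_OFFSET, 0.0)
        else:
            ca[i] = ((n_residues - r) * _CA_STEP, _U_WIDTH, 0.0)
            side = 1.0 if r % 2 == 0 else -1.0
            sc[i] = ca[i] + (0.0, side * _SC_OFFSET, 0.0)
    center = (ca.max(axis=0) + ca.min(axis=0)) / 2.0
    return ca - center, sc - center


def _rot_z(deg: float) -> np.ndarray:
    t = math.radians(deg)
    c, s = math.cos(t), math.sin(t)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _sequence(n_residues: int) -> list[str]:
    seq = list(AB40_SEQUENCE[:n_residues])
    seq += ["GLY"] * (n_residues - len(seq))
    return seq


def build_fibril(spec: FibrilSpec) -> StructureModel:
    """Build the idealized two-protofilament fibril.

    The fibril axis is +z.  Peptide j+1 of a protofilament is peptide j
    translated by ``rise`` along z and rotated by ``imposed_twist`` about the
    axis.  The second protofilament is the first rotated 180° about the axis
    (its lateral offset keeps the two peptide columns from overlapping).
    Per-atom charges come from the residue-level table (Asp/Glu −1, Lys/Arg
    +1, His 0) and sit on the sidechain bead.
    """
    rng = np.random.default_rng(spec.rng_seed)
    seq = _sequence(spec.n_residues)
    ca0, sc0 = _peptide_template(spec.n_residues)
    pf_templates = [
        (ca0 + (0.0, _PF_OFFSET, 0.0), sc0 + (0.0, _PF_OFFSET, 0.0)),
    ]
    flip = _rot_z(180.0)
    pf_templates.append((pf_templates[0][0] @ flip.T, pf_templates[0][1] @ flip.T))

    names, elements, res_names, res_seq, chain_ids, charges = [], [], [], [], [], []
    positions = []
    peptides: list[Peptide] = []
    protofilaments: list[list[int]] = []
    n_pep = spec.n_peptides_per_protofilament
    if 2 * n_pep > len(CHAIN_ALPHABET):
        raise ValueError("too many peptides for single-character chain ids")
    chain_cursor = 0
    for pf, (ca_t, sc_t) in enumerate(pf_templates):
        pf_list = []
        for j in range(n_pep):
            rot = _rot_z(j * spec.imposed_twist)
            shift = np.array([0.0, 0.0, j * spec.rise])
            ca = ca_t @ rot.T + shift
            sc = sc_t @ rot.T + shift
            if spec.include_disordered_stub:
                ca, sc = _randomize_stub(ca, sc, rng)
            cid = CHAIN_ALPHABET[chain_cursor]
            chain_cursor += 1
            for i, res in enumerate(seq):
                q = float(RESIDUE_CHARGES[res])
                names += ["CA", "CB"]
                elements += ["C", "C"]
                res_names += [res, res]
                res_seq += [i + 1, i + 1]
                chain_ids += [cid, cid]
                charges += [0.0, q]
                positions += [ca[i], sc[i]]
            peptides.append(Peptide(cid, 1, spec.n_residues))
            pf_list.append(len(peptides) - 1)
        protofilaments.append(pf_list)

    positions = np.asarray(positions, dtype=float)
    if spec.noise_sigma > 0:
        positions = positions + rng.normal(0.0, spec.noise_sigma, positions.shape)
    model = StructureModel.from_arrays(
        names=names, elements=elements, res_names=res_names, res_seq=res_seq,
        chain_ids=chain_ids, positions=positions, charges=charges,
        role_tag="fibril", peptides=peptides, protofilaments=protofilaments,
    )
    model.assign_default_radii()
    _assign_default_lj(model)
    return model


def _randomize_stub(ca: np.ndarray, sc: np.ndarray, rng: np.random.Generator,
                    n_stub: int = 8, step: float = 3.8):
    """Replace residues 1..n_stub by a random-walk coil anchored at n_stub+1."""
    ca, sc = ca.copy(), sc.copy()
    anchor = ca[n_stub]
    pos = anchor.copy()
    for i in range(n_stub - 1, -1, -1):
        d = rng.normal(size=3)
        pos = pos + step * d / np.linalg.norm(d)
        ca[i] = pos
        d2 = rng.normal(size=3)
        sc[i] = pos + _SC_OFFSET * d2 / np.linalg.norm(d2)
    return ca, sc


# ---------------------------------------------------------------------------
# nanoparticle builder
# ---------------------------------------------------------------------------

def fibonacci_sphere(n: int) -> np.ndarray:
    """n unit vectors on the golden-angle spherical Fibonacci lattice."""
    k = np.arange(n)
    z = 1.0 - 2.0 * (k + 0.5) / n
    phi = 2.0 * math.pi * k / ((1.0 + math.sqrt(5.0)) / 2.0) ** 2
    r = np.sqrt(1.0 - z * z)
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def icosahedral_gold_shell(core_diameter: float = 22.0,
                           bond_length: float = 2.74
                           ) -> tuple[np.ndarray, np.ndarray]:
    """Gold shell on a uniformly subdivided icosahedron surface.

    Each icosahedron face is tiled with equilateral triangles of side exactly
    ``bond_length``, so every bonded Au–Au distance equals ``bond_length``; the
    subdivision frequency is chosen to bring the circumscribed diameter as
    close as possible to ``core_diameter``.  Returns (coords, bonds) where
    bonds is an (n_bonds, 2) index array.
    """
    phi = (1.0 + math.sqrt(5.0)) / 2.0
    verts = np.array([
        (-1, phi, 0), (1, phi, 0), (-1, -phi, 0), (1, -phi, 0),
        (0, -1, phi), (0, 1, phi), (0, -1, -phi), (0, 1, -phi),
        (phi, 0, -1), (phi, 0, 1), (-phi, 0, -1), (-phi, 0, 1),
    ], dtype=float)
    verts /= np.linalg.norm(verts[0])
    faces = np.array([
        (0, 11, 5), (0, 5, 1), (0, 1, 7), (0, 7, 10), (0, 10, 11),
        (1, 5, 9), (5, 11, 4), (11, 10, 2), (10, 7, 6), (7, 1, 8),
        (3, 9, 4), (3, 4, 2), (3, 2, 6), (3, 6, 8), (3, 8, 9),
        (4, 9, 5), (2, 4, 11), (6, 2, 10), (8, 6, 7), (9, 8, 1),
    ])
    edge_unit = np.linalg.norm(verts[0] - verts[11])  # icosahedron edge at R=1
    # frequency: edge = freq * bond_length; circumradius = edge / edge_unit
    freq = max(1, round(core_diameter / 2.0 * edge_unit / bond_length))
    scale = freq * bond_length / edge_unit
    verts = verts * scale

    coords: list[np.ndarray] = []
    index: dict[tuple[int, int, int], int] = {}

    def _point(p: np.ndarray) -> int:
        key = tuple(np.round(p / bond_length * 1e6).astype(np.int64))
        if key not in index:
            index[key] = len(coords)
            coords.append(p)
        return index[key]

    bonds: set[tuple[int, int]] = set()
    for a, b, c in faces:
        va, vb, vc = verts[a], verts[b], verts[c]
        grid = {}
        for i in range(freq + 1):
            for j in range(freq + 1 - i):
                k = freq - i - j
                p = (i * va + j * vb + k * vc) / freq
                grid[(i, j)] = _point(p)
        for (i, j), idx in grid.items():
            for di, dj in ((1, 0), (0, 1), (1, -1)):
                nb = grid.get((i + di, j + dj))
                if nb is not None:
                    bonds.add((min(idx, nb), max(idx, nb)))
    return np.asarray(coords), np.asarray(sorted(bonds), dtype=int)


# ligand bead templates: (name, element, radial offset Å, charge e)
_LIGAND_BEADS: dict[str, list[tuple[str, str, float, float]]] = {
    "Pos-lig": [("SG", "S", 0.0, 0.0), ("EG1", "O", 3.0, 0.0),
                ("EG2", "O", 6.0, 0.0), ("NZ", "N", 9.0, +1.0)],
    "Neg-lig": [("SG", "S", 0.0, 0.0), ("EG1", "O", 3.0, 0.0),
                ("EG2", "O", 6.0, 0.0), ("SO3", "S", 9.0, -1.0)],
}
_LIGAND_RESNAME = {"Pos-lig": "POS", "Neg-lig": "NEG", "Neu-lig": "NEU",
                   "Pep-lig": "PEP"}
_NQ_RING_RADIUS = 1.4   # Å, planar six-bead NQTrp ring
_PEP_CA_STEP = 3.8      # Å per residue along the extended peptide ligand
_AU_S_BOND = 2.4        # Å thiol anchor above the shell circumradius


def _ligand_atoms(ltype: str, origin: np.ndarray, u: np.ndarray,
                  res_seq0: int) -> list[tuple]:
    """Instantiate one ligand extending radially along unit vector u.

    Returns tuples (name, element, res_name, res_seq, position, charge).
    """
    # an arbitrary-but-deterministic transverse axis for off-axis beads
    ref = np.array([0.0, 0.0, 1.0]) if abs(u[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    v = np.cross(u, ref)
    v /= np.linalg.norm(v)
    w = np.cross(u, v)
    out = []
    if ltype in _LIGAND_BEADS:
        resn = _LIGAND_RESNAME[ltype]
        for name, el, off, q in _LIGAND_BEADS[ltype]:
            out.append((name, el, resn, res_seq0, origin + off * u, q))
    elif ltype == "Neu-lig":
        resn = _LIGAND_RESNAME[ltype]
        for name, el, off, q in _LIGAND_BEADS["Pos-lig"][:3]:
            out.append((name, el, resn, res_seq0, origin + off * u, q))
        ring_center = origin + (9.0 + _NQ_RING_RADIUS) * u
        for k in range(6):
            ang = k * math.pi / 3.0
            p = ring_center + _NQ_RING_RADIUS * (math.cos(ang) * u + math.sin(ang) * v)
            out.append((f"CR{k+1}", "C", resn, res_seq0, p, 0.0))
    elif ltype == "Pep-lig":
        for i, res in enumerate(PEP_LIG_SEQUENCE):
            rs = res_seq0 + i
            ca = origin + (2.4 + i * _PEP_CA_STEP) * u
            if res == "CYS":
                out.append(("SG", "S", res, rs, origin, 0.0))
            out.append(("CA", "C", res, rs, ca, 0.0))
            if res != "CYS":
                side = v if i % 2 == 0 else w
                q = float(RESIDUE_CHARGES[res])
                out.append(("CB", "C", res, rs, ca + 1.5 * side, q))
    else:  # pragma: no cover - guarded by NPSpec validation
        raise ValueError(f"unknown ligand type {ltype!r}")
    return out


def _site_types(spec: NPSpec, sites: np.ndarray) -> list[str]:
    """Assign a ligand type to each attachment site.

    Homogeneous placement interleaves the types evenly along the Fibonacci
    ordering (largest-deficit round robin); janus placement splits the sites
    by z-coordinate so one type occupies each hemisphere exactly.
    """
    types = sorted(spec.composition)
    if spec.placement == "janus":
        t_top, t_bot = types[0], types[1]
        n_top = spec.composition[t_top]
        order = np.argsort(-sites[:, 2])  # descending z
        assignment = [""] * len(sites)
        for rank, site in enumerate(order):
            assignment[site] = t_top if rank < n_top else t_bot
        return assignment
    quota = {t: spec.composition[t] for t in types}
    total = spec.n_ligands
    assigned = {t: 0 for t in types}
    assignment = []
    for k in range(total):
        # pick the type furthest behind its target share
        best = max(types, key=lambda t: quota[t] * (k + 1) / total - assigned[t])
        assignment.append(best)
        assigned[best] += 1
    return assignment


def build_nanoparticle(spec: NPSpec) -> StructureModel:
    """Build a ligated gold-core nanoparticle.

    Gold atoms carry exactly zero charge and uniform nearest-neighbour bonds
    of ``au_bond_length``.  Ligand anchor (thiol) sites sit on a deterministic
    spherical Fibonacci lattice just above the shell; each ligand extends
    radially outward.  The ligand map records (ligand_type, atom indices) per
    ligand id.
    """
    core, _bonds = icosahedral_gold_shell(spec.core_diameter, spec.au_bond_length)
    core_radius = float(np.max(np.linalg.norm(core, axis=1)))
    sites_u = fibonacci_sphere(spec.n_ligands)
    site_types = _site_types(spec, sites_u)

    names = [f"AU" for _ in core]
    elements = ["AU"] * len(core)
    res_names = ["AUC"] * len(core)
    res_seq = [1] * len(core)
    chain_ids = ["9"] * len(core)
    charges = [0.0] * len(core)
    positions = [c for c in core]
    ligand_map: dict[int, tuple[str, np.ndarray]] = {}

    cursor = len(core)
    res_cursor = 1
    for lig_id, (u, ltype) in enumerate(zip(sites_u, site_types)):
        origin = (core_radius + _AU_S_BOND) * u
        atoms = _ligand_atoms(ltype, origin, u, res_cursor)
        res_cursor = max(a[3] for a in atoms) + 1
        idx = []
        for name, el, resn, rs, pos, q in atoms:
            names.append(name)
            elements.append(el)
            res_names.append(resn)
            res_seq.append(rs)
            chain_ids.append("8")
            charges.append(q)
            positions.append(pos)
            idx.append(cursor)
            cursor += 1
        ligand_map[lig_id] = (ltype, np.asarray(idx, dtype=int))

    model = StructureModel.from_arrays(
        names=names, elements=elements, res_names=res_names, res_seq=res_seq,
        chain_ids=chain_ids, positions=np.asarray(positions, dtype=float),
        charges=charges, role_tag="nanoparticle", ligand_map=ligand_map,
    )
    model.assign_default_radii()
    _assign_default_lj(model)
    model.validate()
    return model


def _assign_default_lj(model: StructureModel) -> None:
    for el, (eps, rmh) in DEFAULT_LJ.items():
        mask = np.char.upper(model.elements.astype(str)) == el
        model.lj_epsilon[mask] = eps
        model.lj_rmin_half[mask] = rmh


# ---------------------------------------------------------------------------
# trajectory synthesis
# ---------------------------------------------------------------------------

@dataclass
class DriftSpec:
    """Rigid-body motion applied cumulatively per frame to a sub-structure."""

    atom_indices: np.ndarray
    translation_per_frame: tuple[float, float, float] = (0.0, 0.0, 0.0)
    rotation_deg_per_frame: float = 0.0
    rotation_axis: tuple[float, float, float] = (0.0, 0.0, 1.0)


def synthesize_trajectory(model: StructureModel, n_frames: int,
                          noise_sigma: float = 0.0,
                          drift: DriftSpec | None = None,
                          rng_seed: int = 0,
                          frame_dt: float = 10.0) -> Trajectory:
    """Frames of i.i.d. Gaussian noise around the reference coordinates.

    With the default ``frame_dt`` = 10 ps, 500 frames span 5 ns.  The result
    is bit-reproducible under ``rng_seed``.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be non-negative")
    rng = np.random.default_rng(rng_seed)
    ref = model.positions
    frames = np.empty((n_frames, model.n_atoms, 3))
    for i in range(n_frames):
        frame = ref.copy()
        if drift is not None:
            idx = np.asarray(drift.atom_indices, dtype=int)
            sub = frame[idx]
            if drift.rotation_deg_per_frame:
                axis = np.asarray(drift.rotation_axis, dtype=float)
                axis /= np.linalg.norm(axis)
                ang = math.radians(drift.rotation_deg_per_frame * i)
                c, s = math.cos(ang), math.sin(ang)
                center = sub.mean(axis=0)
                rel = sub - center
                sub = (center + rel * c + np.cross(axis, rel) * s
                       + np.outer(rel @ axis, axis) * (1.0 - c))
            sub = sub + np.asarray(drift.translation_per_frame) * i
            frame[idx] = sub
        if noise_sigma > 0:
            frame = frame + rng.normal(0.0, noise_sigma, frame.shape)
        frames[i] = frame
    return Trajectory(topology=model, frames=frames, frame_dt=frame_dt)


# ---------------------------------------------------------------------------
# posing helpers
# ---------------------------------------------------------------------------

def place_near(mobile: StructureModel, reference: StructureModel,
               target_indices: np.ndarray, gap: float = 3.0) -> StructureModel:
    """Translate ``mobile`` so it sits ``gap`` Å outside ``reference``.

    The mobile structure is placed along the outward direction from the
    reference centroid through the centroid of the target atoms, at a
    distance that leaves about ``gap`` Å between the closest surfaces.
    """
    target_indices = np.asarray(target_indices, dtype=int)
    if target_indices.size == 0:
        raise ValueError("empty target selection")
    target = reference.positions[target_indices].mean(axis=0)
    direction = target - reference.positions.mean(axis=0)
    norm = np.linalg.norm(direction)
    if norm < 1e-9:
        direction = np.array([0.0, 0.0, 1.0])
    else:
        direction = direction / norm
    center = mobile.positions.mean(axis=0)
    radius = float(np.max(np.linalg.norm(mobile.positions - center, axis=1)))
    new_center = target + direction * (radius + gap)
    moved = mobile.copy()
    moved.positions = mobile.positions - center + new_center
    # the mobile structure is not a sphere: back off along the approach
    # direction until the closest center-to-center distance is >= gap
    from scipy.spatial import cKDTree
    tree = cKDTree(reference.positions)
    for _ in range(50):
        dmin = float(tree.query(moved.positions, k=1)[0].min())
        if dmin >= gap - 1e-9:
            break
        moved.positions = moved.positions + direction * (gap - dmin)
    return moved
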