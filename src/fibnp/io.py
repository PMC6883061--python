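"""Readers and writers for PDB, PQR, XYZ/multi-model-PDB trajectories, and
the nonbonded parameter table.

File parsing and formatting is delegated to MDAnalysis; this module converts
between MDAnalysis universes and :class:`~fibnp.model.StructureModel` /
:class:`~fibnp.model.Trajectory` and enforces the dialect contracts used
throughout the package (TER after each chain, 3-decimal coordinates, verbatim
1-based residue numbering).
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .model import MissingParameterError, Peptide, StructureModel, Trajectory

__all__ = [
    "read_structure",
    "write_structure",
    "read_trajectory",
    "write_trajectory",
    "load_lj_table",
    "assign_lj_params",
]


def _mda():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        import MDAnalysis as mda
    return mda


def _infer_format(path: str | Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt.lower()
    suffix = Path(path).suffix.lower().lstrip(".")
    if suffix in ("pdb", "pqr", "xyz"):
        return suffix
    raise ValueError(f"cannot infer format from {path!r}; pass format=...")


# --------------------------------------------------------------------------
# structures
# --------------------------------------------------------------------------

def read_structure(path: str | Path, format: str | None = None,
                   role_tag: str = "fibril") -> StructureModel:
    """Read a PDB or PQR file into a StructureModel.

    Atoms keep file order and verbatim residue numbering.  PQR supplies
    per-atom charge and radius; PDB leaves them unset (NaN) so later analyses
    fail loudly rather than assuming zeros.  Each chain with a contiguous
    residue range becomes one peptide entry.
    """
    fmt = _infer_format(path, format)
    if fmt not in ("pdb", "pqr"):
        raise ValueError(f"unsupported structure format {fmt!r}")
    mda = _mda()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe(str(path))
    except Exception as exc:  # noqa: BLE001 - surface parser context
        raise ValueError(f"failed to parse {fmt.upper()} file {path}: {exc}") from exc
    atoms = u.atoms
    n = len(atoms)
    names = atoms.names if hasattr(atoms, "names") else np.array(["X"] * n)
    if hasattr(atoms, "elements"):
        elements = np.asarray(atoms.elements, dtype="U2")
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            from MDAnalysis.topology.guessers import guess_types
            elements = np.asarray(guess_types(names), dtype="U2")
    if hasattr(atoms, "chainIDs"):
        chains = np.asarray(atoms.chainIDs, dtype="U4")
    else:
        chains = np.asarray(atoms.segids, dtype="U4")
    charges = np.asarray(atoms.charges, float) if fmt == "pqr" else None
    radii = np.asarray(atoms.radii, float) if fmt == "pqr" else None
    model = StructureModel.from_arrays(
        names=np.asarray(names, dtype="U6"),
        elements=elements,
        res_names=np.asarray(atoms.resnames, dtype="U4"),
        res_seq=np.asarray(atoms.resids, dtype=int),
        chain_ids=chains,
        positions=np.asarray(atoms.positions, dtype=float),
        charges=charges,
        vdw_radii=radii,
        role_tag=role_tag,
    )
    model.peptides = _peptides_from_chains(model)
    return model


def _peptides_from_chains(model: StructureModel) -> list[Peptide]:
    peptides = []
    seen = []
    for cid in model.chain_ids:
        if cid not in seen:
            seen.append(cid)
    for cid in seen:
        rs = model.res_seq[model.chain_ids == cid]
        peptides.append(Peptide(str(cid), int(rs.min()), int(rs.max())))
    return peptides


def _to_universe(model: StructureModel):
    mda = _mda()
    n = model.n_atoms
    # residue grouping: consecutive (chain_id, res_seq) runs
    if n:
        key = np.array([f"{c}|{r}" for c, r in zip(model.chain_ids, model.res_seq)])
        new_res = np.concatenate([[True], key[1:] != key[:-1]])
        resindex = np.cumsum(new_res) - 1
        res_first = np.nonzero(new_res)[0]
        chain_per_res = model.chain_ids[res_first]
        new_seg = np.concatenate([[True], chain_per_res[1:] != chain_per_res[:-1]])
        segindex = np.cumsum(new_seg) - 1
        n_res, n_seg = int(resindex[-1]) + 1, int(segindex[-1]) + 1
    else:
        resindex = np.empty(0, int)
        res_first = np.empty(0, int)
        segindex = np.empty(0, int)
        n_res = n_seg = 1
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe.empty(
            n, n_residues=n_res, n_segments=n_seg,
            atom_resindex=resindex, residue_segindex=segindex, trajectory=True,
        )
        u.add_TopologyAttr("names", model.names)
        u.add_TopologyAttr("elements", model.elements)
        u.add_TopologyAttr("resnames", model.res_names[res_first] if n else ["UNK"])
        u.add_TopologyAttr("resids", model.res_seq[res_first] if n else [1])
        u.add_TopologyAttr("chainIDs", model.chain_ids)
        seg_first = res_first[np.unique(segindex, return_index=True)[1]] if n else []
        u.add_TopologyAttr(
            "segids", model.chain_ids[seg_first] if n else ["A"])
        charges = np.nan_to_num(model.charges, nan=0.0)
        radii = np.nan_to_num(model.vdw_radii, nan=0.0)
        u.add_TopologyAttr("charges", charges)
        u.add_TopologyAttr("radii", radii)
        if n:
            u.atoms.positions = model.positions
    return u


def write_structure(model: StructureModel, path: str | Path,
                    format: str | None = None) -> None:
    """Write a StructureModel as PDB or PQR.

    PDB uses fixed columns, 3-decimal coordinates, TER after each chain and a
    terminal END record.  PQR additionally requires per-atom charges and
    radii.  Strict PDB serial numbering caps at 99,999 atoms.
    """
    fmt = _infer_format(path, format)
    path = Path(path)
    if fmt == "pdb" and model.n_atoms > 99999:
        raise ValueError(
            "more than 99,999 atoms cannot be written in strict PDB serials; "
            "split the model or use a hybrid-36-capable tool"
        )
    if fmt == "pqr":
        model.require_charges()
        model.require_radii()
    if model.n_atoms == 0:
        path.write_text("END\n")
        return
    u = _to_universe(model)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if fmt == "pdb":
            u.atoms.write(str(path))
            _insert_ter(path, model)
        elif fmt == "pqr":
            u.atoms.write(str(path))
        else:
            raise ValueError(f"unsupported structure format {fmt!r}")


def _insert_ter(path: Path, model: StructureModel) -> None:
    """Re-emit the PDB with a TER record closing every chain."""
    lines = path.read_text().splitlines()
    out: list[str] = []
    chain_iter = iter(model.chain_ids)
    prev_chain = None
    last_atom_line = None
    for line in lines:
        if line.startswith(("ATOM", "HETATM")):
            chain = next(chain_iter)
            if prev_chain is not None and chain != prev_chain:
                out.append(_ter_record(last_atom_line))
            prev_chain = chain
            last_atom_line = line
            out.append(line)
        elif line.startswith("END"):
            if last_atom_line is not None:
                out.append(_ter_record(last_atom_line))
            out.append(line)
        elif line.startswith("TER"):
            continue
        else:
            out.append(line)
    path.write_text("\n".join(out) + "\n")


def _ter_record(atom_line: str | None) -> str:
    if atom_line is None:
        return "TER"
    serial = atom_line[6:11]
    return f"TER   {serial}      {atom_line[17:26]}"


# --------------------------------------------------------------------------
# trajectories
# --------------------------------------------------------------------------

def write_trajectory(traj: Trajectory, path: str | Path,
                     format: str | None = None) -> None:
    """Write frames as multi-frame XYZ (default) or multi-model PDB."""
    fmt = _infer_format(path, format)
    mda = _mda()
    u = _to_universe(traj.topology)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if fmt == "xyz":
            from MDAnalysis.coordinates.XYZ import XYZWriter
            with XYZWriter(str(path), n_atoms=traj.topology.n_atoms) as w:
                for frame in traj.frames:
                    u.atoms.positions = frame
                    w.write(u.atoms)
        elif fmt == "pdb":
            with mda.Writer(str(path), multiframe=True,
                            n_atoms=traj.topology.n_atoms) as w:
                for frame in traj.frames:
                    u.atoms.positions = frame
                    w.write(u.atoms)
        else:
            raise ValueError(f"unsupported trajectory format {fmt!r}")


def read_trajectory(topology: StructureModel, path: str | Path,
                    format: str | None = None, frame_dt: float = 10.0) -> Trajectory:
    """Read a multi-frame XYZ or multi-model PDB against a known topology."""
    _infer_format(path, format)  # validates the extension
    mda = _mda()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(path))
        if len(u.atoms) != topology.n_atoms:
            raise ValueError(
                f"trajectory {path} has {len(u.atoms)} atoms but topology has "
                f"{topology.n_atoms}"
            )
        frames = np.array([u.atoms.positions.copy() for _ in u.trajectory], dtype=float)
    return Trajectory(topology=topology, frames=frames, frame_dt=frame_dt)


# --------------------------------------------------------------------------
# nonbonded parameter table
# --------------------------------------------------------------------------

def load_lj_table(path: str | Path) -> dict[tuple[str, str], tuple[float, float]]:
    """Load a TSV of Lennard-Jones parameters.

    Columns: residue, atom, epsilon (kcal/mol), rmin_half (Å).  A residue of
    ``*`` marks an element-level fallback row keyed by the atom column.
    """
    df = pd.read_csv(path, sep="\t", comment="#",
                     names=["residue", "atom", "epsilon", "rmin_half"],
                     header=0 if _has_header(path) else None)
    table: dict[tuple[str, str], tuple[float, float]] = {}
    for row in df.itertuples(index=False):
        eps, rmh = float(row.epsilon), float(row.rmin_half)
        if eps < 0 or (eps > 0 and rmh <= 0):
            raise ValueError(f"invalid LJ parameters for {row.residue}/{row.atom}")
        table[(str(row.residue).upper(), str(row.atom).upper())] = (eps, rmh)
    return table


def _has_header(path: str | Path) -> bool:
    with open(path) as fh:
        for line in fh:
            if line.strip() and not line.startswith("#"):
                parts = line.split("\t")
                try:
                    float(parts[-1])
                    return False
                except ValueError:
                    return True
    return False


def assign_lj_params(model: StructureModel,
                     table: Mapping[tuple[str, str], tuple[float, float]],
                     strict: bool = False) -> int:
    """Assign LJ parameters by (residue, atom) with element fallback.

    Returns the number of atoms that remain unparameterized (0 when strict,
    otherwise they stay NaN and trip a later ``require_lj``).
    """
    missing = 0
    for i in range(model.n_atoms):
        key = (str(model.res_names[i]).upper(), str(model.names[i]).upper())
        fallback = ("*", str(model.elements[i]).upper())
        if key in table:
            eps, rmh = table[key]
        elif fallback in table:
            eps, rmh = table[fallback]
        else:
            missing += 1
            continue
        model.lj_epsilon[i] = eps
        model.lj_rmin_half[i] = rmh
    if strict and missing:
        raise MissingParameterError(
            f"{missing} atom(s) not covered by the LJ parameter table")
    return missing
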