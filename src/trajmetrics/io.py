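"""Readers and writers for the standard formats the package touches.

PDB handling is delegated to gemmi; this module only maps between gemmi's
hierarchy and the flat atom-table model used here.  Multi-MODEL files become
trajectories with one frame per MODEL and synthetic 0, 1, 2, ... ps times
unless real times are supplied.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd

from .core import Atom, Structure, Trajectory, element_mass, guess_element
from .errors import FormatError, PDBParseError, StructureError

__all__ = ["read_pdb", "write_pdb", "read_xyz_table"]

# PDB %8.3f coordinate fields hold magnitudes below 10^4 A.
_PDB_COORD_LIMIT = 1.0e4


def _atom_mass(g_atom: gemmi.Atom) -> tuple[str, float]:
    el = g_atom.element
    if el.name != "X" and el.weight > 0:
        return el.name, float(el.weight)
    symbol = guess_element(g_atom.name)
    return symbol, element_mass(symbol)


def _resolve_altlocs(residue: gemmi.Residue) -> list[gemmi.Atom]:
    """Keep one conformer per atom name: highest occupancy, ties to altloc 'A'
    (or the first conformer seen)."""
    by_name: dict[str, gemmi.Atom] = {}
    for g_atom in residue:
        prev = by_name.get(g_atom.name)
        if prev is None:
            by_name[g_atom.name] = g_atom
            continue
        if g_atom.occ > prev.occ or (
            g_atom.occ == prev.occ and g_atom.altloc == "A" and prev.altloc != "A"
        ):
            by_name[g_atom.name] = g_atom
    return list(by_name.values())


def _model_to_table(model: gemmi.Model) -> tuple[list[Atom], np.ndarray]:
    atoms: list[Atom] = []
    coords: list[list[float]] = []
    for chain in model:
        for residue in chain:
            for g_atom in _resolve_altlocs(residue):
                element, mass = _atom_mass(g_atom)
                atoms.append(
                    Atom(
                        serial=int(g_atom.serial),
                        name=g_atom.name,
                        element=element,
                        residue_name=residue.name,
                        residue_seq=int(residue.seqid.num),
                        chain_id=chain.name or "A",
                        mass=mass,
                        occupancy=float(g_atom.occ),
                        altloc=g_atom.altloc.strip("\x00 ") if g_atom.altloc else "",
                    )
                )
                coords.append([g_atom.pos.x, g_atom.pos.y, g_atom.pos.z])
    return atoms, np.asarray(coords, dtype=float)


def read_pdb(
    path: str | Path,
    model_policy: str = "first",
    times: np.ndarray | None = None,
) -> Structure | Trajectory:
    """Read a PDB entry.

    Parameters
    ----------
    path
        PDB file with at least one ATOM/HETATM record.
    model_policy
        ``"first"`` returns a :class:`Structure` from the first MODEL;
        ``"all"`` returns a :class:`Trajectory` with one frame per MODEL.
    times
        Optional frame times (ps) overriding the synthetic 0, 1, 2, ... ps
        default for multi-model files.
    """
    path = Path(path)
    if model_policy not in ("first", "all"):
        raise ValueError(f"model_policy must be 'first' or 'all', got {model_policy!r}")
    try:
        st = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:
        raise PDBParseError(f"{path}: {exc}") from exc
    if len(st) == 0:
        raise PDBParseError(f"{path}: no MODEL with ATOM records")

    ref_atoms, ref_coords = _model_to_table(st[0])
    if not ref_atoms:
        raise PDBParseError(f"{path}: no ATOM records")
    meta = {"source": str(path), "format": "pdb"}

    if model_policy == "first":
        return Structure(atoms=ref_atoms, coords=ref_coords, meta={**meta, "model": st[0].num})

    frames = [ref_coords]
    identity = [(a.name, a.residue_name, a.residue_seq, a.chain_id) for a in ref_atoms]
    for model in list(st)[1:]:
        atoms_k, coords_k = _model_to_table(model)
        ident_k = [(a.name, a.residue_name, a.residue_seq, a.chain_id) for a in atoms_k]
        if ident_k != identity:
            raise StructureError(
                f"{path}: MODEL {model.num} atom table differs from MODEL {st[0].num} "
                f"({len(atoms_k)} vs {len(ref_atoms)} atoms)"
            )
        frames.append(coords_k)
    frames_arr = np.stack(frames)
    if times is None:
        times = np.arange(frames_arr.shape[0], dtype=float)
    return Trajectory(atoms=ref_atoms, frames=frames_arr, times=np.asarray(times, float), meta=meta)


def write_pdb(obj: Structure | Trajectory, path: str | Path) -> None:
    """Write a structure or trajectory as a (multi-MODEL) PDB file.

    Coordinates round-trip at the PDB fixed-width precision of 3 decimals;
    magnitudes >= 10^4 A do not fit the format and raise :class:`FormatError`.
    """
    traj = obj.to_trajectory() if isinstance(obj, Structure) else obj
    if np.any(np.abs(traj.frames) >= _PDB_COORD_LIMIT):
        raise FormatError(
            f"coordinate magnitude >= {_PDB_COORD_LIMIT:g} A cannot be written "
            "in fixed-width PDB fields"
        )
    # Group rows into (chain, residue) runs once; gemmi copies on add_*, so
    # each gemmi object is completed before being attached.
    runs: list[tuple[str, int, str, list[int]]] = []
    for i, atom in enumerate(traj.atoms):
        if (
            runs
            and runs[-1][0] == atom.chain_id
            and runs[-1][1] == atom.residue_seq
            and runs[-1][2] == atom.residue_name
        ):
            runs[-1][3].append(i)
        else:
            runs.append((atom.chain_id, atom.residue_seq, atom.residue_name, [i]))

    st = gemmi.Structure()
    st.name = "trajmetrics"
    for k in range(traj.n_frames):
        model = gemmi.Model(str(k + 1))
        chain = None
        for chain_id, resseq, resname, idx in runs:
            residue = gemmi.Residue()
            residue.name = resname
            residue.seqid = gemmi.SeqId(resseq, " ")
            residue.het_flag = "A"
            for i in idx:
                atom = traj.atoms[i]
                g_atom = gemmi.Atom()
                g_atom.name = atom.name
                g_atom.element = gemmi.Element(atom.element)
                g_atom.pos = gemmi.Position(*traj.frames[k, i])
                g_atom.occ = atom.occupancy
                g_atom.b_iso = 0.0
                residue.add_atom(g_atom)
            if chain is None or chain.name != chain_id:
                if chain is not None:
                    model.add_chain(chain)
                chain = gemmi.Chain(chain_id)
            chain.add_residue(residue)
        if chain is not None:
            model.add_chain(chain)
        st.add_model(model)
    Path(path).write_text(st.make_pdb_string())


def read_xyz_table(path: str | Path) -> Trajectory:
    """Read a plain-text frame x atom coordinate table.

    Expected columns (comma- or whitespace-separated, with a header line):
    ``frame``, ``name``, ``resid``, ``x``, ``y``, ``z``; optional ``time``
    (ps), ``resname``, ``chain``, ``element``.  One row per (frame, atom);
    every frame must list the same atoms in the same order.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    df.columns = [str(c).strip().lower() for c in df.columns]
    required = {"frame", "name", "resid", "x", "y", "z"}
    missing = required - set(df.columns)
    if missing:
        raise StructureError(f"{path}: missing columns {sorted(missing)}")

    frame_ids = sorted(df["frame"].unique())
    groups = [df[df["frame"] == fid].reset_index(drop=True) for fid in frame_ids]
    first = groups[0]
    identity = list(zip(first["name"], first["resid"]))
    for fid, grp in zip(frame_ids, groups):
        if list(zip(grp["name"], grp["resid"])) != identity:
            raise StructureError(f"{path}: frame {fid} atom rows differ from frame {frame_ids[0]}")

    atoms = []
    for i, row in first.iterrows():
        element = str(row["element"]).strip() if "element" in df.columns else guess_element(str(row["name"]))
        atoms.append(
            Atom(
                serial=i + 1,
                name=str(row["name"]).strip(),
                element=element,
                residue_name=str(row.get("resname", "ALA")).strip(),
                residue_seq=int(row["resid"]),
                chain_id=str(row.get("chain", "A")).strip(),
                mass=element_mass(element),
            )
        )
    frames = np.stack([grp[["x", "y", "z"]].to_numpy(dtype=float) for grp in groups])
    if "time" in df.columns:
        times = np.array([float(grp["time"].iloc[0]) for grp in groups])
    else:
        warnings.warn(f"{path}: no time column; defaulting to 0, 1, 2, ... ps", stacklevel=2)
        times = np.arange(len(groups), dtype=float)
    return Trajectory(atoms=atoms, frames=frames, times=times, meta={"source": str(path), "format": "xyz_table"})
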