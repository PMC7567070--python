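"""Domain types for structures, trajectories and atom selections.

Internal units are angstrom for lengths and picoseconds for times.  Author
(PDB resSeq) residue numbering is authoritative throughout: the residue
quadruples used for helix-orientation metrics are addressed by it and no
renumbering ever happens.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import gemmi
import numpy as np

from .errors import SelectionError, StructureError

__all__ = [
    "Atom",
    "Structure",
    "Trajectory",
    "Selection",
    "select",
    "element_mass",
    "PRESET_SELECTIONS",
]


def element_mass(symbol: str) -> float:
    """Standard atomic mass (amu) for an element symbol.

    Single authoritative mass table for the whole package, so that the total
    mass M entering mass-weighted RMSD is consistent everywhere.
    """
    el = gemmi.Element(symbol.strip().capitalize() or "X")
    w = el.weight
    if el.name == "X" or not np.isfinite(w) or w <= 0:
        raise ValueError(f"unknown element symbol {symbol!r}")
    return float(w)


def guess_element(atom_name: str) -> str:
    """Infer an element symbol from a PDB atom name (fallback path only)."""
    stripped = re.sub(r"[0-9'\"]", "", atom_name).strip()
    if not stripped:
        raise ValueError(f"cannot infer element from atom name {atom_name!r}")
    # Two-letter symbols in protein context are rare; prefer the single
    # leading letter (CA is a carbon alpha, not calcium, in ATOM records).
    return stripped[0].upper()


@dataclass(frozen=True)
class Atom:
    """One atom of the shared atom table.

    ``residue_seq`` is the author numbering from the source file; ``mass`` is
    in amu and must be positive.
    """

    serial: int
    name: str
    element: str
    residue_name: str
    residue_seq: int
    chain_id: str
    mass: float
    occupancy: float = 1.0
    altloc: str = ""

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("atom name must be non-empty")
        if not (self.mass > 0 and np.isfinite(self.mass)):
            raise ValueError(f"atom mass must be positive and finite, got {self.mass}")
        if not np.isfinite(self.residue_seq):
            raise ValueError("residue_seq must be finite")


def _check_coords(coords: np.ndarray, n_atoms: int, label: str) -> np.ndarray:
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape != (n_atoms, 3):
        raise StructureError(
            f"{label}: expected coordinate shape ({n_atoms}, 3), got {coords.shape}"
        )
    if not np.all(np.isfinite(coords)):
        raise StructureError(f"{label}: non-finite coordinates")
    return coords


@dataclass
class Structure:
    """An atom table plus one coordinate set (N x 3, angstrom)."""

    atoms: list[Atom]
    coords: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = _check_coords(self.coords, len(self.atoms), "Structure")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.atoms])

    def to_trajectory(self, time: float = 0.0) -> "Trajectory":
        return Trajectory(
            atoms=list(self.atoms),
            frames=self.coords[None, :, :].copy(),
            times=np.array([time]),
            meta=dict(self.meta),
        )


@dataclass
class Trajectory:
    """An atom table shared by F coordinate frames (F x N x 3, angstrom).

    ``times`` are in picoseconds and strictly increasing.
    """

    atoms: list[Atom]
    frames: np.ndarray
    times: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise StructureError(
                f"Trajectory: expected (F, N, 3) frames with F >= 1, got {self.frames.shape}"
            )
        if self.frames.shape[1] != len(self.atoms) or self.frames.shape[2] != 3:
            raise StructureError(
                f"Trajectory: frames shape {self.frames.shape} does not match "
                f"{len(self.atoms)} atoms"
            )
        if not np.all(np.isfinite(self.frames)):
            raise StructureError("Trajectory: non-finite coordinates")
        if self.times.shape != (self.frames.shape[0],):
            raise StructureError("Trajectory: one time stamp per frame required")
        if self.n_frames > 1 and not np.all(np.diff(self.times) > 0):
            raise StructureError("Trajectory: times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.atoms])

    def frame(self, index: int) -> Structure:
        return Structure(
            atoms=list(self.atoms),
            coords=self.frames[index].copy(),
            meta={**self.meta, "frame_index": int(index)},
        )

    def window_mask(self, t_start: float, t_end: float) -> np.ndarray:
        """Boolean mask of frames with t_start <= t <= t_end."""
        return (self.times >= t_start) & (self.times <= t_end)


@dataclass(frozen=True)
class Selection:
    """A resolved atom selection: the expression plus sorted unique indices."""

    expression: str
    indices: np.ndarray

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices, dtype=int)
        object.__setattr__(self, "indices", idx)

    @property
    def n_atoms(self) -> int:
        return len(self.indices)


# Named presets; hydrogen atoms are never part of a preset.
PRESET_SELECTIONS: dict[str, frozenset[str]] = {
    "backbone": frozenset({"N", "CA", "C", "O"}),
    "calpha": frozenset({"CA"}),
}

_RESID_TOKEN = re.compile(r"^(-?\d+)(?:-(-?\d+))?$")


def _clause_mask(atoms: list[Atom], clause: str) -> np.ndarray:
    tokens = clause.split()
    if not tokens:
        raise SelectionError("empty clause in selection expression")
    head, args = tokens[0].lower(), tokens[1:]
    if head == "all" and not args:
        return np.ones(len(atoms), dtype=bool)
    if head in PRESET_SELECTIONS and not args:
        names = PRESET_SELECTIONS[head]
        return np.array(
            [a.name in names and a.element != "H" for a in atoms], dtype=bool
        )
    if head == "name":
        if not args:
            raise SelectionError("'name' clause needs at least one atom name")
        names = {t.upper() for t in args}
        return np.array([a.name.upper() in names for a in atoms], dtype=bool)
    if head == "resid":
        if not args:
            raise SelectionError("'resid' clause needs at least one residue number")
        wanted: set[int] = set()
        for tok in args:
            m = _RESID_TOKEN.match(tok)
            if m is None:
                raise SelectionError(f"bad resid token {tok!r}")
            lo = int(m.group(1))
            hi = int(m.group(2)) if m.group(2) is not None else lo
            if hi < lo:
                raise SelectionError(f"empty resid range {tok!r}")
            wanted.update(range(lo, hi + 1))
        return np.array([a.residue_seq in wanted for a in atoms], dtype=bool)
    if head == "chain":
        if not args:
            raise SelectionError("'chain' clause needs at least one chain id")
        chains = set(args)
        return np.array([a.chain_id in chains for a in atoms], dtype=bool)
    raise SelectionError(f"unknown selection clause {clause!r}")


def select(atoms: list[Atom] | Structure | Trajectory, expression: str) -> Selection:
    """Resolve a selection expression against an atom table.

    Grammar: clauses joined by ``and``; each clause is one of ``all``,
    ``backbone``, ``calpha``, ``name <names...>``, ``resid <n|a-b ...>``,
    ``chain <ids...>``.  Resolution is deterministic (sorted indices) and
    order-independent in the clauses.  An empty result is an error so that
    metrics can never silently run on zero atoms.
    """
    if isinstance(atoms, (Structure, Trajectory)):
        atoms = atoms.atoms
    mask = np.ones(len(atoms), dtype=bool)
    for clause in re.split(r"\band\b", expression):
        clause = clause.strip()
        if clause:
            mask &= _clause_mask(atoms, clause)
    if not mask.any():
        raise SelectionError(f"selection {expression!r} matched no atoms")
    return Selection(expression=expression, indices=np.flatnonzero(mask))
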