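"""Structure and trajectory I/O plus atom selection.

Coordinates are Cartesian and in angstroms throughout, as in the PDB;
no unit conversion happens anywhere downstream.  Two on-disk forms are
supported: fixed-column multi-model PDB (read-only, via gemmi) and a
lossless delimited "frame table" dialect (read/write) with the header

    frame,serial,name,element,resname,resnum,chain,x,y,z

used for synthetic trajectories and round-trip fixtures.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np
import pandas as pd

from .errors import (
    ParseError,
    SchemaError,
    SelectionSyntaxError,
    StructuralMismatchError,
)

#: residue names recognised as water unless the caller overrides them
DEFAULT_WATER_NAMES: tuple[str, ...] = ("HOH", "WAT", "SOL")

_FRAME_TABLE_COLUMNS = (
    "frame", "serial", "name", "element", "resname", "resnum", "chain",
    "x", "y", "z",
)


@dataclass(frozen=True)
class AtomRecord:
    """One atom of the shared roster.

    ``position`` is the coordinate of the atom in the first frame it was
    read from; per-frame coordinates live on the :class:`Trajectory`.
    """

    serial: int
    name: str
    element: str
    residue_name: str
    residue_number: int
    chain: str
    position: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if not self.element:
            raise ValueError(f"atom {self.serial} ({self.name}): empty element")
        if not all(np.isfinite(self.position)):
            raise ValueError(f"atom {self.serial} ({self.name}): non-finite position")

    @property
    def identity(self) -> tuple[int, str, int, str]:
        """Roster identity key: (serial, name, residue_number, chain)."""
        return (self.serial, self.name, self.residue_number, self.chain)


@dataclass
class Trajectory:
    """Ordered frames of coordinates over a constant atom roster.

    ``coords`` has shape ``(n_frames, n_atoms, 3)`` in angstroms.
    ``frame_times`` (ps), when present, must be strictly increasing and
    match the frame count.
    """

    roster: list[AtomRecord]
    coords: np.ndarray
    frame_times: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if self.coords.shape[0] < 1:
            raise ValueError("a trajectory needs at least one frame")
        if self.coords.shape[1] != len(self.roster):
            raise StructuralMismatchError(
                f"{self.coords.shape[1]} coordinates per frame but "
                f"{len(self.roster)} roster atoms"
            )
        serials = [a.serial for a in self.roster]
        if len(set(serials)) != len(serials):
            raise ValueError("duplicate atom serials in roster")
        if self.frame_times is not None:
            self.frame_times = np.asarray(self.frame_times, dtype=float)
            if len(self.frame_times) != self.n_frames:
                raise ValueError("frame_times length must equal frame count")
            if np.any(np.diff(self.frame_times) <= 0):
                raise ValueError("frame_times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return len(self.roster)


_NAME_ELEMENT_RE = re.compile(r"[A-Za-z]+")


def _element_from_name(name: str) -> str:
    """Infer an element symbol from an atom name (fallback path only)."""
    m = _NAME_ELEMENT_RE.search(name)
    if not m:
        return ""
    letters = m.group(0)
    # Two-letter elements in PDB atom names start in column 13; heuristically
    # accept known two-letter symbols, else take the first letter.
    two = letters[:2].capitalize()
    if len(letters) >= 2 and gemmi.Element(two).is_metal:
        return two
    if two in ("Cl", "Br", "Fe", "Se", "Zn", "Mg", "Mn", "Cu"):
        return two
    return letters[0].upper()


def _atoms_of_model(model: gemmi.Model) -> Iterable[tuple[AtomRecord, np.ndarray]]:
    for chain in model:
        for residue in chain:
            for atom in residue:
                elem = atom.element.name if atom.element.name != "X" else ""
                if not elem:
                    elem = _element_from_name(atom.name)
                pos = np.array([atom.pos.x, atom.pos.y, atom.pos.z])
                rec = AtomRecord(
                    serial=atom.serial,
                    name=atom.name,
                    element=elem,
                    residue_name=residue.name,
                    residue_number=residue.seqid.num,
                    chain=chain.name,
                    position=tuple(pos),
                )
                yield rec, pos


def read_multimodel_pdb(path: str | Path) -> Trajectory:
    """Read a (possibly multi-model) PDB file into a :class:`Trajectory`.

    One frame per MODEL block, in MODEL-number order; the roster is taken
    from the first model.  ATOM and HETATM records are both ingested.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        structure = gemmi.read_pdb(str(path), split_chain_on_ter=False)
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if len(structure) == 0:
        raise ParseError(f"{path}: no models found")
    roster: list[AtomRecord] = []
    frames: list[np.ndarray] = []
    for i, model in enumerate(structure):
        pairs = list(_atoms_of_model(model))
        if i == 0:
            roster = [rec for rec, _ in pairs]
            if not roster:
                raise ParseError(f"{path}: first model contains no atoms")
        elif len(pairs) != len(roster):
            raise StructuralMismatchError(
                f"model {model.num} has {len(pairs)} atoms, "
                f"first model has {len(roster)}"
            )
        frames.append(np.array([pos for _, pos in pairs]))
    return Trajectory(roster=roster, coords=np.stack(frames))


def read_frame_table(path: str | Path) -> Trajectory:
    """Read the delimited frame-table dialect (comma or tab separated)."""
    path = Path(path)
    try:
        table = pd.read_csv(path, sep=None, engine="python")
    except pd.errors.EmptyDataError as exc:
        raise ParseError(f"{path}: no frames (empty file)") from exc
    missing = [c for c in _FRAME_TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {', '.join(missing)}")
    if len(table) == 0:
        raise ParseError(f"{path}: no frames")
    frames: list[np.ndarray] = []
    roster: list[AtomRecord] = []
    ref_key: list[tuple] = []
    for k, (frame_idx, group) in enumerate(
        sorted(table.groupby("frame"), key=lambda kv: kv[0])
    ):
        key = list(
            zip(group["serial"], group["name"], group["resnum"], group["chain"])
        )
        if k == 0:
            ref_key = key
            roster = [
                AtomRecord(
                    serial=int(r.serial),
                    name=str(r.name),
                    element=str(r.element),
                    residue_name=str(r.resname),
                    residue_number=int(r.resnum),
                    chain=str(r.chain),
                    position=(float(r.x), float(r.y), float(r.z)),
                )
                for r in group.itertuples()
            ]
        elif key != ref_key:
            raise StructuralMismatchError(
                f"frame {frame_idx}: roster differs from first frame"
            )
        frames.append(group[["x", "y", "z"]].to_numpy(dtype=float))
    return Trajectory(roster=roster, coords=np.stack(frames))


def write_frame_table(
    trajectory: Trajectory, path: str | Path, digits: int = 3, sep: str = ","
) -> None:
    """Write a trajectory in the frame-table dialect (coordinates rounded
    to ``digits`` decimals; the round-trip is lossless at that precision)."""
    rows = []
    for f in range(trajectory.n_frames):
        for i, a in enumerate(trajectory.roster):
            x, y, z = trajectory.coords[f, i]
            rows.append(
                (f, a.serial, a.name, a.element, a.residue_name,
                 a.residue_number, a.chain,
                 round(float(x), digits), round(float(y), digits),
                 round(float(z), digits))
            )
    frame = pd.DataFrame(rows, columns=_FRAME_TABLE_COLUMNS)
    frame.to_csv(path, sep=sep, index=False, float_format=f"%.{digits}f")


_FIELD_ALIASES = {
    "name": "name",
    "element": "element",
    "residue_name": "residue_name",
    "resname": "residue_name",
    "residue_number": "residue_number",
    "resnum": "residue_number",
    "chain": "chain",
}

_CLAUSE_RE = re.compile(r"^\s*(\w+)\s*=\s*(\S+)\s*$")


def select(trajectory: Trajectory, expr: str) -> np.ndarray:
    """Resolve a selection expression to roster indices (ascending).

    The expression is a conjunction of equality tests joined by ``and``
    (or ``&``), e.g. ``"element=O and resname=HOH"``.  Matching nothing
    returns an empty array, not an error.
    """
    if not expr or not expr.strip():
        raise SelectionSyntaxError("empty selection expression")
    clauses = re.split(r"\band\b|&", expr)
    tests: list[tuple[str, str]] = []
    for clause in clauses:
        m = _CLAUSE_RE.match(clause)
        if not m:
            raise SelectionSyntaxError(f"malformed clause: {clause.strip()!r}")
        fieldname, value = m.group(1), m.group(2)
        if fieldname not in _FIELD_ALIASES:
            raise SelectionSyntaxError(
                f"unknown field {fieldname!r}; expected one of "
                f"{sorted(set(_FIELD_ALIASES))}"
            )
        tests.append((_FIELD_ALIASES[fieldname], value))
    hits = []
    for i, atom in enumerate(trajectory.roster):
        ok = True
        for fieldname, value in tests:
            actual = getattr(atom, fieldname)
            if fieldname == "residue_number":
                try:
                    ok = actual == int(value)
                except ValueError as exc:
                    raise SelectionSyntaxError(
                        f"residue_number test needs an integer, got {value!r}"
                    ) from exc
            else:
                ok = str(actual) == value
            if not ok:
                break
        if ok:
            hits.append(i)
    return np.array(hits, dtype=int)


def water_oxygen_indices(
    trajectory: Trajectory, water_names: Sequence[str] = DEFAULT_WATER_NAMES
) -> np.ndarray:
    """Indices of water oxygens (residue name in ``water_names``)."""
    names = set(water_names)
    return np.array(
        [
            i
            for i, a in enumerate(trajectory.roster)
            if a.residue_name in names and a.element == "O"
        ],
        dtype=int,
    )
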