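"""Superposition-based comparison of P450-steroid complex structures.

Pairs C-alpha atoms between two complexes by (chain, residue number) —
appropriate when the structures share one protein sequence — superposes
them by least squares, and reports the minimised C-alpha RMSD.  Ligand
atoms can then be compared across complexes in the common frame, e.g.
the position of C15 of one steroid against C16 of another.

Alternate locations: only blank or 'A' altlocs are kept, for
determinism.  Waters are excluded from the protein set; the heme is kept
as context but never enters the RMSD.
"""

from __future__ import annotations

import urllib.request
from dataclasses import dataclass
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd

from .errors import InsufficientPointsError, LookupError_
from .geometry import SuperpositionResult, kabsch
from .structio import DEFAULT_WATER_NAMES, AtomRecord

_HEME_NAMES = ("HEM", "HEC", "HEA", "HEB")


@dataclass
class ComplexStructure:
    """Protein + ligand atoms of one P450-steroid complex."""

    identifier: str
    protein_atoms: list[AtomRecord]
    ligand_atoms: list[AtomRecord]

    def calpha(self) -> list[AtomRecord]:
        return [a for a in self.protein_atoms if a.name == "CA" and a.element == "C"]

    @classmethod
    def from_pdb(
        cls,
        path: str | Path,
        identifier: str | None = None,
        ligand_resnames: tuple[str, ...] | None = None,
        chains: tuple[str, ...] | None = None,
    ) -> "ComplexStructure":
        """Load a single-model PDB file.

        Protein atoms are polymer ATOM records; ligand atoms are HETATMs
        that are neither water nor heme, unless ``ligand_resnames``
        restricts them explicitly.  ``chains`` limits both sets.
        """
        structure = gemmi.read_pdb(str(path), split_chain_on_ter=False)
        structure.setup_entities()
        model = structure[0]
        protein: list[AtomRecord] = []
        ligand: list[AtomRecord] = []
        for chain in model:
            if chains is not None and chain.name not in chains:
                continue
            for residue in chain:
                for atom in residue:
                    if atom.altloc not in ("\0", "", "A"):
                        continue
                    rec = AtomRecord(
                        serial=atom.serial,
                        name=atom.name,
                        element=atom.element.name,
                        residue_name=residue.name,
                        residue_number=residue.seqid.num,
                        chain=chain.name,
                        position=(atom.pos.x, atom.pos.y, atom.pos.z),
                    )
                    if residue.name in DEFAULT_WATER_NAMES:
                        continue
                    is_het = residue.het_flag == "H"
                    if is_het and residue.name not in _HEME_NAMES:
                        if ligand_resnames is None or residue.name in ligand_resnames:
                            ligand.append(rec)
                    elif not is_het:
                        protein.append(rec)
        name = identifier or Path(path).stem.upper()
        return cls(identifier=name, protein_atoms=protein, ligand_atoms=ligand)


def fetch_pdb(pdb_id: str, dest_dir: str | Path, timeout: float = 30.0) -> Path:
    """Download a PDB entry from RCSB (convenience only; analyses accept
    local paths and never require network access)."""
    dest_dir = Path(dest_dir)
    dest_dir.mkdir(parents=True, exist_ok=True)
    dest = dest_dir / f"{pdb_id.lower()}.pdb"
    if not dest.exists():
        url = f"https://files.rcsb.org/download/{pdb_id.upper()}.pdb"
        with urllib.request.urlopen(url, timeout=timeout) as r:
            dest.write_bytes(r.read())
    return dest


def map_calpha(
    a: ComplexStructure, b: ComplexStructure
) -> tuple[list[int], list[int], pd.DataFrame]:
    """Pair C-alpha atoms of two complexes by (chain, residue number).

    Returns index lists into each structure's ``protein_atoms`` plus a
    report of unmatched residues.
    """
    ca_a = {( at.chain, at.residue_number): i
            for i, at in enumerate(a.protein_atoms)
            if at.name == "CA" and at.element == "C"}
    ca_b = {(at.chain, at.residue_number): i
            for i, at in enumerate(b.protein_atoms)
            if at.name == "CA" and at.element == "C"}
    shared = sorted(set(ca_a) & set(ca_b))
    if len(shared) < 3:
        raise InsufficientPointsError(
            f"{a.identifier} vs {b.identifier}: only {len(shared)} shared "
            "C-alpha residues"
        )
    only_a = sorted(set(ca_a) - set(ca_b))
    only_b = sorted(set(ca_b) - set(ca_a))
    report = pd.DataFrame(
        {
            "which": ["a"] * len(only_a) + ["b"] * len(only_b),
            "chain": [k[0] for k in only_a + only_b],
            "residue_number": [k[1] for k in only_a + only_b],
        }
    )
    return [ca_a[k] for k in shared], [ca_b[k] for k in shared], report


def superpose(a: ComplexStructure, b: ComplexStructure) -> SuperpositionResult:
    """Superpose b's mapped C-alpha set onto a's; returns the transform
    carrying b-frame coordinates into a's frame."""
    idx_a, idx_b, _ = map_calpha(a, b)
    pa = np.array([a.protein_atoms[i].position for i in idx_a])
    pb = np.array([b.protein_atoms[i].position for i in idx_b])
    return kabsch(pb, pa)


def calpha_rmsd(a: ComplexStructure, b: ComplexStructure) -> float:
    """Minimised C-alpha RMSD between two complexes (angstrom)."""
    return superpose(a, b).rmsd


def ligand_atom_correspondence(
    a: ComplexStructure, b: ComplexStructure, atom_a: str, atom_b: str
) -> float:
    """Distance between named ligand atoms after protein superposition.

    b's protein is superposed onto a's, b's ligand atom is carried along,
    and the distance to a's ligand atom is returned (angstrom).
    """
    def find(struct: ComplexStructure, name: str) -> np.ndarray:
        for at in struct.ligand_atoms:
            if at.name == name:
                return np.asarray(at.position, float)
        available = sorted({at.name for at in struct.ligand_atoms})
        raise LookupError_(
            f"{struct.identifier}: no ligand atom {name!r}; available: "
            f"{', '.join(available) or '(none)'}"
        )

    pa = find(a, atom_a)
    pb = find(b, atom_b)
    sup = superpose(a, b)
    return float(np.linalg.norm(sup.transform(pb) - pa))


def comparison_report(
    reference: ComplexStructure, others: list[ComplexStructure]
) -> pd.DataFrame:
    """C-alpha RMSD of a reference complex against each other complex."""
    rows = []
    for other in others:
        idx_a, idx_b, _ = map_calpha(reference, other)
        rows.append(
            (
                f"{reference.identifier} vs {other.identifier}",
                len(idx_a),
                calpha_rmsd(reference, other),
            )
        )
    return pd.DataFrame(rows, columns=["pair", "n_mapped", "rmsd_A"])
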