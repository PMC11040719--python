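"""Minimal heavy-atom structure model and PDB/mmCIF I/O.

Parsing is delegated to gemmi; the in-memory model keeps only what the
interface pipeline needs: heavy atoms of standard amino-acid polymer
residues, grouped per chain, with altlocs already resolved.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import gemmi
import numpy as np

from .errors import EmptyStructureError, ParseError
from .geometry import RigidTransform

__all__ = [
    "AtomRecord",
    "Structure",
    "parse_structure",
    "write_aligned",
    "transform_structure",
    "STANDARD_RESIDUES",
    "BACKBONE_ATOMS",
]

STANDARD_RESIDUES = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL UNK".split()
)
BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})


@dataclass(frozen=True)
class AtomRecord:
    """One heavy atom of a polymer residue."""

    serial: int
    atom_name: str
    element: str
    residue_name: str
    residue_seq: int
    icode: str
    chain_id: str
    coords: np.ndarray
    is_backbone: bool
    altloc: str = ""

    def __post_init__(self) -> None:
        xyz = np.asarray(self.coords, dtype=float).reshape(3)
        if not np.all(np.isfinite(xyz)):
            raise ValueError(f"non-finite coordinates for atom {self.atom_name}")
        object.__setattr__(self, "coords", xyz)

    @property
    def residue_id(self) -> tuple[int, str]:
        return (self.residue_seq, self.icode)


@dataclass
class Structure:
    """A protein complex: ordered chains of heavy-atom records."""

    structure_id: str
    chains: dict[str, list[AtomRecord]]
    source_format: str = "PDB"

    def chain_ids(self) -> list[str]:
        return list(self.chains)

    def chain_coords(self, chain_id: str) -> np.ndarray:
        return np.array([a.coords for a in self.chains[chain_id]], dtype=float)

    def residues(self, chain_id: str) -> dict[tuple[int, str], list[AtomRecord]]:
        """Atoms grouped per residue, preserving author order."""
        out: dict[tuple[int, str], list[AtomRecord]] = {}
        for atom in self.chains[chain_id]:
            out.setdefault(atom.residue_id, []).append(atom)
        return out


def _coor_format(path: Path, format_hint: str | None) -> gemmi.CoorFormat:
    if format_hint:
        hint = format_hint.lower()
        if hint in ("pdb",):
            return gemmi.CoorFormat.Pdb
        if hint in ("cif", "mmcif"):
            return gemmi.CoorFormat.Mmcif
        raise ValueError(f"unknown format hint: {format_hint!r}")
    return gemmi.CoorFormat.Detect


def parse_structure(path: str | Path, format_hint: str | None = None) -> Structure:
    """Read a PDB or mmCIF file into the heavy-atom model.

    Hydrogens/deuteriums, waters and non-polymer heteroatoms are dropped;
    only residues of the 20 standard amino acids plus UNK are kept.
    Alternate locations are resolved to the highest-occupancy conformer
    (ties broken by the alphabetically first altloc id).
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    try:
        st = gemmi.read_structure(str(path), format=_coor_format(path, format_hint))
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0:
        raise EmptyStructureError(f"{path}: no models")

    fmt = "mmCIF" if st.input_format == gemmi.CoorFormat.Mmcif else "PDB"
    model = st[0]
    chains: dict[str, list[AtomRecord]] = {}
    serial = 0
    for chain in model:
        records: list[AtomRecord] = []
        for residue in chain:
            if residue.name not in STANDARD_RESIDUES:
                continue
            # resolve altlocs per atom name: highest occupancy, then altloc id
            by_name: dict[str, list[gemmi.Atom]] = {}
            for atom in residue:
                if atom.element.is_hydrogen:
                    continue
                by_name.setdefault(atom.name, []).append(atom)
            for name, alts in by_name.items():
                atom = sorted(alts, key=lambda a: (-a.occ, a.altloc or "~"))[0]
                serial += 1
                records.append(
                    AtomRecord(
                        serial=serial,
                        atom_name=name,
                        element=atom.element.name.upper(),
                        residue_name=residue.name,
                        residue_seq=residue.seqid.num,
                        icode=(residue.seqid.icode or "").strip(),
                        chain_id=chain.name,
                        coords=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                        is_backbone=name in BACKBONE_ATOMS,
                        altloc=atom.altloc or "",
                    )
                )
        if records:
            if chain.name in chains:
                chains[chain.name].extend(records)
            else:
                chains[chain.name] = records
    if not chains:
        raise EmptyStructureError(f"{path}: no polymer protein chains after filtering")
    return Structure(structure_id=st.name or path.stem, chains=chains, source_format=fmt)


def transform_structure(structure: Structure, transform: RigidTransform) -> Structure:
    """Return a copy with every coordinate mapped through ``transform``."""
    chains = {
        cid: [replace(a, coords=transform.apply(a.coords)) for a in atoms]
        for cid, atoms in structure.chains.items()
    }
    return Structure(structure.structure_id, chains, structure.source_format)


def _pdb_atom_name(atom: AtomRecord) -> str:
    # columns 13-16: element right-aligned in 13-14 for one-letter elements
    name = atom.atom_name
    if len(name) >= 4:
        return name[:4]
    if len(atom.element) == 1:
        return f" {name:<3s}"
    return f"{name:<4s}"


def write_pdb(structure: Structure, path: str | Path, remarks: list[str] | None = None) -> None:
    """Write the model as a standard PDB file (heavy atoms only)."""
    lines: list[str] = []
    for remark in remarks or []:
        lines.append(f"REMARK 300 {remark}")
    serial = 0
    for cid, atoms in structure.chains.items():
        for a in atoms:
            serial += 1
            x, y, z = a.coords
            if not all(abs(v) < 10000 for v in (x, y, z)):
                raise ValueError("coordinate out of PDB fixed-width range")
            lines.append(
                f"ATOM  {serial:5d} {_pdb_atom_name(a)} {a.residue_name:>3s} "
                f"{cid[:1]:1s}{a.residue_seq:4d}{(a.icode or ' ')[:1]}   "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}          "
                f"{a.element:>2s}"
            )
        serial += 1
        last = atoms[-1]
        lines.append(
            f"TER   {serial:5d}      {last.residue_name:>3s} "
            f"{cid[:1]:1s}{last.residue_seq:4d}{(last.icode or ' ')[:1]}"
        )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def write_aligned(structure: Structure, transform: RigidTransform, path: str | Path) -> None:
    """Write the structure with ``transform`` applied, as PDB.

    The applied rotation and translation are recorded in REMARK 300 lines
    (6 decimals) so the motion can be replayed or inverted later.
    """
    R = transform.rotation
    t = transform.translation
    remarks = ["ALIGNMENT TRANSFORM  X' = R * X + T"]
    for i in range(3):
        remarks.append(f"R{i + 1} {R[i, 0]:12.6f} {R[i, 1]:12.6f} {R[i, 2]:12.6f}")
    remarks.append(f"T  {t[0]:12.6f} {t[1]:12.6f} {t[2]:12.6f}")
    write_pdb(transform_structure(structure, transform), path, remarks=remarks)
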