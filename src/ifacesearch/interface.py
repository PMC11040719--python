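"""Interface modelling: contact detection, point reduction, pharmacophore typing.

An interface is defined atom-wise: every heavy atom of one chain within a
distance cutoff (default 4.5 A) of any heavy atom of the partner chain
belongs to that chain's side of the interface.  Each side can then be
reduced to one of three point representations:

``calpha``
    one point per interface residue, at its alpha carbon (default);
``restricted``
    heteroatoms (O/N/S), aromatic ring centres of His/Phe/Trp/Tyr, and
    hydrophobic side-chain carbons of Ala/Ile/Leu/Lys/Met/Pro/Val;
``all``
    every heavy atom plus aromatic ring centres.

In the ``restricted`` and ``all`` modes, atom points are additionally
filtered to those solvent-exposed on the isolated (unbound) chain; ring
centres are kept irrespective of exposure.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import cKDTree

from .errors import NoInterfaceError
from .sasa import shrake_rupley_sasa
from .structures import AtomRecord, Structure

__all__ = [
    "PTYPES",
    "InterfacePoint",
    "ChainInterface",
    "InterfacePair",
    "extract_interface",
    "one_sided_interface",
    "compute_solvent_exposure",
    "reduce_points",
    "model_interface",
    "assign_pharmacophore",
    "classify_atom",
    "residue_class_of",
]

# pharmacophore type alphabet; "Ca" denotes the alpha-carbon type
PT_ACCDON = "Acc/Don"
PT_ACC = "Acc"
PT_DON = "Don"
PT_ARO = "Aro"
PT_HYPHOB = "HyPhob"
PT_CA = "Ca"
PT_POSDON = "Pos/Don"
PT_NEGACC = "Neg/Acc"
PT_OTHER = "Other"
PTYPES = (PT_ACCDON, PT_ACC, PT_DON, PT_ARO, PT_HYPHOB, PT_CA, PT_POSDON, PT_NEGACC)

_RESIDUE_CLASS = {
    **{r: "hydrophobic" for r in ("ALA", "VAL", "LEU", "ILE", "MET", "PRO", "GLY")},
    **{r: "aromatic" for r in ("PHE", "TRP", "TYR", "HIS")},
    **{r: "polar" for r in ("SER", "THR", "ASN", "GLN", "CYS")},
    **{r: "positive" for r in ("LYS", "ARG")},
    **{r: "negative" for r in ("ASP", "GLU")},
    "UNK": "special",
}

RING_ATOMS = {
    "PHE": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TYR": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TRP": ("CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
    "HIS": ("CG", "ND1", "CD2", "CE1", "NE2"),
}

# hydrophobic side-chain carbons eligible as "restricted" points
HYDROPHOBIC_CARBONS = {
    "ALA": ("CB",),
    "ILE": ("CB", "CG1", "CG2", "CD1"),
    "LEU": ("CB", "CG", "CD1", "CD2"),
    "LYS": ("CB", "CG", "CD"),
    "MET": ("CB", "CG", "CE"),
    "PRO": ("CB", "CG", "CD"),
    "VAL": ("CB", "CG1", "CG2"),
}

# explicit side-chain assignments; checked before element fallbacks
_SIDECHAIN_TYPES = {
    ("ASN", "OD1"): PT_ACC,
    ("GLN", "OE1"): PT_ACC,
    ("MET", "SD"): PT_ACC,
    ("TRP", "NE1"): PT_DON,
    ("ASN", "ND2"): PT_DON,
    ("GLN", "NE2"): PT_DON,
    ("SER", "OG"): PT_ACCDON,
    ("THR", "OG1"): PT_ACCDON,
    ("TYR", "OH"): PT_ACCDON,
    ("HIS", "ND1"): PT_ACCDON,
    ("HIS", "NE2"): PT_ACCDON,
    ("CYS", "SG"): PT_ACCDON,
    ("LYS", "NZ"): PT_POSDON,
    ("ARG", "NE"): PT_POSDON,
    ("ARG", "NH1"): PT_POSDON,
    ("ARG", "NH2"): PT_POSDON,
    ("ASP", "OD1"): PT_NEGACC,
    ("ASP", "OD2"): PT_NEGACC,
    ("GLU", "OE1"): PT_NEGACC,
    ("GLU", "OE2"): PT_NEGACC,
}


def residue_class_of(residue_name: str) -> str:
    return _RESIDUE_CLASS.get(residue_name, "special")


def classify_atom(residue_name: str, atom_name: str, element: str, is_backbone: bool) -> str:
    """Pharmacophore type of one heavy atom (ring centres handled separately).

    Deterministic table on heavy atoms: His is typed as an ambiguous
    donor/acceptor (no protonation inference), UNK residues fall back to
    element-level typing, and unclassified atoms (e.g. the backbone
    carbonyl carbon) get the neutral type ``Other``.
    """
    element = element.upper()
    if atom_name == "CA" and element == "C":
        return PT_CA
    if is_backbone:
        if atom_name == "OXT":
            return PT_NEGACC
        if atom_name == "O":
            return PT_ACC
        if atom_name == "N":
            return PT_DON
        return PT_OTHER  # backbone carbonyl carbon
    key = (residue_name, atom_name)
    if key in _SIDECHAIN_TYPES:
        return _SIDECHAIN_TYPES[key]
    if residue_name in RING_ATOMS and atom_name in RING_ATOMS[residue_name]:
        return PT_ARO
    if element == "C":
        return PT_HYPHOB
    # element-level fallback (UNK residues, modified naming)
    if element == "O":
        return PT_ACC
    if element == "N":
        return PT_DON
    if element == "S":
        return PT_ACCDON
    return PT_OTHER


@dataclass(frozen=True)
class InterfacePoint:
    """One typed 3-D point of a single-chain interface (atom or ring centre)."""

    coords: np.ndarray
    ptype: str
    element: str
    is_calpha: bool
    is_ring_center: bool
    residue_name: str
    residue_class: str
    residue_seq: int
    icode: str
    is_backbone: bool
    solvent_exposed: bool
    atom_name: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "coords", np.asarray(self.coords, dtype=float).reshape(3))
        if self.is_calpha and self.ptype != PT_CA:
            raise ValueError("alpha-carbon points must carry the Ca type")
        if self.is_ring_center and (self.element != "RING" or not self.solvent_exposed):
            raise ValueError("ring centres must have element RING and count as exposed")

    @property
    def residue_id(self) -> tuple[int, str]:
        return (self.residue_seq, self.icode)


def assign_pharmacophore(point: InterfacePoint) -> str:
    """Pharmacophore type of an interface point (ring centres are aromatic)."""
    if point.is_ring_center:
        return PT_ARO
    return classify_atom(point.residue_name, point.atom_name, point.element, point.is_backbone)


def _point_from_atom(atom: AtomRecord, exposed: bool = True) -> InterfacePoint:
    return InterfacePoint(
        coords=atom.coords,
        ptype=classify_atom(atom.residue_name, atom.atom_name, atom.element, atom.is_backbone),
        element=atom.element,
        is_calpha=(atom.atom_name == "CA" and atom.element == "C"),
        is_ring_center=False,
        residue_name=atom.residue_name,
        residue_class=residue_class_of(atom.residue_name),
        residue_seq=atom.residue_seq,
        icode=atom.icode,
        is_backbone=atom.is_backbone,
        solvent_exposed=exposed,
        atom_name=atom.atom_name,
    )


@dataclass
class ChainInterface:
    """The ordered point set of one chain's side of an interface."""

    structure_id: str
    chain_id: str
    partner_chain_id: str | None
    points: list[InterfacePoint]
    reduction_mode: str = "raw"
    #: all heavy atoms of each interface residue (for Calpha lookup and rings)
    residue_atoms: dict[tuple[int, str], list[AtomRecord]] = field(default_factory=dict)
    #: explicit Calpha coordinates (used when rebuilt from the database)
    calpha_override: np.ndarray | None = None

    @property
    def key(self) -> tuple[str, str, str | None]:
        return (self.structure_id, self.chain_id, self.partner_chain_id)

    def coords(self) -> np.ndarray:
        return np.array([p.coords for p in self.points], dtype=float).reshape(-1, 3)

    def calpha_coords(self) -> np.ndarray:
        """One alpha-carbon coordinate per interface residue (author order)."""
        if self.calpha_override is not None:
            return np.asarray(self.calpha_override, dtype=float).reshape(-1, 3)
        out = []
        for rid, atoms in self.residue_atoms.items():
            for a in atoms:
                if a.atom_name == "CA" and a.element == "C":
                    out.append(a.coords)
                    break
        return np.array(out, dtype=float).reshape(-1, 3)

    def residue_ids(self) -> list[tuple[int, str]]:
        return list(self.residue_atoms)


@dataclass
class InterfacePair:
    """A two-sided interface, or a one-sided query (side_b absent)."""

    side_a: ChainInterface
    side_b: ChainInterface | None = None

    def sides(self) -> list[ChainInterface]:
        return [s for s in (self.side_a, self.side_b) if s is not None]


def _collect_side(
    structure: Structure,
    chain_id: str,
    partner_chain_id: str | None,
    member_idx: np.ndarray,
) -> ChainInterface:
    atoms = structure.chains[chain_id]
    points = [_point_from_atom(atoms[i]) for i in member_idx]
    member_res = {atoms[i].residue_id for i in member_idx}
    residue_atoms: dict[tuple[int, str], list[AtomRecord]] = {}
    for a in atoms:
        if a.residue_id in member_res:
            residue_atoms.setdefault(a.residue_id, []).append(a)
    return ChainInterface(
        structure_id=structure.structure_id,
        chain_id=chain_id,
        partner_chain_id=partner_chain_id,
        points=points,
        reduction_mode="raw",
        residue_atoms=residue_atoms,
    )


def extract_interface(
    structure: Structure, chain_a: str, chain_b: str, cutoff: float = 4.5
) -> InterfacePair:
    """Atom-level interface between two chains.

    Each side holds every heavy atom of its chain within ``cutoff`` of any
    heavy atom of the partner chain.  Raises ``KeyError`` for a missing
    chain and ``NoInterfaceError`` when no atom pair is within the cutoff.
    """
    for cid in (chain_a, chain_b):
        if cid not in structure.chains:
            raise KeyError(f"chain {cid!r} not in structure {structure.structure_id}")
    if chain_a == chain_b:
        raise ValueError("interface chains must be distinct")
    xa = structure.chain_coords(chain_a)
    xb = structure.chain_coords(chain_b)
    tree_a, tree_b = cKDTree(xa), cKDTree(xb)
    pairs = tree_a.query_ball_tree(tree_b, r=cutoff)
    a_idx = np.array(sorted({i for i, nb in enumerate(pairs) if nb}), dtype=int)
    b_idx = np.array(sorted({j for nb in pairs for j in nb}), dtype=int)
    if len(a_idx) == 0 and len(b_idx) == 0:
        raise NoInterfaceError(
            f"no heavy-atom contacts within {cutoff} A between chains "
            f"{chain_a} and {chain_b}"
        )
    return InterfacePair(
        side_a=_collect_side(structure, chain_a, chain_b, a_idx),
        side_b=_collect_side(structure, chain_b, chain_a, b_idx),
    )


def one_sided_interface(
    structure: Structure, chain: str, residues: list[tuple[int, str]]
) -> InterfacePair:
    """One-sided interface from a user-supplied residue list.

    ``residues`` are (seqnum, icode) pairs on ``chain``; all heavy atoms of
    the listed residues become the side's points.
    """
    if chain not in structure.chains:
        raise KeyError(f"chain {chain!r} not in structure {structure.structure_id}")
    if not residues:
        raise NoInterfaceError("empty residue list")
    wanted = [(int(num), str(ic)) for num, ic in residues]
    present = structure.residues(chain)
    missing = [r for r in wanted for _ in [0] if r not in present]
    if missing:
        raise KeyError(f"residues not found on chain {chain}: {sorted(set(missing))}")
    wanted_set = set(wanted)
    atoms = structure.chains[chain]
    idx = np.array([i for i, a in enumerate(atoms) if a.residue_id in wanted_set], dtype=int)
    return InterfacePair(side_a=_collect_side(structure, chain, None, idx))


ExposureTable = dict[tuple[str, int, str, str], bool]


def compute_solvent_exposure(
    structure: Structure, chain: str, threshold: float = 0.1
) -> ExposureTable:
    """Per-atom exposure flags for one chain, computed unbound.

    The chain is taken in isolation (the partner removed), SASA is computed
    with a 1.4 A probe, and an atom counts as solvent-exposed when its
    accessible area exceeds ``threshold`` (A^2).  Keys are
    ``(chain_id, residue_seq, icode, atom_name)``.
    """
    atoms = structure.chains[chain]
    coords = structure.chain_coords(chain)
    areas = shrake_rupley_sasa(coords, [a.element for a in atoms])
    return {
        (chain, a.residue_seq, a.icode, a.atom_name): bool(area > threshold)
        for a, area in zip(atoms, areas)
    }


def _ring_center_points(side: ChainInterface) -> list[InterfacePoint]:
    out: list[InterfacePoint] = []
    for rid, atoms in side.residue_atoms.items():
        rname = atoms[0].residue_name
        if rname not in RING_ATOMS:
            continue
        ring = [a.coords for a in atoms if a.atom_name in RING_ATOMS[rname]]
        if len(ring) < 3:
            continue
        out.append(
            InterfacePoint(
                coords=np.mean(ring, axis=0),
                ptype=PT_ARO,
                element="RING",
                is_calpha=False,
                is_ring_center=True,
                residue_name=rname,
                residue_class=residue_class_of(rname),
                residue_seq=rid[0],
                icode=rid[1],
                is_backbone=False,
                solvent_exposed=True,
                atom_name="RING",
            )
        )
    return out


def _reduce_side(
    side: ChainInterface, mode: str, exposure: ExposureTable | None
) -> ChainInterface:
    def exposed(p: InterfacePoint) -> bool:
        if exposure is None:
            return True
        return exposure.get((side.chain_id, p.residue_seq, p.icode, p.atom_name), True)

    points: list[InterfacePoint]
    if mode == "calpha":
        points = []
        for rid, atoms in side.residue_atoms.items():
            for a in atoms:
                if a.atom_name == "CA" and a.element == "C":
                    points.append(replace(_point_from_atom(a), solvent_exposed=True))
                    break
    elif mode == "restricted":
        points = []
        for p in side.points:
            if p.element in ("O", "N", "S"):
                keep = True
            elif (
                p.residue_name in HYDROPHOBIC_CARBONS
                and p.atom_name in HYDROPHOBIC_CARBONS[p.residue_name]
            ):
                keep = True
            else:
                keep = False
            if keep and exposed(p):
                points.append(replace(p, solvent_exposed=True))
        points.extend(_ring_center_points(side))
    elif mode == "all":
        points = [replace(p, solvent_exposed=True) for p in side.points if exposed(p)]
        points.extend(_ring_center_points(side))
    else:
        raise ValueError(f"unknown reduction mode: {mode!r}")

    if not points:
        raise NoInterfaceError(
            f"reduction ({mode}) left no points on {side.structure_id}:{side.chain_id}"
        )
    return ChainInterface(
        structure_id=side.structure_id,
        chain_id=side.chain_id,
        partner_chain_id=side.partner_chain_id,
        points=points,
        reduction_mode=mode,
        residue_atoms=side.residue_atoms,
    )


def reduce_points(
    pair: InterfacePair,
    mode: str,
    exposure: ExposureTable | None = None,
) -> InterfacePair:
    """Reduce both sides of an interface to the chosen point representation.

    ``exposure`` is a per-atom flag table covering all involved chains (as
    returned by :func:`compute_solvent_exposure`); it is only consulted in
    the ``restricted`` and ``all`` modes.  Raises ``NoInterfaceError`` when
    a side reduces to nothing.
    """
    side_a = _reduce_side(pair.side_a, mode, exposure)
    side_b = _reduce_side(pair.side_b, mode, exposure) if pair.side_b is not None else None
    return InterfacePair(side_a=side_a, side_b=side_b)


def model_interface(
    structure: Structure,
    chain_a: str,
    chain_b: str,
    mode: str = "calpha",
    cutoff: float = 4.5,
) -> InterfacePair:
    """Convenience pipeline: extract, compute unbound exposure, reduce."""
    pair = extract_interface(structure, chain_a, chain_b, cutoff=cutoff)
    exposure: ExposureTable = {}
    if mode in ("restricted", "all"):
        exposure.update(compute_solvent_exposure(structure, chain_a))
        exposure.update(compute_solvent_exposure(structure, chain_b))
    return reduce_points(pair, mode, exposure or None)
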