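"""Synthetic two-chain complexes and decoy panels.

The generator builds small dimers from near-ideal secondary-structure
segments (standard bond lengths and angles, motif torsions with small
per-residue heterogeneity) assembled into compact chains - a two-helix
bundle or a three-strand sheet - with simplified but correctly named side
chains.  The chains are packed to a controllable closest heavy-atom
contact distance, with an induced-fit step that draws near-contact side
chains into the interface band the way complementary surfaces meet in
real complexes.  Decoy sets derive from a base complex:

* *similar* decoys - the base complex under a random rigid motion plus
  Gaussian coordinate noise, with a fraction of non-interface residues
  truncated to alanine (a mutagenesis-style retyping);
* *dissimilar* decoys - independently generated complexes with fresh
  sequences, lengths, packing angles and contact distances.

Everything is deterministic given the spec's seed.  These complexes
emulate the point-set statistics of real interfaces (size, contact
geometry, pharmacophore variety), not real protein energetics.
"""
from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace

import numpy as np
from scipy.optimize import brentq
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from .geometry import RigidTransform
from .interface import extract_interface
from .structures import AtomRecord, BACKBONE_ATOMS, Structure, transform_structure

__all__ = ["SyntheticComplexSpec", "make_toy_complex", "make_decoy_panel", "random_rigid_transform"]

# ideal backbone internal coordinates (Angstroms / degrees)
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O, _B_CA_CB = 1.458, 1.525, 1.329, 1.231, 1.530
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA, _A_CA_C_O, _A_N_CA_CB = 111.2, 116.2, 121.7, 120.5, 110.5
_TORSIONS = {"helix": (-57.0, -47.0), "strand": (-139.0, 135.0)}

_PALETTE = (
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()
)
#: contact-face palettes by azimuth from the packing direction: longer
#: side chains fill the gap where the chain surface curves away, so the
#: contact forms a stripe instead of a single protruding touch
_CONTACT_BANDS = (
    "SER CYS THR VAL".split(),  # facing head-on, short reach
    "LEU ILE ASN ASP".split(),  # oblique, medium reach
    "MET GLN GLU".split(),  # grazing, long reach
)
_BAND_LIMITS_DEG = (30.0, 50.0, 68.0)
#: residues whose side chains sit this close to the partner after rigid
#: placement are pulled into contact by the induced-fit step
_FIT_REACH = 8.5
#: per-residue phi/psi heterogeneity (degrees): real secondary structure
#: is never exactly ideal, and without this distinct complexes would share
#: one exact coordinate lattice
_TORSION_JITTER_DEG = 6.0

# side-chain atoms placed as a zigzag chain beyond CB (rings handled apart)
_SIDE_CHAINS = {
    "GLY": [],
    "ALA": ["CB"],
    "SER": ["CB", "OG"],
    "CYS": ["CB", "SG"],
    "THR": ["CB", "OG1", "CG2"],
    "VAL": ["CB", "CG1", "CG2"],
    "LEU": ["CB", "CG", "CD1", "CD2"],
    "ILE": ["CB", "CG1", "CG2", "CD1"],
    "PRO": ["CB", "CG", "CD"],
    "MET": ["CB", "CG", "SD", "CE"],
    "ASP": ["CB", "CG", "OD1", "OD2"],
    "ASN": ["CB", "CG", "OD1", "ND2"],
    "GLU": ["CB", "CG", "CD", "OE1", "OE2"],
    "GLN": ["CB", "CG", "CD", "OE1", "NE2"],
    "LYS": ["CB", "CG", "CD", "CE", "NZ"],
    "ARG": ["CB", "CG", "CD", "NE", "CZ", "NH1", "NH2"],
}
_HEXA = ("CG", "CD1", "CE1", "CZ", "CE2", "CD2")
_PENTA_HIS = ("CG", "ND1", "CE1", "NE2", "CD2")
_PENTA_TRP = ("CG", "CD1", "NE1", "CE2", "CD2")
_TRP_EXTRA = ("CE3", "CZ3", "CH2", "CZ2")


@dataclass(frozen=True)
class SyntheticComplexSpec:
    """Recipe for a deterministic two-chain toy complex and its decoys."""

    seed: int
    n_residues_per_chain: int = 38
    motif: str = "helix"
    contact_distance: float = 3.8
    noise_sigma: float = 0.3
    retype_fraction: float = 0.2
    crossing_angle_deg: float = 0.0


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _place(a, b, c, bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Internal-coordinate (NeRF) placement of atom D bonded to C."""
    theta = np.deg2rad(angle_deg)
    phi = np.deg2rad(torsion_deg)
    bc = _unit(c - b)
    n = _unit(np.cross(b - a, bc))
    m = np.cross(n, bc)
    d2 = np.array(
        [-bond * np.cos(theta), bond * np.sin(theta) * np.cos(phi), bond * np.sin(theta) * np.sin(phi)]
    )
    return c + d2[0] * bc + d2[1] * m + d2[2] * n


def _backbone(
    n_res: int, motif: str, torsion_jitter: np.ndarray | None = None
) -> list[dict[str, np.ndarray]]:
    phi0, psi0 = _TORSIONS[motif]
    jit = np.zeros((n_res, 2)) if torsion_jitter is None else torsion_jitter
    res: list[dict[str, np.ndarray]] = []
    n0 = np.zeros(3)
    ca0 = np.array([_B_N_CA, 0.0, 0.0])
    ang = np.deg2rad(_A_N_CA_C)
    c0 = ca0 + _B_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])
    res.append({"N": n0, "CA": ca0, "C": c0})
    for i in range(1, n_res):
        prev = res[-1]
        n_next = _place(prev["N"], prev["CA"], prev["C"], _B_C_N, _A_CA_C_N, psi0 + jit[i - 1, 1])
        ca_next = _place(prev["CA"], prev["C"], n_next, _B_N_CA, _A_C_N_CA, 180.0)
        c_next = _place(prev["C"], n_next, ca_next, _B_CA_C, _A_N_CA_C, phi0 + jit[i, 0])
        res.append({"N": n_next, "CA": ca_next, "C": c_next})
    # carbonyl oxygens (anti to the next N; last residue uses the motif psi)
    for i, r in enumerate(res):
        r["O"] = _place(r["N"], r["CA"], r["C"], _B_C_O, _A_CA_C_O, psi0 + jit[i, 1] + 180.0)
    return res


def _ring(center: np.ndarray, u: np.ndarray, p: np.ndarray, names, radius: float):
    out = {}
    n = len(names)
    for k, name in enumerate(names):
        theta = np.pi + 2.0 * np.pi * k / n  # first atom points back to CB
        out[name] = center + radius * (np.cos(theta) * u + np.sin(theta) * p)
    return out


def _side_chain(resname: str, bb: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    if resname == "GLY":
        return {}
    cb = _place(bb["C"], bb["N"], bb["CA"], _B_CA_CB, _A_N_CA_CB, -122.0)
    atoms = {"CB": cb}
    u = _unit(cb - bb["CA"])
    ref = _unit(bb["N"] - bb["CA"])
    p = _unit(np.cross(u, ref))
    if resname in ("PHE", "TYR"):
        center = cb + (1.5 + 1.39) * u
        atoms.update(_ring(center, u, p, _HEXA, 1.39))
        if resname == "TYR":
            atoms["OH"] = center + (1.39 + 1.36) * u
    elif resname == "HIS":
        center = cb + (1.5 + 1.17) * u
        atoms.update(_ring(center, u, p, _PENTA_HIS, 1.17))
    elif resname == "TRP":
        center = cb + (1.5 + 1.17) * u
        atoms.update(_ring(center, u, p, _PENTA_TRP, 1.17))
        hexc = center + 2.1 * u
        for k, name in enumerate(_TRP_EXTRA):
            theta = np.pi / 2 + 2.0 * np.pi * k / 6
            atoms[name] = hexc + 1.39 * (np.cos(theta) * u + np.sin(theta) * p)
    else:
        prev = cb
        for k, name in enumerate(_SIDE_CHAINS[resname][1:]):
            step = 1.52 * (np.cos(0.35) * u + np.sin(0.35) * ((-1.0) ** k) * p)
            prev = prev + step
            atoms[name] = prev
    return atoms


def _element_of(atom_name: str) -> str:
    return atom_name[0]


#: inter-segment packing distances (Angstroms): helix-helix bundle spacing
#: and strand-strand sheet spacing
_SEGMENT_SPACING = {"helix": 10.2, "strand": 4.8}
_N_SEGMENTS = {"helix": 2, "strand": 3}


def _segment_records(
    chain_id: str,
    sequence: list[str],
    motif: str,
    first_seq: int,
    torsion_jitter: np.ndarray | None = None,
) -> list[AtomRecord]:
    bb = _backbone(len(sequence), motif, torsion_jitter)
    records: list[AtomRecord] = []
    for i, resname in enumerate(sequence):
        atoms = {k: bb[i][k] for k in ("N", "CA", "C", "O")}
        atoms.update(_side_chain(resname, bb[i]))
        order = ["N", "CA", "C", "O"] + [n for n in atoms if n not in ("N", "CA", "C", "O")]
        for name in order:
            records.append(
                AtomRecord(
                    serial=0,
                    atom_name=name,
                    element=_element_of(name),
                    residue_name=resname,
                    residue_seq=first_seq + i,
                    icode="",
                    chain_id=chain_id,
                    coords=atoms[name],
                    is_backbone=name in BACKBONE_ATOMS,
                )
            )
    return records


def _build_chain(
    chain_id: str,
    sequence: list[str],
    motif: str,
    torsion_jitter: np.ndarray | None = None,
) -> list[AtomRecord]:
    """A compact chain: antiparallel near-ideal segments packed side by side.

    A helix chain is a two-helix bundle, a strand chain a three-strand
    sheet; this presents a two-dimensional contact face of realistic
    extent rather than the infinitely thin stripe a single straight
    segment would offer.  ``torsion_jitter`` carries small per-residue
    phi/psi deviations (degrees) so distinct chains are geometrically
    distinct, as real secondary structure is.
    """
    n = len(sequence)
    n_seg = _N_SEGMENTS[motif]
    spacing = _SEGMENT_SPACING[motif]
    per = [n // n_seg] * n_seg
    per[-1] += n - sum(per)
    records: list[AtomRecord] = []
    start = 0
    for k, m in enumerate(per):
        jit = None if torsion_jitter is None else torsion_jitter[start : start + m]
        seg = _canonicalize(
            _segment_records(chain_id, sequence[start : start + m], motif, start + 1, jit)
        )
        if k % 2 == 1:  # antiparallel packing
            seg = [dc_replace(a, coords=a.coords * np.array([1.0, -1.0, -1.0])) for a in seg]
        offset = np.array([0.0, k * spacing, 0.0])
        records.extend(dc_replace(a, coords=a.coords + offset) for a in seg)
        start += m
    records = [dc_replace(a, serial=i + 1) for i, a in enumerate(records)]
    return records


def _canonicalize(records: list[AtomRecord]) -> list[AtomRecord]:
    """Centroid at the origin, principal Calpha axis along z."""
    ca = np.array([a.coords for a in records if a.atom_name == "CA"])
    centroid = ca.mean(axis=0)
    _, _, vt = np.linalg.svd(ca - centroid)
    axis = vt[0]
    if axis[2] < 0:
        axis = -axis
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(axis, z)
    s = np.linalg.norm(v)
    if s < 1e-12:
        R = np.eye(3)
    else:
        vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        R = np.eye(3) + vx + vx @ vx * ((1 - axis @ z) / s**2)
    T = RigidTransform(R, -R @ centroid)
    return [dc_replace(a, coords=T.apply(a.coords)) for a in records]


def _contact_angle(records: list[AtomRecord], toward: int) -> float:
    """Azimuth (about z) presenting the flattest surface stripe at +x or -x.

    Scans orientations and returns the one maximizing the number of
    residues whose outermost atom lies within 1 A of the chain's overall
    extent on the contact side - a deterministic stand-in for the
    complementary packing faces of real complexes.
    """
    xyz = np.array([a.coords for a in records])
    res_ids = np.array([a.residue_seq for a in records])
    best_angle, best_count = 0.0, -1
    for deg in range(0, 360, 5):
        th = np.deg2rad(deg)
        x = xyz[:, 0] * np.cos(th) - xyz[:, 1] * np.sin(th)
        proj = toward * x
        extreme = proj.max()
        count = len({int(r) for r, p in zip(res_ids, proj) if p >= extreme - 1.0})
        if count > best_count:
            best_angle, best_count = th, count
    return best_angle


def _rotate_z(records: list[AtomRecord], angle: float) -> list[AtomRecord]:
    c, s = np.cos(angle), np.sin(angle)
    Rz = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
    return [dc_replace(a, coords=Rz @ a.coords) for a in records]


def make_toy_complex(spec: SyntheticComplexSpec) -> Structure:
    """Deterministic two-chain complex with the requested contact geometry.

    Chain A lies with its long axis along z; chain B is flipped
    antiparallel, tilted by ``crossing_angle_deg`` and translated along x
    until the closest heavy-atom distance between the chains equals
    ``contact_distance``.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_residues_per_chain

    flip = Rotation.from_euler("x", 180, degrees=True).as_matrix()
    tilt = Rotation.from_euler("x", spec.crossing_angle_deg, degrees=True).as_matrix()
    R = tilt @ flip

    # probe pass: the backbone (and hence the canonical frame) is
    # sequence-independent given the torsion draws, so a poly-ALA probe
    # fixes the packing azimuth and tells which residues will face the
    # partner chain
    jit_a = rng.normal(0.0, _TORSION_JITTER_DEG, (n, 2))
    jit_b = rng.normal(0.0, _TORSION_JITTER_DEG, (n, 2))
    probe_a = _canonicalize(_build_chain("A", ["ALA"] * n, spec.motif, jit_a))
    probe_b = _canonicalize(_build_chain("B", ["ALA"] * n, spec.motif, jit_b))
    angle_a = _contact_angle(probe_a, toward=+1)
    angle_b = _contact_angle(probe_b, toward=-1)

    def facing_bands(probe: list[AtomRecord], angle: float, toward: int) -> dict[int, int]:
        """Residue -> contact band (0 head-on .. 2 grazing) for one chain."""
        bands: dict[int, int] = {}
        by_res: dict[int, dict[str, np.ndarray]] = {}
        for a in _rotate_z(probe, angle):
            by_res.setdefault(a.residue_seq, {})[a.atom_name] = a.coords
        for rseq, atoms in by_res.items():
            if "CB" not in atoms:
                continue
            u = atoms["CB"] - atoms["CA"]
            u_xy = u[:2] / (np.linalg.norm(u[:2]) + 1e-12)
            theta = np.rad2deg(np.arccos(np.clip(toward * u_xy[0], -1.0, 1.0)))
            for band, limit in enumerate(_BAND_LIMITS_DEG):
                if theta <= limit:
                    bands[rseq] = band
                    break
        return bands

    def draw_seq(bands: dict[int, int]) -> list[str]:
        return [
            str(rng.choice(_CONTACT_BANDS[bands[i + 1]]))
            if (i + 1) in bands
            else str(rng.choice(_PALETTE))
            for i in range(n)
        ]

    chain_a = _rotate_z(
        _canonicalize(
            _build_chain("A", draw_seq(facing_bands(probe_a, angle_a, +1)), spec.motif, jit_a)
        ),
        angle_a,
    )
    chain_b = _rotate_z(
        _canonicalize(
            _build_chain("B", draw_seq(facing_bands(probe_b, angle_b, -1)), spec.motif, jit_b)
        ),
        angle_b,
    )
    xyz_a = np.array([a.coords for a in chain_a])
    base_b = np.array([a.coords for a in chain_b]) @ R.T

    def min_dist(tx: float) -> float:
        return float(cdist(xyz_a, base_b + np.array([tx, 0.0, 0.0])).min())

    lo = 0.0
    hi = 60.0
    while min_dist(lo) > spec.contact_distance and lo > -60.0:
        lo -= 10.0
    while min_dist(hi) < spec.contact_distance:
        hi += 30.0
    tx = brentq(lambda t: min_dist(t) - spec.contact_distance, lo, hi, xtol=1e-6)

    shift = np.array([tx, 0.0, 0.0])
    chain_b = [dc_replace(a, coords=(a.coords @ R.T) + shift) for a in chain_b]

    # induced fit: side chains just outside the cutoff are drawn along the
    # packing axis into the contact band, emulating the surface
    # complementarity of real interfaces; nothing moves below the
    # requested contact distance
    chain_a = _induced_fit(chain_a, chain_b, +1, spec.contact_distance, rng)
    chain_b = _induced_fit(chain_b, chain_a, -1, spec.contact_distance, rng)
    return Structure(
        structure_id=f"toy{spec.seed}",
        chains={"A": chain_a, "B": chain_b},
        source_format="PDB",
    )


def _induced_fit(
    chain: list[AtomRecord],
    partner: list[AtomRecord],
    toward: int,
    contact: float,
    rng: np.random.Generator,
) -> list[AtomRecord]:
    partner_xyz = np.array([a.coords for a in partner])
    by_res: dict[int, list[int]] = {}
    for i, a in enumerate(chain):
        by_res.setdefault(a.residue_seq, []).append(i)
    out = list(chain)
    for rseq, idxs in by_res.items():
        side = [i for i in idxs if chain[i].atom_name not in ("N", "CA", "C", "O")]
        if not side:
            continue
        d = min(float(cdist(chain[i].coords.reshape(1, 3), partner_xyz).min()) for i in side)
        if contact < d <= _FIT_REACH:
            target = contact + float(rng.uniform(0.0, 0.1))
            if d > target:
                delta = np.array([toward * (d - target), 0.0, 0.0])
                for i in side:
                    out[i] = dc_replace(chain[i], coords=chain[i].coords + delta)
    return out


def random_rigid_transform(rng: np.random.Generator, max_translation: float = 20.0) -> RigidTransform:
    """Uniformly random proper rotation plus a bounded random translation."""
    q = rng.normal(size=4)
    R = Rotation.from_quat(q / np.linalg.norm(q)).as_matrix()
    t = rng.uniform(-max_translation, max_translation, size=3)
    return RigidTransform(R, t)


def _truncate_to_alanine(records: list[AtomRecord], residue_ids: set) -> list[AtomRecord]:
    out = []
    for a in records:
        if a.residue_id in residue_ids:
            if a.atom_name not in ("N", "CA", "C", "O", "CB"):
                continue
            a = dc_replace(a, residue_name="ALA")
        out.append(a)
    return out


def make_decoy_panel(
    base: Structure,
    n_similar: int,
    n_dissimilar: int,
    spec: SyntheticComplexSpec,
) -> list[tuple[str, Structure]]:
    """Labeled panel of similar and dissimilar decoys for a base complex.

    Similar decoys ("active") reuse the base coordinates under a random
    rigid motion with Gaussian noise (``noise_sigma``) and alanine
    truncation of ``retype_fraction`` of the non-interface residues.
    Dissimilar decoys ("inactive") are fresh complexes from disjoint
    seeds with varied length, motif, packing angle and contact distance.
    """
    rng = np.random.default_rng(spec.seed + 7)
    iface = extract_interface(base, "A", "B", cutoff=4.5)
    iface_res = {
        ("A", rid): True for rid in iface.side_a.residue_ids()
    } | {("B", rid): True for rid in (iface.side_b.residue_ids() if iface.side_b else [])}

    panel: list[tuple[str, Structure]] = []
    for i in range(n_similar):
        T = random_rigid_transform(rng)
        moved = transform_structure(base, T)
        chains = {}
        for cid, atoms in moved.chains.items():
            non_iface = [a.residue_id for a in atoms if (cid, a.residue_id) not in iface_res]
            unique = sorted(set(non_iface))
            n_retype = int(round(spec.retype_fraction * len(unique)))
            chosen = set(
                unique[k] for k in rng.choice(len(unique), size=n_retype, replace=False)
            ) if n_retype else set()
            new_atoms = _truncate_to_alanine(atoms, chosen)
            if spec.noise_sigma > 0:
                new_atoms = [
                    dc_replace(a, coords=a.coords + rng.normal(0.0, spec.noise_sigma, 3))
                    for a in new_atoms
                ]
            chains[cid] = new_atoms
        panel.append(
            ("active", Structure(f"{base.structure_id}_sim{i}", chains, base.source_format))
        )
    for i in range(n_dissimilar):
        sub = SyntheticComplexSpec(
            seed=spec.seed + 1000 + i,
            n_residues_per_chain=int(rng.integers(24, 41)),
            motif=str(rng.choice(["helix", "helix", "strand"])),
            contact_distance=float(rng.uniform(3.8, 4.5)),
            crossing_angle_deg=float(rng.uniform(-60.0, 60.0)),
        )
        decoy = make_toy_complex(sub)
        decoy.structure_id = f"{base.structure_id}_dis{i}"
        panel.append(("inactive", decoy))
    return panel
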