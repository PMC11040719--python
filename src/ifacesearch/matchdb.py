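"""Interface database: persistence and tetrahedron-filter matching.

Pre-processed single-chain interfaces are stored one point per row in an
embedded SQLite file alongside a ``manifest.json`` recording the build
parameters.  A filter query returns every property- and distance-consistent
ordered 4-point mapping in every stored interface; symmetric and
overlapping mappings are all returned, since each yields its own alignment.
"""
from __future__ import annotations

import json
import logging
import sqlite3
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .errors import ConfigurationError, NoInterfaceError
from .interface import ChainInterface, InterfacePair, InterfacePoint, model_interface
from .structures import parse_structure
from .tetrascan import EDGE_PAIRS, SearchParams, TetrahedronFilter, constraint_key

__all__ = ["InterfaceDB", "Match", "build_db", "match_filter_against_points"]

log = logging.getLogger(__name__)

DB_FILENAME = "db.sqlite"
MANIFEST_FILENAME = "manifest.json"
SCHEMA_VERSION = 1
#: safety cap on mappings per (filter, target interface)
MATCH_CAP = 10_000

_SCHEMA = """
CREATE TABLE meta (key TEXT PRIMARY KEY, value TEXT);
CREATE TABLE interfaces (
    id INTEGER PRIMARY KEY,
    structure_id TEXT NOT NULL,
    chain_id TEXT NOT NULL,
    partner_chain_id TEXT NOT NULL,
    n_points INTEGER NOT NULL,
    calpha_json TEXT NOT NULL,
    UNIQUE (structure_id, chain_id, partner_chain_id)
);
CREATE TABLE points (
    interface_id INTEGER NOT NULL REFERENCES interfaces(id),
    idx INTEGER NOT NULL,
    x REAL, y REAL, z REAL,
    ptype TEXT, element TEXT,
    residue_class TEXT, residue_name TEXT,
    residue_seq INTEGER, icode TEXT, atom_name TEXT,
    is_backbone INTEGER, is_calpha INTEGER, is_ring_center INTEGER,
    solvent_exposed INTEGER,
    PRIMARY KEY (interface_id, idx)
);
"""


@dataclass(frozen=True)
class Match:
    """One consistent 4-point mapping of a filter inside a target interface."""

    filter_id: int
    target_key: tuple[str, str, str]
    corner_mapping: tuple[tuple[int, int], ...]  # (query corner idx, target point idx)


def _edge_interval_lookup(flt: TetrahedronFilter) -> dict[tuple[int, int], tuple[float, float]]:
    out = {}
    for (i, j), iv in zip(EDGE_PAIRS, flt.edge_intervals):
        out[(i, j)] = iv
        out[(j, i)] = iv
    return out


def match_filter_against_points(
    flt: TetrahedronFilter,
    point_keys: list[tuple],
    dist: np.ndarray,
    cap: int = MATCH_CAP,
) -> list[tuple[int, int, int, int]]:
    """All ordered 4-tuples of target point indices satisfying a filter.

    ``point_keys`` are the target points' constraint keys at the filter's
    hierarchy level; ``dist`` the target's pairwise distance matrix.  Corner
    constraints are tested by key equality and the six distances against
    the filter's toleranced intervals.  Candidate corners are joined
    smallest-candidate-set first; results come back sorted
    lexicographically in filter corner order.
    """
    cands: list[np.ndarray] = []
    for c in flt.corner_constraints:
        idx = np.array([i for i, k in enumerate(point_keys) if k == c], dtype=int)
        if idx.size == 0:
            return []
        cands.append(idx)
    order = sorted(range(4), key=lambda c: (len(cands[c]), c))
    intervals = _edge_interval_lookup(flt)

    results: list[tuple[int, int, int, int]] = []
    assigned: dict[int, int] = {}

    def extend(pos: int) -> None:
        if len(results) >= cap:
            return
        if pos == 4:
            results.append(tuple(assigned[c] for c in range(4)))  # type: ignore[arg-type]
            return
        corner = order[pos]
        cand = cands[corner]
        for prev_corner, tgt in assigned.items():
            lo, hi = intervals[(prev_corner, corner)]
            d = dist[cand, tgt]
            cand = cand[(d >= lo) & (d <= hi) & (cand != tgt)]
            if cand.size == 0:
                return
        for t in cand:
            assigned[corner] = int(t)
            extend(pos + 1)
            if len(results) >= cap:
                break
        del assigned[corner]

    extend(0)
    if len(results) >= cap:
        log.warning("match cap (%d) reached for a filter; mappings truncated", cap)
    return sorted(results)


@dataclass
class _Entry:
    key: tuple[str, str, str]
    interface: ChainInterface
    coords: np.ndarray
    _dist: np.ndarray | None = None
    _keys: dict[int, list[tuple]] | None = None

    def dist(self) -> np.ndarray:
        if self._dist is None:
            self._dist = squareform(pdist(self.coords)) if len(self.coords) > 1 else np.zeros((1, 1))
        return self._dist

    def keys_at(self, level: int) -> list[tuple]:
        if self._keys is None:
            self._keys = {}
        if level not in self._keys:
            self._keys[level] = [constraint_key(p, level) for p in self.interface.points]
        return self._keys[level]


class InterfaceDB:
    """Directory-backed store of reduced, typed single-chain interfaces.

    Both orientations of every interacting chain pair are stored as
    separate entries, so one-sided queries see every side.
    """

    def __init__(self, directory: str | Path):
        self.directory = Path(directory)
        db_path = self.directory / DB_FILENAME
        manifest_path = self.directory / MANIFEST_FILENAME
        if not db_path.exists() or not manifest_path.exists():
            raise FileNotFoundError(f"not an interface database directory: {directory}")
        self.manifest = json.loads(manifest_path.read_text())
        self.params = SearchParams(**self.manifest["params"])
        self._conn = sqlite3.connect(str(db_path))
        self._entries: dict[tuple[str, str, str], _Entry] | None = None

    # -- access ---------------------------------------------------------
    def keys(self) -> list[tuple[str, str, str]]:
        rows = self._conn.execute(
            "SELECT structure_id, chain_id, partner_chain_id FROM interfaces ORDER BY id"
        ).fetchall()
        return [tuple(r) for r in rows]  # type: ignore[misc]

    def __len__(self) -> int:
        return self._conn.execute("SELECT COUNT(*) FROM interfaces").fetchone()[0]

    def _load_entries(self) -> dict[tuple[str, str, str], _Entry]:
        if self._entries is not None:
            return self._entries
        entries: dict[tuple[str, str, str], _Entry] = {}
        ifaces = self._conn.execute(
            "SELECT id, structure_id, chain_id, partner_chain_id, calpha_json "
            "FROM interfaces ORDER BY id"
        ).fetchall()
        for iid, sid, cid, pcid, calpha_json in ifaces:
            rows = self._conn.execute(
                "SELECT x, y, z, ptype, element, residue_class, residue_name, residue_seq,"
                " icode, atom_name, is_backbone, is_calpha, is_ring_center, solvent_exposed"
                " FROM points WHERE interface_id = ? ORDER BY idx",
                (iid,),
            ).fetchall()
            points = [
                InterfacePoint(
                    coords=np.array(r[0:3]),
                    ptype=r[3],
                    element=r[4],
                    residue_class=r[5],
                    residue_name=r[6],
                    residue_seq=r[7],
                    icode=r[8],
                    atom_name=r[9],
                    is_backbone=bool(r[10]),
                    is_calpha=bool(r[11]),
                    is_ring_center=bool(r[12]),
                    solvent_exposed=bool(r[13]),
                )
                for r in rows
            ]
            iface = ChainInterface(
                structure_id=sid,
                chain_id=cid,
                partner_chain_id=pcid,
                points=points,
                reduction_mode=self.params.reduction_mode,
                calpha_override=np.array(json.loads(calpha_json), dtype=float).reshape(-1, 3),
            )
            entries[(sid, cid, pcid)] = _Entry(
                key=(sid, cid, pcid), interface=iface, coords=iface.coords()
            )
        self._entries = entries
        return entries

    def get_entry(self, key: tuple[str, str, str]) -> ChainInterface:
        return self._load_entries()[key].interface

    def target_pairs(self) -> list[InterfacePair]:
        """Group complementary entries (A->B, B->A) into two-sided targets."""
        entries = self._load_entries()
        pairs: list[InterfacePair] = []
        seen: set[frozenset] = set()
        for sid, cid, pcid in entries:
            tag = frozenset([(sid, cid, pcid), (sid, pcid, cid)])
            if tag in seen:
                continue
            seen.add(tag)
            side_a = entries[(sid, cid, pcid)].interface
            mirror = entries.get((sid, pcid, cid))
            pairs.append(InterfacePair(side_a=side_a, side_b=mirror.interface if mirror else None))
        return pairs

    # -- querying -------------------------------------------------------
    def query_filter(self, flt: TetrahedronFilter, filter_id: int = 0) -> list[Match]:
        """All consistent mappings of one filter over all stored interfaces."""
        if flt.hierarchy_level != self.params.filter_hierarchy_level:
            raise ConfigurationError(
                f"database built at hierarchy level {self.params.filter_hierarchy_level}, "
                f"filter requires level {flt.hierarchy_level}; rebuild the database"
            )
        query_corners = flt.source[1]
        out: list[Match] = []
        for key, entry in self._load_entries().items():
            if len(entry.interface.points) < 4:
                continue
            hits = match_filter_against_points(
                flt, entry.keys_at(flt.hierarchy_level), entry.dist()
            )
            for mapping in hits:
                out.append(
                    Match(
                        filter_id=filter_id,
                        target_key=key,
                        corner_mapping=tuple(zip(query_corners, mapping)),
                    )
                )
        return out

    def close(self) -> None:
        self._conn.close()


def build_db(
    structures: list[str | Path],
    params: SearchParams,
    out: str | Path,
) -> tuple["InterfaceDB", list[dict]]:
    """Build an interface database from complex structure files.

    For every interacting chain pair of every structure, both reduced,
    typed sides are stored as separate entries.  Sides reducing to fewer
    than four points (e.g. three-residue peptide chains in Calpha mode)
    are skipped and reported.  Returns the opened database plus the build
    report (one record per skipped item).
    """
    if not structures:
        raise ValueError("empty input list")
    out_dir = Path(out)
    out_dir.mkdir(parents=True, exist_ok=True)
    db_path = out_dir / DB_FILENAME
    if db_path.exists():
        db_path.unlink()
    conn = sqlite3.connect(str(db_path))
    conn.executescript(_SCHEMA)

    report: list[dict] = []
    n_stored = 0
    for path in structures:
        path = Path(path)
        try:
            st = parse_structure(path)
        except Exception as exc:  # noqa: BLE001 - build must report, not die
            report.append({"file": str(path), "skipped": "structure", "reason": str(exc)})
            continue
        chain_ids = st.chain_ids()
        any_stored = False
        for i in range(len(chain_ids)):
            for j in range(i + 1, len(chain_ids)):
                ca, cb = chain_ids[i], chain_ids[j]
                try:
                    pair = model_interface(st, ca, cb, mode=params.reduction_mode,
                                           cutoff=params.interface_cutoff)
                except NoInterfaceError:
                    continue
                for side in pair.sides():
                    if len(side.points) < 4:
                        report.append(
                            {
                                "file": str(path),
                                "skipped": f"{side.chain_id}->{side.partner_chain_id}",
                                "reason": f"only {len(side.points)} reduced points",
                            }
                        )
                        continue
                    _insert_entry(conn, side)
                    n_stored += 1
                    any_stored = True
        if not any_stored:
            report.append({"file": str(path), "skipped": "structure", "reason": "no interface stored"})

    conn.execute("INSERT INTO meta VALUES ('schema_version', ?)", (str(SCHEMA_VERSION),))
    conn.commit()
    conn.close()

    manifest = {
        "schema_version": SCHEMA_VERSION,
        "params": _params_dict(params),
        "n_entries": n_stored,
        "report": report,
    }
    (out_dir / MANIFEST_FILENAME).write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return InterfaceDB(out_dir), report


def _params_dict(params: SearchParams) -> dict:
    return {
        "min_dist": params.min_dist,
        "max_dist": params.max_dist,
        "dist_tolerance": params.dist_tolerance,
        "scoring_radius": params.scoring_radius,
        "noffilters": params.noffilters,
        "filter_hierarchy_level": params.filter_hierarchy_level,
        "two_sided_scoring": params.two_sided_scoring,
        "reduction_mode": params.reduction_mode,
    }


def _insert_entry(conn: sqlite3.Connection, side: ChainInterface) -> None:
    calpha = side.calpha_coords()
    cur = conn.execute(
        "INSERT INTO interfaces (structure_id, chain_id, partner_chain_id, n_points, calpha_json)"
        " VALUES (?, ?, ?, ?, ?)",
        (
            side.structure_id,
            side.chain_id,
            side.partner_chain_id or "",
            len(side.points),
            json.dumps([[round(v, 6) for v in row] for row in calpha.tolist()]),
        ),
    )
    iid = cur.lastrowid
    conn.executemany(
        "INSERT INTO points VALUES (?,?,?,?,?,?,?,?,?,?,?,?,?,?,?,?)",
        [
            (
                iid,
                idx,
                float(p.coords[0]),
                float(p.coords[1]),
                float(p.coords[2]),
                p.ptype,
                p.element,
                p.residue_class,
                p.residue_name,
                p.residue_seq,
                p.icode,
                p.atom_name,
                int(p.is_backbone),
                int(p.is_calpha),
                int(p.is_ring_center),
                int(p.solvent_exposed),
            )
            for idx, p in enumerate(side.points)
        ],
    )
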