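"""SQLite-backed spectral warehouse: predicted fragment-intensity sets on a
collision-energy grid.

Fragmentation predictors emit one spectrum per precursor per (normalized)
collision energy.  Predicting across a grid (default NCE 20..40, i.e. 21
variants) and storing every variant lets the optimal energy be chosen later
against the actual DIA data.  Identical intensity sets across neighbouring
energies are stored once, keyed by a content hash (nonredundant storage).

Schema (PRAGMA user_version = 1)::

    precursor(id, modified_sequence, charge, protein_group, irt0)
    payload(hash PRIMARY KEY, fragments_json)
    spectrum(precursor_id, ce, payload_hash)
"""

from __future__ import annotations

import hashlib
import json
import sqlite3
from typing import Iterable, Mapping, Optional, Sequence, Union

from .libio import FragmentIon, PrecursorRecord, SpectralLibrary

SCHEMA_VERSION = 1

DEFAULT_CE_GRID = tuple(range(20, 41))

CEPolicy = Union[int, Mapping[tuple[int, int], int]]


class WarehouseError(RuntimeError):
    pass


def _payload_json(fragments: Sequence[FragmentIon]) -> str:
    ordered = sorted(fragments, key=lambda f: (f.ion_type, f.ordinal, f.frag_charge))
    return json.dumps(
        [[f.ion_type, f.ordinal, f.frag_charge, f.intensity, f.mz] for f in ordered],
        separators=(",", ":"),
    )


def _payload_hash(payload: str) -> str:
    return hashlib.sha1(payload.encode()).hexdigest()


def _fragments_from_json(payload: str) -> list[FragmentIon]:
    return [FragmentIon(ion_type=t, ordinal=o, frag_charge=z, intensity=i, mz=mz)
            for t, o, z, i, mz in json.loads(payload)]


class WarehouseStore:
    """Handle over a warehouse SQLite database (file or in-memory)."""

    def __init__(self, path: str = ":memory:"):
        self.path = path
        self.conn = sqlite3.connect(path)
        self.conn.execute("PRAGMA foreign_keys=ON")

    # -- construction -------------------------------------------------------

    def _init_schema(self, ce_grid: Sequence[int]) -> None:
        c = self.conn
        c.executescript(
            """
            CREATE TABLE meta(key TEXT PRIMARY KEY, value TEXT);
            CREATE TABLE precursor(
                id INTEGER PRIMARY KEY,
                modified_sequence TEXT NOT NULL,
                charge INTEGER NOT NULL,
                protein_group TEXT,
                irt0 REAL NOT NULL,
                UNIQUE(modified_sequence, charge));
            CREATE TABLE payload(
                hash TEXT PRIMARY KEY,
                fragments_json TEXT NOT NULL);
            CREATE TABLE spectrum(
                precursor_id INTEGER NOT NULL REFERENCES precursor(id),
                ce INTEGER NOT NULL,
                payload_hash TEXT NOT NULL REFERENCES payload(hash),
                PRIMARY KEY(precursor_id, ce));
            """
        )
        c.execute(f"PRAGMA user_version={SCHEMA_VERSION}")
        c.execute("INSERT INTO meta VALUES('ce_grid', ?)",
                  (json.dumps(list(ce_grid)),))
        c.commit()

    # -- properties ----------------------------------------------------------

    @property
    def ce_grid(self) -> tuple[int, ...]:
        row = self.conn.execute(
            "SELECT value FROM meta WHERE key='ce_grid'").fetchone()
        return tuple(json.loads(row[0]))

    @property
    def n_precursors(self) -> int:
        return self.conn.execute("SELECT COUNT(*) FROM precursor").fetchone()[0]

    @property
    def n_payloads(self) -> int:
        return self.conn.execute("SELECT COUNT(*) FROM payload").fetchone()[0]

    def precursor_keys(self) -> list[tuple[str, int]]:
        return [(s, z) for s, z in self.conn.execute(
            "SELECT modified_sequence, charge FROM precursor "
            "ORDER BY modified_sequence, charge")]

    def n_spectra(self, modified_sequence: str, charge: int) -> int:
        """Retrievable intensity sets for one precursor (= |ce_grid|)."""
        return self.conn.execute(
            "SELECT COUNT(*) FROM spectrum s JOIN precursor p ON p.id=s.precursor_id"
            " WHERE p.modified_sequence=? AND p.charge=?",
            (modified_sequence, charge)).fetchone()[0]

    def n_distinct_payloads(self, modified_sequence: str, charge: int) -> int:
        """Stored (deduplicated) payloads backing one precursor's spectra."""
        return self.conn.execute(
            "SELECT COUNT(DISTINCT s.payload_hash) FROM spectrum s "
            "JOIN precursor p ON p.id=s.precursor_id"
            " WHERE p.modified_sequence=? AND p.charge=?",
            (modified_sequence, charge)).fetchone()[0]

    def irt0(self, modified_sequence: str, charge: int) -> float:
        row = self.conn.execute(
            "SELECT irt0 FROM precursor WHERE modified_sequence=? AND charge=?",
            (modified_sequence, charge)).fetchone()
        if row is None:
            raise KeyError((modified_sequence, charge))
        return row[0]

    def close(self) -> None:
        self.conn.close()


def build_warehouse(
    prediction_tables: Mapping[int, SpectralLibrary],
    ce_grid: Sequence[int] = DEFAULT_CE_GRID,
    path: str = ":memory:",
    dedup: bool = True,
) -> WarehouseStore:
    """Build a warehouse from one predicted library per collision energy.

    Every table must cover the identical precursor key set; the grid must be
    strictly increasing and match the supplied tables exactly.
    """
    ce_grid = tuple(int(c) for c in ce_grid)
    if list(ce_grid) != sorted(set(ce_grid)):
        raise WarehouseError("ce_grid must be strictly increasing")
    if set(prediction_tables) != set(ce_grid):
        raise WarehouseError(
            f"ce_grid {ce_grid} does not match supplied tables "
            f"{sorted(prediction_tables)}")

    key_sets = {ce: set(lib.records) for ce, lib in prediction_tables.items()}
    universe = set().union(*key_sets.values())
    offenders = sorted(
        k for k in universe if any(k not in ks for ks in key_sets.values()))
    if offenders:
        raise WarehouseError(
            f"{len(offenders)} precursor(s) absent from some CE tables, "
            f"e.g. {offenders[:3]}")

    store = WarehouseStore(path)
    store._init_schema(ce_grid)
    c = store.conn
    ref = prediction_tables[ce_grid[0]]
    for key in sorted(universe):
        rec = ref.records[key]
        cur = c.execute(
            "INSERT INTO precursor(modified_sequence, charge, protein_group, irt0)"
            " VALUES(?,?,?,?)",
            (rec.modified_sequence, rec.precursor_charge, rec.protein_group,
             rec.irt))
        pid = cur.lastrowid
        for ce in ce_grid:
            frags = prediction_tables[ce].records[key].fragments
            payload = _payload_json(frags)
            h = _payload_hash(payload) if dedup else f"{pid}:{ce}"
            c.execute("INSERT OR IGNORE INTO payload VALUES(?,?)", (h, payload))
            c.execute("INSERT INTO spectrum VALUES(?,?,?)", (pid, ce, h))
    c.commit()
    return store


def query_spectrum(store: WarehouseStore, modified_sequence: str,
                   charge: int, ce: int) -> list[FragmentIon]:
    """Return the stored fragment set for a precursor at one grid energy."""
    if ce not in store.ce_grid:
        raise ValueError(f"CE {ce} outside grid {store.ce_grid[0]}..{store.ce_grid[-1]}")
    row = store.conn.execute(
        "SELECT y.fragments_json FROM spectrum s"
        " JOIN precursor p ON p.id=s.precursor_id"
        " JOIN payload y ON y.hash=s.payload_hash"
        " WHERE p.modified_sequence=? AND p.charge=? AND s.ce=?",
        (modified_sequence, charge, ce)).fetchone()
    if row is None:
        raise KeyError(f"unknown precursor ({modified_sequence!r}, {charge})")
    return _fragments_from_json(row[0])


def materialize_library(store: WarehouseStore, ce_policy: CEPolicy,
                        species_regex: Optional[str] = None) -> SpectralLibrary:
    """Extract one library from the warehouse under a CE policy.

    ``ce_policy`` is either a single fixed energy or a map from
    ``(peptide_length, charge)`` bins to the energy selected for that bin.
    The library iRT is the prediction-native value (``irt0``).
    """
    from .libio import infer_species, strip_modifications, DEFAULT_SPECIES_REGEX

    lib = SpectralLibrary(meta={"source": f"warehouse:{store.path}",
                                "processing": []})
    grid = store.ce_grid
    fixed = isinstance(ce_policy, int)
    if fixed and ce_policy not in grid:
        raise ValueError(f"fixed CE {ce_policy} outside grid")
    for seq, z in store.precursor_keys():
        if fixed:
            ce = int(ce_policy)
        else:
            bin_key = (len(strip_modifications(seq)), z)
            if bin_key not in ce_policy:
                raise WarehouseError(f"CE policy does not cover bin {bin_key}")
            ce = int(ce_policy[bin_key])
        frags = query_spectrum(store, seq, z, ce)
        pg = store.conn.execute(
            "SELECT protein_group FROM precursor WHERE modified_sequence=? "
            "AND charge=?", (seq, z)).fetchone()[0] or ""
        lib.add(PrecursorRecord(
            modified_sequence=seq, precursor_charge=z, fragments=frags,
            irt=store.irt0(seq, z), protein_group=pg,
            species=infer_species(pg, species_regex or DEFAULT_SPECIES_REGEX)))
    lib.tag("CE-fixed%d" % ce_policy if fixed else "CE-LZ")
    return lib
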