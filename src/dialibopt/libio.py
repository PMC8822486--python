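"""In-memory spectral-library model and tabular readers/writers.

A DIA spectral library is a set of precursors (modified peptide sequence +
charge state), each carrying annotated fragment ions ("transitions") with
relative intensities, a normalized retention time on the iRT scale, and the
protein group(s) the peptide maps to.  Two on-disk dialects are supported:
the OpenSwath transition-list TSV and a Spectronaut-style CSV.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Optional

import pandas as pd
from pyteomics import mass as _pmass

CANONICAL_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: modification tags such as ``(UniMod:4)`` or ``[+57.02]`` embedded in a
#: modified sequence; kept verbatim in keys, stripped for length/mass work.
_MOD_TAG = re.compile(r"(\(.*?\)|\[.*?\])")

#: default rule mapping a protein accession to a species tag, e.g.
#: ``sp|P12345|ALBU_MOUSE`` -> ``MOUSE``.
DEFAULT_SPECIES_REGEX = r"_([A-Z0-9]+)$"


class LibraryFormatError(ValueError):
    """A file does not conform to the expected library dialect."""


@dataclass(frozen=True, order=True)
class FragmentIon:
    """One annotated fragment ion (transition).

    The annotation triple ``(ion_type, ordinal, frag_charge)`` identifies the
    fragment within a spectrum; intensity is relative (any positive scale).
    """

    ion_type: str  # 'b' or 'y'
    ordinal: int
    frag_charge: int
    intensity: float
    mz: Optional[float] = None

    def __post_init__(self) -> None:
        if self.ion_type not in ("b", "y"):
            raise ValueError(f"unsupported ion type {self.ion_type!r}")
        if self.ordinal < 1:
            raise ValueError("fragment ordinal must be >= 1")
        if self.frag_charge < 1:
            raise ValueError("fragment charge must be >= 1")
        if self.intensity < 0:
            raise ValueError("fragment intensity must be nonnegative")

    @property
    def annotation(self) -> tuple[str, int, int]:
        return (self.ion_type, self.ordinal, self.frag_charge)


def strip_modifications(modified_sequence: str) -> str:
    """Return the plain amino-acid sequence with modification tags removed."""
    return _MOD_TAG.sub("", modified_sequence).strip(".").replace("_", "")


def fragment_mz(stripped_sequence: str, ion: FragmentIon) -> float:
    """Monoisotopic m/z of a b- or y-ion of the given stripped sequence."""
    if ion.ion_type == "b":
        sub = stripped_sequence[: ion.ordinal]
    else:
        sub = stripped_sequence[-ion.ordinal :]
    return _pmass.fast_mass(sub, ion_type=ion.ion_type, charge=ion.frag_charge)


@dataclass
class PrecursorRecord:
    """A peptide precursor ion with its fragment set and metadata."""

    modified_sequence: str
    precursor_charge: int
    fragments: list[FragmentIon]
    irt: float
    protein_group: str = ""
    precursor_mz: Optional[float] = None
    species: Optional[str] = None

    def __post_init__(self) -> None:
        if not 1 <= self.precursor_charge <= 6:
            raise ValueError(
                f"precursor charge {self.precursor_charge} outside 1..6"
            )
        seen: set[tuple[str, int, int]] = set()
        for f in self.fragments:
            if f.annotation in seen:
                raise LibraryFormatError(
                    f"duplicate fragment annotation {f.annotation} in "
                    f"{self.key}"
                )
            seen.add(f.annotation)

    @property
    def stripped_sequence(self) -> str:
        return strip_modifications(self.modified_sequence)

    @property
    def key(self) -> tuple[str, int]:
        return (self.modified_sequence, self.precursor_charge)

    @property
    def peptide_length(self) -> int:
        return len(self.stripped_sequence)

    def is_predictable(
        self,
        min_len: int = 7,
        max_len: int = 30,
        charges: Iterable[int] = (2, 3),
    ) -> tuple[bool, Optional[str]]:
        """Check the precursor against prediction-model constraints.

        Returns ``(ok, reason)`` where reason is one of ``length``,
        ``charge`` or ``noncanonical`` when the record fails.
        """
        seq = self.stripped_sequence
        if not set(seq) <= CANONICAL_RESIDUES:
            return False, "noncanonical"
        if not min_len <= len(seq) <= max_len:
            return False, "length"
        if self.precursor_charge not in set(charges):
            return False, "charge"
        return True, None


@dataclass
class SpectralLibrary:
    """Keyed collection of precursor records with provenance metadata.

    ``meta['processing']`` is an ordered, append-only list of the
    transformation steps applied (e.g. ``['CE-LZ', '_RT', '_Pr', '_Tr']``).
    """

    records: dict[tuple[str, int], PrecursorRecord] = field(default_factory=dict)
    meta: dict = field(default_factory=lambda: {"source": None, "processing": []})

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[PrecursorRecord]:
        return iter(self.records.values())

    def __contains__(self, key: tuple[str, int]) -> bool:
        return key in self.records

    def add(self, record: PrecursorRecord) -> None:
        if record.key in self.records:
            raise ValueError(f"duplicate precursor key {record.key}")
        self.records[record.key] = record

    def with_records(self, records: Iterable[PrecursorRecord]) -> "SpectralLibrary":
        """New library with the given records and a copy of this meta."""
        out = SpectralLibrary(meta={**self.meta, "processing": list(self.meta.get("processing", []))})
        for r in records:
            out.add(r)
        return out

    def tag(self, step: str) -> None:
        self.meta.setdefault("processing", []).append(step)

    @property
    def n_transitions(self) -> int:
        return sum(len(r.fragments) for r in self)

    def variant_name(self) -> str:
        return "".join(self.meta.get("processing", [])) or "STD"


# ---------------------------------------------------------------------------
# OpenSwath TSV dialect
# ---------------------------------------------------------------------------

# canonical name -> accepted column aliases (legacy TPP/OpenMS and snake_case)
_OSW_ALIASES: dict[str, tuple[str, ...]] = {
    "modified_sequence": ("FullUniModPeptideName", "ModifiedPeptideSequence",
                          "modified_sequence", "full_unimod_peptide_name"),
    "precursor_charge": ("PrecursorCharge", "precursor_charge", "Charge"),
    "intensity": ("LibraryIntensity", "library_intensity", "RelativeIntensity",
                  "relative_intensity"),
    "irt": ("NormalizedRetentionTime", "normalized_retention_time", "Tr_recalibrated",
            "iRT", "irt"),
    "ion_type": ("FragmentType", "fragment_type", "FragmentIonType"),
    "ordinal": ("FragmentSeriesNumber", "fragment_series_number", "FragmentNumber"),
    "frag_charge": ("FragmentCharge", "fragment_charge"),
    "protein_group": ("ProteinName", "protein_name", "ProteinId", "ProteinGroup"),
}
_OSW_OPTIONAL: dict[str, tuple[str, ...]] = {
    "precursor_mz": ("PrecursorMz", "precursor_mz"),
    "product_mz": ("ProductMz", "product_mz", "FragmentMz"),
}


def _resolve_columns(columns: Iterable[str], required: dict[str, tuple[str, ...]]
                     ) -> dict[str, str]:
    present = {c: c for c in columns}
    resolved = {}
    for canon, aliases in required.items():
        for a in aliases:
            if a in present:
                resolved[canon] = a
                break
    return resolved


def infer_species(protein_group: str, regex: str = DEFAULT_SPECIES_REGEX
                  ) -> Optional[str]:
    """Parse a species tag from the first accession matching ``regex``."""
    pat = re.compile(regex)
    for acc in protein_group.split(";"):
        m = pat.search(acc.strip())
        if m:
            return m.group(1)
    return None


def read_openswath_tsv(path, species_regex: str = DEFAULT_SPECIES_REGEX
                       ) -> SpectralLibrary:
    """Read an OpenSwath transition-list TSV into a :class:`SpectralLibrary`.

    Rows are grouped by (modified sequence, precursor charge); the iRT is
    taken from the normalized-retention-time column.  Both the legacy TPP
    column names and snake_case synonyms are accepted.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = _resolve_columns(df.columns, _OSW_ALIASES)
    missing = set(_OSW_ALIASES) - set(cols)
    if missing:
        raise LibraryFormatError(
            "missing required column(s): "
            + ", ".join(sorted(_OSW_ALIASES[m][0] for m in missing))
        )
    opt = _resolve_columns(df.columns, _OSW_OPTIONAL)

    lib = SpectralLibrary(meta={"source": f"openswath_tsv:{path}", "processing": []})
    if df.empty:
        return lib
    for (seq, z), grp in df.groupby([cols["modified_sequence"],
                                     cols["precursor_charge"]], sort=True):
        z = int(z)
        frags = []
        for _, row in grp.iterrows():
            frags.append(FragmentIon(
                ion_type=str(row[cols["ion_type"]]).lower(),
                ordinal=int(row[cols["ordinal"]]),
                frag_charge=int(row[cols["frag_charge"]]),
                intensity=float(row[cols["intensity"]]),
                mz=float(row[opt["product_mz"]]) if "product_mz" in opt
                and pd.notna(row[opt["product_mz"]]) else None,
            ))
        first = grp.iloc[0]
        pg = str(first[cols["protein_group"]])
        lib.add(PrecursorRecord(
            modified_sequence=str(seq),
            precursor_charge=z,
            fragments=frags,
            irt=float(first[cols["irt"]]),
            protein_group=pg,
            precursor_mz=float(first[opt["precursor_mz"]])
            if "precursor_mz" in opt and pd.notna(first[opt["precursor_mz"]])
            else None,
            species=infer_species(pg, species_regex),
        ))
    return lib


def _sorted_fragments(rec: PrecursorRecord) -> list[FragmentIon]:
    return sorted(rec.fragments, key=lambda f: (f.ion_type, f.ordinal, f.frag_charge))


def _library_rows(lib: SpectralLibrary) -> Iterator[tuple[PrecursorRecord, FragmentIon]]:
    for key in sorted(lib.records):
        rec = lib.records[key]
        if not rec.fragments:
            raise ValueError(f"record {key} has no fragments; refusing to write")
        for frag in _sorted_fragments(rec):
            yield rec, frag


def _precursor_mz(rec: PrecursorRecord) -> float:
    if rec.precursor_mz is not None:
        return rec.precursor_mz
    return _pmass.fast_mass(rec.stripped_sequence, charge=rec.precursor_charge)


def write_openswath_tsv(lib: SpectralLibrary, path) -> None:
    """Write the library as an OpenSwath transition TSV (legacy headers).

    Row order is deterministic: precursor key, then ion type / ordinal /
    fragment charge.  Missing fragment m/z values are computed from
    monoisotopic residue masses.
    """
    rows = []
    for rec, frag in _library_rows(lib):
        rows.append({
            "PrecursorMz": round(_precursor_mz(rec), 6),
            "ProductMz": round(frag.mz if frag.mz is not None
                               else fragment_mz(rec.stripped_sequence, frag), 6),
            "LibraryIntensity": frag.intensity,
            "NormalizedRetentionTime": rec.irt,
            "PeptideSequence": rec.stripped_sequence,
            "FullUniModPeptideName": rec.modified_sequence,
            "PrecursorCharge": rec.precursor_charge,
            "FragmentType": frag.ion_type,
            "FragmentSeriesNumber": frag.ordinal,
            "FragmentCharge": frag.frag_charge,
            "ProteinName": rec.protein_group,
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_spectronaut_csv(lib: SpectralLibrary, path) -> None:
    """Write the library in a Spectronaut-style CSV layout."""
    rows = []
    for rec, frag in _library_rows(lib):
        rows.append({
            "PrecursorMz": round(_precursor_mz(rec), 6),
            "FragmentMz": round(frag.mz if frag.mz is not None
                                else fragment_mz(rec.stripped_sequence, frag), 6),
            "RelativeIntensity": frag.intensity,
            "iRT": rec.irt,
            "StrippedPeptide": rec.stripped_sequence,
            "ModifiedPeptide": rec.modified_sequence,
            "PrecursorCharge": rec.precursor_charge,
            "FragmentType": frag.ion_type,
            "FragmentNumber": frag.ordinal,
            "FragmentCharge": frag.frag_charge,
            "ProteinGroups": rec.protein_group,
        })
    pd.DataFrame(rows).to_csv(path, index=False)


def filter_predictable(
    lib: SpectralLibrary,
    min_len: int = 7,
    max_len: int = 30,
    charges: Iterable[int] = (2, 3),
) -> tuple[SpectralLibrary, dict[str, int]]:
    """Keep precursors a fragmentation predictor can handle.

    Retains records with peptide length in ``[min_len, max_len]``, precursor
    charge in ``charges`` and canonical residues only.  Returns the filtered
    library and per-reason removal counts.
    """
    removed = {"length": 0, "charge": 0, "noncanonical": 0}
    kept = []
    for rec in lib:
        ok, reason = rec.is_predictable(min_len, max_len, charges)
        if ok:
            kept.append(rec)
        else:
            removed[reason] += 1
    out = lib.with_records(kept)
    return out, removed


def copy_record(rec: PrecursorRecord, **changes) -> PrecursorRecord:
    """Shallow-copy a record, optionally replacing fields."""
    return replace(rec, fragments=list(changes.pop("fragments", rec.fragments)),
                   **changes)
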