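"""Library scope refinement from a first-pass peptide-centric analysis.

A predicted whole-proteome library is much wider than what any one DIA run
can detect, which inflates the search space.  This module trims it using a
first-pass analysis report (DIA-NN-style TSV): protein-group subsetting to
identifications passing a relaxed protein-level FDR (the ``_Pr`` variant)
and per-spectrum top-N transition filtering (the ``_Tr`` variant).  It also
carries the plain q-value report filter used for final result tables.
"""

from __future__ import annotations

from typing import Iterable

import pandas as pd

from .libio import LibraryFormatError, SpectralLibrary, copy_record

# canonical name -> DIA-NN main-report aliases
_REPORT_ALIASES: dict[str, tuple[str, ...]] = {
    "precursor_id": ("Precursor.Id", "precursor_id", "PrecursorId"),
    "protein_group": ("Protein.Group", "protein_group", "ProteinGroup",
                      "Protein.Ids"),
    "run": ("Run", "run", "File.Name"),
    "q_value_precursor": ("Q.Value", "q_value", "q_value_precursor"),
    "q_value_protein_group": ("PG.Q.Value", "pg_q_value",
                              "q_value_protein_group", "Global.PG.Q.Value"),
}


class AnalysisReport:
    """Peptide-centric analysis report with precursor/protein q-values."""

    REQUIRED = ("precursor_id", "protein_group", "run",
                "q_value_precursor", "q_value_protein_group")

    def __init__(self, df: pd.DataFrame):
        colmap = {}
        for canon, aliases in _REPORT_ALIASES.items():
            for a in aliases:
                if a in df.columns:
                    colmap[a] = canon
                    break
        df = df.rename(columns=colmap)
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise LibraryFormatError(
                "report missing required column(s): " + ", ".join(missing))
        for c in ("q_value_precursor", "q_value_protein_group"):
            df[c] = df[c].astype(float)
            if ((df[c] < 0) | (df[c] > 1)).any():
                raise LibraryFormatError(f"{c} outside [0, 1]")
        self.df = df.reset_index(drop=True)

    @classmethod
    def read_tsv(cls, path) -> "AnalysisReport":
        return cls(pd.read_csv(path, sep="\t"))

    def __len__(self) -> int:
        return len(self.df)


def filter_report(report: AnalysisReport, q_precursor: float = 0.01,
                  q_protein: float = 0.01) -> AnalysisReport:
    """Rows passing both precursor- and protein-group-level q thresholds."""
    df = report.df
    keep = (df["q_value_precursor"] <= q_precursor) & \
           (df["q_value_protein_group"] <= q_protein)
    return AnalysisReport(df[keep].reset_index(drop=True))


def detectable_proteins(report: AnalysisReport,
                        q_protein: float = 0.05) -> set[str]:
    """Protein groups identified at a (relaxed) protein-level FDR."""
    df = report.df
    return set(df.loc[df["q_value_protein_group"] <= q_protein,
                      "protein_group"].unique())


def subset_proteins(lib: SpectralLibrary, allowed: Iterable[str],
                    match: str = "accession") -> tuple[SpectralLibrary, float]:
    """Keep library records whose protein group is in ``allowed`` (``_Pr``).

    ``match='group'`` requires the full semicolon-joined group string to be
    listed; ``match='accession'`` keeps a record if any single accession is
    shared with any allowed group.  Returns the trimmed library and the
    retention fraction.
    """
    allowed = set(allowed)
    if not allowed:
        raise ValueError("allowed protein set is empty")
    if match not in ("group", "accession"):
        raise ValueError(f"unknown match mode {match!r}")
    if match == "accession":
        allowed_acc = {a.strip() for g in allowed for a in g.split(";")}

    kept = []
    for rec in lib:
        if match == "group":
            hit = rec.protein_group in allowed
        else:
            hit = bool({a.strip() for a in rec.protein_group.split(";")}
                       & allowed_acc)
        if hit:
            kept.append(rec)
    if not kept:
        raise ValueError(
            "protein subsetting removed every record — identifier spaces of "
            "the library and the report likely do not match")
    out = lib.with_records(kept)
    if out.meta.get("processing", [])[-1:] != ["_Pr"]:
        out.tag("_Pr")
    return out, len(kept) / max(len(lib), 1)


def _topn_sort_key(f):
    # highest intensity first; ties: lower ordinal, then b before y, then
    # lower fragment charge — fully deterministic output ordering
    return (-f.intensity, f.ordinal, f.ion_type, f.frag_charge)


def top_n_transitions(lib: SpectralLibrary, n_min: int = 6, n_max: int = 14,
                      keep_short: bool = False) -> SpectralLibrary:
    """Keep each spectrum's ``n_max`` most intense fragments (``_Tr``).

    Records left with fewer than ``n_min`` fragments are dropped unless
    ``keep_short`` is set.
    """
    if not 1 <= n_min <= n_max:
        raise ValueError("need 1 <= n_min <= n_max")
    kept = []
    for rec in lib:
        frags = sorted(rec.fragments, key=_topn_sort_key)[:n_max]
        if len(frags) < n_min and not keep_short:
            continue
        kept.append(copy_record(rec, fragments=frags))
    out = lib.with_records(kept)
    if out.meta.get("processing", [])[-1:] != ["_Tr"]:
        out.tag("_Tr")
    return out
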