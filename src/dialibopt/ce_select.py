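"""Collision-energy calibration by spectrum-spectrum matching.

Observed consensus spectra (from a spectrum-centric search of the DIA data)
are compared against every predicted CE variant of the matching precursor
using the normalized dot product over annotation-matched fragments.
Comparisons are binned by peptide length and precursor charge; per bin the
energy maximizing the median dot product is selected (CE-LZ policy), or a
single global optimum can be chosen for a fixed-CE workflow.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .libio import FragmentIon, SpectralLibrary
from .warehouse import WarehouseStore, query_spectrum


@dataclass(frozen=True)
class SimilarityRecord:
    """Dot-product score of one observed spectrum vs one CE variant."""

    modified_sequence: str
    charge: int
    peptide_length: int
    ce: int
    dot_product: float

    @property
    def bin(self) -> tuple[int, int]:
        return (self.peptide_length, self.charge)


@dataclass
class CEMap:
    """Selected collision energy per (peptide length, charge) bin."""

    bins: dict[tuple[int, int], int]
    n_precursors: dict[tuple[int, int], int] = field(default_factory=dict)
    median_dot: dict[tuple[int, int], float] = field(default_factory=dict)
    fallback_bins: set[tuple[int, int]] = field(default_factory=set)
    global_ce: Optional[int] = None

    def __getitem__(self, bin_key: tuple[int, int]) -> int:
        return self.bins[bin_key]

    def to_json(self, path) -> None:
        obj = {
            "bins": {f"{l},{z}": ce for (l, z), ce in sorted(self.bins.items())},
            "n_precursors": {f"{l},{z}": n
                             for (l, z), n in sorted(self.n_precursors.items())},
            "median_dot": {f"{l},{z}": d
                           for (l, z), d in sorted(self.median_dot.items())},
            "fallback_bins": sorted(f"{l},{z}" for l, z in self.fallback_bins),
            "global_ce": self.global_ce,
        }
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "CEMap":
        with open(path) as fh:
            obj = json.load(fh)
        parse = lambda s: tuple(int(x) for x in s.split(","))
        return cls(
            bins={parse(k): v for k, v in obj["bins"].items()},
            n_precursors={parse(k): v for k, v in obj["n_precursors"].items()},
            median_dot={parse(k): v for k, v in obj["median_dot"].items()},
            fallback_bins={parse(k) for k in obj["fallback_bins"]},
            global_ce=obj.get("global_ce"),
        )


def dot_product(observed: Sequence[FragmentIon],
                predicted: Sequence[FragmentIon]) -> float:
    """Normalized spectral dot product over annotation-matched fragments.

    Fragments are paired by exact annotation ``(ion_type, ordinal,
    frag_charge)``; the score is

        sum over matched pairs of I_obs * I_pred
        -----------------------------------------------------
        sqrt( sum of all I_obs^2  *  sum of all I_pred^2 )

    so unmatched fragments dilute the score through the norms only.  The
    score lies in [0, 1], is symmetric, and is invariant under positive
    rescaling of either spectrum.
    """
    if not observed or not predicted:
        raise ValueError("dot product undefined for an empty spectrum")
    obs = {f.annotation: f.intensity for f in observed}
    pred = {f.annotation: f.intensity for f in predicted}
    num = sum(obs[a] * pred[a] for a in obs.keys() & pred.keys())
    den = math.sqrt(sum(v * v for v in obs.values())
                    * sum(v * v for v in pred.values()))
    if den == 0.0:
        raise ValueError("dot product undefined for an all-zero spectrum")
    return num / den


def score_all(calib: SpectralLibrary, store: WarehouseStore
              ) -> tuple[list[SimilarityRecord], int]:
    """Score every calibration precursor against every CE variant.

    Returns the similarity records (one per matched precursor x grid energy)
    and the count of calibration precursors with no warehouse entry.
    """
    grid = store.ce_grid
    known = set(store.precursor_keys())
    records: list[SimilarityRecord] = []
    unmatched = 0
    for rec in calib:
        if rec.key not in known:
            unmatched += 1
            continue
        for ce in grid:
            pred = query_spectrum(store, rec.modified_sequence,
                                  rec.precursor_charge, ce)
            records.append(SimilarityRecord(
                modified_sequence=rec.modified_sequence,
                charge=rec.precursor_charge,
                peptide_length=rec.peptide_length,
                ce=ce,
                dot_product=dot_product(rec.fragments, pred),
            ))
    if not records:
        raise ValueError("no calibration precursor matched the warehouse; "
                         "CE calibration impossible")
    return records, unmatched


def _median_table(records: Iterable[SimilarityRecord]
                  ) -> dict[tuple[int, int], dict[int, float]]:
    """(bin -> ce -> median dot product) and implicit per-bin n."""
    scores: dict[tuple[int, int], dict[int, list[float]]] = {}
    for r in records:
        scores.setdefault(r.bin, {}).setdefault(r.ce, []).append(r.dot_product)
    return {b: {ce: float(np.median(v)) for ce, v in per_ce.items()}
            for b, per_ce in scores.items()}


def _argmax_lowest_ce(per_ce: Mapping[int, float]) -> tuple[int, float]:
    best_ce = min(ce for ce in per_ce
                  if per_ce[ce] == max(per_ce.values()))
    return best_ce, per_ce[best_ce]


def select_ce_per_bin(records: Sequence[SimilarityRecord],
                      min_bin_n: int = 20) -> CEMap:
    """Select the argmax-median CE per (length, charge) bin.

    Ties go to the lowest energy.  Bins with fewer than ``min_bin_n``
    precursors inherit the global optimum and are flagged as fallback.
    """
    if not records:
        raise ValueError("no similarity records")
    table = _median_table(records)
    n_per_bin: dict[tuple[int, int], set[str]] = {}
    for r in records:
        n_per_bin.setdefault(r.bin, set()).add(f"{r.modified_sequence}/{r.charge}")
    global_ce = select_ce_global(records)

    cemap = CEMap(bins={}, global_ce=global_ce)
    for b, per_ce in table.items():
        n = len(n_per_bin[b])
        cemap.n_precursors[b] = n
        if n < min_bin_n:
            cemap.bins[b] = global_ce
            cemap.fallback_bins.add(b)
            cemap.median_dot[b] = per_ce.get(global_ce, float("nan"))
        else:
            ce, med = _argmax_lowest_ce(per_ce)
            cemap.bins[b] = ce
            cemap.median_dot[b] = med
    return cemap


def select_ce_global(records: Sequence[SimilarityRecord]) -> int:
    """Single fixed CE maximizing the pooled median dot product."""
    if not records:
        raise ValueError("no similarity records")
    pooled: dict[int, list[float]] = {}
    for r in records:
        pooled.setdefault(r.ce, []).append(r.dot_product)
    medians = {ce: float(np.median(v)) for ce, v in pooled.items()}
    ce, _ = _argmax_lowest_ce(medians)
    return ce


def score_table(records: Sequence[SimilarityRecord]):
    """Long-format (length, charge, ce, median_dot, n) table for plotting."""
    import pandas as pd

    table = _median_table(records)
    rows = [{"peptide_length": l, "charge": z, "ce": ce, "median_dot": d}
            for (l, z), per_ce in sorted(table.items())
            for ce, d in sorted(per_ce.items())]
    return pd.DataFrame(rows)
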