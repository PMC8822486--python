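"""Seeded synthetic-data generator with planted ground truth.

Emulates every input of the library-optimization workflow so each stage is
testable without any deposited data: per-CE predicted transition tables
with a planted fragmentation optimum per (peptide length, charge) bin, an
"observed" calibration library with retention-time distortion and anchor
peptides, and an LFQ-style two-species quant matrix with known mixing
ratios.  All outputs are byte-deterministic for a fixed seed.

CE response model: every fragment of a precursor peaks at the bin's true
optimum ``mu`` but decays with its own Gaussian width, so the *relative*
intensity pattern (what a normalized spectral dot product sees) drifts
smoothly as the prediction energy moves away from ``mu``::

    I_f(c) = base_f * exp(-(c - mu)^2 / (2 * sigma_f^2)),   sigma_f ~ U around sigma_ce

A single shared width would only rescale the whole spectrum, which a
scale-invariant similarity cannot detect; the per-fragment widths are what
make the optimum recoverable.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .benchmark import MixDesign, QuantMatrix
from .libio import FragmentIon, PrecursorRecord, SpectralLibrary
from .rt_calib import IRT_KIT, IrtAnchorSet

_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


@dataclass
class SynthConfig:
    """Study conditions for the synthetic workflow inputs."""

    n_precursors_per_bin: int = 100
    lengths: Sequence[int] = tuple(range(8, 30, 2))  # 11 lengths in 7..30
    charges: Sequence[int] = (2, 3)
    ce_grid: Sequence[int] = tuple(range(20, 41))
    sigma_ce: float = 4.0              # mean per-fragment CE response width
    sigma_ce_spread: float = 2.0       # half-range of per-fragment widths
    intensity_noise_sigma: float = 0.15  # lognormal sigma on observed spectra
    n_fragments: int = 10
    irt_range: tuple[float, float] = (-20.0, 120.0)
    # observed-RT model: rt_seconds = rt_intercept + rt_slope*irt + sigmoid
    rt_slope: float = 30.0
    rt_intercept: float = 1200.0
    rt_sigmoid_amplitude: float = 0.0
    rt_sigmoid_scale: float = 30.0
    rt_noise_sigma: float = 0.0        # seconds
    # prediction-scale distortion: irt0 = pred_slope*irt + pred_intercept (+sigmoid)
    pred_slope: float = 1.0
    pred_intercept: float = 0.0
    # quant benchmark
    species_ratios: dict = field(default_factory=lambda: {"MOUSE": 6.0,
                                                          "YEAST": 1.0 / 6.0})
    n_analytes: int = 2000
    runs_per_condition: int = 3
    quant_noise_sigma: float = 0.0     # lognormal sigma per replicate
    bad_fraction: float = 0.0          # planted out-of-band analytes
    tolerance: float = 0.20
    seed: int = 1

    def rng(self, stream: str) -> np.random.Generator:
        # stable cross-process stream separation (no PYTHONHASHSEED exposure)
        tag = zlib.crc32(stream.encode()) % (2**31)
        return np.random.default_rng(np.random.SeedSequence([self.seed, tag]))


def _true_ce(length: int, charge: int, ce_grid: Sequence[int]) -> int:
    """Planted optimum: increases with length and charge, clipped to grid."""
    mu = 22 + 0.4 * (length - 7) + 5 * (charge - 2)
    return int(np.clip(round(mu), min(ce_grid), max(ce_grid)))


def _random_peptides(rng: np.random.Generator, n: int, length: int
                     ) -> list[str]:
    seqs: set[str] = set()
    while len(seqs) < n:
        block = ["".join(rng.choice(_AA, size=length))
                 for _ in range(n - len(seqs))]
        seqs.update(block)
    return sorted(seqs)[:n]


@dataclass
class SynthTruth:
    """Ground-truth sidecar for a generated warehouse/calibration pair."""

    bin_optimum: dict[tuple[int, int], int]
    true_irt: dict[tuple[str, int], float]
    fragment_widths: dict[tuple[str, int], list[float]]

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({
                "bin_optimum": {f"{l},{z}": c
                                for (l, z), c in sorted(self.bin_optimum.items())},
                "true_irt": {f"{s}/{z}": v
                             for (s, z), v in sorted(self.true_irt.items())},
            }, fh, indent=1, sort_keys=True)


def gen_warehouse_tables(cfg: SynthConfig
                         ) -> tuple[dict[int, SpectralLibrary], SynthTruth]:
    """Per-CE predicted transition tables with a planted optimum per bin."""
    rng = cfg.rng("warehouse")
    grid = tuple(cfg.ce_grid)
    bin_optimum: dict[tuple[int, int], int] = {}
    true_irt: dict[tuple[str, int], float] = {}
    widths: dict[tuple[str, int], list[float]] = {}

    tables = {ce: SpectralLibrary(meta={"source": f"synth:ce{ce}",
                                        "processing": []}) for ce in grid}
    species = sorted(cfg.species_ratios) or ["MOUSE"]
    pidx = 0
    for length in cfg.lengths:
        peptides = _random_peptides(rng, cfg.n_precursors_per_bin *
                                    len(cfg.charges), length)
        for zi, charge in enumerate(cfg.charges):
            bin_key = (length, charge)
            mu = _true_ce(length, charge, grid)
            bin_optimum[bin_key] = mu
            chunk = peptides[zi * cfg.n_precursors_per_bin:
                             (zi + 1) * cfg.n_precursors_per_bin]
            for seq in chunk:
                n_frag = min(cfg.n_fragments, 2 * (length - 1))
                base = rng.dirichlet(np.ones(n_frag)) + 1e-4
                sig = rng.uniform(cfg.sigma_ce - cfg.sigma_ce_spread,
                                  cfg.sigma_ce + cfg.sigma_ce_spread,
                                  size=n_frag)
                irt = rng.uniform(*cfg.irt_range)
                sp = species[pidx % len(species)]
                pg = f"sp|Q{pidx:05d}|SYN{pidx:05d}_{sp}"
                pidx += 1
                annots = _fragment_annotations(length, n_frag)
                true_irt[(seq, charge)] = irt
                widths[(seq, charge)] = sig.tolist()
                for ce in grid:
                    decay = np.exp(-((ce - mu) ** 2) / (2.0 * sig ** 2))
                    frags = [FragmentIon(ion_type=t, ordinal=o, frag_charge=fz,
                                         intensity=float(b * d))
                             for (t, o, fz), b, d in zip(annots, base, decay)]
                    tables[ce].add(PrecursorRecord(
                        modified_sequence=seq, precursor_charge=charge,
                        fragments=frags, irt=cfg.pred_slope * irt
                        + cfg.pred_intercept, protein_group=pg, species=sp))
    return tables, SynthTruth(bin_optimum=bin_optimum, true_irt=true_irt,
                              fragment_widths=widths)


def _fragment_annotations(length: int, n: int) -> list[tuple[str, int, int]]:
    """First n annotations alternating y/b series, singly charged."""
    out = []
    for k in range(1, length):
        out.append(("y", k, 1))
        if len(out) == n:
            break
        out.append(("b", k, 1))
        if len(out) == n:
            break
    return out


def _rt_distortion(cfg: SynthConfig, irt: np.ndarray) -> np.ndarray:
    mid = 0.5 * (cfg.irt_range[0] + cfg.irt_range[1])
    rt = cfg.rt_intercept + cfg.rt_slope * irt
    if cfg.rt_sigmoid_amplitude:
        rt = rt + cfg.rt_sigmoid_amplitude * np.tanh(
            (irt - mid) / cfg.rt_sigmoid_scale)
    return rt


def gen_calibration_lib(cfg: SynthConfig,
                        tables: dict[int, SpectralLibrary],
                        truth: SynthTruth,
                        match_fraction: float = 1.0
                        ) -> tuple[SpectralLibrary, IrtAnchorSet]:
    """Observed calibration library plus RT anchor table.

    Each observed spectrum is the warehouse spectrum at the bin's true
    optimum with multiplicative lognormal intensity noise; the observed RT
    (stored as the record iRT after anchor conversion upstream would be
    applied — here the raw observed-scale iRT) follows the configured
    linear+sigmoid distortion of the true iRT plus Gaussian noise.
    """
    rng = cfg.rng("calibration")
    grid = tuple(cfg.ce_grid)
    ref = tables[grid[0]]
    keys = sorted(ref.records)
    if match_fraction < 1.0:
        n_keep = int(round(match_fraction * len(keys)))
        keys = sorted(rng.choice(len(keys), size=n_keep, replace=False))
        keys = [sorted(ref.records)[i] for i in keys]

    lib = SpectralLibrary(meta={"source": "synth:calibration", "processing": []})
    for seq, z in keys:
        bin_key = (len(seq), z)
        mu = truth.bin_optimum[bin_key]
        pred = tables[mu].records[(seq, z)]
        noise = (np.exp(rng.normal(0.0, cfg.intensity_noise_sigma,
                                   size=len(pred.fragments)))
                 if cfg.intensity_noise_sigma > 0
                 else np.ones(len(pred.fragments)))
        frags = [FragmentIon(ion_type=f.ion_type, ordinal=f.ordinal,
                             frag_charge=f.frag_charge,
                             intensity=float(f.intensity * m))
                 for f, m in zip(pred.fragments, noise)]
        irt_true = truth.true_irt[(seq, z)]
        rt_obs = float(_rt_distortion(cfg, np.array([irt_true]))[0])
        if cfg.rt_noise_sigma > 0:
            rt_obs += float(rng.normal(0.0, cfg.rt_noise_sigma))
        lib.add(PrecursorRecord(
            modified_sequence=seq, precursor_charge=z, fragments=frags,
            irt=rt_obs, protein_group=pred.protein_group,
            species=pred.species))

    anchors_irt = np.array(sorted(IRT_KIT.values()))
    anchors_pep = sorted(IRT_KIT, key=IRT_KIT.get)
    rt = _rt_distortion(cfg, anchors_irt)
    if cfg.rt_noise_sigma > 0:
        rt = rt + rng.normal(0.0, cfg.rt_noise_sigma, size=len(rt))
    return lib, IrtAnchorSet(peptides=anchors_pep, known_irt=anchors_irt,
                             observed_rt=rt)


def gen_quant(cfg: SynthConfig
              ) -> tuple[QuantMatrix, MixDesign, pd.Series]:
    """Two-species, two-condition quant matrix with planted validity truth.

    Analyte base abundance is lognormal; condition means are scaled by the
    species mixing ratio; replicate intensities carry multiplicative
    lognormal noise.  A planted fraction of "bad" analytes get their
    condition-A mean pushed far outside the tolerance band; the returned
    boolean series marks the analytes planted as good.
    """
    rng = cfg.rng("quant")
    species = sorted(cfg.species_ratios)
    n = cfg.n_analytes
    sp = np.array([species[i % len(species)] for i in range(n)])
    base = rng.lognormal(mean=np.log(1e5), sigma=1.0, size=n)

    ids = [f"PEP{i:05d}_{sp[i]}" for i in range(n)]
    good = np.ones(n, dtype=bool)
    if cfg.bad_fraction > 0:
        n_bad = int(round(cfg.bad_fraction * n))
        bad_idx = rng.choice(n, size=n_bad, replace=False)
        good[bad_idx] = False

    runs = {}
    for cond in ("A", "B"):
        for rep in range(cfg.runs_per_condition):
            run = f"{cond}{rep + 1}"
            ratio = np.array([cfg.species_ratios[s] for s in sp])
            mean = base * ratio if cond == "A" else base.copy()
            # planted bad analytes: shift condition-A mean 3x out of band
            if cond == "A":
                mean = np.where(good, mean, mean * 3.0)
            mult = (np.exp(rng.normal(0.0, cfg.quant_noise_sigma, size=n))
                    if cfg.quant_noise_sigma > 0 else 1.0)
            runs[run] = mean * mult
    values = pd.DataFrame(runs, index=ids)
    run_condition = {r: r[0] for r in values.columns}
    analyte_species = dict(zip(ids, sp))
    design = MixDesign(ratios=dict(cfg.species_ratios),
                       tolerance=cfg.tolerance)
    return (QuantMatrix(values=values, run_condition=run_condition,
                        analyte_species=analyte_species),
            design, pd.Series(good, index=ids, name="planted_good"))


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

def preset(name: str, seed: int = 1) -> SynthConfig:
    """Named study conditions: ce-recovery, rt-recovery, lfq-mix."""
    if name == "ce-recovery":
        return SynthConfig(
            n_precursors_per_bin=100,
            lengths=tuple(range(7, 30, 2)),  # 12 lengths x 2 charges = 24 bins
            charges=(2, 3),
            intensity_noise_sigma=0.15,
            seed=seed,
        )
    if name == "rt-recovery":
        return SynthConfig(
            n_precursors_per_bin=40,
            lengths=(8, 12, 16, 20),
            charges=(2,),
            rt_sigmoid_amplitude=400.0,
            rt_noise_sigma=15.0,
            pred_slope=1.1,
            pred_intercept=-4.0,
            seed=seed,
        )
    if name == "lfq-mix":
        return SynthConfig(n_analytes=2000, quant_noise_sigma=0.1,
                           runs_per_condition=3, seed=seed)
    raise ValueError(f"unknown preset {name!r}")
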