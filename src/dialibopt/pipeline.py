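"""Full optimization pipeline: CE selection -> RT replacement -> protein
subsetting -> transition filtering, with provenance stamping.

Each stage can be toggled, mapping onto the library variants: the fixed-CE
baseline ("STD"), length/charge-variable CE ("CE-LZ"), and the cumulative
``_RT``, ``_Pr`` and ``_Tr`` refinements.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import dataclass, field
from importlib.metadata import version, PackageNotFoundError
from pathlib import Path
from typing import Optional

from . import ce_select, refine, rt_calib
from .libio import SpectralLibrary, filter_predictable, write_openswath_tsv
from .refine import AnalysisReport
from .warehouse import WarehouseStore, materialize_library

log = logging.getLogger("dialibopt")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[stage {stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Stage toggles and thresholds for one pipeline run."""

    ce_mode: str = "variable"          # 'fixed' | 'variable' | 'off'
    fixed_ce: int = 30                 # used when ce_mode != 'variable'
    rt: bool = True
    pr: bool = True
    tr: bool = True
    q_protein: float = 0.05
    n_min: int = 6
    n_max: int = 14
    keep_short: bool = False
    rt_frac: float = 0.25
    rt_kind: str = "piecewise_linear"
    min_bin_n: int = 20
    protein_match: str = "accession"
    seed: int = 1
    out_dir: Optional[str] = None

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**json.load(fh))


@dataclass
class StageReport:
    name: str
    n_in: int
    n_out: int
    detail: dict = field(default_factory=dict)


def run_pipeline(cfg: RunConfig,
                 store: WarehouseStore,
                 calib: Optional[SpectralLibrary] = None,
                 anchors: Optional[rt_calib.IrtAnchorSet] = None,
                 report: Optional[AnalysisReport] = None,
                 ) -> tuple[SpectralLibrary, list[StageReport]]:
    """Run the stages in order and return the final library plus reports.

    ``calib`` (and ``anchors`` for RT work) are required when CE selection
    or RT calibration is enabled; ``report`` is required for protein
    subsetting.  Any stage failure raises :class:`PipelineError` naming the
    stage; the library produced by the preceding stages is attached as
    ``err.partial`` so partial outputs can be retained.
    """
    stages: list[StageReport] = []
    lib: Optional[SpectralLibrary] = None

    def _fail(stage: str, msg: str):
        err = PipelineError(stage, msg)
        err.partial = lib
        raise err

    # -- stage 1: collision-energy policy -----------------------------------
    if cfg.ce_mode == "variable":
        if calib is None:
            _fail("ce", "variable CE selection needs a calibration library")
        calib_f, removed = filter_predictable(calib)
        try:
            records, unmatched = ce_select.score_all(calib_f, store)
            cemap = ce_select.select_ce_per_bin(records, min_bin_n=cfg.min_bin_n)
        except ValueError as e:
            _fail("ce", str(e))
        # cover every warehouse bin; uncovered bins fall back to the global CE
        policy = dict(cemap.bins)
        from .libio import strip_modifications
        for seq, z in store.precursor_keys():
            b = (len(strip_modifications(seq)), z)
            policy.setdefault(b, cemap.global_ce)
        lib = materialize_library(store, policy)
        stages.append(StageReport("ce", store.n_precursors, len(lib),
                                  {"mode": "variable",
                                   "bins": len(cemap.bins),
                                   "fallback_bins": len(cemap.fallback_bins),
                                   "global_ce": cemap.global_ce,
                                   "unmatched_calibration": unmatched,
                                   "calib_removed": removed}))
    elif cfg.ce_mode in ("fixed", "off"):
        lib = materialize_library(store, int(cfg.fixed_ce))
        stages.append(StageReport("ce", store.n_precursors, len(lib),
                                  {"mode": cfg.ce_mode, "ce": cfg.fixed_ce}))
    else:
        _fail("ce", f"unknown ce_mode {cfg.ce_mode!r}")

    # -- stage 2: retention-time replacement ---------------------------------
    if cfg.rt:
        if calib is None or anchors is None:
            _fail("rt", "RT calibration needs a calibration library and anchors")
        rt_map = rt_calib.fit_rt_to_irt(anchors)
        keys = [k for k in sorted(calib.records) if k in lib.records]
        if len(keys) < 10:
            _fail("rt", f"only {len(keys)} calibration targets overlap the library")
        predicted = [lib.records[k].irt for k in keys]
        observed = [float(rt_map(calib.records[k].irt)) for k in keys]
        try:
            model = rt_calib.fit_calibration(predicted, observed,
                                             frac=cfg.rt_frac,
                                             kind=cfg.rt_kind, seed=cfg.seed)
        except ValueError as e:
            _fail("rt", str(e))
        lib = rt_calib.apply_rt(lib, model)
        stages.append(StageReport("rt", len(lib), len(lib),
                                  {"kind": model.kind,
                                   "residual_mad": model.residual_mad,
                                   "anchor_r2": rt_map.r_squared,
                                   "n_calibration_targets": len(keys)}))

    # -- stage 3: protein subsetting -----------------------------------------
    if cfg.pr:
        if report is None:
            _fail("pr", "protein subsetting needs a first-pass analysis report")
        allowed = refine.detectable_proteins(report, q_protein=cfg.q_protein)
        n_in = len(lib)
        try:
            lib, retained = refine.subset_proteins(lib, allowed,
                                                   match=cfg.protein_match)
        except ValueError as e:
            _fail("pr", str(e))
        stages.append(StageReport("pr", n_in, len(lib),
                                  {"q_protein": cfg.q_protein,
                                   "allowed_groups": len(allowed),
                                   "retained_fraction": retained}))

    # -- stage 4: transition filtering ---------------------------------------
    if cfg.tr:
        n_in = len(lib)
        lib = refine.top_n_transitions(lib, n_min=cfg.n_min, n_max=cfg.n_max,
                                       keep_short=cfg.keep_short)
        stages.append(StageReport("tr", n_in, len(lib),
                                  {"n_min": cfg.n_min, "n_max": cfg.n_max}))

    for s in stages:
        log.info("stage %-3s %6d -> %6d  %s", s.name, s.n_in, s.n_out, s.detail)

    if cfg.out_dir:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_openswath_tsv(lib, out / f"library_{lib.variant_name()}.tsv")
        _write_provenance(out / "provenance.json", cfg, lib, stages)
    return lib, stages


def _write_provenance(path, cfg: RunConfig, lib: SpectralLibrary,
                      stages: list[StageReport]) -> None:
    try:
        pkg_version = version("dialibopt")
    except PackageNotFoundError:
        pkg_version = "unknown"
    with open(path, "w") as fh:
        json.dump({
            "package_version": pkg_version,
            "python": platform.python_version(),
            "config": {k: v for k, v in vars(cfg).items()},
            "variant": lib.variant_name(),
            "n_precursors": len(lib),
            "n_transitions": lib.n_transitions,
            "stages": [{"name": s.name, "n_in": s.n_in, "n_out": s.n_out,
                        "detail": s.detail} for s in stages],
        }, fh, indent=1, sort_keys=True)
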