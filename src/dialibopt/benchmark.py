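"""Ground-truth species-mixture validation and quantification metrics.

In a two-proteome benchmark design, samples of condition A and B contain
two species mixed at known, inverted ratios (e.g. 6:1 and 1:6 v/v
mouse-yeast), so every analyte's cross-condition ratio has a known
expectation determined solely by its species.  An identification is
"valid" when its observed linear-scale ratio falls within a +/-20%
tolerance band around that expectation.  Quality metrics summarize the
log2 fold-change distributions (IQR = precision, KDE-mode offset =
accuracy), within-condition replicate CVs, and percent deviation from the
expected ratio.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde


@dataclass
class MixDesign:
    """Expected linear ratio (condition A over B) per species."""

    ratios: dict[str, float]
    tolerance: float = 0.20
    condition_a: str = "A"
    condition_b: str = "B"

    def __post_init__(self) -> None:
        if not 0 < self.tolerance < 1:
            raise ValueError("tolerance must be in (0, 1)")
        if any(r <= 0 for r in self.ratios.values()):
            raise ValueError("expected ratios must be positive")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"ratios": self.ratios, "tolerance": self.tolerance,
                       "condition_a": self.condition_a,
                       "condition_b": self.condition_b}, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "MixDesign":
        with open(path) as fh:
            o = json.load(fh)
        return cls(ratios=o["ratios"], tolerance=o["tolerance"],
                   condition_a=o.get("condition_a", "A"),
                   condition_b=o.get("condition_b", "B"))


@dataclass
class QuantMatrix:
    """Analyte x run intensity matrix with condition and species labels."""

    values: pd.DataFrame  # index: analyte id, columns: run id, NaN = missing
    run_condition: dict[str, str]
    analyte_species: dict[str, str]

    def __post_init__(self) -> None:
        missing = set(self.values.columns) - set(self.run_condition)
        if missing:
            raise ValueError(f"runs without condition label: {sorted(missing)}")
        conds = set(self.run_condition.values())
        for c in conds:
            if not any(v == c for v in self.run_condition.values()):
                raise ValueError(f"condition {c} has no runs")

    def runs_of(self, condition: str) -> list[str]:
        return [r for r in self.values.columns
                if self.run_condition[r] == condition]

    def to_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t", index_label="analyte")


def preprocess(matrix: QuantMatrix, drop_nonpos_log2: bool = True,
               median_normalize: bool = False) -> QuantMatrix:
    """Entry-level cleanup before ratio work.

    Intensities with log2 <= 0 (i.e. <= 1 on the linear scale) are set to
    missing; optional median normalization rescales each run so all
    run-level medians of log2 intensity equal their grand median.
    """
    vals = matrix.values.copy().astype(float)
    if drop_nonpos_log2:
        vals = vals.mask(vals <= 1.0)
    if median_normalize:
        log2 = np.log2(vals)
        run_med = log2.median(axis=0, skipna=True)
        grand = float(np.nanmedian(run_med.to_numpy()))
        vals = vals.mul(2.0 ** (grand - run_med), axis=1)
    return QuantMatrix(values=vals, run_condition=dict(matrix.run_condition),
                       analyte_species=dict(matrix.analyte_species))


def _condition_summary(matrix: QuantMatrix, aggregator: str) -> pd.DataFrame:
    out = {}
    for cond in sorted(set(matrix.run_condition.values())):
        sub = matrix.values[matrix.runs_of(cond)]
        if aggregator == "mean":
            out[cond] = sub.mean(axis=1, skipna=True)
        elif aggregator == "geometric_mean":
            out[cond] = np.exp(np.log(sub).mean(axis=1, skipna=True))
        else:
            raise ValueError(f"unknown aggregator {aggregator!r}")
    return pd.DataFrame(out)


def ratio_validate(matrix: QuantMatrix, design: MixDesign,
                   aggregator: str = "mean") -> pd.DataFrame:
    """Per-analyte observed-vs-expected ratio check.

    Observed ratio = aggregated condition-A intensity over condition-B
    intensity on the linear scale; ``valid`` when it lies in the inclusive
    band ``[(1-tol)*r, (1+tol)*r]`` around the species' expected ratio
    ``r``.  Analytes missing a whole condition, or without a species
    expectation, are excluded (column ``excluded_reason``).
    """
    summ = _condition_summary(matrix, aggregator)
    a, b = design.condition_a, design.condition_b
    if a not in summ.columns or b not in summ.columns:
        raise ValueError(f"matrix lacks condition {a!r} or {b!r}")
    rows = []
    tol = design.tolerance
    for analyte in matrix.values.index:
        sp = matrix.analyte_species.get(analyte)
        va, vb = summ.at[analyte, a], summ.at[analyte, b]
        reason = None
        if sp not in design.ratios:
            reason = "unknown_species"
        elif not np.isfinite(va) or not np.isfinite(vb) or vb == 0:
            reason = "missing_condition"
        if reason:
            rows.append({"analyte": analyte, "species": sp,
                         "observed_ratio": np.nan, "expected_ratio": np.nan,
                         "valid": False, "excluded_reason": reason})
            continue
        r = design.ratios[sp]
        obs = va / vb
        # inclusive band with a relative epsilon so exact-boundary ratios
        # (e.g. 0.8*r) are not lost to floating-point rounding
        eps = 1e-9
        lo, hi = (1 - tol) * r * (1 - eps), (1 + tol) * r * (1 + eps)
        rows.append({"analyte": analyte, "species": sp,
                     "observed_ratio": obs, "expected_ratio": r,
                     "valid": bool(lo <= obs <= hi),
                     "excluded_reason": None})
    return pd.DataFrame(rows).set_index("analyte")


def valid_counts(validation: pd.DataFrame) -> dict[str, int]:
    usable = validation[validation["excluded_reason"].isna()]
    return {"n_tested": int(len(usable)),
            "n_valid": int(usable["valid"].sum()),
            "n_excluded": int(validation["excluded_reason"].notna().sum())}


def _kde_mode(x: np.ndarray, grid_points: int = 512) -> float:
    """Mode of a distribution as the argmax of a Silverman-bandwidth KDE."""
    x = x[np.isfinite(x)]
    if len(np.unique(x)) == 1:
        return float(x[0])
    kde = gaussian_kde(x, bw_method="silverman")
    lo, hi = x.min(), x.max()
    pad = 0.1 * (hi - lo)
    grid = np.linspace(lo - pad, hi + pad, grid_points)
    return float(grid[np.argmax(kde(grid))])


def quality_metrics(matrix: QuantMatrix, design: MixDesign,
                    aggregator: str = "mean",
                    min_analytes: int = 3) -> dict:
    """Precision, accuracy, replicate-CV and percent-change summaries.

    Returns per-species IQR of the log2 fold-change distribution, the
    KDE-mode offset from log2(expected ratio), per-condition distributions
    of replicate CV (sd/mean per analyte), and per-species percent change
    ``100*(observed/expected - 1)``.
    """
    summ = _condition_summary(matrix, aggregator)
    a, b = design.condition_a, design.condition_b
    with np.errstate(divide="ignore", invalid="ignore"):
        log2fc = np.log2(summ[a] / summ[b])

    per_species: dict[str, dict] = {}
    for sp, r in design.ratios.items():
        ids = [an for an in matrix.values.index
               if matrix.analyte_species.get(an) == sp]
        fc = log2fc.loc[ids].to_numpy()
        fc = fc[np.isfinite(fc)]
        if len(fc) < min_analytes:
            per_species[sp] = {"missing": f"only {len(fc)} analytes"}
            continue
        q75, q25 = np.percentile(fc, [75, 25])
        mode = _kde_mode(fc)
        obs_ratio = 2.0 ** fc
        per_species[sp] = {
            "n": int(len(fc)),
            "log2fc_iqr": float(q75 - q25),
            "mode_offset": float(mode - np.log2(r)),
            "pct_change": (100.0 * (obs_ratio / r - 1.0)).tolist(),
        }

    cv: dict[str, dict] = {}
    for cond in sorted(set(matrix.run_condition.values())):
        sub = matrix.values[matrix.runs_of(cond)]
        if sub.shape[1] < 2:
            cv[cond] = {"missing": "fewer than 2 replicates"}
            continue
        sd = sub.std(axis=1, ddof=1, skipna=True)
        mean = sub.mean(axis=1, skipna=True)
        vals = (sd / mean).to_numpy()
        vals = vals[np.isfinite(vals)]
        cv[cond] = {"n": int(len(vals)),
                    "median_cv": float(np.median(vals)) if len(vals) else np.nan,
                    "cv": vals.tolist()}
    return {"per_species": per_species, "replicate_cv": cv}


def compare_libraries(results: Mapping[str, dict[str, int]],
                      baseline: str) -> pd.DataFrame:
    """Valid-identification counts relative to a named baseline library.

    ``results`` maps library name to ``{level: count}`` (e.g. peptide /
    protein counts); the output adds ``pct_change`` columns,
    ``100*(count/baseline - 1)`` per level.
    """
    if baseline not in results:
        raise ValueError(f"baseline {baseline!r} not among results")
    base = results[baseline]
    if any(v == 0 for v in base.values()):
        raise ValueError("baseline has a zero count; percent change undefined")
    rows = []
    for name, counts in results.items():
        row = {"library": name, **counts}
        for level, count in counts.items():
            row[f"pct_change_{level}"] = 100.0 * (count / base[level] - 1.0)
        rows.append(row)
    return pd.DataFrame(rows).set_index("library")


def quantify_sum(fragment_table: pd.DataFrame,
                 analyte_col: str = "analyte",
                 run_col: str = "run",
                 intensity_col: str = "intensity") -> pd.DataFrame:
    """Stand-in quantifier: per-analyte, per-run sum of fragment signals.

    Deliberately simple (no MaxLFQ-style pairwise ratio modelling); used for
    end-to-end synthetic benchmarks where the generator controls the truth.
    """
    return (fragment_table
            .groupby([analyte_col, run_col])[intensity_col].sum()
            .unstack(run_col))
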