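import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from dialibopt import synthgen as sg
from dialibopt.benchmark import (
    MixDesign,
    QuantMatrix,
    compare_libraries,
    preprocess,
    quality_metrics,
    quantify_sum,
    ratio_validate,
    valid_counts,
)


def _matrix(values, species=None):
    df = pd.DataFrame(values)  # outer keys are runs -> columns; rows: analytes
    run_condition = {c: c[0] for c in df.columns}
    species = species or {a: "MOUSE" for a in df.index}
    return QuantMatrix(values=df, run_condition=run_condition,
                       analyte_species=species)


def _design(ratio=6.0, tol=0.20):
    return MixDesign(ratios={"MOUSE": ratio}, tolerance=tol)


class TestPreprocess:
    def test_log2_nonpositive_entries_removed(self):
        m = _matrix({"A1": {"x": 1.0, "y": 2.0}, "B1": {"x": 0.5, "y": 8.0}})
        out = preprocess(m)
        assert np.isnan(out.values.at["x", "A1"])
        assert np.isnan(out.values.at["x", "B1"])
        assert out.values.at["y", "A1"] == 2.0

    def test_normalized_run_medians_equal(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(rng.lognormal(10, 1, size=(50, 4)),
                          index=[f"a{i}" for i in range(50)],
                          columns=["A1", "A2", "B1", "B2"])
        df["B1"] *= 7.0  # per-run scale distortion
        m = QuantMatrix(values=df, run_condition={c: c[0] for c in df.columns},
                        analyte_species={a: "MOUSE" for a in df.index})
        out = preprocess(m, median_normalize=True)
        meds = np.log2(out.values).median(axis=0)
        assert np.allclose(meds, meds.iloc[0])

    def test_normalization_preserves_within_run_rank_order(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(rng.lognormal(8, 1, size=(30, 2)),
                          columns=["A1", "B1"],
                          index=[f"a{i}" for i in range(30)])
        m = QuantMatrix(values=df, run_condition={"A1": "A", "B1": "B"},
                        analyte_species={a: "MOUSE" for a in df.index})
        out = preprocess(m, median_normalize=True)
        for c in df.columns:
            assert (df[c].rank() == out.values[c].rank()).all()


class TestRatioValidate:
    @pytest.mark.parametrize("obs_over_base,valid", [
        (6.0, True),        # exact
        (4.8, True),        # 0.8 * 6, inclusive lower bound
        (7.2, True),        # 1.2 * 6, inclusive upper bound
        (7.3, False),       # just above the band
        (4.7, False),       # just below the band
    ])
    def test_band_boundaries(self, obs_over_base, valid):
        m = _matrix({"A1": {"x": obs_over_base * 100}, "B1": {"x": 100.0}})
        out = ratio_validate(m, _design())
        assert bool(out.at["x", "valid"]) is valid
        assert out.at["x", "observed_ratio"] == pytest.approx(obs_over_base)

    def test_missing_condition_excluded_and_counted(self):
        m = _matrix({"A1": {"x": np.nan, "y": 600.0},
                     "B1": {"x": 50.0, "y": 100.0}})
        out = ratio_validate(m, _design())
        assert out.at["x", "excluded_reason"] == "missing_condition"
        counts = valid_counts(out)
        assert counts == {"n_tested": 1, "n_valid": 1, "n_excluded": 1}

    def test_validity_invariant_under_global_rescaling(self):
        rng = np.random.default_rng(4)
        base = rng.lognormal(8, 1, 100)
        vals = {"A1": dict(zip(range(100), base * 6)),
                "B1": dict(zip(range(100), base))}
        m1 = _matrix(vals)
        m2 = QuantMatrix(values=m1.values * 1234.5,
                         run_condition=m1.run_condition,
                         analyte_species=m1.analyte_species)
        v1 = ratio_validate(m1, _design())
        v2 = ratio_validate(m2, _design())
        assert (v1["valid"] == v2["valid"]).all()

    def test_normalization_restores_validity_under_per_run_scaling(self):
        # symmetric two-species design: per-run value multisets are equal, so
        # median normalization removes arbitrary run factors without touching
        # the species fold changes
        rng = np.random.default_rng(5)
        base = rng.lognormal(8, 0.5, 100)
        ids = [f"m{i}" for i in range(100)] + [f"y{i}" for i in range(100)]
        df = pd.DataFrame(
            {"A1": np.concatenate([base * 6, base]),
             "A2": np.concatenate([base * 6, base]),
             "B1": np.concatenate([base, base * 6]),
             "B2": np.concatenate([base, base * 6])}, index=ids)
        df["A2"] *= 3.0  # arbitrary per-run factor breaks raw ratios
        species = {a: ("MOUSE" if a.startswith("m") else "YEAST") for a in ids}
        design = MixDesign(ratios={"MOUSE": 6.0, "YEAST": 1 / 6})
        m = QuantMatrix(values=df, run_condition={c: c[0] for c in df.columns},
                        analyte_species=species)
        raw = ratio_validate(m, design)
        fixed = ratio_validate(preprocess(m, median_normalize=True), design)
        assert not raw["valid"].all()
        assert fixed["valid"].all()

    def test_noisy_valid_fraction_matches_analytic_probability(self):
        """One run per condition, lognormal noise sigma: the log ratio error
        is N(0, 2 sigma^2), so P(valid) has a closed form; the empirical
        fraction must sit within 3 binomial SE of it."""
        sigma = 0.1
        cfg = sg.SynthConfig(n_analytes=2000, quant_noise_sigma=sigma,
                             runs_per_condition=1, seed=9)
        matrix, design, _ = sg.gen_quant(cfg)
        frac = np.mean(ratio_validate(matrix, design)["valid"])
        s = sigma * np.sqrt(2)
        p = norm.cdf(np.log(1.2) / s) - norm.cdf(np.log(0.8) / s)
        se = np.sqrt(p * (1 - p) / 2000)
        assert abs(frac - p) <= 3 * se


class TestQualityMetrics:
    def test_replicate_cv_values(self):
        m = _matrix({"A1": {"x": 100, "y": 90}, "A2": {"x": 100, "y": 100},
                     "A3": {"x": 100, "y": 110}, "B1": {"x": 1, "y": 1},
                     "B2": {"x": 1, "y": 1}})
        out = quality_metrics(m, _design(), min_analytes=1)
        cv = dict(zip(m.values.index, out["replicate_cv"]["A"]["cv"]))
        assert cv["x"] == pytest.approx(0.0)
        assert cv["y"] == pytest.approx(0.10)

    def test_mode_offset_near_zero_for_centered_distribution(self):
        rng = np.random.default_rng(6)
        n = 500
        fc = rng.normal(np.log2(6), 0.1, n)
        df = pd.DataFrame({"A1": 2.0 ** fc * 1000, "B1": np.full(n, 1000.0)},
                          index=[f"a{i}" for i in range(n)])
        m = QuantMatrix(values=df, run_condition={"A1": "A", "B1": "B"},
                        analyte_species={a: "MOUSE" for a in df.index})
        out = quality_metrics(m, _design())
        assert abs(out["per_species"]["MOUSE"]["mode_offset"]) < 0.05

    def test_insufficient_analytes_reported_missing(self):
        m = _matrix({"A1": {"x": 600.0}, "B1": {"x": 100.0}})
        out = quality_metrics(m, _design(), min_analytes=3)
        assert "missing" in out["per_species"]["MOUSE"]
        assert "missing" in out["replicate_cv"]["A"]

    def test_iqr_matches_percentile_oracle(self):
        rng = np.random.default_rng(8)
        n = 200
        fc = rng.normal(np.log2(6), 0.3, n)
        df = pd.DataFrame({"A1": 2.0 ** fc * 1e4, "B1": np.full(n, 1e4)},
                          index=[f"a{i}" for i in range(n)])
        m = QuantMatrix(values=df, run_condition={"A1": "A", "B1": "B"},
                        analyte_species={a: "MOUSE" for a in df.index})
        out = quality_metrics(m, _design())
        q75, q25 = np.percentile(fc, [75, 25])
        assert out["per_species"]["MOUSE"]["log2fc_iqr"] == \
               pytest.approx(q75 - q25, abs=1e-9)


class TestCompareLibraries:
    def test_percent_change_vs_baseline(self):
        out = compare_libraries({"STD": {"peptide": 1000},
                                 "OPT": {"peptide": 1080}}, baseline="STD")
        assert out.at["OPT", "pct_change_peptide"] == pytest.approx(8.0)
        assert out.at["STD", "pct_change_peptide"] == pytest.approx(0.0)

    def test_antisymmetric_under_baseline_swap(self):
        res = {"STD": {"p": 1000}, "OPT": {"p": 1100}}
        a = compare_libraries(res, "STD").at["OPT", "pct_change_p"]
        b = compare_libraries(res, "OPT").at["STD", "pct_change_p"]
        # (1+a/100)*(1+b/100) == 1
        assert (1 + a / 100) * (1 + b / 100) == pytest.approx(1.0)

    def test_zero_baseline_is_an_error(self):
        with pytest.raises(ValueError):
            compare_libraries({"STD": {"p": 0}, "OPT": {"p": 5}}, "STD")


def test_quantify_sum_aggregates_fragments():
    table = pd.DataFrame({
        "analyte": ["x", "x", "y"],
        "run": ["A1", "A1", "A1"],
        "intensity": [1.0, 2.0, 5.0]})
    out = quantify_sum(table)
    assert out.at["x", "A1"] == 3.0
    assert out.at["y", "A1"] == 5.0
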