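import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dialibopt import synthgen as sg
from dialibopt.ce_select import (
    SimilarityRecord,
    dot_product,
    score_all,
    select_ce_global,
    select_ce_per_bin,
)
from dialibopt.libio import FragmentIon, filter_predictable


def F(t, o, i):
    return FragmentIon(t, o, 1, i)


class TestDotProduct:
    def test_identical_spectra_score_one(self):
        s = [F("b", 2, 0.4), F("y", 3, 1.0)]
        assert dot_product(s, s) == pytest.approx(1.0)

    def test_disjoint_annotations_score_zero(self):
        assert dot_product([F("b", 2, 1.0)], [F("y", 5, 1.0)]) == 0.0

    def test_hand_computed_example(self):
        obs = [F("b", 2, 1.0), F("y", 3, 0.5)]
        pred = [F("b", 2, 0.5), F("y", 3, 1.0), F("y", 4, 0.2)]
        expect = 1.0 / math.sqrt(1.25 * 1.29)
        assert dot_product(obs, pred) == pytest.approx(expect)
        assert expect == pytest.approx(0.788, abs=1e-3)

    def test_empty_spectrum_is_an_error(self):
        with pytest.raises(ValueError):
            dot_product([], [F("b", 2, 1.0)])

    @given(st.data())
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_contract_properties(self, data):
        """Symmetry, [0,1] range, scale invariance, oracle equality."""
        def spectrum():
            annots = data.draw(st.lists(
                st.tuples(st.sampled_from("by"), st.integers(1, 12),
                          st.integers(1, 2)),
                min_size=1, max_size=10, unique=True))
            return [FragmentIon(t, o, z,
                                data.draw(st.floats(1e-3, 1e3)))
                    for t, o, z in annots]

        a, b = spectrum(), spectrum()
        s = dot_product(a, b)
        assert 0.0 <= s <= 1.0 + 1e-12
        assert dot_product(b, a) == pytest.approx(s)
        scale = data.draw(st.floats(0.01, 100.0))
        scaled = [FragmentIon(f.ion_type, f.ordinal, f.frag_charge,
                              f.intensity * scale) for f in a]
        assert dot_product(scaled, b) == pytest.approx(s)
        # brute-force oracle: explicit double loop over annotation pairs
        num = sum(fa.intensity * fb.intensity for fa in a for fb in b
                  if fa.annotation == fb.annotation)
        den = math.sqrt(sum(f.intensity ** 2 for f in a)
                        * sum(f.intensity ** 2 for f in b))
        assert s == pytest.approx(num / den)


class TestScoreAll:
    def test_one_record_per_matched_precursor_and_ce(self, small_synth):
        calib, _ = filter_predictable(small_synth["calib"])
        records, unmatched = score_all(calib, small_synth["store"])
        assert unmatched == 0
        assert len(records) == len(calib) * len(small_synth["cfg"].ce_grid)

    def test_unmatched_precursors_counted(self, small_synth):
        from conftest import make_record
        calib, _ = filter_predictable(small_synth["calib"])
        calib.add(make_record("WWWWWWWWK", 2))
        records, unmatched = score_all(calib, small_synth["store"])
        assert unmatched == 1

    def test_scores_compose_with_direct_dot_product(self, small_synth):
        from dialibopt.warehouse import query_spectrum
        calib, _ = filter_predictable(small_synth["calib"])
        records, _ = score_all(calib, small_synth["store"])
        spot = records[17]
        rec = calib.records[(spot.modified_sequence, spot.charge)]
        pred = query_spectrum(small_synth["store"], spot.modified_sequence,
                              spot.charge, spot.ce)
        assert spot.dot_product == pytest.approx(dot_product(rec.fragments, pred))


def _brute_force_ce_map(records, min_bin_n):
    """Oracle: materialize the full (bin x ce) median table, then argmax."""
    import collections
    by_bin = collections.defaultdict(lambda: collections.defaultdict(list))
    precursors = collections.defaultdict(set)
    for r in records:
        by_bin[r.bin][r.ce].append(r.dot_product)
        precursors[r.bin].add((r.modified_sequence, r.charge))
    pooled = collections.defaultdict(list)
    for r in records:
        pooled[r.ce].append(r.dot_product)
    gmed = {ce: np.median(v) for ce, v in pooled.items()}
    gbest = min(ce for ce in gmed if gmed[ce] == max(gmed.values()))
    out = {}
    for b, per_ce in by_bin.items():
        med = {ce: np.median(v) for ce, v in per_ce.items()}
        if len(precursors[b]) < min_bin_n:
            out[b] = gbest
        else:
            out[b] = min(ce for ce in med if med[ce] == max(med.values()))
    return out, gbest


class TestSelection:
    def test_noise_free_recovery_is_exact(self, small_synth):
        calib, _ = filter_predictable(small_synth["calib"])
        records, _ = score_all(calib, small_synth["store"])
        cemap = select_ce_per_bin(records, min_bin_n=1)
        assert cemap.bins == small_synth["truth"].bin_optimum

    def test_noisy_recovery_within_one(self):
        cfg = sg.SynthConfig(n_precursors_per_bin=50, lengths=(10, 15, 20),
                             charges=(2, 3), intensity_noise_sigma=0.2,
                             seed=5)
        tables, truth = sg.gen_warehouse_tables(cfg)
        from dialibopt.warehouse import build_warehouse
        store = build_warehouse(tables, cfg.ce_grid)
        calib, _ = sg.gen_calibration_lib(cfg, tables, truth)
        records, _ = score_all(filter_predictable(calib)[0], store)
        cemap = select_ce_per_bin(records, min_bin_n=1)
        hits = sum(abs(cemap.bins[b] - mu) <= 1
                   for b, mu in truth.bin_optimum.items())
        assert hits >= 0.9 * len(truth.bin_optimum)

    def test_matches_brute_force_oracle(self, small_synth):
        calib, _ = filter_predictable(small_synth["calib"])
        records, _ = score_all(calib, small_synth["store"])
        for floor in (1, 10, 999):
            oracle, gbest = _brute_force_ce_map(records, floor)
            cemap = select_ce_per_bin(records, min_bin_n=floor)
            assert cemap.bins == oracle
            assert cemap.global_ce == gbest

    def test_single_ce_grid_selects_that_ce(self):
        recs = [SimilarityRecord("PEPK", 2, 4, 25, 0.9)]
        assert select_ce_per_bin(recs, min_bin_n=1).bins == {(4, 2): 25}
        assert select_ce_global(recs) == 25

    def test_fallback_bins_inherit_global_optimum(self, small_synth):
        calib, _ = filter_predictable(small_synth["calib"])
        records, _ = score_all(calib, small_synth["store"])
        cemap = select_ce_per_bin(records, min_bin_n=10 ** 6)
        assert cemap.fallback_bins == set(cemap.bins)
        assert all(ce == cemap.global_ce for ce in cemap.bins.values())

    def test_tie_breaks_to_lowest_ce(self):
        recs = [SimilarityRecord("PEPK", 2, 4, ce, 0.5) for ce in (30, 22, 26)]
        assert select_ce_global(recs) == 22

    def test_global_equals_per_bin_on_one_bin(self, small_synth):
        calib, _ = filter_predictable(small_synth["calib"])
        records, _ = score_all(calib, small_synth["store"])
        one_bin = [r for r in records if r.bin == (8, 2)]
        cemap = select_ce_per_bin(one_bin, min_bin_n=1)
        assert cemap.bins[(8, 2)] == select_ce_global(one_bin)

    def test_cemap_json_round_trip(self, small_synth, tmp_path):
        from dialibopt.ce_select import CEMap
        calib, _ = filter_predictable(small_synth["calib"])
        records, _ = score_all(calib, small_synth["store"])
        cemap = select_ce_per_bin(records, min_bin_n=5)
        cemap.to_json(tmp_path / "ce.json")
        back = CEMap.from_json(tmp_path / "ce.json")
        assert back.bins == cemap.bins
        assert back.global_ce == cemap.global_ce
        assert back.fallback_bins == cemap.fallback_bins


def test_similarity_decreases_away_from_optimum(small_synth):
    """Noise-free dot product vs the spectrum at mu falls with |ce - mu|."""
    truth = small_synth["truth"]
    tables = small_synth["tables"]
    key = sorted(tables[20].records)[0]
    mu = truth.bin_optimum[(len(key[0]), key[1])]
    ref = tables[mu].records[key].fragments
    grid = small_synth["cfg"].ce_grid
    up = [dot_product(tables[ce].records[key].fragments, ref)
          for ce in grid if ce >= mu]
    down = [dot_product(tables[ce].records[key].fragments, ref)
            for ce in grid if ce <= mu]
    assert all(np.diff(up) <= 1e-12)
    assert all(np.diff(down[::-1]) <= 1e-12)
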