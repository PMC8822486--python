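import numpy as np
import pytest

from dialibopt import (
    FragmentIon,
    PrecursorRecord,
    SpectralLibrary,
    build_warehouse,
)
from dialibopt import synthgen as sg


def make_record(seq="PEPTIDEK", charge=2, irt=50.0, protein="sp|P1|X_MOUSE",
                fragments=None):
    if fragments is None:
        fragments = [FragmentIon("b", 2, 1, 0.3),
                     FragmentIon("y", 3, 1, 1.0),
                     FragmentIon("y", 5, 1, 0.6)]
    return PrecursorRecord(modified_sequence=seq, precursor_charge=charge,
                           fragments=fragments, irt=irt, protein_group=protein)


@pytest.fixture
def tiny_library():
    lib = SpectralLibrary()
    lib.add(make_record("PEPTIDEK", 2, irt=10.0, protein="sp|P1|A_MOUSE"))
    lib.add(make_record("ACDEFGHIK", 2, irt=40.0, protein="sp|P2|B_YEAST"))
    lib.add(make_record("LMNPQRSTVK", 3, irt=80.0,
                        protein="sp|P3|C_MOUSE;sp|P4|D_MOUSE"))
    return lib


@pytest.fixture(scope="session")
def small_synth():
    """Shared small synthetic workflow: tables, truth, store, calibration."""
    cfg = sg.SynthConfig(n_precursors_per_bin=12, lengths=(8, 12, 16),
                         charges=(2, 3), intensity_noise_sigma=0.0, seed=11)
    tables, truth = sg.gen_warehouse_tables(cfg)
    store = build_warehouse(tables, cfg.ce_grid)
    calib, anchors = sg.gen_calibration_lib(cfg, tables, truth)
    return {"cfg": cfg, "tables": tables, "truth": truth, "store": store,
            "calib": calib, "anchors": anchors}
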