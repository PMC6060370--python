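import numpy as np
import pandas as pd
import pytest

from sweepscan.panel import GenotypeMatrix, make_marker_map


def make_panel(dosage, positions=None, chroms=None, subpops=None):
    """Small hand-built panel helper used across the suite."""
    dosage = np.asarray(dosage, dtype=float)
    ns, nm = dosage.shape
    positions = positions if positions is not None else [(i + 1) * 1000 for i in range(nm)]
    chroms = chroms if chroms is not None else ["1"] * nm
    subpops = subpops if subpops is not None else ["popA"] * ns
    return GenotypeMatrix(
        [f"s{i + 1}" for i in range(ns)],
        list(subpops),
        make_marker_map([f"m{i + 1}" for i in range(nm)], chroms, positions),
        dosage,
    )


@pytest.fixture
def two_pop_panel():
    """4 samples x 4 markers, two subpopulations, one missing call."""
    dosage = [
        [0, 1, 2, 0],
        [0, 1, 2, 1],
        [2, 1, 0, np.nan],
        [2, 2, 0, 1],
    ]
    return make_panel(dosage, subpops=["popA", "popA", "popB", "popB"])


@pytest.fixture
def windows_frame():
    def _make(rows):
        return pd.DataFrame(rows, columns=["chrom", "start", "end"])

    return _make
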