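"""Windowed F_ST, the d_i scan, and empirical thresholding."""

import math

import numpy as np
import pandas as pd
import pytest

from sweepscan.fst import (
    DiScore,
    FstPanel,
    compute_di,
    significant_windows,
    snp_fst_components,
    window_fst,
    window_index,
    window_span,
)

from conftest import make_panel


# ---------------------------------------------------------------------------
# Independent Weir–Cockerham (1984) oracle: a separate transcription of the
# published two-population variance components, computed per SNP from raw
# genotype columns with explicit loops.
# ---------------------------------------------------------------------------

def wc_oracle_components(col_i, col_j):
    gi = [x for x in col_i if not math.isnan(x)]
    gj = [x for x in col_j if not math.isnan(x)]
    n1, n2 = len(gi), len(gj)
    p1 = sum(gi) / (2 * n1)
    p2 = sum(gj) / (2 * n2)
    h1 = sum(1 for x in gi if x == 1) / n1
    h2 = sum(1 for x in gj if x == 1) / n2
    r = 2
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1 ** 2 + n2 ** 2) / (r * nbar)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    c = hbar / 2
    return a, a + b + c


def wc_oracle_window(cols_i, cols_j):
    """Ratio of sums over informative SNPs of one window."""
    num = den = 0.0
    for col_i, col_j in zip(cols_i, cols_j):
        gi = [x for x in col_i if not math.isnan(x)]
        gj = [x for x in col_j if not math.isnan(x)]
        if not gi or not gj:
            continue
        p1, p2 = sum(gi) / (2 * len(gi)), sum(gj) / (2 * len(gj))
        if p1 == p2 and p1 in (0.0, 1.0):
            continue
        a, tot = wc_oracle_components(col_i, col_j)
        num += a
        den += tot
    return num / den if den != 0 else float("nan")


class TestSnpComponents:
    def test_identical_intermediate_frequencies_give_near_zero(self):
        # the unbiased estimator subtracts within-population sampling noise,
        # so the among-population component vanishes only as n grows
        a, tot = snp_fst_components(10_000, 10_000, 10_000, 10_000)
        assert a / tot == pytest.approx(0.0, abs=1e-4)
        a10, tot10 = snp_fst_components(10, 10, 10, 10)
        assert abs(a10) > abs(a)  # finite-sample correction shrinks with n
        assert tot10 > 0

    def test_fixed_difference_limit_approaches_one(self):
        a, tot = snp_fst_components(2000, 1000, 0, 1000, het_i=0, het_j=0)
        assert a / tot == pytest.approx(1.0, abs=1e-3)

    def test_matches_independent_textbook_evaluation(self):
        # n=12 vs 15 genotypes, alt counts 5 vs 20, explicit genotype columns
        col_i = [1, 1, 1, 1, 1, 0, 0, 0, 0, 0, 0, 0]
        col_j = [2, 2, 2, 2, 2, 2, 2, 2, 1, 1, 1, 1, 0, 0, 0]
        exp_a, exp_tot = wc_oracle_components(col_i, col_j)
        got_a, got_tot = snp_fst_components(
            5, 12, 20, 15, het_i=col_i.count(1), het_j=col_j.count(1)
        )
        assert got_a == pytest.approx(exp_a, abs=1e-14)
        assert got_tot == pytest.approx(exp_tot, abs=1e-14)

    def test_requires_called_genotypes(self):
        with pytest.raises(ValueError):
            snp_fst_components(0, 0, 5, 10)


class TestWindowFst:
    def test_window_coordinate_arithmetic(self):
        assert window_index([30_595_130])[0] == 3059
        assert window_span(3059) == (30_590_001, 30_600_000)

    def test_single_snp_window_equals_snp_ratio(self):
        dosage = np.array([[0, 2], [1, 2], [2, 0], [2, 1]], dtype=float)
        g = make_panel(dosage, positions=[5_000, 25_000],
                       subpops=["popA", "popA", "popB", "popB"])
        panel = window_fst(g)
        a0, t0 = snp_fst_components(1, 2, 4, 2, het_i=1, het_j=0)
        assert panel.pair("popA", "popB")[0] == pytest.approx(a0 / t0, abs=1e-14)

    def test_two_snp_window_is_ratio_of_sums_not_mean_of_ratios(self):
        rng = np.random.default_rng(42)
        dosage = rng.integers(0, 3, size=(8, 2)).astype(float)
        g = make_panel(dosage, positions=[1_000, 2_000],
                       subpops=["popA"] * 4 + ["popB"] * 4)
        panel = window_fst(g)
        cols_i = [dosage[:4, m] for m in range(2)]
        cols_j = [dosage[4:, m] for m in range(2)]
        expected = wc_oracle_window(cols_i, cols_j)
        got = panel.pair("popA", "popB")[0]
        assert got == pytest.approx(expected, abs=1e-12)
        ratios = [
            wc_oracle_window([ci], [cj]) for ci, cj in zip(cols_i, cols_j)
        ]
        assert got != pytest.approx(np.mean(ratios), abs=1e-6)

    def test_matches_oracle_on_random_small_panels(self):
        # the acceptance-grade estimator equivalence at unit-test scale
        rng = np.random.default_rng(7)
        for trial in range(20):
            nm = int(rng.integers(1, 11))
            dosage = rng.integers(0, 3, size=(18, nm)).astype(float)
            dosage[rng.random(dosage.shape) < 0.08] = np.nan
            g = make_panel(
                dosage,
                positions=sorted(rng.choice(np.arange(1, 30_000), nm, replace=False)),
                subpops=["popA"] * 6 + ["popB"] * 6 + ["popC"] * 6,
            )
            panel = window_fst(g, window_size=10_000)
            masks = {p: g.sample_mask(p) for p in ("popA", "popB", "popC")}
            widx = window_index(g.markers["pos"].to_numpy())
            for pi, pj in (("popA", "popB"), ("popA", "popC"), ("popB", "popC")):
                for wi, wrow in panel.windows.iterrows():
                    sel = widx == wrow["index"]
                    cols_i = [dosage[masks[pi], m] for m in np.nonzero(sel)[0]]
                    cols_j = [dosage[masks[pj], m] for m in np.nonzero(sel)[0]]
                    expected = wc_oracle_window(cols_i, cols_j)
                    got = panel.pair(pi, pj)[wi]
                    if math.isnan(expected):
                        assert math.isnan(got)
                    else:
                        assert got == pytest.approx(expected, abs=1e-12)


def _panel_from_values(values_by_pair, n_windows):
    windows = pd.DataFrame(
        {
            "chrom": ["1"] * n_windows,
            "index": range(n_windows),
            "start": [i * 10_000 + 1 for i in range(n_windows)],
            "end": [(i + 1) * 10_000 for i in range(n_windows)],
            "n_snps": [1] * n_windows,
        }
    )
    return FstPanel(
        windows=windows,
        values={k: np.asarray(v, float) for k, v in values_by_pair.items()},
    )


class TestDi:
    def test_flat_fst_gives_zero_di_everywhere(self):
        panel = _panel_from_values(
            {("popA", "popB"): [0.1, 0.1, 0.1, 0.2],
             ("popA", "popC"): [0.3, 0.3, 0.3, 0.3],
             ("popB", "popC"): [0.2, 0.1, 0.2, 0.3]},
            4,
        )
        with pytest.warns(UserWarning):
            scores = compute_di(panel)
        # the constant-spread pair contributes a zero summand
        assert np.allclose(
            scores.di["popA"],
            (panel.values[("popA", "popB")] - 0.125) / np.std([0.1, 0.1, 0.1, 0.2]),
        )

    def test_matches_hand_computed_zscore_sums(self):
        vals = {
            ("popA", "popB"): [0.10, 0.30, 0.20, 0.40],
            ("popA", "popC"): [0.05, 0.15, 0.25, 0.35],
            ("popB", "popC"): [0.50, 0.10, 0.30, 0.10],
        }
        panel = _panel_from_values(vals, 4)
        scores = compute_di(panel)

        def z(v):
            v = np.asarray(v)
            return (v - v.mean()) / v.std()

        for pop, pairs in {
            "popA": [("popA", "popB"), ("popA", "popC")],
            "popB": [("popA", "popB"), ("popB", "popC")],
            "popC": [("popA", "popC"), ("popB", "popC")],
        }.items():
            expected = sum(z(vals[k]) for k in pairs)
            assert np.allclose(scores.di[pop], expected, atol=1e-12)

    def test_per_subpop_mean_is_exactly_zero(self):
        rng = np.random.default_rng(3)
        vals = {
            ("popA", "popB"): rng.normal(0.1, 0.05, 50),
            ("popA", "popC"): rng.normal(0.2, 0.08, 50),
            ("popB", "popC"): rng.normal(0.15, 0.03, 50),
        }
        scores = compute_di(_panel_from_values(vals, 50))
        for pop in ("popA", "popB", "popC"):
            assert abs(scores.di[pop].mean()) < 1e-12


class TestSignificantWindows:
    def _scores(self, di_values):
        n = len(di_values)
        windows = pd.DataFrame(
            {
                "chrom": ["1"] * n,
                "index": range(n),
                "start": [i * 10_000 + 1 for i in range(n)],
                "end": [(i + 1) * 10_000 for i in range(n)],
                "n_snps": [1] * n,
            }
        )
        return DiScore(windows=windows, di={"popA": np.asarray(di_values, float)})

    def test_top_fraction_count_uses_ceiling(self):
        rng = np.random.default_rng(0)
        scores = self._scores(rng.normal(size=217_806))
        sig = significant_windows(scores, 0.001)
        assert len(sig["popA"]) == 218

    def test_thousand_windows_select_one(self):
        scores = self._scores(np.arange(1000))
        sig = significant_windows(scores, 0.001)
        assert len(sig["popA"]) == 1
        assert sig["popA"]["d_i"].iloc[0] == 999

    def test_ties_broken_by_position(self):
        with pytest.warns(UserWarning, match="coarse"):
            scores = self._scores(np.zeros(10))
            sig = significant_windows(scores, 0.25)
        assert sig["popA"]["start"].tolist() == [1, 10_001, 20_001]
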