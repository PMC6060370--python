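"""Windowed pairwise F_ST and the d_i population-divergence scan.

Per-SNP differentiation between two subpopulations is measured with the
Weir & Cockerham (1984) variance components (a: among populations,
b: among individuals within populations, c: within individuals), computed
from called genotypes only.  Window F_ST is the ratio of sums
``sum(a) / sum(a+b+c)`` over the informative SNPs of a non-overlapping
window grid anchored at position 1 (1-based closed intervals
``[w*k+1, w*(k+1)]``).  Negative window values are retained so that the
downstream standardization is unbiased.

The d_i statistic for subpopulation ``i`` in window ``w`` sums the
standardized deviations of its pairwise window F_ST values from their
genome-wide means:

    d_i(w) = sum_{j != i} (F_ST^{ij}(w) - E[F_ST^{ij}]) / sd[F_ST^{ij}]

Moments are taken over the windows analyzed for every pair, so the
genome-wide mean of d_i is exactly zero for each subpopulation by
construction.  Significance is empirical: the top ``top_fraction`` of each
subpopulation's d_i distribution.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel import GenotypeMatrix

__all__ = [
    "snp_fst_components",
    "window_fst",
    "compute_di",
    "significant_windows",
    "window_span",
    "FstPanel",
    "DiScore",
]


def window_span(chrom_index: int, window_size: int = 10_000) -> tuple[int, int]:
    """1-based closed span of window ``chrom_index`` on the anchored grid."""
    return chrom_index * window_size + 1, (chrom_index + 1) * window_size


def window_index(pos: np.ndarray, window_size: int = 10_000) -> np.ndarray:
    """Grid index of 1-based positions (pos 1..w -> 0, w+1..2w -> 1, ...)."""
    return (np.asarray(pos, dtype=np.int64) - 1) // window_size


def snp_fst_components(alt_i, n_i, alt_j, n_j, het_i=None, het_j=None):
    """Weir–Cockerham (1984) two-population variance components for one SNP.

    Parameters
    ----------
    alt_i, alt_j : float
        Alternate-allele counts in each population (0 .. 2n).
    n_i, n_j : float
        Called diploid genotype counts.
    het_i, het_j : float, optional
        Observed heterozygote counts; when omitted the Hardy–Weinberg
        expectation ``2 p (1-p) n`` is used (allele-count-only input).

    Returns
    -------
    (a, a_plus_b_plus_c) : tuple of float
        The among-population component and the total.  Both are zero for a
        SNP monomorphic for the same allele in both populations
        (non-informative).

    Raises
    ------
    ValueError
        If either population has no called genotypes.
    """
    if n_i < 1 or n_j < 1:
        raise ValueError("both populations need >=1 called genotype")
    r = 2.0
    n = np.array([n_i, n_j], dtype=float)
    p = np.array([alt_i / (2.0 * n_i), alt_j / (2.0 * n_j)])
    if het_i is None:
        het_i = 2.0 * p[0] * (1.0 - p[0]) * n_i
    if het_j is None:
        het_j = 2.0 * p[1] * (1.0 - p[1]) * n_j
    h = np.array([het_i / n_i, het_j / n_j])

    nbar = n.mean()
    if nbar <= 1.0:
        # single individual per pop: b undefined; fall back to totals only
        raise ValueError("Weir-Cockerham components need mean sample size > 1")
    nc = (r * nbar - (n ** 2).sum() / (r * nbar)) / (r - 1.0)
    pbar = (n * p).sum() / (r * nbar)
    s2 = (n * (p - pbar) ** 2).sum() / ((r - 1.0) * nbar)
    hbar = (n * h).sum() / (r * nbar)

    a = (nbar / nc) * (
        s2
        - (pbar * (1.0 - pbar) - ((r - 1.0) / r) * s2 - hbar / 4.0) / (nbar - 1.0)
    )
    b = (nbar / (nbar - 1.0)) * (
        pbar * (1.0 - pbar)
        - ((r - 1.0) / r) * s2
        - ((2.0 * nbar - 1.0) / (4.0 * nbar)) * hbar
    )
    c = hbar / 2.0
    return float(a), float(a + b + c)


def _pair_key(i: str, j: str) -> tuple[str, str]:
    return (i, j) if i <= j else (j, i)


@dataclass
class FstPanel:
    """Per-window pairwise F_ST with genome-wide moments.

    ``windows`` lists the union of analyzed windows (chrom, index, start,
    end, n_snps).  ``values[(i, j)]`` is aligned with ``windows`` and holds
    nan where a pair had no informative SNP in a window.  ``mean``/``sd``
    are each pair's genome-wide moments over its analyzed windows (sd with
    divisor N, fixed for reproducibility).
    """

    windows: pd.DataFrame
    values: dict[tuple[str, str], np.ndarray]
    mean: dict[tuple[str, str], float] = field(default_factory=dict)
    sd: dict[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for key, v in self.values.items():
            ok = ~np.isnan(v)
            self.mean[key] = float(np.mean(v[ok])) if ok.any() else float("nan")
            self.sd[key] = float(np.std(v[ok])) if ok.any() else float("nan")

    def pair(self, i: str, j: str) -> np.ndarray:
        return self.values[_pair_key(i, j)]

    def subpops(self) -> list[str]:
        seen: dict[str, None] = {}
        for i, j in self.values:
            seen.setdefault(i, None)
            seen.setdefault(j, None)
        return list(seen)


def _per_pair_window_fst(
    g: GenotypeMatrix, pop_i: str, pop_j: str, win_of: np.ndarray, n_windows: int
) -> np.ndarray:
    """Ratio-of-sums window F_ST for one subpopulation pair."""
    di = g.dosage[g.sample_mask(pop_i)]
    dj = g.dosage[g.sample_mask(pop_j)]
    ni = (~np.isnan(di)).sum(axis=0).astype(float)
    nj = (~np.isnan(dj)).sum(axis=0).astype(float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        alt_i = np.nansum(di, axis=0)
        alt_j = np.nansum(dj, axis=0)
        het_i = np.nansum(di == 1.0, axis=0).astype(float)
        het_j = np.nansum(dj == 1.0, axis=0).astype(float)

    a = np.full(g.n_markers, np.nan)
    tot = np.full(g.n_markers, np.nan)
    callable_ = (ni >= 1) & (nj >= 1) & (ni + nj > 2)
    for m in np.nonzero(callable_)[0]:
        p_i = alt_i[m] / (2 * ni[m])
        p_j = alt_j[m] / (2 * nj[m])
        if p_i == p_j and p_i in (0.0, 1.0):
            continue  # monomorphic for the same allele in both: non-informative
        a[m], tot[m] = snp_fst_components(
            alt_i[m], ni[m], alt_j[m], nj[m], het_i[m], het_j[m]
        )

    num = np.zeros(n_windows)
    den = np.zeros(n_windows)
    informative = ~np.isnan(a)
    np.add.at(num, win_of[informative], a[informative])
    np.add.at(den, win_of[informative], tot[informative])
    out = np.full(n_windows, np.nan)
    nonzero = den != 0.0
    out[nonzero] = num[nonzero] / den[nonzero]
    return out


def window_fst(
    g: GenotypeMatrix,
    pairs: list[tuple[str, str]] | None = None,
    window_size: int = 10_000,
) -> FstPanel:
    """Windowed pairwise F_ST over a non-overlapping grid.

    Computes the ratio-of-sums Weir–Cockerham estimate per window for every
    requested subpopulation pair (default: all pairs).  Windows with no
    informative SNP for a pair carry nan for that pair; windows with no
    retained SNP at all are absent.
    """
    pops = g.subpop_labels()
    if pairs is None:
        pairs = [
            (pops[i], pops[j])
            for i in range(len(pops))
            for j in range(i + 1, len(pops))
        ]
    if not pairs:
        raise ValueError("need at least two subpopulations")

    chrom = g.markers["chrom"].to_numpy()
    widx = window_index(g.markers["pos"].to_numpy(), window_size)
    keys = pd.DataFrame({"chrom": chrom, "index": widx})
    uniq = keys.drop_duplicates().reset_index(drop=True)
    uniq = uniq.sort_values(
        by=["chrom", "index"],
        key=lambda s: s.map(_chrom_sort_key) if s.name == "chrom" else s,
    ).reset_index(drop=True)
    lut = {t: i for i, t in enumerate(uniq.itertuples(index=False, name=None))}
    win_of = np.array([lut[(c, w)] for c, w in zip(chrom, widx)])
    n_windows = len(uniq)

    starts = uniq["index"].to_numpy() * window_size + 1
    windows = pd.DataFrame(
        {
            "chrom": uniq["chrom"],
            "index": uniq["index"],
            "start": starts,
            "end": starts + window_size - 1,
            "n_snps": np.bincount(win_of, minlength=n_windows),
        }
    )
    values = {
        _pair_key(i, j): _per_pair_window_fst(g, i, j, win_of, n_windows)
        for i, j in pairs
    }
    return FstPanel(windows=windows, values=values)


def _chrom_sort_key(c: str):
    try:
        return (0, int(str(c)), "")
    except ValueError:
        return (1, 0, str(c))


@dataclass
class DiScore:
    """Per-window d_i values and empirical significance per subpopulation.

    ``windows`` holds the common analyzed window set; ``di[pop]`` is aligned
    with it.  ``threshold``/``significant`` are filled by
    :func:`significant_windows`.
    """

    windows: pd.DataFrame
    di: dict[str, np.ndarray]
    threshold: dict[str, float] = field(default_factory=dict)
    significant: dict[str, pd.DataFrame] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: chrom, start, end, subpop, n_snps, d_i, flag."""
        rows = []
        for pop, vals in self.di.items():
            sig_idx = set()
            if pop in self.significant:
                sig_idx = set(self.significant[pop].index)
            for i, rec in enumerate(self.windows.itertuples(index=True)):
                rows.append(
                    {
                        "chrom": rec.chrom,
                        "start": rec.start,
                        "end": rec.end,
                        "subpop": pop,
                        "n_snps": rec.n_snps,
                        "d_i": vals[i],
                        "significant": rec.Index in sig_idx,
                    }
                )
        return pd.DataFrame(rows)


def compute_di(panel: FstPanel, subpops: list[str] | None = None) -> DiScore:
    """d_i per window per subpopulation from a pairwise F_ST panel.

    Restricted to windows analyzed for **every** pair, with each pair's
    moments recomputed over that common set, so the per-subpopulation
    genome-wide mean of d_i is exactly zero.  A pair with zero spread
    contributes nothing (with a warning).
    """
    pops = subpops or panel.subpops()
    if len(pops) < 2:
        raise ValueError("d_i needs at least two subpopulations")
    common = np.ones(len(panel.windows), dtype=bool)
    for i in range(len(pops)):
        for j in range(i + 1, len(pops)):
            common &= ~np.isnan(panel.pair(pops[i], pops[j]))
    if common.sum() < 2:
        raise ValueError("need >=2 windows analyzed for all pairs")

    windows = panel.windows.loc[common].reset_index(drop=True)
    z: dict[tuple[str, str], np.ndarray] = {}
    for i in range(len(pops)):
        for j in range(i + 1, len(pops)):
            key = _pair_key(pops[i], pops[j])
            v = panel.values[key][common]
            sd = float(np.std(v))
            if sd == 0.0:
                warnings.warn(
                    f"pair {key} has zero F_ST spread; its d_i summand is 0"
                )
                z[key] = np.zeros(common.sum())
            else:
                z[key] = (v - v.mean()) / sd
    di = {
        pop: np.sum(
            [z[_pair_key(pop, other)] for other in pops if other != pop], axis=0
        )
        for pop in pops
    }
    return DiScore(windows=windows, di=di)


def significant_windows(
    scores: DiScore, top_fraction: float = 0.001
) -> dict[str, pd.DataFrame]:
    """Top ``top_fraction`` of each subpopulation's empirical d_i distribution.

    Selects ``k = ceil(top_fraction * N)`` windows per subpopulation; ties
    at the k-th value are broken by (chrom, start) ascending.  Fills
    ``scores.threshold`` and ``scores.significant`` and returns the latter.
    """
    n = len(scores.windows)
    if n < 1000:
        warnings.warn(
            f"only {n} windows; empirical top-{top_fraction:g} threshold is coarse"
        )
    k = math.ceil(top_fraction * n)
    order_chrom = scores.windows["chrom"].map(_chrom_sort_key)
    for pop, vals in scores.di.items():
        df = scores.windows.copy()
        df["d_i"] = vals
        df["_ck"] = order_chrom
        df = df.sort_values(
            by=["d_i", "_ck", "start"], ascending=[False, True, True], kind="mergesort"
        )
        top = df.iloc[:k].drop(columns="_ck")
        scores.threshold[pop] = float(top["d_i"].iloc[-1])
        scores.significant[pop] = top.sort_index()
    return scores.significant
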