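"""Bundled reference tables from a published genome scan of six American
Quarter Horse performance subpopulations (cutting, halter, racing, reining,
western pleasure, working cow; ~2M imputed SNPs on 143 horses).

These small TSVs are worked-example inputs for the ROI/consensus machinery:

* ``qh_di_roi_counts.tsv`` — per-subpopulation counts of d_i ROI and of
  annotated genes within them.
* ``qh_shared_di_windows.tsv`` — the d_i windows significant in two or
  more subpopulations (one position per 10 kb window, 0/1 membership).
* ``qh_hapflk_roi.tsv`` — the hapFLK ROI with their lowest p-value, gene
  symbols, and per-subpopulation overlap with the other two methods.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .fst import window_index, window_span
from .roi import ROI

SUBPOPS = [
    "cutting",
    "halter",
    "racing",
    "reining",
    "western_pleasure",
    "working_cow",
]

# windows analyzed genome-wide per subpopulation in the reference scan
N_WINDOWS_REFERENCE = 217_806
WINDOW_SIZE = 10_000


def _read(name: str) -> pd.DataFrame:
    with resources.files("sweepscan.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t", dtype={"chrom": str})


def load_di_roi_counts() -> pd.DataFrame:
    """Per-subpopulation d_i ROI and gene counts (columns subpop, n_roi,
    n_genes)."""
    return _read("qh_di_roi_counts.tsv")


def load_shared_window_sets() -> dict[str, pd.DataFrame]:
    """Per-subpopulation significant-window sets from the shared-window table.

    Each reported position is snapped to its 10 kb window on the anchored
    grid, yielding frames with ``chrom``, ``start``, ``end`` suitable for
    :func:`sweepscan.roi.sharing_matrix` and :func:`~sweepscan.roi.merge_windows`.
    """
    df = _read("qh_shared_di_windows.tsv")
    out: dict[str, pd.DataFrame] = {}
    idx = window_index(df["pos"].to_numpy(), WINDOW_SIZE)
    spans = [window_span(int(i), WINDOW_SIZE) for i in idx]
    base = pd.DataFrame(
        {
            "chrom": df["chrom"],
            "start": [s for s, _ in spans],
            "end": [e for _, e in spans],
            "pos": df["pos"],
        }
    )
    for pop in SUBPOPS:
        out[pop] = (
            base[df[pop] == 1].reset_index(drop=True).drop(columns="pos")
        )
    return out


def load_hapflk_rois() -> tuple[list[ROI], pd.DataFrame]:
    """The published hapFLK ROI as :class:`~sweepscan.roi.ROI` objects plus
    the raw table (gene symbols, per-subpopulation method overlap)."""
    df = _read("qh_hapflk_roi.tsv")
    rois = [
        ROI(
            chrom=str(rec.chrom),
            start=int(rec.start),
            end=int(rec.end),
            method="hapflk",
            subpop="all",
            peak_stat=float(rec.lowest_p),
        )
        for rec in df.itertuples(index=False)
    ]
    return rois, df


def hapflk_gene_symbols(df: pd.DataFrame | None = None) -> set[str]:
    """Distinct gene symbols across the hapFLK ROI table."""
    if df is None:
        _, df = load_hapflk_rois()
    genes: set[str] = set()
    for cell in df["genes"]:
        if cell and cell != ".":
            genes.update(g.strip() for g in str(cell).split(","))
    return genes
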