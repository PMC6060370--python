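"""Regions of interest: merging, cross-subpopulation sharing, cross-method
overlap, and gene annotation.

Coordinates are 1-based closed throughout; BED input/output (0-based
half-open) is converted at the boundary.  Significant windows or SNP runs
within ``max_gap`` (default 500 kb, edge-to-edge, inclusive) on the same
chromosome merge into a single ROI; a lone significant window is itself an
ROI.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ROI",
    "merge_windows",
    "sharing_matrix",
    "method_overlap",
    "annotate_genes",
    "read_gene_annotation",
]


@dataclass
class ROI:
    """A merged significant interval with provenance."""

    chrom: str
    start: int  # 1-based closed
    end: int
    method: str  # di | hapflk | lhs
    subpop: str  # subpopulation label, or "all" for joint scans
    n_windows: int = 1
    peak_stat: float = float("nan")
    members: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self):
        if self.end < self.start:
            raise ValueError("ROI needs end >= start")

    @property
    def span(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "ROI") -> bool:
        return (
            str(self.chrom) == str(other.chrom)
            and self.start <= other.end
            and other.start <= self.end
        )


def _chrom_sort_key(c):
    try:
        return (0, int(str(c)), "")
    except ValueError:
        return (1, 0, str(c))


def merge_windows(
    windows: pd.DataFrame,
    max_gap: int = 500_000,
    method: str = "di",
    subpop: str = "all",
    stat_col: str | None = None,
) -> list[ROI]:
    """Single-linkage merge of significant windows into ROI.

    ``windows`` needs ``chrom``, ``start``, ``end`` columns (1-based
    closed).  Windows on the same chromosome whose edge-to-edge gap is
    ``<= max_gap`` join the same ROI; merging is idempotent and
    order-invariant (input is sorted internally).
    """
    if windows.empty:
        return []
    df = windows.sort_values(
        by=["chrom", "start"],
        key=lambda s: s.map(_chrom_sort_key) if s.name == "chrom" else s,
        kind="mergesort",
    )
    rois: list[ROI] = []
    cur = None
    for rec in df.itertuples(index=False):
        stat = float(getattr(rec, stat_col)) if stat_col else float("nan")
        if (
            cur is not None
            and str(rec.chrom) == cur.chrom
            and rec.start - cur.end <= max_gap
        ):
            cur.end = max(cur.end, int(rec.end))
            cur.n_windows += 1
            cur.members.append((int(rec.start), int(rec.end)))
            if stat_col and (np.isnan(cur.peak_stat) or stat > cur.peak_stat):
                cur.peak_stat = stat
        else:
            cur = ROI(
                chrom=str(rec.chrom),
                start=int(rec.start),
                end=int(rec.end),
                method=method,
                subpop=subpop,
                n_windows=1,
                peak_stat=stat,
                members=[(int(rec.start), int(rec.end))],
            )
            rois.append(cur)
    return rois


def rois_to_frame(rois: list[ROI]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": r.chrom,
                "start": r.start,
                "end": r.end,
                "method": r.method,
                "subpop": r.subpop,
                "n_windows": r.n_windows,
                "peak_stat": r.peak_stat,
            }
            for r in rois
        ],
        columns=["chrom", "start", "end", "method", "subpop", "n_windows", "peak_stat"],
    )


def write_bed(rois: list[ROI], path) -> None:
    """Export ROI as BED (0-based half-open) with method/subpop in the name."""
    with open(path, "w") as fh:
        fh.write('track name=ROI description="coordinates converted to 0-based half-open"\n')
        for r in rois:
            fh.write(f"{r.chrom}\t{r.start - 1}\t{r.end}\t{r.method}:{r.subpop}\n")


# ---------------------------------------------------------------------------
# Sharing across subpopulations
# ---------------------------------------------------------------------------

def sharing_matrix(window_sets: dict[str, pd.DataFrame]):
    """Window-by-subpopulation membership from per-subpopulation significant
    window sets on a common grid.

    ``window_sets`` maps subpopulation label -> frame with ``chrom`` and
    ``start`` columns (window identity on the shared grid).  Returns
    ``(matrix, histogram, pairwise)``: a boolean frame indexed by
    ``(chrom, start)`` for windows significant in >=1 subpopulation with a
    ``multiplicity`` column; the histogram of multiplicities; and the
    symmetric pairwise intersection counts.
    """
    pops = list(window_sets)
    members: dict[tuple, dict[str, bool]] = {}
    for pop, df in window_sets.items():
        for rec in df.itertuples(index=False):
            members.setdefault((str(rec.chrom), int(rec.start)), {})[pop] = True
    index = sorted(members, key=lambda t: (_chrom_sort_key(t[0]), t[1]))
    mat = pd.DataFrame(
        [[members[w].get(p, False) for p in pops] for w in index],
        index=pd.MultiIndex.from_tuples(index, names=["chrom", "start"]),
        columns=pops,
        dtype=bool,
    )
    mat["multiplicity"] = mat[pops].sum(axis=1)
    histogram = mat["multiplicity"].value_counts().sort_index()
    pairwise = pd.DataFrame(0, index=pops, columns=pops, dtype=int)
    for i, a in enumerate(pops):
        for b in pops[i:]:
            n = int((mat[a] & mat[b]).sum())
            pairwise.loc[a, b] = pairwise.loc[b, a] = n
    return mat, histogram, pairwise


def method_overlap(a: list[ROI], b: list[ROI]) -> tuple[pd.DataFrame, float]:
    """Which elements of ``a`` are overlapped (>=1 bp) by any element of ``b``.

    Returns a per-element table and the overlapped fraction of ``a``
    (nan when ``a`` is empty).
    """
    rows = []
    for r in a:
        hit = next((s for s in b if r.overlaps(s)), None)
        rows.append(
            {
                "chrom": r.chrom,
                "start": r.start,
                "end": r.end,
                "subpop": r.subpop,
                "overlapped": hit is not None,
                "by": f"{hit.method}:{hit.chrom}:{hit.start}-{hit.end}" if hit else "",
            }
        )
    table = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "subpop", "overlapped", "by"]
    )
    frac = float(table["overlapped"].mean()) if len(table) else float("nan")
    return table, frac


# ---------------------------------------------------------------------------
# Gene annotation
# ---------------------------------------------------------------------------

def read_gene_annotation(path) -> pd.DataFrame:
    """Gene intervals from BED or GFF3 as a 1-based closed frame.

    BED (0-based half-open) is detected by extension or column shape; the
    gene name is BED column 4 or the GFF3 ``Name=``/``gene_id=``/``ID=``
    attribute.  Malformed lines raise with their line number.
    """
    path = str(path)
    genes = []
    is_gff = path.endswith((".gff", ".gff3", ".gtf"))
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            try:
                if is_gff:
                    if len(parts) < 9:
                        raise ValueError("expected 9 GFF3 columns")
                    if parts[2] not in ("gene", "protein_coding_gene"):
                        continue
                    chrom, start, end = parts[0], int(parts[3]), int(parts[4])
                    attrs = dict(
                        kv.split("=", 1)
                        for kv in parts[8].split(";")
                        if "=" in kv
                    )
                    name = attrs.get("Name") or attrs.get("gene_id") or attrs.get("ID")
                    if name is None:
                        raise ValueError("no Name/gene_id/ID attribute")
                else:
                    if len(parts) < 3:
                        raise ValueError("expected >=3 BED columns")
                    chrom = parts[0]
                    start = int(parts[1]) + 1  # 0-based half-open -> 1-based closed
                    end = int(parts[2])
                    name = parts[3] if len(parts) > 3 else f"feature_{lineno}"
                if end < start:
                    raise ValueError("empty or inverted interval")
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed annotation line ({exc})")
            genes.append({"chrom": str(chrom), "start": start, "end": end, "gene": name})
    return pd.DataFrame(genes, columns=["chrom", "start", "end", "gene"])


def annotate_genes(
    rois: list[ROI], annotation: pd.DataFrame
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Genes overlapping each ROI (>=1 bp, 1-based closed on both sides).

    Returns a per-ROI table with the gene list, and per-subpopulation
    distinct-gene counts (a gene hit by two ROI of one subpopulation
    counts once for that subpopulation).
    """
    rows = []
    per_pop: dict[str, set] = {}
    for r in rois:
        sel = annotation[
            (annotation["chrom"] == str(r.chrom))
            & (annotation["start"] <= r.end)
            & (annotation["end"] >= r.start)
        ]
        names = sorted(set(sel["gene"]))
        rows.append(
            {
                "chrom": r.chrom,
                "start": r.start,
                "end": r.end,
                "method": r.method,
                "subpop": r.subpop,
                "n_genes": len(names),
                "genes": ",".join(names),
            }
        )
        per_pop.setdefault(r.subpop, set()).update(names)
    table = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "method", "subpop", "n_genes", "genes"]
    )
    return table, {pop: len(gs) for pop, gs in per_pop.items()}
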