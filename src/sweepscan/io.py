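"""Genotype panel readers/writers (PLINK PED/MAP, VCF) and marker QC.

PED/MAP is the whitespace-delimited PLINK text format: one sample per PED
row (family id, individual id, father, mother, sex, phenotype, then two
allele columns per marker, ``0 0`` meaning missing), one marker per MAP row
(chrom, id, cM, bp).  The family-id column carries the subpopulation label.

Allele coding in PED carries no reference/alternate orientation, so dosage
is recoded deterministically against the first allele seen at each marker
in file order.  A marker whose first called genotype is homozygous for the
alternate allele is therefore read back with flipped coding (dosage d maps
to 2-d) — an equivalent panel for every statistic in this package, all of
which are invariant to allele relabeling.  VCF round-trips are always exact
because REF/ALT orientation is explicit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .panel import GenotypeMatrix, is_autosome, make_marker_map

__all__ = [
    "read_plink",
    "write_plink",
    "read_vcf",
    "write_vcf",
    "apply_qc",
    "QCReport",
]


class ParseError(ValueError):
    """Malformed genotype file; message carries the offending line number."""


# ---------------------------------------------------------------------------
# PLINK PED/MAP
# ---------------------------------------------------------------------------

def read_plink(ped_path, map_path) -> GenotypeMatrix:
    """Read a PED/MAP pair into a :class:`GenotypeMatrix`.

    Dosage counts the alternate allele, where the reference at each marker
    is the first non-missing allele seen in file order; ``0 0`` is missing.
    """
    ped_path, map_path = Path(ped_path), Path(map_path)
    chroms, ids, positions = [], [], []
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) < 4:
                raise ParseError(
                    f"{map_path}:{lineno}: expected >=4 MAP columns, got {len(parts)}"
                )
            chroms.append(parts[0])
            ids.append(parts[1])
            positions.append(int(parts[3]))
    n_markers = len(ids)

    sample_ids, subpops, rows = [], [], []
    # per-marker reference allele, assigned on first sight
    ref: list[str | None] = [None] * n_markers
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 6 + 2 * n_markers:
                raise ParseError(
                    f"{ped_path}:{lineno}: expected {6 + 2 * n_markers} columns "
                    f"for {n_markers} MAP markers, got {len(parts)}"
                )
            subpops.append(parts[0])
            sample_ids.append(parts[1])
            row = np.empty(n_markers)
            for m in range(n_markers):
                a1, a2 = parts[6 + 2 * m], parts[7 + 2 * m]
                if a1 == "0" or a2 == "0":
                    row[m] = np.nan
                    continue
                if ref[m] is None:
                    ref[m] = a1
                seen = {a1, a2} - {ref[m]}
                if len(seen) > 1:
                    raise ParseError(
                        f"{ped_path}:{lineno}: marker {ids[m]} has >2 alleles"
                    )
                row[m] = (a1 != ref[m]) + (a2 != ref[m])
            rows.append(row)
    dosage = np.vstack(rows) if rows else np.empty((0, n_markers))
    return GenotypeMatrix(sample_ids, subpops, make_marker_map(ids, chroms, positions), dosage)


def write_plink(g: GenotypeMatrix, ped_path, map_path, alleles=("A", "B")) -> None:
    """Write a panel as PED/MAP; reference allele written as ``alleles[0]``."""
    if g.n_samples == 0 or g.n_markers == 0:
        raise ValueError("refusing to write an empty panel")
    ref, alt = alleles
    with open(map_path, "w") as fh:
        for rec in g.markers.itertuples(index=False):
            fh.write(f"{rec.chrom}\t{rec.marker_id}\t0\t{rec.pos}\n")
    code = {0.0: f"{ref} {ref}", 1.0: f"{ref} {alt}", 2.0: f"{alt} {alt}"}
    with open(ped_path, "w") as fh:
        for i, (sid, pop) in enumerate(zip(g.sample_ids, g.subpops)):
            gt = [
                "0 0" if math.isnan(d) else code[d] for d in g.dosage[i]
            ]
            fh.write(f"{pop} {sid} 0 0 0 -9 " + " ".join(gt) + "\n")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

_POP_HEADER = "##SAMPLE=<ID={sid},Population={pop}>"


def write_vcf(g: GenotypeMatrix, path) -> None:
    """Write a minimal VCF v4.2 with GT and per-sample population header lines."""
    if g.n_samples == 0 or g.n_markers == 0:
        raise ValueError("refusing to write an empty panel")
    code = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for sid, pop in zip(g.sample_ids, g.subpops):
            fh.write(_POP_HEADER.format(sid=sid, pop=pop) + "\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(g.sample_ids)
            + "\n"
        )
        for m, rec in enumerate(g.markers.itertuples(index=False)):
            gts = [
                "./." if math.isnan(d) else code[d] for d in g.dosage[:, m]
            ]
            fh.write(
                f"{rec.chrom}\t{rec.pos}\t{rec.marker_id}\tA\tB\t.\t.\t.\tGT\t"
                + "\t".join(gts)
                + "\n"
            )


def read_vcf(path, subpop_labels: dict[str, str] | None = None) -> GenotypeMatrix:
    """Read a biallelic GT-only VCF into a :class:`GenotypeMatrix`.

    Phase is discarded.  Subpopulation labels come from
    ``##SAMPLE=<ID=...,Population=...>`` header lines (as written by
    :func:`write_vcf`) or the ``subpop_labels`` mapping; one of the two must
    cover every sample.  Multiallelic records are rejected: every scan in
    this package is biallelic.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    labels = dict(subpop_labels or {})
    for line in vcf.raw_header.splitlines():
        if line.startswith("##SAMPLE=<") and "Population=" in line:
            body = line[len("##SAMPLE=<"):].rstrip(">")
            fields = dict(kv.split("=", 1) for kv in body.split(","))
            if "ID" in fields and fields["ID"] not in labels:
                labels[fields["ID"]] = fields["Population"]
    missing_labels = [s for s in samples if s not in labels]
    if missing_labels:
        raise ValueError(
            f"no subpopulation label for samples: {missing_labels[:5]}"
        )

    ids, chroms, positions, rows = [], [], [], []
    for var in vcf:
        if len(var.ALT) != 1:
            raise ValueError(
                f"multiallelic site at {var.CHROM}:{var.POS}; biallelic-only scan"
            )
        ids.append(var.ID if var.ID not in (None, ".") else f"{var.CHROM}_{var.POS}")
        chroms.append(var.CHROM)
        positions.append(var.POS)
        # gt_types: 0 hom-ref, 1 het, 2 hom-alt (gts012), 3 unknown
        gt = np.asarray(var.gt_types, dtype=float)
        gt[gt == 3] = np.nan
        rows.append(gt)
    vcf.close()
    dosage = np.vstack(rows).T if rows else np.empty((len(samples), 0))
    return GenotypeMatrix(
        samples,
        [labels[s] for s in samples],
        make_marker_map(ids, chroms, positions),
        dosage,
    )


# ---------------------------------------------------------------------------
# Marker QC
# ---------------------------------------------------------------------------

@dataclass
class QCReport:
    """Per-filter marker attrition; each marker counted at its first failing
    filter, in the fixed order non-autosomal -> call-rate -> MAF."""

    n_input: int
    n_removed_nonautosomal: int
    n_removed_call_rate: int
    n_removed_maf: int
    n_retained: int

    def __post_init__(self) -> None:
        total = (
            self.n_retained
            + self.n_removed_nonautosomal
            + self.n_removed_call_rate
            + self.n_removed_maf
        )
        assert total == self.n_input, "QC attrition does not sum to input"

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("filter\tn_markers\n")
            fh.write(f"input\t{self.n_input}\n")
            fh.write(f"removed_nonautosomal\t{self.n_removed_nonautosomal}\n")
            fh.write(f"removed_call_rate\t{self.n_removed_call_rate}\n")
            fh.write(f"removed_maf\t{self.n_removed_maf}\n")
            fh.write(f"retained\t{self.n_retained}\n")


def apply_qc(
    g: GenotypeMatrix,
    min_call_rate: float = 0.95,
    min_maf: float = 0.05,
    autosomes_only: bool = True,
) -> tuple[GenotypeMatrix, QCReport]:
    """Marker QC: drop non-autosomal markers, then markers with call rate
    below ``min_call_rate``, then markers with pooled MAF below ``min_maf``.

    Removal is strict (``<``): a marker exactly at a threshold is retained.
    MAF is computed across all samples pooled, not per subpopulation.
    """
    if g.n_markers == 0:
        raise ValueError("empty panel")
    autosomal = np.asarray([is_autosome(c) for c in g.markers["chrom"]])
    call = g.call_rate()
    maf = g.maf()
    fail_auto = ~autosomal if autosomes_only else np.zeros(g.n_markers, bool)
    fail_call = call < min_call_rate
    with np.errstate(invalid="ignore"):
        fail_maf = ~(maf >= min_maf)  # nan MAF (all-missing) fails too
    keep = ~(fail_auto | fail_call | fail_maf)
    # first-failing-filter attribution
    n_auto = int(fail_auto.sum())
    n_call = int((fail_call & ~fail_auto).sum())
    n_maf = int((fail_maf & ~fail_auto & ~fail_call).sum())
    report = QCReport(
        n_input=g.n_markers,
        n_removed_nonautosomal=n_auto,
        n_removed_call_rate=n_call,
        n_removed_maf=n_maf,
        n_retained=int(keep.sum()),
    )
    if not keep.any():
        raise ValueError("QC removed every marker; nothing left to analyze")
    return g.subset_markers(keep), report
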