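"""Core genotype container shared by every scan.

A :class:`GenotypeMatrix` holds a samples x markers diploid dosage matrix
(0/1/2 copies of the alternate allele, ``nan`` = missing) together with a
marker map and a per-sample subpopulation label.  All statistics in this
package consume this container; readers and the simulator produce it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = np.nan

_NON_AUTOSOMES = {"X", "Y", "MT", "M", "XY", "W", "Z"}


def is_autosome(chrom: str | int) -> bool:
    """True when a chromosome label denotes an autosome (positive integer)."""
    s = str(chrom).strip()
    if s.upper().startswith("CHR"):
        s = s[3:]
    if s.upper() in _NON_AUTOSOMES:
        return False
    try:
        return int(s) > 0
    except ValueError:
        return False


def make_marker_map(marker_ids, chroms, positions) -> pd.DataFrame:
    """Build a marker map frame and validate it.

    Positions are 1-based.  Within a chromosome positions must be strictly
    increasing and marker identifiers must be unique panel-wide.
    """
    df = pd.DataFrame(
        {
            "marker_id": [str(m) for m in marker_ids],
            "chrom": [str(c) for c in chroms],
            "pos": np.asarray(positions, dtype=np.int64),
        }
    )
    if df["marker_id"].duplicated().any():
        dup = df.loc[df["marker_id"].duplicated(), "marker_id"].iloc[0]
        raise ValueError(f"duplicate marker id: {dup!r}")
    if (df["pos"] < 1).any():
        raise ValueError("marker positions must be >= 1 (1-based)")
    for chrom, grp in df.groupby("chrom", sort=False):
        if not np.all(np.diff(grp["pos"].to_numpy()) > 0):
            raise ValueError(
                f"positions not strictly increasing on chromosome {chrom}"
            )
    return df


@dataclass
class GenotypeMatrix:
    """Samples x markers diploid dosage matrix with subpopulation labels.

    Attributes
    ----------
    sample_ids : list of str
    subpops : list of str
        Subpopulation label per sample, aligned with ``sample_ids``.
    markers : pandas.DataFrame
        Columns ``marker_id``, ``chrom`` (string label), ``pos`` (1-based bp).
    dosage : numpy.ndarray, shape (n_samples, n_markers)
        Float array with values in {0, 1, 2} and ``nan`` for missing calls.
    """

    sample_ids: list[str]
    subpops: list[str]
    markers: pd.DataFrame
    dosage: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.ndim != 2:
            raise ValueError("dosage must be 2-D (samples x markers)")
        ns, nm = self.dosage.shape
        if len(self.sample_ids) != ns:
            raise ValueError("sample_ids length does not match dosage rows")
        if len(self.subpops) != ns:
            raise ValueError("every sample needs a subpopulation label")
        if len(self.markers) != nm:
            raise ValueError("marker map length does not match dosage columns")
        valid = np.isnan(self.dosage) | np.isin(self.dosage, (0.0, 1.0, 2.0))
        if not valid.all():
            raise ValueError("dosage values must be 0, 1, 2 or nan")

    # -- basic shape ----------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosage.shape[1]

    def subpop_labels(self) -> list[str]:
        """Unique subpopulation labels in first-appearance order."""
        seen: dict[str, None] = {}
        for s in self.subpops:
            seen.setdefault(s, None)
        return list(seen)

    def sample_mask(self, subpop: str) -> np.ndarray:
        return np.asarray([s == subpop for s in self.subpops])

    def subset_samples(self, mask: np.ndarray) -> "GenotypeMatrix":
        mask = np.asarray(mask, dtype=bool)
        return GenotypeMatrix(
            [s for s, m in zip(self.sample_ids, mask) if m],
            [s for s, m in zip(self.subpops, mask) if m],
            self.markers,
            self.dosage[mask],
        )

    def subset_markers(self, mask: np.ndarray) -> "GenotypeMatrix":
        mask = np.asarray(mask, dtype=bool)
        return GenotypeMatrix(
            self.sample_ids,
            self.subpops,
            self.markers.loc[mask].reset_index(drop=True),
            self.dosage[:, mask],
        )

    def restrict_chrom(self, chrom: str) -> "GenotypeMatrix":
        return self.subset_markers((self.markers["chrom"] == str(chrom)).to_numpy())

    # -- per-marker summaries -------------------------------------------
    def call_rate(self) -> np.ndarray:
        """Fraction of non-missing genotypes per marker, pooled samples."""
        return 1.0 - np.isnan(self.dosage).mean(axis=0)

    def allele_freq(self, mask: np.ndarray | None = None) -> np.ndarray:
        """Alternate-allele frequency per marker (nan if no calls)."""
        d = self.dosage if mask is None else self.dosage[np.asarray(mask, bool)]
        with np.errstate(invalid="ignore"):
            return np.nanmean(d, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        """Minor-allele frequency per marker across all samples pooled."""
        p = self.allele_freq()
        return np.minimum(p, 1.0 - p)

    def __eq__(self, other: object) -> bool:  # used by round-trip tests
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.sample_ids == other.sample_ids
            and self.subpops == other.subpops
            and self.markers.reset_index(drop=True).equals(
                other.markers.reset_index(drop=True)
            )
            and np.array_equal(self.dosage, other.dosage, equal_nan=True)
        )
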