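"""Local-haplotype-sharing (LHS) scan per subpopulation.

At each marker the sharing score is the probability that two haplotypes
drawn at random from a subpopulation descend from the same ancestral
haplotype cluster of the fitted LD model:

    s(m) = sum_k f_k(m)^2

with ``f_k(m)`` the subpopulation's expected cluster frequency.  The score
is the local haplotype homozygosity of the cluster mosaic: 1/K_effective
under even sharing, approaching 1 where one ancestral haplotype dominates
(e.g. under a sweep).

This scan deliberately does **not** reproduce any Bayesian
ancestral-haplotype association model: significance is an empirical-tail
analog (genome-wide median/MAD standardization, normal upper tail) and is
labeled as such in all outputs.  Isolated single-marker flags ("orphan
signals") are removed, since a single SNP does not constitute a shared
haplotype; surviving runs of flagged markers are exported as intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .flk import ClusterModel, cluster_frequencies
from .panel import GenotypeMatrix

__all__ = ["lhs_score", "lhs_significant", "LhsTrack"]


@dataclass
class LhsTrack:
    """Per-marker sharing scores for one subpopulation on one chromosome."""

    subpop: str
    chrom: str
    positions: np.ndarray
    score: np.ndarray  # s(m) in [1/K, 1]
    z: np.ndarray | None = None
    flagged: np.ndarray | None = None
    runs: pd.DataFrame | None = field(default=None)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "chrom": self.chrom,
                "pos": self.positions,
                "subpop": self.subpop,
                "lhs": self.score,
            }
        )
        if self.z is not None:
            df["z"] = self.z
            df["significant"] = self.flagged
        return df


def lhs_score(model: ClusterModel, g: GenotypeMatrix, subpop: str) -> LhsTrack:
    """Sharing score s(m) = sum_k f_k(m)^2 for one subpopulation.

    Cluster frequencies are posterior expectations from the fitted model,
    averaged over EM restarts (cluster homozygosity is invariant to the
    label switching between restarts).
    """
    if not g.sample_mask(subpop).any():
        raise ValueError(f"no samples labeled {subpop!r}")
    scores = np.zeros(len(model.positions))
    for fit in model.fits:
        f = cluster_frequencies(fit, g, subpop)  # (M, K)
        scores += (f ** 2).sum(axis=1)
    scores /= len(model.fits)
    return LhsTrack(
        subpop=subpop,
        chrom=model.chrom,
        positions=model.positions,
        score=scores,
    )


def lhs_significant(
    track: LhsTrack,
    threshold_logbf_analog: float = 5.0,
    min_run: int = 2,
) -> pd.DataFrame:
    """Flag markers in the extreme upper tail of the sharing track and
    collapse them into runs, dropping orphans.

    Scores are standardized genome-wide by median/MAD; a marker is flagged
    when ``-log10`` of its normal upper-tail probability exceeds
    ``threshold_logbf_analog`` (an empirical analog of a log-Bayes-factor
    cutoff, not a Bayes factor).  Runs of fewer than ``min_run``
    consecutive flagged markers are removed as orphan signals.  Returns
    one row per surviving run: chrom, start, end (1-based closed, marker
    positions), n_snps, peak score.  Fills ``track.z/flagged/runs``.
    """
    s = track.score
    med = np.median(s)
    mad = np.median(np.abs(s - med)) * 1.4826
    if mad <= 0.0:
        raise ValueError("constant sharing track (zero MAD): cannot standardize")
    z = (s - med) / mad
    tail = np.maximum(stats.norm.sf(z), np.finfo(float).tiny)
    flagged = -np.log10(tail) > threshold_logbf_analog

    runs = []
    i = 0
    n = len(flagged)
    while i < n:
        if not flagged[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and flagged[j + 1]:
            j += 1
        if j - i + 1 >= min_run:
            runs.append(
                {
                    "chrom": track.chrom,
                    "start": int(track.positions[i]),
                    "end": int(track.positions[j]),
                    "subpop": track.subpop,
                    "n_snps": j - i + 1,
                    "peak_score": float(s[i : j + 1].max()),
                }
            )
        else:
            flagged[i : j + 1] = False  # orphan removed
        i = j + 1

    track.z = z
    track.flagged = flagged
    track.runs = pd.DataFrame(
        runs, columns=["chrom", "start", "end", "subpop", "n_snps", "peak_score"]
    )
    return track.runs
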