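"""Synthetic structured genotype panels with known selective sweeps.

The generator reproduces the statistical structure the downstream scans
assume, at desk scale:

* **Hierarchical drift** — per-SNP ancestral frequencies are uniform on
  [0.05, 0.95]; each branch of a two-level population tree draws its
  frequency from the Balding–Nichols beta
  ``Beta(p(1-F)/F, (1-p)(1-F)/F)``, so a branch with drift parameter ``F``
  has ``Var(p_i) = F p (1-p)`` exactly and the expected pairwise
  Weir–Cockerham F_ST between two independently drifted subpopulations is
  ``F``.
* **Linkage disequilibrium** — each subpopulation carries a small pool of
  founder haplotypes; individual haplotypes are mosaics of founders with a
  per-bp copying switch rate, giving fastPHASE-style block LD.  The pool is
  frequency-matched: at each SNP, ``round(n_founders * p_sub)`` founders
  carry the alternate allele (random placement), so the founder bottleneck
  adds only a ``O(1/n_founders^2)`` quantization error to the realized
  subpopulation frequency instead of an extra ``p(1-p)/n_founders`` of
  drift, and the realized mean F_ST stays at the Balding–Nichols
  expectation.
* **Selective sweeps** — inside a sweep interval, a chosen fraction of the
  target subpopulation's haplotypes copy one favored founder, raising both
  allele-frequency divergence and local haplotype homozygosity, so that
  frequency-based (d_i, FLK) and haplotype-based (hapFLK, LHS) scans both
  see the signal.

Everything is reproducible from the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .panel import GenotypeMatrix, make_marker_map


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class SweepSpec:
    """One injected sweep: on ``chrom`` in ``[start, end]`` (1-based closed),
    ``favored_fraction`` of the target subpopulation's haplotypes copy a
    single favored founder haplotype."""

    target_subpop: str
    chrom: str
    start: int
    end: int
    favored_fraction: float = 0.9

    def __post_init__(self):
        if self.end <= self.start:
            raise ConfigError("sweep interval needs end > start")
        if not 0.5 < self.favored_fraction <= 1.0:
            raise ConfigError("favored_fraction must lie in (0.5, 1]")


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic panel.

    ``tree`` groups subpopulation indices into a two-level hierarchy; with
    the default single group every subpopulation drifts independently from
    the ancestral pool, giving expected pairwise F_ST ~= ``drift_f``.
    ``copying_switch_rate`` is the per-bp probability governing founder
    mosaic switches (interval switch probability ``1 - exp(-rate * dist)``).
    """

    n_subpops: int = 2
    samples_per_subpop: int = 50
    n_chromosomes: int = 1
    chrom_length: int = 10_000_000
    n_snps_per_chrom: int = 2_000
    drift_f: float = 0.05
    tree: tuple[tuple[int, ...], ...] | None = None
    n_founder_haplotypes: int = 16
    copying_switch_rate: float = 1e-5
    missing_rate: float = 0.0
    sweeps: tuple[SweepSpec, ...] = ()
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.drift_f < 1.0:
            raise ConfigError("drift_f must lie strictly inside (0, 1)")
        if self.n_founder_haplotypes < 2:
            raise ConfigError("need at least 2 founder haplotypes")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ConfigError("missing_rate must lie in [0, 1)")
        if self.n_subpops < 1 or self.samples_per_subpop < 1:
            raise ConfigError("need at least one subpopulation and sample")
        labels = set(self.subpop_labels())
        chroms = set(self.chrom_labels())
        for sw in self.sweeps:
            if sw.target_subpop not in labels:
                raise ConfigError(f"unknown sweep target {sw.target_subpop!r}")
            if str(sw.chrom) not in chroms:
                raise ConfigError(f"unknown sweep chromosome {sw.chrom!r}")
            if sw.start < 1 or sw.end > self.chrom_length:
                raise ConfigError("sweep interval outside chromosome bounds")
        if self.tree is not None:
            members = sorted(i for grp in self.tree for i in grp)
            if members != list(range(self.n_subpops)):
                raise ConfigError(
                    "tree groups must partition subpopulation indices 0..n-1"
                )

    def subpop_labels(self) -> list[str]:
        return [f"pop{i + 1}" for i in range(self.n_subpops)]

    def chrom_labels(self) -> list[str]:
        return [str(c + 1) for c in range(self.n_chromosomes)]


@dataclass
class SweepTruth:
    """Ground truth of injected sweeps.

    ``records`` carries one entry per sweep: the spec itself plus the
    realized frequency, per subpopulation, of the favored founder's allele
    at the marker nearest the sweep midpoint (the sweep core).
    """

    records: list[dict] = field(default_factory=list)

    def intervals(self) -> list[tuple[str, int, int, str]]:
        """(chrom, start, end, target_subpop) per injected sweep; 1-based closed."""
        return [
            (r["spec"].chrom, r["spec"].start, r["spec"].end, r["spec"].target_subpop)
            for r in self.records
        ]

    def write_bed(self, bed_path, tsv_path) -> None:
        """Truth intervals as BED (0-based half-open) + TSV sidecar with labels."""
        with open(bed_path, "w") as fh:
            for i, (chrom, start, end, _pop) in enumerate(self.intervals()):
                fh.write(f"{chrom}\t{start - 1}\t{end}\tsweep{i + 1}\n")
        with open(tsv_path, "w") as fh:
            fh.write("name\tchrom\tstart_1based\tend_1based\ttarget_subpop"
                     "\tfavored_fraction\tcore_pos\tcore_freqs\n")
            for i, rec in enumerate(self.records):
                sw = rec["spec"]
                freqs = ",".join(
                    f"{pop}:{f:.4f}" for pop, f in rec["core_freq"].items()
                )
                fh.write(
                    f"sweep{i + 1}\t{sw.chrom}\t{sw.start}\t{sw.end}\t"
                    f"{sw.target_subpop}\t{sw.favored_fraction}\t"
                    f"{rec['core_pos']}\t{freqs}\n"
                )


# ---------------------------------------------------------------------------


def _unique_sorted_positions(rng: np.random.Generator, length: int, k: int) -> np.ndarray:
    """k distinct 1-based positions, uniform without replacement, sorted."""
    if k > length:
        raise ConfigError("more SNPs than base pairs on a chromosome")
    chosen: set[int] = set()
    while len(chosen) < k:
        draw = rng.integers(1, length + 1, size=2 * (k - len(chosen)))
        for v in draw:
            if len(chosen) >= k:
                break
            chosen.add(int(v))
    return np.sort(np.fromiter(chosen, dtype=np.int64, count=k))


def _balding_nichols(rng, p: np.ndarray, f: float) -> np.ndarray:
    """One Balding–Nichols draw per SNP around frequencies ``p``."""
    a = p * (1.0 - f) / f
    b = (1.0 - p) * (1.0 - f) / f
    q = rng.beta(a, b)
    return np.clip(q, 1e-9, 1.0 - 1e-9)


def simulate_panel(config: SimConfig) -> tuple[GenotypeMatrix, SweepTruth]:
    """Generate a structured diploid panel plus ground truth.

    See the module docstring for the generative model.  Bit-identical
    output for identical config (the seed is part of the config).
    """
    rng = np.random.default_rng(config.seed)
    labels = config.subpop_labels()
    n_pop, n_per = config.n_subpops, config.samples_per_subpop
    n_hap = 2 * n_per
    groups = (
        config.tree
        if config.tree is not None
        else (tuple(range(n_pop)),)
    )
    group_of = {}
    for gi, grp in enumerate(groups):
        for pi in grp:
            group_of[pi] = gi

    marker_ids, chroms_col, pos_col = [], [], []
    dosage_blocks = []
    truth = SweepTruth()
    # haplotype allele matrices per chromosome per subpop for truth bookkeeping
    for ci, chrom in enumerate(config.chrom_labels()):
        pos = _unique_sorted_positions(rng, config.chrom_length, config.n_snps_per_chrom)
        nm = len(pos)
        marker_ids.extend(f"snp_{chrom}_{i + 1}" for i in range(nm))
        chroms_col.extend([chrom] * nm)
        pos_col.extend(pos.tolist())

        p_anc = rng.uniform(0.05, 0.95, size=nm)
        # two-level drift: ancestral -> group -> subpopulation; with a single
        # group the group branch is skipped so pairwise drift equals drift_f
        if len(groups) > 1:
            p_group = [
                _balding_nichols(rng, p_anc, config.drift_f) for _ in groups
            ]
        else:
            p_group = [p_anc]
        p_sub = [
            _balding_nichols(rng, p_group[group_of[pi]], config.drift_f)
            for pi in range(n_pop)
        ]

        # switch probability per inter-marker interval
        gaps = np.diff(pos).astype(float)
        p_switch = 1.0 - np.exp(-config.copying_switch_rate * gaps)

        chrom_haps = []  # per subpop: (n_hap, nm) allele matrix
        for pi in range(n_pop):
            nf = config.n_founder_haplotypes
            # frequency-matched founder pool: round(nf * p) alt alleles per
            # SNP, placed uniformly at random among the founders
            counts = np.round(nf * p_sub[pi]).astype(np.int64)
            order = np.argsort(rng.random((nf, nm)), axis=0)
            founders = (order < counts[None, :]).astype(np.int8)
            # founder-index path per haplotype: markov mosaic
            path = np.empty((n_hap, nm), dtype=np.int32)
            path[:, 0] = rng.integers(0, config.n_founder_haplotypes, size=n_hap)
            switches = rng.random((n_hap, nm - 1)) < p_switch[None, :]
            dests = rng.integers(0, config.n_founder_haplotypes, size=(n_hap, nm - 1))
            for m in range(1, nm):
                path[:, m] = np.where(
                    switches[:, m - 1], dests[:, m - 1], path[:, m - 1]
                )
            # sweeps targeting this subpop on this chromosome
            for sw in config.sweeps:
                if sw.target_subpop != labels[pi] or str(sw.chrom) != chrom:
                    continue
                in_iv = (pos >= sw.start) & (pos <= sw.end)
                if not in_iv.any():
                    continue
                n_fav = int(round(sw.favored_fraction * n_hap))
                fav_haps = rng.choice(n_hap, size=n_fav, replace=False)
                path[np.ix_(fav_haps, np.nonzero(in_iv)[0])] = 0
            haps = founders[path, np.arange(nm)[None, :]]
            chrom_haps.append(haps)

        block = np.concatenate(
            [haps[0::2] + haps[1::2] for haps in chrom_haps], axis=0
        ).astype(float)
        dosage_blocks.append(block)

        # realized core-allele frequencies for sweeps on this chromosome
        for sw in config.sweeps:
            if str(sw.chrom) != chrom:
                continue
            mid = (sw.start + sw.end) // 2
            core = int(np.argmin(np.abs(pos - mid)))
            pi_target = labels.index(sw.target_subpop)
            # majority allele at the core in the target subpop marks the
            # swept haplotype class
            fav_allele = int(chrom_haps[pi_target][:, core].mean() >= 0.5)
            core_freq = {
                labels[pi]: float(
                    (chrom_haps[pi][:, core] == fav_allele).mean()
                )
                for pi in range(n_pop)
            }
            truth.records.append(
                {"spec": sw, "core_pos": int(pos[core]), "core_freq": core_freq}
            )

    dosage = np.concatenate(dosage_blocks, axis=1)
    if config.missing_rate > 0:
        mask = rng.random(dosage.shape) < config.missing_rate
        dosage[mask] = np.nan

    sample_ids = [
        f"{labels[pi]}_s{si + 1}" for pi in range(n_pop) for si in range(n_per)
    ]
    subpops = [labels[pi] for pi in range(n_pop) for _ in range(n_per)]
    markers = make_marker_map(marker_ids, chroms_col, pos_col)
    return GenotypeMatrix(sample_ids, subpops, markers, dosage), truth


def balding_nichols_panel(
    n_subpops: int,
    samples_per_subpop: int,
    n_snps: int,
    drift_f: float,
    seed: int = 0,
    chrom_length: int = 100_000_000,
) -> GenotypeMatrix:
    """A pure Balding–Nichols null panel: independent SNPs, no LD, no sweeps.

    Per SNP, ancestral frequency ~ U(0.05, 0.95), each subpopulation's
    frequency is one ``Beta(p(1-F)/F, (1-p)(1-F)/F)`` draw, and genotypes
    are binomial(2, p_i).  This is the matched null for drift-model tests
    (e.g. FLK calibration against ``F = drift_f * I``), free of the founder
    pool used by :func:`simulate_panel`.
    """
    if not 0.0 < drift_f < 1.0:
        raise ConfigError("drift_f must lie strictly inside (0, 1)")
    rng = np.random.default_rng(seed)
    pos = _unique_sorted_positions(rng, chrom_length, n_snps)
    p_anc = rng.uniform(0.05, 0.95, size=n_snps)
    dosage = np.concatenate(
        [
            rng.binomial(
                2, _balding_nichols(rng, p_anc, drift_f)[None, :],
                size=(samples_per_subpop, n_snps),
            )
            for _ in range(n_subpops)
        ],
        axis=0,
    ).astype(float)
    labels = [f"pop{i + 1}" for i in range(n_subpops)]
    markers = make_marker_map(
        [f"snp_{i + 1}" for i in range(n_snps)], ["1"] * n_snps, pos
    )
    return GenotypeMatrix(
        [f"{lab}_s{si + 1}" for lab in labels for si in range(samples_per_subpop)],
        [lab for lab in labels for _ in range(samples_per_subpop)],
        markers,
        dosage,
    )


def write_panel(panel: GenotypeMatrix, fmt: str, prefix) -> list[str]:
    """Write a panel as ``ped_map`` or ``vcf``; returns the file paths."""
    from . import io as gio

    prefix = str(prefix)
    if fmt == "ped_map":
        paths = [prefix + ".ped", prefix + ".map"]
        gio.write_plink(panel, *paths)
    elif fmt == "vcf":
        paths = [prefix + ".vcf"]
        gio.write_vcf(panel, paths[0])
    else:
        raise ConfigError(f"unknown panel format {fmt!r}")
    return paths


# ---------------------------------------------------------------------------


def _overlaps(a_start, a_end, b_start, b_end) -> bool:
    return a_start <= b_end and b_start <= a_end


def evaluate_recovery(detected, truth: SweepTruth) -> tuple[float, float]:
    """Precision/recall of detected ROI against injected sweeps (>=1 bp overlap).

    Recall counts a truth interval as recovered when at least one detected
    ROI of the correct subpopulation (or a population-agnostic ROI labeled
    ``"all"``) overlaps it.  Precision is the fraction of detected ROI
    overlapping any truth interval; it is ``nan`` when nothing was detected.
    """
    truths = truth.intervals()
    if not truths:
        raise ValueError("no truth intervals to evaluate against")
    hits = 0
    for chrom, start, end, pop in truths:
        for roi in detected:
            if str(roi.chrom) != str(chrom):
                continue
            if roi.subpop not in (pop, "all"):
                continue
            if _overlaps(roi.start, roi.end, start, end):
                hits += 1
                break
    recall = hits / len(truths)
    if not detected:
        return float("nan"), recall
    n_true_pos = sum(
        any(
            str(roi.chrom) == str(chrom) and _overlaps(roi.start, roi.end, start, end)
            for chrom, start, end, _pop in truths
        )
        for roi in detected
    )
    return n_true_pos / len(detected), recall
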