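"""FLK and hapFLK haplotype-differentiation scans.

FLK tests a SNP's per-population allele frequencies against the drift
expected under a hierarchical population history.  The history enters as a
population kinship matrix ``F`` built from pairwise Reynolds distances via
a neighbor-joining tree (midpoint-rooted; no outgroup): ``F[i, j]`` is the
branch length shared by populations ``i`` and ``j`` from the root to their
most recent common ancestor, and ``F[i, i]`` is the root-to-leaf length.
The statistic is the quadratic form

    T = (p - p0 1)^T [p0 (1 - p0) F]^{-1} (p - p0 1),
    p0 = (1^T F^{-1} p) / (1^T F^{-1} 1),

chi-square with ``n_pops - 1`` degrees of freedom under drift.

hapFLK applies the same quadratic form to *local haplotype-cluster
frequencies* from a fastPHASE-style LD model: a hidden-Markov mosaic of K
ancestral haplotype clusters with per-marker cluster weights, cluster
allele frequencies, and jump probabilities, fitted to unphased genotypes
with a diploid (cluster-pair) EM and averaged over random restarts.
Because the null distribution of the summed form is not a clean
chi-square, hapFLK p-values come from a genome-wide robust standardization
(median/MAD, normal upper tail).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .panel import GenotypeMatrix

__all__ = [
    "reynolds_distance",
    "reynolds_distance_matrix",
    "kinship_from_tree",
    "KinshipMatrix",
    "flk_test",
    "flk_scan",
    "fit_cluster_model",
    "ClusterModel",
    "hapflk_scan",
    "cluster_frequencies",
]

SIGNIFICANCE_MLOG10P = 4.0  # genome-scan significance: -log10 p > 4


# ---------------------------------------------------------------------------
# Reynolds distances and tree-derived kinship
# ---------------------------------------------------------------------------

def reynolds_distance(
    freqs_i: np.ndarray,
    freqs_j: np.ndarray,
    n_i: np.ndarray | None = None,
    n_j: np.ndarray | None = None,
) -> float:
    """Reynolds theta distance between two populations from per-SNP
    alternate-allele frequencies (nan entries are dropped pairwise).

    When diploid sample sizes ``n_i``/``n_j`` (called genotypes per SNP) are
    given, the binomial sampling variance of the frequency estimates is
    subtracted from the numerator, giving a population-level theta rather
    than one inflated by ``~1/(2n)``; the result is clipped at 0.
    """
    p, q = np.asarray(freqs_i, float), np.asarray(freqs_j, float)
    ok = ~(np.isnan(p) | np.isnan(q))
    num = (p[ok] - q[ok]) ** 2
    if n_i is not None and n_j is not None:
        ni = np.broadcast_to(np.asarray(n_i, float), p.shape)[ok]
        nj = np.broadcast_to(np.asarray(n_j, float), p.shape)[ok]
        num = (
            num
            - p[ok] * (1 - p[ok]) / np.maximum(2 * ni - 1, 1)
            - q[ok] * (1 - q[ok]) / np.maximum(2 * nj - 1, 1)
        )
    den = np.sum(p[ok] + q[ok] - 2.0 * p[ok] * q[ok])
    if den <= 0.0:
        raise ValueError("no SNP informative in both populations")
    return max(float(np.sum(num) / den), 0.0)


def reynolds_distance_matrix(
    g: GenotypeMatrix, correct_sample_size: bool = True
) -> pd.DataFrame:
    """Pairwise Reynolds distances between all subpopulations of a panel."""
    pops = g.subpop_labels()
    freqs, counts = {}, {}
    for p in pops:
        mask = g.sample_mask(p)
        freqs[p] = g.allele_freq(mask)
        counts[p] = (~np.isnan(g.dosage[mask])).sum(axis=0).astype(float)
    d = np.zeros((len(pops), len(pops)))
    for i in range(len(pops)):
        for j in range(i + 1, len(pops)):
            a, b = pops[i], pops[j]
            d[i, j] = d[j, i] = reynolds_distance(
                freqs[a],
                freqs[b],
                counts[a] if correct_sample_size else None,
                counts[b] if correct_sample_size else None,
            )
    return pd.DataFrame(d, index=pops, columns=pops)


def drift_kinship(g: GenotypeMatrix) -> KinshipMatrix:
    """Kinship matrix estimated from a panel.

    The pairwise Reynolds theta between two populations estimates the
    *mean* of their two root-to-leaf drift coefficients, not the sum, so
    distances are doubled before neighbor joining to make tree branch
    lengths additive in drift; sampling variance is removed from theta so
    the diagonal reflects population drift only (the per-SNP sampling term
    is added back inside :func:`flk_scan`)."""
    return kinship_from_tree(2.0 * reynolds_distance_matrix(g))


@dataclass
class KinshipMatrix:
    """Population covariance structure derived from a rooted tree."""

    labels: list[str]
    matrix: np.ndarray  # (n_pops, n_pops), symmetric PSD
    tree_newick: str

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.matrix, index=self.labels, columns=self.labels).to_csv(
            path, sep="\t"
        )


def kinship_from_tree(distances: pd.DataFrame) -> KinshipMatrix:
    """Kinship matrix from a distance matrix via neighbor joining.

    The NJ tree is midpoint-rooted (no outgroup is assumed); negative NJ
    branch lengths are clipped to zero with a warning.  For two
    populations the root is placed midway between them.
    """
    labels = list(distances.index)
    n = len(labels)
    if n < 2:
        raise ValueError("kinship needs at least two populations")
    d = np.asarray(distances, dtype=float)
    if n == 2:
        half = d[0, 1] / 2.0
        return KinshipMatrix(
            labels,
            np.diag([half, half]),
            f"({labels[0]}:{half:g},{labels[1]}:{half:g});",
        )

    from skbio import DistanceMatrix
    from skbio.tree import nj

    tree = nj(DistanceMatrix(d, ids=labels))
    clipped = False
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
            clipped = True
    if clipped:
        warnings.warn("negative neighbor-joining branch lengths clipped to 0")
    tree = tree.root_at_midpoint()

    F = np.zeros((n, n))
    tips = {t.name: t for t in tree.tips()}
    for i, a in enumerate(labels):
        F[i, i] = tree.distance(tips[a], tree.root())
        for j in range(i + 1, n):
            mrca = tree.lowest_common_ancestor([tips[a], tips[labels[j]]])
            F[i, j] = F[j, i] = tree.distance(mrca, tree.root())
    return KinshipMatrix(labels, F, str(tree).strip())


# ---------------------------------------------------------------------------
# FLK
# ---------------------------------------------------------------------------

def _corrected_kinship(F: np.ndarray, n_genotypes: np.ndarray) -> np.ndarray:
    """Add the binomial sampling variance of finite samples to the diagonal:
    Var(p_hat_i) = p(1-p) [F_ii + (1 - F_ii) / (2 n_i)]."""
    F = F.copy()
    d = np.arange(len(F))
    F[d, d] = F[d, d] + (1.0 - F[d, d]) / (2.0 * n_genotypes)
    return F


def flk_test(p: np.ndarray, F: np.ndarray) -> tuple[float, float]:
    """FLK statistic and chi-square p-value for one SNP.

    ``p`` holds per-population alternate-allele frequencies; ``F`` is the
    (possibly sample-size-corrected) kinship.  Monomorphic SNPs (all
    frequencies equal to 0 or 1) are the caller's responsibility to skip.
    Singular kinship falls back to a pseudo-inverse with a warning.
    """
    p = np.asarray(p, float)
    npop = len(p)
    ones = np.ones(npop)
    try:
        Finv = np.linalg.inv(F)
    except np.linalg.LinAlgError:
        warnings.warn("singular kinship matrix: using pseudo-inverse")
        Finv = np.linalg.pinv(F)
    p0 = float(ones @ Finv @ p) / float(ones @ Finv @ ones)
    var = p0 * (1.0 - p0)
    if var <= 0.0:
        return 0.0, 1.0
    dev = p - p0
    T = float(dev @ Finv @ dev) / var
    T = max(T, 0.0)
    pval = float(stats.chi2.sf(T, df=npop - 1))
    return T, max(pval, np.finfo(float).tiny)


def flk_scan(
    g: GenotypeMatrix,
    kinship: KinshipMatrix,
    correct_sample_size: bool = True,
    threshold: float = SIGNIFICANCE_MLOG10P,
) -> pd.DataFrame:
    """Per-SNP FLK over a panel.

    Returns a frame with chrom, pos, T, p, -log10 p and a significance flag
    at ``-log10 p > threshold``.  SNPs monomorphic across all populations
    pooled are skipped (nan statistic, no flag).
    """
    pops = kinship.labels
    masks = [g.sample_mask(p) for p in pops]
    freqs = np.stack([g.allele_freq(m) for m in masks])  # (npop, M)
    ns = np.stack(
        [(~np.isnan(g.dosage[m])).sum(axis=0).astype(float) for m in masks]
    )
    M = g.n_markers
    T = np.full(M, np.nan)
    pv = np.full(M, np.nan)
    for m in range(M):
        p = freqs[:, m]
        if np.isnan(p).any() or (ns[:, m] < 1).any():
            continue
        pooled = float((p * ns[:, m]).sum() / ns[:, m].sum())
        if pooled <= 0.0 or pooled >= 1.0:
            continue  # monomorphic overall
        F = (
            _corrected_kinship(kinship.matrix, ns[:, m])
            if correct_sample_size
            else kinship.matrix
        )
        T[m], pv[m] = flk_test(p, F)
    with np.errstate(invalid="ignore"):
        mlog = -np.log10(pv)
    return pd.DataFrame(
        {
            "chrom": g.markers["chrom"],
            "pos": g.markers["pos"],
            "T": T,
            "p": pv,
            "mlog10p": mlog,
            "significant": mlog > threshold,
        }
    )


# ---------------------------------------------------------------------------
# Haplotype-cluster model (fastPHASE-style diploid HMM)
# ---------------------------------------------------------------------------

_THETA_EPS = 1e-4
_ALPHA_EPS = 1e-6
_RHO_MIN, _RHO_MAX = 1e-6, 0.999


@dataclass
class ClusterModel:
    """Fitted haplotype-cluster HMM ensemble.

    Each entry of ``fits`` holds per-marker cluster weights ``alpha``
    (M, K; rows sum to 1), cluster allele frequencies ``theta`` (M, K),
    jump probabilities ``rho`` (M; entry 0 unused), the final
    log-likelihood and the EM log-likelihood trace.  ``chrom`` records the
    chromosome the model was fitted on; marker order matches the panel.
    """

    K: int
    n_fits: int
    chrom: str
    positions: np.ndarray
    fits: list[dict] = field(default_factory=list)

    @property
    def best_fit(self) -> dict:
        return max(self.fits, key=lambda f: f["loglik"])


def _genotype_codes(dosage_col: np.ndarray) -> np.ndarray:
    """0/1/2 genotype, 3 = missing."""
    codes = np.where(np.isnan(dosage_col), 3.0, dosage_col)
    return codes.astype(np.int64)


def _emission_stack(theta_m: np.ndarray) -> np.ndarray:
    """(4, K, K) emission matrices for genotypes 0,1,2 and missing."""
    t = theta_m
    o = np.ones_like(t)
    e0 = np.outer(1 - t, 1 - t)
    e1 = np.outer(t, 1 - t) + np.outer(1 - t, t)
    e2 = np.outer(t, t)
    em = np.outer(o, o)
    return np.stack([e0, e1, e2, em])


def _forward(codes, alpha, theta, rho):
    """Scaled forward pass; returns A (N,M,K,K), scales (N,M), loglik sum."""
    N, M = codes.shape[0], theta.shape[0]
    K = theta.shape[1]
    A = np.empty((N, M, K, K))
    scales = np.empty((N, M))
    E = _emission_stack(theta[0])[codes[:, 0]]
    a0 = np.outer(alpha[0], alpha[0])[None, :, :] * E
    c = a0.sum(axis=(1, 2))
    A[:, 0] = a0 / c[:, None, None]
    scales[:, 0] = c
    for m in range(1, M):
        prev = A[:, m - 1]
        r, al = rho[m], alpha[m]
        rows = prev.sum(axis=2)
        cols = prev.sum(axis=1)
        pred = (
            (1 - r) ** 2 * prev
            + r * (1 - r) * (rows[:, :, None] * al[None, None, :])
            + r * (1 - r) * (al[None, :, None] * cols[:, None, :])
            + r * r * np.outer(al, al)[None, :, :]
        )
        anew = pred * _emission_stack(theta[m])[codes[:, m]]
        c = anew.sum(axis=(1, 2))
        c = np.maximum(c, np.finfo(float).tiny)
        A[:, m] = anew / c[:, None, None]
        scales[:, m] = c
    return A, scales, float(np.log(scales).sum())


def _em_fit(codes, positions, K, rng, max_iter, tol, switch_rate_init=1e-5):
    """One EM fit of the diploid cluster HMM from a random start."""
    N, M = codes.shape
    pooled = np.array(
        [
            codes[codes[:, m] != 3, m].mean() / 2.0 if (codes[:, m] != 3).any() else 0.5
            for m in range(M)
        ]
    )
    theta = np.clip(
        pooled[:, None] + rng.uniform(-0.3, 0.3, size=(M, K)), _THETA_EPS, 1 - _THETA_EPS
    )
    alpha = rng.dirichlet(np.full(K, 5.0), size=M)
    alpha = np.clip(alpha, _ALPHA_EPS, None)
    alpha /= alpha.sum(axis=1, keepdims=True)
    rho = np.empty(M)
    rho[0] = 0.0
    gaps = np.diff(positions).astype(float)
    rho[1:] = np.clip(1.0 - np.exp(-switch_rate_init * gaps), _RHO_MIN, _RHO_MAX)

    trace = []
    loglik = -np.inf
    for _ in range(max_iter):
        A, scales, ll = _forward(codes, alpha, theta, rho)
        trace.append(ll)

        # backward + accumulate sufficient statistics marker by marker
        B = np.ones((N, K, K))
        num = np.zeros((M, K))
        den = np.zeros((M, K))
        jump_into = np.zeros((M, K))
        jump_tot = np.zeros(M)
        alpha0_acc = np.zeros(K)
        for m in range(M - 1, -1, -1):
            gamma = A[:, m] * B
            gamma /= np.maximum(gamma.sum(axis=(1, 2)), np.finfo(float).tiny)[
                :, None, None
            ]
            rows = gamma.sum(axis=2)
            cols = gamma.sum(axis=1)
            usage = rows + cols
            cm = codes[:, m]
            # theta sufficient stats (missing genotypes excluded)
            den[m] = usage[cm != 3].sum(axis=0)
            hom = usage[cm == 2].sum(axis=0)
            if (cm == 1).any():
                th = theta[m]
                w1 = np.outer(th, 1 - th)
                w1 = w1 / np.maximum(w1 + w1.T, np.finfo(float).tiny)
                gh = gamma[cm == 1]
                num[m] = (
                    hom
                    + (gh * w1[None]).sum(axis=(0, 2))
                    + (gh * (1 - w1)[None]).sum(axis=(0, 1))
                )
            else:
                num[m] = hom
            if m == 0:
                alpha0_acc = usage.sum(axis=0)
                break

            # jump statistics between m-1 and m
            r, al = rho[m], alpha[m]
            E = _emission_stack(theta[m])[codes[:, m]]
            G = E * B
            c = scales[:, m][:, None, None]
            Ga = G @ al  # (N,K)
            atG = np.einsum("k,nkl->nl", al, G)  # (N,K)
            F = A[:, m - 1]
            Gt = (1 - r) * G + r * Ga[:, :, None]
            Gs = (1 - r) * G + r * atG[:, None, :]
            fc = F.sum(axis=1)  # column sums over i -> index j
            fr = F.sum(axis=2)  # row sums over j -> index i
            cstep = scales[:, m][:, None]
            j1 = r * al[None, :] * np.einsum("nj,nkj->nk", fc, Gt) / cstep
            j2 = r * al[None, :] * np.einsum("ni,nil->nl", fr, Gs) / cstep
            jump_into[m] = (j1 + j2).sum(axis=0)
            jump_tot[m] = jump_into[m].sum()

            # backward recursion to m-1
            aG = atG  # alpha^T G
            B = (
                (1 - r) ** 2 * G
                + (1 - r) * r * (Ga[:, :, None] + aG[:, None, :])
                + r * r * np.einsum("nk,k->n", Ga, al)[:, None, None]
            ) / c

        # ----- M-step -----
        theta = np.where(den > 1e-12, num / np.maximum(den, 1e-12), theta)
        theta = np.clip(theta, _THETA_EPS, 1 - _THETA_EPS)
        new_alpha = alpha.copy()
        new_alpha[0] = alpha0_acc / alpha0_acc.sum()
        ok = jump_tot[1:] > 1e-10
        new_alpha[1:][ok] = jump_into[1:][ok] / jump_tot[1:][ok][:, None]
        alpha = np.clip(new_alpha, _ALPHA_EPS, None)
        alpha /= alpha.sum(axis=1, keepdims=True)
        rho[1:] = np.clip(jump_tot[1:] / (2.0 * N), _RHO_MIN, _RHO_MAX)

        if ll - loglik < tol * abs(ll) and np.isfinite(loglik):
            loglik = ll
            break
        loglik = ll
    return {
        "alpha": alpha,
        "theta": theta,
        "rho": rho,
        "loglik": loglik,
        "loglik_trace": trace,
    }


def fit_cluster_model(
    g: GenotypeMatrix,
    K: int = 10,
    n_fits: int = 5,
    seed: int = 0,
    max_iter: int = 100,
    tol: float = 1e-6,
) -> ClusterModel:
    """Fit the diploid haplotype-cluster HMM on a single chromosome.

    Runs ``n_fits`` EM restarts (seeds ``seed + fit_index``); all fits are
    retained so downstream statistics can average over restarts, which
    smooths the label-switching and local-optimum noise of any single fit.
    """
    chroms = g.markers["chrom"].unique()
    if len(chroms) != 1:
        raise ValueError(
            f"cluster model is fitted one chromosome at a time, got {list(chroms)}"
        )
    if K < 1:
        raise ValueError("K must be >= 1")
    codes = _genotype_codes(g.dosage)
    positions = g.markers["pos"].to_numpy()
    model = ClusterModel(
        K=K, n_fits=n_fits, chrom=str(chroms[0]), positions=positions
    )
    for f in range(n_fits):
        rng = np.random.default_rng(seed + f)
        model.fits.append(
            _em_fit(codes, positions, K, rng, max_iter, tol)
        )
    return model


def cluster_frequencies(
    fit: dict, g: GenotypeMatrix, subpop: str | None = None
) -> np.ndarray:
    """Expected local cluster frequencies (M, K) for one fit.

    Averages each individual's posterior cluster usage (two haplotypes per
    individual) over the samples of ``subpop`` (or all samples).
    """
    sub = g if subpop is None else g.subset_samples(g.sample_mask(subpop))
    codes = _genotype_codes(sub.dosage)
    alpha, theta, rho = fit["alpha"], fit["theta"], fit["rho"]
    N, M = codes.shape
    K = theta.shape[1]
    A, scales, _ = _forward(codes, alpha, theta, rho)
    B = np.ones((N, K, K))
    out = np.empty((M, K))
    for m in range(M - 1, -1, -1):
        gamma = A[:, m] * B
        gamma /= np.maximum(gamma.sum(axis=(1, 2)), np.finfo(float).tiny)[
            :, None, None
        ]
        usage = gamma.sum(axis=2) + gamma.sum(axis=1)
        out[m] = usage.mean(axis=0) / 2.0
        if m == 0:
            break
        r, al = rho[m], alpha[m]
        G = _emission_stack(theta[m])[codes[:, m]] * B
        Ga = G @ al
        atG = np.einsum("k,nkl->nl", al, G)
        B = (
            (1 - r) ** 2 * G
            + (1 - r) * r * (Ga[:, :, None] + atG[:, None, :])
            + r * r * np.einsum("nk,k->n", Ga, al)[:, None, None]
        ) / scales[:, m][:, None, None]
    return out


def hapflk_scan(
    model: ClusterModel,
    g: GenotypeMatrix,
    kinship: KinshipMatrix,
    threshold: float = SIGNIFICANCE_MLOG10P,
) -> pd.DataFrame:
    """hapFLK scan over the markers of a fitted cluster model.

    Per fit and marker the FLK quadratic form is evaluated on each
    cluster's per-population frequency vector and averaged over clusters
    (halved, so K = 2 reduces to the biallelic FLK on one cluster).  The
    statistic is then averaged over EM restarts, and p-values come from a
    genome-wide median/MAD standardization with a normal upper tail.
    """
    pops = kinship.labels
    n_per_pop = np.array([g.sample_mask(p).sum() for p in pops], dtype=float)
    M = len(model.positions)
    stat_fits = np.zeros((model.n_fits, M))
    for fi, fit in enumerate(model.fits):
        freqs = np.stack(
            [cluster_frequencies(fit, g, p) for p in pops]
        )  # (npop, M, K)
        F = _corrected_kinship(kinship.matrix, n_per_pop)
        Finv = np.linalg.inv(F)
        ones = np.ones(len(pops))
        denom0 = float(ones @ Finv @ ones)
        for m in range(M):
            s = 0.0
            for k in range(model.K):
                fk = freqs[:, m, k]
                p0 = float(ones @ Finv @ fk) / denom0
                var = p0 * (1.0 - p0)
                if var <= 1e-12:
                    continue
                dev = fk - p0
                s += max(float(dev @ Finv @ dev) / var, 0.0)
            stat_fits[fi, m] = 0.5 * s
    stat = stat_fits.mean(axis=0)

    med = np.median(stat)
    mad = np.median(np.abs(stat - med)) * 1.4826
    if mad <= 0:
        raise ValueError("degenerate hapFLK distribution (zero MAD)")
    z = (stat - med) / mad
    pv = np.maximum(stats.norm.sf(z), np.finfo(float).tiny)
    mlog = -np.log10(pv)
    return pd.DataFrame(
        {
            "chrom": model.chrom,
            "pos": model.positions,
            "hapflk": stat,
            "p": pv,
            "mlog10p": mlog,
            "significant": mlog > threshold,
        }
    )
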