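"""The 42 summary statistics describing one admixed/source sample set.

Grouping (fixed order, see SUMMARY_NAMES):

* within population H (5): mean pairwise allele-sharing dissimilarity
  (ASD), mean and variance of per-SNP unbiased heterozygosity, mean and
  variance of individual method-of-moments inbreeding F;
* admixture pattern (32): mode, mean, variance, skewness, kurtosis,
  min, max and the nine deciles of the ASD-MDS African admixture
  proportions alpha, and the same sixteen for the African-European
  angles theta;
* between populations (5): Weir-Cockerham Fst of H against either
  source, mean cross-population ASD against either source, and the
  f3(H; Eur, Afr) admixture statistic.

Conventions: Fisher moment skewness and Pearson (non-excess) kurtosis;
deciles are linearly interpolated empirical quantiles (numpy default);
the mode is the argmax of a Gaussian kernel density (Silverman
bandwidth) on a 512-point grid; alpha is not clipped to [0, 1] so the
min/max statistics can register projection overshoot.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats as sps
from scipy.spatial.distance import pdist, squareform

from .simulate import SampleSet

__all__ = [
    "ASDMatrix",
    "MDSEmbedding",
    "AdmixtureProjection",
    "SUMMARY_NAMES",
    "asd_matrix",
    "classical_mds",
    "project_admixture",
    "heterozygosity_stats",
    "inbreeding_stats",
    "wc_fst",
    "f3_statistic",
    "distribution_stats",
    "compute_summary_vector",
]


@dataclass
class ASDMatrix:
    """Symmetric pairwise allele-sharing dissimilarity matrix in [0, 1]."""

    values: np.ndarray

    def __post_init__(self):
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("ASD matrix must be square")
        if not np.allclose(v, v.T) or not np.allclose(np.diag(v), 0):
            raise ValueError("ASD matrix must be symmetric with zero diagonal")


@dataclass
class MDSEmbedding:
    coordinates: np.ndarray  # (n, k)
    eigenvalues: np.ndarray  # (k,) decreasing
    labels: np.ndarray  # (n,) population label per row


@dataclass
class AdmixtureProjection:
    """Per admixed individual: projected African fraction and angle."""

    alpha: np.ndarray  # unclipped fractions
    theta: np.ndarray  # radians in [0, pi]; NaN where undefined


def asd_matrix(genotypes: np.ndarray) -> ASDMatrix:
    """Pairwise ASD: mean over shared non-missing sites of 1 - IBS/2.

    With diploid counts a, b in {0, 1, 2} the number of shared alleles
    is IBS = 2 - |a - b|, so per-site dissimilarity is |a - b| / 2.
    Missing genotypes are NaN; a pair with no shared site is an error.
    """
    g = np.asarray(genotypes, dtype=float)
    if g.ndim != 2 or g.shape[0] < 2:
        raise ValueError("need a 2-D genotype matrix with >= 2 individuals")
    if np.isnan(g).any():
        n = g.shape[0]
        out = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                ok = ~(np.isnan(g[i]) | np.isnan(g[j]))
                if not ok.any():
                    raise ValueError(f"pair ({i},{j}) shares no non-missing site")
                out[i, j] = out[j, i] = np.abs(g[i, ok] - g[j, ok]).mean() / 2.0
        return ASDMatrix(out)
    d = pdist(g, metric="cityblock") / (2.0 * g.shape[1])
    return ASDMatrix(squareform(d))


def classical_mds(asd: ASDMatrix, k: int = 2,
                  labels: Optional[np.ndarray] = None) -> MDSEmbedding:
    """Torgerson metric MDS: double-centre the squared dissimilarities,
    take the top-k eigenpairs, coordinates = eigenvector * sqrt(eigenvalue)."""
    D = asd.values
    n = D.shape[0]
    if k < 1 or n < k + 1:
        raise ValueError("need n >= k + 1 points")
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    evals, evecs = np.linalg.eigh((B + B.T) / 2.0)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    if evals[0] <= 0:
        raise ValueError("no positive eigenvalue: degenerate configuration")
    # rank-deficient configurations (e.g. collinear points) legitimately
    # have ~0 trailing eigenvalues: those axes get zero coordinates; a
    # substantially negative eigenvalue among the top k is an error
    top = evals[:k].copy()
    if np.any(top < -1e-8 * evals[0]):
        raise ValueError(f"fewer than k={k} positive eigenvalues")
    top[top < 0] = 0.0
    coords = evecs[:, :k] * np.sqrt(top)
    evals = np.concatenate([top, evals[k:]])
    if labels is None:
        labels = np.full(n, "", dtype=object)
    return MDSEmbedding(coordinates=coords, eigenvalues=evals[:k],
                        labels=np.asarray(labels))


def project_admixture(embedding: MDSEmbedding, admixed_label: str = "H",
                      afr_label: str = "AFR", eur_label: str = "EUR") -> AdmixtureProjection:
    """African admixture fractions and angles from an MDS embedding.

    alpha_i is the position of individual i's orthogonal projection on
    the segment joining the source centroids, scaled so the European
    centroid maps to 0 and the African centroid to 1 (unclipped).
    theta_i is the angle at x_i between the directions towards the two
    centroids; it is undefined (NaN, with a warning) for an individual
    coincident with a centroid.
    """
    lab = embedding.labels
    X = embedding.coordinates
    afr = X[lab == afr_label]
    eur = X[lab == eur_label]
    if len(afr) < 2 or len(eur) < 2:
        raise ValueError("both source populations need >= 2 members")
    c_afr = afr.mean(axis=0)
    c_eur = eur.mean(axis=0)
    axis = c_afr - c_eur
    d2 = float(axis @ axis)
    if d2 <= 0:
        raise ValueError("coincident source centroids")
    H = X[lab == admixed_label]
    alpha = (H - c_eur) @ axis / d2
    va = c_afr - H
    ve = c_eur - H
    na = np.linalg.norm(va, axis=1)
    ne = np.linalg.norm(ve, axis=1)
    ok = (na > 0) & (ne > 0)
    theta = np.full(len(H), np.nan)
    cosang = np.einsum("ij,ij->i", va[ok], ve[ok]) / (na[ok] * ne[ok])
    theta[ok] = np.arccos(np.clip(cosang, -1.0, 1.0))
    if not ok.all():
        warnings.warn("angle undefined for individual(s) at a source centroid",
                      stacklevel=2)
    return AdmixtureProjection(alpha=alpha, theta=theta)


def heterozygosity_stats(genotypes: np.ndarray) -> tuple[float, float]:
    """Mean and variance over SNPs of unbiased gene diversity
    2p(1-p) * 2n/(2n-1)."""
    g = np.asarray(genotypes, dtype=float)
    n = g.shape[0]
    if n < 2:
        raise ValueError("need >= 2 individuals")
    p = g.mean(axis=0) / 2.0
    het = 2.0 * p * (1.0 - p) * (2 * n) / (2 * n - 1)
    return float(het.mean()), float(het.var())


def inbreeding_stats(genotypes: np.ndarray) -> tuple[float, float]:
    """Mean and variance over individuals of method-of-moments F.

    F_i = (O_hom,i - E_hom) / (L_poly - E_hom) over polymorphic sites,
    with E_hom = sum_s (1 - 2 p_s (1 - p_s) * 2n/(2n-1)) (the
    small-sample-corrected expected homozygosity under random mating).
    """
    g = np.asarray(genotypes, dtype=float)
    n = g.shape[0]
    if n < 2:
        raise ValueError("need >= 2 individuals")
    p = g.mean(axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    if not poly.any():
        raise ValueError("no polymorphic sites")
    gp = g[:, poly]
    pp = p[poly]
    L = int(poly.sum())
    e_het = 2.0 * pp * (1.0 - pp) * (2 * n) / (2 * n - 1)
    E_hom = float(np.sum(1.0 - e_het))
    if abs(L - E_hom) < 1e-12:
        raise ValueError("expected homozygosity equals site count: F undefined")
    O_hom = (gp != 1).sum(axis=1).astype(float)
    F = (O_hom - E_hom) / (L - E_hom)
    return float(F.mean()), float(F.var())


def _wc_components(ga: np.ndarray, gb: np.ndarray):
    """Weir & Cockerham (1984) per-site variance components a, b, c for
    two populations of diploids (no inbreeding decomposition needed for
    the ratio-of-sums estimator)."""
    ga = np.asarray(ga, dtype=float)
    gb = np.asarray(gb, dtype=float)
    n1, n2 = ga.shape[0], gb.shape[0]
    if n1 < 2 or n2 < 2:
        raise ValueError("need >= 2 individuals per population")
    r = 2.0
    p1 = ga.mean(axis=0) / 2.0
    p2 = gb.mean(axis=0) / 2.0
    h1 = (ga == 1).mean(axis=0)
    h2 = (gb == 1).mean(axis=0)
    n_bar = (n1 + n2) / 2.0
    n_c = (r * n_bar - (n1**2 + n2**2) / (r * n_bar)) / (r - 1)
    p_bar = (n1 * p1 + n2 * p2) / (r * n_bar)
    s2 = (n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2) / ((r - 1) * n_bar)
    h_bar = (n1 * h1 + n2 * h2) / (r * n_bar)
    a = (n_bar / n_c) * (
        s2
        - (1.0 / (n_bar - 1))
        * (p_bar * (1 - p_bar) - (r - 1) / r * s2 - h_bar / 4.0)
    )
    b = (n_bar / (n_bar - 1)) * (
        p_bar * (1 - p_bar)
        - (r - 1) / r * s2
        - (2 * n_bar - 1) / (4 * n_bar) * h_bar
    )
    c = h_bar / 2.0
    return a, b, c


def wc_fst(pop_a: np.ndarray, pop_b: np.ndarray) -> float:
    """Weir & Cockerham (1984) two-population Fst, ratio of sums over SNPs."""
    a, b, c = _wc_components(pop_a, pop_b)
    denom = float(np.sum(a + b + c))
    if denom == 0.0:
        raise ValueError("Fst undefined: all sites monomorphic overall")
    return float(np.sum(a) / denom)


def f3_statistic(h: np.ndarray, src1: np.ndarray, src2: np.ndarray) -> float:
    """f3(H; src1, src2) with the finite-sample heterozygosity correction.

    mean over SNPs of (p_H - p_1)(p_H - p_2) - h_H / (2 n_H), where h_H
    is the unbiased heterozygosity of H and n_H its diploid sample size.
    Significantly negative values signal admixture of H between the two
    sources.
    """
    h = np.asarray(h, dtype=float)
    n_h = h.shape[0]
    if n_h < 2:
        raise ValueError("need >= 2 individuals in H")
    p_h = h.mean(axis=0) / 2.0
    p_1 = np.asarray(src1, dtype=float).mean(axis=0) / 2.0
    p_2 = np.asarray(src2, dtype=float).mean(axis=0) / 2.0
    poly = ~((p_h == p_1) & (p_h == p_2) & ((p_h == 0) | (p_h == 1)))
    if not poly.any():
        raise ValueError("no polymorphic sites")
    het = 2.0 * p_h * (1.0 - p_h) * (2 * n_h) / (2 * n_h - 1)
    vals = (p_h - p_1) * (p_h - p_2) - het / (2.0 * n_h)
    return float(vals[poly].mean())


def distribution_stats(values: np.ndarray) -> np.ndarray:
    """The 16 distribution descriptors: mode, mean, variance, skewness,
    kurtosis (Pearson), min, max, and the nine deciles."""
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 2:
        raise ValueError("need >= 2 finite values")
    if x.size < 10:
        raise ValueError("need >= 10 values for deciles")
    if np.ptp(x) == 0:
        mode = float(x[0])
        skew = 0.0
        kurt = 0.0
    else:
        kde = sps.gaussian_kde(x, bw_method="silverman")
        grid = np.linspace(x.min(), x.max(), 512)
        mode = float(grid[np.argmax(kde(grid))])
        skew = float(sps.skew(x))
        kurt = float(sps.kurtosis(x, fisher=False))
    deciles = np.percentile(x, np.arange(10, 100, 10))
    return np.array(
        [mode, x.mean(), x.var(), skew, kurt, x.min(), x.max(), *deciles]
    )


def _dist_names(prefix: str) -> list[str]:
    base = ["mode", "mean", "var", "skew", "kurt", "min", "max"]
    return [f"{prefix}_{b}" for b in base] + [
        f"{prefix}_d{q}" for q in range(10, 100, 10)
    ]


#: fixed 42-name order of the summary vector
SUMMARY_NAMES: tuple[str, ...] = tuple(
    ["asd_mean_H", "het_mean_H", "het_var_H", "F_mean_H", "F_var_H"]
    + _dist_names("alpha")
    + _dist_names("theta")
    + ["fst_afr_H", "fst_eur_H", "asd_mean_afr_H", "asd_mean_eur_H", "f3_H_eur_afr"]
)


def compute_summary_vector(samples: SampleSet, mds_axes: int = 2) -> np.ndarray:
    """The 42 summary statistics of one sample set, in SUMMARY_NAMES order.

    The MDS used for the admixture projection is computed on the pooled
    admixed + African-source + European-source samples.
    """
    H, A, E = samples.admixed, samples.afr, samples.eur
    n_h, n_a, n_e = len(H), len(A), len(E)
    pooled = np.vstack([H, A, E])
    labels = np.array(["H"] * n_h + ["AFR"] * n_a + ["EUR"] * n_e, dtype=object)
    asd = asd_matrix(pooled)
    D = asd.values
    iH = slice(0, n_h)
    iA = slice(n_h, n_h + n_a)
    iE = slice(n_h + n_a, n_h + n_a + n_e)

    within = D[iH, iH]
    asd_mean_h = float(within[np.triu_indices(n_h, k=1)].mean())
    het_m, het_v = heterozygosity_stats(H)
    f_m, f_v = inbreeding_stats(H)

    emb = classical_mds(asd, k=mds_axes, labels=labels)
    proj = project_admixture(emb)
    alpha_block = distribution_stats(proj.alpha)
    theta_block = distribution_stats(proj.theta[np.isfinite(proj.theta)])

    between = np.array(
        [
            wc_fst(A, H),
            wc_fst(E, H),
            float(D[iA, iH].mean()),
            float(D[iE, iH].mean()),
            f3_statistic(H, E, A),
        ]
    )
    vec = np.concatenate(
        [[asd_mean_h, het_m, het_v, f_m, f_v], alpha_block, theta_block, between]
    )
    assert vec.size == 42
    return vec
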