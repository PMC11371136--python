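"""Mixed-model genome-wide association scan with haplotype follow-up.

The scan uses the EMMAX approximation: a single-variance-component
linear mixed model

    y = X b + u + e,   u ~ N(0, sigma2_g * K),   e ~ N(0, sigma2_e * I)

is fitted once under the null by restricted maximum likelihood (REML),
and the estimated variance components are then reused for every marker's
generalized-least-squares test.  K is a genomic kinship matrix; the
default estimator is the VanRaden centered cross-product (guaranteed
positive semi-definite), with allele-sharing (IBS) as an option.

Spectral shortcut: with eigendecomposition K = U diag(lambda) U', the
rotated model has independent residuals with variances proportional to
``lambda_i + delta`` (delta = sigma2_e / sigma2_g), so both the REML
profile likelihood and the per-marker GLS reduce to weighted least
squares with weights ``1 / (lambda_i + delta)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .simgen import GenotypePanel

__all__ = [
    "LMMFit",
    "AssociationResult",
    "HaplotypeGrouping",
    "maf",
    "maf_filter",
    "impute_missing",
    "kinship",
    "pca_structure",
    "fit_null_lmm",
    "scan_snps",
    "bonferroni_threshold",
    "significant_hits",
    "haplotype_groups",
    "compare_haplotypes",
]


@dataclass
class LMMFit:
    """Null-model variance components at the restricted-likelihood optimum."""

    sigma2_g: float
    sigma2_e: float
    delta: float                 # sigma2_e / sigma2_g
    reml_loglik: float
    eigenvalues: np.ndarray = field(repr=False)
    eigenvectors: np.ndarray = field(repr=False)

    @property
    def heritability(self) -> float:
        tot = self.sigma2_g + self.sigma2_e
        return self.sigma2_g / tot if tot > 0 else 0.0


@dataclass
class AssociationResult:
    """Per-SNP association table plus scan-level metadata.

    ``table`` columns: chrom, pos, id, maf, beta, se, stat, p,
    neglog10p, significant.
    """

    table: pd.DataFrame
    threshold: float      # Bonferroni -log10 threshold T
    m: int                # post-filter SNP count
    alpha: float


@dataclass
class HaplotypeGrouping:
    snp_ids: list[str]
    assignments: pd.Series          # accession_id -> haplotype label
    group_sizes: dict[str, int]
    minor_groups: list[str]
    statistic: float = math.nan
    p_value: float = math.nan
    group_means: dict[str, float] = field(default_factory=dict)


def maf(dosages: np.ndarray) -> float:
    """Folded minor-allele frequency of one SNP's diploid dosage vector."""
    d = np.asarray(dosages, dtype=float)
    d = d[np.isfinite(d)]
    if d.size == 0:
        raise ValueError("all-missing SNP")
    p = d.sum() / (2.0 * d.size)
    return float(min(p, 1.0 - p))


def maf_filter(panel: GenotypePanel, threshold: float = 0.05
               ) -> tuple[GenotypePanel, int]:
    """Retain SNPs with folded MAF strictly greater than ``threshold``.

    Returns the filtered panel and the retained count m (the Bonferroni
    denominator).  Marker order is preserved.
    """
    d = panel.dosages
    with np.errstate(invalid="ignore"):
        n_obs = np.sum(np.isfinite(d), axis=0)
        p = np.nansum(d, axis=0) / np.maximum(2.0 * n_obs, 1.0)
    folded = np.minimum(p, 1.0 - p)
    mask = (n_obs > 0) & (folded > threshold)
    sub = panel.subset_snps(mask)
    return sub, sub.n_snp


def impute_missing(panel: GenotypePanel) -> np.ndarray:
    """Complete dosage matrix with per-SNP mean imputation of missing."""
    d = panel.dosages.copy()
    missing = ~np.isfinite(d)
    if missing.any():
        n_obs = np.sum(~missing, axis=0)
        if np.any(n_obs == 0):
            raise ValueError("all-missing SNP cannot be imputed")
        col_mean = np.nansum(d, axis=0) / n_obs
        d[missing] = np.broadcast_to(col_mean, d.shape)[missing]
    return d


def kinship(panel: GenotypePanel, method: str = "vanraden") -> np.ndarray:
    """Genomic relationship matrix over accessions.

    ``vanraden`` (default): standardize each SNP by centering at 2*p and
    scaling by sqrt(2*p*(1-p)), then cross-product / SNP count — PSD by
    construction.  ``ibs``: mean allele-sharing proportion.
    Missing dosages are mean-imputed first.
    """
    if panel.n_snp < 2:
        raise ValueError("need >= 2 SNPs for a kinship estimate")
    X = impute_missing(panel)
    p = X.mean(axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    if not poly.any():
        raise ValueError("monomorphic-only panel")
    X = X[:, poly]
    p = p[poly]
    if method == "vanraden":
        Z = (X - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))
        K = (Z @ Z.T) / Z.shape[1]
    elif method == "ibs":
        # allele-sharing: 1 - |g_i - g_j| / 2 averaged over SNPs
        n = X.shape[0]
        K = np.empty((n, n))
        for i in range(n):
            K[i] = 1.0 - np.abs(X - X[i]).mean(axis=1) / 2.0
    else:
        raise ValueError(f"unknown kinship method {method!r}")
    return (K + K.T) / 2.0


def pca_structure(K: np.ndarray, n_pc: int) -> np.ndarray:
    """Top principal-component scores of a kinship matrix.

    Columns are unit-norm eigenvectors ordered by decreasing eigenvalue;
    each column's sign is fixed so its largest-magnitude loading is
    positive.
    """
    K = np.asarray(K, dtype=float)
    evals, evecs = np.linalg.eigh(K)
    if np.min(evals) < -1e-6 * max(1.0, np.max(np.abs(evals))):
        raise ValueError("matrix is not positive semi-definite")
    order = np.argsort(evals)[::-1]
    rank = int(np.sum(evals > 1e-10 * max(np.max(evals), 1.0)))
    if n_pc > rank:
        raise ValueError(f"n_pc={n_pc} exceeds rank {rank}")
    scores = evecs[:, order[:n_pc]]
    for j in range(n_pc):
        i = int(np.argmax(np.abs(scores[:, j])))
        if scores[i, j] < 0:
            scores[:, j] = -scores[:, j]
    return scores


def _reml_neg_loglik(log10_delta: float, lam: np.ndarray, Ut_y: np.ndarray,
                     Ut_X: np.ndarray) -> float:
    delta = 10.0 ** log10_delta
    n, q = Ut_X.shape
    w = 1.0 / (lam + delta)
    XtWX = Ut_X.T @ (w[:, None] * Ut_X)
    XtWy = Ut_X.T @ (w * Ut_y)
    b = np.linalg.solve(XtWX, XtWy)
    r = Ut_y - Ut_X @ b
    rss = float(np.sum(w * r * r))
    sign, logdet_XtWX = np.linalg.slogdet(XtWX)
    _, logdet_XtX = np.linalg.slogdet(Ut_X.T @ Ut_X)
    ll = -0.5 * ((n - q) * math.log(2.0 * math.pi * rss / (n - q))
                 + (n - q)
                 + float(np.sum(np.log(lam + delta)))
                 + logdet_XtWX - logdet_XtX)
    return -ll


def fit_null_lmm(y: np.ndarray, K: np.ndarray,
                 covariates: np.ndarray | None = None) -> LMMFit:
    """REML fit of the null mixed model via spectral decomposition.

    The variance ratio ``delta = sigma2_e / sigma2_g`` is profiled on a
    grid over ``log10(delta) in [-5, 5]`` and refined by bounded 1-D
    optimization around the best grid point; deterministic given inputs.
    """
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite phenotype values")
    n = y.size
    if np.ptp(y) < 1e-12:
        raise ValueError("constant phenotype: variance components degenerate")
    X = np.ones((n, 1)) if covariates is None else np.column_stack(
        [np.ones(n), np.asarray(covariates, dtype=float)])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient covariates")
    lam, U = np.linalg.eigh((np.asarray(K, dtype=float) +
                             np.asarray(K, dtype=float).T) / 2.0)
    lam = np.maximum(lam, 0.0)
    Ut_y = U.T @ y
    Ut_X = U.T @ X

    grid = np.linspace(-5.0, 5.0, 41)
    vals = [_reml_neg_loglik(g, lam, Ut_y, Ut_X) for g in grid]
    i = int(np.argmin(vals))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(
        _reml_neg_loglik, bounds=(lo, hi), args=(lam, Ut_y, Ut_X),
        method="bounded", options={"xatol": 1e-8})
    log10_delta = float(res.x)
    delta = 10.0 ** log10_delta

    q = X.shape[1]
    w = 1.0 / (lam + delta)
    b = np.linalg.solve(Ut_X.T @ (w[:, None] * Ut_X), Ut_X.T @ (w * Ut_y))
    r = Ut_y - Ut_X @ b
    sigma2_g = float(np.sum(w * r * r) / (n - q))
    sigma2_e = sigma2_g * delta
    return LMMFit(sigma2_g=sigma2_g, sigma2_e=sigma2_e, delta=delta,
                  reml_loglik=-float(res.fun), eigenvalues=lam,
                  eigenvectors=U)


def scan_snps(panel: GenotypePanel, y: np.ndarray, null_fit: LMMFit,
              covariates: np.ndarray | None = None,
              alpha: float = 0.05) -> AssociationResult:
    """EMMAX-style association scan over a MAF-filtered, imputed panel.

    Variance components are fixed from the null fit; each SNP gets a
    generalized-least-squares effect estimate and a two-sided t test
    with ``n - q - 1`` degrees of freedom (q = fixed covariates incl.
    intercept).  Deterministic given inputs.
    """
    y = np.asarray(y, dtype=float)
    n = panel.n_acc
    if y.size != n:
        raise ValueError("phenotype / panel dimension mismatch")
    G = impute_missing(panel)
    if np.any(G.std(axis=0) < 1e-12):
        raise ValueError("zero-variance SNP after imputation; MAF-filter first")
    X = np.ones((n, 1)) if covariates is None else np.column_stack(
        [np.ones(n), np.asarray(covariates, dtype=float)])
    q = X.shape[1]

    U, lam = null_fit.eigenvectors, null_fit.eigenvalues
    sw = np.sqrt(1.0 / (lam + null_fit.delta))
    yt = sw * (U.T @ y)
    Xt = sw[:, None] * (U.T @ X)
    Gt = sw[:, None] * (U.T @ G)

    # residualize y and every SNP against the fixed covariates
    Q, _ = np.linalg.qr(Xt)
    y_r = yt - Q @ (Q.T @ yt)
    G_r = Gt - Q @ (Q.T @ Gt)

    gg = np.sum(G_r * G_r, axis=0)
    gy = G_r.T @ y_r
    beta = gy / gg
    dof = n - q - 1
    rss = np.sum(y_r * y_r) - beta * gy
    sigma2 = np.maximum(rss, 0.0) / dof
    se = np.sqrt(sigma2 / gg)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = beta / se
    p = 2.0 * stats.t.sf(np.abs(tstat), dof)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    neglog10p = -np.log10(p)

    mafs = np.array([maf(panel.dosages[:, j]) for j in range(panel.n_snp)])
    T = bonferroni_threshold(alpha, panel.n_snp)
    table = pd.DataFrame({
        "chrom": panel.markers["chrom"].to_numpy(),
        "pos": panel.markers["pos"].to_numpy(),
        "id": panel.markers["id"].to_numpy(),
        "maf": mafs,
        "beta": beta,
        "se": se,
        "stat": tstat,
        "p": p,
        "neglog10p": neglog10p,
        "significant": neglog10p >= T,
    })
    return AssociationResult(table=table, threshold=T, m=panel.n_snp,
                             alpha=alpha)


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Bonferroni-corrected -log10(p) significance threshold.

    ``T = -log10(alpha / m)`` for m tests at family-wise level alpha.
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must be in (0, 1)")
    if m < 1:
        raise ValueError("m must be >= 1")
    return float(-math.log10(alpha / m))


def significant_hits(result: AssociationResult,
                     threshold: float | None = None) -> pd.DataFrame:
    """SNPs at or above the -log10(p) threshold, strongest first.

    Sorted by p ascending; ties broken by (chromosome, position).
    """
    T = result.threshold if threshold is None else threshold
    hits = result.table[result.table["neglog10p"] >= T]
    return hits.sort_values(["p", "chrom", "pos"],
                            kind="mergesort").reset_index(drop=True)


def haplotype_groups(panel: GenotypePanel, snp_ids: list[str],
                     min_size: int = 10) -> HaplotypeGrouping:
    """Group accessions by their exact allele combination at chosen SNPs.

    Accessions with any missing call at the selected SNPs are excluded.
    Groups smaller than ``min_size`` are reported but labeled minor.
    Labels are ``H1, H2, ...`` in decreasing group size.
    """
    ids = list(panel.markers["id"])
    try:
        idx = [ids.index(s) for s in snp_ids]
    except ValueError as err:
        raise KeyError(f"unknown SNP id in {snp_ids}") from err
    sub = panel.dosages[:, idx]
    complete = np.all(np.isfinite(sub), axis=1)
    keys = [tuple(int(v) for v in row) for row in sub[complete]]
    accs = np.array(panel.accession_ids)[complete]

    order = pd.Series(keys).value_counts()
    label_of = {key: f"H{i + 1}" for i, key in enumerate(order.index)}
    labels = [label_of[k] for k in keys]
    assignments = pd.Series(labels, index=accs, name="haplotype")
    sizes = {lab: int((assignments == lab).sum())
             for lab in sorted(set(labels), key=lambda s: int(s[1:]))}
    minor = [lab for lab, n in sizes.items() if n < min_size]
    return HaplotypeGrouping(snp_ids=list(snp_ids), assignments=assignments,
                             group_sizes=sizes, minor_groups=minor)


def compare_haplotypes(trait: pd.Series,
                       grouping: HaplotypeGrouping) -> HaplotypeGrouping:
    """Test a trait difference between the retained haplotype groups.

    Two groups: Welch's unequal-variance two-sample t test.  More than
    two: Kruskal-Wallis rank test.  Minor groups are excluded.  Returns
    the grouping with ``statistic``, ``p_value`` and ``group_means``
    filled in.
    """
    retained = [lab for lab in grouping.group_sizes
                if lab not in grouping.minor_groups]
    samples, means = [], {}
    for lab in retained:
        accs = grouping.assignments.index[grouping.assignments == lab]
        vals = trait.reindex(accs).dropna().to_numpy(dtype=float)
        if vals.size >= 2:
            samples.append(vals)
            means[lab] = float(vals.mean())
    if len(samples) < 2:
        raise ValueError("need >= 2 retained groups with >= 2 members each")
    if len(samples) == 2:
        if (np.ptp(samples[0]) < 1e-12 and np.ptp(samples[1]) < 1e-12
                and samples[0][0] == samples[1][0]):
            stat, p = 0.0, 1.0
        else:
            stat, p = stats.ttest_ind(samples[0], samples[1],
                                      equal_var=False)
    else:
        stat, p = stats.kruskal(*samples)
    grouping.statistic = float(stat)
    grouping.p_value = float(p)
    grouping.group_means = means
    return grouping
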