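"""Differential expression on NB counts: TMM normalization, moment
dispersion estimation with shrinkage, per-gene NB likelihood-ratio
tests, BH correction, DE filtering, Venn partitions, and cross-arm
log-fold-change comparisons.

The testing route is: TMM effective library sizes -> per-group
method-of-moments dispersions shrunk toward the common (median) value ->
per-gene negative-binomial GLM (log link, library-size offset, group
indicator) fitted by IRLS -> likelihood-ratio statistic against
chi-square(1) -> Benjamini-Hochberg FDR. DE calls use strict cutoffs
FDR < 0.001 and |log2FC| > 1.5 by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import rankdata

from .synthetic import CountMatrix

__all__ = [
    "GeneSet",
    "tmm_factors",
    "effective_libsizes",
    "log_cpm",
    "estimate_dispersions",
    "de_test",
    "bh_adjust",
    "filter_de",
    "venn_partition",
    "compare_logfc",
]


@dataclass(frozen=True)
class GeneSet:
    """A labelled set of gene ids with a regulation direction."""

    label: str
    genes: frozenset[str]
    direction: str = "up"  # "up" | "down" | "any"

    def __len__(self) -> int:
        return len(self.genes)


# ---------------------------------------------------------------------------
# TMM normalization
# ---------------------------------------------------------------------------

def _tmm_pair(obs, obs_n, ref, ref_n, trim_m: float, trim_a: float) -> float:
    """Scaling factor of one library against the reference: weighted
    trimmed mean of M-values, doubly trimmed by M and by A."""
    keep = (obs > 0) & (ref > 0)
    p_obs = obs[keep] / obs_n
    p_ref = ref[keep] / ref_n
    m = np.log2(p_obs / p_ref)
    a = 0.5 * np.log2(p_obs * p_ref)
    # inverse approximate (delta-method) binomial variances as weights
    w = (obs_n - obs[keep]) / (obs_n * obs[keep]) + (ref_n - ref[keep]) / (
        ref_n * ref[keep]
    )
    if m.size == 0 or np.max(np.abs(m)) < 1e-6:
        return 1.0
    n = m.size
    lo_m, hi_m = np.floor(n * trim_m) + 1, n - np.floor(n * trim_m)
    lo_a, hi_a = np.floor(n * trim_a) + 1, n - np.floor(n * trim_a)
    rm, ra = rankdata(m), rankdata(a)
    sel = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
    if not sel.any():
        return 1.0
    f = np.sum(m[sel] / w[sel]) / np.sum(1.0 / w[sel])
    return float(2.0**f)


def tmm_factors(
    counts: CountMatrix | pd.DataFrame, trim_m: float = 0.3, trim_a: float = 0.05
) -> pd.Series:
    """Trimmed-mean-of-M-values scaling factors, one per library.

    The reference library is the one whose depth-normalized 75th
    percentile is closest to the mean of that statistic. Factors are
    rescaled to geometric mean 1, so effective library size is
    ``depth * factor``.

    Raises
    ------
    ValueError
        If fewer than 2 samples, or any library has zero total count
        (the offending sample is named).
    """
    mat = counts.counts if isinstance(counts, CountMatrix) else counts
    y = mat.to_numpy(dtype=float)
    samples = list(mat.columns)
    if y.shape[1] < 2:
        raise ValueError("TMM needs at least 2 samples")
    depths = y.sum(axis=0)
    if (depths == 0).any():
        bad = samples[int(np.argmax(depths == 0))]
        raise ValueError(f"library '{bad}' has zero total count")
    q75 = np.quantile(y, 0.75, axis=0) / depths
    ref = int(np.argmin(np.abs(q75 - q75.mean())))
    factors = np.array(
        [
            1.0
            if s == ref
            else _tmm_pair(y[:, s], depths[s], y[:, ref], depths[ref], trim_m, trim_a)
            for s in range(y.shape[1])
        ]
    )
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=samples, name="tmm_factor")


def effective_libsizes(
    counts: CountMatrix | pd.DataFrame, factors: pd.Series
) -> pd.Series:
    mat = counts.counts if isinstance(counts, CountMatrix) else counts
    depths = mat.sum(axis=0).astype(float)
    return depths * factors.reindex(depths.index)


def log_cpm(
    counts: CountMatrix | pd.DataFrame,
    factors: pd.Series | None = None,
    prior_count: float = 2.0,
) -> pd.DataFrame:
    """log2 counts per million on TMM-effective library sizes:
    ``log2((count + prior) / (eff_libsize + 2 * prior) * 1e6)``.

    Finite for zero counts; invariant to jointly scaling counts and
    library size.
    """
    if prior_count < 0:
        raise ValueError("prior_count must be >= 0")
    mat = counts.counts if isinstance(counts, CountMatrix) else counts
    if factors is None:
        factors = tmm_factors(mat)
    eff = effective_libsizes(mat, factors).to_numpy()
    vals = np.log2(
        (mat.to_numpy(dtype=float) + prior_count) / (eff + 2.0 * prior_count)[None, :] * 1e6
    )
    return pd.DataFrame(vals, index=mat.index, columns=mat.columns)


# ---------------------------------------------------------------------------
# Dispersion estimation
# ---------------------------------------------------------------------------

def estimate_dispersions(
    counts: CountMatrix,
    factors: pd.Series | None = None,
    prior_weight: float = 10.0,
) -> pd.Series:
    """Per-gene NB dispersions by method of moments with shrinkage.

    Counts are rescaled to a common effective depth; within each
    (condition, timepoint) group the raw estimate is
    ``(var - mean) / mean^2``, pooled across groups with df weights.
    Each gene is then shrunk toward the common (median) dispersion with
    prior weight ``w``: ``phi_g = (w * phi_common + n_g * phi_hat_g) /
    (w + n_g)``, floored at 1e-6.
    """
    if factors is None:
        factors = tmm_factors(counts)
    eff = effective_libsizes(counts, factors)
    groups = counts.design.groupby(["condition", "timepoint"], observed=True)[
        "sample_id"
    ].apply(list)
    for key, members in groups.items():
        if len(members) < 2:
            raise ValueError(f"group {key} has a single replicate")
    scale = eff.mean() / eff
    y = counts.counts.to_numpy(dtype=float) * scale.to_numpy()[None, :]
    col_pos = {s: i for i, s in enumerate(counts.samples)}

    num = np.zeros(y.shape[0])
    den = np.zeros(y.shape[0])
    for members in groups:
        idx = [col_pos[s] for s in members]
        sub = y[:, idx]
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        ok = m > 0
        phi_grp = np.zeros_like(m)
        phi_grp[ok] = (v[ok] - m[ok]) / m[ok] ** 2
        df = len(idx) - 1
        num += np.where(ok, df * phi_grp, 0.0)
        den += np.where(ok, df, 0.0)
    phi_hat = np.where(den > 0, num / np.maximum(den, 1.0), 0.0)
    phi_hat = np.clip(phi_hat, 0.0, None)
    phi_common = float(np.median(phi_hat))
    n_g = len(counts.samples)
    phi = (prior_weight * phi_common + n_g * phi_hat) / (prior_weight + n_g)
    return pd.Series(np.maximum(phi, 1e-6), index=counts.genes, name="dispersion")


# ---------------------------------------------------------------------------
# NB GLM likelihood-ratio test
# ---------------------------------------------------------------------------

def _nb_loglik(y: np.ndarray, mu: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Row-wise NB log-likelihood; phi is per gene (column vector)."""
    r = 1.0 / phi
    p = r / (r + mu)
    return stats.nbinom.logpmf(y, r, p).sum(axis=1)


def _irls_nb(
    y: np.ndarray,
    x: np.ndarray,
    offset: np.ndarray,
    phi: np.ndarray,
    max_iter: int = 60,
    tol: float = 1e-8,
):
    """Vectorized IRLS for per-gene NB GLMs sharing a two-column design
    ``[1, x]`` (x may be all-zero for the intercept-only model).

    Returns (beta0, beta1, mu, converged) arrays over genes.
    """
    g, s = y.shape
    has_slope = np.any(x != 0)
    exp_off = np.exp(offset)
    base = np.log(np.maximum(y.sum(axis=1) / exp_off.sum(), 1e-8))
    b0 = base.copy()
    b1 = np.zeros(g)
    converged = np.zeros(g, dtype=bool)
    active = np.ones(g, dtype=bool)
    for _ in range(max_iter):
        eta = b0[:, None] + b1[:, None] * x[None, :] + offset[None, :]
        mu = np.clip(np.exp(eta), 1e-10, 1e12)
        w = mu / (1.0 + phi * mu)
        z = (eta - offset[None, :]) + (y - mu) / mu
        sw = w.sum(axis=1)
        r1 = (w * z).sum(axis=1)
        if has_slope:
            swx = (w * x[None, :]).sum(axis=1)
            swxx = (w * x[None, :] ** 2).sum(axis=1)
            r2 = (w * z * x[None, :]).sum(axis=1)
            det = sw * swxx - swx**2
            det = np.where(np.abs(det) < 1e-12, np.nan, det)
            nb0 = (swxx * r1 - swx * r2) / det
            nb1 = (sw * r2 - swx * r1) / det
        else:
            nb0 = r1 / np.maximum(sw, 1e-12)
            nb1 = b1
        nb0 = np.where(np.isfinite(nb0), nb0, b0)
        nb1 = np.where(np.isfinite(nb1), nb1, b1)
        step = np.maximum(np.abs(nb0 - b0), np.abs(nb1 - b1))
        newly = active & (step < tol)
        converged |= newly
        active &= ~newly
        b0, b1 = nb0, nb1
        if not active.any():
            break
    eta = b0[:, None] + b1[:, None] * x[None, :] + offset[None, :]
    mu = np.clip(np.exp(eta), 1e-10, 1e12)
    return b0, b1, mu, converged


def de_test(
    counts: CountMatrix,
    contrast: tuple[str, int],
    factors: pd.Series | None = None,
    dispersions: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-gene NB likelihood-ratio test of treated vs control at one
    timepoint.

    ``contrast = (treated_condition, timepoint)``; control samples are
    the 'control' condition at the same timepoint. The full model has a
    group indicator on the log scale with an effective-library-size
    offset; the statistic ``2 * (ll_full - ll_reduced)`` is referred to
    chi-square(1). Genes whose fit fails to converge are assigned p = 1
    (a warning counts them).

    Returns a DataFrame with columns gene_id, logFC (log2, treated vs
    control), pvalue, fdr, contrast.
    """
    treated_cond, timepoint = contrast
    design = counts.design
    sel = design["timepoint"] == int(timepoint)
    treated = design.loc[sel & (design["condition"] == treated_cond), "sample_id"]
    control = design.loc[sel & (design["condition"] == "control"), "sample_id"]
    if treated.empty or control.empty:
        raise ValueError(f"contrast {contrast!r} matches no (treated, control) samples")

    if factors is None:
        factors = tmm_factors(counts)
    if dispersions is None:
        dispersions = estimate_dispersions(counts, factors=factors)

    samples = list(control) + list(treated)
    y = counts.counts[samples].to_numpy(dtype=float)
    eff = effective_libsizes(counts, factors)[samples].to_numpy()
    offset = np.log(eff)
    x = np.array([0.0] * len(control) + [1.0] * len(treated))
    phi = dispersions.to_numpy()[:, None]

    b0_f, b1_f, mu_f, conv_f = _irls_nb(y, x, offset, phi)
    b0_r, _, mu_r, conv_r = _irls_nb(y, np.zeros_like(x), offset, phi)

    ll_full = _nb_loglik(y, mu_f, phi)
    ll_red = _nb_loglik(y, mu_r, phi)
    lrt = np.clip(2.0 * (ll_full - ll_red), 0.0, None)
    pvals = stats.chi2.sf(lrt, df=1)

    all_zero = y.sum(axis=1) == 0
    failed = ~(conv_f & conv_r) & ~all_zero
    pvals = np.where(all_zero | failed, 1.0, pvals)
    logfc = np.where(all_zero, 0.0, b1_f / np.log(2.0))
    if failed.any():
        warnings.warn(
            f"{int(failed.sum())} gene(s) did not converge; p set to 1", RuntimeWarning
        )
    return pd.DataFrame(
        {
            "gene_id": counts.genes,
            "logFC": logfc,
            "pvalue": pvals,
            "fdr": bh_adjust(pvals),
            "contrast": f"{treated_cond}_vs_control_{timepoint}h",
        }
    )


# ---------------------------------------------------------------------------
# Multiple testing, filtering, set comparisons
# ---------------------------------------------------------------------------

def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values with enforced monotonicity."""
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvalues must be one-dimensional")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def filter_de(
    table: pd.DataFrame, fdr_max: float = 0.001, lfc_min: float = 1.5
) -> tuple[GeneSet, GeneSet]:
    """Split a DE table into up/down gene sets with strict cutoffs
    ``fdr < fdr_max`` and ``logFC > lfc_min`` (resp. ``< -lfc_min``)."""
    if fdr_max <= 0 or lfc_min <= 0:
        raise ValueError("thresholds must be positive")
    sig = table["fdr"] < fdr_max
    label = str(table["contrast"].iloc[0]) if len(table) else "de"
    up = frozenset(table.loc[sig & (table["logFC"] > lfc_min), "gene_id"])
    down = frozenset(table.loc[sig & (table["logFC"] < -lfc_min), "gene_id"])
    return GeneSet(label, up, "up"), GeneSet(label, down, "down")


def venn_partition(a: GeneSet, b: GeneSet) -> tuple[frozenset, frozenset, frozenset]:
    """Disjoint partition (only_a, shared, only_b) of two same-direction
    gene sets."""
    if a.direction != b.direction:
        raise ValueError("gene sets have different directions")
    shared = a.genes & b.genes
    return a.genes - shared, shared, b.genes - shared


def compare_logfc(
    x, y, method: str = "t", paired: bool = True
) -> tuple[float, float]:
    """Two-sided comparison of matched (or independent) logFC vectors.

    ``method='t'`` is a paired t-test when ``paired`` else Welch;
    ``method='wilcoxon'`` is the signed-rank test when ``paired`` else
    the rank-sum (Mann-Whitney, exact for small untied samples).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if min(x.size, y.size) < 3:
        raise ValueError("need at least 3 observations per vector")
    if paired and x.size != y.size:
        raise ValueError("paired comparison needs equal-length vectors")
    if method == "t":
        if paired:
            if np.allclose(x, y):
                return 0.0, 1.0
            res = stats.ttest_rel(x, y)
        else:
            res = stats.ttest_ind(x, y, equal_var=False)
    elif method == "wilcoxon":
        if paired:
            if np.all(x - y == 0):
                raise ValueError("signed-rank test undefined: all paired differences zero")
            res = stats.wilcoxon(x, y)
        else:
            res = stats.mannwhitneyu(x, y, alternative="two-sided")
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(res.statistic), float(res.pvalue)
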