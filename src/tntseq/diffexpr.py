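"""Negative-binomial Wald test for two-condition differential expression.

A deliberately small, transparent reimplementation of the standard
count-based DE recipe: median-of-ratios size factors, per-gene NB model
with mean/dispersion parameterisation (Var = mu + alpha * mu^2),
method-of-moments dispersion shrunk toward an ``a0 + a1/mu`` trend, a
per-condition mean MLE, and a Wald test on the log2 fold change with
a two-sided normal tail. No independent filtering, no outlier handling,
no p-value adjustment: significance calls use raw p-values, matching
the downstream thresholds (p < 0.05, |log2FC| > 1).

Fold-change direction: ``log2_fold_change > 0`` means higher expression in
condition B (the second argument) than in condition A.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .quantify import counts_to_tpm

log = logging.getLogger(__name__)

LN2 = float(np.log(2.0))

#: clipping range for dispersion estimates
MIN_DISPERSION = 1e-8
MAX_DISPERSION = 10.0

#: weight of the trend in log-dispersion shrinkage is
#: PRIOR_DF / (PRIOR_DF + residual df)
PRIOR_DF = 6.0

RESULT_COLUMNS = ["base_mean", "log2_fold_change", "lfc_se", "stat", "p_value"]


def estimate_size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors, normalised to geometric mean 1.

    Each sample's factor is the median over genes of the ratio of its count
    to the gene's geometric mean across samples; only genes with nonzero
    counts in every sample contribute.
    """
    vals = counts.values.astype(float)
    if vals.shape[1] == 1:
        return pd.Series([1.0], index=counts.columns, name="size_factor")
    allpos = (vals > 0).all(axis=1)
    if not allpos.any():
        raise ValueError("no gene with nonzero counts in all samples; "
                         "size factors undefined")
    logv = np.log(vals[allpos])
    logref = logv.mean(axis=1, keepdims=True)
    logsf = np.median(logv - logref, axis=0)
    logsf -= logsf.mean()  # geometric mean of factors = 1
    return pd.Series(np.exp(logsf), index=counts.columns, name="size_factor")


def _fit_dispersion_trend(base_mean: np.ndarray, alpha_mom: np.ndarray) -> tuple[float, float]:
    """Fit alpha(mu) = a0 + a1/mu to positive moment estimates.

    Two-pass least squares: an initial fit, then a refit excluding genes
    whose estimate deviates from the trend by more than a fixed ratio
    (guards against a handful of outlier genes dominating the fit).
    """
    use = alpha_mom > MIN_DISPERSION * 10
    if use.sum() < 2:
        med = float(np.median(alpha_mom[alpha_mom > 0])) if (alpha_mom > 0).any() else 0.01
        return max(med, MIN_DISPERSION), 0.0
    x = 1.0 / base_mean[use]
    y = alpha_mom[use]
    for _ in range(2):
        A = np.column_stack([np.ones_like(x), x])
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        a0, a1 = float(coef[0]), float(coef[1])
        fit = np.maximum(a0 + a1 * x, MIN_DISPERSION)
        ratio = y / fit
        keep = (ratio > 1e-4) & (ratio < 15.0)
        if keep.all() or keep.sum() < 2:
            break
        x, y = x[keep], y[keep]
    return max(a0, MIN_DISPERSION), max(a1, 0.0)


def estimate_dispersions(norm_counts: np.ndarray, n_a: int,
                         shrink: bool = True) -> np.ndarray:
    """Per-gene NB dispersions from normalised counts (conditions pooled).

    Method of moments within each condition, then (optionally) shrunk
    toward the fitted mean-dispersion trend with trend weight
    ``PRIOR_DF / (PRIOR_DF + residual df)``. Shrinkage combines the two on
    the natural scale: the moment estimator is noisy but close to unbiased,
    and averaging on a log scale would systematically pull dispersions down
    (Jensen) and inflate Wald statistics. Genes whose moment estimate is
    non-positive (under-dispersed) take the trend value directly.
    """
    n = norm_counts.shape[1]
    groups = [norm_counts[:, :n_a], norm_counts[:, n_a:]]
    mu = norm_counts.mean(axis=1)
    ss = np.zeros(norm_counts.shape[0])
    df = 0
    for g in groups:
        if g.shape[1] >= 2:
            ss += ((g - g.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
            df += g.shape[1] - 1
    if df == 0:
        # single replicate per condition: pool both conditions as pseudo-replicates
        log.warning("no within-condition replication; pooling conditions for "
                    "dispersion estimation")
        ss = ((norm_counts - mu[:, None]) ** 2).sum(axis=1)
        df = n - 1
    s2 = ss / df
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha_mom = (s2 - mu) / mu**2
    alpha_mom = np.where(np.isfinite(alpha_mom), alpha_mom, 0.0)
    a0, a1 = _fit_dispersion_trend(mu, np.clip(alpha_mom, 0, MAX_DISPERSION))
    alpha_trend = np.clip(a0 + a1 / np.maximum(mu, 1e-8), MIN_DISPERSION, MAX_DISPERSION)
    if not shrink:
        return np.clip(np.where(alpha_mom > 0, alpha_mom, alpha_trend),
                       MIN_DISPERSION, MAX_DISPERSION)
    w = PRIOR_DF / (PRIOR_DF + df)
    pos = alpha_mom > MIN_DISPERSION
    alpha = np.where(
        pos,
        w * alpha_trend + (1 - w) * np.clip(alpha_mom, MIN_DISPERSION, None),
        alpha_trend,
    )
    return np.clip(alpha, MIN_DISPERSION, MAX_DISPERSION)


def _nb_mean_mle(k: np.ndarray, s: np.ndarray, alpha: float) -> float:
    """MLE of the NB mean mu with sample means s_j * mu and known dispersion.

    Newton iterations on the score
        l'(mu) = sum_j [ k_j/mu - (k_j + 1/alpha) * alpha s_j / (1 + alpha s_j mu) ].
    For alpha -> 0 this reduces to the Poisson solution sum(k)/sum(s).
    """
    if k.sum() == 0:
        return 0.0
    mu = max(float(np.mean(k / s)), 1e-8)
    if alpha < 1e-12:
        return float(k.sum() / s.sum())
    for _ in range(50):
        denom = 1.0 + alpha * s * mu
        score = np.sum(k / mu - (k + 1.0 / alpha) * alpha * s / denom)
        curv = np.sum(-k / mu**2 + (k + 1.0 / alpha) * (alpha * s) ** 2 / denom**2)
        if curv >= 0:
            break
        step = score / curv
        new = mu - step
        if new <= 0:
            new = mu / 2.0
        if abs(new - mu) < 1e-12 * max(mu, 1.0):
            mu = new
            break
        mu = new
    return float(mu)


def _observed_information(k: np.ndarray, s: np.ndarray, alpha: float, mu: float) -> float:
    """Observed Fisher information for mu at the MLE (negative log-lik curvature)."""
    denom = 1.0 + alpha * s * mu
    return float(np.sum(k / mu**2 - (k + 1.0 / alpha) * (alpha * s) ** 2 / denom**2))


def _expected_information(s: np.ndarray, alpha: float, mu: float) -> float:
    return float(np.sum(s / (mu * (1.0 + alpha * s * mu))))


def nb_wald_test(counts_a: pd.DataFrame, counts_b: pd.DataFrame,
                 annotation: pd.DataFrame | None = None,
                 *,
                 min_tpm: float = 1.0,
                 dispersion: float | np.ndarray | None = None,
                 shrink: bool = True,
                 size_factors: pd.Series | None = None,
                 zero_mean_floor: float = 0.5) -> pd.DataFrame:
    """Two-condition NB Wald test; log2FC is condition B over condition A.

    Parameters
    ----------
    counts_a, counts_b
        Raw counts for the samples of each condition (same gene index).
    annotation
        If given, genes are prefiltered to mean TPM > ``min_tpm`` across all
        samples before testing; without annotation no TPM prefilter applies.
    dispersion
        Known per-gene dispersion(s); skips estimation and shrinkage
        (used for cross-checks against a direct likelihood fit).
    shrink
        Shrink moment dispersions toward the mean-dispersion trend.
    size_factors
        Override the median-of-ratios size factors.
    zero_mean_floor
        Pseudo-mean used in place of a zero condition mean when forming the
        fold change and its standard error.

    Returns
    -------
    DataFrame indexed by gene_id with columns base_mean, log2_fold_change,
    lfc_se, stat, p_value.
    """
    if not counts_a.index.equals(counts_b.index):
        raise ValueError("condition matrices must share an identical gene index")
    n_a, n_b = counts_a.shape[1], counts_b.shape[1]
    if n_a < 1 or n_b < 1:
        raise ValueError("each condition needs at least one sample")
    if min(n_a, n_b) < 2:
        log.warning("fewer than 2 replicates in a condition; dispersion will be pooled")
    counts = pd.concat([counts_a, counts_b], axis=1)

    nonzero = counts.sum(axis=1) > 0
    n_dropped = int((~nonzero).sum())
    if n_dropped:
        log.info("dropping %d all-zero gene row(s)", n_dropped)
    counts = counts.loc[nonzero]

    if annotation is not None:
        tpm = counts_to_tpm(counts, annotation)
        keep = tpm.mean(axis=1) > min_tpm
        counts = counts.loc[keep]

    if counts.shape[0] == 0:
        return pd.DataFrame(columns=RESULT_COLUMNS)

    if size_factors is None:
        sf = estimate_size_factors(counts).values
    else:
        sf = np.asarray(size_factors, dtype=float)
        if sf.shape[0] != n_a + n_b:
            raise ValueError("size_factors length must equal total sample count")

    vals = counts.values.astype(float)
    norm = vals / sf
    base_mean = norm.mean(axis=1)

    if dispersion is None:
        alpha = estimate_dispersions(norm, n_a, shrink=shrink)
    else:
        alpha = np.broadcast_to(np.asarray(dispersion, dtype=float),
                                (vals.shape[0],)).copy()
        alpha = np.clip(alpha, MIN_DISPERSION, None)

    s_a, s_b = sf[:n_a], sf[n_a:]
    k_a, k_b = vals[:, :n_a], vals[:, n_a:]

    lfc = np.empty(vals.shape[0])
    se = np.empty(vals.shape[0])
    for i in range(vals.shape[0]):
        mu_a = _nb_mean_mle(k_a[i], s_a, alpha[i])
        mu_b = _nb_mean_mle(k_b[i], s_b, alpha[i])
        var = 0.0
        for mu, k, s in ((mu_a, k_a[i], s_a), (mu_b, k_b[i], s_b)):
            if mu <= 0:
                mu_eff = zero_mean_floor
                info = _expected_information(s, alpha[i], mu_eff)
            else:
                mu_eff = mu
                info = _observed_information(k, s, alpha[i], mu)
                if info <= 0:
                    info = _expected_information(s, alpha[i], mu)
            var += 1.0 / (info * (mu_eff * LN2) ** 2)
        mu_a_eff = mu_a if mu_a > 0 else zero_mean_floor
        mu_b_eff = mu_b if mu_b > 0 else zero_mean_floor
        lfc[i] = np.log2(mu_b_eff / mu_a_eff)
        se[i] = np.sqrt(var)

    stat = lfc / se
    p = 2.0 * stats.norm.sf(np.abs(stat))
    p = np.minimum(p, 1.0)
    return pd.DataFrame(
        {
            "base_mean": base_mean,
            "log2_fold_change": lfc,
            "lfc_se": se,
            "stat": stat,
            "p_value": p,
        },
        index=counts.index,
    )


def call_degs(results: pd.DataFrame, p_threshold: float = 0.05,
              lfc_threshold: float = 1.0) -> tuple[set[str], set[str]]:
    """Up/down DEG sets at strict thresholds (p < t and |log2FC| > l)."""
    if p_threshold <= 0 or lfc_threshold <= 0:
        raise ValueError("thresholds must be > 0")
    sig = results["p_value"] < p_threshold
    up = set(results.index[sig & (results["log2_fold_change"] > lfc_threshold)])
    down = set(results.index[sig & (results["log2_fold_change"] < -lfc_threshold)])
    return up, down
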