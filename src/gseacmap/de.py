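"""Differential expression: TMM scaling, log-CPM, moderated t, BH, DEG filter.

The chain mirrors the standard count-based workflow for a two-group design:
trimmed-mean-of-M-values (TMM) factors put samples on a common scale,
expression is transformed to log2 counts-per-million with a small offset,
a per-gene two-group linear fit yields log fold changes and residual
variances, and an empirical-Bayes step shrinks the variances toward a
common prior before forming moderated t-statistics. Multiple testing is
controlled with the Benjamini–Hochberg step-up procedure, and genes are
called differentially expressed at fold change > ``fc_threshold`` (strict,
on |log2FC|) and BH FDR < ``de_fdr``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .config import PipelineConfig
from .containers import CountMatrix, DeTable, NormalizedMatrix
from .errors import ValidationError

_TRIM_M = 0.30  # two-sided trim fraction on M-values (log-ratios)
_TRIM_A = 0.05  # two-sided trim fraction on A-values (abundance)
_MIN_USABLE = 10


# ---------------------------------------------------------------------------
# TMM normalization
# ---------------------------------------------------------------------------

def _tmm_pair(obs: np.ndarray, ref: np.ndarray, n_obs: float, n_ref: float) -> float | None:
    """Weighted trimmed mean of M-values of one sample against the reference.

    Returns the log2 factor, or None when fewer than ``_MIN_USABLE`` genes
    have nonzero counts in both samples.
    """
    ok = (obs > 0) & (ref > 0)
    if ok.sum() < _MIN_USABLE:
        return None
    o = obs[ok].astype(float)
    r = ref[ok].astype(float)
    m = np.log2((o / n_obs) / (r / n_ref))
    a = 0.5 * np.log2((o / n_obs) * (r / n_ref))
    # inverse asymptotic (delta-method) variance of M
    w = 1.0 / (1.0 / o - 1.0 / n_obs + 1.0 / r - 1.0 / n_ref)
    n = len(m)
    lo_m = int(np.floor(n * _TRIM_M)) + 1
    hi_m = n + 1 - lo_m
    lo_a = int(np.floor(n * _TRIM_A)) + 1
    hi_a = n + 1 - lo_a
    rank_m = stats.rankdata(m, method="ordinal")
    rank_a = stats.rankdata(a, method="ordinal")
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if keep.sum() == 0 or not np.isfinite(w[keep]).all():
        return None
    f = float(np.sum(w[keep] * m[keep]) / np.sum(w[keep]))
    return f


def tmm_factors(cm: CountMatrix, ref_sample: str | None = None) -> tuple[np.ndarray, list[str]]:
    """TMM scaling factors per sample, rescaled to geometric mean 1.

    The reference sample defaults to the one whose upper-quartile CPM is
    closest to the mean upper-quartile. Samples with fewer than 10 genes
    usable after trimming fall back to factor 1 with a warning record.

    Returns
    -------
    (factors, warnings) : factors aligned with ``cm.samples``; warnings is a
    list of human-readable fallback notices.
    """
    cm.validate_design()
    lib = cm.library_sizes.astype(float)
    cpm = cm.counts / lib * 1e6
    uq = np.percentile(cpm, 75, axis=0)
    if ref_sample is None:
        ref_idx = int(np.argmin(np.abs(uq - uq.mean())))
    else:
        if ref_sample not in cm.samples:
            raise ValidationError(f"reference sample {ref_sample!r} not in matrix")
        ref_idx = cm.samples.index(ref_sample)
    notes: list[str] = []
    log_factors = np.zeros(len(cm.samples))
    ref = cm.counts[:, ref_idx]
    for j, s in enumerate(cm.samples):
        if j == ref_idx:
            continue
        f = _tmm_pair(cm.counts[:, j], ref, lib[j], lib[ref_idx])
        if f is None:
            notes.append(f"sample {s!r}: < {_MIN_USABLE} usable genes, factor set to 1")
            log_factors[j] = 0.0
        else:
            log_factors[j] = f
    factors = 2.0 ** log_factors
    factors /= np.exp(np.mean(np.log(factors)))  # geometric mean 1
    return factors, notes


# ---------------------------------------------------------------------------
# log-CPM (voom-style offsets, optional precision weights)
# ---------------------------------------------------------------------------

def log_cpm(cm: CountMatrix, factors: np.ndarray, weights: bool = False,
            lowess_span: float = 0.5) -> NormalizedMatrix:
    """Transform counts to log2-CPM using TMM effective library sizes.

    ``x = log2((c + 0.5) / (L + 1) * 1e6)`` with ``L = column_sum * factor``.
    With ``weights=True`` a mean–variance trend (lowess of sqrt residual sd
    against average log2 count) is fitted from an ordinary two-group fit and
    per-observation precision weights ``w = trend(fitted log-count)^-4`` are
    attached; otherwise all weights are implicitly 1.
    """
    factors = np.asarray(factors, dtype=float)
    if factors.shape != (len(cm.samples),):
        raise ValidationError("one TMM factor per sample required")
    eff = cm.library_sizes * factors
    x = np.log2((cm.counts + 0.5) / (eff + 1.0) * 1e6)
    w = None
    if weights:
        w = _voom_weights(cm, x, eff, lowess_span)
    return NormalizedMatrix(list(cm.genes), list(cm.samples), dict(cm.conditions),
                            x, factors, eff, w)


def _voom_weights(cm: CountMatrix, x: np.ndarray, eff: np.ndarray,
                  span: float) -> np.ndarray:
    """Precision weights from a lowess mean–variance trend (voom-style)."""
    from statsmodels.nonparametric.smoothers_lowess import lowess

    ctrl, trt = cm.group_indices()
    fitted = x.copy()
    fitted[:, ctrl] = x[:, ctrl].mean(axis=1, keepdims=True)
    fitted[:, trt] = x[:, trt].mean(axis=1, keepdims=True)
    resid = x - fitted
    df = x.shape[1] - 2
    sd = np.sqrt((resid ** 2).sum(axis=1) / df)
    # average log2 count per gene (log-CPM shifted back to the count scale)
    mean_logcount = x.mean(axis=1) + np.mean(np.log2(eff + 1.0)) - np.log2(1e6)
    trend = lowess(np.sqrt(sd), mean_logcount, frac=span, return_sorted=True)
    tx, ty = trend[:, 0], np.maximum(trend[:, 1], 1e-4)
    # per-observation fitted log-count: fitted log-CPM + sample-specific offset
    offsets = np.log2(eff + 1.0) - np.log2(1e6)
    obs_logcount = fitted + offsets[None, :]
    pred = np.interp(obs_logcount, tx, ty)
    return pred ** -4.0


# ---------------------------------------------------------------------------
# empirical-Bayes moderated t
# ---------------------------------------------------------------------------

def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration (|step| < 1e-8)."""
    if y <= 0:
        raise ValidationError("trigamma inverse needs y > 0")
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(100):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-8:
            break
    return float(x)


@dataclass
class _FDistFit:
    d0: float
    s0_2: float


def _fit_f_dist(s2: np.ndarray, df: float) -> _FDistFit:
    """Estimate prior df d0 and prior variance s0^2 from sample variances.

    Moment matching on log s2: under the hierarchical model
    s2_g | sigma_g^2 ~ sigma_g^2 chi^2_df / df with sigma_g^2 drawn from a
    scaled inverse chi-square prior (d0, s0^2), the excess variance of
    e_g = log s2_g - digamma(df/2) + log(df/2) over trigamma(df/2) equals
    trigamma(d0/2); the prior variance follows from the mean of e_g.
    """
    ok = s2 > 0
    if not ok.any():
        raise ValidationError("all residual variances are zero")
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = float(np.mean(e))
    n = len(e)
    if n < 2:
        return _FDistFit(np.inf, float(np.exp(e_mean)))
    e_var = float(np.var(e, ddof=1)) - float(special.polygamma(1, df / 2.0))
    if e_var <= 0:
        # no excess spread: variances consistent with a single common value
        return _FDistFit(np.inf, float(np.exp(e_mean)))
    d0 = 2.0 * _trigamma_inverse(e_var)
    s0_2 = float(np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return _FDistFit(d0, s0_2)


def squeeze_variance(s2: np.ndarray, df: float, d0: float, s0_2: float) -> np.ndarray:
    """Posterior variance ``(d0*s0_2 + df*s2) / (d0 + df)``; s0_2 when d0 is inf."""
    s2 = np.asarray(s2, dtype=float)
    if np.isinf(d0):
        return np.full_like(s2, s0_2)
    return (d0 * s0_2 + df * s2) / (d0 + df)


def moderated_t(norm: NormalizedMatrix) -> DeTable:
    """Two-group moderated t-statistics on log2-CPM values.

    Per gene, the ordinary (optionally precision-weighted) two-group fit
    gives logFC (treated − control) and residual variance s2 with
    df = n − 2. Empirical-Bayes hyperparameters (d0, s0²) are estimated by
    matching the mean and variance of log s2 to a scaled F distribution via
    trigamma inversion; the posterior variance
    ``s~² = (d0·s0² + df·s2) / (d0 + df)`` replaces s2 in the t-statistic,
    which is referred to a t distribution with d0 + df degrees of freedom.
    """
    ctrl, trt = norm.group_indices()
    n1, n2 = len(ctrl), len(trt)
    if n1 < 2 or n2 < 2:
        raise ValidationError("need >= 2 samples per condition")
    x = norm.logcpm
    df_resid = n1 + n2 - 2

    if norm.weights is None:
        mean_c = x[:, ctrl].mean(axis=1)
        mean_t = x[:, trt].mean(axis=1)
        rss = ((x[:, ctrl] - mean_c[:, None]) ** 2).sum(axis=1) + \
              ((x[:, trt] - mean_t[:, None]) ** 2).sum(axis=1)
        s2 = rss / df_resid
        var_coef = 1.0 / n1 + 1.0 / n2
        var_coef = np.full(x.shape[0], var_coef)
    else:
        w = norm.weights
        wc, wt = w[:, ctrl], w[:, trt]
        sum_wc, sum_wt = wc.sum(axis=1), wt.sum(axis=1)
        mean_c = (wc * x[:, ctrl]).sum(axis=1) / sum_wc
        mean_t = (wt * x[:, trt]).sum(axis=1) / sum_wt
        rss = (wc * (x[:, ctrl] - mean_c[:, None]) ** 2).sum(axis=1) + \
              (wt * (x[:, trt] - mean_t[:, None]) ** 2).sum(axis=1)
        s2 = rss / df_resid
        var_coef = 1.0 / sum_wc + 1.0 / sum_wt

    logfc = mean_t - mean_c
    avg = x.mean(axis=1)

    if len(norm.genes) == 1:
        warnings.warn("single gene: prior df set to infinity (pure pooling)")
        fit = _FDistFit(np.inf, float(s2[0]) if s2[0] > 0 else 1.0)
    else:
        fit = _fit_f_dist(s2, df_resid)

    s2_post = squeeze_variance(s2, df_resid, fit.d0, fit.s0_2)
    t = logfc / np.sqrt(s2_post * var_coef)
    if np.isinf(fit.d0):
        p = 2.0 * stats.norm.sf(np.abs(t))
        df_col = np.full_like(s2, np.inf)
    else:
        df_total = fit.d0 + df_resid
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
        df_col = np.full_like(s2, df_total)

    table = pd.DataFrame(
        {
            "logFC": logfc,
            "avg_expr": avg,
            "s2": s2,
            "t": t,
            "df_total": df_col,
            "p": p,
            "fdr": bh_adjust(p),
        },
        index=pd.Index(norm.genes, name="gene"),
    )
    return DeTable(table, float(fit.d0), float(fit.s0_2))


# ---------------------------------------------------------------------------
# Benjamini–Hochberg
# ---------------------------------------------------------------------------

def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, mapped back to input order.

    ``q_(i) = min_{j >= i} m * p_(j) / j`` on the sorted p-values, clipped
    at 1.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValidationError("p must be one-dimensional")
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValidationError("p-values must be finite and within [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


# ---------------------------------------------------------------------------
# DEG filter
# ---------------------------------------------------------------------------

def filter_degs(de: DeTable, config: PipelineConfig) -> DeTable:
    """Assign up/down/ns status using strict |log2FC| > log2(fc_threshold)
    and fdr < de_fdr; returns a new DeTable with the status column set."""
    table = de.table.copy()
    lfc_cut = np.log2(config.fc_threshold)
    sig = table["fdr"] < config.de_fdr
    up = sig & (table["logFC"] > lfc_cut)
    down = sig & (table["logFC"] < -lfc_cut)
    status = np.where(up, "up", np.where(down, "down", "ns"))
    table["status"] = status
    return DeTable(table, de.d0, de.s0_2)


def run_de(cm: CountMatrix, config: PipelineConfig) -> DeTable:
    """Counts → filtered DE table in one call (TMM → log-CPM → EB t → BH → filter)."""
    factors, _ = tmm_factors(cm)
    norm = log_cpm(cm, factors, weights=config.use_voom_weights)
    de = moderated_t(norm)
    return filter_degs(de, config)
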