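"""Uniform moderated differential engine for counts and log-scale tables.

One pipeline serves OTU/genus count tables, inferred KO tables and host
expression matrices: count tables go through a voom-style transform
(log2-cpm plus per-observation precision weights read off an empirical
mean-variance trend), log2 tables use unit weights; each feature is then fit
by (weighted) least squares on group means, variances are squeezed toward a
pooled prior by empirical Bayes, and features are called differential by the
combined gate |log2FC| >= 1 and raw p <= 0.05 (fold change >= 2, uncorrected
p; a Benjamini-Hochberg column is emitted for information only).

The moderated t uses a scaled inverse chi-square prior on the per-feature
residual variances; its hyperparameters (prior df d0, prior variance s0^2)
are estimated by matching moments of log s^2 through digamma/trigamma
identities, with d0 = infinity when the observed spread of log s^2 does not
exceed what equal true variances would produce.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.nonparametric.smoothers_lowess import lowess as sm_lowess
from statsmodels.stats.multitest import multipletests

from .io_formats import Design, FeatureTable, ValidationError

logger = logging.getLogger("komix.diff")

#: s_g^2 below this is floored to the 1st percentile of positive variances.
VARIANCE_FLOOR = 1e-12
#: Floor on the lowess sqrt-residual-SD trend so weights stay finite.
TREND_FLOOR = 1e-3
LOWESS_SPAN = 0.5
LOWESS_ITER = 3

RESULT_COLUMNS = [
    "feature", "contrast", "log2fc", "se", "ci_low", "ci_high",
    "t_mod", "df_total", "p_raw", "fdr", "direction",
]


@dataclass
class VoomFit:
    """Log2-cpm matrix, per-observation precision weights and the trend."""

    logcpm: FeatureTable        # scale=log2
    weights: pd.DataFrame       # same shape, finite and > 0
    trend_x: np.ndarray         # fitted mean log2-count grid (sorted)
    trend_y: np.ndarray         # sqrt residual SD at those points

    def trend(self, x: np.ndarray) -> np.ndarray:
        """Piecewise-linear trend, clamped to boundary values outside range."""
        return np.interp(x, self.trend_x, self.trend_y)


@dataclass
class DifferentialResult:
    """Per-feature, per-contrast moderated statistics and direction calls."""

    table: pd.DataFrame
    lfc_threshold: float = 1.0
    p_threshold: float = 0.05

    def for_contrast(self, contrast: tuple[str, str]) -> pd.DataFrame:
        label = contrast_label(contrast)
        return self.table[self.table.contrast == label]

    def contrasts(self) -> list[str]:
        return list(dict.fromkeys(self.table.contrast))


def contrast_label(contrast: tuple[str, str]) -> str:
    return f"{contrast[0]}-{contrast[1]}"


def _group_index(design: Design, sample_ids) -> tuple[list[str], np.ndarray]:
    """Ordered group labels and per-sample group indices for given samples."""
    missing = [s for s in sample_ids if s not in design.groups]
    if missing:
        raise ValidationError(f"samples not in design: {missing[:5]}")
    labels = list(dict.fromkeys(design.groups[s] for s in sample_ids))
    idx = np.array([labels.index(design.groups[s]) for s in sample_ids])
    return labels, idx


def voom_transform(counts: FeatureTable, design: Design) -> VoomFit:
    """Counts -> log2-cpm with precision weights from the mean-variance trend.

    Steps: y = log2((c + 0.5)/(L + 1) * 1e6) with L the library size;
    a group-means model is fit to y; LOWESS of sqrt(residual SD) on average
    log2 count gives the trend; each observation's fitted log2 count is mapped
    through the trend and weighted by trend(.)^-4.
    """
    if counts.scale != "counts":
        raise ValidationError("voom_transform expects a counts-scale table")
    sample_ids = [s for s in design.sample_ids if s in counts.values.columns]
    missing = set(design.sample_ids) - set(sample_ids)
    if missing:
        raise ValidationError(f"design samples absent from table: {sorted(missing)[:5]}")
    c = counts.values[sample_ids].to_numpy()
    n_feat, n_samp = c.shape
    if n_feat < 10:
        logger.warning("voom trend fitted on only %d features", n_feat)
    lib = c.sum(axis=0)
    zero_lib = [sample_ids[j] for j in np.nonzero(lib == 0)[0]]
    if zero_lib:
        raise ValidationError(f"samples with zero library size: {zero_lib}")

    y = np.log2((c + 0.5) / (lib + 1.0) * 1e6)

    labels, gidx = _group_index(design, sample_ids)
    n_groups = len(labels)
    if n_samp - n_groups < 1:
        raise ValidationError("no residual degrees of freedom for the voom trend")
    # group-means fit
    fitted = np.empty_like(y)
    for g in range(n_groups):
        cols = gidx == g
        fitted[:, cols] = y[:, cols].mean(axis=1, keepdims=True)
    resid = y - fitted
    sigma = np.sqrt((resid**2).sum(axis=1) / (n_samp - n_groups))

    # mean log2 count per feature (log2-cpm mean shifted back to count scale)
    sx = y.mean(axis=1) + np.mean(np.log2(lib + 1.0)) - np.log2(1e6)
    sy = np.sqrt(sigma)

    smoothed = sm_lowess(sy, sx, frac=LOWESS_SPAN, it=LOWESS_ITER,
                         return_sorted=True)
    trend_x = smoothed[:, 0]
    trend_y = np.maximum(smoothed[:, 1], TREND_FLOOR)

    fitted_logcount = fitted + (np.log2(lib + 1.0) - np.log2(1e6))[None, :]
    w = np.interp(fitted_logcount, trend_x, trend_y) ** (-4.0)

    logcpm = FeatureTable(
        values=pd.DataFrame(y, index=counts.values.index, columns=sample_ids),
        scale="log2",
        feature_meta=counts.feature_meta,
    )
    weights = pd.DataFrame(w, index=counts.values.index, columns=sample_ids)
    return VoomFit(logcpm=logcpm, weights=weights,
                   trend_x=trend_x, trend_y=trend_y)


def trigamma_inverse(x: float, tol: float = 1e-10, max_iter: int = 50) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton's method."""
    if x <= 0:
        return np.inf
    if x < 1e-6:
        return 1.0 / x
    y = 1.0 / np.sqrt(x) if x > 10 else 0.5 + 1.0 / x
    for _ in range(max_iter):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) / y < tol:
            break
    return float(y)


def estimate_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match a scaled inverse chi-square prior to observed variances.

    Works on z = log s^2, whose mean and variance under the model involve
    digamma/trigamma of the degrees of freedom.  Returns (d0, s0_squared);
    d0 = inf when the spread of z is no larger than expected under equal
    true variances.
    """
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1) - special.polygamma(1, df / 2.0)
    if evar > 0:
        d0 = 2.0 * trigamma_inverse(evar)
        s0_sq = np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
    else:
        d0 = np.inf
        s0_sq = np.exp(emean)
    return float(d0), float(s0_sq)


def _apply_variance_floor(s2: np.ndarray) -> np.ndarray:
    s2 = s2.copy()
    low = s2 < VARIANCE_FLOOR
    if low.any():
        positive = s2[~low]
        floor = np.percentile(positive, 1) if positive.size else 1e-8
        s2[low] = max(floor, 1e-8)
    return s2


def fit_moderated(
    y: FeatureTable,
    design: Design,
    contrast: tuple[str, str],
    weights: pd.DataFrame | None = None,
    prior_df: float | None = None,
    ci_level: float = 0.95,
    lfc_threshold: float = 1.0,
    p_threshold: float = 0.05,
    strict_p: bool = False,
) -> DifferentialResult:
    """Weighted group-means fit with empirical-Bayes variance moderation.

    The full group-means model supplies the pooled residual variance; the
    contrast coefficient is beta = mean(A) - mean(B) on the log2 scale.
    ``prior_df`` overrides the estimated prior degrees of freedom (0 gives
    the ordinary t, inf fully pooled variances).
    """
    if y.scale != "log2":
        raise ValidationError("fit_moderated expects a log2-scale table")
    a, b = contrast
    sample_ids = [s for s in design.sample_ids if s in y.values.columns]
    labels, gidx = _group_index(design, sample_ids)
    for g in (a, b):
        if g not in labels:
            raise ValidationError(f"contrast group {g!r} not present in data")
    Y = y.values[sample_ids].to_numpy()
    n_feat, n_samp = Y.shape
    W = (
        np.ones_like(Y)
        if weights is None
        else weights.reindex(index=y.values.index, columns=sample_ids).to_numpy()
    )
    if not np.all(np.isfinite(W)) or (W <= 0).any():
        raise ValidationError("weights must be finite and positive")

    n_groups = len(labels)
    df_resid = n_samp - n_groups
    if df_resid < 1:
        raise ValidationError(
            "no residual degrees of freedom (one sample per group)"
        )

    sw = np.empty((n_feat, n_groups))
    mu = np.empty((n_feat, n_groups))
    for g in range(n_groups):
        cols = gidx == g
        wg = W[:, cols]
        sw[:, g] = wg.sum(axis=1)
        mu[:, g] = (wg * Y[:, cols]).sum(axis=1) / sw[:, g]
    fitted = mu[:, gidx]
    s2 = (W * (Y - fitted) ** 2).sum(axis=1) / df_resid
    s2 = _apply_variance_floor(s2)

    ia, ib = labels.index(a), labels.index(b)
    beta = mu[:, ia] - mu[:, ib]
    u = np.sqrt(1.0 / sw[:, ia] + 1.0 / sw[:, ib])  # unscaled SE

    if prior_df is None:
        d0, s0_sq = estimate_prior(s2, df_resid)
    else:
        d0 = float(prior_df)
        _, s0_sq = estimate_prior(s2, df_resid)
    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
        df_total = np.inf
    elif d0 == 0:
        s2_post = s2
        df_total = float(df_resid)
    else:
        s2_post = (d0 * s0_sq + df_resid * s2) / (d0 + df_resid)
        df_total = d0 + df_resid

    se = u * np.sqrt(s2_post)
    t_mod = beta / se
    p_raw = 2.0 * stats.t.sf(np.abs(t_mod), df_total)
    p_raw = np.clip(p_raw, np.finfo(float).tiny, 1.0)
    tq = stats.t.ppf(0.5 + ci_level / 2.0, df_total)
    ci_low = beta - tq * se
    ci_high = beta + tq * se
    fdr = multipletests(p_raw, method="fdr_bh")[1]

    direction = classify_direction(beta, p_raw, lfc_threshold, p_threshold,
                                   strict_p)

    table = pd.DataFrame(
        {
            "feature": y.values.index,
            "contrast": contrast_label(contrast),
            "log2fc": beta,
            "se": se,
            "ci_low": ci_low,
            "ci_high": ci_high,
            "t_mod": t_mod,
            "df_total": df_total,
            "p_raw": p_raw,
            "fdr": fdr,
            "direction": direction,
        }
    )
    return DifferentialResult(table=table, lfc_threshold=lfc_threshold,
                              p_threshold=p_threshold)


def classify_direction(
    log2fc,
    p_raw,
    lfc_threshold: float = 1.0,
    p_threshold: float = 0.05,
    strict_p: bool = False,
):
    """The FC >= 2, p <= 0.05 gate: 'up', 'down' or 'ns' per feature.

    ``strict_p`` switches the p comparison from <= to < (both readings of
    the gate occur in practice); the fold-change gate is always inclusive.
    """
    log2fc = np.asarray(log2fc, dtype=float)
    p_raw = np.asarray(p_raw, dtype=float)
    pass_p = p_raw < p_threshold if strict_p else p_raw <= p_threshold
    return np.where(
        (log2fc >= lfc_threshold) & pass_p, "up",
        np.where((log2fc <= -lfc_threshold) & pass_p, "down", "ns"),
    )


def select_differential(
    res: DifferentialResult, contrast: tuple[str, str] | None = None
) -> tuple[set[str], set[str]]:
    """Feature id sets called up / down by the FC >= 2, p <= 0.05 gate."""
    t = res.table if contrast is None else res.for_contrast(contrast)
    up = set(t.loc[t.direction == "up", "feature"])
    down = set(t.loc[t.direction == "down", "feature"])
    return up, down


def run_differential(
    table: FeatureTable,
    design: Design,
    contrasts: list[tuple[str, str]] | None = None,
    use_voom: bool | None = None,
    prior_df: float | None = None,
    ci_level: float = 0.95,
    lfc_threshold: float = 1.0,
    p_threshold: float = 0.05,
    strict_p: bool = False,
) -> DifferentialResult:
    """Run the uniform differential pipeline over the design's contrasts.

    Count tables are voom-transformed first (use_voom defaults to the table's
    scale); log2 tables go straight to the moderated fit with unit weights.
    """
    if use_voom is None:
        use_voom = table.scale == "counts"
    if use_voom and table.scale == "log2":
        raise ValidationError("voom requested on a log2-scale table")
    contrasts = list(contrasts if contrasts is not None else design.contrasts)
    if not contrasts:
        raise ValidationError("no contrasts to test")

    if use_voom:
        fit = voom_transform(table, design)
        y, w = fit.logcpm, fit.weights
    else:
        y, w = table, None

    frames = []
    for contrast in contrasts:
        res = fit_moderated(
            y, design, contrast, weights=w, prior_df=prior_df,
            ci_level=ci_level, lfc_threshold=lfc_threshold,
            p_threshold=p_threshold, strict_p=strict_p,
        )
        frames.append(res.table)
    return DifferentialResult(
        table=pd.concat(frames, ignore_index=True),
        lfc_threshold=lfc_threshold, p_threshold=p_threshold,
    )


def write_differential(res: DifferentialResult, path) -> None:
    out = res.table.copy()
    out["df"] = out.pop("df_total")
    out = out[["feature", "contrast", "log2fc", "ci_low", "ci_high",
               "t_mod", "df", "p_raw", "fdr", "direction"]]
    out.to_csv(path, sep="\t", index=False, float_format="%.10g",
               encoding="utf-8")
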