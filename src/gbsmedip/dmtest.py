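"""Two-group differential-methylation tests on window count matrices.

Three test families are provided:

* :func:`mann_whitney_matrix` — the recommended test: per-window two-sided
  Mann-Whitney U on normalized counts.  Exact null distribution for small
  tie-free samples, tie-corrected normal approximation with continuity
  correction otherwise.  The whole matrix is tested in vectorized passes so
  that millions of null windows are feasible.
* :func:`moderated_t_matrix` — an empirical-Bayes moderated t-test on
  log2CPM, with hyperparameters (prior df, prior variance) obtained by
  moment-matching the log sample variances to a scaled log-F distribution.
* :func:`nb_lrt_matrix` — a per-window negative-binomial likelihood-ratio
  test with log effective-library-size offsets; the dispersion is profiled
  by maximum likelihood under the alternative and held fixed for the null
  fit.  This is a deliberately simplified single-window analog of the
  NB maximum-likelihood GLM tests used in RNA-seq software: it shares no
  information across windows.

All tests return a tidy results frame (window_id, method, effect, p_value)
and multiple-testing correction is applied separately with
:func:`adjust_pvalues`.
"""

from __future__ import annotations

import logging
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .counting import CountMatrix
from .normalize import NormalizedMatrix, effective_library_sizes, tmm_factors

logger = logging.getLogger(__name__)

_TINY = np.finfo(float).tiny


def _design_masks(design: pd.Series, columns) -> tuple[np.ndarray, np.ndarray, list]:
    design = pd.Series(design).loc[list(columns)]
    labels = sorted(design.unique())
    if len(labels) != 2:
        raise ValueError(f"exactly two groups required, got {labels}")
    g = design.to_numpy()
    return g == labels[0], g == labels[1], labels


# ---------------------------------------------------------------------------
# Mann-Whitney
# ---------------------------------------------------------------------------


@lru_cache(maxsize=None)
def mw_exact_cdf(n1: int, n2: int) -> np.ndarray:
    """CDF of the exact (tie-free) null distribution of the Mann-Whitney U statistic.

    The number of rank arrangements with U = u equals the number of
    partitions of u into at most n1 parts, each at most n2; built by the
    classic recurrence f[i,j](u) = f[i,j-1](u) + f[i-1,j](u-j) over the
    maximal part size j.
    """
    u_max = n1 * n2
    f = np.zeros((n1 + 1, u_max + 1))
    f[:, 0] = 1.0  # only the empty partition when no parts are allowed yet
    for j in range(1, n2 + 1):
        g = f.copy()
        for i in range(1, n1 + 1):
            g[i, j:] += g[i - 1, : u_max + 1 - j]
        f = g
    counts = f[n1]
    total = counts.sum()  # equals C(n1 + n2, n1)
    return np.cumsum(counts) / total


def _mw_exact_pvalues(u_min: np.ndarray, n1: int, n2: int) -> np.ndarray:
    """Two-sided exact p: 2 * P(U <= min(U1, U2)), capped at 1 (symmetric null)."""
    cdf = mw_exact_cdf(n1, n2)
    p = 2.0 * cdf[u_min.astype(np.intp)]
    return np.minimum(p, 1.0)


def _rank_rows(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise midranks and tie-correction term sum(t^3 - t) per row."""
    m, n = x.shape
    ranks = stats.rankdata(x, axis=1)
    xs = np.sort(x, axis=1)
    # run-length encode equal-value runs; rows always start a new run
    starts = np.ones((m, n), dtype=bool)
    starts[:, 1:] = xs[:, 1:] != xs[:, :-1]
    flat = starts.ravel()
    run_id = np.cumsum(flat) - 1
    sizes = np.bincount(run_id, weights=np.ones(m * n))
    row_of_run = np.repeat(np.arange(m), n)[flat]
    ties = np.bincount(row_of_run, weights=sizes**3 - sizes, minlength=m)
    return ranks, ties


def mann_whitney_matrix(
    values: NormalizedMatrix | pd.DataFrame,
    design: pd.Series,
    exact_max_n: int = 12,
    continuity: bool = True,
) -> pd.DataFrame:
    """Two-sided Mann-Whitney U test per window (row).

    Exact p-values are used when n1 + n2 <= ``exact_max_n`` and the window
    has no ties; otherwise the normal approximation with tie correction
    (and continuity correction) is applied.  All-constant windows get p = 1.
    The reported effect is the U statistic of the first (alphabetical)
    group.
    """
    v = values.values if isinstance(values, NormalizedMatrix) else values
    mask1, mask2, _ = _design_masks(design, v.columns)
    x = v.to_numpy(dtype=float)
    n1, n2 = int(mask1.sum()), int(mask2.sum())
    if min(n1, n2) < 1:
        raise ValueError("each group needs at least one sample")
    ranks, tie_term = _rank_rows(x)
    r1 = ranks[:, mask1].sum(axis=1)
    u1 = r1 - n1 * (n1 + 1) / 2.0
    n = n1 + n2
    p = np.ones(x.shape[0])

    has_ties = tie_term > 0
    exact_ok = (~has_ties) & (n <= exact_max_n)
    if exact_ok.any():
        u_min = np.minimum(u1[exact_ok], n1 * n2 - u1[exact_ok])
        p[exact_ok] = _mw_exact_pvalues(np.round(u_min), n1, n2)

    approx = ~exact_ok
    if approx.any():
        mu = n1 * n2 / 2.0
        sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term[approx] / (n * (n - 1)))
        sigma = np.sqrt(np.maximum(sigma2, 0.0))
        num = np.abs(u1[approx] - mu)
        if continuity:
            num = np.maximum(num - 0.5, 0.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(sigma > 0, num / sigma, 0.0)
        p[approx] = np.clip(2.0 * stats.norm.sf(z), _TINY, 1.0)

    # fully constant windows: sigma == 0 -> z = 0 -> p = 1 already
    return pd.DataFrame(
        {
            "window_id": v.index,
            "method": "mann_whitney",
            "effect": u1,
            "p_value": p,
        }
    ).reset_index(drop=True)


# ---------------------------------------------------------------------------
# Moderated t (log2CPM + empirical-Bayes variance shrinkage)
# ---------------------------------------------------------------------------


def trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration."""
    if x <= 0:
        return np.inf
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif / y) < 1e-10:
            break
    return float(y)


def log2_cpm(
    counts: CountMatrix | pd.DataFrame,
    eff_sizes: pd.Series | None = None,
    prior_count: float = 0.5,
) -> pd.DataFrame:
    """log2 counts-per-million on effective library sizes, with a
    library-size-proportional prior count (edgeR's ``cpm(log=TRUE)`` formula)."""
    c = counts.counts if isinstance(counts, CountMatrix) else counts
    if eff_sizes is None:
        eff_sizes = effective_library_sizes(c, tmm_factors(c))
    lib = eff_sizes.loc[list(c.columns)].to_numpy(dtype=float)
    pc = prior_count * lib / lib.mean()
    arr = c.to_numpy(dtype=float)
    return pd.DataFrame(
        np.log2((arr + pc) / (lib + 2 * pc) * 1e6), index=c.index, columns=c.columns
    )


def fit_f_dist(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match sample variances to a scaled F distribution.

    Returns (d0, s0^2): the prior degrees of freedom and prior variance such
    that s^2 ~ s0^2 * F(df, d0), estimated from the mean and excess variance
    of log s^2 via digamma/trigamma inversion.  d0 = inf means the log
    variances are no more dispersed than chi-square sampling alone explains.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = np.isfinite(s2) & (s2 > 0)
    if ok.sum() < 2:
        return np.inf, float(np.nanmedian(s2[ok])) if ok.any() else 1.0
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1) - special.polygamma(1, df / 2.0)
    if evar > 0:
        d0 = 2.0 * trigamma_inverse(evar)
        s0_sq = np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
    else:
        d0 = np.inf
        s0_sq = np.exp(emean)
    if not np.isfinite(s0_sq) or s0_sq <= 0:
        logger.warning("prior-variance estimate degenerate; disabling moderation")
        d0, s0_sq = np.inf, float(np.exp(emean))
    return float(d0), float(s0_sq)


def moderated_t_matrix(
    counts: CountMatrix | pd.DataFrame,
    design: pd.Series | None = None,
    prior_count: float = 0.5,
    eff_sizes: pd.Series | None = None,
    moderate: bool = True,
) -> pd.DataFrame:
    """Empirical-Bayes moderated t-test on log2CPM values.

    Per window, a two-group linear model gives the mean log2CPM difference
    (the log2 fold change), pooled residual variance s^2 on n - 2 df; the
    posterior variance (d0*s0^2 + df*s^2) / (d0 + df) replaces s^2 in the t
    statistic, which is referred to a t distribution with d0 + df degrees of
    freedom.  With ``moderate=False`` this is the ordinary equal-variance
    two-sample t-test on log2CPM.
    """
    if isinstance(counts, CountMatrix) and design is None:
        design = counts.design
    if design is None:
        raise ValueError("a design is required")
    c = counts.counts if isinstance(counts, CountMatrix) else counts
    mask1, mask2, _ = _design_masks(design, c.columns)
    n1, n2 = int(mask1.sum()), int(mask2.sum())
    if min(n1, n2) < 2:
        raise ValueError("each group needs at least two samples")
    logcpm = log2_cpm(c, eff_sizes=eff_sizes, prior_count=prior_count).to_numpy()
    m1 = logcpm[:, mask1].mean(axis=1)
    m2 = logcpm[:, mask2].mean(axis=1)
    diff = m2 - m1
    rss = ((logcpm[:, mask1] - m1[:, None]) ** 2).sum(axis=1) + (
        (logcpm[:, mask2] - m2[:, None]) ** 2
    ).sum(axis=1)
    df_resid = n1 + n2 - 2
    s2 = rss / df_resid
    stdev_unscaled2 = 1.0 / n1 + 1.0 / n2
    if moderate:
        d0, s0_sq = fit_f_dist(s2, df_resid)
    else:
        d0, s0_sq = 0.0, 0.0
    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
        df_total = np.inf
    else:
        s2_post = (d0 * s0_sq + df_resid * s2) / (d0 + df_resid)
        df_total = d0 + df_resid
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / np.sqrt(s2_post * stdev_unscaled2)
    t = np.where(np.isfinite(t), t, 0.0)
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p = np.clip(p, _TINY, 1.0)
    df_out = c.index if hasattr(c, "index") else np.arange(len(p))
    return pd.DataFrame(
        {"window_id": df_out, "method": "moderated_t", "effect": diff, "p_value": p}
    ).reset_index(drop=True)


# ---------------------------------------------------------------------------
# Negative-binomial likelihood-ratio test
# ---------------------------------------------------------------------------


def _nb_loglik(y: np.ndarray, mu: np.ndarray, r: np.ndarray) -> np.ndarray:
    """Row-wise NB log-likelihood; parameterization var = mu + mu^2 / r."""
    r = r[:, None] if r.ndim == 1 else r
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = (
            special.gammaln(y + r)
            - special.gammaln(r)
            - special.gammaln(y + 1.0)
            + r * np.log(r / (r + mu))
            + y * np.log(mu / (r + mu))
        )
        ll = np.where((y == 0) & (mu == 0), 0.0, ll)
    return np.nansum(ll, axis=1)


def _fit_beta(
    y: np.ndarray, eff: np.ndarray, r: np.ndarray, n_iter: int = 50
) -> np.ndarray:
    """Per-row MLE of the log mean rate beta with offsets log(eff), dispersion fixed.

    Solves sum_j (y_ij - mu_ij) * r_i / (r_i + mu_ij) = 0 with
    mu_ij = exp(beta_i) * eff_j, by damped Newton steps on beta.
    """
    tot = y.sum(axis=1)
    beta = np.log((tot + 0.5) / eff.sum())
    r_col = r[:, None]
    for _ in range(n_iter):
        mu = np.exp(beta)[:, None] * eff[None, :]
        score = ((y - mu) * r_col / (r_col + mu)).sum(axis=1)
        info = (mu * r_col * (r_col + y) / (r_col + mu) ** 2).sum(axis=1)
        step = np.where(info > 0, score / np.maximum(info, 1e-12), 0.0)
        step = np.clip(step, -2.0, 2.0)
        beta = beta + step
        if np.max(np.abs(step)) < 1e-10:
            break
    return beta


def _update_dispersion(
    y: np.ndarray,
    mu: np.ndarray,
    log_r: np.ndarray,
    r_min: float,
    r_max: float,
    n_iter: int = 30,
) -> np.ndarray:
    """Per-row Newton ascent of the profile NB log-likelihood in theta = log r."""
    for _ in range(n_iter):
        r = np.exp(log_r)[:, None]
        d1 = (
            special.digamma(y + r)
            - special.digamma(r)
            + np.log(r)
            + 1.0
            - np.log(r + mu)
            - (r + y) / (r + mu)
        ).sum(axis=1)
        d2 = (
            special.polygamma(1, y + r)
            - special.polygamma(1, r)
            + 1.0 / r
            - 2.0 / (r + mu)
            + (r + y) / (r + mu) ** 2
        ).sum(axis=1)
        r1 = np.exp(log_r)
        g = r1 * d1  # d/dtheta
        h = r1 * d1 + r1**2 * d2  # d2/dtheta2
        with np.errstate(divide="ignore", invalid="ignore"):
            step = np.where(h < 0, -g / np.where(h < 0, h, -1.0), np.sign(g) * 0.5)
        step = np.clip(np.nan_to_num(step), -1.0, 1.0)
        log_r = np.clip(log_r + step, np.log(r_min), np.log(r_max))
        if np.max(np.abs(step)) < 1e-9:
            break
    return log_r


def nb_lrt_matrix(
    counts: CountMatrix | pd.DataFrame,
    design: pd.Series | None = None,
    eff_sizes: pd.Series | None = None,
    dispersion: float | np.ndarray | None = None,
    r_min: float = 1e-8,
    r_max: float = 1e8,
) -> pd.DataFrame:
    """Per-window negative-binomial likelihood-ratio test with library offsets.

    Alternative model: group-specific NB means mu_gj = exp(beta_g) * eff_j;
    null model: one beta for all samples.  The per-window dispersion r
    (variance = mu + mu^2/r) is estimated by profile maximum likelihood
    under the alternative (floored at ``r_min``) and held fixed for the
    null fit; 2(l_alt - l_null) is referred to chi-square with 1 df.
    A fixed ``dispersion`` can be supplied instead (e.g. a very large value
    approximates the Poisson model).  All-zero windows get p = 1.
    """
    if isinstance(counts, CountMatrix) and design is None:
        design = counts.design
    if design is None:
        raise ValueError("a design is required")
    c = counts.counts if isinstance(counts, CountMatrix) else counts
    mask1, mask2, _ = _design_masks(design, c.columns)
    if min(mask1.sum(), mask2.sum()) < 2:
        raise ValueError("each group needs at least two samples")
    if eff_sizes is None:
        eff_sizes = c.sum(axis=0).astype(float)
    eff = eff_sizes.loc[list(c.columns)].to_numpy(dtype=float)
    eff = eff / eff.mean()  # offsets on a unit scale for numerical stability
    y = c.to_numpy(dtype=float)
    m = y.shape[0]
    y1, y2 = y[:, mask1], y[:, mask2]
    e1, e2 = eff[mask1], eff[mask2]

    fixed_r = dispersion is not None
    if fixed_r:
        log_r = np.log(np.clip(np.broadcast_to(np.asarray(dispersion, float), (m,)), r_min, r_max))
        log_r = np.array(log_r, dtype=float)
    else:
        mean0 = np.maximum(y.mean(axis=1), 1e-8)
        var0 = y.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            r_init = np.where(var0 > mean0, mean0**2 / (var0 - mean0), 10.0)
        log_r = np.log(np.clip(np.nan_to_num(r_init, nan=10.0), r_min, r_max))

    # alternate group-mean and dispersion updates under the alternative
    for _ in range(8):
        r = np.exp(log_r)
        b1 = _fit_beta(y1, e1, r)
        b2 = _fit_beta(y2, e2, r)
        if fixed_r:
            break
        mu = np.concatenate(
            [np.exp(b1)[:, None] * e1[None, :], np.exp(b2)[:, None] * e2[None, :]], axis=1
        )
        y_cat = np.concatenate([y1, y2], axis=1)
        new_log_r = _update_dispersion(y_cat, mu, log_r, r_min, r_max)
        done = np.max(np.abs(new_log_r - log_r)) < 1e-8
        log_r = new_log_r
        if done:
            break

    r = np.exp(log_r)
    b1 = _fit_beta(y1, e1, r)
    b2 = _fit_beta(y2, e2, r)
    b0 = _fit_beta(y, eff, r)
    mu_alt = np.concatenate(
        [np.exp(b1)[:, None] * e1[None, :], np.exp(b2)[:, None] * e2[None, :]], axis=1
    )
    mu_null = np.exp(b0)[:, None] * eff[None, :]
    y_cat = np.concatenate([y1, y2], axis=1)
    ll_alt = _nb_loglik(y_cat, mu_alt, r)
    ll_null = _nb_loglik(y, mu_null, r)
    lrt = np.maximum(2.0 * (ll_alt - ll_null), 0.0)
    p = np.clip(stats.chi2.sf(lrt, df=1), _TINY, 1.0)
    bad = ~np.isfinite(lrt) | (y.sum(axis=1) == 0)
    p[bad] = 1.0
    effect = (b2 - b1) / np.log(2.0)  # log2 fold change group2/group1
    return pd.DataFrame(
        {
            "window_id": c.index,
            "method": "nb_lrt",
            "effect": effect,
            "p_value": p,
            "converged": ~bad,
        }
    ).reset_index(drop=True)


# ---------------------------------------------------------------------------
# Multiple-testing correction
# ---------------------------------------------------------------------------


def adjust_pvalues(p, method: str = "BH") -> np.ndarray:
    """Benjamini-Hochberg step-up ("BH") or Bonferroni adjusted p-values,
    returned in the input order."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if method == "BH":
        return multipletests(p, method="fdr_bh")[1]
    if method.lower() == "bonferroni":
        return np.minimum(p * p.size, 1.0)
    raise ValueError(f"unknown correction {method!r}")


def attach_adjusted(results: pd.DataFrame, corrections=("BH", "bonferroni")) -> pd.DataFrame:
    """Add one adjusted-p column per correction to a results frame."""
    out = results.copy()
    for corr in corrections:
        out[f"p_{corr}"] = adjust_pvalues(out["p_value"].to_numpy(), corr)
    return out


def read_external_pvalues(path) -> pd.DataFrame:
    """Adapter for p-value tables produced by external tools.

    Expected TSV columns: window_id, method, p (effect optional).  This lets
    externally computed results (e.g. edgeR quasi-likelihood or DESeq2 run
    in R) enter the benchmark without reimplementing those tools.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"window_id", "method", "p"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"external p-value table missing columns {sorted(missing)}")
    out = df.rename(columns={"p": "p_value"})
    if ((out["p_value"] <= 0) | (out["p_value"] > 1)).any():
        raise ValueError("external p-values must lie in (0, 1]")
    if "effect" not in out.columns:
        out["effect"] = np.nan
    return out[["window_id", "method", "effect", "p_value"]]
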