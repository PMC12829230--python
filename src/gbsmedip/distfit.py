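"""Per-window distribution fitting and AIC model comparison.

Count-based differential tests assume the window counts follow a negative
binomial distribution; this module checks that assumption window by
window.  Five candidate families are fit by maximum likelihood — normal,
Poisson, negative binomial, uniform and logistic — and ranked by
AIC = 2k - 2 log L.  Windows where a family's MLE does not exist (e.g. the
NB dispersion MLE diverges when the sample variance does not exceed the
mean) are reported as non-converged rather than dropped, so the fraction
of windows "breaking assumptions" is itself a result.

Discrete families fit to real-valued (normalized) data are handled by
scaling back to pseudo-counts and rounding; the report flags the rounding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

FAMILIES = ("normal", "poisson", "nbinom", "uniform", "logistic")

#: free parameters per family
N_PARAMS = {"normal": 2, "poisson": 1, "nbinom": 2, "uniform": 2, "logistic": 2}

DISCRETE = {"poisson", "nbinom"}


@dataclass(frozen=True)
class FamilyFit:
    family: str
    log_likelihood: float
    k: int
    converged: bool
    rounded: bool = False

    @property
    def aic(self) -> float:
        return 2 * self.k - 2 * self.log_likelihood


def _nb_loglik_scalar(x: np.ndarray, mu: float, r: float) -> float:
    return float(
        np.sum(
            special.gammaln(x + r)
            - special.gammaln(r)
            - special.gammaln(x + 1)
            + r * np.log(r / (r + mu))
            + np.where(x > 0, x * np.log(mu / (r + mu)), 0.0)
        )
    )


def fit_family(values, family: str) -> FamilyFit:
    """Maximum-likelihood fit of one family to one window's values.

    Returns the maximized log-likelihood, the parameter count k and a
    convergence flag.  Discrete families require (near-)integer nonnegative
    input; real-valued input is rounded and the fit flagged ``rounded``.
    Degenerate inputs (all values equal) are non-converged for families
    whose MLE is undefined there (uniform, logistic scale -> 0, NB).
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 values")
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}; choose from {FAMILIES}")
    k = N_PARAMS[family]
    rounded = False
    constant = np.ptp(x) == 0

    if family in DISCRETE:
        if (x < 0).any():
            raise ValueError(f"{family} requires nonnegative values")
        xr = np.round(x)
        rounded = not np.allclose(x, xr)
        x = xr

    if family == "normal":
        mu, sigma2 = x.mean(), x.var()  # MLE (ddof=0)
        if sigma2 <= 0:
            return FamilyFit(family, -np.inf, k, False, rounded)
        ll = float(np.sum(stats.norm.logpdf(x, mu, np.sqrt(sigma2))))
        return FamilyFit(family, ll, k, np.isfinite(ll), rounded)

    if family == "poisson":
        lam = x.mean()
        if lam <= 0:
            # all-zero window: likelihood sup approached at lambda -> 0
            return FamilyFit(family, 0.0, k, False, rounded)
        ll = float(np.sum(stats.poisson.logpmf(x, lam)))
        return FamilyFit(family, ll, k, np.isfinite(ll), rounded)

    if family == "nbinom":
        mu = x.mean()
        if mu <= 0 or x.var(ddof=1) <= mu:
            # dispersion MLE undefined (diverges to the Poisson boundary)
            return FamilyFit(family, -np.inf, k, False, rounded)
        # mu-MLE is the sample mean; profile the size parameter r
        r0 = mu**2 / (x.var(ddof=1) - mu)
        res = optimize.minimize_scalar(
            lambda lr: -_nb_loglik_scalar(x, mu, np.exp(lr)),
            bracket=(np.log(r0) - 1, np.log(r0) + 1),
            method="brent",
        )
        ll = -res.fun
        return FamilyFit(family, float(ll), k, bool(res.success and np.isfinite(ll)), rounded)

    if family == "uniform":
        lo, hi = x.min(), x.max()
        if hi <= lo:
            return FamilyFit(family, -np.inf, k, False, rounded)
        ll = -x.size * np.log(hi - lo)
        return FamilyFit(family, float(ll), k, True, rounded)

    # logistic
    if constant:
        return FamilyFit(family, -np.inf, k, False, rounded)
    loc, scale = stats.logistic.fit(x)
    ll = float(np.sum(stats.logistic.logpdf(x, loc, scale)))
    return FamilyFit(family, ll, k, bool(np.isfinite(ll) and scale > 0), rounded)


def best_family_per_window(
    matrix: pd.DataFrame,
    families=FAMILIES,
    discrete_scale: float | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Fit every family to every window (row) and pick the AIC-best per window.

    ``matrix``: windows x samples values (raw counts or normalized values).
    ``discrete_scale``: when fitting discrete families to normalized data,
    values are multiplied by this factor before rounding to pseudo-counts
    (e.g. the inverse of the normalization scale); continuous families see
    the data unchanged.

    Returns (long-format fit report, per-window best family, summary
    fractions).  The summary maps each family to the fraction of windows
    where it is the AIC minimum among converged fits, plus a "failed"
    fraction for windows with no converged fit at all.
    """
    if matrix.shape[1] < 3:
        raise ValueError("need at least 3 samples per window")
    unknown = set(families) - set(FAMILIES)
    if unknown:
        raise ValueError(f"unknown families {sorted(unknown)}")
    records = []
    best = []
    arr = matrix.to_numpy(dtype=float)
    for i, wid in enumerate(matrix.index):
        row = arr[i]
        fits = {}
        for fam in families:
            vals = row
            if fam in DISCRETE and discrete_scale is not None:
                vals = row * discrete_scale
            try:
                fit = fit_family(vals, fam)
            except ValueError:
                fit = FamilyFit(fam, -np.inf, N_PARAMS[fam], False)
            fits[fam] = fit
            records.append(
                {
                    "window_id": wid,
                    "family": fam,
                    "log_likelihood": fit.log_likelihood,
                    "k": fit.k,
                    "aic": fit.aic,
                    "converged": fit.converged,
                    "rounded": fit.rounded,
                }
            )
        converged = {f: ft for f, ft in fits.items() if ft.converged}
        best.append(min(converged, key=lambda f: converged[f].aic) if converged else "failed")
    report = pd.DataFrame.from_records(records)
    best_s = pd.Series(best, index=matrix.index, name="best_family")
    frac = best_s.value_counts(normalize=True)
    summary = frac.reindex(list(families) + ["failed"], fill_value=0.0)
    summary.name = "fraction"
    return report, best_s, summary
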