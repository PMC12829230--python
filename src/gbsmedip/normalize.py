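"""Effective-library-size normalization by trimmed mean of M-values (TMM).

Between-sample scaling follows Robinson & Oshlack's TMM as implemented in
edgeR's ``calcNormFactors``: log ratios (M) and average log abundances (A)
against a reference sample are doubly trimmed (30% on M, 5% on A) and the
surviving M values are averaged with inverse asymptotic-variance weights.
Raw counts are divided by the effective library size (column sum x TMM
factor); an optional scale multiplier turns the result into TMM-CPM.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .counting import CountMatrix

logger = logging.getLogger(__name__)


@dataclass
class TmmFactors:
    """Per-sample TMM scaling factors, rescaled to geometric mean 1."""

    factors: pd.Series
    reference_sample: str
    trim_m: float = 0.30
    trim_a: float = 0.05

    def __post_init__(self) -> None:
        if (self.factors <= 0).any():
            raise ValueError("TMM factors must be positive")


@dataclass
class NormalizedMatrix:
    """Counts divided by effective library sizes (zeros preserved)."""

    values: pd.DataFrame
    scale: float = 1.0

    def __post_init__(self) -> None:
        arr = self.values.to_numpy()
        if arr.size and (not np.all(np.isfinite(arr)) or (arr < 0).any()):
            raise ValueError("normalized values must be finite and nonnegative")


def _tmm_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    lib_obs: float,
    lib_ref: float,
    trim_m: float,
    trim_a: float,
) -> float:
    """TMM factor of one sample against the reference (before geometric-mean rescale)."""
    keep = (obs > 0) & (ref > 0)
    if not keep.any():
        return np.nan
    obs, ref = obs[keep].astype(float), ref[keep].astype(float)
    m = np.log2((obs / lib_obs) / (ref / lib_ref))
    a = 0.5 * np.log2((obs / lib_obs) * (ref / lib_ref))
    # asymptotic variance of M (delta method on binomial counts)
    v = (lib_obs - obs) / (lib_obs * obs) + (lib_ref - ref) / (lib_ref * ref)
    finite = np.isfinite(m) & np.isfinite(a)
    m, a, v = m[finite], a[finite], v[finite]
    if m.size == 0:
        return np.nan
    if np.max(np.abs(m)) < 1e-6:  # identical relative profiles
        return 1.0
    n = m.size
    lo_m = np.floor(n * trim_m) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * trim_a) + 1
    hi_a = n + 1 - lo_a
    rm = rankdata(m)
    ra = rankdata(a)
    keep2 = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
    if not keep2.any():
        return 1.0
    f = np.sum(m[keep2] / v[keep2]) / np.sum(1.0 / v[keep2])
    if not np.isfinite(f):
        return 1.0
    if abs(f) < 1e-6:
        f = 0.0
    return float(2.0**f)


def tmm_factors(
    counts: CountMatrix | pd.DataFrame,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
) -> TmmFactors:
    """Compute TMM scaling factors for every sample.

    The reference is the sample whose 75th percentile of library-size-scaled
    counts is closest to the mean such percentile.  A sample sharing no
    nonzero window with the reference gets factor 1 with a warning.  Factors
    are rescaled so their geometric mean is exactly 1.
    """
    c = counts.counts if isinstance(counts, CountMatrix) else counts
    if c.shape[1] < 2:
        raise ValueError("TMM needs at least 2 samples")
    lib = c.sum(axis=0).astype(float)
    if (lib == 0).any():
        raise ValueError("all-zero sample column")
    arr = c.to_numpy().astype(float)
    q75 = np.quantile(arr / lib.to_numpy(), 0.75, axis=0)
    ref_idx = int(np.argmin(np.abs(q75 - q75.mean())))
    ref = arr[:, ref_idx]
    lib_ref = float(lib.iloc[ref_idx])
    raw = np.empty(c.shape[1])
    for j in range(c.shape[1]):
        if j == ref_idx:
            raw[j] = 1.0
            continue
        f = _tmm_pair(arr[:, j], ref, float(lib.iloc[j]), lib_ref, trim_m, trim_a)
        if np.isnan(f):
            logger.warning(
                "sample %s shares no nonzero window with reference %s; factor set to 1",
                c.columns[j],
                c.columns[ref_idx],
            )
            f = 1.0
        raw[j] = f
    factors = raw / np.exp(np.mean(np.log(raw)))
    return TmmFactors(
        factors=pd.Series(factors, index=c.columns),
        reference_sample=str(c.columns[ref_idx]),
        trim_m=trim_m,
        trim_a=trim_a,
    )


def effective_library_sizes(
    counts: CountMatrix | pd.DataFrame, factors: TmmFactors | pd.Series
) -> pd.Series:
    """Column sum x TMM factor, per sample."""
    c = counts.counts if isinstance(counts, CountMatrix) else counts
    f = factors.factors if isinstance(factors, TmmFactors) else factors
    lib = c.sum(axis=0).astype(float)
    if (lib == 0).any():
        bad = list(lib.index[lib == 0])
        raise ValueError(f"zero column sum for samples {bad}")
    return lib * f.loc[lib.index]


def normalize_counts(
    counts: CountMatrix | pd.DataFrame,
    eff_sizes: pd.Series,
    scale: float = 1.0,
) -> NormalizedMatrix:
    """Divide each sample's counts by its effective library size.

    With ``scale=1e6`` the result is TMM-normalized counts per million.
    """
    c = counts.counts if isinstance(counts, CountMatrix) else counts
    if (eff_sizes <= 0).any():
        raise ValueError("effective library sizes must be positive")
    values = c.div(eff_sizes.loc[list(c.columns)], axis=1) * scale
    return NormalizedMatrix(values=values, scale=scale)


def tmm_normalize(
    counts: CountMatrix | pd.DataFrame, scale: float = 1.0
) -> tuple[NormalizedMatrix, TmmFactors, pd.Series]:
    """One-call TMM pipeline: factors, effective sizes, normalized matrix."""
    factors = tmm_factors(counts)
    eff = effective_library_sizes(counts, factors)
    return normalize_counts(counts, eff, scale=scale), factors, eff
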