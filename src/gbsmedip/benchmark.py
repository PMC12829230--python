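"""Benchmark metrics: p-value uniformity, FPR, confusion matrices, TPR,
ROC/AUC, and the orchestration that runs every test over a simulated or
null dataset.

Two complementary evaluations are supported:

* **Null calibration** — count matrices are randomized within windows
  (destroying any group signal) and each test's p-values are checked for
  uniformity; the fraction below alpha is the empirical false-positive
  rate of the test itself.
* **Power benchmark** — tests run on the DMR simulation are scored
  against the simulation's truth labels: confusion matrix at an adjusted-p
  cutoff, TPR, and ROC curves (score = 1 - p, per correction and raw).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve as _sk_roc_curve

from .counting import CountMatrix
from .dmtest import (
    adjust_pvalues,
    mann_whitney_matrix,
    moderated_t_matrix,
    nb_lrt_matrix,
)
from .normalize import tmm_normalize
from .simulate import randomize_null

METHODS = ("mw", "modt", "nblrt")


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def as_dict(self) -> dict:
        return {"tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn}


@dataclass
class RocCurve:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float


def fpr(null_pvalues, alpha: float = 0.05) -> float:
    """Fraction of null p-values strictly below alpha."""
    p = np.asarray(null_pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    return float(np.mean(p < alpha))


def uniformity(null_pvalues, n_bins: int = 100) -> dict:
    """Uniformity diagnostics for a null p-value sample.

    Returns the QQ pairs (theoretical quantiles (i - 0.5)/m vs sorted
    observed p), the fraction of mass in each of ``n_bins`` equal bins of
    [0, 1], and the maximum absolute quantile deviation from the diagonal.
    """
    p = np.sort(np.asarray(null_pvalues, dtype=float))
    if p.size == 0:
        raise ValueError("empty p-value vector")
    m = p.size
    theoretical = (np.arange(1, m + 1) - 0.5) / m
    hist, _ = np.histogram(p, bins=n_bins, range=(0.0, 1.0))
    # p = 1 exactly belongs in the last bin; numpy already closes the right edge
    return {
        "qq_theoretical": theoretical,
        "qq_observed": p,
        "bin_fractions": hist / m,
        "max_deviation": float(np.max(np.abs(p - theoretical))),
    }


def confusion_at_alpha(
    adjusted_p: pd.Series, truth: pd.DataFrame, alpha: float = 0.05
) -> ConfusionMatrix:
    """Confusion matrix at an adjusted-p cutoff against simulation truth.

    Positives are windows with ``is_true_dmr`` True; a call is adjusted
    p < alpha.  The p-value index must match the truth index exactly.
    """
    adjusted_p = pd.Series(adjusted_p)
    if set(adjusted_p.index) != set(truth.index):
        raise ValueError("window ids of p-values and truth labels differ")
    adj = adjusted_p.loc[truth.index].to_numpy()
    pos = truth["is_true_dmr"].to_numpy(dtype=bool)
    call = adj < alpha
    return ConfusionMatrix(
        tp=int((call & pos).sum()),
        fp=int((call & ~pos).sum()),
        tn=int((~call & ~pos).sum()),
        fn=int((~call & pos).sum()),
    )


def tpr(cm: ConfusionMatrix) -> float:
    """True positive rate TP / (TP + FN)."""
    if cm.tp + cm.fn == 0:
        raise ValueError("no positive windows in truth")
    return cm.tp / (cm.tp + cm.fn)


def roc_auc(p_values: pd.Series, truth: pd.DataFrame) -> RocCurve:
    """ROC curve and trapezoidal AUC with score = 1 - p against truth labels."""
    p_values = pd.Series(p_values)
    if set(p_values.index) != set(truth.index):
        raise ValueError("window ids of p-values and truth labels differ")
    y = truth["is_true_dmr"].to_numpy(dtype=bool)
    if y.all() or not y.any():
        raise ValueError("ROC needs both classes present in truth")
    score = 1.0 - p_values.loc[truth.index].to_numpy(dtype=float)
    fpr_, tpr_, thr = _sk_roc_curve(y, score)
    return RocCurve(fpr=fpr_, tpr=tpr_, thresholds=thr, auc=float(_sk_auc(fpr_, tpr_)))


def _run_method(method: str, counts: CountMatrix, norm, eff) -> pd.DataFrame:
    if method == "mw":
        return mann_whitney_matrix(norm, counts.design)
    if method == "modt":
        return moderated_t_matrix(counts, counts.design, eff_sizes=eff)
    if method == "nblrt":
        return nb_lrt_matrix(counts, counts.design, eff_sizes=eff)
    raise ValueError(f"unknown method {method!r}; choose from {METHODS}")


def run_benchmark(
    counts: CountMatrix,
    truth: pd.DataFrame,
    methods=METHODS,
    corrections=("BH", "bonferroni"),
    alpha: float = 0.05,
    external: pd.DataFrame | None = None,
    scale: float = 1e6,
) -> dict:
    """Run every requested test on a simulated matrix and score it.

    ``external`` optionally supplies a tidy p-value table (window_id,
    method, p_value) from tools run outside this package; it must cover
    every window.  Returns a JSON-serializable report keyed by
    method -> correction with confusion counts, TPR, and AUC on both
    adjusted and raw p-values.
    """
    methods = list(methods)
    if not methods and external is None:
        raise ValueError("no methods requested")
    norm, factors, eff = tmm_normalize(counts, scale=scale)
    results: dict[str, pd.Series] = {}
    for method in methods:
        res = _run_method(method, counts, norm, eff)
        results[method] = res.set_index("window_id")["p_value"]
    if external is not None:
        for method, grp in external.groupby("method"):
            p = grp.set_index("window_id")["p_value"]
            missing = set(truth.index) - set(p.index)
            if missing:
                raise ValueError(
                    f"external table for {method!r} missing windows: {sorted(missing)[:10]}"
                )
            results[str(method)] = p.loc[truth.index]

    report: dict = {"alpha": alpha, "methods": {}}
    for method, p in results.items():
        entry: dict = {
            "auc_raw": roc_auc(p, truth).auc,
            "corrections": {},
        }
        for corr in corrections:
            adj = pd.Series(adjust_pvalues(p.to_numpy(), corr), index=p.index)
            cm = confusion_at_alpha(adj, truth, alpha)
            entry["corrections"][corr] = {
                **cm.as_dict(),
                "tpr": tpr(cm),
                "auc": roc_auc(adj, truth).auc,
            }
        report["methods"][method] = entry
    return report


def run_null_benchmark(
    counts: CountMatrix,
    methods=("mw",),
    n_iter: int = 1000,
    subset: int = 10000,
    seed: int | None = None,
    alpha: float = 0.05,
    n_bins: int = 100,
    scale: float = 1e6,
) -> dict:
    """Null-randomization calibration: FPR and uniformity per method.

    Streams ``n_iter`` randomized matrices (each ``subset`` windows with
    counts permuted within window) through each test against the original
    group labels, accumulating only the per-bin histogram, the below-alpha
    count and the running extreme of the QQ deviation — memory stays
    constant in the number of iterations.
    """
    if not methods:
        raise ValueError("no methods requested")
    acc = {
        m: {"below": 0, "n": 0, "hist": np.zeros(n_bins, dtype=np.int64)} for m in methods
    }
    for null_cm in randomize_null(counts, n_iter=n_iter, subset=subset, seed=seed):
        norm, factors, eff = tmm_normalize(null_cm, scale=scale)
        for method in methods:
            res = _run_method(method, null_cm, norm, eff)
            p = res["p_value"].to_numpy()
            a = acc[method]
            a["below"] += int((p < alpha).sum())
            a["n"] += p.size
            a["hist"] += np.histogram(p, bins=n_bins, range=(0.0, 1.0))[0]
    out = {"alpha": alpha, "n_iter": n_iter, "subset": subset, "methods": {}}
    for method, a in acc.items():
        out["methods"][method] = {
            "n_pvalues": a["n"],
            "fpr": a["below"] / a["n"],
            "bin_fractions": (a["hist"] / a["n"]).tolist(),
        }
    return out
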