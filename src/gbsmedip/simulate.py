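"""Synthetic data: the DMR benchmark simulator, null randomizations, and
aligned-fragment fixtures.

The benchmark simulation emulates the count structure of a GBS-MeDIP
experiment on two groups of individuals.  Windows fall into three strata —
"high", "low" and "non" differentially methylated — each subdivided by
fold change and by baseline coverage.  Per window, group-1 counts are
negative-binomial with mean equal to the coverage, group-2 counts with
mean coverage x fold change; the NB dispersion (size) parameter is drawn
once per window from a normal distribution centred on the coverage and
truncated below at a small floor, so low-coverage strata are strongly
overdispersed.

Truth labelling follows the benchmark's literal rule: high and low strata
are positives, the non stratum is the negative class.  Because the printed
fold changes assign near-1 ratios to the "low" stratum and extreme ratios
to "non", a "corrected" design variant is also provided in which the non
stratum is simulated at fold change 1 (a genuine null).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .counting import CountMatrix

#: baseline NB means tested per fold change
DEFAULT_COVERAGES = (0.1, 0.5, 0.7, 0.9, 1, 5, 10, 20, 50)

#: (class, fold changes, total windows) of the default benchmark design
DEFAULT_STRATA = (
    ("high", (7.0, 2.5, 1.23), 8100),
    ("low", (0.96, 0.8, 0.62), 7200),
    ("non", (0.43, 0.2, 0.13), 1800),
)


@dataclass(frozen=True)
class SimStratum:
    cls: str
    fold_change: float
    coverage: float
    n_windows: int


@dataclass
class SimDesign:
    """Full specification of one benchmark simulation.

    ``strata`` lists every (class, fold change, coverage) cell with its
    window count; ``sd_frac`` scales the dispersion draw
    r ~ Normal(coverage, coverage * sd_frac), truncated below at
    ``dispersion_floor``.
    """

    strata: list[SimStratum]
    n_per_group: int = 5
    sd_frac: float = 0.25
    dispersion_floor: float = 1e-3
    seed: int | None = None

    @property
    def n_windows(self) -> int:
        return sum(s.n_windows for s in self.strata)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(s.cls, s.fold_change, s.coverage, s.n_windows) for s in self.strata],
            columns=["cls", "fold_change", "coverage", "n_windows"],
        )


def _allocate(total: int, n_cells: int) -> list[int]:
    """Split ``total`` across ``n_cells`` round-robin (first cells get the remainder)."""
    base, rem = divmod(total, n_cells)
    return [base + (1 if i < rem else 0) for i in range(n_cells)]


def build_design(
    variant: str = "paper",
    coverages=DEFAULT_COVERAGES,
    strata_spec=DEFAULT_STRATA,
    n_per_group: int = 5,
    sd_frac: float = 0.25,
    dispersion_floor: float = 1e-3,
    seed: int | None = None,
) -> SimDesign:
    """Build the default 17,100-window benchmark design.

    Each class total is split equally across its three fold changes, and
    each fold change's windows are spread round-robin across the nine
    coverages.  ``variant="corrected"`` replaces the non-DMR fold changes
    with 1.0 so that the negative class is a true null.
    """
    if variant not in {"paper", "corrected"}:
        raise ValueError("variant must be 'paper' or 'corrected'")
    if any(c <= 0 for c in coverages):
        raise ValueError("coverages must be positive")
    strata: list[SimStratum] = []
    for cls, fcs, total in strata_spec:
        if total < 0:
            raise ValueError("negative window count")
        if variant == "corrected" and cls == "non":
            fcs = tuple(1.0 for _ in fcs)
        per_fc = _allocate(total, len(fcs))
        for fc, n_fc in zip(fcs, per_fc):
            per_cov = _allocate(n_fc, len(coverages))
            for cov, n_cell in zip(coverages, per_cov):
                if n_cell > 0:
                    strata.append(SimStratum(cls, float(fc), float(cov), n_cell))
    return SimDesign(
        strata=strata,
        n_per_group=n_per_group,
        sd_frac=sd_frac,
        dispersion_floor=dispersion_floor,
        seed=seed,
    )


def simulate_counts(
    design: SimDesign, seed: int | None = None
) -> tuple[CountMatrix, pd.DataFrame]:
    """Draw one benchmark count matrix and its truth labels.

    Returns (CountMatrix with a two-group design, truth DataFrame with
    columns window_id, cls, fold_change, coverage, dispersion, is_true_dmr).
    Sampling is fully deterministic given the seed.
    """
    if seed is None:
        seed = design.seed
    rng = np.random.default_rng(seed)
    n = design.n_per_group
    samples = [f"g1_{i + 1}" for i in range(n)] + [f"g2_{i + 1}" for i in range(n)]
    groups = pd.Series(["g1"] * n + ["g2"] * n, index=samples)

    rows, truth_rows = [], []
    widx = 0
    for s in design.strata:
        r = rng.normal(s.coverage, s.coverage * design.sd_frac, size=s.n_windows)
        r = np.maximum(r, design.dispersion_floor)
        mu1, mu2 = s.coverage, s.coverage * s.fold_change
        p1 = r / (r + mu1)
        p2 = r / (r + mu2)
        c1 = rng.negative_binomial(r[:, None], p1[:, None], size=(s.n_windows, n))
        c2 = rng.negative_binomial(r[:, None], p2[:, None], size=(s.n_windows, n))
        rows.append(np.concatenate([c1, c2], axis=1))
        for k in range(s.n_windows):
            truth_rows.append(
                (f"w{widx:06d}", s.cls, s.fold_change, s.coverage, r[k], s.cls != "non")
            )
            widx += 1
    mat = np.concatenate(rows, axis=0)
    window_ids = [t[0] for t in truth_rows]
    counts = pd.DataFrame(mat, index=pd.Index(window_ids, name="window_id"), columns=samples)
    truth = pd.DataFrame(
        truth_rows,
        columns=["window_id", "cls", "fold_change", "coverage", "dispersion", "is_true_dmr"],
    ).set_index("window_id")
    return CountMatrix(counts, design=groups), truth


def randomize_null(
    counts: CountMatrix | pd.DataFrame,
    n_iter: int = 1000,
    subset: int = 10000,
    seed: int | None = None,
):
    """Yield null count matrices: per iteration, ``subset`` windows sampled
    without replacement and each window's counts independently permuted
    across individuals (the per-window count multiset is conserved, any
    group association is destroyed).

    If the matrix has fewer than ``subset`` windows the subset is drawn
    with replacement and a warning is issued.
    """
    cm = counts if isinstance(counts, CountMatrix) else CountMatrix(counts)
    c = cm.counts
    rng = np.random.default_rng(seed)
    arr = c.to_numpy()
    m = arr.shape[0]
    replace_draw = m < subset
    if replace_draw:
        import warnings

        warnings.warn(
            f"matrix has {m} windows < subset {subset}; sampling with replacement",
            stacklevel=2,
        )
    for _ in range(n_iter):
        idx = rng.choice(m, size=subset, replace=replace_draw)
        sub = rng.permuted(arr[idx], axis=1)
        yield CountMatrix(
            pd.DataFrame(sub, index=c.index[idx], columns=c.columns), design=cm.design
        )


def synth_fragments(
    n_pairs: int,
    genome_spec: dict[str, int],
    seed: int | None = None,
    samples=("s1", "s2"),
    frag_mean: float = 180.0,
    frag_sd: float = 40.0,
    stack: int = 1,
    low_mapq_frac: float = 0.0,
    discordant_frac: float = 0.0,
    mapq_pass: int = 42,
    mapq_fail: int = 5,
    locus_spacing: int = 2000,
) -> pd.DataFrame:
    """Reproducible aligned-fragment fixture emulating PstI cut-site stacks.

    ``n_pairs`` loci are placed on a ``locus_spacing`` grid (so loci never
    merge into one window); each locus emits ``stack`` identical fragments
    per drawn sample — the stacked-read signature of an enzymatic cut site.
    Fractions of low-MAPQ and discordant records are injected for filter
    tests.  The per-locus, per-sample count of *eligible* fragments
    (concordant, MAPQ above threshold) is returned in
    ``result.attrs["ledger"]``.
    """
    rng = np.random.default_rng(seed)
    chroms = list(genome_spec)
    rows = []
    ledger: dict[tuple[str, int, int, str], int] = {}
    for _ in range(n_pairs):
        chrom = chroms[rng.integers(len(chroms))]
        clen = genome_spec[chrom]
        n_slots = max(clen // locus_spacing, 1)
        slot = int(rng.integers(n_slots))
        length = int(np.clip(rng.normal(frag_mean, frag_sd), 50, locus_spacing - 10))
        start = slot * locus_spacing
        end = start + length
        sample = samples[rng.integers(len(samples))]
        for _copy in range(stack):
            low = rng.random() < low_mapq_frac
            discordant = rng.random() < discordant_frac
            mapq = mapq_fail if low else mapq_pass
            rows.append((chrom, start, end, mapq, not discordant, sample))
            if not low and not discordant:
                key = (chrom, start, end, sample)
                ledger[key] = ledger.get(key, 0) + 1
    df = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "mapq", "proper_pair", "sample_id"]
    )
    if len(df) == 0:
        df = pd.DataFrame(
            columns=["chrom", "start", "end", "mapq", "proper_pair", "sample_id"]
        ).astype({"start": np.int64, "end": np.int64, "mapq": np.int64, "proper_pair": bool})
    df.attrs["ledger"] = pd.DataFrame(
        [(c, s, e, smp, n) for (c, s, e, smp), n in sorted(ledger.items())],
        columns=["chrom", "start", "end", "sample_id", "n_eligible"],
    )
    return df
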