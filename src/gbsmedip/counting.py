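"""Windows x samples count matrices from aligned fragments.

Counting mirrors a featureCounts-style run on paired-end data: each
properly paired fragment no longer than ``max_fragment_len`` is assigned
at most once.  PCR/optical duplicates are deliberately retained — in
GBS-MeDIP the PstI cut site makes identical fragment coordinates the
expected signal, not an artifact.  An unfiltered coverage counter
(the in-package analog of ``bedtools multicov``) is provided as the
baseline the filtered counts are compared against.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .windows import WindowSet, _validate_fragments

AMBIGUOUS_POLICIES = ("drop", "all", "largest")


@dataclass
class CountMatrix:
    """Integer windows x samples counts plus the sample -> group design.

    ``counts``: DataFrame indexed by window_id with one column per sample.
    ``design``: optional Series mapping sample_id -> group label; required
    by the differential tests, not by counting itself.
    """

    counts: pd.DataFrame
    design: pd.Series | None = None

    def __post_init__(self) -> None:
        c = self.counts
        arr = c.to_numpy()
        if arr.size and (not np.issubdtype(arr.dtype, np.number) or (arr < 0).any()):
            raise ValueError("counts must be nonnegative numbers")
        if arr.size and np.issubdtype(arr.dtype, np.floating) and not np.all(arr == np.round(arr)):
            raise ValueError("counts must be integral")
        self.counts = c.astype(np.int64) if arr.size else c
        if self.design is not None:
            design = pd.Series(self.design)
            missing = [s for s in c.columns if s not in design.index]
            if missing:
                raise ValueError(f"samples without a group label: {missing}")
            self.design = design.loc[list(c.columns)]

    @property
    def window_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def groups(self) -> tuple[np.ndarray, np.ndarray]:
        """Boolean masks (group1, group2) over the sample axis, by sorted label."""
        if self.design is None:
            raise ValueError("CountMatrix has no design")
        labels = sorted(self.design.unique())
        if len(labels) != 2:
            raise ValueError(f"expected exactly 2 groups, got {labels}")
        g = self.design.to_numpy()
        return g == labels[0], g == labels[1]


def _window_arrays(window_set: WindowSet) -> dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Per chromosome: (starts, ends, row-index into the full window table)."""
    w = window_set.windows
    out = {}
    for chrom, grp in w.groupby("chrom", sort=False):
        out[chrom] = (
            grp["start"].to_numpy(),
            grp["end"].to_numpy(),
            grp.index.to_numpy(),
        )
    return out


def _assign(
    fragments: pd.DataFrame,
    window_set: WindowSet,
    policy: str,
    count_every_overlap: bool,
) -> tuple[np.ndarray, list[str]]:
    """Return a (n_windows, n_samples) count array and the sample order.

    ``count_every_overlap=True`` implements the raw-coverage baseline: every
    fragment/window overlap increments, no ambiguity policy.
    """
    windows = window_set.windows
    samples = sorted(fragments["sample_id"].unique())
    sample_index = {s: j for j, s in enumerate(samples)}
    mat = np.zeros((len(windows), len(samples)), dtype=np.int64)
    per_chrom = _window_arrays(window_set)
    for chrom, sub in fragments.groupby("chrom", sort=False):
        if chrom not in per_chrom:
            continue
        wstarts, wends, wrows = per_chrom[chrom]
        fs = sub["start"].to_numpy()
        fe = sub["end"].to_numpy()
        cols = sub["sample_id"].map(sample_index).to_numpy()
        # windows overlapping [fs, fe): first with end > fs, last with start < fe
        lo = np.searchsorted(wends, fs, side="right")
        hi = np.searchsorted(wstarts, fe, side="left")
        for k in range(len(fs)):
            i, j = lo[k], hi[k]
            n_hit = j - i
            if n_hit <= 0:
                continue
            if count_every_overlap:
                mat[wrows[i:j], cols[k]] += 1
            elif n_hit == 1:
                mat[wrows[i], cols[k]] += 1
            elif policy == "all":
                mat[wrows[i:j], cols[k]] += 1
            elif policy == "largest":
                ov = np.minimum(wends[i:j], fe[k]) - np.maximum(wstarts[i:j], fs[k])
                mat[wrows[i + int(np.argmax(ov))], cols[k]] += 1  # argmax ties -> leftmost
            # policy == "drop": not counted
    return mat, samples


def count_fragments(
    fragments: pd.DataFrame,
    window_set: WindowSet,
    max_fragment_len: int = 1500,
    ambiguous: str = "drop",
    design: pd.Series | None = None,
) -> CountMatrix:
    """Count properly paired fragments of length <= ``max_fragment_len`` per window.

    Fragments overlapping (>= 1 bp) exactly one window increment it; a
    fragment overlapping several windows follows the ``ambiguous`` policy:
    ``drop`` (default, not counted), ``all`` (counted in every overlapped
    window), or ``largest`` (window of largest overlap, ties to leftmost).
    Duplicate fragments all count.
    """
    if ambiguous not in AMBIGUOUS_POLICIES:
        raise ValueError(f"ambiguous must be one of {AMBIGUOUS_POLICIES}")
    df = _validate_fragments(fragments)
    ok = df["proper_pair"] & ((df["end"] - df["start"]) <= max_fragment_len)
    mat, samples = _assign(df.loc[ok], window_set, ambiguous, count_every_overlap=False)
    counts = pd.DataFrame(mat, index=window_set.windows["window_id"].to_numpy(), columns=samples)
    counts.index.name = "window_id"
    return CountMatrix(counts, design=design)


def raw_coverage(
    fragments: pd.DataFrame,
    window_set: WindowSet,
    design: pd.Series | None = None,
) -> CountMatrix:
    """Unfiltered per-window coverage: every fragment/window overlap counts.

    No proper-pair requirement, no length cap, no ambiguity policy — the
    internal analog of running ``bedtools multicov`` on the window BED.
    """
    df = _validate_fragments(fragments)
    mat, samples = _assign(df, window_set, "all", count_every_overlap=True)
    counts = pd.DataFrame(mat, index=window_set.windows["window_id"].to_numpy(), columns=samples)
    counts.index.name = "window_id"
    return CountMatrix(counts, design=design)


def compare_counts(filtered: CountMatrix, raw: CountMatrix) -> pd.DataFrame:
    """Long-format per-cell concordance table (window, sample, filtered, raw, delta).

    Used for the diagonal filtered-vs-coverage diagnostic; cells off the
    diagonal are fragments removed by the pairing/length/ambiguity filters.
    """
    if filtered.window_ids != raw.window_ids or filtered.sample_ids != raw.sample_ids:
        raise ValueError("filtered and raw matrices must share windows and samples")
    f = filtered.counts.stack()
    r = raw.counts.stack()
    out = pd.DataFrame({"filtered": f, "raw": r})
    out["delta"] = out["raw"] - out["filtered"]
    out.index.names = ["window_id", "sample_id"]
    return out.reset_index()
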