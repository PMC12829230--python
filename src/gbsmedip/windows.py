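"""Window definition from concordant read-pair coordinates.

GBS-MeDIP libraries are built from PstI-digested, size-selected DNA, so
aligned fragments stack at fixed cut sites.  The counting unit is not a
gene model but a set of genomic windows derived from the data itself:
concordant read-pair intervals are merged, and merged intervals longer
than a cap are re-split into chunks close to the mean fragment length so
that no window grows beyond the resolution of the library.

Coordinates are 0-based half-open in memory; SAF files on disk use the
1-based inclusive convention expected by featureCounts-style tools.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Columns of a plain-text fragment table.
FRAGMENT_COLUMNS = ["chrom", "start", "end", "mapq", "proper_pair", "sample_id"]

SAF_COLUMNS = ["GeneID", "Chr", "Start", "End", "Strand"]


@dataclass(frozen=True)
class AlignedFragment:
    """One concordant read pair collapsed to its genomic span (0-based half-open).

    ``template_length`` is carried as reported by the aligner and is not
    required to equal ``end - start``.
    """

    chrom: str
    start: int
    end: int
    mapq: int
    proper_pair: bool
    sample_id: str
    template_length: int | None = None

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError("fragment start must be < end")
        if self.mapq < 0:
            raise ValueError("mapq must be >= 0")


def fragments_to_table(fragments) -> pd.DataFrame:
    """Build a fragment DataFrame from :class:`AlignedFragment` records."""
    return _validate_fragments(
        pd.DataFrame(
            [
                (f.chrom, f.start, f.end, f.mapq, f.proper_pair, f.sample_id)
                for f in fragments
            ],
            columns=FRAGMENT_COLUMNS,
        )
    )


@dataclass(frozen=True)
class GenomicWindow:
    """One counting window, 0-based half-open."""

    chrom: str
    start: int
    end: int
    window_id: str

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"window {self.window_id}: start must be < end")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class WindowSet:
    """Ordered, non-overlapping windows plus the mean fragment length used to build them.

    ``windows`` is a DataFrame with columns chrom, start, end, window_id,
    sorted by (chrom, start).
    """

    windows: pd.DataFrame
    mean_fragment_length: float | None = None

    def __post_init__(self) -> None:
        w = self.windows.reset_index(drop=True)
        required = ["chrom", "start", "end", "window_id"]
        missing = [c for c in required if c not in w.columns]
        if missing:
            raise ValueError(f"WindowSet missing columns {missing}")
        w = w[required].copy()
        w["start"] = w["start"].astype(np.int64)
        w["end"] = w["end"].astype(np.int64)
        if (w["start"] >= w["end"]).any():
            raise ValueError("window with start >= end")
        if w["window_id"].duplicated().any():
            dup = w.loc[w["window_id"].duplicated(), "window_id"].iloc[0]
            raise ValueError(f"duplicate window_id {dup!r}")
        w = w.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
        # non-overlap check within chromosome
        for _, grp in w.groupby("chrom", sort=False):
            if (grp["start"].to_numpy()[1:] < grp["end"].to_numpy()[:-1]).any():
                raise ValueError("overlapping windows in WindowSet")
        self.windows = w

    def __len__(self) -> int:
        return len(self.windows)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, WindowSet):
            return NotImplemented
        return self.windows.equals(other.windows)

    def iter_windows(self):
        for row in self.windows.itertuples(index=False):
            yield GenomicWindow(row.chrom, int(row.start), int(row.end), row.window_id)


def make_fragment_table(records) -> pd.DataFrame:
    """Coerce an iterable of (chrom, start, end, mapq, proper_pair, sample_id)
    tuples/dicts into a validated fragment DataFrame."""
    df = pd.DataFrame(list(records), columns=FRAGMENT_COLUMNS)
    return _validate_fragments(df)


def _validate_fragments(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in FRAGMENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"fragment table missing columns {missing}")
    out = df[list(df.columns)].copy()
    out["start"] = out["start"].astype(np.int64)
    out["end"] = out["end"].astype(np.int64)
    out["mapq"] = out["mapq"].astype(np.int64)
    out["proper_pair"] = out["proper_pair"].astype(bool)
    return out


def read_fragment_tsv(path) -> pd.DataFrame:
    """Read a plain-text fragment table (TSV with header).

    Expected columns: chrom, start, end, mapq, proper_pair, sample_id and
    optionally template_length.  ``proper_pair`` accepts 0/1 or True/False.
    """
    df = pd.read_csv(path, sep="\t")
    if "proper_pair" in df.columns and df["proper_pair"].dtype == object:
        df["proper_pair"] = df["proper_pair"].map(
            lambda v: str(v).strip().lower() in {"1", "true", "t", "yes"}
        )
    return _validate_fragments(df)


def write_fragment_tsv(fragments: pd.DataFrame, path) -> None:
    out = fragments.copy()
    out["proper_pair"] = out["proper_pair"].astype(int)
    out.to_csv(path, sep="\t", index=False)


def fragments_from_bam(path, sample_id: str | None = None) -> pd.DataFrame:
    """Extract one fragment per concordant read pair from a coordinate-sorted BAM.

    The fragment spans the leftmost mate start to that plus the absolute
    template length.  Secondary and supplementary alignments are skipped; no
    MAPQ filter is applied here (see :func:`extract_fragments`).
    """
    import pysam  # optional dependency, only needed for the BAM path

    rows = []
    label = sample_id
    with pysam.AlignmentFile(str(path), "rb") as bam:
        if label is None:
            label = next(iter(bam.header.get("RG", [{}])), {}).get("SM", "sample")
        for read in bam.fetch(until_eof=True):
            if read.is_secondary or read.is_supplementary or read.is_unmapped:
                continue
            if not read.is_read1:
                continue
            tlen = read.template_length
            proper = bool(read.is_proper_pair)
            start = min(read.reference_start, read.next_reference_position or read.reference_start)
            end = start + abs(tlen) if tlen else read.reference_end
            if end is None or end <= start:
                continue
            rows.append(
                {
                    "chrom": read.reference_name,
                    "start": start,
                    "end": end,
                    "mapq": read.mapping_quality,
                    "proper_pair": proper,
                    "sample_id": label,
                    "template_length": abs(tlen),
                }
            )
    return _validate_fragments(pd.DataFrame(rows, columns=FRAGMENT_COLUMNS + ["template_length"]))


def extract_fragments(fragments: pd.DataFrame, mapq_min: int = 10) -> pd.DataFrame:
    """Keep concordant (properly paired) fragments with MAPQ strictly above ``mapq_min``.

    Returns the filtered table; the number of records rejected for each
    reason is stored in ``result.attrs["rejects"]``.  An input with no
    concordant pairs at all yields an empty table and a warning.
    """
    df = _validate_fragments(fragments)
    malformed = (df["start"] >= df["end"]) | (df["mapq"] < 0)
    discordant = ~df["proper_pair"] & ~malformed
    low_mapq = (df["mapq"] <= mapq_min) & df["proper_pair"] & ~malformed
    keep = df["proper_pair"] & (df["mapq"] > mapq_min) & ~malformed
    out = df.loc[keep].reset_index(drop=True)
    out.attrs["rejects"] = {
        "malformed": int(malformed.sum()),
        "not_proper_pair": int(discordant.sum()),
        "low_mapq": int(low_mapq.sum()),
    }
    if len(df) and not df["proper_pair"].any():
        logger.warning("no concordant read pairs in input; returning empty fragment set")
    return out


def mean_fragment_length(fragments: pd.DataFrame) -> float:
    """Arithmetic mean of fragment lengths (end - start), over all fragments."""
    if len(fragments) == 0:
        raise ValueError("no fragments")
    return float((fragments["end"] - fragments["start"]).mean())


def _merge_intervals(starts: np.ndarray, ends: np.ndarray) -> list[tuple[int, int]]:
    """Merge sorted-by-start intervals; bookended intervals (end == next start) merge."""
    order = np.argsort(starts, kind="stable")
    starts, ends = starts[order], ends[order]
    merged: list[tuple[int, int]] = []
    cur_s, cur_e = int(starts[0]), int(ends[0])
    for s, e in zip(starts[1:], ends[1:]):
        if s <= cur_e:  # overlap or bookend
            cur_e = max(cur_e, int(e))
        else:
            merged.append((cur_s, cur_e))
            cur_s, cur_e = int(s), int(e)
    merged.append((cur_s, cur_e))
    return merged


def _split_interval(start: int, end: int, chunk: int, min_window: int) -> list[tuple[int, int]]:
    """Split [start, end) into consecutive chunks of ``chunk`` bp; a final
    remainder shorter than ``min_window`` is absorbed into the previous chunk."""
    pieces = [(s, min(s + chunk, end)) for s in range(start, end, chunk)]
    if len(pieces) > 1 and (pieces[-1][1] - pieces[-1][0]) < min_window:
        last = pieces.pop()
        prev = pieces.pop()
        pieces.append((prev[0], last[1]))
    return pieces


def define_windows(
    fragments: pd.DataFrame,
    max_window: int = 300,
    min_window: int = 20,
    mean_length: float | None = None,
) -> WindowSet:
    """Build the counting windows from concordant fragments.

    Per chromosome, fragment intervals are merged (overlapping or bookended
    intervals become one); merged intervals longer than ``max_window`` are
    re-split into consecutive chunks of ``round(mean fragment length)`` bp,
    with a sub-``min_window`` remainder folded into the preceding chunk.
    The mean length is computed over all input fragments before merging,
    strand ignored, unless given explicitly.
    """
    if len(fragments) == 0:
        raise ValueError("no fragments")
    mean_len = mean_fragment_length(fragments) if mean_length is None else float(mean_length)
    chunk = max(int(round(mean_len)), 1)
    rows = []
    for chrom in sorted(fragments["chrom"].unique()):
        sub = fragments.loc[fragments["chrom"] == chrom]
        for s, e in _merge_intervals(sub["start"].to_numpy(), sub["end"].to_numpy()):
            pieces = [(s, e)] if (e - s) <= max_window else _split_interval(s, e, chunk, min_window)
            for ps, pe in pieces:
                rows.append((chrom, ps, pe, f"{chrom}_{ps}_{pe}"))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "window_id"])
    return WindowSet(df, mean_fragment_length=mean_len)


def write_saf(window_set: WindowSet, path) -> None:
    """Write a SAF table (GeneID, Chr, Start, End, Strand; 1-based inclusive).

    The mean fragment length, when known, is preserved in a leading comment
    so that a round trip restores the full WindowSet.
    """
    w = window_set.windows
    with open(path, "w") as fh:
        if window_set.mean_fragment_length is not None:
            fh.write(f"# mean_fragment_length={window_set.mean_fragment_length!r}\n")
        fh.write("\t".join(SAF_COLUMNS) + "\n")
        for row in w.itertuples(index=False):
            fh.write(f"{row.window_id}\t{row.chrom}\t{row.start + 1}\t{row.end}\t+\n")


def read_saf(path) -> WindowSet:
    """Read a SAF table back into a WindowSet (coordinates converted to 0-based half-open)."""
    mean_len: float | None = None
    rows = []
    with open(path) as fh:
        lineno = 0
        header_seen = False
        for line in fh:
            lineno += 1
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                if "mean_fragment_length=" in line:
                    mean_len = float(line.split("=", 1)[1])
                continue
            fields = line.split("\t")
            if not header_seen:
                if fields[: len(SAF_COLUMNS)] != SAF_COLUMNS:
                    raise ValueError(f"malformed SAF header at line {lineno}: {line!r}")
                header_seen = True
                continue
            if len(fields) < 5:
                raise ValueError(f"malformed SAF line {lineno}: expected 5 fields, got {len(fields)}")
            gene_id, chrom, start, end, _strand = fields[:5]
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise ValueError(f"malformed SAF line {lineno}: non-integer coordinate") from exc
            rows.append((chrom, start_i - 1, end_i, gene_id))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "window_id"])
    return WindowSet(df, mean_fragment_length=mean_len)


def write_bed(window_set: WindowSet, path) -> None:
    """Write windows as BED4 (0-based half-open, as BED requires)."""
    with open(path, "w") as fh:
        for row in window_set.windows.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{row.window_id}\n")
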