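"""Genome tiling into fixed-width windows and per-sample read counting.

Coordinates are 0-based half-open throughout.  Reads are assigned to a
window by their 5' mapped start coordinate (configurable to midpoint);
strand is ignored.  The trailing partial window of each chromosome is
kept so every mapped read is countable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

__all__ = [
    "GenomeWindows",
    "WindowCountMatrix",
    "bin_reads",
    "count_reads",
    "filter_windows",
]


@dataclass(frozen=True)
class GenomeWindows:
    """Contiguous, non-overlapping tiling of a genome into fixed windows.

    Window starts are multiples of ``window_size``; the last window of a
    chromosome may be shorter (partial) when the chromosome length is not
    a multiple of the window size.
    """

    window_size: int
    chrom_names: tuple[str, ...]
    chrom_lengths: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.window_size <= 0:
            raise ValueError("window_size must be positive")
        if len(self.chrom_names) != len(self.chrom_lengths):
            raise ValueError("chrom_names and chrom_lengths length mismatch")
        if any(l <= 0 for l in self.chrom_lengths):
            raise ValueError("chromosome lengths must be positive")

    @property
    def windows_per_chrom(self) -> np.ndarray:
        return np.array(
            [-(-l // self.window_size) for l in self.chrom_lengths], dtype=np.int64
        )

    @property
    def offsets(self) -> np.ndarray:
        """Cumulative window-index offset of each chromosome."""
        return np.concatenate([[0], np.cumsum(self.windows_per_chrom)])

    @property
    def n_windows(self) -> int:
        return int(self.windows_per_chrom.sum())

    def chrom_index(self, chrom: str) -> int:
        try:
            return self.chrom_names.index(chrom)
        except ValueError:
            raise KeyError(f"unknown chromosome {chrom!r}") from None

    def locate(self, chrom: str, pos: int) -> int:
        """Global window index containing position ``pos`` on ``chrom``."""
        c = self.chrom_index(chrom)
        if not 0 <= pos < self.chrom_lengths[c]:
            raise ValueError(f"position {pos} outside {chrom}")
        return int(self.offsets[c]) + pos // self.window_size

    def coords(self, index: np.ndarray | int):
        """Map global window indices to (chrom_idx, start, end) arrays."""
        idx = np.atleast_1d(np.asarray(index, dtype=np.int64))
        offs = self.offsets
        ci = np.searchsorted(offs, idx, side="right") - 1
        local = idx - offs[ci]
        starts = local * self.window_size
        lens = np.asarray(self.chrom_lengths, dtype=np.int64)
        ends = np.minimum(starts + self.window_size, lens[ci])
        return ci, starts, ends

    def to_frame(self) -> pd.DataFrame:
        idx = np.arange(self.n_windows)
        ci, starts, ends = self.coords(idx)
        return pd.DataFrame(
            {
                "chrom": np.asarray(self.chrom_names, dtype=object)[ci],
                "start": starts,
                "end": ends,
            },
            index=idx,
        )


@dataclass
class WindowCountMatrix:
    """Integer read counts over genome windows (rows) per sample (columns)."""

    counts: np.ndarray
    samples: list[str]
    groups: list[str]
    windows: GenomeWindows
    library_sizes: np.ndarray
    window_index: np.ndarray = field(default=None)  # type: ignore[assignment]
    generation: str = ""

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be 2-D (windows x samples)")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        n_w, n_s = self.counts.shape
        if len(self.samples) != n_s or len(self.groups) != n_s:
            raise ValueError("sample/group labels must match column count")
        self.library_sizes = np.asarray(self.library_sizes, dtype=np.int64)
        if self.library_sizes.shape != (n_s,):
            raise ValueError("library_sizes must have one entry per sample")
        if self.window_index is None:
            self.window_index = np.arange(n_w, dtype=np.int64)
        else:
            self.window_index = np.asarray(self.window_index, dtype=np.int64)
        if self.window_index.shape != (n_w,):
            raise ValueError("window_index must have one entry per row")

    @property
    def n_windows(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def group_mask(self, group: str) -> np.ndarray:
        return np.array([g == group for g in self.groups], dtype=bool)

    def to_frame(self) -> pd.DataFrame:
        ci, starts, ends = self.windows.coords(self.window_index)
        names = np.asarray(self.windows.chrom_names, dtype=object)[ci]
        df = pd.DataFrame({"chrom": names, "start": starts, "end": ends})
        for j, s in enumerate(self.samples):
            df[s] = self.counts[:, j]
        return df

    def write_tsv(self, path: str | Path) -> None:
        df = self.to_frame()
        header = pd.DataFrame(
            [["#group", "", ""] + self.groups], columns=df.columns
        )
        with open(path, "w") as fh:
            header.to_csv(fh, sep="\t", index=False, header=False)
            df.to_csv(fh, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path, windows: GenomeWindows) -> "WindowCountMatrix":
        with open(path) as fh:
            first = fh.readline().rstrip("\n").split("\t")
            if first[0] != "#group":
                raise ValueError("count matrix TSV must start with a #group line")
            groups = first[3:]
            df = pd.read_csv(fh, sep="\t")
        samples = list(df.columns[3:])
        counts = df[samples].to_numpy(dtype=np.int64)
        idx = np.array(
            [windows.locate(c, s) for c, s in zip(df["chrom"], df["start"])],
            dtype=np.int64,
        )
        return cls(
            counts=counts,
            samples=samples,
            groups=groups,
            windows=windows,
            library_sizes=counts.sum(axis=0),
            window_index=idx,
        )


def _read_starts_bed(path: str | Path, assign: str) -> pd.DataFrame:
    if not _nonempty(path):
        return pd.DataFrame({"chrom": [], "pos": []})
    raw = pd.read_csv(
        path, sep="\t", header=None, comment="#", dtype=str, skip_blank_lines=True
    )
    if raw.shape[1] < 3:
        raise ValueError(f"{path}: BED needs at least 3 columns")
    cols = raw.iloc[:, :3]
    cols.columns = ["chrom", "start", "end"]
    start = pd.to_numeric(cols["start"], errors="coerce")
    end = pd.to_numeric(cols["end"], errors="coerce")
    bad = start.isna() | end.isna()
    if bad.any():
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 1
        raise ValueError(f"{path}: malformed BED record at line {line}")
    pos = start if assign == "start" else (start + end) // 2
    return pd.DataFrame({"chrom": cols["chrom"], "pos": pos.astype(np.int64)})


def _nonempty(path: str | Path) -> bool:
    return Path(path).stat().st_size > 0


def _read_starts_sam(path: str | Path, assign: str) -> pd.DataFrame:
    chroms: list[str] = []
    poss: list[int] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped:
                continue
            if assign == "start":
                p = rec.reference_start
            else:
                p = (rec.reference_start + rec.reference_end) // 2
            chroms.append(rec.reference_name)
            poss.append(p)
    return pd.DataFrame({"chrom": chroms, "pos": np.array(poss, dtype=np.int64)})


def count_reads(
    path: str | Path,
    genome_windows: GenomeWindows,
    assign: str = "start",
) -> tuple[np.ndarray, int]:
    """Count reads of one BED/SAM file into windows.

    Returns (counts vector over all windows, number of skipped reads).
    Reads on chromosomes absent from ``genome_windows`` are skipped with
    a warning.
    """
    if assign not in ("start", "midpoint"):
        raise ValueError("assign must be 'start' or 'midpoint'")
    suffix = Path(path).suffix.lower()
    if suffix == ".sam":
        df = _read_starts_sam(path, assign)
    else:
        df = _read_starts_bed(path, assign)
    counts = np.zeros(genome_windows.n_windows, dtype=np.int64)
    skipped = 0
    if len(df) == 0:
        return counts, skipped
    name_to_idx = {n: i for i, n in enumerate(genome_windows.chrom_names)}
    ci = df["chrom"].map(name_to_idx)
    known = ci.notna().to_numpy()
    skipped = int((~known).sum())
    if skipped:
        warnings.warn(
            f"{path}: skipped {skipped} reads on unknown chromosomes", stacklevel=2
        )
    ci = ci[known].to_numpy(dtype=np.int64)
    pos = df["pos"].to_numpy()[known]
    lens = np.asarray(genome_windows.chrom_lengths, dtype=np.int64)
    inside = (pos >= 0) & (pos < lens[ci])
    if not inside.all():
        n_out = int((~inside).sum())
        skipped += n_out
        warnings.warn(f"{path}: skipped {n_out} reads outside chromosome bounds",
                      stacklevel=2)
        ci, pos = ci[inside], pos[inside]
    gidx = genome_windows.offsets[ci] + pos // genome_windows.window_size
    np.add.at(counts, gidx, 1)
    return counts, skipped


def bin_reads(
    read_files: Mapping[str, str | Path],
    groups: Mapping[str, str] | Sequence[str],
    genome_windows: GenomeWindows,
    assign: str = "start",
    generation: str = "",
) -> WindowCountMatrix:
    """Bin one read file per sample into a :class:`WindowCountMatrix`.

    ``groups`` maps sample name -> group label (or is a sequence aligned
    with the mapping order of ``read_files``).
    """
    samples = list(read_files)
    if isinstance(groups, Mapping):
        group_list = [groups[s] for s in samples]
    else:
        group_list = list(groups)
    cols = []
    for s in samples:
        c, _ = count_reads(read_files[s], genome_windows, assign=assign)
        cols.append(c)
    counts = np.stack(cols, axis=1)
    return WindowCountMatrix(
        counts=counts,
        samples=samples,
        groups=group_list,
        windows=genome_windows,
        library_sizes=counts.sum(axis=0),
        generation=generation,
    )


def filter_windows(matrix: WindowCountMatrix, min_total: int = 10) -> WindowCountMatrix:
    """Keep windows with total count across samples >= ``min_total``.

    The returned matrix's ``window_index`` maps rows back to genome
    coordinates, so downstream region calling stays coordinate-aware.
    """
    if min_total < 0:
        raise ValueError("min_total must be >= 0")
    keep = matrix.counts.sum(axis=1) >= min_total
    return replace(
        matrix,
        counts=matrix.counts[keep],
        window_index=matrix.window_index[keep],
        library_sizes=matrix.library_sizes,
    )
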