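"""Reference window grid: overlapping sliding windows with GC and gap content.

The genome is tiled with windows of a fixed size whose step is half the
window size, so every base (except the chromosome ends) is covered by two
windows. Windows are enumerated over *all* sequences, including unplaced
scaffolds, in reference order. Windows with more than 50% gap bases (N/n)
are dropped from the grid, but their indices are never reused: the index
space is the pre-filter enumeration, which keeps the duplicated-window
record and per-sample depth vectors aligned no matter how gappy the
assembly is.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Union

import numpy as np

GAP_MAX_FRACTION = 0.5

ReferenceLike = Union[str, Path, Mapping[str, str]]


def load_sequences(reference: ReferenceLike) -> dict[str, str]:
    """Return chromosome sequences in reference order.

    ``reference`` may be a FASTA path or an already-loaded mapping
    ``{name: sequence}`` (the simulator hands sequences around in memory).
    """
    if isinstance(reference, Mapping):
        return dict(reference)
    from pyfaidx import Fasta

    fa = Fasta(str(reference), as_raw=True, rebuild=True)
    seqs = {name: str(fa[name][:]) for name in fa.keys()}
    fa.close()
    if not seqs:
        raise ValueError(f"reference {reference} contains no sequences")
    return seqs


def compute_gc(sequence: str) -> float:
    """GC fraction (G+C)/(A+C+G+T) of a sequence, ignoring N bases.

    Returns ``nan`` when the sequence contains no A/C/G/T at all.
    """
    if not sequence:
        raise ValueError("sequence must be non-empty")
    arr = np.frombuffer(sequence.upper().encode("ascii"), dtype=np.uint8)
    gc = int(np.count_nonzero((arr == ord("G")) | (arr == ord("C"))))
    at = int(np.count_nonzero((arr == ord("A")) | (arr == ord("T"))))
    denom = gc + at
    if denom == 0:
        return float("nan")
    return gc / denom


@dataclass
class WindowGrid:
    """Retained sliding windows of one reference, 0-based half-open.

    ``index`` holds each retained window's position in the pre-filter
    enumeration (all windows of all chromosomes, in reference order);
    ``start``/``chrom_id`` etc. are aligned arrays over retained windows
    only.
    """

    window_size: int
    step: int
    chroms: list[str]
    chrom_lengths: dict[str, int]
    index: np.ndarray
    chrom_id: np.ndarray
    start: np.ndarray
    gc: np.ndarray
    gap: np.ndarray
    _row_of: dict[int, int] | None = field(default=None, repr=False, compare=False)

    @property
    def n_windows(self) -> int:
        return len(self.index)

    @property
    def end(self) -> np.ndarray:
        return self.start + self.window_size

    def chrom_name(self, row: int) -> str:
        return self.chroms[int(self.chrom_id[row])]

    def prefilter_layout(self) -> tuple[dict[str, int], dict[str, int]]:
        """(offset, count) of the pre-filter window enumeration per chrom."""
        offsets: dict[str, int] = {}
        counts: dict[str, int] = {}
        off = 0
        for c in self.chroms:
            L = self.chrom_lengths[c]
            n = (L - self.window_size) // self.step + 1 if L >= self.window_size else 0
            offsets[c] = off
            counts[c] = n
            off += n
        return offsets, counts

    @property
    def row_of(self) -> dict[int, int]:
        """Map pre-filter window index -> row in the retained arrays."""
        if self._row_of is None:
            self._row_of = {int(gi): r for r, gi in enumerate(self.index)}
        return self._row_of

    def rows_of_chrom(self, name: str) -> np.ndarray:
        if name not in self.chrom_lengths:
            raise KeyError(
                f"chromosome {name!r} not in grid; available: {', '.join(self.chroms)}"
            )
        cid = self.chroms.index(name)
        return np.flatnonzero(self.chrom_id == cid)

    def same_layout(self, other: "WindowGrid") -> bool:
        return (
            self.window_size == other.window_size
            and self.chroms == other.chroms
            and np.array_equal(self.index, other.index)
        )


def build_window_grid(reference: ReferenceLike, window_size: int) -> WindowGrid:
    """Tile a reference with half-overlapping sliding windows.

    Trailing partial windows are dropped; windows with gap fraction > 0.5
    are filtered out but keep their slot in the index space.
    """
    if window_size < 2 or window_size % 2 != 0:
        raise ValueError(
            "window_size must be an even integer >= 2 so that the step "
            "(window_size / 2) is integral"
        )
    step = window_size // 2
    seqs = load_sequences(reference)
    if not seqs or all(len(s) == 0 for s in seqs.values()):
        raise ValueError("reference is empty")

    chroms = list(seqs)
    chrom_lengths = {c: len(seqs[c]) for c in chroms}
    idx_parts, cid_parts, start_parts, gc_parts, gap_parts = [], [], [], [], []
    offset = 0
    for ci, c in enumerate(chroms):
        arr = np.frombuffer(seqs[c].upper().encode("ascii"), dtype=np.uint8)
        L = len(arr)
        n_pre = (L - window_size) // step + 1 if L >= window_size else 0
        if n_pre == 0:
            continue
        is_n = (arr == ord("N")).astype(np.int64)
        is_gc = ((arr == ord("G")) | (arr == ord("C"))).astype(np.int64)
        is_at = ((arr == ord("A")) | (arr == ord("T"))).astype(np.int64)
        cn = np.concatenate([[0], np.cumsum(is_n)])
        cgc = np.concatenate([[0], np.cumsum(is_gc)])
        cat = np.concatenate([[0], np.cumsum(is_at)])
        starts = np.arange(n_pre, dtype=np.int64) * step
        ends = starts + window_size
        ncount = cn[ends] - cn[starts]
        gccount = cgc[ends] - cgc[starts]
        atcount = cat[ends] - cat[starts]
        gap_frac = ncount / window_size
        denom = gccount + atcount
        with np.errstate(invalid="ignore", divide="ignore"):
            gc_frac = np.where(denom > 0, gccount / np.maximum(denom, 1), np.nan)
        keep = gap_frac <= GAP_MAX_FRACTION
        idx_parts.append(offset + np.flatnonzero(keep))
        cid_parts.append(np.full(int(keep.sum()), ci, dtype=np.int32))
        start_parts.append(starts[keep])
        gc_parts.append(gc_frac[keep])
        gap_parts.append(gap_frac[keep])
        offset += n_pre

    def _cat(parts, dtype):
        if not parts:
            return np.empty(0, dtype=dtype)
        return np.concatenate(parts).astype(dtype)

    return WindowGrid(
        window_size=window_size,
        step=step,
        chroms=chroms,
        chrom_lengths=chrom_lengths,
        index=_cat(idx_parts, np.int64),
        chrom_id=_cat(cid_parts, np.int32),
        start=_cat(start_parts, np.int64),
        gc=_cat(gc_parts, np.float64),
        gap=_cat(gap_parts, np.float64),
    )


def write_grid(grid: WindowGrid, path: str | Path) -> None:
    """Serialize a grid to the tab-separated window-grid file."""
    with open(path, "w") as fh:
        fh.write(f"#window_size={grid.window_size}\tstep={grid.step}\n")
        lengths = ",".join(f"{c}:{grid.chrom_lengths[c]}" for c in grid.chroms)
        fh.write(f"#chroms={lengths}\n")
        fh.write("index\tchrom\tstart\tend\tgc\tgap\n")
        for r in range(grid.n_windows):
            fh.write(
                f"{grid.index[r]}\t{grid.chrom_name(r)}\t{grid.start[r]}\t"
                f"{grid.start[r] + grid.window_size}\t{grid.gc[r]:.6f}\t"
                f"{grid.gap[r]:.6f}\n"
            )


def read_grid(path: str | Path) -> WindowGrid:
    with open(path) as fh:
        header1 = fh.readline().strip()
        header2 = fh.readline().strip()
        if not header1.startswith("#window_size=") or not header2.startswith("#chroms="):
            raise ValueError(f"{path}: not a window-grid file (bad header)")
        fields = dict(kv.split("=", 1) for kv in header1[1:].split("\t"))
        window_size = int(fields["window_size"])
        chrom_lengths: dict[str, int] = {}
        for item in header2[len("#chroms="):].split(","):
            name, L = item.rsplit(":", 1)
            chrom_lengths[name] = int(L)
        chroms = list(chrom_lengths)
        body = fh.read()
    import pandas as pd

    df = pd.read_csv(io.StringIO(body), sep="\t")
    cid = np.array([chroms.index(c) for c in df["chrom"]], dtype=np.int32)
    return WindowGrid(
        window_size=window_size,
        step=window_size // 2,
        chroms=chroms,
        chrom_lengths=chrom_lengths,
        index=df["index"].to_numpy(np.int64),
        chrom_id=cid,
        start=df["start"].to_numpy(np.int64),
        gc=df["gc"].to_numpy(np.float64),
        gap=df["gap"].to_numpy(np.float64),
    )
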