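"""Duplicated-window record: linking windows of near-identical sequence.

Segmental duplications make reads multi-map, smearing read depth across all
copies of a repeat. To undo that, windows whose sequence is highly similar
(default >=97% identity) are linked together so their raw depths can later
be summed into an absolute copy-number signal.

The record is built from *nonoverlapping* windows: each window's sequence
is searched against the whole reference with an exact k-mer seed (k=16)
followed by gap-free full-window identity scoring, a deterministic
desk-scale analogue of running a precise aligner. Hits are mapped to the
nearest nonoverlapping window. Windows with more than ``max_hits`` hits are
treated as low-complexity and left uncorrected (self-only link). The
nonoverlapping links are then projected onto the overlapping analysis grid
by mapping each grid window to the nonoverlapping windows it intersects and
shifting partner coordinates accordingly.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .windows import ReferenceLike, WindowGrid, build_window_grid, load_sequences

SEED_KMER = 16


@dataclass
class DupWindowRecord:
    """Partner lists per retained grid window, in pre-filter index space."""

    links: dict[int, tuple[int, ...]]
    window_size: int
    similarity_threshold: float = 0.97
    max_hits: int = 20

    def partners(self, gi: int) -> tuple[int, ...]:
        return self.links.get(int(gi), (int(gi),))


def find_similar_windows(
    reference: ReferenceLike,
    window_size: int,
    similarity_threshold: float = 0.97,
    max_hits: int = 20,
    k: int = SEED_KMER,
) -> dict[tuple[int, int], tuple[tuple[int, int], ...]]:
    """Similarity links between nonoverlapping windows.

    Returns ``{(chrom_idx, win_idx): ((chrom_idx, win_idx), ...)}`` where
    ``win_idx`` enumerates nonoverlapping windows of size ``window_size``
    per chromosome. Every window links at least to itself.
    """
    if not (0 < similarity_threshold <= 1):
        raise ValueError("similarity_threshold must be in (0, 1]")
    if max_hits < 1:
        raise ValueError("max_hits must be >= 1")
    seqs = load_sequences(reference)
    chroms = list(seqs)
    arrs = {
        ci: np.frombuffer(seqs[c].upper().encode("ascii"), dtype=np.uint8)
        for ci, c in enumerate(chroms)
    }
    raws = {ci: a.tobytes() for ci, a in arrs.items()}
    ws = window_size
    stride = max(1, k // 2)
    # genome-wide seed index; a shared exact k-mer guarantees a candidate
    # whenever an identical stretch of >= 2k-1 bases exists
    kindex: dict[bytes, list[tuple[int, int]]] = {}
    for ci in arrs:
        b = raws[ci]
        for p in range(0, len(b) - k + 1, stride):
            km = b[p : p + k]
            if b"N" in km:
                continue
            kindex.setdefault(km, []).append((ci, p))

    candidate_cap = 20 * max_hits
    links: dict[tuple[int, int], tuple[tuple[int, int], ...]] = {}
    for ci in arrs:
        b = raws[ci]
        n_win = len(b) // ws
        for m in range(n_win):
            s = m * ws
            wbytes = b[s : s + ws]
            warr = arrs[ci][s : s + ws]
            cands: set[tuple[int, int]] = set()
            overflow = False
            for off in range(0, ws - k + 1):
                hitlist = kindex.get(wbytes[off : off + k])
                if not hitlist:
                    continue
                for cj, p in hitlist:
                    cands.add((cj, p - off))
                if len(cands) > candidate_cap:
                    overflow = True
                    break
            partners: set[tuple[int, int]] = set()
            if not overflow:
                for cj, g in cands:
                    if g < 0 or g + ws > len(arrs[cj]):
                        continue
                    ident = np.count_nonzero(warr == arrs[cj][g : g + ws]) / ws
                    if ident >= similarity_threshold:
                        # nearest nonoverlapping window (half-up rounding)
                        mj = int((g + ws // 2) // ws)
                        mj = min(max(mj, 0), len(arrs[cj]) // ws - 1)
                        if len(arrs[cj]) // ws > 0:
                            partners.add((cj, mj))
            if overflow or len(partners) > max_hits:
                partners = {(ci, m)}
            partners.add((ci, m))
            links[(ci, m)] = tuple(sorted(partners))
    return links


def build_dup_record(
    reference: ReferenceLike,
    window_size: int,
    similarity_threshold: float = 0.97,
    max_hits: int = 20,
    grid: WindowGrid | None = None,
    k: int = SEED_KMER,
) -> DupWindowRecord:
    """Build the duplicated-window record projected onto the analysis grid."""
    seqs = load_sequences(reference)
    if grid is None:
        grid = build_window_grid(seqs, window_size)
    elif grid.window_size != window_size:
        raise ValueError(
            f"window_size mismatch: grid has {grid.window_size}, requested {window_size}"
        )
    nl = find_similar_windows(seqs, window_size, similarity_threshold, max_hits, k=k)
    ws = window_size
    step = grid.step
    offsets, counts = grid.prefilter_layout()
    chrom_off = [offsets[c] for c in grid.chroms]
    chrom_cnt = [counts[c] for c in grid.chroms]
    chrom_len = [grid.chrom_lengths[c] for c in grid.chroms]
    n_nonov = [L // ws for L in chrom_len]
    row_of = grid.row_of

    links: dict[int, tuple[int, ...]] = {}
    for r in range(grid.n_windows):
        gi = int(grid.index[r])
        ci = int(grid.chrom_id[r])
        s = int(grid.start[r])
        partners = {gi}
        parents = [s // ws]
        if s % ws:
            parents.append(s // ws + 1)
        for kp in parents:
            if kp >= n_nonov[ci]:
                continue
            for cj, mj in nl.get((ci, kp), ()):
                if (cj, mj) == (ci, kp):
                    continue
                pstart = mj * ws + (s - kp * ws)
                if pstart < 0 or pstart + ws > chrom_len[cj]:
                    continue
                pgi = chrom_off[cj] + pstart // step
                if pgi in row_of:
                    partners.add(pgi)
        if len(partners) > max_hits:
            partners = {gi}
        links[gi] = tuple(sorted(partners))
    return DupWindowRecord(
        links=links,
        window_size=window_size,
        similarity_threshold=similarity_threshold,
        max_hits=max_hits,
    )


def save_dup_record(record: DupWindowRecord, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            f"#window_size={record.window_size}\t"
            f"threshold={record.similarity_threshold}\t"
            f"max_hits={record.max_hits}\n"
        )
        for gi in sorted(record.links):
            fh.write(f"{gi}\t{';'.join(str(j) for j in record.links[gi])}\n")


def load_dup_record(path: str | Path, grid: WindowGrid | None = None) -> DupWindowRecord:
    """Load a record file; validates indices against ``grid`` when given."""
    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith("#window_size="):
            raise ValueError(f"{path}:1: not a duplicated-window record file")
        fields = dict(kv.split("=", 1) for kv in header[1:].split("\t"))
        window_size = int(fields["window_size"])
        threshold = float(fields.get("threshold", 0.97))
        max_hits = int(fields.get("max_hits", 20))
        if grid is not None and grid.window_size != window_size:
            raise ValueError(
                f"window_size mismatch: record has {window_size}, "
                f"grid has {grid.window_size}"
            )
        valid = grid.row_of if grid is not None else None
        links: dict[int, tuple[int, ...]] = {}
        for lineno, line in enumerate(fh, start=2):
            line = line.strip()
            if not line:
                continue
            try:
                gi_s, rest = line.split("\t")
                gi = int(gi_s)
                partners = tuple(sorted({int(x) for x in rest.split(";")} | {gi}))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed record line") from exc
            if valid is not None:
                bad = [j for j in partners if j not in valid]
                if bad:
                    raise ValueError(
                        f"{path}:{lineno}: window index {bad[0]} not in grid"
                    )
            links[gi] = partners
    if not links and grid is not None:
        links = {int(gi): (int(gi),) for gi in grid.index}
    return DupWindowRecord(
        links=links,
        window_size=window_size,
        similarity_threshold=threshold,
        max_hits=max_hits,
    )
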