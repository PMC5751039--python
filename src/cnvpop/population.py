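"""Population-level CNV window selection and CNVR assembly.

Normalized per-sample profiles are stacked into a samples x windows
matrix. Each sample x window cell is flagged against two criteria at once:
a per-sample statistical criterion (beyond mean +/- 2*STDEV of that
sample's genome-wide normalized depth) and an empirical criterion on the
expected depth of heterozygous events (0.65 / 1.35 for outbred cohorts;
0.25 / 1.75 for strictly self-bred ones). Windows carried by enough of the
population (allele frequency >= 0.05 or >= 2 homozygous individuals) become
candidates; runs of candidates, tolerating one unselected window per four
consecutive positions, become initial CNVR calls; nearby calls whose
per-sample depths correlate are merged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .individual import SampleDepthProfile
from .windows import WindowGrid

# flag codes
NORMAL, HET_LOSS, HOM_LOSS, HET_GAIN, HOM_GAIN = 0, -1, -2, 1, 2

# empirical normalized-depth bounds (loss, gain)
EMPIRICAL_BOUNDS = {"outbred": (0.65, 1.35), "selfbred": (0.25, 1.75)}
HOM_BOUNDS = (0.25, 1.75)


@dataclass
class PopulationDepthMatrix:
    sample_ids: list[str]
    depths: np.ndarray  # (n_samples, n_windows)
    grid: WindowGrid
    sample_mean: np.ndarray
    sample_std: np.ndarray
    flags: np.ndarray | None = None  # int8, same shape as depths
    mode: str = "outbred"
    candidate_mask: np.ndarray | None = None
    window_af: np.ndarray | None = None

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)


@dataclass
class CNVRCall:
    """A merged copy-number-variable region."""

    chrom: str
    start: int
    end: int
    member_rows: list[int]  # candidate member windows (grid rows)
    type: str  # loss / gain / mixed
    sample_depths: np.ndarray  # per-sample median depth over member windows
    af: float
    provenance: list[str] = field(default_factory=list)
    id: str = ""

    @property
    def n_windows(self) -> int:
        return len(self.member_rows)

    @property
    def length(self) -> int:
        return self.end - self.start


def assemble_matrix(
    profiles: list[SampleDepthProfile], grid: WindowGrid
) -> PopulationDepthMatrix:
    """Stack normalized profiles into a samples x windows matrix."""
    if len(profiles) < 2:
        raise ValueError("population assembly needs at least 2 samples")
    rows = []
    for p in profiles:
        if p.stage != "normalized":
            raise ValueError(f"sample {p.sample_id}: profile stage is {p.stage}, not normalized")
        if p.window_size != grid.window_size or len(p.depths) != grid.n_windows:
            raise ValueError(
                f"sample {p.sample_id}: profile does not match the grid "
                f"(window_size {p.window_size}, {len(p.depths)} windows)"
            )
        rows.append(p.depths)
    depths = np.vstack(rows)
    return PopulationDepthMatrix(
        sample_ids=[p.sample_id for p in profiles],
        depths=depths,
        grid=grid,
        sample_mean=depths.mean(axis=1),
        sample_std=depths.std(axis=1, ddof=0),
    )


def flag_individual_candidates(
    matrix: PopulationDepthMatrix, mode: str = "outbred"
) -> np.ndarray:
    """Flag each sample x window cell as normal / het / hom loss / gain."""
    if mode not in EMPIRICAL_BOUNDS:
        raise ValueError(f"mode must be one of {sorted(EMPIRICAL_BOUNDS)}")
    lo_emp, hi_emp = EMPIRICAL_BOUNDS[mode]
    hom_lo, hom_hi = HOM_BOUNDS
    d = matrix.depths
    mean = matrix.sample_mean[:, None]
    std = matrix.sample_std[:, None]
    stat_lo = d < mean - 2 * std
    stat_hi = d > mean + 2 * std
    flags = np.zeros(d.shape, dtype=np.int8)
    if mode == "outbred":
        flags[stat_lo & (d < lo_emp)] = HET_LOSS
        flags[stat_hi & (d > hi_emp)] = HET_GAIN
        flags[d < hom_lo] = HOM_LOSS
        flags[d > hom_hi] = HOM_GAIN
    else:  # selfbred: both criteria at the homozygous empirical bounds
        flags[stat_lo & (d < lo_emp)] = HOM_LOSS
        flags[stat_hi & (d > hi_emp)] = HOM_GAIN
    matrix.flags = flags
    matrix.mode = mode
    return flags


def window_allele_frequency(flags_col: np.ndarray) -> float:
    """Alternative-allele frequency from one window's flag column.

    Diploid bookkeeping: AF = (#het + 2*#hom) / (2*N), pooling loss and
    gain carriers.
    """
    n = len(flags_col)
    n_het = int(np.count_nonzero((flags_col == HET_LOSS) | (flags_col == HET_GAIN)))
    n_hom = int(np.count_nonzero((flags_col == HOM_LOSS) | (flags_col == HOM_GAIN)))
    return (n_het + 2 * n_hom) / (2 * n)


def select_population_windows(
    matrix: PopulationDepthMatrix,
    min_af: float = 0.05,
    min_hom: int = 2,
    keep_all_het: bool = False,
) -> np.ndarray:
    """Select candidate CNV windows supported by the population."""
    if matrix.flags is None:
        raise ValueError("flags not computed; run flag_individual_candidates first")
    f = matrix.flags
    n = matrix.n_samples
    n_het = np.count_nonzero((f == HET_LOSS) | (f == HET_GAIN), axis=0)
    n_hom = np.count_nonzero((f == HOM_LOSS) | (f == HOM_GAIN), axis=0)
    af = (n_het + 2 * n_hom) / (2 * n)
    if keep_all_het:
        selected = (n_het + n_hom) >= 1
    else:
        selected = (af >= min_af) | (n_hom >= min_hom)
    matrix.candidate_mask = selected
    matrix.window_af = af
    return selected


def adjacent_correlation(
    matrix: PopulationDepthMatrix, window_a: int, window_b: int
) -> tuple[float, float]:
    """Pearson correlation of two windows' depth columns and its p-value.

    The p-value comes from the Student t statistic t = r*sqrt(n-2)/sqrt(1-r^2)
    with n-2 degrees of freedom (two-sided). Zero-variance columns yield an
    undefined r, reported as (nan, 1.0) — never significant.
    """
    n = matrix.n_samples
    if n < 4:
        raise ValueError("correlation test needs at least 4 samples (df = n - 2 >= 2)")
    a = matrix.depths[:, window_a]
    b = matrix.depths[:, window_b]
    if np.std(a) == 0 or np.std(b) == 0:
        return float("nan"), 1.0
    r, p = stats.pearsonr(a, b)
    return float(r), float(p)


def _region_af(matrix: PopulationDepthMatrix, member_rows: list[int]) -> float:
    lo_emp, hi_emp = EMPIRICAL_BOUNDS[matrix.mode]
    hom_lo, hom_hi = HOM_BOUNDS
    d = np.median(matrix.depths[:, member_rows], axis=1)
    n_hom = int(np.count_nonzero((d < hom_lo) | (d > hom_hi)))
    n_het = int(
        np.count_nonzero(((d < lo_emp) & (d >= hom_lo)) | ((d > hi_emp) & (d <= hom_hi)))
    )
    if matrix.mode == "selfbred":
        n_het = 0
    return (n_het + 2 * n_hom) / (2 * matrix.n_samples)


def _call_from_members(
    matrix: PopulationDepthMatrix, member_rows: list[int], provenance: list[str]
) -> CNVRCall:
    grid = matrix.grid
    first, last = member_rows[0], member_rows[-1]
    has_loss = bool(np.any(matrix.flags[:, member_rows] < 0))
    has_gain = bool(np.any(matrix.flags[:, member_rows] > 0))
    if has_loss and has_gain:
        kind = "mixed"
    elif has_gain:
        kind = "gain"
    else:
        kind = "loss"
    return CNVRCall(
        chrom=grid.chrom_name(first),
        start=int(grid.start[first]),
        end=int(grid.start[last] + grid.window_size),
        member_rows=list(member_rows),
        type=kind,
        sample_depths=np.median(matrix.depths[:, member_rows], axis=1),
        af=_region_af(matrix, member_rows),
        provenance=provenance,
    )


def define_cnvrs(
    matrix: PopulationDepthMatrix,
    candidates: np.ndarray | None = None,
    min_run: int = 5,
) -> list[CNVRCall]:
    """Assemble candidate windows into initial CNVR calls.

    A call is a run of >= ``min_run`` consecutive grid positions that are
    candidates, tolerating at most one non-candidate window in any four
    consecutive positions; tolerated windows are excluded from the region's
    member windows (and hence from its depth). Runs never start or end on a
    tolerated window. Windows dropped by the gap filter count as
    non-candidates for the tolerance rule but can never be members.
    """
    if candidates is None:
        candidates = matrix.candidate_mask
    if candidates is None:
        raise ValueError("no candidate window set; run select_population_windows first")
    grid = matrix.grid
    offsets, counts = grid.prefilter_layout()
    calls: list[CNVRCall] = []
    for chrom in grid.chroms:
        off, n_pre = offsets[chrom], counts[chrom]
        if n_pre == 0:
            continue
        # 2 = candidate, 1 = retained non-candidate, 0 = gap-dropped
        status = np.zeros(n_pre, dtype=np.int8)
        rows = grid.rows_of_chrom(chrom)
        local = grid.index[rows] - off
        status[local] = 1
        status[local[candidates[rows]]] = 2
        row_at = {int(li): int(r) for li, r in zip(local, rows)}
        i = 0
        while i < n_pre:
            if status[i] != 2:
                i += 1
                continue
            kinds = ["C"]
            j = i + 1
            while j < n_pre:
                if status[j] == 2:
                    kinds.append("C")
                    j += 1
                elif (
                    j + 1 < n_pre
                    and status[j + 1] == 2
                    and "S" not in kinds[-3:]
                ):
                    kinds.append("S")
                    j += 1
                else:
                    break
            if len(kinds) >= min_run:
                members = [
                    row_at[i + k] for k, kind in enumerate(kinds) if kind == "C"
                ]
                call = _call_from_members(matrix, members, provenance=[])
                call.provenance = [f"init:{call.chrom}:{call.start}-{call.end}"]
                calls.append(call)
            i = j
    for k, c in enumerate(calls):
        c.id = f"cnvr_{k:05d}"
    return calls


def merge_adjacent_cnvrs(
    calls: list[CNVRCall],
    matrix: PopulationDepthMatrix,
    max_gap_frac: float = 0.2,
    p_thresh: float = 0.01,
) -> list[CNVRCall]:
    """Merge nearby same-chromosome calls with correlated depths.

    Two adjacent calls merge when the gap between them is less than
    ``max_gap_frac`` of their combined length AND the Pearson correlation
    of their per-sample region depths is positive and significant at
    ``p_thresh``. The sweep is strictly left-to-right and repeated until no
    merge fires.
    """
    n = matrix.n_samples
    calls = sorted(calls, key=lambda c: (matrix.grid.chroms.index(c.chrom), c.start))

    def _correlated(a: CNVRCall, b: CNVRCall) -> bool:
        if n < 4:
            return False
        x, y = a.sample_depths, b.sample_depths
        if np.std(x) == 0 or np.std(y) == 0:
            return False
        r, p = stats.pearsonr(x, y)
        return r > 0 and p < p_thresh

    changed = True
    while changed:
        changed = False
        out: list[CNVRCall] = []
        for c in calls:
            if out:
                prev = out[-1]
                if prev.chrom == c.chrom:
                    gap = max(0, c.start - prev.end)
                    if gap < max_gap_frac * (prev.length + c.length) and _correlated(
                        prev, c
                    ):
                        members = sorted(set(prev.member_rows) | set(c.member_rows))
                        merged = _call_from_members(
                            matrix, members, prev.provenance + c.provenance
                        )
                        merged.id = prev.id
                        out[-1] = merged
                        changed = True
                        continue
            out.append(c)
        calls = out
    for k, c in enumerate(calls):
        c.id = f"cnvr_{k:05d}"
    return calls


def write_cnvr_table(calls: list[CNVRCall], matrix: PopulationDepthMatrix, path) -> None:
    """BED-like CNVR table plus the per-sample region-depth columns."""
    with open(path, "w") as fh:
        cols = "\t".join(matrix.sample_ids)
        fh.write(f"#chrom\tstart\tend\tid\ttype\tn_windows\tallele_frequency\t{cols}\n")
        for c in calls:
            depths = "\t".join(f"{d:.6g}" for d in c.sample_depths)
            fh.write(
                f"{c.chrom}\t{c.start}\t{c.end}\t{c.id}\t{c.type}\t"
                f"{c.n_windows}\t{c.af:.6g}\t{depths}\n"
            )
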