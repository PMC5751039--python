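"""Per-sample read-depth processing: raw counts through corrections to the
normalized profile.

The stages are ordered and each depends on the previous one:

1. raw          - reads whose center falls in a window (0x504-filtered)
2. absolute     - depths summed over linked duplicated windows
3. gc_corrected - per-GC-bin multiplicative correction anchored at 40% GC
4. normalized   - divided by the genome-wide median (diploid == 1.0)

Sex-chromosome depths of heterogametic individuals are doubled between GC
correction and normalization, so X/Z windows are comparable across sexes.
The normalized profile is persisted as a small tab-separated intermediate
file so population assembly never re-touches alignments.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .dupdb import DupWindowRecord
from .windows import WindowGrid

READ_FILTER_MASK = 0x504  # unmapped | secondary | PCR duplicate

STAGES = ("raw", "absolute", "gc_corrected", "normalized")

UNPLACED_PREFIXES = ("scaffold", "chrUn", "unplaced")


@dataclass
class SampleDepthProfile:
    """One sample's window depth vector at a given processing stage."""

    sample_id: str
    stage: str
    depths: np.ndarray
    window_size: int
    inferred_sex: str = "unknown"  # homogametic / heterogametic / unknown

    def __post_init__(self):
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")


@dataclass
class GCModel:
    """Fitted per-GC-bin depth means used for the GC correction, for audit."""

    bin_width: float  # GC percent per bin
    bin_means: np.ndarray  # effective (post-borrowing) mean depth per bin
    bin_counts: np.ndarray  # windows per bin
    rd40: float  # reference mean at the 40% GC bin
    global_median: float  # median corrected depth


def _read_center(start: int, end: int) -> int:
    # floor midpoint of the half-open aligned span [start, end)
    return (start + end) // 2


def count_raw_depth(
    alignments: str | Path, grid: WindowGrid, sample_id: str | None = None
) -> SampleDepthProfile:
    """Count reads per window from a coordinate-addressable SAM/BAM.

    A read contributes +1 to every retained window containing its center.
    Reads matching the 0x504 flag mask (unmapped, secondary, duplicate) are
    skipped; single-end reads and each mate of a pair count independently.
    """
    import pysam

    depths = np.zeros(grid.n_windows, dtype=np.float64)
    offsets, counts = grid.prefilter_layout()
    row_of = grid.row_of
    step = grid.step
    ws = grid.window_size
    skipped_chroms: set[str] = set()
    n_used = 0
    with pysam.AlignmentFile(str(alignments), check_sq=False) as af:
        for read in af.fetch(until_eof=True):
            if read.flag & READ_FILTER_MASK:
                continue
            chrom = read.reference_name
            if chrom not in offsets:
                if chrom not in skipped_chroms:
                    skipped_chroms.add(chrom)
                    warnings.warn(
                        f"{alignments}: chromosome {chrom!r} absent from grid; skipping",
                        stacklevel=2,
                    )
                continue
            start = read.reference_start
            end = read.reference_end
            if end is None:
                end = start + (read.query_length or 1)
            center = _read_center(start, end)
            n_used += 1
            s0 = (center // step) * step
            for s in (s0 - step, s0):
                if s < 0 or not (s <= center < s + ws):
                    continue
                k = s // step
                if k >= counts[chrom]:
                    continue
                row = row_of.get(offsets[chrom] + k)
                if row is not None:
                    depths[row] += 1
    if n_used == 0:
        raise ValueError(f"{alignments}: no usable reads after the 0x504 filter")
    sid = sample_id or os.path.splitext(os.path.basename(str(alignments)))[0]
    return SampleDepthProfile(sid, "raw", depths, grid.window_size)


def absolute_correction(
    profile: SampleDepthProfile, dup: DupWindowRecord, grid: WindowGrid
) -> SampleDepthProfile:
    """Sum raw depths over each window's duplicated-window partners.

    Recovers the absolute copy-number signal at segmental duplications:
    multi-mapped reads smeared over near-identical windows are pooled, so
    a window's depth reflects the total copy count of its sequence.
    """
    if profile.stage != "raw":
        raise ValueError(f"absolute correction expects a raw profile, got {profile.stage}")
    if dup.window_size != grid.window_size:
        raise ValueError("duplicated-window record and grid window_size differ")
    row_of = grid.row_of
    out = profile.depths.copy()
    for gi, partners in dup.links.items():
        if len(partners) <= 1:
            continue
        row = row_of.get(gi)
        if row is None:
            raise ValueError(f"duplicated-window record references dropped window {gi}")
        total = 0.0
        for j in partners:
            rj = row_of.get(j)
            if rj is None:
                raise ValueError(f"duplicated-window record references dropped window {j}")
            total += profile.depths[rj]
        out[row] = total
    return replace(profile, stage="absolute", depths=out)


def _effective_bin_means(
    bins: np.ndarray, depths: np.ndarray, min_bin_windows: int, n_bins: int = 101
) -> tuple[np.ndarray, np.ndarray]:
    counts = np.bincount(bins, minlength=n_bins)
    sums = np.bincount(bins, weights=depths, minlength=n_bins)
    populated = np.flatnonzero(counts >= max(min_bin_windows, 1))
    if populated.size == 0:
        raise ValueError(
            "no GC bin holds enough windows for correction; lower "
            "min_bin_windows or choose a different reference bin"
        )
    raw_means = np.full(n_bins, np.nan)
    raw_means[populated] = sums[populated] / counts[populated]
    eff = np.empty(n_bins)
    for b in range(n_bins):
        if counts[b] >= min_bin_windows:
            eff[b] = raw_means[b]
        else:
            # borrow the nearest populated bin; ties resolve to the lower bin
            d = np.abs(populated - b)
            eff[b] = raw_means[populated[int(np.argmin(d))]]
    return eff, counts


def gc_correction(
    profile: SampleDepthProfile,
    grid: WindowGrid,
    min_bin_windows: int = 100,
    ref_bin: int = 40,
) -> tuple[SampleDepthProfile, GCModel]:
    """Multiplicative GC-bias correction anchored at the 40%-GC bin.

    Each window's depth is scaled by (mean depth at 40% GC) / (mean depth
    of its own 1%-GC bin). Bins holding fewer than ``min_bin_windows``
    windows borrow the nearest populated bin.
    """
    if profile.stage != "absolute":
        raise ValueError(f"GC correction expects an absolute profile, got {profile.stage}")
    gc = np.nan_to_num(grid.gc, nan=0.5)
    bins = np.clip(np.floor(gc * 100 + 0.5).astype(int), 0, 100)
    eff_means, counts = _effective_bin_means(bins, profile.depths, min_bin_windows)
    rd40 = float(eff_means[ref_bin])
    if not rd40 > 0:
        raise ValueError(
            f"reference GC bin {ref_bin}% has zero mean depth after borrowing; "
            "choose a different reference bin"
        )
    factors = rd40 / eff_means[bins]
    corrected = profile.depths * factors
    model = GCModel(
        bin_width=1.0,
        bin_means=eff_means,
        bin_counts=counts,
        rd40=rd40,
        global_median=float(np.median(corrected)),
    )
    return replace(profile, stage="gc_corrected", depths=corrected), model


def sex_correction(
    profile: SampleDepthProfile,
    grid: WindowGrid,
    sex_chrom_name: str,
    het_ratio: float = 0.6,
    unplaced_prefixes: tuple[str, ...] = UNPLACED_PREFIXES,
) -> SampleDepthProfile:
    """Detect heterogametic individuals and double their sex-chrom depths.

    An individual whose sex-chromosome median depth is < ``het_ratio``
    times the autosomal median is called heterogametic (XY/ZW) and the sex
    chromosome is doubled; otherwise nothing changes. Unplaced scaffolds
    (identified by name prefix) are excluded from the autosomal median and
    never corrected.
    """
    if profile.stage != "gc_corrected":
        raise ValueError(f"sex correction expects a gc_corrected profile, got {profile.stage}")
    if not sex_chrom_name:
        return profile
    if sex_chrom_name not in grid.chrom_lengths:
        raise ValueError(
            f"sex chromosome {sex_chrom_name!r} not in grid; available: "
            f"{', '.join(grid.chroms)}"
        )
    sex_rows = grid.rows_of_chrom(sex_chrom_name)
    placed = [
        c
        for c in grid.chroms
        if c != sex_chrom_name and not c.startswith(tuple(unplaced_prefixes))
    ]
    auto_mask = np.isin(
        grid.chrom_id, [grid.chroms.index(c) for c in placed]
    )
    if sex_rows.size == 0 or not auto_mask.any():
        return replace(profile, inferred_sex="unknown")
    sex_median = float(np.median(profile.depths[sex_rows]))
    auto_median = float(np.median(profile.depths[auto_mask]))
    if auto_median <= 0:
        raise ValueError("autosomal median depth is zero; cannot infer sex")
    out = profile.depths
    if sex_median < het_ratio * auto_median:
        out = profile.depths.copy()
        out[sex_rows] *= 2.0
        sex = "heterogametic"
    else:
        sex = "homogametic"
    return replace(profile, depths=out, inferred_sex=sex)


def normalize(profile: SampleDepthProfile) -> SampleDepthProfile:
    """Divide by the genome-wide median so diploid regions sit at 1.0."""
    if profile.stage != "gc_corrected":
        raise ValueError(f"normalization expects a gc_corrected profile, got {profile.stage}")
    med = float(np.median(profile.depths))
    if med <= 0:
        raise ValueError("global median depth is zero; cannot normalize")
    return replace(profile, stage="normalized", depths=profile.depths / med)


def write_profile(profile: SampleDepthProfile, path: str | Path, grid: WindowGrid) -> None:
    """Persist a profile as the per-sample intermediate file."""
    with open(path, "w") as fh:
        fh.write(
            f"#sample={profile.sample_id}\twindow_size={profile.window_size}\t"
            f"sex={profile.inferred_sex}\tstage={profile.stage}\n"
        )
        fh.write("chrom\tstart\tend\tdepth\n")
        for r in range(grid.n_windows):
            fh.write(
                f"{grid.chrom_name(r)}\t{grid.start[r]}\t"
                f"{grid.start[r] + grid.window_size}\t{profile.depths[r]:.17g}\n"
            )


def read_profile(path: str | Path, grid: WindowGrid) -> SampleDepthProfile:
    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith("#sample="):
            raise ValueError(f"{path}: not a depth-profile file")
        fields = dict(kv.split("=", 1) for kv in header[1:].split("\t"))
        window_size = int(fields["window_size"])
        if window_size != grid.window_size:
            raise ValueError(
                f"window_size mismatch: profile {fields['sample']} has "
                f"{window_size}, grid has {grid.window_size}"
            )
        fh.readline()  # column header
        depths = np.empty(grid.n_windows, dtype=np.float64)
        r = 0
        for line in fh:
            if not line.strip():
                continue
            chrom, start, _end, depth = line.rstrip("\n").split("\t")
            if r >= grid.n_windows:
                raise ValueError(f"{path}: more windows than the grid has")
            if chrom != grid.chrom_name(r) or int(start) != grid.start[r]:
                raise ValueError(
                    f"{path}: window {r} ({chrom}:{start}) does not match the grid"
                )
            depths[r] = float(depth)
            r += 1
        if r != grid.n_windows:
            raise ValueError(f"{path}: fewer windows ({r}) than the grid ({grid.n_windows})")
    return SampleDepthProfile(
        sample_id=fields["sample"],
        stage=fields["stage"],
        depths=depths,
        window_size=window_size,
        inferred_sex=fields.get("sex", "unknown"),
    )
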