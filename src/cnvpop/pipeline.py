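"""End-to-end convenience wrappers tying the pipeline stages together."""

from __future__ import annotations

from dataclasses import replace

from .dupdb import DupWindowRecord
from .genotype import GenotypeResult, genotype_cnvrs
from .individual import (
    SampleDepthProfile,
    absolute_correction,
    gc_correction,
    normalize,
    sex_correction,
)
from .population import (
    CNVRCall,
    PopulationDepthMatrix,
    assemble_matrix,
    define_cnvrs,
    flag_individual_candidates,
    merge_adjacent_cnvrs,
    select_population_windows,
)
from .windows import WindowGrid


def correct_profile(
    raw: SampleDepthProfile,
    grid: WindowGrid,
    dup: DupWindowRecord | None = None,
    sex_chrom: str | None = None,
    min_bin_windows: int = 100,
) -> SampleDepthProfile:
    """raw -> absolute -> GC-corrected -> (sex-corrected) -> normalized."""
    if dup is not None:
        p = absolute_correction(raw, dup, grid)
    else:
        p = replace(raw, stage="absolute", depths=raw.depths.copy())
    p, _model = gc_correction(p, grid, min_bin_windows=min_bin_windows)
    if sex_chrom:
        p = sex_correction(p, grid, sex_chrom)
    return normalize(p)


def detect_cnvrs(
    profiles: list[SampleDepthProfile],
    grid: WindowGrid,
    mode: str = "outbred",
    min_af: float = 0.05,
    min_hom: int = 2,
    keep_all_het: bool = False,
    min_run: int = 5,
    max_gap_frac: float = 0.2,
    p_thresh: float = 0.01,
) -> tuple[PopulationDepthMatrix, list[CNVRCall]]:
    """Normalized profiles -> flagged matrix -> merged CNVR calls."""
    matrix = assemble_matrix(profiles, grid)
    flag_individual_candidates(matrix, mode=mode)
    select_population_windows(
        matrix, min_af=min_af, min_hom=min_hom, keep_all_het=keep_all_het
    )
    calls = define_cnvrs(matrix, min_run=min_run)
    calls = merge_adjacent_cnvrs(calls, matrix, max_gap_frac=max_gap_frac, p_thresh=p_thresh)
    return matrix, calls


def run_pipeline(
    raw_profiles: list[SampleDepthProfile],
    grid: WindowGrid,
    dup: DupWindowRecord | None = None,
    sex_chrom: str | None = None,
    min_bin_windows: int = 100,
    seed: int = 0,
    **detect_kwargs,
) -> tuple[PopulationDepthMatrix, list[CNVRCall], list[GenotypeResult]]:
    """Full pipeline from raw counts to genotyped CNVRs."""
    normalized = [
        correct_profile(p, grid, dup=dup, sex_chrom=sex_chrom, min_bin_windows=min_bin_windows)
        for p in raw_profiles
    ]
    matrix, calls = detect_cnvrs(normalized, grid, **detect_kwargs)
    results = genotype_cnvrs(calls, matrix, seed=seed)
    return matrix, calls, results
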