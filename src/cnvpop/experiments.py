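"""Self-contained benchmark experiments on simulated data.

Each experiment builds its inputs from the synthetic-data generator, runs
the pipeline, and measures recovery against the known truth. The designs
are scaled-down versions of classic segmental-duplication and population
CNV validation set-ups: a 5-Mb source sequence, 20 tandem 5-kb segmental
duplications or a dozen planted 4-kb CNVs, 30 individuals at x20 coverage
with 400-bp windows (the recommended window size for that coverage).
"""

from __future__ import annotations

import math
import tempfile
from pathlib import Path

import numpy as np

from .dupdb import build_dup_record
from .evaluate import intervals_match, mendelian_inconsistency
from .genotype import fit_mixture, genotype_cnvrs, write_vcf
from .pipeline import correct_profile, detect_cnvrs
from .simulate import (
    plant_cnv_events,
    simulate_counts,
    simulate_population,
    simulate_reference,
    simulate_trios,
    write_pedigree,
)
from .windows import build_window_grid


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def sd_correction_experiment(
    seed: int = 1,
    length: int = 5_000_000,
    n_sd: int = 20,
    sd_length: int = 5000,
    n_individuals: int = 30,
    window_size: int = 400,
    coverage: float = 20.0,
) -> dict:
    """Absolute copy-number recovery in tandem segmental duplications.

    Individuals carry 2-6 total copies of each duplicated unit; reads smear
    uniformly over the two assembled copies, so uncorrected depth reads out
    roughly half the true copy number. Measures per-individual integer-CN
    accuracy and per-true-CN stratum means with and without the
    duplicated-window summation.
    """
    truth = simulate_reference(length, n_sd=n_sd, sd_length=sd_length, seed=seed)
    grid = build_window_grid(truth.sequences, window_size)
    dup = build_dup_record(truth.sequences, window_size, grid=grid)
    geno = simulate_population(truth, n_individuals, hwe=False, seed=seed + 1)
    raw = simulate_counts(truth, geno, grid, coverage=coverage, seed=seed + 2)
    corrected = [correct_profile(p, grid, dup=dup) for p in raw.values()]
    uncorrected = [correct_profile(p, grid, dup=None) for p in raw.values()]

    event_rows = []
    for ev in truth.events:
        lo, hi = ev.start, ev.copy2_end if ev.kind == "assembled_SD" else ev.end
        rows = grid.rows_of_chrom(ev.chrom)
        sel = rows[(grid.start[rows] >= lo) & (grid.start[rows] + window_size <= hi)]
        event_rows.append(sel)

    n_pairs = 0
    n_correct = 0
    strata: dict[int, list[float]] = {}
    strata_unc: dict[int, list[float]] = {}
    for ei in range(len(truth.events)):
        for si in range(n_individuals):
            true_cn = int(geno.cn[ei, si])
            cn_c = 2.0 * float(np.median(corrected[si].depths[event_rows[ei]]))
            cn_u = 2.0 * float(np.median(uncorrected[si].depths[event_rows[ei]]))
            n_pairs += 1
            n_correct += int(_round_half_up(cn_c) == true_cn)
            strata.setdefault(true_cn, []).append(cn_c)
            strata_unc.setdefault(true_cn, []).append(cn_u)
    stratum_means = {c: float(np.mean(v)) for c, v in sorted(strata.items())}
    stratum_means_unc = {c: float(np.mean(v)) for c, v in sorted(strata_unc.items())}
    n_correct_unc = sum(
        int(_round_half_up(v) == c) for c, vals in strata_unc.items() for v in vals
    )
    return {
        "n_pairs": n_pairs,
        "accuracy": n_correct / n_pairs,
        "accuracy_uncorrected": n_correct_unc / n_pairs,
        "stratum_means": stratum_means,
        "stratum_means_uncorrected": stratum_means_unc,
        "max_stratum_error": max(abs(m - c) for c, m in stratum_means.items()),
        "uncorrected_to_true_ratio": float(
            np.mean([m / c for c, m in stratum_means_unc.items()])
        ),
    }


def cnvr_recovery_experiment(
    seed: int = 1,
    length: int = 5_000_000,
    n_events: int = 12,
    event_length: int = 4000,
    n_individuals: int = 30,
    window_size: int = 400,
    coverage: float = 20.0,
) -> dict:
    """Planted-CNVR recovery and false calls on a matched null genome.

    Deletions and duplications at allele frequencies 0.1-0.3 are planted on
    a 5-Mb genome; recovery requires a call with >=50% reciprocal overlap.
    The null arm runs the identical pipeline on the same design with no
    events planted.
    """
    truth = simulate_reference(length, seed=seed)
    plant_cnv_events(truth, n_events=n_events, event_length=event_length, seed=seed + 1)
    grid = build_window_grid(truth.sequences, window_size)
    dup = build_dup_record(truth.sequences, window_size, grid=grid)
    geno = simulate_population(truth, n_individuals, hwe=True, seed=seed + 2)
    raw = simulate_counts(truth, geno, grid, coverage=coverage, seed=seed + 3)
    profiles = [correct_profile(p, grid, dup=dup) for p in raw.values()]
    _matrix, calls = detect_cnvrs(profiles, grid)

    recovered = 0
    for ev in truth.events:
        t = (ev.chrom, ev.start, ev.end)
        if any(intervals_match(t, (c.chrom, c.start, c.end)) for c in calls):
            recovered += 1

    null_truth = simulate_reference(length, seed=seed + 10)
    null_grid = build_window_grid(null_truth.sequences, window_size)
    null_geno = simulate_population(null_truth, n_individuals, hwe=True, seed=seed + 11)
    null_raw = simulate_counts(null_truth, null_geno, null_grid, coverage=coverage, seed=seed + 12)
    null_profiles = [correct_profile(p, null_grid, dup=None) for p in null_raw.values()]
    _m, null_calls = detect_cnvrs(null_profiles, null_grid)

    return {
        "n_events": len(truth.events),
        "n_calls": len(calls),
        "recovery_rate": recovered / len(truth.events),
        "null_calls": len(null_calls),
    }


def genotyping_experiment(
    seed: int = 1,
    n_cnvrs: int = 50,
    n_samples: int = 60,
    sigma: float = 0.1,
) -> dict:
    """Integer-CN recovery from well-separated copy-number clusters.

    Each simulated CNVR draws true copy numbers under Hardy-Weinberg at a
    frequency in 0.1-0.5 (deletions and duplications alternating), adds
    Gaussian noise of ``sigma`` around the integer cluster means
    (separation 1 CN), and checks the mixture genotyper's assignments and
    silhouette.
    """
    rng = np.random.default_rng(seed)
    n_total = 0
    n_correct = 0
    silhouettes = []
    for i in range(n_cnvrs):
        af = float(rng.uniform(0.1, 0.5))
        nalt = rng.binomial(2, af, n_samples)
        true_cn = 2 - nalt if i % 2 == 0 else 2 + nalt
        est = np.maximum(true_cn + rng.normal(0, sigma, n_samples), 0.0)
        res = fit_mixture(est, seed=seed + i, cnvr_id=f"sim_{i:03d}")
        n_total += n_samples
        n_correct += int(np.sum(res.cn_integer == true_cn))
        if not np.isnan(res.silhouette):
            silhouettes.append(res.silhouette)
    return {
        "n_genotypes": n_total,
        "accuracy": n_correct / n_total,
        "mean_silhouette": float(np.mean(silhouettes)) if silhouettes else float("nan"),
        "n_multicluster": len(silhouettes),
    }


def trio_experiment(
    seed: int = 1,
    length: int = 2_000_000,
    n_events: int = 8,
    event_length: int = 4000,
    n_trios: int = 10,
    window_size: int = 400,
    coverage: float = 30.0,
    workdir: str | Path | None = None,
) -> dict:
    """Full pipeline on simulated trios: Mendelian inconsistency of the
    resulting VCF (0 by construction), and detection of a deliberately
    corrupted child genotype."""
    truth = simulate_reference(length, seed=seed)
    plant_cnv_events(
        truth, n_events=n_events, event_length=event_length, afs=(0.3,), seed=seed + 1
    )
    grid = build_window_grid(truth.sequences, window_size)
    geno = simulate_trios(truth, n_trios, seed=seed + 2)
    raw = simulate_counts(truth, geno, grid, coverage=coverage, seed=seed + 3)
    profiles = [correct_profile(raw[sid], grid) for sid in geno.sample_ids]
    matrix, calls = detect_cnvrs(profiles, grid)
    results = genotype_cnvrs(calls, matrix, seed=seed + 4)

    tmpdir = Path(workdir) if workdir else Path(tempfile.mkdtemp(prefix="cnvpop_trio_"))
    tmpdir.mkdir(parents=True, exist_ok=True)
    vcf_path = tmpdir / "trios.vcf"
    ped_path = tmpdir / "trios.ped"
    write_vcf(results, calls, matrix.sample_ids, vcf_path, grid)
    write_pedigree(geno, ped_path)
    frac, _flags = mendelian_inconsistency(vcf_path, ped_path)

    # corrupt one child genotype at a biallelic CNVR and re-score
    corrupted_frac = float("nan")
    corrupted_id = None
    for call, res in zip(calls, results):
        cn = res.cn_integer
        biallelic = (call.type == "loss" and cn.max() <= 2) or (
            call.type == "gain" and 2 <= cn.min() and cn.max() <= 4
        )
        if not biallelic:
            continue
        for t in range(n_trios):
            f_i, m_i, c_i = 3 * t, 3 * t + 1, 3 * t + 2
            if cn[f_i] == 2 and cn[m_i] == 2:
                bad = res.cn_integer.copy()
                bad[c_i] = 1 if call.type == "loss" else 3
                res_bad = [
                    r if r.cnvr_id != res.cnvr_id else
                    type(res)(**{**res.__dict__, "cn_integer": bad})
                    for r in results
                ]
                bad_vcf = tmpdir / "trios_corrupted.vcf"
                write_vcf(res_bad, calls, matrix.sample_ids, bad_vcf, grid)
                corrupted_frac, bad_flags = mendelian_inconsistency(bad_vcf, ped_path)
                corrupted_id = next(
                    (f["id"] for f in bad_flags if f["inconsistent_children"]), None
                )
                break
        if corrupted_id is not None:
            break

    return {
        "n_calls": len(calls),
        "inconsistency": frac,
        "corrupted_inconsistency": corrupted_frac,
        "corrupted_flagged": corrupted_id is not None,
    }
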