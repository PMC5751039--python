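"""Synthetic references, populations, trios and window counts with known
truth.

The generator emulates the segmental-duplication simulation design used to
exercise the absolute copy-number correction: nonoverlapping donor regions
of a random source sequence are inserted as tandem duplications
(``assembled_SD``) or flagged as two-copy while left single-copy in the
assembly (``collapsed_SD``); individuals are assigned 2-6 total copies of
each duplicated unit. Plain deletions/duplications can additionally be
planted with population allele frequencies for CNVR-recovery experiments.

Counts-level simulation is the default: per-window read counts are drawn
as Poisson(lambda * factor) with lambda = coverage * window_size /
read_length, where the factor encodes each individual's copy number, the
multi-mapping smearing of assembled duplications (reads split uniformly
across the two reference copies), sex-chromosome ploidy, and an optional
GC-bias curve. Alignment emission writes minimal single-end SAM records
whose centers are consistent with the same model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .individual import SampleDepthProfile
from .windows import WindowGrid

BIALLELIC_KINDS = ("deletion", "duplication")
SD_KINDS = ("collapsed_SD", "assembled_SD")


@dataclass
class Event:
    """One planted event, coordinates in the *final* reference."""

    chrom: str
    start: int
    end: int
    kind: str
    af: float
    copy2_start: int = -1  # second tandem copy (assembled_SD only)
    copy2_end: int = -1

    def intervals(self) -> list[tuple[int, int]]:
        if self.kind == "assembled_SD":
            return [(self.start, self.end), (self.copy2_start, self.copy2_end)]
        return [(self.start, self.end)]


@dataclass
class SimulationTruth:
    sequences: dict[str, str]
    events: list[Event]
    seed: int
    sex_chrom: str | None = None


@dataclass
class PopulationGenotypes:
    sample_ids: list[str]
    cn: np.ndarray  # (n_events, n_samples) diploid copy number per event
    sexes: list[str] = field(default_factory=list)
    pedigree: list[tuple[str, str, str, str]] = field(default_factory=list)


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return bytes(rng.choice(np.frombuffer(b"ACGT", np.uint8), size=length)).decode()


def _place_nonoverlapping(
    rng: np.random.Generator,
    length: int,
    n: int,
    span: int,
    occupied: list[tuple[int, int]],
    margin: int,
    max_tries: int = 10000,
) -> list[int]:
    placed = list(occupied)
    starts = []
    for _ in range(n):
        for attempt in range(max_tries):
            s = int(rng.integers(margin, length - span - margin))
            if all(s + span + margin <= a or s >= b + margin for a, b in placed):
                placed.append((s, s + span))
                starts.append(s)
                break
        else:
            raise ValueError(
                f"could not place {n} nonoverlapping regions of {span} bp "
                f"in {length} bp"
            )
    return sorted(starts)


def simulate_reference(
    length: int,
    n_sd: int = 0,
    sd_length: int = 5000,
    sd_kind: str = "assembled_SD",
    gap_config: dict | None = None,
    sex_chrom_length: int = 0,
    seed: int = 0,
    chrom_name: str = "chr1",
) -> SimulationTruth:
    """Random reference with planted segmental duplications and gaps.

    ``sd_kind`` may be ``assembled_SD`` (tandem copy inserted, reference
    grows by sd_length per SD), ``collapsed_SD`` (single copy kept,
    flagged two-copy in truth) or ``mixed`` (alternating).
    """
    if n_sd > 0 and n_sd * sd_length * 3 > length:
        raise ValueError("infeasible packing: n_sd * sd_length too large for length")
    rng = np.random.default_rng(seed)
    source = _random_sequence(rng, length)
    if gap_config:
        n_gaps = int(gap_config.get("n_gaps", 0))
        gap_len = int(gap_config.get("gap_length", 1000))
    else:
        n_gaps, gap_len = 0, 0

    donor_starts = (
        _place_nonoverlapping(rng, length, n_sd, sd_length, [], margin=sd_length)
        if n_sd
        else []
    )
    kinds = []
    for i in range(n_sd):
        if sd_kind == "mixed":
            kinds.append(SD_KINDS[i % 2])
        elif sd_kind in SD_KINDS:
            kinds.append(sd_kind)
        else:
            raise ValueError(f"unknown sd_kind {sd_kind!r}")

    seq_parts = []
    events: list[Event] = []
    pos = 0
    shift = 0
    for s, kind in zip(donor_starts, kinds):
        seq_parts.append(source[pos : s + sd_length])
        donor = source[s : s + sd_length]
        if kind == "assembled_SD":
            seq_parts.append(donor)  # tandem copy
            events.append(
                Event(
                    chrom=chrom_name,
                    start=s + shift,
                    end=s + shift + sd_length,
                    kind=kind,
                    af=1.0,
                    copy2_start=s + shift + sd_length,
                    copy2_end=s + shift + 2 * sd_length,
                )
            )
            shift += sd_length
        else:
            events.append(
                Event(chrom=chrom_name, start=s + shift, end=s + shift + sd_length,
                      kind=kind, af=1.0)
            )
        pos = s + sd_length
    seq_parts.append(source[pos:])
    final = "".join(seq_parts)

    if n_gaps:
        occupied = [(iv[0], iv[1]) for e in events for iv in e.intervals()]
        gap_starts = _place_nonoverlapping(
            rng, len(final), n_gaps, gap_len, occupied, margin=gap_len
        )
        arr = bytearray(final.encode())
        for g in gap_starts:
            arr[g : g + gap_len] = b"N" * gap_len
        final = arr.decode()

    sequences = {chrom_name: final}
    sex_chrom = None
    if sex_chrom_length:
        sex_chrom = "chrX"
        sequences[sex_chrom] = _random_sequence(rng, sex_chrom_length)
    return SimulationTruth(sequences=sequences, events=events, seed=seed,
                           sex_chrom=sex_chrom)


def plant_cnv_events(
    truth: SimulationTruth,
    n_events: int,
    event_length: int = 4000,
    kinds: tuple[str, ...] = BIALLELIC_KINDS,
    afs: tuple[float, ...] = (0.1, 0.2, 0.3),
    seed: int = 0,
    chrom: str | None = None,
) -> SimulationTruth:
    """Mark deletion/duplication events on the reference (no sequence edit:
    these are individual-level variants relative to the assembly)."""
    rng = np.random.default_rng(seed)
    chrom = chrom or next(iter(truth.sequences))
    L = len(truth.sequences[chrom])
    occupied = [
        (iv[0], iv[1]) for e in truth.events if e.chrom == chrom for iv in e.intervals()
    ]
    starts = _place_nonoverlapping(
        rng, L, n_events, event_length, occupied, margin=event_length
    )
    order = rng.permutation(n_events)
    for i, s in enumerate(starts):
        truth.events.append(
            Event(
                chrom=chrom,
                start=s,
                end=s + event_length,
                kind=kinds[int(order[i]) % len(kinds)],
                af=float(afs[int(order[i]) % len(afs)]),
            )
        )
    return truth


def simulate_population(
    truth: SimulationTruth,
    n_individuals: int,
    hwe: bool = True,
    seed: int = 0,
    cn_range: tuple[int, int] = (2, 6),
) -> PopulationGenotypes:
    """Diploid copy number per event per individual.

    SD events get direct copy-number assignment (uniform over
    ``cn_range``); biallelic deletions/duplications are sampled under
    Hardy-Weinberg at the event's allele frequency when ``hwe`` is set,
    else every carrier allele is assigned directly from the frequency as a
    haploid draw (equivalent here).
    """
    rng = np.random.default_rng(seed)
    cn = np.full((len(truth.events), n_individuals), 2, dtype=np.int64)
    for ei, ev in enumerate(truth.events):
        if ev.kind in SD_KINDS:
            cn[ei] = rng.integers(cn_range[0], cn_range[1] + 1, n_individuals)
        else:
            if not 0 <= ev.af <= 1:
                raise ValueError(f"event {ei}: allele frequency {ev.af} outside [0,1]")
            if hwe:
                nalt = rng.binomial(2, ev.af, n_individuals)
            else:
                nalt = 2 * rng.binomial(1, ev.af, n_individuals)
            cn[ei] = 2 - nalt if ev.kind == "deletion" else 2 + nalt
    sexes = []
    if truth.sex_chrom:
        sexes = [
            "heterogametic" if x else "homogametic"
            for x in rng.integers(0, 2, n_individuals)
        ]
    return PopulationGenotypes(
        sample_ids=[f"S{i:03d}" for i in range(n_individuals)],
        cn=cn,
        sexes=sexes,
    )


def simulate_trios(
    truth: SimulationTruth, n_trios: int, seed: int = 0
) -> PopulationGenotypes:
    """Parents under Hardy-Weinberg; each child inherits one allele from
    each parent, so trios are Mendelian-consistent by construction.

    Samples are ordered father, mother, child per trio.
    """
    for ev in truth.events:
        if ev.kind not in BIALLELIC_KINDS:
            raise ValueError("trio simulation supports biallelic deletion/duplication events only")
    rng = np.random.default_rng(seed)
    n_samples = 3 * n_trios
    cn = np.full((len(truth.events), n_samples), 2, dtype=np.int64)
    sample_ids = []
    pedigree = []
    for t in range(n_trios):
        f, m, c = f"F{t:03d}", f"M{t:03d}", f"C{t:03d}"
        sample_ids += [f, m, c]
        pedigree.append((f"fam{t:03d}", c, f, m))
    for ei, ev in enumerate(truth.events):
        for t in range(n_trios):
            nf = int(rng.binomial(2, ev.af))
            nm = int(rng.binomial(2, ev.af))
            a_f = int(rng.random() < nf / 2)
            a_m = int(rng.random() < nm / 2)
            nalt = (nf, nm, a_f + a_m)
            for k, na in enumerate(nalt):
                col = 3 * t + k
                cn[ei, col] = 2 - na if ev.kind == "deletion" else 2 + na
    return PopulationGenotypes(sample_ids=sample_ids, cn=cn, pedigree=pedigree)


def _event_window_factors(
    truth: SimulationTruth, grid: WindowGrid
) -> list[list[tuple[int, float, int]]]:
    """Per event: (grid row, overlap fraction, interval count) touched."""
    ws = grid.window_size
    out = []
    for ev in truth.events:
        touched: dict[int, float] = {}
        rows = grid.rows_of_chrom(ev.chrom)
        starts = grid.start[rows]
        for a, b in ev.intervals():
            lo = int(np.searchsorted(starts, a - ws, side="right"))
            hi = int(np.searchsorted(starts, b, side="left"))
            for k in range(lo, hi):
                ws_start = int(starts[k])
                ov = min(b, ws_start + ws) - max(a, ws_start)
                if ov > 0:
                    r = int(rows[k])
                    touched[r] = touched.get(r, 0.0) + ov / ws
        out.append([(r, min(f, 1.0), len(ev.intervals())) for r, f in touched.items()])
    return out


def simulate_counts(
    truth: SimulationTruth,
    genotypes: PopulationGenotypes,
    grid: WindowGrid,
    coverage: float = 20.0,
    read_length: int = 100,
    gc_bias=None,
    seed: int = 0,
) -> dict[str, SampleDepthProfile]:
    """Raw per-window read counts for every individual.

    Copy-number multipliers: a unique-region event with diploid CN c scales
    depth by c/2 over its span; a collapsed duplication routes both real
    copies onto the single assembled window (c/2 with c counting all real
    copies, i.e. depth doubles at c=4); an assembled tandem duplication
    smears reads uniformly over its two reference copies (c/4 each).
    """
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    rng = np.random.default_rng(seed)
    lam = coverage * grid.window_size / read_length
    base = np.ones(grid.n_windows)
    if gc_bias is not None:
        base = base * gc_bias(grid.gc)
    ev_factors = _event_window_factors(truth, grid)
    sex_rows = (
        grid.rows_of_chrom(truth.sex_chrom)
        if truth.sex_chrom and truth.sex_chrom in grid.chrom_lengths
        else np.empty(0, dtype=int)
    )
    profiles: dict[str, SampleDepthProfile] = {}
    for si, sid in enumerate(genotypes.sample_ids):
        factor = base.copy()
        for ei, touched in enumerate(ev_factors):
            c = int(genotypes.cn[ei, si])
            n_copies = len(truth.events[ei].intervals())
            mult = c / (2 * n_copies)
            for r, frac, _ in touched:
                factor[r] += (mult - 1.0) * frac
        if genotypes.sexes and genotypes.sexes[si] == "heterogametic":
            factor[sex_rows] *= 0.5
        counts = rng.poisson(np.maximum(lam * factor, 0.0)).astype(np.float64)
        profiles[sid] = SampleDepthProfile(sid, "raw", counts, grid.window_size)
    return profiles


def write_sam(
    truth: SimulationTruth,
    genotypes: PopulationGenotypes,
    sample_index: int,
    grid: WindowGrid,
    path: str | Path,
    coverage: float = 20.0,
    read_length: int = 100,
    seed: int = 0,
) -> None:
    """Emit minimal coordinate-sorted single-end SAM for one individual,
    with read centers following the same depth model as simulate_counts."""
    import pysam

    rng = np.random.default_rng(seed)
    step = grid.step
    lam_bin = coverage * step / read_length
    ev_mult: dict[str, list[tuple[int, int, float]]] = {c: [] for c in grid.chroms}
    for ei, ev in enumerate(truth.events):
        c = int(genotypes.cn[ei, sample_index])
        mult = c / (2 * len(ev.intervals()))
        for a, b in ev.intervals():
            ev_mult[ev.chrom].append((a, b, mult))
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [
            {"SN": c, "LN": grid.chrom_lengths[c]} for c in grid.chroms
        ],
    }
    half = (read_length - 1) // 2
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        rid = 0
        for ci, chrom in enumerate(grid.chroms):
            L = grid.chrom_lengths[chrom]
            seq_is_het = (
                genotypes.sexes
                and truth.sex_chrom == chrom
                and genotypes.sexes[sample_index] == "heterogametic"
            )
            for b0 in range(0, L // step):
                lo, hi = b0 * step, (b0 + 1) * step
                mult = 1.0
                for a, b, m in ev_mult[chrom]:
                    ov = min(b, hi) - max(a, lo)
                    if ov > 0:
                        mult += (m - 1.0) * ov / step
                if seq_is_het:
                    mult *= 0.5
                n = int(rng.poisson(max(lam_bin * mult, 0.0)))
                if n == 0:
                    continue
                centers = np.sort(rng.integers(lo, hi, n))
                for c0 in centers:
                    start = int(min(max(c0 - half, 0), max(L - read_length, 0)))
                    a = pysam.AlignedSegment()
                    a.query_name = f"r{rid}"
                    a.query_sequence = "A" * read_length
                    a.flag = 0
                    a.reference_id = ci
                    a.reference_start = start
                    a.mapping_quality = 60
                    a.cigartuples = [(0, read_length)]
                    out.write(a)
                    rid += 1


def write_fasta(sequences: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_truth(truth: SimulationTruth, genotypes: PopulationGenotypes | None, path) -> None:
    """Tab-separated truth table: events and optional per-sample CNs."""
    with open(path, "w") as fh:
        cols = "\t".join(genotypes.sample_ids) if genotypes else ""
        fh.write(
            "#chrom\tstart\tend\tkind\taf\tcopy2_start\tcopy2_end"
            + ("\t" + cols if cols else "")
            + "\n"
        )
        for ei, ev in enumerate(truth.events):
            row = [
                ev.chrom, str(ev.start), str(ev.end), ev.kind, f"{ev.af:g}",
                str(ev.copy2_start), str(ev.copy2_end),
            ]
            if genotypes:
                row += [str(int(c)) for c in genotypes.cn[ei]]
            fh.write("\t".join(row) + "\n")


def write_pedigree(genotypes: PopulationGenotypes, path) -> None:
    with open(path, "w") as fh:
        for fam, child, father, mother in genotypes.pedigree:
            fh.write(f"{fam}\t{child}\t{father}\t{mother}\n")
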