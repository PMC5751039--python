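"""Callset scoring: interval matching, sensitivity against a truth set,
trio Mendelian inconsistency, and genotype concordance between callsets.

Interval matching follows the usual structural-variant convention: two
calls match when they share >=50% reciprocal overlap, or when either call
is >=90% covered by the other.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

RECIPROCAL_FRACTION = 0.5
COVERAGE_FRACTION = 0.9

Interval = tuple[str, int, int]


def reciprocal_overlap(a: Interval, b: Interval) -> tuple[float, float]:
    """Overlap length as a fraction of each half-open interval."""
    ca, sa, ea = a
    cb, sb, eb = b
    if ea <= sa or eb <= sb:
        raise ValueError("zero-length interval")
    if ca != cb:
        return 0.0, 0.0
    ov = max(0, min(ea, eb) - max(sa, sb))
    return ov / (ea - sa), ov / (eb - sb)


def intervals_match(
    a: Interval,
    b: Interval,
    reciprocal: float = RECIPROCAL_FRACTION,
    coverage: float = COVERAGE_FRACTION,
) -> bool:
    fa, fb = reciprocal_overlap(a, b)
    return (fa >= reciprocal and fb >= reciprocal) or fa >= coverage or fb >= coverage


@dataclass
class CallRecord:
    chrom: str
    start: int
    end: int
    af: float = float("nan")

    @property
    def interval(self) -> Interval:
        return (self.chrom, self.start, self.end)

    @property
    def length(self) -> int:
        return self.end - self.start


def sensitivity(
    calls: list[CallRecord],
    truth_db: list[CallRecord],
    min_len: int = 2500,
    min_af: float = 0.05,
    reciprocal: float = RECIPROCAL_FRACTION,
) -> float:
    """Fraction of truth entries matched by >= 1 call.

    Both sets are filtered identically: length > ``min_len`` and allele
    frequency >= ``min_af`` (NaN frequencies pass, for truth sets without
    one).
    """

    def _keep(r: CallRecord) -> bool:
        return r.length > min_len and (np.isnan(r.af) or r.af >= min_af)

    truth_f = [r for r in truth_db if _keep(r)]
    calls_f = [r for r in calls if _keep(r)]
    if not truth_f:
        raise ValueError("truth set is empty after length/frequency filtering")
    hit = 0
    for t in truth_f:
        if any(
            intervals_match(t.interval, c.interval, reciprocal=reciprocal)
            for c in calls_f
        ):
            hit += 1
    return hit / len(truth_f)


def _alleles_for_cn(cn: int, kind: str) -> tuple[int, int] | None:
    """Diploid allele pair (0 = ref, 1 = alt) for a biallelic CNVR."""
    table = {0: (1, 1), 1: (0, 1), 2: (0, 0)} if kind == "loss" else {
        2: (0, 0), 3: (0, 1), 4: (1, 1)
    }
    return table.get(cn)


def read_vcf_records(path: str | Path) -> tuple[list[dict], list[str]]:
    """Parse a cnvpop VCF into plain records (pysam-backed)."""
    import pysam

    records = []
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        for rec in vf:
            svtype = rec.info.get("SVTYPE")
            kind = {"DEL": "loss", "DUP": "gain"}.get(svtype, "mixed")
            cn = {s: rec.samples[s].get("CN") for s in samples}
            af_val = rec.info.get("AF", float("nan"))
            if isinstance(af_val, tuple):
                af_val = sum(af_val)
            # half-open end from SVLEN when present: htslib's stop applies the
            # padding-base convention to symbolic alleles, off by one here
            svlen = rec.info.get("SVLEN")
            if isinstance(svlen, tuple):
                svlen = svlen[0]
            end = rec.start + abs(int(svlen)) if svlen is not None else rec.stop
            records.append(
                {
                    "chrom": rec.chrom,
                    "start": rec.start,  # pysam is 0-based
                    "end": end,
                    "id": rec.id,
                    "kind": kind,
                    "af": float(af_val),
                    "cn": cn,
                }
            )
    return records, samples


def read_pedigree(path: str | Path) -> list[tuple[str, str, str, str]]:
    trios = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts or parts[0].startswith("#"):
                continue
            if len(parts) < 4:
                raise ValueError(f"{path}: pedigree line needs family, child, father, mother")
            trios.append(tuple(parts[:4]))
    return trios


def mendelian_inconsistency(
    vcf: str | Path, pedigree: str | Path | list[tuple[str, str, str, str]]
) -> tuple[float, list[dict]]:
    """Fraction of trio x CNVR genotypes no parental transmission explains.

    Only biallelic CNVRs are scored: losses with all CN in {0,1,2} and
    gains with all CN in {2,3,4} (maximum copy number 4). A child is
    consistent when some pairing of one allele from each parent reproduces
    its genotype.
    """
    trios = pedigree if isinstance(pedigree, list) else read_pedigree(pedigree)
    records, samples = read_vcf_records(vcf)
    sample_set = set(samples)
    for fam, child, father, mother in trios:
        missing = {child, father, mother} - sample_set
        if missing:
            raise ValueError(f"pedigree sample(s) {sorted(missing)} missing from VCF")
    n_scored = 0
    n_bad = 0
    flags = []
    for rec in records:
        if rec["kind"] not in ("loss", "gain"):
            continue
        cns = [c for c in rec["cn"].values() if c is not None]
        valid = {0, 1, 2} if rec["kind"] == "loss" else {2, 3, 4}
        if not all(c in valid for c in cns):
            continue  # not biallelic under the CN<=4 model
        rec_bad = []
        for fam, child, father, mother in trios:
            gf = _alleles_for_cn(rec["cn"][father], rec["kind"])
            gm = _alleles_for_cn(rec["cn"][mother], rec["kind"])
            gc = _alleles_for_cn(rec["cn"][child], rec["kind"])
            if gf is None or gm is None or gc is None:
                continue
            n_scored += 1
            ok = any(
                tuple(sorted((a, b))) == gc for a in gf for b in gm
            )
            if not ok:
                n_bad += 1
                rec_bad.append(child)
        flags.append({"id": rec["id"], "inconsistent_children": rec_bad})
    if n_scored == 0:
        return 0.0, flags
    return n_bad / n_scored, flags


def genotype_concordance(
    vcf_a: str | Path, vcf_b: str | Path, coverage_fraction: float = COVERAGE_FRACTION
) -> float:
    """Exact integer-CN agreement over record pairs with >=90% reciprocal
    overlap, across the samples shared by both files."""
    rec_a, samples_a = read_vcf_records(vcf_a)
    rec_b, samples_b = read_vcf_records(vcf_b)
    shared = [s for s in samples_a if s in set(samples_b)]
    if not shared:
        raise ValueError("no shared samples between the two VCFs")
    n_pairs = 0
    n_cn = 0
    n_eq = 0
    for ra in rec_a:
        ia = (ra["chrom"], ra["start"], ra["end"])
        for rb in rec_b:
            fa, fb = reciprocal_overlap(ia, (rb["chrom"], rb["start"], rb["end"]))
            if fa >= coverage_fraction and fb >= coverage_fraction:
                n_pairs += 1
                for s in shared:
                    ca, cb = ra["cn"][s], rb["cn"][s]
                    if ca is None or cb is None:
                        continue
                    n_cn += 1
                    n_eq += int(ca == cb)
    if n_pairs == 0 or n_cn == 0:
        raise ValueError("no matched record pairs at the coverage threshold")
    return n_eq / n_cn
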