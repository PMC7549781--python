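"""SNP-level allele-specific expression from RNA-seq allele count tables.

Input is a table of allele read counts at transcribed SNPs (one row per
SNP per sample), not alignments: counting reads over a handful of SNPs
after N-masked remapping is an upstream recipe, and the statistics start
from the counts. Positions are 1-based as printed in genome browsers; the
export helper converts explicitly to 0-based half-open intervals.

An explicit ``l_allele`` column ("ref" or "alt") maps each SNP's alleles
onto the L/E haplotypes, since ref/alt orientation need not be consistent
across SNPs.
"""

from __future__ import annotations

import math
from collections.abc import Iterable, Sequence
from dataclasses import dataclass, replace

import pandas as pd

from ._utils import round_half_away
from .ase import DIRECTION_E, DIRECTION_L, DIRECTION_NS, binomial_ase_test
from .exceptions import ValidationError

ALLELE_COUNT_COLUMNS = ["chrom", "pos", "ref_allele", "alt_allele", "sample_id",
                        "k_ref", "k_alt", "feature_label", "l_allele"]

#: Heterozygote RNA-seq coverage this skewed usually means residual
#: reference-mapping bias rather than biology.
EXTREME_SKEW = 0.95


@dataclass(frozen=True)
class AlleleCountRecord:
    chrom: str
    pos: int                      # 1-based, as printed
    ref_allele: str
    alt_allele: str
    sample_id: str
    k_ref: int
    k_alt: int
    feature_label: str
    l_allele: str = "ref"         # which allele carries the L haplotype

    def __post_init__(self):
        if self.k_ref < 0 or self.k_alt < 0:
            raise ValidationError("negative read counts")
        if self.ref_allele == self.alt_allele:
            raise ValidationError("ref and alt alleles must differ")
        if self.l_allele not in ("ref", "alt"):
            raise ValidationError("l_allele must be 'ref' or 'alt'")
        if self.pos < 1:
            raise ValidationError("positions are 1-based; pos must be >= 1")

    @property
    def k_l(self) -> int:
        return self.k_ref if self.l_allele == "ref" else self.k_alt

    @property
    def k_e(self) -> int:
        return self.k_alt if self.l_allele == "ref" else self.k_ref

    @property
    def depth(self) -> int:
        return self.k_ref + self.k_alt


@dataclass
class SnpAseResult:
    record: AlleleCountRecord
    p_value: float
    direction: str
    l_fraction: float
    skew_warning: bool
    skipped: bool = False


def test_snp_ase(record: AlleleCountRecord, p0: float = 0.5,
                 alpha: float = 0.05) -> SnpAseResult:
    """Exact binomial test of L vs E reads against 1:1 (or ``p0``) at one SNP."""
    if record.depth == 0:
        return SnpAseResult(record, 1.0, DIRECTION_NS, math.nan,
                            skew_warning=False, skipped=True)
    p = binomial_ase_test(record.k_l, record.k_e, p0)
    frac = record.k_l / record.depth
    if p < alpha:
        direction = DIRECTION_L if frac > p0 else DIRECTION_E
    else:
        direction = DIRECTION_NS
    return SnpAseResult(record, p, direction, frac,
                        skew_warning=max(frac, 1 - frac) > EXTREME_SKEW)


test_snp_ase.__test__ = False  # library API, not a pytest case


def combine_samples(records: Sequence[AlleleCountRecord]) -> AlleleCountRecord:
    """Sum counts of the same SNP across samples (order-invariant)."""
    if not records:
        raise ValidationError("no records to combine")
    first = records[0]
    for r in records[1:]:
        if (r.chrom, r.pos, r.ref_allele, r.alt_allele, r.l_allele) != \
           (first.chrom, first.pos, first.ref_allele, first.alt_allele,
                first.l_allele):
            raise ValidationError(
                f"cannot combine mismatched records at {r.chrom}:{r.pos}")
    return replace(first,
                   sample_id="+".join(sorted(r.sample_id for r in records)),
                   k_ref=sum(r.k_ref for r in records),
                   k_alt=sum(r.k_alt for r in records))


def to_bed_interval(record: AlleleCountRecord) -> tuple[str, int, int]:
    """0-based half-open interval of the SNP for BED-style export."""
    return record.chrom, record.pos - 1, record.pos


def isoform_share(fpkms: Sequence[float]) -> list[float]:
    """Each isoform's share of summed isoform abundance (FPKM or copies)."""
    if any(f < 0 for f in fpkms):
        raise ValidationError("abundances must be non-negative")
    total = float(sum(fpkms))
    if total == 0:
        raise ValidationError("all isoform abundances are zero")
    return [f / total for f in fpkms]


def isoform_share_percent(fpkm_isoform: float, *other_fpkms: float) -> int:
    """Reported percentage (nearest integer) of one isoform among all."""
    share = isoform_share([fpkm_isoform, *other_fpkms])[0]
    return round_half_away(100.0 * share)


def read_allele_counts(path) -> list[AlleleCountRecord]:
    frame = pd.read_csv(path, sep="\t")
    missing = [c for c in ALLELE_COUNT_COLUMNS if c not in frame.columns]
    if missing:
        raise ValidationError(f"allele count table missing columns: {missing}")
    return [AlleleCountRecord(
        chrom=str(r.chrom), pos=int(r.pos), ref_allele=str(r.ref_allele),
        alt_allele=str(r.alt_allele), sample_id=str(r.sample_id),
        k_ref=int(r.k_ref), k_alt=int(r.k_alt),
        feature_label=str(r.feature_label), l_allele=str(r.l_allele))
        for r in frame.itertuples()]


def write_allele_counts(records: Iterable[AlleleCountRecord], path) -> None:
    pd.DataFrame([{
        "chrom": r.chrom, "pos": r.pos, "ref_allele": r.ref_allele,
        "alt_allele": r.alt_allele, "sample_id": r.sample_id,
        "k_ref": r.k_ref, "k_alt": r.k_alt, "feature_label": r.feature_label,
        "l_allele": r.l_allele} for r in records],
        columns=ALLELE_COUNT_COLUMNS).to_csv(path, sep="\t", index=False)


def feature_ase_report(records: Sequence[AlleleCountRecord],
                       alpha: float = 0.05) -> pd.DataFrame:
    """Per-SNP tests plus a combined (summed across samples) test per SNP."""
    rows = []
    by_snp: dict[tuple, list[AlleleCountRecord]] = {}
    for rec in records:
        by_snp.setdefault((rec.chrom, rec.pos), []).append(rec)
    for (chrom, pos), recs in sorted(by_snp.items()):
        for rec in recs:
            res = test_snp_ase(rec, alpha=alpha)
            rows.append(_row(res, combined=False))
        res = test_snp_ase(combine_samples(recs), alpha=alpha)
        rows.append(_row(res, combined=True))
    return pd.DataFrame(rows)


def _row(res: SnpAseResult, combined: bool) -> dict:
    r = res.record
    return {"chrom": r.chrom, "pos": r.pos, "feature_label": r.feature_label,
            "sample_id": r.sample_id, "combined": combined,
            "k_l": r.k_l, "k_e": r.k_e, "l_fraction": res.l_fraction,
            "p_value": res.p_value, "direction": res.direction,
            "skew_warning": res.skew_warning, "skipped": res.skipped}
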