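"""Allele-expression imbalance and nonsense-mediated-decay classification.

At a heterozygous site the two alleles should be represented roughly equally
in mRNA. A truncating allele degraded by nonsense-mediated decay (NMD) is
depleted instead; a truncating allele escaping NMD (common when the premature
stop falls in the last coding exon) is not. Both are read out with an exact
binomial test on the ALT read count:

* left-sided test against a null ALT proportion of 0.45 — the null is shifted
  below 0.5 to roughly absorb reference-mapping bias — detects depletion;
* right-sided test against 0.5 (no bias assumed) detects ALT overexpression.

P-values are exact binomial tail probabilities, never normal approximations:
``p_left = P(X <= alt)`` and ``p_right = P(X >= alt)`` with
``X ~ Binomial(ref + alt, null)``.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass, field
from typing import Optional

from scipy.stats import binom

from .errors import PipelineError

TRUNCATING_CONSEQUENCES = frozenset({"nonsense", "frameshift"})

NMD_CONSISTENT = "consistent_with_nmd"
NMD_ESCAPE = "escapes_nmd"
NMD_ESCAPE_OVEREXPRESSED = "escapes_with_alt_overexpression"
NMD_NOT_APPLICABLE = "not_applicable"
NMD_INCONCLUSIVE = "inconclusive"


@dataclass(frozen=True)
class AlleleCount:
    sample_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    ref_reads: int
    alt_reads: int

    def __post_init__(self):
        if self.ref_reads < 0 or self.alt_reads < 0:
            raise PipelineError("negative allele read counts")

    @property
    def total(self) -> int:
        return self.ref_reads + self.alt_reads

    @property
    def key(self):
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class AseResult:
    counts: AlleleCount
    null_alt_proportion: float
    side: str  # 'left' or 'right'
    p_value: float


def ase_binomial_test(
    counts: AlleleCount, side: str, null_alt_proportion: float
) -> AseResult:
    """Exact one-sided binomial test of allele balance.

    left:  p = P(X <= alt_reads); right: p = P(X >= alt_reads),
    X ~ Binomial(ref + alt, null_alt_proportion).
    """
    if not 0 < null_alt_proportion < 1:
        raise PipelineError(
            f"null ALT proportion must be in (0,1), got {null_alt_proportion}"
        )
    if side not in ("left", "right"):
        raise PipelineError(f"side must be 'left' or 'right', got {side!r}")
    n = counts.total
    if n == 0:
        raise PipelineError("allele counts sum to zero; site not testable")
    if side == "left":
        p = float(binom.cdf(counts.alt_reads, n, null_alt_proportion))
    else:
        p = float(binom.sf(counts.alt_reads - 1, n, null_alt_proportion))
    return AseResult(counts, null_alt_proportion, side, min(p, 1.0))


def qualify_variant_sites(
    records: list, min_alt_reads: int = 10
) -> list:
    """Heterozygous exonic sites with sufficient ALT support.

    ``records`` are dicts (or dataclasses with the same attribute names) with
    sample_id, chrom, pos, ref, alt, genotype ('het'/'hom'/...), ref_reads,
    alt_reads and an optional ``exonic`` boolean (missing -> assumed exonic).
    Records without allele depths are skipped with a warning.
    """
    out = []
    for rec in records:
        get = rec.get if isinstance(rec, dict) else lambda k, d=None, r=rec: getattr(r, k, d)
        ref_reads, alt_reads = get("ref_reads"), get("alt_reads")
        if ref_reads is None or alt_reads is None:
            _warnings.warn(
                f"site {get('chrom')}:{get('pos')} in {get('sample_id')} "
                "has no allele depths; skipped"
            )
            continue
        if get("genotype") != "het":
            continue
        if get("exonic", True) is False:
            continue
        if alt_reads < min_alt_reads:
            continue
        out.append(
            AlleleCount(
                sample_id=get("sample_id"),
                chrom=get("chrom"),
                pos=int(get("pos")),
                ref=get("ref"),
                alt=get("alt"),
                ref_reads=int(ref_reads),
                alt_reads=int(alt_reads),
            )
        )
    return out


def read_allele_counts_vcf(path) -> list:
    """Per-sample allele-count records from a VCF 4.x with AD genotype fields.

    Returns the raw record dicts consumed by :func:`qualify_variant_sites`;
    multi-allelic sites contribute one record per ALT allele.
    """
    import pysam

    records = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf.fetch() if vcf.index is not None else vcf:
            for sample_id, call in rec.samples.items():
                gt = call.get("GT")
                ad = call.get("AD")
                alleles = [a for a in (gt or ()) if a is not None]
                if not alleles:
                    continue
                for alt_idx, alt in enumerate(rec.alts or (), start=1):
                    if alt_idx not in alleles:
                        continue
                    genotype = "het" if len(set(alleles)) > 1 else "hom"
                    ref_reads = alt_reads = None
                    if ad is not None and len(ad) > alt_idx and ad[0] is not None:
                        ref_reads, alt_reads = ad[0], ad[alt_idx]
                    records.append(
                        {
                            "sample_id": sample_id,
                            "chrom": rec.chrom,
                            "pos": rec.pos,
                            "ref": rec.ref,
                            "alt": alt,
                            "genotype": genotype,
                            "ref_reads": ref_reads,
                            "alt_reads": alt_reads,
                        }
                    )
    return records


@dataclass
class NmdCall:
    chrom: str
    pos: int
    ref: str
    alt: str
    sample_id: str
    status: str
    p_left: Optional[float] = None
    p_right: Optional[float] = None
    last_coding_exon: Optional[bool] = None
    expression_z: Optional[float] = None
    notes: list = field(default_factory=list)


def classify_nmd(
    variant,
    ase_left: Optional[AseResult],
    ase_right: Optional[AseResult] = None,
    expression_z: Optional[float] = None,
    alpha: float = 0.05,
) -> NmdCall:
    """Classify a variant's transcript fate from allele-imbalance evidence.

    Truncating heterozygous variants with a significant left-sided depletion
    test are ``consistent_with_nmd``; without depletion they ``escape`` NMD,
    upgraded to ``escapes_with_alt_overexpression`` when the right-sided test
    is significant. A premature stop in the transcript's last coding exon is
    recorded as supporting rationale for escape but never overrides the
    statistical call. Non-truncating or non-heterozygous variants are
    ``not_applicable``; truncating sites without a testable imbalance result
    are ``inconclusive``.
    """
    truncating = variant.consequence in TRUNCATING_CONSEQUENCES or getattr(
        variant, "splice_truncating", False
    )
    last_exon = None
    if variant.exon_context is not None:
        last_exon = bool(variant.exon_context[2])
    call = NmdCall(
        chrom=variant.chrom,
        pos=variant.pos,
        ref=variant.ref,
        alt=variant.alt,
        sample_id=getattr(variant, "sample_id", ""),
        status=NMD_NOT_APPLICABLE,
        last_coding_exon=last_exon,
        expression_z=expression_z,
    )
    if not truncating or variant.zygosity != "HET":
        return call
    if ase_left is None:
        call.status = NMD_INCONCLUSIVE
        call.notes.append("no allele-imbalance test available")
        return call
    call.p_left = ase_left.p_value
    if ase_right is not None:
        call.p_right = ase_right.p_value
    if ase_left.p_value < alpha:
        call.status = NMD_CONSISTENT
    else:
        call.status = NMD_ESCAPE
        if ase_right is not None and ase_right.p_value < alpha:
            call.status = NMD_ESCAPE_OVEREXPRESSED
        if last_exon:
            call.notes.append("premature stop in last coding exon supports escape")
    if expression_z is not None and abs(expression_z) < 2.0:
        call.notes.append("normal overall gene expression")
    return call
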