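"""Percent-spliced-in and per-gene normalized exon usage.

PSI for a collapsed exon bin is computed purely from junction-spanning reads:
inclusion support is the mean of the two flanking inclusion junction counts
(the single available flank for first/last bins), exclusion support is the sum
of counts over junctions that bridge the bin entirely, and
``psi = inclusion / (inclusion + exclusion)``.

Exon usage normalizes collapsed-exon read counts within each gene by exon
length (a per-gene transcripts-per-million scheme), yielding usage fractions
that sum to one over the gene's bins, so a change in one exon's representation
is visible independent of overall gene expression. Outlying usage in one
sample is flagged with a robust z-score (median/MAD) against the cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .annotation import AnnotationIndex, ExonBin
from .errors import PipelineError
from .junctions import CohortJunctionMatrix

MAD_CONSISTENCY = 1.4826  # normal-consistency factor for median absolute deviation


@dataclass
class PsiValue:
    sample_id: str
    gene: str
    bin_id: str
    inclusion_reads: Optional[float]
    exclusion_reads: int
    psi: Optional[float]
    flags: set = field(default_factory=set)


def _flank_counts(bin: ExonBin, matrix: CohortJunctionMatrix, index: AnnotationIndex, sample_id):
    """(upstream_flank, downstream_flank) inclusion counts, None when the
    catalog has no junction abutting that side of the bin."""
    cat = index.catalog
    gene = bin.gene_symbol
    up_exists = (bin.start - 1) in cat.ends.get(gene, ())
    down_exists = (bin.end + 1) in cat.starts.get(gene, ())

    meta = matrix.meta
    up = down = None
    if up_exists:
        m = (meta["chrom"] == bin.chrom) & (meta["end"] == bin.start - 1)
        up = int(matrix.counts.loc[m.to_numpy(), sample_id].sum())
    if down_exists:
        m = (meta["chrom"] == bin.chrom) & (meta["start"] == bin.end + 1)
        down = int(matrix.counts.loc[m.to_numpy(), sample_id].sum())
    return up, down


def compute_psi(
    bin: ExonBin,
    matrix: CohortJunctionMatrix,
    index: AnnotationIndex,
    sample_id: str,
    flank_mode: str = "mean",
) -> PsiValue:
    """PSI of one exon bin in one sample from junction-spanning reads only.

    ``flank_mode`` 'mean' (default) or 'sum' controls how the two flanking
    inclusion counts are combined. Exclusion counts any junction in the matrix
    (annotated or not) whose intron covers the whole bin.
    """
    if flank_mode not in ("mean", "sum"):
        raise ValueError(f"flank_mode must be 'mean' or 'sum', got {flank_mode!r}")
    up, down = _flank_counts(bin, matrix, index, sample_id)
    flanks = [c for c in (up, down) if c is not None]
    if not flanks:
        return PsiValue(
            sample_id, bin.gene_symbol, bin.bin_id, None, 0, None,
            flags={"no_flanking_junctions"},
        )
    inclusion = float(np.mean(flanks)) if flank_mode == "mean" else float(np.sum(flanks))

    meta = matrix.meta
    bridging = (
        (meta["chrom"] == bin.chrom)
        & (meta["start"] < bin.start)
        & (meta["end"] > bin.end)
    )
    exclusion = int(matrix.counts.loc[bridging.to_numpy(), sample_id].sum())

    flags = set()
    if len(flanks) == 1:
        flags.add("single_flank")
    denom = inclusion + exclusion
    psi = inclusion / denom if denom > 0 else None
    if psi is None:
        flags.add("no_spliced_reads")
    return PsiValue(sample_id, bin.gene_symbol, bin.bin_id, inclusion, exclusion, psi, flags)


def compute_psi_table(
    matrix: CohortJunctionMatrix, index: AnnotationIndex, flank_mode: str = "mean"
) -> pd.DataFrame:
    """PSI for every (gene bin, sample) as a long-form DataFrame."""
    rows = []
    for gene in index.genes():
        for bin in index.bins[gene]:
            for sample_id in matrix.samples:
                v = compute_psi(bin, matrix, index, sample_id, flank_mode=flank_mode)
                rows.append(
                    {
                        "sample_id": v.sample_id,
                        "gene": v.gene,
                        "bin_id": v.bin_id,
                        "inclusion_reads": v.inclusion_reads,
                        "exclusion_reads": v.exclusion_reads,
                        "psi": v.psi,
                        "flags": ";".join(sorted(v.flags)),
                    }
                )
    return pd.DataFrame(
        rows,
        columns=["sample_id", "gene", "bin_id", "inclusion_reads",
                 "exclusion_reads", "psi", "flags"],
    )


@dataclass
class ExonUsage:
    sample_id: str
    gene: str
    bin_id: str
    raw_count: int
    length_normalized_rate: float
    usage_fraction: Optional[float]
    flags: set = field(default_factory=set)


def normalize_exon_usage(counts: dict, bins: list, sample_id: str = "") -> list:
    """Length-normalize one gene's bin counts for one sample.

    ``counts`` maps bin_id -> raw count; every count must refer to a known bin.
    Rates are reads per kilobase of bin; usage fractions are rates divided by
    the gene total (absent, with flag ``unexpressed``, for an all-zero gene).
    """
    by_id = {b.bin_id: b for b in bins}
    unknown = sorted(set(counts) - set(by_id))
    if unknown:
        raise PipelineError(f"counts reference unknown exon bins: {unknown}")
    rates = {
        bin_id: counts.get(bin_id, 0) / (by_id[bin_id].length_bp / 1000.0)
        for bin_id in by_id
    }
    total = sum(rates.values())
    out = []
    for b in bins:
        rate = rates[b.bin_id]
        if total > 0:
            out.append(
                ExonUsage(sample_id, b.gene_symbol, b.bin_id,
                          int(counts.get(b.bin_id, 0)), rate, rate / total)
            )
        else:
            out.append(
                ExonUsage(sample_id, b.gene_symbol, b.bin_id,
                          int(counts.get(b.bin_id, 0)), rate, None,
                          flags={"unexpressed"})
            )
    return out


def usage_table(exon_counts: pd.DataFrame, index: AnnotationIndex) -> pd.DataFrame:
    """Cohort exon-usage table from long-form counts (sample_id, gene, bin_id, count)."""
    rows = []
    for (sample_id, gene), grp in exon_counts.groupby(["sample_id", "gene"], sort=True):
        if gene not in index.bins:
            raise PipelineError(f"exon counts reference unknown gene {gene}")
        counts = dict(zip(grp["bin_id"], grp["count"]))
        for u in normalize_exon_usage(counts, index.bins[gene], sample_id):
            rows.append(
                {
                    "sample_id": u.sample_id,
                    "gene": u.gene,
                    "bin_id": u.bin_id,
                    "raw_count": u.raw_count,
                    "length_normalized_rate": u.length_normalized_rate,
                    "usage_fraction": u.usage_fraction,
                    "flags": ";".join(sorted(u.flags)),
                }
            )
    return pd.DataFrame(
        rows,
        columns=["sample_id", "gene", "bin_id", "raw_count",
                 "length_normalized_rate", "usage_fraction", "flags"],
    )


@dataclass(frozen=True)
class UsageOutlier:
    gene: str
    bin_id: str
    z_score: float
    usage_fraction: float
    cohort_median: float


@dataclass
class OutlierResult:
    outliers: list
    flags: set = field(default_factory=set)


def flag_usage_outliers(
    usage: pd.DataFrame,
    sample_id: str,
    z_threshold: float = 3.0,
    min_fold_change: float = 1.6,
) -> OutlierResult:
    """Exon bins where one sample's usage fraction is a cohort outlier.

    The deviation is measured as a robust z-score against the cohort median
    with MAD scale (1.4826 consistency factor). A bin is flagged only when
    both |z| >= ``z_threshold`` and the usage odds ``f/(1-f)`` differ from the
    cohort-median odds by at least ``min_fold_change`` in either direction —
    scaling one bin's count by k scales its usage odds by exactly k, so the
    odds ratio reads directly as the fold-change of the underlying count and
    does not saturate for high-usage bins. The magnitude condition encodes
    that a shift must be large enough to matter, not merely precise relative
    to a tight cohort. Bins with fewer than 3
    samples carrying a defined fraction are skipped; a cohort smaller than 3
    yields an empty result with flag ``insufficient_cohort``.
    """
    result = OutlierResult(outliers=[])
    if usage["sample_id"].nunique() < 3:
        result.flags.add("insufficient_cohort")
        return result
    defined = usage[usage["usage_fraction"].notna()]
    for (gene, bin_id), grp in defined.groupby(["gene", "bin_id"], sort=True):
        if len(grp) < 3:
            continue
        target = grp[grp["sample_id"] == sample_id]
        if target.empty:
            continue
        x = float(target["usage_fraction"].iloc[0])
        vals = grp["usage_fraction"].to_numpy(dtype=float)
        med = float(np.median(vals))
        mad = float(np.median(np.abs(vals - med)))
        delta = x - med
        if 0 < x < 1 and 0 < med < 1:
            odds_x, odds_m = x / (1 - x), med / (1 - med)
            fold = max(odds_x / odds_m, odds_m / odds_x)
        else:
            fold = np.inf if x != med else 1.0
        if fold < min_fold_change:
            continue
        scale = MAD_CONSISTENCY * mad
        z = delta / scale if scale > 0 else np.inf * np.sign(delta)
        if abs(z) >= z_threshold:
            result.outliers.append(UsageOutlier(gene, bin_id, float(z), x, med))
    result.outliers.sort(key=lambda o: (o.gene, o.bin_id))
    return result


def gene_expression_z(exon_counts: pd.DataFrame) -> pd.DataFrame:
    """Robust cohort z-score of gene-level expression per sample.

    Gene totals are normalized by each sample's grand total, log2(x+1)
    transformed, and scored as (value - cohort median) / (1.4826 * MAD).
    Used as the simple outlier-expression check accompanying truncating
    variants (|z| < 2 reads as normal overall expression).
    """
    totals = exon_counts.groupby(["sample_id", "gene"], sort=True)["count"].sum().unstack(fill_value=0)
    lib = totals.sum(axis=1)
    norm = np.log2(totals.div(lib.replace(0, np.nan), axis=0) * 1e6 + 1)
    med = norm.median(axis=0)
    dev = norm - med
    mad = dev.abs().median(axis=0) * MAD_CONSISTENCY
    z = dev.div(mad.replace(0, np.nan))
    z = z.where(dev != 0, 0.0)  # zero deviation is zero z even at zero MAD
    z = z.mask(z.isna(), np.inf * np.sign(dev))
    out = z.stack().rename("expression_z").reset_index()
    return out
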