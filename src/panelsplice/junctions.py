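"""Splice-junction analysis.

Reads per-sample STAR ``SJ.out.tab`` junction tables, combines them into a
cohort matrix annotated against the panel junction catalog, and applies the
two-stage novel-junction filter used for diagnostic triage:

1. an unannotated junction needs >= 10 non-duplicate uniquely mapped reads
   (clinical SNP-calling convention), and
2. its support must reach >= 10% of the overlapping canonical junction
   (the strongest annotated junction sharing one of its splice sites).

Candidate events are then classified as exon skips, novel donor/acceptor use,
novel pairings, or — for annotated junctions whose cohort-normalized usage
drops while the intron accumulates coverage — intron retention.

Multimapping reads are never counted toward junction support; only the
``unique_reads`` column of SJ.out.tab enters any statistic. A per-sample
pre-filter drops junctions with fewer than 5 supporting reads, mirroring the
alignment-stage filter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .annotation import AnnotationIndex
from .errors import FormatError, PipelineError

STRAND_OF_CODE = {0: ".", 1: "+", 2: "-"}

#: annotation status values for a junction in the cohort matrix
ANNOTATED = "annotated"
NOVEL_BOTH = "novel_both_sites_known"
NOVEL_ONE = "novel_one_site_known"
NOVEL_UNKNOWN = "novel_unknown"


@dataclass(frozen=True)
class JunctionRecord:
    chrom: str
    intron_start: int  # first intronic base, 1-based
    intron_end: int  # last intronic base, 1-based
    strand_code: int
    motif_code: int
    annotated_flag: int
    unique_reads: int
    multimapping_reads: int
    max_overhang: int

    def __post_init__(self):
        if self.intron_start > self.intron_end:
            raise FormatError(
                f"junction {self.chrom}:{self.intron_start}-{self.intron_end} inverted"
            )
        if self.unique_reads < 0 or self.multimapping_reads < 0:
            raise FormatError("negative junction read counts")

    @property
    def strand(self) -> str:
        return STRAND_OF_CODE[self.strand_code]

    @property
    def key(self):
        return (self.chrom, self.intron_start, self.intron_end, self.strand)


def read_junction_table(path, min_reads_prefilter: int = 5) -> list:
    """Parse one STAR SJ.out.tab file (9 tab-separated columns).

    Junctions with ``unique_reads`` below ``min_reads_prefilter`` are dropped.
    Multimapping read counts are carried for reference but never contribute to
    support anywhere downstream.
    """
    records = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) != 9:
            raise FormatError(
                f"{path}: line {lineno}: expected 9 columns (SJ.out.tab), got {len(fields)}"
            )
        try:
            rec = JunctionRecord(
                chrom=fields[0],
                intron_start=int(fields[1]),
                intron_end=int(fields[2]),
                strand_code=int(fields[3]),
                motif_code=int(fields[4]),
                annotated_flag=int(fields[5]),
                unique_reads=int(fields[6]),
                multimapping_reads=int(fields[7]),
                max_overhang=int(fields[8]),
            )
        except ValueError as exc:
            raise FormatError(f"{path}: line {lineno}: {exc}") from exc
        if rec.unique_reads >= min_reads_prefilter:
            records.append(rec)
    return records


@dataclass
class CohortJunctionMatrix:
    """Per-junction x per-sample unique read counts with annotation metadata.

    ``counts`` is indexed by junction key ``(chrom, start, end, strand)`` with
    one column per sample; absent sample x junction entries are 0. ``meta``
    shares the index and carries status / gene / transcripts.
    """

    counts: pd.DataFrame
    meta: pd.DataFrame

    @property
    def samples(self) -> list:
        return list(self.counts.columns)

    @property
    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def count(self, key, sample_id) -> int:
        return int(self.counts.at[key, sample_id])


def _annotate_junction(index: AnnotationIndex, chrom, start, end, strand):
    """Return (status, gene, transcripts) for one junction key."""
    hit = index.catalog.lookup(chrom, start, end, strand)
    if hit:
        key, tids = hit
        return ANNOTATED, index.catalog.gene_of_intron[key], tuple(sorted(tids))
    gene = index.assign_gene(chrom, start, end)
    if gene is None:
        return NOVEL_UNKNOWN, None, ()
    known_start = start in index.catalog.starts.get(gene, ())
    known_end = end in index.catalog.ends.get(gene, ())
    if known_start and known_end:
        return NOVEL_BOTH, gene, ()
    if known_start or known_end:
        return NOVEL_ONE, gene, ()
    return NOVEL_UNKNOWN, gene, ()


def build_cohort_matrix(samples: dict, index: AnnotationIndex) -> CohortJunctionMatrix:
    """Combine per-sample junction records into one cohort matrix.

    ``samples`` maps sample_id -> list of JunctionRecord. Junction keys are the
    union across samples; a duplicate key within one sample is an error.
    """
    if not samples:
        raise PipelineError("build_cohort_matrix requires at least one sample")
    col_data = {}
    for sample_id, records in samples.items():
        seen = {}
        for rec in records:
            if rec.key in seen:
                raise PipelineError(
                    f"sample {sample_id}: duplicate junction {rec.key}"
                )
            seen[rec.key] = rec.unique_reads
        col_data[sample_id] = seen

    all_keys = sorted({k for col in col_data.values() for k in col})
    counts = pd.DataFrame(
        {
            s: [col_data[s].get(k, 0) for k in all_keys]
            for s in col_data
        },
        index=pd.Index(all_keys, tupleize_cols=False),
        dtype=int,
    )

    meta_rows = []
    for chrom, start, end, strand in all_keys:
        status, gene, tids = _annotate_junction(index, chrom, start, end, strand)
        meta_rows.append(
            {
                "chrom": chrom,
                "start": start,
                "end": end,
                "strand": strand,
                "status": status,
                "gene": gene,
                "transcripts": tids,
            }
        )
    meta = pd.DataFrame(meta_rows, index=counts.index)
    return CohortJunctionMatrix(counts=counts, meta=meta)


@dataclass
class SpliceEvent:
    """A candidate aberrant-splicing observation in one sample."""

    sample_id: str
    gene: Optional[str]
    chrom: str
    start: int
    end: int
    strand: str
    status: str
    supporting_reads: int
    canonical_reference_reads: Optional[int] = None
    support_fraction: Optional[float] = None
    usage_ratio: Optional[float] = None
    event_class: Optional[str] = None
    skipped_bins: tuple = ()
    flags: set = field(default_factory=set)

    @property
    def key(self):
        return (self.chrom, self.start, self.end, self.strand)


def _canonical_reference(matrix: CohortJunctionMatrix, key, sample_id, mode: str):
    """Same-sample read count of annotated junctions sharing a splice site.

    ``mode`` 'max' (default, the hardest denominator to pass) or 'sum'.
    Returns None when no annotated junction shares a site with the candidate.
    """
    chrom, start, end, _ = key
    meta = matrix.meta
    mask = (
        (meta["status"] == ANNOTATED)
        & (meta["chrom"] == chrom)
        & ((meta["start"] == start) | (meta["end"] == end))
    )
    if not mask.any():
        return None
    vals = matrix.counts.loc[mask.to_numpy(), sample_id]
    return int(vals.max()) if mode == "max" else int(vals.sum())


def filter_candidate_junctions(
    matrix: CohortJunctionMatrix,
    min_reads: int = 10,
    min_fraction: float = 0.10,
    reference_mode: str = "max",
) -> list:
    """Apply both novel-junction rules; one event per passing (junction, sample).

    A candidate with no overlapping canonical junction cannot be held to the
    fraction rule and passes it with flag ``no_canonical_reference``. Every
    emitted event carries ``needs_manual_review`` (read-level confirmation is
    outside this pipeline).
    """
    if reference_mode not in ("max", "sum"):
        raise ValueError(f"reference_mode must be 'max' or 'sum', got {reference_mode!r}")
    events = []
    novel = matrix.meta.index[(matrix.meta["status"] != ANNOTATED).to_numpy()]
    for key in novel:
        row = matrix.meta.loc[[key]].iloc[0]
        for sample_id in matrix.samples:
            n = int(matrix.counts.at[key, sample_id])
            if n < min_reads:
                continue
            ref = _canonical_reference(matrix, key, sample_id, reference_mode)
            flags = {"needs_manual_review"}
            if ref is None:
                frac = None
                flags.add("no_canonical_reference")
            elif ref == 0:
                frac = None
                flags.add("zero_canonical_reference")
            else:
                frac = n / ref
                if frac < min_fraction:
                    continue
            events.append(
                SpliceEvent(
                    sample_id=sample_id,
                    gene=row["gene"],
                    chrom=row["chrom"],
                    start=int(row["start"]),
                    end=int(row["end"]),
                    strand=row["strand"],
                    status=row["status"],
                    supporting_reads=n,
                    canonical_reference_reads=ref,
                    support_fraction=frac,
                    flags=flags,
                )
            )
    events.sort(key=lambda e: (e.sample_id, e.chrom, e.start, e.end, e.strand))
    return events


def canonical_usage_ratio(
    matrix: CohortJunctionMatrix, key, sample_id
) -> Optional[float]:
    """Library-size-normalized usage of an annotated junction relative to the
    median of the other samples.

    Library size is the sample's total unique junction reads. Returns None when
    the median normalized count of the other samples is zero (ratio undefined).
    """
    if len(matrix.samples) < 2:
        raise PipelineError("canonical_usage_ratio needs a cohort of >= 2 samples")
    lib = matrix.library_sizes
    if lib[sample_id] == 0:
        return None
    others = [s for s in matrix.samples if s != sample_id]
    other_norm = [matrix.counts.at[key, s] / lib[s] for s in others if lib[s] > 0]
    if not other_norm:
        return None
    med = float(np.median(other_norm))
    if med == 0.0:
        return None
    return (matrix.counts.at[key, sample_id] / lib[sample_id]) / med


def _spanned_bins(index: AnnotationIndex, gene: str, start: int, end: int) -> tuple:
    """Exon bins of ``gene`` fully contained in the intron [start, end]."""
    return tuple(
        b.bin_id for b in index.bins.get(gene, []) if start <= b.start and b.end <= end
    )


def _novel_side(index: AnnotationIndex, event: SpliceEvent) -> Optional[str]:
    """'donor' or 'acceptor' for the unannotated side of a one-site-novel event."""
    gene = event.gene
    known_start = event.start in index.catalog.starts.get(gene, ())
    strand = index.gene_strand(gene)
    # on '+' the intron start is the donor side; on '-' it is the acceptor side
    if known_start:
        novel_at_start = False
    else:
        novel_at_start = True
    if strand == "+":
        return "donor" if novel_at_start else "acceptor"
    return "acceptor" if novel_at_start else "donor"


def lookup_intron_coverage(
    intron_coverage: Optional[pd.DataFrame], gene, chrom, start, end, sample_id
):
    """Row of the per-intron coverage table for one intron/sample, or None.

    Expected columns: chrom, start, end, gene, sample_id, mean_depth and
    optionally flank_depth (mean coverage of the flanking exons).
    """
    if intron_coverage is None or intron_coverage.empty:
        return None
    m = (
        (intron_coverage["chrom"] == chrom)
        & (intron_coverage["start"] == start)
        & (intron_coverage["end"] == end)
        & (intron_coverage["sample_id"] == sample_id)
    )
    if "gene" in intron_coverage.columns:
        m &= intron_coverage["gene"] == gene
    hits = intron_coverage[m]
    return None if hits.empty else hits.iloc[0]


def classify_event(
    event: SpliceEvent,
    index: AnnotationIndex,
    intron_coverage: Optional[pd.DataFrame] = None,
    usage_ratio_threshold: float = 0.8,
    min_intron_coverage: float = 5.0,
    rel_flank_coverage: float = 0.10,
) -> SpliceEvent:
    """Assign an event class in place and return the event.

    Novel junctions: both sites annotated and spanning at least one whole exon
    bin -> ``exon_skip``; both sites annotated otherwise -> ``novel_pair``; one
    annotated site -> ``novel_donor`` / ``novel_acceptor`` by which side is
    unannotated (strand-aware).

    Annotated junctions are tested for intron retention: cohort usage ratio
    below ``usage_ratio_threshold`` and mean intron coverage of at least
    ``max(min_intron_coverage, rel_flank_coverage * flanking exon coverage)``.
    Missing coverage data leaves the class unset with flag
    ``coverage_unavailable``.
    """
    if event.status == ANNOTATED:
        if event.usage_ratio is None or event.usage_ratio >= usage_ratio_threshold:
            return event
        cov = lookup_intron_coverage(
            intron_coverage, event.gene, event.chrom, event.start, event.end, event.sample_id
        )
        if cov is None:
            event.flags.add("coverage_unavailable")
            return event
        threshold = min_intron_coverage
        if "flank_depth" in cov.index and not pd.isna(cov["flank_depth"]):
            threshold = max(threshold, rel_flank_coverage * float(cov["flank_depth"]))
        if float(cov["mean_depth"]) >= threshold:
            event.event_class = "intron_retention"
        return event

    if event.gene is None:
        event.flags.add("unassigned_gene")
        return event

    if event.status == NOVEL_BOTH:
        spanned = _spanned_bins(index, event.gene, event.start, event.end)
        if spanned:
            event.event_class = "exon_skip"
            event.skipped_bins = spanned
        else:
            event.event_class = "novel_pair"
    elif event.status == NOVEL_ONE:
        side = _novel_side(index, event)
        event.event_class = f"novel_{side}"
    return event


def detect_retention_events(
    matrix: CohortJunctionMatrix,
    index: AnnotationIndex,
    intron_coverage: Optional[pd.DataFrame],
    usage_ratio_threshold: float = 0.8,
    min_intron_coverage: float = 5.0,
    rel_flank_coverage: float = 0.10,
) -> list:
    """Scan annotated junctions for intron retention across the cohort.

    Constructs a usage-anomaly event for every (annotated junction, sample)
    whose cohort usage ratio falls below the threshold, then classifies it
    against the intron coverage table; only events classified
    ``intron_retention`` are returned.
    """
    if len(matrix.samples) < 2:
        return []
    events = []
    annotated = matrix.meta.index[(matrix.meta["status"] == ANNOTATED).to_numpy()]
    for key in annotated:
        row = matrix.meta.loc[[key]].iloc[0]
        for sample_id in matrix.samples:
            ratio = canonical_usage_ratio(matrix, key, sample_id)
            if ratio is None or ratio >= usage_ratio_threshold:
                continue
            event = SpliceEvent(
                sample_id=sample_id,
                gene=row["gene"],
                chrom=row["chrom"],
                start=int(row["start"]),
                end=int(row["end"]),
                strand=row["strand"],
                status=ANNOTATED,
                supporting_reads=int(matrix.counts.at[key, sample_id]),
                usage_ratio=ratio,
                flags={"needs_manual_review"},
            )
            classify_event(
                event,
                index,
                intron_coverage,
                usage_ratio_threshold=usage_ratio_threshold,
                min_intron_coverage=min_intron_coverage,
                rel_flank_coverage=rel_flank_coverage,
            )
            if event.event_class == "intron_retention":
                events.append(event)
    events.sort(key=lambda e: (e.sample_id, e.chrom, e.start, e.end, e.strand))
    return events


def events_to_frame(events: list) -> pd.DataFrame:
    """Tabular view of SpliceEvents (stable column order, sorted flags)."""
    rows = []
    for e in events:
        rows.append(
            {
                "sample_id": e.sample_id,
                "gene": e.gene,
                "chrom": e.chrom,
                "start": e.start,
                "end": e.end,
                "strand": e.strand,
                "status": e.status,
                "event_class": e.event_class,
                "supporting_reads": e.supporting_reads,
                "canonical_reference_reads": e.canonical_reference_reads,
                "support_fraction": e.support_fraction,
                "usage_ratio": e.usage_ratio,
                "skipped_bins": ";".join(e.skipped_bins),
                "flags": ";".join(sorted(e.flags)),
            }
        )
    cols = [
        "sample_id", "gene", "chrom", "start", "end", "strand", "status",
        "event_class", "supporting_reads", "canonical_reference_reads",
        "support_fraction", "usage_ratio", "skipped_bins", "flags",
    ]
    return pd.DataFrame(rows, columns=cols)
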