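"""Panel annotation models.

Parses a gene-panel definition and a (GENCODE-dialect) GTF into the three
structures the rest of the pipeline works against:

* :class:`TranscriptModel` — ordered exon intervals per transcript, with the
  index of the last coding exon when CDS features are present;
* collapsed :class:`ExonBin` s — disjoint intervals obtained by flattening the
  overlapping exons of all of a gene's transcripts (DEXSeq-style), so exon
  counts are unambiguous;
* :class:`JunctionCatalog` — every annotated intron keyed by
  ``(chrom, intron_start, intron_end, strand)`` with the transcripts using it,
  plus per-gene indexes of annotated splice-site positions.

All coordinates are 1-based closed intervals, matching both GTF and the STAR
``SJ.out.tab`` junction convention, and intron coordinates are the first and
last intronic base.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import gffutils

from .errors import AnnotationError

PANEL_CLASSES = frozenset({"PID", "VEOIBD"})


@dataclass(frozen=True)
class PanelEntry:
    gene_symbol: str
    classes: frozenset

    def __post_init__(self):
        if not self.classes:
            raise AnnotationError(f"panel gene {self.gene_symbol} has no disease class")
        unknown = set(self.classes) - PANEL_CLASSES
        if unknown:
            raise AnnotationError(
                f"panel gene {self.gene_symbol} has unknown classes {sorted(unknown)}"
            )


@dataclass
class GenePanel:
    """A targeted panel: gene symbols tagged with disease classes (PID / VEOIBD)."""

    entries: list

    def __post_init__(self):
        symbols = [e.gene_symbol for e in self.entries]
        if len(symbols) != len(set(symbols)):
            dupes = sorted({s for s in symbols if symbols.count(s) > 1})
            raise AnnotationError(f"duplicate panel gene symbols: {dupes}")

    @classmethod
    def from_entries(cls, entries: Iterable) -> "GenePanel":
        return cls([PanelEntry(g, frozenset(c)) for g, c in entries])

    @classmethod
    def from_tsv(cls, path) -> "GenePanel":
        """Read a two-column TSV: gene_symbol <tab> semicolon-separated classes."""
        entries = []
        for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 2:
                raise AnnotationError(
                    f"{path}: line {lineno}: expected 2 tab-separated columns, got {len(fields)}"
                )
            gene, classes = fields
            entries.append((gene, [c for c in classes.split(";") if c]))
        return cls.from_entries(entries)

    def genes(self) -> list:
        return [e.gene_symbol for e in self.entries]

    def classes_of(self, gene: str) -> frozenset:
        for e in self.entries:
            if e.gene_symbol == gene:
                return e.classes
        raise KeyError(gene)


@dataclass(frozen=True)
class PanelSummary:
    n_total: int
    n_pid: int
    n_veoibd: int
    n_both: int


def panel_summary(panel: GenePanel) -> PanelSummary:
    """Class composition of the panel; satisfies inclusion-exclusion
    ``n_pid + n_veoibd - n_both == n_total`` by construction."""
    n_pid = sum("PID" in e.classes for e in panel.entries)
    n_veo = sum("VEOIBD" in e.classes for e in panel.entries)
    n_both = sum(len(e.classes) == 2 for e in panel.entries)
    return PanelSummary(len(panel.entries), n_pid, n_veo, n_both)


@dataclass
class TranscriptModel:
    transcript_id: str
    gene_symbol: str
    chrom: str
    strand: str
    exons: list  # ordered list of (start, end), 1-based closed, genomic order
    coding_end_exon_index: Optional[int] = None  # index into ``exons`` (genomic order)
    coding_end_low_confidence: bool = False

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"{self.transcript_id}: bad strand {self.strand!r}")
        prev_end = None
        for s, e in self.exons:
            if s > e:
                raise AnnotationError(f"{self.transcript_id}: exon interval [{s},{e}] inverted")
            if prev_end is not None and s <= prev_end:
                raise AnnotationError(
                    f"{self.transcript_id}: exons overlap or are unsorted at [{s},{e}]"
                )
            prev_end = e

    def introns(self) -> list:
        """Gaps between consecutive exons as (first, last) intronic base."""
        return [
            (self.exons[i][1] + 1, self.exons[i + 1][0] - 1)
            for i in range(len(self.exons) - 1)
        ]

    def last_coding_exon_index(self) -> Optional[int]:
        """Genomic-order index of the last coding exon in *transcript* orientation."""
        return self.coding_end_exon_index


@dataclass(frozen=True)
class ExonBin:
    gene_symbol: str
    bin_id: str
    chrom: str
    start: int
    end: int

    @property
    def length_bp(self) -> int:
        return self.end - self.start + 1


def flatten_exons(transcripts: list) -> list:
    """Collapse the exons of one gene's transcripts into disjoint bins.

    Bin boundaries fall exactly at the distinct exon start/end coordinates, so
    every base covered by some transcript exon lands in exactly one bin and the
    operation is idempotent.
    """
    if not transcripts:
        return []
    genes = {t.gene_symbol for t in transcripts}
    if len(genes) > 1:
        raise AnnotationError(f"flatten_exons requires a single gene, got {sorted(genes)}")
    gene = genes.pop()
    chroms = {t.chrom for t in transcripts}
    if len(chroms) > 1:
        raise AnnotationError(f"gene {gene} has exons on multiple chromosomes: {sorted(chroms)}")
    chrom = chroms.pop()

    intervals = [iv for t in transcripts for iv in t.exons]
    cuts = sorted({s for s, _ in intervals} | {e + 1 for _, e in intervals})
    bins = []
    for a, b in zip(cuts[:-1], cuts[1:]):
        seg = (a, b - 1)
        if any(s <= seg[0] and seg[1] <= e for s, e in intervals):
            bins.append(seg)
    return [
        ExonBin(gene, f"{gene}:{i:03d}", chrom, s, e)
        for i, (s, e) in enumerate(bins, start=1)
    ]


@dataclass
class JunctionCatalog:
    """Annotated introns and per-gene splice-site indexes."""

    introns: dict = field(default_factory=dict)  # (chrom,start,end,strand) -> set of tids
    gene_of_intron: dict = field(default_factory=dict)
    starts: dict = field(default_factory=dict)  # gene -> set of intron start positions
    ends: dict = field(default_factory=dict)  # gene -> set of intron end positions

    def add(self, chrom: str, start: int, end: int, strand: str, gene: str, tid: str):
        key = (chrom, start, end, strand)
        self.introns.setdefault(key, set()).add(tid)
        self.gene_of_intron[key] = gene
        self.starts.setdefault(gene, set()).add(start)
        self.ends.setdefault(gene, set()).add(end)

    def lookup(self, chrom: str, start: int, end: int, strand: str):
        """Transcripts using this intron, or None. Unknown strand ('.') matches either."""
        if strand == ".":
            for st in ("+", "-"):
                hit = self.introns.get((chrom, start, end, st))
                if hit:
                    return (chrom, start, end, st), hit
            return None
        key = (chrom, start, end, strand)
        hit = self.introns.get(key)
        return (key, hit) if hit else None


@dataclass
class AnnotationIndex:
    panel: GenePanel
    transcripts: dict  # gene -> list of TranscriptModel
    bins: dict  # gene -> list of ExonBin
    catalog: JunctionCatalog
    gene_spans: dict  # gene -> (chrom, start, end, strand)
    warnings: list = field(default_factory=list)

    def genes(self) -> list:
        return sorted(self.transcripts)

    def assign_gene(self, chrom: str, start: int, end: int) -> Optional[str]:
        """Gene whose span contains both splice sites; ties go to the gene
        sharing the most annotated splice sites, then lexicographic symbol."""
        candidates = [
            g
            for g, (c, s, e, _) in self.gene_spans.items()
            if c == chrom and s <= start and end <= e
        ]
        if not candidates:
            return None
        if len(candidates) == 1:
            return candidates[0]

        def score(g):
            shared = (start in self.catalog.starts.get(g, ())) + (
                end in self.catalog.ends.get(g, ())
            )
            return (-shared, g)

        return min(candidates, key=score)

    def gene_strand(self, gene: str) -> str:
        return self.gene_spans[gene][3]


def _validate_gtf_lines(gtf_path):
    for lineno, line in enumerate(Path(gtf_path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        if len(line.split("\t")) < 8:
            raise AnnotationError(
                f"{gtf_path}: line {lineno}: not a valid GTF record (fewer than 8 fields)"
            )


def index_from_transcripts(
    panel: GenePanel, transcripts_by_gene: dict, warnings: Optional[list] = None
) -> AnnotationIndex:
    """Assemble an AnnotationIndex from already-built transcript models."""
    bins = {g: flatten_exons(ts) for g, ts in transcripts_by_gene.items()}
    catalog = JunctionCatalog()
    spans = {}
    for gene, ts in transcripts_by_gene.items():
        lo = min(t.exons[0][0] for t in ts)
        hi = max(t.exons[-1][1] for t in ts)
        spans[gene] = (ts[0].chrom, lo, hi, ts[0].strand)
        for t in ts:
            for s, e in t.introns():
                catalog.add(t.chrom, s, e, t.strand, gene, t.transcript_id)
    return AnnotationIndex(
        panel=panel,
        transcripts=transcripts_by_gene,
        bins=bins,
        catalog=catalog,
        gene_spans=spans,
        warnings=warnings or [],
    )


def load_annotation(gtf_path, panel: GenePanel) -> AnnotationIndex:
    """Parse a GTF restricted to panel genes into an :class:`AnnotationIndex`.

    Panel genes absent from the GTF are recorded as warnings; finding zero
    panel genes is a hard error. Transcript models keep the genomic-order index
    of the last coding exon (from CDS features when present; otherwise the
    transcript's last exon, flagged low-confidence).
    """
    gtf_path = Path(gtf_path)
    if not gtf_path.exists():
        raise AnnotationError(f"GTF not found: {gtf_path}")
    _validate_gtf_lines(gtf_path)
    try:
        db = gffutils.create_db(
            str(gtf_path),
            ":memory:",
            disable_infer_genes=True,
            disable_infer_transcripts=True,
            keep_order=True,
        )
    except Exception as exc:  # gffutils raises assorted types on bad input
        raise AnnotationError(f"failed to parse GTF {gtf_path}: {exc}") from exc

    wanted = set(panel.genes())
    transcripts: dict = {}
    for t in db.features_of_type("transcript"):
        gene = t.attributes.get("gene_name", [None])[0]
        if gene not in wanted:
            continue
        exons = sorted(
            (f.start, f.end) for f in db.children(t, featuretype="exon")
        )
        if not exons:
            continue
        cds = sorted((f.start, f.end) for f in db.children(t, featuretype="CDS"))
        coding_idx, low_conf = None, False
        if cds:
            # last coding exon in transcript orientation: the exon containing
            # the CDS end (+) or CDS start (-)
            pos = cds[-1][1] if t.strand == "+" else cds[0][0]
            for i, (s, e) in enumerate(exons):
                if s <= pos <= e:
                    coding_idx = i
                    break
        else:
            coding_idx = len(exons) - 1 if t.strand == "+" else 0
            low_conf = True
        transcripts.setdefault(gene, []).append(
            TranscriptModel(
                transcript_id=t.id,
                gene_symbol=gene,
                chrom=t.seqid,
                strand=t.strand,
                exons=exons,
                coding_end_exon_index=coding_idx,
                coding_end_low_confidence=low_conf,
            )
        )

    if not transcripts:
        raise AnnotationError(
            f"none of the {len(wanted)} panel genes were found in {gtf_path}"
        )

    warnings = [
        f"panel gene {g} not present in annotation {gtf_path.name}"
        for g in sorted(wanted - set(transcripts))
    ]
    return index_from_transcripts(panel, transcripts, warnings)
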