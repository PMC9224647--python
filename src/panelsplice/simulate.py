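"""Synthetic targeted-RNA-seq cohorts with injected splicing aberrations.

Generates, for a configurable cohort (default 13 samples over a ~20-gene
panel), every file the analysis pipeline consumes — GTF annotation, panel
definition, per-sample STAR ``SJ.out.tab`` junction tables, collapsed-exon
count tables, per-sample allele-depth tables with a variant-annotation
side-table, and per-intron coverage summaries — together with a ground-truth
manifest of every injected aberration.

Count model
-----------
Baseline junction and exon counts are negative-binomial around per-junction
expected depths ``mean_junction_depth x gene_factor x junction_factor x
library_factor``; gene factors are log-normal to mimic the uneven pull-down
efficiency of a targeted panel, and sample library factors are log-normal.
Heterozygous-site allele depths are Binomial(n, mapping_bias) with a default
ALT proportion of 0.45 to emulate reference-mapping bias.

Event injection
---------------
Injected aberrations reallocate reads rather than add them, so read totals at
an event locus are conserved:

* ``leaky_exon_skip`` moves a Binomial(depth, f) share of the flanking
  inclusion reads onto a skip junction (magnitude f = skip fraction);
* ``intron_retention`` sets the canonical junction to the ``u`` fraction of
  its expected depth (magnitude u = residual canonical usage) and deposits the
  complementary coverage in the intron;
* ``extended_splice_site`` moves a fixed fraction of canonical-junction reads
  onto a junction with a shifted acceptor;
* ``nmd_truncation`` / ``nmd_escape_truncation`` create a heterozygous
  truncating site whose ALT reads are scaled by a decay factor d < 1
  (or amplification factor >= 1 for escape);
* ``usage_shift`` scales one exon bin's count.

Genes hosting injected events have their gene factor pinned to 1 so the
manifest magnitude is the simulated effect size; all other loci carry the full
sampling noise. All randomness flows from one seed via deterministic
substreams; outputs are byte-identical across runs with the same seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .annotation import GenePanel, TranscriptModel, index_from_transcripts
from .errors import PipelineError

DEFAULT_GENE_SYMBOLS = [
    "CTLA4", "TRAF3", "MERTK", "CAT", "UNC13D", "TCF25", "PIK3CD", "TYK2",
    "XIAP", "BTK", "NOD2", "MEFV", "NCF1", "NCF2", "WAS", "CARD11", "ERBIN",
    "RBCK1", "LRBA", "STAT3", "FOXP3", "IL10RA", "STXBP2", "DOCK8", "AIRE",
    "STAT1", "JAK1", "IL2RA", "CASP10", "FAS",
]

EVENT_KINDS = frozenset(
    {
        "leaky_exon_skip",
        "intron_retention",
        "extended_splice_site",
        "nmd_truncation",
        "nmd_escape_truncation",
        "usage_shift",
    }
)


@dataclass
class SimConfig:
    n_samples: int = 13
    n_genes: int = 20
    exons_per_gene: tuple = (4, 9)
    mean_junction_depth: float = 500.0
    depth_dispersion: float = 0.01
    mapping_bias: float = 0.45
    variant_depth_factor: float = 1.2  # site depth relative to junction depth
    gene_factor_sigma: float = 0.6
    junction_factor_sigma: float = 0.15
    library_sigma: float = 0.10
    seed: int = 0

    def validate(self):
        if self.n_samples < 2:
            raise PipelineError("n_samples must be >= 2")
        if self.n_genes < 1:
            raise PipelineError("n_genes must be >= 1")
        lo, hi = self.exons_per_gene
        if lo < 2 or hi < lo:
            raise PipelineError(f"bad exons_per_gene range {self.exons_per_gene}")
        if self.mean_junction_depth <= 0:
            raise PipelineError("mean_junction_depth must be positive")
        if self.depth_dispersion < 0:
            raise PipelineError("depth_dispersion must be >= 0")
        if not 0 < self.mapping_bias < 1:
            raise PipelineError("mapping_bias must be in (0,1)")


@dataclass
class EventSpec:
    kind: str
    gene: str
    target_index: int  # exon index (skip/usage/nmd) or intron index (retention/extension)
    magnitude: float
    affected_samples: tuple

    def __post_init__(self):
        if self.kind not in EVENT_KINDS:
            raise PipelineError(f"unknown event kind {self.kind!r}")
        if self.magnitude <= 0:
            raise PipelineError("event magnitude must be positive")


@dataclass
class VariantSpec:
    """A variant to place in the allele-depth + annotation tables."""

    gene: str
    pos: int
    consequence: str
    samples: tuple
    ref: str = "G"
    alt: str = "A"
    hgvs: str = ""
    gnomad_af: Optional[float] = None
    subpopulation: Optional[str] = None
    subpopulation_af: Optional[float] = None
    trap_score: Optional[float] = None
    exon_index: Optional[int] = None
    last_coding_exon: bool = False
    splice_truncating: bool = False
    alt_fraction: Optional[float] = None  # expected ALT proportion; default mapping_bias
    depth_scale: float = 1.0


@dataclass
class SynGene:
    symbol: str
    chrom: str
    strand: str
    exons: list  # (start, end) 1-based closed, genomic order
    classes: tuple

    def introns(self) -> list:
        return [
            (self.exons[i][1] + 1, self.exons[i + 1][0] - 1)
            for i in range(len(self.exons) - 1)
        ]

    @property
    def transcript_id(self) -> str:
        return f"{self.symbol}-T1"

    def last_coding_exon_genomic_index(self) -> int:
        """Genomic index of the transcript-orientation last exon (all genes are
        coding end-to-end in this simulator, minus short terminal UTR stubs)."""
        return len(self.exons) - 1 if self.strand == "+" else 0


@dataclass
class SyntheticCohort:
    config: SimConfig
    genes: list  # SynGene
    panel: GenePanel
    index: object  # AnnotationIndex
    sample_ids: list
    junction_counts: dict  # (chrom,start,end,strand) -> np.ndarray over samples
    junction_annotated: dict  # key -> bool
    expected_depth: dict  # key -> np.ndarray of expected depths per sample
    exon_counts: pd.DataFrame  # sample_id, gene, bin_id, count
    allele_rows: list  # dicts for the allele-depth table
    variant_annotation: list  # dicts for the annotation side-table
    intron_coverage: list  # dicts for the coverage table
    truth: list = field(default_factory=list)
    sj_rows: dict = field(default_factory=dict)  # sample_id -> list of 9-field rows

    def gene(self, symbol: str) -> SynGene:
        for g in self.genes:
            if g.symbol == symbol:
                return g
        raise KeyError(symbol)

    # ------------------------------------------------------------------ output
    def gtf_text(self) -> str:
        lines = []
        for g in self.genes:
            span = (g.exons[0][0], g.exons[-1][1])
            attrs = f'gene_id "{g.symbol}"; gene_name "{g.symbol}";'
            lines.append(
                f"{g.chrom}\tsim\tgene\t{span[0]}\t{span[1]}\t.\t{g.strand}\t.\t{attrs}"
            )
            tattrs = (
                f'gene_id "{g.symbol}"; transcript_id "{g.transcript_id}"; '
                f'gene_name "{g.symbol}";'
            )
            lines.append(
                f"{g.chrom}\tsim\ttranscript\t{span[0]}\t{span[1]}\t.\t{g.strand}\t.\t{tattrs}"
            )
            for i, (s, e) in enumerate(g.exons, start=1):
                eattrs = tattrs + f' exon_number "{i}";'
                lines.append(
                    f"{g.chrom}\tsim\texon\t{s}\t{e}\t.\t{g.strand}\t.\t{eattrs}"
                )
            # CDS spans the transcript minus 30 bp UTR stubs at each end
            cds_lo = g.exons[0][0] + 30
            cds_hi = g.exons[-1][1] - 30
            for i, (s, e) in enumerate(g.exons, start=1):
                cs, ce = max(s, cds_lo), min(e, cds_hi)
                if cs <= ce:
                    eattrs = tattrs + f' exon_number "{i}";'
                    lines.append(
                        f"{g.chrom}\tsim\tCDS\t{cs}\t{ce}\t.\t{g.strand}\t0\t{eattrs}"
                    )
        return "\n".join(lines) + "\n"

    def panel_text(self) -> str:
        return "".join(f"{g.symbol}\t{';'.join(g.classes)}\n" for g in self.genes)

    def write(self, outdir) -> Path:
        """Serialize every pipeline input plus the truth manifest; returns the
        manifest path. Purely a serialization step: repeated calls are
        byte-identical."""
        outdir = Path(outdir)
        (outdir / "samples").mkdir(parents=True, exist_ok=True)
        (outdir / "annotation.gtf").write_text(self.gtf_text())
        (outdir / "panel.tsv").write_text(self.panel_text())

        sample_files = []
        for s in self.sample_ids:
            sj_path = outdir / "samples" / f"{s}.SJ.out.tab"
            sj_path.write_text(
                "".join("\t".join(str(x) for x in row) + "\n" for row in self.sj_rows[s])
            )
            ec = self.exon_counts[self.exon_counts["sample_id"] == s]
            ec_path = outdir / "samples" / f"{s}.exon_counts.tsv"
            ec[["gene", "bin_id", "count"]].to_csv(ec_path, sep="\t", index=False)
            sample_files.append(
                {
                    "id": s,
                    "junctions": str(sj_path.relative_to(outdir)),
                    "exon_counts": str(ec_path.relative_to(outdir)),
                }
            )

        allele = pd.DataFrame(
            self.allele_rows,
            columns=["sample_id", "chrom", "pos", "ref", "alt",
                     "ref_reads", "alt_reads", "zygosity"],
        )
        allele.to_csv(outdir / "allele_depths.tsv", sep="\t", index=False)

        ann_cols = [
            "chrom", "pos", "ref", "alt", "gene", "hgvs", "consequence",
            "gnomad_af", "subpopulation", "subpopulation_af", "trap_score",
            "transcript_id", "exon_index", "last_coding_exon", "splice_truncating",
        ]
        pd.DataFrame(self.variant_annotation, columns=ann_cols).to_csv(
            outdir / "variant_annotation.tsv", sep="\t", index=False
        )

        cov_cols = ["chrom", "start", "end", "gene", "sample_id", "mean_depth", "flank_depth"]
        pd.DataFrame(self.intron_coverage, columns=cov_cols).to_csv(
            outdir / "intron_coverage.tsv", sep="\t", index=False
        )

        manifest = {
            "gtf": "annotation.gtf",
            "panel": "panel.tsv",
            "samples": sample_files,
            "allele_depths": "allele_depths.tsv",
            "variant_annotation": "variant_annotation.tsv",
            "intron_coverage": "intron_coverage.tsv",
            "truth": self.truth,
            "config": asdict(self.config),
        }
        path = outdir / "manifest.json"
        path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
        return path


# --------------------------------------------------------------------- builders

def _nb_draw(rng, mu, dispersion):
    """Negative-binomial draw with mean mu and variance mu + dispersion*mu^2
    (Poisson when dispersion == 0)."""
    mu = np.asarray(mu, dtype=float)
    if dispersion == 0:
        return rng.poisson(mu)
    r = 1.0 / dispersion
    p = r / (r + mu)
    return rng.negative_binomial(r, p)


def simulate_genes(config: SimConfig, rng) -> list:
    """Synthetic gene structures laid out along one chromosome."""
    genes = []
    cursor = 10_000
    lo, hi = config.exons_per_gene
    for i in range(config.n_genes):
        symbol = (
            DEFAULT_GENE_SYMBOLS[i]
            if i < len(DEFAULT_GENE_SYMBOLS)
            else f"GENE{i + 1:03d}"
        )
        n_exons = int(rng.integers(lo, hi + 1))
        exons = []
        pos = cursor
        for j in range(n_exons):
            length = int(rng.integers(80, 301))
            exons.append((pos, pos + length - 1))
            pos += length + int(rng.integers(200, 2001))
        strand = "+" if rng.random() < 0.5 else "-"
        r = rng.random()
        classes = ("PID",) if r < 0.25 else (("VEOIBD",) if r < 0.8 else ("PID", "VEOIBD"))
        genes.append(SynGene(symbol, "chr1", strand, exons, classes))
        cursor = exons[-1][1] + 50_000
    return genes


def _build_index(genes, panel):
    transcripts = {
        g.symbol: [
            TranscriptModel(
                transcript_id=g.transcript_id,
                gene_symbol=g.symbol,
                chrom=g.chrom,
                strand=g.strand,
                exons=list(g.exons),
                coding_end_exon_index=g.last_coding_exon_genomic_index(),
            )
        ]
        for g in genes
    }
    return index_from_transcripts(panel, transcripts)


def simulate_cohort(
    config: SimConfig,
    events: Optional[list] = None,
    variants: Optional[list] = None,
) -> SyntheticCohort:
    """Build a full synthetic cohort, inject ``events`` and ``variants``, and
    return the in-memory cohort (call ``.write(outdir)`` to serialize)."""
    config.validate()
    events = list(events or [])
    variants = list(variants or [])

    seen_loci = set()
    for ev in events:
        locus = (tuple(ev.affected_samples), ev.gene, ev.kind, ev.target_index)
        for s in ev.affected_samples:
            k = (s, ev.gene, ev.target_index, ev.kind)
            if k in seen_loci:
                raise PipelineError(f"duplicate event at {k}")
            seen_loci.add(k)

    ss = np.random.SeedSequence(config.seed)
    rng_genes, rng_counts, rng_inject, rng_artifacts = [
        np.random.default_rng(c) for c in ss.spawn(4)
    ]

    genes = simulate_genes(config, rng_genes)
    by_symbol = {g.symbol: g for g in genes}
    for ev in events:
        if ev.gene not in by_symbol:
            raise PipelineError(f"event targets unknown gene {ev.gene}")
    for vs in variants:
        if vs.gene not in by_symbol:
            raise PipelineError(f"variant targets unknown gene {vs.gene}")

    panel = GenePanel.from_entries([(g.symbol, list(g.classes)) for g in genes])
    index = _build_index(genes, panel)
    sample_ids = [f"S{i + 1:02d}" for i in range(config.n_samples)]

    pinned = {ev.gene for ev in events} | {vs.gene for vs in variants}
    gene_factor = {}
    for g in genes:
        f = float(rng_counts.lognormal(0.0, config.gene_factor_sigma))
        gene_factor[g.symbol] = 1.0 if g.symbol in pinned else f
    lib_factor = rng_counts.lognormal(0.0, config.library_sigma, size=config.n_samples)

    # baseline junction counts over annotated introns
    junction_counts = {}
    junction_annotated = {}
    expected_depth = {}
    for g in genes:
        for s, e in g.introns():
            key = (g.chrom, s, e, g.strand)
            jf = float(rng_counts.lognormal(0.0, config.junction_factor_sigma))
            mu = config.mean_junction_depth * gene_factor[g.symbol] * jf * lib_factor
            junction_counts[key] = _nb_draw(rng_counts, mu, config.depth_dispersion).astype(int)
            junction_annotated[key] = True
            expected_depth[key] = mu

    # baseline exon counts
    ec_rows = []
    for g in genes:
        for b in index.bins[g.symbol]:
            mu = (
                config.mean_junction_depth
                * gene_factor[g.symbol]
                * (b.length_bp / 150.0)
                * lib_factor
            )
            counts = _nb_draw(rng_counts, mu, config.depth_dispersion)
            for si, s in enumerate(sample_ids):
                ec_rows.append(
                    {"sample_id": s, "gene": g.symbol, "bin_id": b.bin_id,
                     "count": int(counts[si])}
                )
    exon_counts = pd.DataFrame(ec_rows)

    # baseline common heterozygous polymorphisms (excluded by frequency
    # downstream; they exercise the ASE machinery without creating findings)
    allele_rows = []
    variant_annotation = []
    for g in genes:
        if rng_counts.random() > 0.7 or len(g.exons) < 2:
            continue
        ex = g.exons[1]
        pos = (ex[0] + ex[1]) // 2
        carriers = [s for si, s in enumerate(sample_ids) if rng_counts.random() < 0.5]
        mu_site = (
            config.variant_depth_factor
            * config.mean_junction_depth
            * gene_factor[g.symbol]
        )
        for s in carriers:
            si = sample_ids.index(s)
            n = int(rng_counts.poisson(mu_site * lib_factor[si]))
            alt = int(rng_counts.binomial(n, config.mapping_bias)) if n else 0
            allele_rows.append(
                {"sample_id": s, "chrom": g.chrom, "pos": pos, "ref": "C",
                 "alt": "T", "ref_reads": n - alt, "alt_reads": alt,
                 "zygosity": "HET"}
            )
        variant_annotation.append(
            {
                "chrom": g.chrom, "pos": pos, "ref": "C", "alt": "T",
                "gene": g.symbol, "hgvs": f"{g.symbol}:common_snp",
                "consequence": "synonymous", "gnomad_af": 0.30,
                "subpopulation": None, "subpopulation_af": None,
                "trap_score": None, "transcript_id": g.transcript_id,
                "exon_index": 1, "last_coding_exon": False,
                "splice_truncating": False,
            }
        )

    cohort = SyntheticCohort(
        config=config,
        genes=genes,
        panel=panel,
        index=index,
        sample_ids=sample_ids,
        junction_counts=junction_counts,
        junction_annotated=junction_annotated,
        expected_depth=expected_depth,
        exon_counts=exon_counts,
        allele_rows=allele_rows,
        variant_annotation=variant_annotation,
        intron_coverage=[],
        truth=[],
    )
    cohort._lib_factor = lib_factor
    cohort._gene_factor = gene_factor

    for ev in events:
        inject_event(cohort, ev, rng_inject)
    for vs in variants:
        inject_variant(cohort, vs, rng_inject)

    _finalize_sj_rows(cohort, rng_artifacts)
    return cohort


# -------------------------------------------------------------------- injection

def _sample_indexes(cohort, samples):
    out = []
    for s in samples:
        if s not in cohort.sample_ids:
            raise PipelineError(f"unknown sample {s}")
        out.append(cohort.sample_ids.index(s))
    return out


def inject_event(cohort: SyntheticCohort, spec: EventSpec, rng) -> None:
    """Apply one aberration to the affected samples and record the truth entry."""
    gene = cohort.gene(spec.gene)
    handler = {
        "leaky_exon_skip": _inject_skip,
        "intron_retention": _inject_retention,
        "extended_splice_site": _inject_extension,
        "nmd_truncation": _inject_truncation,
        "nmd_escape_truncation": _inject_truncation,
        "usage_shift": _inject_usage_shift,
    }[spec.kind]
    handler(cohort, gene, spec, rng)


def _inject_skip(cohort, gene, spec, rng):
    i = spec.target_index
    introns = gene.introns()
    if not 0 < i < len(gene.exons) - 1:
        raise PipelineError(
            f"leaky_exon_skip needs an internal exon; got index {i} of {gene.symbol}"
        )
    up_key = (gene.chrom, *introns[i - 1], gene.strand)
    dn_key = (gene.chrom, *introns[i], gene.strand)
    skip_key = (gene.chrom, introns[i - 1][0], introns[i][1], gene.strand)
    counts_skip = cohort.junction_counts.setdefault(
        skip_key, np.zeros(len(cohort.sample_ids), dtype=int)
    )
    cohort.junction_annotated.setdefault(skip_key, False)
    f = spec.magnitude
    for si in _sample_indexes(cohort, spec.affected_samples):
        c_up = int(cohort.junction_counts[up_key][si])
        c_dn = int(cohort.junction_counts[dn_key][si])
        depth = int(round((c_up + c_dn) / 2))
        s = int(rng.binomial(depth, f)) if depth else 0
        cohort.junction_counts[up_key][si] = max(c_up - s, 0)
        cohort.junction_counts[dn_key][si] = max(c_dn - s, 0)
        counts_skip[si] += s
        ref = max(cohort.junction_counts[up_key][si], cohort.junction_counts[dn_key][si])
        detectable = s >= 10 and ref > 0 and s / ref >= 0.10
        cohort.truth.append(
            {
                "sample": cohort.sample_ids[si], "kind": spec.kind,
                "gene": gene.symbol, "target_index": i,
                "magnitude": f, "detectable": bool(detectable),
                "expected_class": "exon_skip",
            }
        )


def _inject_retention(cohort, gene, spec, rng):
    i = spec.target_index
    introns = gene.introns()
    if not 0 <= i < len(introns):
        raise PipelineError(f"intron index {i} out of range for {gene.symbol}")
    key = (gene.chrom, *introns[i], gene.strand)
    u = spec.magnitude
    if u > 1:
        raise PipelineError("retention magnitude is a residual usage fraction in (0,1]")
    affected = set(_sample_indexes(cohort, spec.affected_samples))
    for si, s in enumerate(cohort.sample_ids):
        mu = float(cohort.expected_depth[key][si])
        if si in affected:
            cohort.junction_counts[key][si] = int(round(u * mu))
            depth = max(6.0, round(0.5 * (1 - u) * mu, 1))
        else:
            depth = float(rng.poisson(1.0))
        cohort.intron_coverage.append(
            {
                "chrom": gene.chrom, "start": introns[i][0], "end": introns[i][1],
                "gene": gene.symbol, "sample_id": s,
                "mean_depth": depth, "flank_depth": round(mu, 1),
            }
        )
    for si in sorted(affected):
        mu = float(cohort.expected_depth[key][si])
        detectable = u < 0.8 and max(6.0, 0.5 * (1 - u) * mu) >= max(5.0, 0.10 * mu)
        cohort.truth.append(
            {
                "sample": cohort.sample_ids[si], "kind": spec.kind,
                "gene": gene.symbol, "target_index": i,
                "magnitude": u, "detectable": bool(detectable),
                "expected_class": "intron_retention",
            }
        )


def _inject_extension(cohort, gene, spec, rng, shift: int = 8):
    """Move a fraction of canonical reads onto an acceptor extended ``shift``
    bases into the intron (the novel acceptor sits upstream of the canonical
    one, so the intron ends earlier)."""
    i = spec.target_index
    introns = gene.introns()
    if not 0 <= i < len(introns):
        raise PipelineError(f"intron index {i} out of range for {gene.symbol}")
    start, end = introns[i]
    key = (gene.chrom, start, end, gene.strand)
    novel_key = (gene.chrom, start, end - shift, gene.strand)
    counts_novel = cohort.junction_counts.setdefault(
        novel_key, np.zeros(len(cohort.sample_ids), dtype=int)
    )
    cohort.junction_annotated.setdefault(novel_key, False)
    m = spec.magnitude
    if m > 1:
        raise PipelineError("extension magnitude is a fraction in (0,1]")
    # which side is novel depends on strand: intron end is the acceptor on '+'
    expected_class = "novel_acceptor" if gene.strand == "+" else "novel_donor"
    for si in _sample_indexes(cohort, spec.affected_samples):
        c = int(cohort.junction_counts[key][si])
        s = int(round(m * c))
        cohort.junction_counts[key][si] = c - s
        counts_novel[si] += s
        detectable = s >= 10 and (c - s) > 0 and s / (c - s) >= 0.10
        cohort.truth.append(
            {
                "sample": cohort.sample_ids[si], "kind": spec.kind,
                "gene": gene.symbol, "target_index": i,
                "magnitude": m, "detectable": bool(detectable),
                "expected_class": expected_class,
            }
        )


def _truncation_params(bias, factor):
    return bias * factor / (bias * factor + (1 - bias))


def _inject_truncation(cohort, gene, spec, rng):
    """Heterozygous truncating site; ALT reads scaled by the magnitude
    (decay factor < 1 for NMD, >= 1 for escape / overexpression)."""
    escape = spec.kind == "nmd_escape_truncation"
    i = spec.target_index
    if not 0 <= i < len(gene.exons):
        raise PipelineError(f"exon index {i} out of range for {gene.symbol}")
    if escape and i != gene.last_coding_exon_genomic_index():
        raise PipelineError(
            "nmd_escape_truncation is modeled in the last coding exon; "
            f"expected index {gene.last_coding_exon_genomic_index()}"
        )
    ex = gene.exons[i]
    pos = (ex[0] + ex[1]) // 2 + 3
    cfg = cohort.config
    p_alt = _truncation_params(cfg.mapping_bias, spec.magnitude)
    mu_site = cfg.variant_depth_factor * cfg.mean_junction_depth * cohort._gene_factor[gene.symbol]
    for si in _sample_indexes(cohort, spec.affected_samples):
        n = int(rng.poisson(mu_site * cohort._lib_factor[si]))
        alt = int(rng.binomial(n, p_alt)) if n else 0
        cohort.allele_rows.append(
            {"sample_id": cohort.sample_ids[si], "chrom": gene.chrom, "pos": pos,
             "ref": "C", "alt": "A", "ref_reads": n - alt, "alt_reads": alt,
             "zygosity": "HET"}
        )
        cohort.truth.append(
            {
                "sample": cohort.sample_ids[si], "kind": spec.kind,
                "gene": gene.symbol, "target_index": i,
                "magnitude": spec.magnitude, "detectable": bool(alt >= 10),
                "expected_class": "escapes_nmd" if escape else "consistent_with_nmd",
            }
        )
    cohort.variant_annotation.append(
        {
            "chrom": gene.chrom, "pos": pos, "ref": "C", "alt": "A",
            "gene": gene.symbol, "hgvs": f"{gene.symbol}:p.trunc",
            "consequence": "nonsense", "gnomad_af": None,
            "subpopulation": None, "subpopulation_af": None, "trap_score": None,
            "transcript_id": gene.transcript_id, "exon_index": i,
            "last_coding_exon": bool(i == gene.last_coding_exon_genomic_index()),
            "splice_truncating": False,
        }
    )


def _inject_usage_shift(cohort, gene, spec, rng):
    i = spec.target_index
    bins = cohort.index.bins[gene.symbol]
    if not 0 <= i < len(bins):
        raise PipelineError(f"bin index {i} out of range for {gene.symbol}")
    bin_id = bins[i].bin_id
    for s in spec.affected_samples:
        mask = (
            (cohort.exon_counts["sample_id"] == s)
            & (cohort.exon_counts["bin_id"] == bin_id)
        )
        new_count = int(round(
            float(cohort.exon_counts.loc[mask, "count"].iloc[0]) * (1 + spec.magnitude)
        ))
        cohort.exon_counts.loc[mask, "count"] = new_count
        # realized detectability: the shifted count must clear the cohort's
        # typical level by the outlier rule's fold margin
        others = cohort.exon_counts[
            (cohort.exon_counts["bin_id"] == bin_id)
            & (cohort.exon_counts["sample_id"] != s)
        ]["count"]
        med = float(np.median(others)) if len(others) else 0.0
        detectable = med > 0 and new_count / med >= 1.7
        cohort.truth.append(
            {
                "sample": s, "kind": spec.kind, "gene": gene.symbol,
                "target_index": i, "magnitude": spec.magnitude,
                "detectable": bool(detectable), "expected_class": "usage_outlier",
            }
        )


def inject_variant(cohort: SyntheticCohort, spec: VariantSpec, rng) -> None:
    """Place a variant (allele depths + annotation row) without a splice event."""
    gene = cohort.gene(spec.gene)
    cfg = cohort.config
    p_alt = spec.alt_fraction if spec.alt_fraction is not None else cfg.mapping_bias
    mu_site = (
        cfg.variant_depth_factor
        * cfg.mean_junction_depth
        * cohort._gene_factor[gene.symbol]
        * spec.depth_scale
    )
    for si in _sample_indexes(cohort, spec.samples):
        n = int(rng.poisson(mu_site * cohort._lib_factor[si]))
        alt = int(rng.binomial(n, p_alt)) if n else 0
        cohort.allele_rows.append(
            {"sample_id": cohort.sample_ids[si], "chrom": gene.chrom,
             "pos": spec.pos, "ref": spec.ref, "alt": spec.alt,
             "ref_reads": n - alt, "alt_reads": alt, "zygosity": "HET"}
        )
    cohort.variant_annotation.append(
        {
            "chrom": gene.chrom, "pos": spec.pos, "ref": spec.ref, "alt": spec.alt,
            "gene": gene.symbol, "hgvs": spec.hgvs or f"{gene.symbol}:{spec.pos}",
            "consequence": spec.consequence, "gnomad_af": spec.gnomad_af,
            "subpopulation": spec.subpopulation,
            "subpopulation_af": spec.subpopulation_af,
            "trap_score": spec.trap_score, "transcript_id": gene.transcript_id,
            "exon_index": spec.exon_index,
            "last_coding_exon": spec.last_coding_exon,
            "splice_truncating": spec.splice_truncating,
        }
    )


def _finalize_sj_rows(cohort: SyntheticCohort, rng) -> None:
    """Freeze the per-sample SJ.out.tab rows (multimapper and overhang columns
    are drawn here once, so serialization is deterministic)."""
    keys = sorted(cohort.junction_counts)
    strand_code = {"+": 1, "-": 2, ".": 0}
    for si, s in enumerate(cohort.sample_ids):
        rows = []
        for key in keys:
            chrom, start, end, strand = key
            c = int(cohort.junction_counts[key][si])
            if c <= 0:
                continue
            mm = int(rng.poisson(0.02 * c))
            overhang = int(rng.integers(25, 76))
            rows.append(
                (
                    chrom, start, end, strand_code[strand],
                    1 if strand == "+" else 2,
                    1 if cohort.junction_annotated[key] else 0,
                    c, mm, overhang,
                )
            )
        cohort.sj_rows[s] = rows


# ---------------------------------------------------------------- demo cohort

#: anchored effect sizes used by the demonstration cohort
DEMO_SKIP_FRACTION = 0.15
DEMO_RETENTION_USAGE_HIGH = 0.6
DEMO_RETENTION_USAGE_LOW = 0.4
DEMO_NMD_DECAY = 0.5
DEMO_ESCAPE_AMPLIFICATION = 1.6
DEMO_EXTENSION_FRACTION = 0.3
DEMO_USAGE_SHIFT = 1.5  # 2.5-fold usage increase, well clear of count noise

#: the demonstration sample carrying an oligogenic four-finding profile
DEMO_MULTI_EVENT_SAMPLE = "S13"


def demo_events(genes_by_symbol, sample_ids=None) -> tuple:
    """The standard demonstration event set: one aberration of each kind at
    the anchored magnitudes, plus the companion variants that make the
    splice events linkable. Returns (events, variants).

    With fewer than 13 samples the event-to-sample assignment wraps around
    while keeping the multi-event sample (always the last one) to itself.
    """
    if sample_ids is None:
        sample_ids = [f"S{i + 1:02d}" for i in range(13)]
    multi = sample_ids[-1]
    n_rest = max(len(sample_ids) - 1, 1)

    def pick(*idxs):
        return tuple(dict.fromkeys(sample_ids[i % n_rest] for i in idxs))

    def internal_exon(gene):
        return len(genes_by_symbol[gene].exons) // 2

    mertk = genes_by_symbol["MERTK"]
    mertk_exon = internal_exon("MERTK")
    cat = genes_by_symbol["CAT"]
    unc = genes_by_symbol["UNC13D"]
    tyk2 = genes_by_symbol["TYK2"]
    cat_intron = cat.introns()[1]
    unc_intron = unc.introns()[0]
    tyk2_intron = tyk2.introns()[1]

    events = [
        EventSpec("leaky_exon_skip", "MERTK", mertk_exon, DEMO_SKIP_FRACTION,
                  pick(4, 8)),
        EventSpec("intron_retention", "CAT", 1, DEMO_RETENTION_USAGE_HIGH,
                  (multi,)),
        EventSpec("intron_retention", "UNC13D", 0, DEMO_RETENTION_USAGE_LOW,
                  (multi,)),
        EventSpec("extended_splice_site", "TYK2", 1, DEMO_EXTENSION_FRACTION,
                  pick(6)),
        EventSpec("nmd_truncation", "CTLA4",
                  internal_exon("CTLA4"), DEMO_NMD_DECAY, pick(1)),
        EventSpec("nmd_truncation", "PIK3CD",
                  internal_exon("PIK3CD"), DEMO_NMD_DECAY, (multi,)),
        EventSpec("nmd_escape_truncation", "TRAF3",
                  genes_by_symbol["TRAF3"].last_coding_exon_genomic_index(),
                  DEMO_ESCAPE_AMPLIFICATION, pick(5)),
        EventSpec("usage_shift", "TCF25", internal_exon("TCF25"),
                  DEMO_USAGE_SHIFT, pick(3)),
    ]
    variants = [
        # leaky exonic splice variant at the last base of the skipped exon;
        # common in one subpopulation, so only event linkage rescues it
        VariantSpec("MERTK", mertk.exons[mertk_exon][1], "missense",
                    pick(4, 8), hgvs="MERTK:leaky_splice",
                    gnomad_af=0.0108, subpopulation="AFR", subpopulation_af=0.14,
                    exon_index=mertk_exon),
        # donor+5 intronic variant above the probably-damaging TraP boundary
        VariantSpec("CAT", cat.introns()[1][0] + 4, "intronic",
                    (multi,), hgvs="CAT:donor+5",
                    gnomad_af=0.0029, subpopulation="SAS", subpopulation_af=0.01,
                    trap_score=0.95, splice_truncating=True),
        # acceptor-8 intronic variant
        VariantSpec("UNC13D", unc_intron[1] - 7, "intronic",
                    (multi,), hgvs="UNC13D:acceptor-8",
                    gnomad_af=0.0027, subpopulation="SAS", subpopulation_af=0.01,
                    trap_score=0.96, splice_truncating=True),
        # variant at the shifted acceptor created by the extension event
        VariantSpec("TYK2", tyk2_intron[1] - 8, "intronic", pick(6),
                    hgvs="TYK2:ext_acceptor", gnomad_af=0.001, trap_score=0.94),
        # rare in-frame deletion: a DNA-only exonic candidate
        VariantSpec("TYK2", (tyk2.exons[2][0] + tyk2.exons[2][1]) // 2,
                    "nonframeshift_del", (multi,),
                    hgvs="TYK2:inframe_del", gnomad_af=2.63e-5, exon_index=2),
    ]
    return events, variants


def demo_cohort(seed: int = 0, n_samples: int = 13) -> SyntheticCohort:
    """A 13-sample cohort with one aberration of each kind at the anchored
    magnitudes (leaky skip 0.15 in two samples; residual canonical usage
    0.6/0.4 retentions; a truncation under decay, one escaping with ALT
    amplification; an extended acceptor; a doubled exon bin), with the
    multi-event sample carrying four finding-producing lesions."""
    config = SimConfig(n_samples=n_samples, seed=seed)
    config.validate()
    probe = simulate_genes(config, np.random.default_rng(np.random.SeedSequence(seed).spawn(4)[0]))
    genes_by_symbol = {g.symbol: g for g in probe}
    sample_ids = [f"S{i + 1:02d}" for i in range(n_samples)]
    events, variants = demo_events(genes_by_symbol, sample_ids)
    return simulate_cohort(config, events=events, variants=variants)
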