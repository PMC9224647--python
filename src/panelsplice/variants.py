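"""Variant prioritization and variant-to-splice-event linkage.

Ranks annotated variants with the panel's quality / rarity / splice-damage
rules: exonic protein-altering variants need ALT depth >= 10 non-duplicate
unique reads and a population frequency at or below ``max_af`` (taking the
worst of global and subpopulation frequency); splice-region or intronic
variants qualify on a TraP score at or above the probably-damaging boundary.

A variant lying within a few bases of a detected splice event's affected
splice site is linked to the event and promoted to splice candidate
regardless of population frequency — frequency-based dismissal of
splice-affecting variants is a documented failure mode of DNA-only triage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from .errors import FormatError
from .junctions import SpliceEvent

EXONIC_PROTEIN_ALTERING = frozenset(
    {"missense", "nonsense", "frameshift", "nonframeshift_del", "nonframeshift_ins"}
)
SPLICE_RELEVANT = frozenset({"splice_region", "intronic"})

TIER_EXONIC = "exonic_candidate"
TIER_SPLICE = "splice_candidate"
TIER_EXCLUDED = "excluded"


@dataclass
class VariantSite:
    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    sample_id: str = ""
    hgvs: str = ""
    zygosity: str = "HET"  # HET / HOM / HEMI
    consequence: str = "missense"
    gnomad_af: Optional[float] = None
    subpopulation: Optional[str] = None
    subpopulation_af: Optional[float] = None
    trap_score: Optional[float] = None
    alt_depth: int = 0
    exon_context: Optional[tuple] = None  # (transcript_id, exon_index, last_coding_exon)
    splice_truncating: bool = False
    annotations: dict = field(default_factory=dict)  # pass-through (SIFT/PolyPhen/CADD...)

    def __post_init__(self):
        for af in (self.gnomad_af, self.subpopulation_af):
            if af is not None and not 0 <= af <= 1:
                raise FormatError(f"allele frequency {af} outside [0,1] at {self.key}")

    @property
    def key(self):
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def effective_af(self) -> Optional[float]:
        """Worst (maximum) of global and subpopulation frequency."""
        afs = [af for af in (self.gnomad_af, self.subpopulation_af) if af is not None]
        return max(afs) if afs else None


@dataclass
class PrioritizedVariant:
    site: VariantSite
    tier: str
    reasons: list = field(default_factory=list)


def prioritize_variants(
    sites: list,
    max_af: float = 0.02,
    trap_min: float = 0.93,
    min_alt_reads: int = 10,
) -> list:
    """Tier variants as exonic candidates, splice candidates, or excluded.

    Deterministic and order-independent: the result is sorted by
    (tier, effective AF ascending with absent first, gene, position).
    Every non-excluded variant carries at least one reason; every excluded
    variant carries a machine-readable reason for the exclusion.
    """
    out = []
    for site in sites:
        reasons = []
        eff_af = site.effective_af
        if site.consequence in EXONIC_PROTEIN_ALTERING:
            if site.alt_depth < min_alt_reads:
                out.append(
                    PrioritizedVariant(site, TIER_EXCLUDED,
                                       [f"alt_depth<{min_alt_reads}"])
                )
                continue
            if eff_af is not None and eff_af > max_af:
                out.append(
                    PrioritizedVariant(site, TIER_EXCLUDED,
                                       [f"af>{max_af}"])
                )
                continue
            reasons.append("exonic_protein_altering")
            reasons.append("af_absent" if eff_af is None else f"af<={max_af}")
            out.append(PrioritizedVariant(site, TIER_EXONIC, reasons))
        elif site.consequence in SPLICE_RELEVANT:
            if site.trap_score is not None and site.trap_score >= trap_min:
                out.append(
                    PrioritizedVariant(site, TIER_SPLICE,
                                       [f"trap>={trap_min}"])
                )
            else:
                out.append(
                    PrioritizedVariant(site, TIER_EXCLUDED, ["low_trap"])
                )
        else:
            out.append(PrioritizedVariant(site, TIER_EXCLUDED, ["consequence"]))

    tier_order = {TIER_EXONIC: 0, TIER_SPLICE: 1, TIER_EXCLUDED: 2}
    out.sort(
        key=lambda pv: (
            tier_order[pv.tier],
            pv.site.effective_af if pv.site.effective_af is not None else -1.0,
            pv.site.gene,
            pv.site.chrom,
            pv.site.pos,
        )
    )
    return out


@dataclass(frozen=True)
class Linkage:
    variant_key: tuple
    sample_id: str
    event: SpliceEvent
    distance_bp: int


def _anchor_positions(event: SpliceEvent) -> list:
    """Genomic positions a causal variant would sit near for this event.

    The junction boundaries (for intron retention, the retained intron's
    terminal windows are anchored at the same positions); for an exon skip,
    additionally the boundaries of the skipped exon itself, where a leaky
    exonic splice variant sits.
    """
    return [event.start, event.end]


def link_variant_to_splice_event(
    variant: VariantSite,
    events: list,
    window_bp: int = 10,
    index=None,
) -> Optional[Linkage]:
    """Link a variant to the nearest detected splice event within ``window_bp``.

    Requires the same gene and sample. Anchors are the event's junction
    boundaries; for exon skips the skipped bins' start/end coordinates are
    anchors too (an exonic variant at the last base of a skipped exon links).
    Returns the closest linkage, or None.
    """
    best = None
    for event in events:
        if event.gene != variant.gene or event.sample_id != variant.sample_id:
            continue
        anchors = _anchor_positions(event)
        if index is not None and event.skipped_bins:
            for b in index.bins.get(event.gene, []):
                if b.bin_id in event.skipped_bins:
                    anchors.extend([b.start, b.end])
        dist = min(abs(variant.pos - a) for a in anchors)
        if dist <= window_bp and (best is None or dist < best.distance_bp):
            best = Linkage(variant.key, variant.sample_id, event, dist)
    return best


def apply_linkages(prioritized: list, linkages: dict) -> list:
    """Promote variants linked to splice events to splice candidates.

    ``linkages`` maps (sample_id, variant key) -> Linkage. Promotion ignores
    population frequency entirely; the linkage reason records the event class.
    """
    for pv in prioritized:
        link = linkages.get((pv.site.sample_id, pv.site.key))
        if link is None:
            continue
        cls = link.event.event_class or "unclassified_event"
        if pv.tier != TIER_SPLICE:
            pv.tier = TIER_SPLICE
        pv.reasons = [r for r in pv.reasons if not r.startswith("af>")]
        pv.reasons.append(f"linked_to_{cls}")
    return prioritized


def read_variant_annotation_tsv(path) -> pd.DataFrame:
    """Annotation side-table: one row per variant with consequence, AFs, TraP
    score and exon context. Columns: chrom, pos, ref, alt, gene, hgvs,
    consequence, gnomad_af, subpopulation, subpopulation_af, trap_score,
    transcript_id, exon_index, last_coding_exon, splice_truncating."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"chrom", "pos", "ref", "alt", "gene", "consequence"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    return df


def variants_from_tables(
    allele_counts: pd.DataFrame, annotation: pd.DataFrame
) -> list:
    """Join per-sample allele depths with the variant annotation side-table
    into :class:`VariantSite` records (one per sample x variant)."""
    ann = annotation.set_index(["chrom", "pos", "ref", "alt"])
    sites = []
    for _, row in allele_counts.iterrows():
        key = (row["chrom"], int(row["pos"]), row["ref"], row["alt"])
        if key not in ann.index:
            continue
        a = ann.loc[key]
        if isinstance(a, pd.DataFrame):
            a = a.iloc[0]
        exon_ctx = None
        if (
            "transcript_id" in a.index
            and pd.notna(a.get("transcript_id"))
            and pd.notna(a.get("exon_index"))
        ):
            exon_ctx = (
                a["transcript_id"],
                int(a["exon_index"]),
                bool(a["last_coding_exon"]),
            )

        def _opt(name):
            v = a.get(name)
            return None if v is None or pd.isna(v) else float(v)

        sites.append(
            VariantSite(
                chrom=key[0],
                pos=key[1],
                ref=key[2],
                alt=key[3],
                gene=a["gene"],
                sample_id=row["sample_id"],
                hgvs=a.get("hgvs", "") if pd.notna(a.get("hgvs", "")) else "",
                zygosity=row.get("zygosity", "HET"),
                consequence=a["consequence"],
                gnomad_af=_opt("gnomad_af"),
                subpopulation=a.get("subpopulation") if pd.notna(a.get("subpopulation")) else None,
                subpopulation_af=_opt("subpopulation_af"),
                trap_score=_opt("trap_score"),
                alt_depth=int(row["alt_reads"]),
                exon_context=exon_ctx,
                splice_truncating=bool(a.get("splice_truncating", False))
                if pd.notna(a.get("splice_truncating", False))
                else False,
            )
        )
    return sites
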