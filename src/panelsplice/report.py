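"""Evidence integration and the end-to-end pipeline driver.

Variant, splicing, allele-imbalance and exon-usage evidence streams are
combined into one per-sample findings table: each retained variant becomes a
row, merged with any splice event it is linked to; splice events with no
candidate variant and exon-usage outliers become rows of their own. Rows
without any RNA-level support are marked DNA-only. Every row carries
provenance identifiers back to the upstream records, and the effective
configuration (every threshold in force) is logged and written next to the
findings so the filter funnel can be audited.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import ase as ase_mod
from . import junctions as junc_mod
from . import psi as psi_mod
from . import variants as var_mod
from .annotation import GenePanel, load_annotation, panel_summary
from .config import PipelineConfig
from .errors import PipelineError

FINDINGS_COLUMNS = [
    "sample_id", "gene", "hgvs", "variant_key", "predicted_effect",
    "variant_type", "zygosity", "splice_effect_rna", "ase_nmd_status",
    "p_left", "p_right", "gnomad_af", "subpopulation_af", "trap_score",
    "tier", "supporting_reads", "support_fraction", "usage_ratio",
    "usage_z", "reasons", "flags", "provenance",
]

#: controlled vocabulary for the RNA splice-effect column
SPLICE_EFFECT_NONE = "-"


def _splice_effect_label(event: junc_mod.SpliceEvent) -> str:
    if event.event_class == "intron_retention":
        return "intron retention"
    if event.event_class == "exon_skip":
        leaky = event.support_fraction is not None and event.support_fraction < 0.5
        return "leaky exon skip" if leaky else "exon skip"
    if event.event_class in ("novel_donor", "novel_acceptor", "novel_pair"):
        return "extended splice site"
    return SPLICE_EFFECT_NONE


def _event_id(event: junc_mod.SpliceEvent) -> str:
    return f"event:{event.sample_id}:{event.chrom}:{event.start}-{event.end}:{event.strand}"


def _variant_id(sample_id, key) -> str:
    return f"variant:{sample_id}:{key[0]}:{key[1]}:{key[2]}>{key[3]}"


def integrate_evidence(
    prioritized: list,
    events: list,
    ase_results: dict,
    nmd_calls: dict,
    usage_flags: dict,
    linkages: dict,
) -> pd.DataFrame:
    """Merge all evidence streams into the findings table.

    ``ase_results`` maps (sample_id, variant key) -> {'left': AseResult,
    'right': AseResult or None}; ``nmd_calls`` maps the same key to NmdCall;
    ``usage_flags`` maps sample_id -> OutlierResult; ``linkages`` maps
    (sample_id, variant key) -> Linkage. A linkage referencing an event or
    variant not present in the inputs is a cross-run mismatch and an error.
    """
    event_ids = {_event_id(e) for e in events}
    variant_keys = {(pv.site.sample_id, pv.site.key) for pv in prioritized}
    for (sample_id, vkey), link in linkages.items():
        if (sample_id, vkey) not in variant_keys:
            raise PipelineError(f"linkage references unknown variant {vkey} in {sample_id}")
        if _event_id(link.event) not in event_ids:
            raise PipelineError(f"linkage references unknown event {_event_id(link.event)}")

    rows = []
    linked_event_ids = set()
    for pv in prioritized:
        if pv.tier == var_mod.TIER_EXCLUDED:
            continue
        site = pv.site
        skey = (site.sample_id, site.key)
        link = linkages.get(skey)
        ase = ase_results.get(skey, {})
        nmd = nmd_calls.get(skey)
        flags = set()
        splice_effect = SPLICE_EFFECT_NONE
        supporting = support_fraction = usage_ratio = None
        provenance = [_variant_id(site.sample_id, site.key)]
        if link is not None:
            ev = link.event
            linked_event_ids.add(_event_id(ev))
            splice_effect = _splice_effect_label(ev)
            supporting = ev.supporting_reads
            support_fraction = ev.support_fraction
            usage_ratio = ev.usage_ratio
            flags |= ev.flags
            provenance.append(_event_id(ev))
        left = ase.get("left")
        right = ase.get("right")
        # effect-level RNA evidence: a linked splice event or a decay/escape
        # call; a computable allele-balance test alone does not qualify
        if link is None and nmd is None:
            flags.add("DNA-only")
        rows.append(
            {
                "sample_id": site.sample_id,
                "gene": site.gene,
                "hgvs": site.hgvs or _variant_id(site.sample_id, site.key),
                "variant_key": f"{site.chrom}:{site.pos}:{site.ref}>{site.alt}",
                "predicted_effect": site.hgvs or site.consequence,
                "variant_type": site.consequence,
                "zygosity": site.zygosity,
                "splice_effect_rna": splice_effect,
                "ase_nmd_status": nmd.status if nmd is not None else None,
                "p_left": left.p_value if left is not None else None,
                "p_right": right.p_value if right is not None else None,
                "gnomad_af": site.gnomad_af,
                "subpopulation_af": site.subpopulation_af,
                "trap_score": site.trap_score,
                "tier": pv.tier,
                "supporting_reads": supporting,
                "support_fraction": support_fraction,
                "usage_ratio": usage_ratio,
                "usage_z": None,
                "reasons": ";".join(pv.reasons),
                "flags": ";".join(sorted(flags)),
                "provenance": ";".join(provenance),
            }
        )

    for ev in events:
        eid = _event_id(ev)
        if eid in linked_event_ids or ev.event_class is None:
            continue
        rows.append(
            {
                "sample_id": ev.sample_id,
                "gene": ev.gene,
                "hgvs": SPLICE_EFFECT_NONE,
                "variant_key": SPLICE_EFFECT_NONE,
                "predicted_effect": ev.event_class,
                "variant_type": SPLICE_EFFECT_NONE,
                "zygosity": SPLICE_EFFECT_NONE,
                "splice_effect_rna": _splice_effect_label(ev),
                "ase_nmd_status": None,
                "p_left": None,
                "p_right": None,
                "gnomad_af": None,
                "subpopulation_af": None,
                "trap_score": None,
                "tier": "splice_event",
                "supporting_reads": ev.supporting_reads,
                "support_fraction": ev.support_fraction,
                "usage_ratio": ev.usage_ratio,
                "usage_z": None,
                "reasons": "unlinked_splice_event",
                "flags": ";".join(sorted(ev.flags)),
                "provenance": eid,
            }
        )

    for sample_id in sorted(usage_flags):
        for outlier in usage_flags[sample_id].outliers:
            rows.append(
                {
                    "sample_id": sample_id,
                    "gene": outlier.gene,
                    "hgvs": SPLICE_EFFECT_NONE,
                    "variant_key": SPLICE_EFFECT_NONE,
                    "predicted_effect": "exon usage outlier",
                    "variant_type": SPLICE_EFFECT_NONE,
                    "zygosity": SPLICE_EFFECT_NONE,
                    "splice_effect_rna": SPLICE_EFFECT_NONE,
                    "ase_nmd_status": None,
                    "p_left": None,
                    "p_right": None,
                    "gnomad_af": None,
                    "subpopulation_af": None,
                    "trap_score": None,
                    "tier": "usage_outlier",
                    "supporting_reads": None,
                    "support_fraction": None,
                    "usage_ratio": None,
                    "usage_z": outlier.z_score,
                    "reasons": f"bin:{outlier.bin_id}",
                    "flags": "",
                    "provenance": f"usage:{sample_id}:{outlier.bin_id}",
                }
            )

    df = pd.DataFrame(rows, columns=FINDINGS_COLUMNS)
    df = df.sort_values(
        ["sample_id", "gene", "variant_key", "provenance"], kind="mergesort"
    ).reset_index(drop=True)
    return df


# ------------------------------------------------------------------- pipeline

def _read_manifest(path) -> dict:
    path = Path(path)
    if not path.exists():
        raise PipelineError(f"manifest not found: {path}")
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    for key in ("gtf", "panel", "samples"):
        if key not in data:
            raise PipelineError(f"manifest missing required key {key!r}")
    return data


def run_pipeline(
    manifest_path,
    out_dir,
    config: Optional[PipelineConfig] = None,
    log=print,
) -> pd.DataFrame:
    """Execute the full analysis: annotate -> junctions -> PSI/usage ->
    ASE/NMD -> prioritize -> link -> report.

    ``manifest_path`` points to a JSON/YAML manifest listing the annotation,
    panel, and per-sample input files (the layout written by the simulator).
    All intermediate tables, the findings table, and the effective
    configuration are written under ``out_dir``. Missing input files are
    reported, naming the file and sample, before any computation starts.
    """
    config = config or PipelineConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = _read_manifest(manifest_path)
    base = Path(manifest_path).parent

    def resolve(rel):
        return base / rel

    missing = []
    for key in ("gtf", "panel"):
        if not resolve(manifest[key]).exists():
            missing.append(f"{key}: {manifest[key]}")
    for s in manifest["samples"]:
        for key in ("junctions", "exon_counts"):
            if not resolve(s[key]).exists():
                missing.append(f"sample {s['id']} {key}: {s[key]}")
    for key in ("allele_depths", "variant_annotation", "intron_coverage"):
        if key in manifest and not resolve(manifest[key]).exists():
            missing.append(f"{key}: {manifest[key]}")
    if missing:
        raise PipelineError("missing input files: " + "; ".join(missing))

    config.to_yaml(out_dir / "effective_config.yaml")
    log(f"[config] {config.to_dict()}")

    # ---- annotate
    panel = GenePanel.from_tsv(resolve(manifest["panel"]))
    index = load_annotation(resolve(manifest["gtf"]), panel)
    summary = panel_summary(panel)
    log(
        f"[annotate] genes_in={len(panel.entries)} genes_found={len(index.genes())} "
        f"warnings={len(index.warnings)} panel_total={summary.n_total}"
    )

    # ---- junctions
    per_sample = {}
    for s in manifest["samples"]:
        per_sample[s["id"]] = junc_mod.read_junction_table(
            resolve(s["junctions"]), min_reads_prefilter=config.min_reads_prefilter
        )
    matrix = junc_mod.build_cohort_matrix(per_sample, index)
    candidates = junc_mod.filter_candidate_junctions(
        matrix,
        min_reads=config.min_junction_reads,
        min_fraction=config.min_junction_fraction,
        reference_mode=config.canonical_reference_mode,
    )
    intron_cov = None
    if "intron_coverage" in manifest:
        intron_cov = pd.read_csv(resolve(manifest["intron_coverage"]), sep="\t",
                                 dtype={"chrom": str})
    for ev in candidates:
        junc_mod.classify_event(
            ev, index, intron_cov,
            usage_ratio_threshold=config.usage_ratio_threshold,
            min_intron_coverage=config.retention_min_coverage,
            rel_flank_coverage=config.retention_rel_flank,
        )
    retention = junc_mod.detect_retention_events(
        matrix, index, intron_cov,
        usage_ratio_threshold=config.usage_ratio_threshold,
        min_intron_coverage=config.retention_min_coverage,
        rel_flank_coverage=config.retention_rel_flank,
    )
    events = candidates + retention
    log(
        f"[junctions] junctions={matrix.counts.shape[0]} samples={len(matrix.samples)} "
        f"novel_candidates={len(candidates)} retention={len(retention)}"
    )
    events_frame = junc_mod.events_to_frame(events)
    events_frame.to_csv(out_dir / "splice_events.tsv", sep="\t", index=False)
    (out_dir / "splice_events.json").write_text(
        json.dumps(events_frame.to_dict(orient="records"), indent=2, sort_keys=True,
                   default=str) + "\n"
    )

    # ---- PSI / usage
    ec_frames = []
    for s in manifest["samples"]:
        df = pd.read_csv(resolve(s["exon_counts"]), sep="\t")
        df.insert(0, "sample_id", s["id"])
        ec_frames.append(df)
    exon_counts = pd.concat(ec_frames, ignore_index=True)
    psi_table = psi_mod.compute_psi_table(matrix, index, flank_mode=config.psi_flank_mode)
    usage = psi_mod.usage_table(exon_counts, index)
    usage_flags = {
        s["id"]: psi_mod.flag_usage_outliers(
            usage, s["id"],
            z_threshold=config.usage_z_threshold,
            min_fold_change=config.usage_min_fold,
        )
        for s in manifest["samples"]
    }
    n_usage_flags = sum(len(r.outliers) for r in usage_flags.values())
    expr_z = psi_mod.gene_expression_z(exon_counts)
    log(f"[usage] bins={usage.shape[0]} usage_outliers={n_usage_flags}")
    psi_table.to_csv(out_dir / "psi.tsv", sep="\t", index=False)
    usage.to_csv(out_dir / "exon_usage.tsv", sep="\t", index=False)

    # ---- variants + ASE/NMD
    sites, ase_results, nmd_calls = [], {}, {}
    if "allele_depths" in manifest and "variant_annotation" in manifest:
        allele = pd.read_csv(resolve(manifest["allele_depths"]), sep="\t",
                             dtype={"chrom": str})
        annotation = var_mod.read_variant_annotation_tsv(resolve(manifest["variant_annotation"]))
        sites = var_mod.variants_from_tables(allele, annotation)
        expr_lookup = {
            (r["sample_id"], r["gene"]): r["expression_z"]
            for _, r in expr_z.iterrows()
        }
        for site in sites:
            if site.zygosity != "HET":
                continue
            if site.consequence in ("intronic", "splice_region"):
                continue
            if site.alt_depth < config.min_alt_reads:
                continue
            arow = allele[
                (allele["sample_id"] == site.sample_id)
                & (allele["chrom"] == site.chrom)
                & (allele["pos"] == site.pos)
                & (allele["alt"] == site.alt)
            ].iloc[0]
            counts = ase_mod.AlleleCount(
                site.sample_id, site.chrom, site.pos, site.ref, site.alt,
                int(arow["ref_reads"]), int(arow["alt_reads"]),
            )
            left = ase_mod.ase_binomial_test(counts, "left", config.ase_null_left)
            truncating = (
                site.consequence in ase_mod.TRUNCATING_CONSEQUENCES
                or site.splice_truncating
            )
            right = (
                ase_mod.ase_binomial_test(counts, "right", config.ase_null_right)
                if truncating
                else None
            )
            skey = (site.sample_id, site.key)
            ase_results[skey] = {"left": left, "right": right}
            if truncating:
                nmd_calls[skey] = ase_mod.classify_nmd(
                    site, left, right,
                    expression_z=expr_lookup.get((site.sample_id, site.gene)),
                    alpha=config.ase_alpha,
                )
    log(f"[ase] sites={len(sites)} tested={len(ase_results)} nmd_calls={len(nmd_calls)}")

    prioritized = var_mod.prioritize_variants(
        sites,
        max_af=config.max_af,
        trap_min=config.trap_min,
        min_alt_reads=config.min_alt_reads,
    )
    linkages = {}
    for pv in prioritized:
        link = var_mod.link_variant_to_splice_event(
            pv.site, events, window_bp=config.link_window_bp, index=index
        )
        if link is not None:
            linkages[(pv.site.sample_id, pv.site.key)] = link
    var_mod.apply_linkages(prioritized, linkages)
    n_kept = sum(pv.tier != var_mod.TIER_EXCLUDED for pv in prioritized)
    log(
        f"[prioritize] sites_in={len(sites)} kept={n_kept} "
        f"linked={len(linkages)}"
    )

    findings = integrate_evidence(
        prioritized, events, ase_results, nmd_calls, usage_flags, linkages
    )
    findings.to_csv(out_dir / "findings.tsv", sep="\t", index=False)

    nmd_json = [
        {
            "sample_id": c.sample_id, "chrom": c.chrom, "pos": c.pos,
            "ref": c.ref, "alt": c.alt, "status": c.status,
            "p_left": c.p_left, "p_right": c.p_right,
            "last_coding_exon": c.last_coding_exon,
            "expression_z": c.expression_z, "notes": c.notes,
        }
        for c in nmd_calls.values()
    ]
    (out_dir / "nmd_calls.json").write_text(
        json.dumps(sorted(nmd_json, key=lambda r: (r["sample_id"], r["chrom"], r["pos"])),
                   indent=2, sort_keys=True) + "\n"
    )
    log(f"[report] findings_rows={len(findings)}")
    return findings
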