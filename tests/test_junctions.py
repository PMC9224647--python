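"""Junction parsing, cohort matrix assembly, the novel-junction filter, and
event classification."""

import numpy as np
import pandas as pd
import pytest

from panelsplice.annotation import TranscriptModel
from panelsplice.errors import FormatError, PipelineError
from panelsplice.junctions import (
    ANNOTATED,
    NOVEL_BOTH,
    NOVEL_ONE,
    NOVEL_UNKNOWN,
    SpliceEvent,
    build_cohort_matrix,
    canonical_usage_ratio,
    classify_event,
    detect_retention_events,
    filter_candidate_junctions,
    read_junction_table,
)

from conftest import make_index, records_from_counts


class TestReadJunctionTable:
    def test_parses_star_fields_and_ignores_multimappers(self, tmp_path):
        p = tmp_path / "sj.tab"
        p.write_text("chr2\t100\t200\t1\t1\t1\t25\t3\t40\n")
        (rec,) = read_junction_table(p)
        assert rec.unique_reads == 25
        assert rec.multimapping_reads == 3  # carried, never added to support
        assert rec.key == ("chr2", 100, 200, "+")

    def test_prefilter_drops_low_support(self, tmp_path):
        p = tmp_path / "sj.tab"
        lines = [
            f"chr1\t{100 + i * 1000}\t{500 + i * 1000}\t1\t1\t1\t{u}\t0\t40"
            for i, u in enumerate([4, 5, 5, 9, 10, 50])
        ]
        p.write_text("\n".join(lines) + "\n")
        recs = read_junction_table(p, min_reads_prefilter=5)
        assert len(recs) == 5
        assert all(r.unique_reads >= 5 for r in recs)

    def test_wrong_column_count_names_line(self, tmp_path):
        p = tmp_path / "sj.tab"
        p.write_text("chr1\t100\t200\t1\t1\t1\t25\t3\t40\nchr1\t300\t400\t1\n")
        with pytest.raises(FormatError, match="line 2"):
            read_junction_table(p)


class TestCohortMatrix:
    def test_union_semantics_fill_zero(self, six_exon_gene_index):
        index = six_exon_gene_index
        intron0 = ("chr1", 101, 500, "+")
        samples = records_from_counts(
            index, {"A": {intron0: 30}, "B": {}}
        )
        m = build_cohort_matrix(samples, index)
        assert m.count(intron0, "A") == 30
        assert m.count(intron0, "B") == 0

    def test_annotated_junction_has_transcripts(self, six_exon_gene_index):
        index = six_exon_gene_index
        intron0 = ("chr1", 101, 500, "+")
        m = build_cohort_matrix(records_from_counts(index, {"A": {intron0: 30}}), index)
        row = m.meta.loc[[intron0]].iloc[0]
        assert row["status"] == ANNOTATED
        assert row["transcripts"] == ("GENE1-T1",)
        assert row["gene"] == "GENE1"

    def test_shifted_acceptor_is_one_site_novel(self, six_exon_gene_index):
        index = six_exon_gene_index
        shifted = ("chr1", 101, 492, "+")  # donor annotated, acceptor 8 bp off
        m = build_cohort_matrix(records_from_counts(index, {"A": {shifted: 30}}), index)
        assert m.meta.loc[[shifted]].iloc[0]["status"] == NOVEL_ONE

    def test_exon_skip_junction_is_both_sites_novel_pairing(self, six_exon_gene_index):
        index = six_exon_gene_index
        skip = ("chr1", 601, 1500, "+")  # exon-2 donor to exon-4 acceptor
        m = build_cohort_matrix(records_from_counts(index, {"A": {skip: 30}}), index)
        assert m.meta.loc[[skip]].iloc[0]["status"] == NOVEL_BOTH

    def test_unknown_strand_matches_catalog(self, six_exon_gene_index):
        index = six_exon_gene_index
        unknown = ("chr1", 101, 500, ".")
        m = build_cohort_matrix(records_from_counts(index, {"A": {unknown: 30}}), index)
        assert m.meta.loc[[unknown]].iloc[0]["status"] == ANNOTATED

    def test_duplicate_junction_in_sample_rejected(self, six_exon_gene_index):
        from conftest import junction_record

        recs = [junction_record("chr1", 101, 500), junction_record("chr1", 101, 500)]
        with pytest.raises(PipelineError, match="duplicate junction"):
            build_cohort_matrix({"A": recs}, six_exon_gene_index)


class TestNovelJunctionFilter:
    def make_matrix(self, index, novel_count, canonical_count):
        intron0 = ("chr1", 101, 500, "+")  # canonical sharing the donor
        novel = ("chr1", 101, 492, "+")
        samples = records_from_counts(
            index, {"A": {intron0: canonical_count, novel: novel_count}}
        )
        return build_cohort_matrix(samples, index)

    def test_below_min_reads_not_emitted(self, six_exon_gene_index):
        m = self.make_matrix(six_exon_gene_index, novel_count=9, canonical_count=20)
        assert filter_candidate_junctions(m) == []

    def test_below_fraction_not_emitted(self, six_exon_gene_index):
        m = self.make_matrix(six_exon_gene_index, novel_count=12, canonical_count=200)
        assert filter_candidate_junctions(m) == []

    def test_passing_both_rules_emitted(self, six_exon_gene_index):
        m = self.make_matrix(six_exon_gene_index, novel_count=30, canonical_count=200)
        (ev,) = filter_candidate_junctions(m)
        assert ev.supporting_reads == 30
        assert ev.canonical_reference_reads == 200
        assert ev.support_fraction == pytest.approx(0.15)
        assert "needs_manual_review" in ev.flags

    def test_reference_mode_sum(self, six_exon_gene_index):
        index = six_exon_gene_index
        # two canonical junctions share sites with the skip candidate
        i0, i1, skip = (
            ("chr1", 101, 500, "+"),
            ("chr1", 601, 1000, "+"),
            ("chr1", 101, 1000, "+"),
        )
        m = build_cohort_matrix(
            records_from_counts(index, {"A": {i0: 90, i1: 60, skip: 12}}), index
        )
        assert filter_candidate_junctions(m, reference_mode="max")[0].canonical_reference_reads == 90
        assert filter_candidate_junctions(m, reference_mode="sum") == []  # 12/150 < 0.1


def brute_force_filter(matrix, min_reads, min_fraction):
    """Independent double-loop reference for the novel-junction filter."""
    out = []
    for key in matrix.counts.index:
        meta = matrix.meta.loc[[key]].iloc[0]
        if meta["status"] == ANNOTATED:
            continue
        for sample in matrix.samples:
            n = int(matrix.counts.at[key, sample])
            if n < min_reads:
                continue
            refs = []
            for other in matrix.counts.index:
                om = matrix.meta.loc[[other]].iloc[0]
                if om["status"] != ANNOTATED or om["chrom"] != meta["chrom"]:
                    continue
                if om["start"] == meta["start"] or om["end"] == meta["end"]:
                    refs.append(int(matrix.counts.at[other, sample]))
            if refs and max(refs) > 0:
                if n / max(refs) < min_fraction:
                    continue
            out.append((key, sample, n))
    return sorted(out, key=lambda t: (t[1], t[0]))


def random_matrix(seed, n_samples=None, max_junctions=30):
    """Random cohort matrix over a random multi-gene index."""
    rng = np.random.default_rng(seed)
    n_genes = int(rng.integers(1, 4))
    transcripts = {}
    pos = 1
    for gi in range(n_genes):
        n_exons = int(rng.integers(3, 7))
        exons = []
        for _ in range(n_exons):
            length = int(rng.integers(50, 150))
            exons.append((pos, pos + length - 1))
            pos += length + int(rng.integers(100, 400))
        gene = f"G{gi}"
        transcripts[gene] = [TranscriptModel(f"{gene}-T1", gene, "chr1", "+", exons)]
        pos += 5000
    index = make_index(transcripts)
    n_samples = n_samples or int(rng.integers(2, 14))
    counts = {f"S{i}": {} for i in range(n_samples)}
    introns = list(index.catalog.introns)
    keys = set()
    for key in introns:
        keys.add(key)
    # novel junctions: perturb catalog introns
    for key in introns:
        if rng.random() < 0.6:
            chrom, s, e, st = key
            kind = rng.random()
            if kind < 0.4:
                keys.add((chrom, s, e - int(rng.integers(5, 20)), st))
            elif kind < 0.7:
                keys.add((chrom, s + int(rng.integers(5, 20)), e, st))
            else:
                keys.add((chrom, s, e + 600, st))
    keys = sorted(keys)[:max_junctions]
    for sample in counts:
        for key in keys:
            if rng.random() < 0.8:
                counts[sample][key] = int(rng.integers(0, 60))
    samples = records_from_counts(index, counts)
    # drop empty samples (build requires >= 1 sample overall)
    samples = {s: r for s, r in samples.items() if r} or {"S0": []}
    return build_cohort_matrix(samples, index), index


@pytest.mark.parametrize("seed", range(25))
def test_filter_matches_brute_force_and_is_monotone(seed):
    matrix, _ = random_matrix(seed)
    for min_reads, min_fraction in [(10, 0.10), (5, 0.05), (20, 0.3)]:
        got = sorted(
            ((e.chrom, e.start, e.end, e.strand), e.sample_id, e.supporting_reads)
            for e in filter_candidate_junctions(matrix, min_reads, min_fraction)
        )
        expected = sorted(brute_force_filter(matrix, min_reads, min_fraction))
        assert got == expected
    # monotonicity in both thresholds
    base = len(filter_candidate_junctions(matrix, 10, 0.10))
    assert len(filter_candidate_junctions(matrix, 15, 0.10)) <= base
    assert len(filter_candidate_junctions(matrix, 10, 0.20)) <= base


class TestCanonicalUsageRatio:
    def build(self, index, counts_by_sample):
        return build_cohort_matrix(records_from_counts(index, counts_by_sample), index)

    def test_identical_samples_ratio_one(self, six_exon_gene_index):
        intron = ("chr1", 101, 500, "+")
        other = ("chr1", 601, 1000, "+")
        m = self.build(
            six_exon_gene_index,
            {s: {intron: 100, other: 100} for s in "ABCD"},
        )
        assert canonical_usage_ratio(m, intron, "A") == pytest.approx(1.0)

    @pytest.mark.parametrize("count,expected", [(60, 0.6), (40, 0.4)])
    def test_reduced_usage_recovered(self, six_exon_gene_index, count, expected):
        # models reduced canonical-donor usage at equal library sizes
        intron = ("chr1", 101, 500, "+")
        other = ("chr1", 601, 1000, "+")
        counts = {s: {intron: 100, other: 100} for s in "BCDE"}
        counts["A"] = {intron: count, other: 100 + (100 - count)}
        m = self.build(six_exon_gene_index, counts)
        assert canonical_usage_ratio(m, intron, "A") == pytest.approx(expected, abs=1e-9)

    def test_scale_invariance(self, six_exon_gene_index):
        intron = ("chr1", 101, 500, "+")
        other = ("chr1", 601, 1000, "+")
        counts = {s: {intron: 80, other: 120} for s in "ABC"}
        m1 = self.build(six_exon_gene_index, counts)
        counts["A"] = {k: v * 7 for k, v in counts["A"].items()}
        m2 = self.build(six_exon_gene_index, counts)
        assert canonical_usage_ratio(m1, intron, "A") == pytest.approx(
            canonical_usage_ratio(m2, intron, "A")
        )

    def test_zero_median_returns_none(self, six_exon_gene_index):
        intron = ("chr1", 101, 500, "+")
        other = ("chr1", 601, 1000, "+")
        counts = {"A": {intron: 50, other: 50}, "B": {other: 10}, "C": {other: 10}}
        m = self.build(six_exon_gene_index, counts)
        assert canonical_usage_ratio(m, intron, "A") is None


class TestClassifyEvent:
    def test_skip_of_whole_exon(self, six_exon_gene_index):
        # junction joining exon-4 donor to exon-6 acceptor skips exon 5
        ev = SpliceEvent("A", "GENE1", "chr1", 1601, 2500, "+", NOVEL_BOTH, 30)
        classify_event(ev, six_exon_gene_index)
        assert ev.event_class == "exon_skip"
        assert ev.skipped_bins == ("GENE1:005",)

    def test_novel_acceptor_extension(self, six_exon_gene_index):
        ev = SpliceEvent("A", "GENE1", "chr1", 101, 492, "+", NOVEL_ONE, 30)
        classify_event(ev, six_exon_gene_index)
        assert ev.event_class == "novel_acceptor"

    def test_novel_donor_on_minus_strand(self):
        exons = [(1 + 500 * i, 100 + 500 * i) for i in range(3)]
        t = TranscriptModel("GM-T1", "GM", "chr1", "-", exons)
        index = make_index({"GM": [t]})
        # acceptor (start side on '-') annotated, end side novel
        ev = SpliceEvent("A", "GM", "chr1", 101, 492, "-", NOVEL_ONE, 30)
        classify_event(ev, index)
        assert ev.event_class == "novel_donor"

    def test_intron_retention_rule(self, six_exon_gene_index):
        cov = pd.DataFrame(
            [{"chrom": "chr1", "start": 101, "end": 500, "gene": "GENE1",
              "sample_id": "A", "mean_depth": 30.0, "flank_depth": 100.0}]
        )
        ev = SpliceEvent("A", "GENE1", "chr1", 101, 500, "+", ANNOTATED, 60,
                         usage_ratio=0.6)
        classify_event(ev, six_exon_gene_index, cov)
        assert ev.event_class == "intron_retention"

    def test_retention_without_coverage_is_flagged_unset(self, six_exon_gene_index):
        ev = SpliceEvent("A", "GENE1", "chr1", 101, 500, "+", ANNOTATED, 60,
                         usage_ratio=0.6)
        classify_event(ev, six_exon_gene_index, None)
        assert ev.event_class is None
        assert "coverage_unavailable" in ev.flags

    def test_retention_requires_low_usage(self, six_exon_gene_index):
        cov = pd.DataFrame(
            [{"chrom": "chr1", "start": 101, "end": 500, "gene": "GENE1",
              "sample_id": "A", "mean_depth": 30.0, "flank_depth": 100.0}]
        )
        ev = SpliceEvent("A", "GENE1", "chr1", 101, 500, "+", ANNOTATED, 95,
                         usage_ratio=0.95)
        classify_event(ev, six_exon_gene_index, cov)
        assert ev.event_class is None


def test_detect_retention_events_end_to_end(six_exon_gene_index):
    index = six_exon_gene_index
    intron = ("chr1", 101, 500, "+")
    other = ("chr1", 601, 1000, "+")
    counts = {s: {intron: 100, other: 100} for s in "BCDE"}
    counts["A"] = {intron: 60, other: 140}
    cov = pd.DataFrame(
        [{"chrom": "chr1", "start": 101, "end": 500, "gene": "GENE1",
          "sample_id": s, "mean_depth": d, "flank_depth": 100.0}
         for s, d in [("A", 25.0), ("B", 1.0), ("C", 0.0), ("D", 2.0), ("E", 1.0)]]
    )
    m = build_cohort_matrix(records_from_counts(index, counts), index)
    events = detect_retention_events(m, index, cov)
    assert len(events) == 1
    assert events[0].sample_id == "A"
    assert events[0].event_class == "intron_retention"
    assert events[0].usage_ratio == pytest.approx(0.6, abs=1e-9)
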