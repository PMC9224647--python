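"""The synthetic-cohort generator: determinism, count model, event injection."""

import filecmp
from pathlib import Path

import numpy as np
import pytest

from panelsplice.errors import PipelineError
from panelsplice.junctions import (
    build_cohort_matrix,
    canonical_usage_ratio,
    filter_candidate_junctions,
    read_junction_table,
)
from panelsplice.psi import compute_psi
from panelsplice.simulate import (
    EventSpec,
    SimConfig,
    demo_cohort,
    inject_event,
    simulate_cohort,
)


def small_config(seed, **kw):
    defaults = dict(n_samples=3, n_genes=4, seed=seed)
    defaults.update(kw)
    return SimConfig(**defaults)


def matrix_of(cohort):
    samples = {}
    for i, s in enumerate(cohort.sample_ids):
        recs = []
        for key in sorted(cohort.junction_counts):
            c = int(cohort.junction_counts[key][i])
            if c >= 5:
                from conftest import junction_record

                recs.append(
                    junction_record(
                        key[0], key[1], key[2], {"+": 1, "-": 2}[key[3]],
                        unique=c,
                        annotated=1 if cohort.junction_annotated[key] else 0,
                    )
                )
        samples[s] = recs
    return build_cohort_matrix(samples, cohort.index)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kw",
        [
            {"n_samples": 1},
            {"mean_junction_depth": 0},
            {"mapping_bias": 0.0},
            {"mapping_bias": 1.0},
            {"exons_per_gene": (1, 3)},
            {"depth_dispersion": -1},
        ],
    )
    def test_invalid_config_rejected_before_output(self, kw):
        with pytest.raises(PipelineError):
            simulate_cohort(small_config(0, **kw))

    def test_minimal_two_sample_cohort_valid(self):
        cohort = simulate_cohort(small_config(0, n_samples=2))
        assert len(cohort.sample_ids) == 2


class TestDeterminism:
    def test_same_seed_byte_identical_outputs(self, tmp_path):
        for d in ("a", "b"):
            demo_cohort(seed=11, n_samples=4).write(tmp_path / d)
        a_files = sorted(p for p in (tmp_path / "a").rglob("*") if p.is_file())
        for fa in a_files:
            fb = tmp_path / "b" / fa.relative_to(tmp_path / "a")
            assert fb.exists()
            assert fa.read_bytes() == fb.read_bytes(), fa.name

    def test_different_seeds_differ(self, tmp_path):
        simulate_cohort(small_config(1)).write(tmp_path / "a")
        simulate_cohort(small_config(2)).write(tmp_path / "b")
        assert (
            (tmp_path / "a" / "samples" / "S01.SJ.out.tab").read_bytes()
            != (tmp_path / "b" / "samples" / "S01.SJ.out.tab").read_bytes()
        )

    def test_write_is_pure_serialization(self, tmp_path):
        cohort = simulate_cohort(small_config(5))
        cohort.write(tmp_path / "x")
        cohort.write(tmp_path / "y")
        fa = tmp_path / "x" / "samples" / "S01.SJ.out.tab"
        fb = tmp_path / "y" / "samples" / "S01.SJ.out.tab"
        assert fa.read_bytes() == fb.read_bytes()


def test_event_free_cohorts_pass_filter_silently():
    """Without injected aberrations the novel-junction filter stays quiet."""
    clean = 0
    n_seeds = 30
    for seed in range(n_seeds):
        cohort = simulate_cohort(small_config(seed, n_samples=4))
        events = filter_candidate_junctions(matrix_of(cohort))
        clean += not events
    assert clean / n_seeds >= 0.95


def test_outputs_parse_with_pipeline_readers(tmp_path):
    cohort = simulate_cohort(small_config(3))
    cohort.write(tmp_path)
    recs = read_junction_table(tmp_path / "samples" / "S01.SJ.out.tab")
    assert recs and all(r.unique_reads >= 5 for r in recs)


class TestSkipInjection:
    def test_read_conservation_is_exact(self, rng):
        cohort = simulate_cohort(small_config(9, n_genes=4, exons_per_gene=(6, 6)))
        gene = cohort.genes[0]
        introns = gene.introns()
        up = (gene.chrom, *introns[1], gene.strand)
        dn = (gene.chrom, *introns[2], gene.strand)
        pre_mean = (cohort.junction_counts[up][0] + cohort.junction_counts[dn][0]) / 2
        spec = EventSpec("leaky_exon_skip", gene.symbol, 2, 0.15,
                         (cohort.sample_ids[0],))
        inject_event(cohort, spec, rng)
        skip = (gene.chrom, introns[1][0], introns[2][1], gene.strand)
        post_mean = (cohort.junction_counts[up][0] + cohort.junction_counts[dn][0]) / 2
        assert post_mean + cohort.junction_counts[skip][0] == pytest.approx(pre_mean)

    @pytest.mark.parametrize("f", [0.05, 0.15, 0.5])
    def test_skip_fraction_recovered_at_high_depth(self, f, rng):
        # PSI converges to 1-f; at depth 1e4 binomial error is ~0.004
        cohort = simulate_cohort(
            small_config(17, n_samples=2, n_genes=2, exons_per_gene=(6, 6),
                         mean_junction_depth=1e4)
        )
        gene = cohort.genes[0]
        spec = EventSpec("leaky_exon_skip", gene.symbol, 2, f, ("S01",))
        inject_event(cohort, spec, rng)
        m = matrix_of(cohort)
        bin = cohort.index.bins[gene.symbol][2]
        v = compute_psi(bin, m, cohort.index, "S01")
        assert v.psi == pytest.approx(1 - f, abs=0.02)


class TestRetentionInjection:
    @pytest.mark.parametrize("u", [0.6, 0.4])
    def test_canonical_usage_recovered(self, u):
        cohort = simulate_cohort(
            SimConfig(n_samples=13, seed=23),
            events=[EventSpec("intron_retention", "CTLA4", 1, u, ("S03",))],
        )
        gene = cohort.gene("CTLA4")
        key = (gene.chrom, *gene.introns()[1], gene.strand)
        ratio = canonical_usage_ratio(matrix_of(cohort), key, "S03")
        assert ratio == pytest.approx(u, abs=0.05)

    def test_intron_coverage_rows_emitted_for_all_samples(self):
        cohort = simulate_cohort(
            small_config(4),
            events=[EventSpec("intron_retention", "CTLA4", 0, 0.5, ("S02",))],
        )
        rows = [r for r in cohort.intron_coverage]
        assert {r["sample_id"] for r in rows} == set(cohort.sample_ids)
        affected = [r for r in rows if r["sample_id"] == "S02"]
        assert affected[0]["mean_depth"] >= 5.0


class TestTruncationInjection:
    def test_decayed_allele_detected_as_depleted(self, rng):
        from panelsplice.ase import AlleleCount, ase_binomial_test

        hits = 0
        reps = 40
        cohort = simulate_cohort(small_config(31))
        spec = EventSpec("nmd_truncation", "TRAF3",
                         len(cohort.gene("TRAF3").exons) // 2, 0.5, ("S01",))
        for _ in range(reps):
            inject_event(cohort, spec, rng)
            row = cohort.allele_rows[-1]
            counts = AlleleCount("S01", row["chrom"], row["pos"], row["ref"],
                                 row["alt"], row["ref_reads"], row["alt_reads"])
            p = ase_binomial_test(counts, "left", 0.45).p_value
            hits += p < 0.05
        assert hits / reps >= 0.95

    def test_escape_requires_last_coding_exon(self, rng):
        cohort = simulate_cohort(small_config(2))
        gene = cohort.gene("TRAF3")
        wrong = (gene.last_coding_exon_genomic_index() + 1) % len(gene.exons)
        with pytest.raises(PipelineError, match="last coding exon"):
            inject_event(
                cohort,
                EventSpec("nmd_escape_truncation", "TRAF3", wrong, 1.6, ("S01",)),
                rng,
            )


def test_demo_cohort_truth_covers_every_event_kind():
    cohort = demo_cohort(seed=3)
    kinds = {t["kind"] for t in cohort.truth}
    assert kinds == {
        "leaky_exon_skip", "intron_retention", "extended_splice_site",
        "nmd_truncation", "nmd_escape_truncation", "usage_shift",
    }
    assert all(t["detectable"] for t in cohort.truth)
    # the multi-event sample carries four finding-producing lesions
    from panelsplice.simulate import DEMO_MULTI_EVENT_SAMPLE

    s13 = [t for t in cohort.truth if t["sample"] == DEMO_MULTI_EVENT_SAMPLE]
    assert len(s13) == 3  # PIK3CD truncation + two retentions (the in-frame
    # deletion is a plain variant, not a splice event)
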